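"""Per-site stranded allele-count containers and the pipeline's file formats.

The pipeline's atomic observation is a :class:`SitePileup`: for one genomic
site in one sample, the number of reads supporting each allele, split by
strand.  A :class:`MultiSamplePileup` aligns several samples on a shared site
list (all samples cover every site, possibly at depth 0), which is what the
paired caller consumes.

Formats of record:

* a tab-separated counts table (see :func:`read_counts_tsv`), the canonical
  input;
* BED (0-based half-open) for restricting to target regions;
* VCF v4.2 for emitting calls (see :func:`write_vcf`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class PileupFormatError(ValueError):
    """Raised for malformed counts tables (carries the offending line number)."""


@dataclass(frozen=True, order=True)
class SiteKey:
    """Genomic site identity: chromosome, 1-based position, reference allele."""

    chrom: str
    pos: int
    ref: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")


@dataclass
class ReadEvidence:
    """Per-supporting-read attributes used by quality masking and read filters.

    ``dist_to_indel`` is ``math.inf`` when no indel lies on the read.
    ``strand`` is '+' or '-' so that strand support can be re-derived after
    reads are discarded.
    """

    mismatches: int
    dist_to_read_end: int
    dist_to_indel: float
    base_quality: float
    mapping_quality: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if min(self.mismatches, self.dist_to_read_end, self.base_quality,
               self.mapping_quality) < 0 or self.dist_to_indel < 0:
            raise ValueError("read evidence fields must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class SitePileup:
    """Stranded allele counts for one (sample, site).

    ``counts`` maps allele symbol -> (forward, reverse).  Indel alleles are
    opaque tokens (VCF-style anchored strings such as ``"TA"`` or ``"+A"``)
    living alongside the four bases.  Depth equals the sum of all counts.
    """

    key: SiteKey
    sample: str
    counts: dict[str, tuple[int, int]]
    evidence: dict[str, list[ReadEvidence]] | None = None

    @property
    def depth(self) -> int:
        return int(sum(f + r for f, r in self.counts.values()))

    def allele_count(self, allele: str) -> int:
        f, r = self.counts.get(allele, (0, 0))
        return f + r

    def allele_strands(self, allele: str) -> tuple[int, int]:
        return tuple(self.counts.get(allele, (0, 0)))

    def vaf(self, allele: str) -> float:
        d = self.depth
        return self.allele_count(allele) / d if d else 0.0

    def validate(self) -> None:
        for a, (f, r) in self.counts.items():
            if f < 0 or r < 0:
                raise ValueError(f"negative count for allele {a} at {self.key}")


class MultiSamplePileup:
    """Several samples' pileups aligned on one ordered site list.

    Stores base-allele counts as a dense ``(n_sites, 4, 2)`` integer array per
    sample (A,C,G,T x fwd,rev) with sparse side tables for indel alleles and
    read evidence; :meth:`pileup` materialises a :class:`SitePileup` view.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        counts: Mapping[str, np.ndarray],
        indels: Mapping[str, dict[int, dict[str, tuple[int, int]]]] | None = None,
        evidence: Mapping[str, dict[tuple[int, str], list[ReadEvidence]]] | None = None,
    ) -> None:
        req = {"chrom", "pos", "ref"}
        if not req.issubset(sites.columns):
            raise ValueError(f"sites frame needs columns {sorted(req)}")
        self.sites = sites.reset_index(drop=True)
        self.samples = list(counts)
        self._counts = {s: np.asarray(c, dtype=np.int64) for s, c in counts.items()}
        n = len(self.sites)
        for s, c in self._counts.items():
            if c.shape != (n, 4, 2):
                raise ValueError(f"counts for {s}: expected shape {(n, 4, 2)}, got {c.shape}")
        self._indels = {s: dict(indels.get(s, {})) if indels else {} for s in self.samples}
        self._evidence = {s: dict(evidence.get(s, {})) if evidence else {} for s in self.samples}

    # -- accessors ---------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_key(self, i: int) -> SiteKey:
        row = self.sites.iloc[i]
        return SiteKey(str(row["chrom"]), int(row["pos"]), str(row["ref"]))

    def depth(self, sample: str, i: int) -> int:
        d = int(self._counts[sample][i].sum())
        for f, r in self._indels[sample].get(i, {}).values():
            d += f + r
        return d

    def depths(self, sample: str) -> np.ndarray:
        """Vector of total depths (base alleles only are dense; indels added)."""
        d = self._counts[sample].sum(axis=(1, 2))
        for i, toks in self._indels[sample].items():
            d[i] += sum(f + r for f, r in toks.values())
        return d

    def base_counts(self, sample: str) -> np.ndarray:
        """The dense (n_sites, 4, 2) base-allele count array (a view)."""
        return self._counts[sample]

    def indel_counts(self, sample: str, i: int) -> dict[str, tuple[int, int]]:
        return dict(self._indels[sample].get(i, {}))

    def evidence_for(self, sample: str, i: int, allele: str) -> list[ReadEvidence] | None:
        return self._evidence[sample].get((i, allele))

    def pileup(self, sample: str, i: int) -> SitePileup:
        key = self.site_key(i)
        c = self._counts[sample][i]
        counts = {b: (int(c[j, 0]), int(c[j, 1])) for j, b in enumerate(BASES)}
        counts.update(self._indels[sample].get(i, {}))
        ev = {a: list(v) for (j, a), v in self._evidence[sample].items() if j == i}
        return SitePileup(key, sample, counts, ev or None)

    # -- mutation-free helpers --------------------------------------------
    def with_counts(self, counts, indels=None, evidence=None) -> "MultiSamplePileup":
        return MultiSamplePileup(self.sites, counts,
                                 indels if indels is not None else self._indels,
                                 evidence if evidence is not None else self._evidence)

    def subset_sites(self, idx: np.ndarray) -> "MultiSamplePileup":
        idx = np.asarray(idx)
        remap = {int(old): new for new, old in enumerate(idx)}
        counts = {s: c[idx] for s, c in self._counts.items()}
        indels = {s: {remap[i]: t for i, t in d.items() if i in remap}
                  for s, d in self._indels.items()}
        evid = {s: {(remap[i], a): v for (i, a), v in d.items() if i in remap}
                for s, d in self._evidence.items()}
        return MultiSamplePileup(self.sites.iloc[idx], counts, indels, evid)


# ---------------------------------------------------------------------------
# counts TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "sample", "chrom", "pos", "ref", "depth",
    "A_fwd", "A_rev", "C_fwd", "C_rev", "G_fwd", "G_rev", "T_fwd", "T_rev",
    "indels", "evidence",
]


def _evidence_to_json(ev: list[ReadEvidence]) -> list[list]:
    return [[e.mismatches, e.dist_to_read_end,
             None if math.isinf(e.dist_to_indel) else e.dist_to_indel,
             e.base_quality, e.mapping_quality, e.strand] for e in ev]


def _evidence_from_json(rows: list[list]) -> list[ReadEvidence]:
    return [ReadEvidence(int(m), int(de), math.inf if di is None else float(di),
                         float(bq), float(mq), str(st))
            for m, de, di, bq, mq, st in rows]


def write_counts_tsv(pileup: MultiSamplePileup, path) -> None:
    """Write the canonical tab-separated counts table.

    Columns (header line '#'-prefixed): sample, chrom, pos, ref, depth, then
    forward/reverse counts for A,C,G,T, then a JSON indel-count blob and a
    JSON evidence blob ('.' when empty).
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
        for sample in pileup.samples:
            c = pileup.base_counts(sample)
            depths = pileup.depths(sample)
            chroms = pileup.sites["chrom"].to_numpy()
            poss = pileup.sites["pos"].to_numpy()
            refs = pileup.sites["ref"].to_numpy()
            for i in range(pileup.n_sites):
                indels = pileup.indel_counts(sample, i)
                ind_s = json.dumps({a: list(fr) for a, fr in indels.items()}) if indels else "."
                ev = {a: _evidence_to_json(v)
                      for (j, a), v in pileup._evidence[sample].items() if j == i}
                ev_s = json.dumps(ev) if ev else "."
                row = [sample, chroms[i], str(poss[i]), refs[i], str(int(depths[i]))]
                row += [str(int(x)) for x in c[i].ravel()]
                row += [ind_s, ev_s]
                fh.write("\t".join(row) + "\n")


def read_counts_tsv(path) -> MultiSamplePileup:
    """Parse the counts TSV; malformed rows are rejected with their line number."""
    records: dict[str, list] = {}
    site_order: list[tuple[str, int, str]] = []
    seen_sites: dict[tuple[str, int, str], int] = {}
    seen_rows: set[tuple[str, str, int]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise PileupFormatError("empty file (missing header)")
        cols = header.lstrip("#").rstrip("\n").split("\t")
        if cols[: len(_TSV_COLUMNS)] != _TSV_COLUMNS:
            missing = [c for c in _TSV_COLUMNS if c not in cols]
            raise PileupFormatError(f"header missing columns: {missing}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_TSV_COLUMNS):
                raise PileupFormatError(
                    f"line {lineno}: expected {len(_TSV_COLUMNS)} fields, got {len(parts)}")
            sample, chrom, pos_s, ref, depth_s = parts[:5]
            try:
                pos = int(pos_s)
                depth = int(depth_s)
                counts = [int(x) for x in parts[5:13]]
            except ValueError as exc:
                raise PileupFormatError(f"line {lineno}: non-integer count field ({exc})")
            if depth < 0 or any(x < 0 for x in counts):
                raise PileupFormatError(f"line {lineno}: negative count")
            indels = {} if parts[13] == "." else {
                a: (int(f), int(r)) for a, (f, r) in json.loads(parts[13]).items()}
            evid = {} if parts[14] == "." else {
                a: _evidence_from_json(v) for a, v in json.loads(parts[14]).items()}
            total = sum(counts) + sum(f + r for f, r in indels.values())
            if total != depth:
                raise PileupFormatError(
                    f"line {lineno}: depth {depth} != sum of counts {total}")
            rowkey = (sample, chrom, pos)
            if rowkey in seen_rows:
                raise PileupFormatError(f"line {lineno}: duplicate (sample, site) row")
            seen_rows.add(rowkey)
            sk = (chrom, pos, ref)
            if sk not in seen_sites:
                seen_sites[sk] = len(site_order)
                site_order.append(sk)
            records.setdefault(sample, []).append((seen_sites[sk], counts, indels, evid))
    n = len(site_order)
    sites = pd.DataFrame(site_order, columns=["chrom", "pos", "ref"])
    counts_arr: dict[str, np.ndarray] = {}
    indel_map: dict[str, dict] = {}
    evid_map: dict[str, dict] = {}
    for sample, rows in records.items():
        arr = np.zeros((n, 4, 2), dtype=np.int64)
        ind: dict[int, dict[str, tuple[int, int]]] = {}
        evd: dict[tuple[int, str], list[ReadEvidence]] = {}
        for i, counts, indels, evid in rows:
            arr[i] = np.asarray(counts).reshape(4, 2)
            if indels:
                ind[i] = indels
            for a, v in evid.items():
                evd[(i, a)] = v
        counts_arr[sample] = arr
        indel_map[sample] = ind
        evid_map[sample] = evd
    return MultiSamplePileup(sites, counts_arr, indel_map, evid_map)


# ---------------------------------------------------------------------------
# samtools-mpileup convenience converter
# ---------------------------------------------------------------------------

def from_mpileup(path, sample_names: list[str]) -> MultiSamplePileup:
    """Convert samtools-mpileup text output to a MultiSamplePileup.

    Handles the common base-column grammar: ``.``/``,`` (ref fwd/rev), case
    for strand on substitutions, ``^X`` read starts, ``$`` read ends,
    ``+N``/``-N`` indel insertions (recorded as ``+SEQ``/``-SEQ`` allele
    tokens on the strand of the preceding base), and ``*`` placeholders
    (ignored).  The counts TSV remains the dialect of record.
    """
    site_rows = []
    per_sample_counts: dict[str, list[np.ndarray]] = {s: [] for s in sample_names}
    per_sample_indels: dict[str, dict[int, dict[str, tuple[int, int]]]] = {s: {} for s in sample_names}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            chrom, pos, ref = parts[0], int(parts[1]), parts[2].upper()
            site_rows.append((chrom, pos, ref))
            for si, sample in enumerate(sample_names):
                depth_col = 3 + 3 * si
                bases = parts[depth_col + 1] if len(parts) > depth_col + 1 else ""
                arr = np.zeros((4, 2), dtype=np.int64)
                indels: dict[str, tuple[int, int]] = {}
                j = 0
                last_strand = 0
                while j < len(bases):
                    ch = bases[j]
                    if ch == "^":
                        j += 2
                        continue
                    if ch == "$":
                        j += 1
                        continue
                    if ch in "+-":
                        k = j + 1
                        while k < len(bases) and bases[k].isdigit():
                            k += 1
                        ln = int(bases[j + 1:k])
                        seq = bases[k:k + ln]
                        tok = ch + seq.upper()
                        f, r = indels.get(tok, (0, 0))
                        indels[tok] = (f + (1 - last_strand), r + last_strand)
                        j = k + ln
                        continue
                    if ch in ".,":
                        strand = 0 if ch == "." else 1
                        if ref in _BASE_INDEX:
                            arr[_BASE_INDEX[ref], strand] += 1
                        last_strand = strand
                    elif ch.upper() in _BASE_INDEX:
                        strand = 0 if ch.isupper() else 1
                        arr[_BASE_INDEX[ch.upper()], strand] += 1
                        last_strand = strand
                    # '*', 'N', '<', '>' contribute nothing
                    j += 1
                per_sample_counts[sample].append(arr)
                if indels:
                    per_sample_indels[sample][i] = indels
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref"])
    counts = {s: np.stack(v) if v else np.zeros((0, 4, 2), dtype=np.int64)
              for s, v in per_sample_counts.items()}
    return MultiSamplePileup(sites, counts, per_sample_indels)


# ---------------------------------------------------------------------------
# quality masking
# ---------------------------------------------------------------------------

def apply_quality_mask(pileup: MultiSamplePileup, min_base_q: float,
                       min_map_q: float) -> MultiSamplePileup:
    """Drop supporting reads below base/mapping quality thresholds.

    Only alleles carrying read evidence are masked; counts without evidence
    pass through unchanged and are listed on the result's ``no_evidence``
    attribute.  Masking is idempotent and never increases a count.
    """
    new_counts = {s: c.copy() for s, c in
                  ((s, pileup.base_counts(s)) for s in pileup.samples)}
    new_indels = {s: {i: dict(d) for i, d in pileup._indels[s].items()}
                  for s in pileup.samples}
    new_evid: dict[str, dict] = {s: {} for s in pileup.samples}
    flagged: list[tuple[str, int, str]] = []
    for s in pileup.samples:
        for (i, allele), reads in pileup._evidence[s].items():
            ok = lambda e: e.base_quality >= min_base_q and e.mapping_quality >= min_map_q
            keep = [e for e in reads if ok(e)]
            removed = [e for e in reads if not ok(e)]
            drop_f = sum(1 for e in removed if e.strand == "+")
            drop_r = len(removed) - drop_f
            if allele in _BASE_INDEX:
                bi = _BASE_INDEX[allele]
                new_counts[s][i, bi, 0] = max(0, new_counts[s][i, bi, 0] - drop_f)
                new_counts[s][i, bi, 1] = max(0, new_counts[s][i, bi, 1] - drop_r)
            elif allele in new_indels[s].get(i, {}):
                f, r = new_indels[s][i][allele]
                new_indels[s][i][allele] = (max(0, f - drop_f), max(0, r - drop_r))
            new_evid[s][(i, allele)] = keep
    masked = MultiSamplePileup(pileup.sites, new_counts, new_indels, new_evid)
    # flag alleles with counts but no evidence (unmaskable)
    for s in pileup.samples:
        withe = {(i, a) for (i, a) in pileup._evidence[s]}
        c = pileup.base_counts(s)
        nz = np.argwhere(c.sum(axis=2) > 0)
        for i, bi in nz:
            if (int(i), BASES[bi]) not in withe:
                flagged.append((s, int(i), BASES[bi]))
    masked.no_evidence = flagged  # type: ignore[attr-defined]
    return masked


# ---------------------------------------------------------------------------
# BED restriction
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open intervals)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            rows.append((p[0], int(p[1]), int(p[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def restrict_to_bed(pileup: MultiSamplePileup, bed: pd.DataFrame) -> MultiSamplePileup:
    """Keep only sites falling inside the BED intervals.

    BED is 0-based half-open; pileup positions are 1-based, so position p is
    inside [start, end) iff start < p <= end.
    """
    keep = np.zeros(pileup.n_sites, dtype=bool)
    pos = pileup.sites["pos"].to_numpy()
    chrom = pileup.sites["chrom"].to_numpy()
    for c, grp in bed.groupby("chrom"):
        mask_c = chrom == c
        if not mask_c.any():
            continue
        p = pos[mask_c]
        inside = np.zeros(p.size, dtype=bool)
        for _, row in grp.iterrows():
            inside |= (p > row["start"]) & (p <= row["end"])
        keep[np.flatnonzero(mask_c)] |= inside
    return pileup.subset_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_INFO_HEADER = [
    '##INFO=<ID=SS,Number=1,Type=String,Description="Somatic status (GERMLINE/SOMATIC/LOH/UNKNOWN)">',
    '##INFO=<ID=SPV,Number=1,Type=Float,Description="Somatic p-value (one-sided Fisher exact)">',
    '##INFO=<ID=VAFC,Number=1,Type=Float,Description="Variant allele fraction in case">',
    '##INFO=<ID=VAFN,Number=1,Type=Float,Description="Variant allele fraction in control (max across controls)">',
    '##INFO=<ID=DPC,Number=1,Type=Integer,Description="Depth in case">',
    '##INFO=<ID=DPN,Number=.,Type=Integer,Description="Depth in control(s)">',
    '##INFO=<ID=ADF,Number=1,Type=Integer,Description="Alt-supporting reads, forward strand (case)">',
    '##INFO=<ID=ADR,Number=1,Type=Integer,Description="Alt-supporting reads, reverse strand (case)">',
]


def write_vcf(calls: Iterable, path, extra_header: Iterable[str] = ()) -> None:
    """Write variant calls as VCF v4.2.

    FILTER is PASS when the call failed no filters, otherwise the
    semicolon-joined failed-filter names.  Calls are sorted by coordinate;
    duplicate records with conflicting content are rejected.
    """
    calls = sorted(calls, key=lambda c: (c.key.chrom, c.key.pos, c.alt, c.sample_case))
    seen: dict[tuple, tuple] = {}
    for c in calls:
        k = (c.key.chrom, c.key.pos, c.key.ref, c.alt, c.sample_case)
        payload = (c.status, round(c.p_somatic, 12), c.vaf_case)
        if k in seen and seen[k] != payload:
            raise ValueError(f"conflicting duplicate VCF records at {k}")
        seen[k] = payload
    filters = sorted({f for c in calls for f in c.filters_failed})
    chroms = []
    for c in calls:
        if c.key.chrom not in chroms:
            chroms.append(c.key.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=deepsoma\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        for ch in chroms:
            fh.write(f"##contig=<ID={ch}>\n")
        for line in _VCF_INFO_HEADER:
            fh.write(line + "\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        for f in filters:
            fh.write(f'##FILTER=<ID={f},Description="Failed {f}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        emitted = set()
        for c in calls:
            k = (c.key.chrom, c.key.pos, c.key.ref, c.alt, c.sample_case)
            if k in emitted:
                continue
            emitted.add(k)
            ref, alt = _vcf_alleles(c.key.ref, c.alt)
            filt = "PASS" if not c.filters_failed else ";".join(c.filters_failed)
            dpn = ",".join(str(d) for d in c.depth_controls) if c.depth_controls else "."
            info = (f"SS={c.status};SPV={c.p_somatic:.6g};VAFC={c.vaf_case:.6g};"
                    f"VAFN={c.vaf_control:.6g};DPC={c.depth_case};DPN={dpn};"
                    f"ADF={c.alt_fwd_case};ADR={c.alt_rev_case}")
            fh.write(f"{c.key.chrom}\t{c.key.pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\n")


def _vcf_alleles(ref: str, alt: str) -> tuple[str, str]:
    """Map internal allele tokens to VCF REF/ALT strings.

    Substitutions pass through.  '+SEQ' insertions become REF, REF+SEQ;
    '-SEQ' deletions become REF+SEQ, REF (anchored on the site's ref base).
    """
    if alt.startswith("+"):
        return ref, ref + alt[1:]
    if alt.startswith("-"):
        return ref + alt[1:], ref
    return ref, alt
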