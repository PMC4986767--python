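"""Synthetic deep-sequencing pileups and ddPCR droplet sets with known truth.

The generator emulates targeted-capture deep sequencing of the kind used to
screen for somatic mosaicism: ~1000x mean depth per site, germline SNPs at
50%/100% allele fraction shared by all tissues of one individual, planted
somatic clones at low (1-10%) fraction restricted to particular samples,
uniform per-base substitution error, and cross-mapping artifact alleles that
recur at low fraction across most samples (the signature of paralogous-gene
misalignment).  Every non-reference read traces to one of those channels, so
each downstream stage can be scored against exact truth.

Depths are negative-binomial (Poisson when the dispersion is zero) because
capture depth is overdispersed in practice.  Reads are counts, not
sequences: read-level evidence (mismatches, distance to read end / indel) is
drawn per supporting read, which is all the downstream filters consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pileups import BASES, _BASE_INDEX, MultiSamplePileup, ReadEvidence

__all__ = [
    "SimConfig", "PlantedVariant", "ArtifactSite", "Truth", "FluorModel",
    "simulate_pileups", "simulate_aliquot_pair", "simulate_droplets",
]


@dataclass
class PlantedVariant:
    """A somatic clone: an alternate allele at ``site`` present at ``vaf`` in
    the listed samples only."""

    site: int
    alt: str
    vaf: float
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0 < self.vaf <= 0.5):
            raise ValueError(f"planted VAF must be in (0, 0.5], got {self.vaf}")


@dataclass
class ArtifactSite:
    """A recurrent cross-mapping artifact: a low-fraction allele appearing in
    a given fraction of all samples."""

    site: int
    alt: str
    vaf: float
    sample_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.vaf <= 0.25):
            raise ValueError(f"artifact VAF must be in (0, 0.25], got {self.vaf}")
        if not (0 <= self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in [0, 1]")


@dataclass
class SimConfig:
    """Conditions for one simulated sequencing experiment.

    Defaults mirror the targeted-capture study design the pipeline is built
    for: ~1000x mean depth, 1e-3 per-base substitution error, balanced
    strands, and germline SNP rates giving a realistic het/hom mix over a
    sub-megabase target.
    """

    n_sites: int
    samples: tuple[str, ...] = ("S1",)
    mean_depth: float = 1000.0
    depth_dispersion: float = 0.0
    error_rate: float = 0.001
    germline_het_rate: float = 0.001
    germline_hom_rate: float = 0.0005
    somatic_plants: list[PlantedVariant] = field(default_factory=list)
    artifact_sites: list[ArtifactSite] = field(default_factory=list)
    strand_bias: float = 0.5
    error_strand_bias: float | None = None  # strand-asymmetric error mode
    attach_evidence: bool = False
    chrom: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be non-negative")
        if not (0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")
        for p in (self.germline_het_rate, self.germline_hom_rate,
                  self.strand_bias):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.germline_het_rate + self.germline_hom_rate > 1:
            raise ValueError("germline het + hom rate must not exceed 1")
        seen: dict[tuple[int, str], float] = {}
        for pv in self.somatic_plants:
            if not (0 <= pv.site < self.n_sites):
                raise ValueError(f"planted site {pv.site} out of range")
            k = (pv.site, pv.alt)
            if k in seen and seen[k] != pv.vaf:
                raise ValueError(
                    f"conflicting plants at site {pv.site} allele {pv.alt}")
            seen[k] = pv.vaf
            unknown = set(pv.samples) - set(self.samples)
            if unknown:
                raise ValueError(f"plant targets unknown samples {sorted(unknown)}")
        for a in self.artifact_sites:
            if not (0 <= a.site < self.n_sites):
                raise ValueError(f"artifact site {a.site} out of range")


class Truth(pd.DataFrame):
    """Ground-truth table: sample, chrom, pos, ref, allele, class, true_vaf.

    Class is one of germline_het, germline_hom, somatic, artifact; at most
    one class per (sample, site, allele).
    """

    _metadata: list[str] = []

    @property
    def _constructor(self):
        return Truth


_TRUTH_COLS = ["sample", "chrom", "pos", "ref", "allele", "klass", "true_vaf"]


def write_truth_tsv(truth: Truth, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> Truth:
    return Truth(pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str}))


def _pick_other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[rng.integers(0, 3)]


def simulate_pileups(config: SimConfig) -> tuple[MultiSamplePileup, Truth]:
    """Draw stranded allele-count tables plus exact truth for every sample.

    Per sample and site: depth ~ NB(mean, dispersion); template alleles
    multinomial around the truth fractions (het 0.5, hom 1.0, plants and
    artifacts at their stated VAF); each read independently substituted with
    probability ``error_rate``, errors uniform over the three non-reference
    bases; each allele's reads split fwd/rev with ``strand_bias``.
    Reproducible bit-for-bit given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, e = config.n_sites, config.error_rate

    refs = rng.choice(np.array(BASES), size=n)
    sites = pd.DataFrame({
        "chrom": config.chrom,
        "pos": np.arange(1, n + 1, dtype=np.int64) * 10,  # spaced positions
        "ref": refs,
    })

    # one underlying genome: germline truth shared by all samples.
    # engineered plant/artifact sites are reserved — a germline allele on
    # top of them would make the site's truth fractions ambiguous
    u = rng.random(n)
    reserved = np.zeros(n, dtype=bool)
    for pv in config.somatic_plants:
        reserved[pv.site] = True
    for art in config.artifact_sites:
        reserved[art.site] = True
    is_het = (u < config.germline_het_rate) & ~reserved
    is_hom = (~is_het) & (u < config.germline_het_rate + config.germline_hom_rate) & ~reserved
    germline: dict[int, tuple[str, float, str]] = {}
    for i in np.flatnonzero(is_het):
        germline[int(i)] = (_pick_other_base(rng, refs[i]), 0.5, "germline_het")
    for i in np.flatnonzero(is_hom):
        germline[int(i)] = (_pick_other_base(rng, refs[i]), 1.0, "germline_hom")

    # artifacts: deterministic count of affected samples, random choice of which
    artifact_assign: list[tuple[ArtifactSite, list[str]]] = []
    for art in config.artifact_sites:
        k = int(round(art.sample_fraction * len(config.samples)))
        chosen = list(rng.choice(np.array(config.samples), size=k, replace=False)) if k else []
        artifact_assign.append((art, chosen))

    # special sites get a per-site multinomial; plain sites go vectorised
    special: dict[int, dict[str, list]] = {}  # site -> sample -> [(allele, vaf, class)]

    def add_special(i: int, sample: str, allele: str, vaf: float, klass: str) -> None:
        special.setdefault(i, {}).setdefault(sample, []).append((allele, vaf, klass))

    for pv in config.somatic_plants:
        if pv.alt == refs[pv.site]:
            raise ValueError(
                f"planted alt {pv.alt!r} equals ref at site {pv.site}")
    for art in config.artifact_sites:
        if art.alt == refs[art.site]:
            raise ValueError(
                f"artifact alt {art.alt!r} equals ref at site {art.site}")

    for i, (alt, vaf, klass) in germline.items():
        for s in config.samples:
            add_special(i, s, alt, vaf, klass)
    for pv in config.somatic_plants:
        for s in pv.samples:
            add_special(pv.site, s, pv.alt, pv.vaf, "somatic")
    for art, chosen in artifact_assign:
        for s in chosen:
            add_special(art.site, s, art.alt, art.vaf, "artifact")

    special_idx = np.array(sorted(special), dtype=np.int64)
    plain_mask = np.ones(n, dtype=bool)
    plain_mask[special_idx] = False
    ref_idx = np.array([_BASE_INDEX[r] for r in refs])

    counts: dict[str, np.ndarray] = {}
    indels: dict[str, dict[int, dict[str, tuple[int, int]]]] = {}
    evidence: dict[str, dict[tuple[int, str], list[ReadEvidence]]] = {}
    truth_rows: list[tuple] = []

    for sample in config.samples:
        depths = _draw_depths(rng, n, config.mean_depth, config.depth_dispersion)
        arr = np.zeros((n, 4, 2), dtype=np.int64)
        ind: dict[int, dict[str, tuple[int, int]]] = {}
        evd: dict[tuple[int, str], list[ReadEvidence]] = {}

        # plain sites: pure ref templates + uniform substitution error
        pidx = np.flatnonzero(plain_mask)
        d_plain = depths[pidx]
        if e > 0:
            n_err = rng.binomial(d_plain, e)
            err3 = rng.multinomial(n_err, [1 / 3] * 3)
        else:
            n_err = np.zeros(d_plain.size, dtype=np.int64)
            err3 = np.zeros((d_plain.size, 3), dtype=np.int64)
        n_ref = d_plain - n_err
        # scatter: non-ref base order is the 3 bases != ref, ascending
        other = np.argsort(np.where(np.arange(4)[None, :] == ref_idx[pidx][:, None],
                                    4, np.arange(4)[None, :]), axis=1)[:, :3]
        ref_bias = config.strand_bias
        err_bias = config.strand_bias if config.error_strand_bias is None \
            else config.error_strand_bias
        fwd_ref = rng.binomial(n_ref, ref_bias)
        fwd_err = rng.binomial(err3, err_bias)
        arr[pidx, ref_idx[pidx], 0] = fwd_ref
        arr[pidx, ref_idx[pidx], 1] = n_ref - fwd_ref
        rows = np.repeat(np.arange(pidx.size), 3)
        arr[pidx[rows], other.ravel(), 0] += fwd_err.ravel()
        arr[pidx[rows], other.ravel(), 1] += (err3 - fwd_err).ravel()

        # special sites: explicit truth fractions then error mixing
        for i in special_idx:
            i = int(i)
            entries = special[i].get(sample, [])
            depth = int(depths[i])
            alleles = [refs[i]] + [a for a, _, _ in entries]
            fracs = np.array([0.0] + [v for _, v, _ in entries])
            if fracs.sum() > 1 + 1e-9:
                raise ValueError(f"truth fractions exceed 1 at site {i}")
            fracs[0] = max(0.0, 1.0 - fracs[1:].sum())
            tokens = list(BASES)
            indel_tok = next((a for a in alleles if a not in _BASE_INDEX), None)
            if indel_tok is not None:
                tokens.append(indel_tok)
            p = np.zeros(len(tokens))
            for a, fr in zip(alleles, fracs):
                p[tokens.index(a)] += fr
            if e > 0:
                # errors substitute base reads uniformly to the other 3 bases;
                # indel-supporting reads are left untouched
                p_base = p[:4].copy()
                total_base = p_base.sum()
                mix = p_base * (1 - e) + (total_base - p_base) * (e / 3)
                p = np.concatenate([mix, p[4:]])
            draw = rng.multinomial(depth, p) if depth > 0 else np.zeros(len(p), dtype=int)
            fwd = rng.binomial(draw, config.strand_bias)
            arr[i, :, 0] = fwd[:4]
            arr[i, :, 1] = draw[:4] - fwd[:4]
            if indel_tok is not None and draw[4] > 0:
                ind[i] = {indel_tok: (int(fwd[4]), int(draw[4] - fwd[4]))}
            if config.attach_evidence:
                for a, _, _ in entries:
                    ti = tokens.index(a) if a in tokens else 4
                    f_n, r_n = (int(fwd[ti]), int(draw[ti] - fwd[ti]))
                    if f_n + r_n:
                        evd[(i, a)] = _draw_clean_evidence(rng, f_n, r_n)
            for a, v, klass in entries:
                truth_rows.append((sample, config.chrom, int(sites["pos"][i]),
                                   refs[i], a, klass, v))
        counts[sample] = arr
        indels[sample] = ind
        evidence[sample] = evd

    pileup = MultiSamplePileup(sites, counts, indels, evidence)
    truth = Truth(pd.DataFrame(truth_rows, columns=_TRUTH_COLS))
    return pileup, truth


def _draw_depths(rng: np.random.Generator, n: int, mean: float,
                 dispersion: float) -> np.ndarray:
    """Depth ~ Poisson(mean) when dispersion 0, else NB with
    Var = mean + dispersion * mean^2."""
    if dispersion == 0:
        return rng.poisson(mean, size=n)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=n)


def _draw_clean_evidence(rng: np.random.Generator, n_fwd: int, n_rev: int
                         ) -> list[ReadEvidence]:
    """Well-behaved supporting reads: few mismatches, mid-read position,
    no nearby indel, qualities above the standard masks."""
    out = []
    for strand, m in (("+", n_fwd), ("-", n_rev)):
        for _ in range(m):
            out.append(ReadEvidence(
                mismatches=int(rng.choice([0, 1, 2], p=[0.8, 0.15, 0.05])),
                dist_to_read_end=int(rng.integers(6, 46)),
                dist_to_indel=math.inf,
                base_quality=float(rng.integers(25, 41)),
                mapping_quality=60.0,
                strand=strand,
            ))
    return out


def simulate_aliquot_pair(config: SimConfig) -> tuple[MultiSamplePileup, Truth]:
    """Two aliquots of one DNA pool sequenced independently.

    Both samples share the same underlying genome (identical germline and
    artifact truth) and differ only by sampling noise; the truth table
    records zero true somatic differences.  Plants restricted to one aliquot
    are rejected.
    """
    cfg = config
    if len(cfg.samples) != 2:
        cfg = replace(cfg, samples=("aliquot_a", "aliquot_b"))
    for pv in cfg.somatic_plants:
        if set(pv.samples) != set(cfg.samples):
            raise ValueError(
                "aliquot pair cannot carry somatic plants differing between aliquots")
    return simulate_pileups(cfg)


# ---------------------------------------------------------------------------
# ddPCR droplets
# ---------------------------------------------------------------------------

@dataclass
class FluorModel:
    """Two-cluster fluorescence model: empty droplets at baseline, occupied
    droplets high in the matching channel.  Defaults straddle the standard
    FAM>4000 / HEX<3000 gates."""

    baseline_mean: float = 500.0
    baseline_sd: float = 200.0
    positive_mean: float = 8000.0
    positive_sd: float = 500.0


def simulate_droplets(cn_wt: float, cn_var: float, n_droplets: int,
                      v_droplet: float = 0.00085,
                      fluor_model: FluorModel | None = None,
                      seed: int = 0):
    """Simulate a duplex ddPCR reaction.

    Wild-type and variant template occupancies are independent Poisson with
    means ``cn * v_droplet`` (copies/uL times droplet volume in uL).  A
    droplet holding at least one template of a channel emits the positive
    signal in that channel (HEX for wild type, FAM for variant); otherwise
    baseline noise.  Returns a :class:`deepsoma.ddpcr.DropletSet`.
    """
    from .ddpcr import DropletSet  # local import to avoid a cycle

    if cn_wt < 0 or cn_var < 0:
        raise ValueError("copy numbers must be non-negative")
    if n_droplets <= 0 or v_droplet <= 0:
        raise ValueError("n_droplets and v_droplet must be positive")
    fm = fluor_model or FluorModel()
    rng = np.random.default_rng(seed)
    occ_wt = rng.poisson(cn_wt * v_droplet, size=n_droplets)
    occ_var = rng.poisson(cn_var * v_droplet, size=n_droplets)
    base_h = rng.normal(fm.baseline_mean, fm.baseline_sd, size=n_droplets)
    base_f = rng.normal(fm.baseline_mean, fm.baseline_sd, size=n_droplets)
    pos_h = rng.normal(fm.positive_mean, fm.positive_sd, size=n_droplets)
    pos_f = rng.normal(fm.positive_mean, fm.positive_sd, size=n_droplets)
    hex_sig = np.clip(np.where(occ_wt > 0, pos_h, base_h), 0, None)
    fam_sig = np.clip(np.where(occ_var > 0, pos_f, base_f), 0, None)
    return DropletSet(fam=fam_sig, hex=hex_sig)
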