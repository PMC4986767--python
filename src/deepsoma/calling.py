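"""Paired and unpaired somatic variant calling on allele-count pileups.

The paired caller genotypes the case and each control at every candidate
allele, tests the case/control count contrast with a one-sided Fisher exact
test, and classifies the site as GERMLINE (variant present in case and
control), SOMATIC (case only, significant contrast), or LOH (control only,
significant contrast).  LOH calls are carried under the somatic umbrella
downstream, because a het site turning homozygous in a subset of cells is
itself a somatic event.

The unpaired caller has no control to test against; it screens each sample's
alleles against the expected background under a configurable per-base error
rate, again with a one-sided Fisher exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .pileups import BASES, _BASE_INDEX, MultiSamplePileup, SiteKey, SitePileup

__all__ = [
    "CallerParams", "Genotype", "VariantCall", "DegenerateTableWarning",
    "call_genotype", "fisher_somatic_p", "classify_paired",
    "call_unpaired", "call_sample_set",
]

GERMLINE = "GERMLINE"
SOMATIC = "SOMATIC"
LOH = "LOH"
UNKNOWN = "UNKNOWN"

REF = "REF"
HET = "HET"
HOM = "HOM"
LOW_COVERAGE = "LOW_COVERAGE"


class DegenerateTableWarning(UserWarning):
    """Emitted when a Fisher table is all zeros (p fixed at 1)."""


@dataclass
class CallerParams:
    """Calling thresholds.

    Defaults are the standard deep-somatic settings: 50x minimum coverage in
    each sample, at least 2 variant-supporting reads on at least 1 strand,
    minimum variant fraction 1%, homozygous above 75%, purities fixed at 1,
    minimum mean base quality 15 for supporting reads (when read evidence is
    present), calling p threshold 0.99 and somatic significance 0.05.
    ``error_rate`` parameterises the unpaired background test.
    """

    min_coverage_normal: int = 50
    min_coverage_case: int = 50
    min_reads2: int = 2
    min_strands2: int = 1
    min_var_freq: float = 0.01
    min_freq_for_hom: float = 0.75
    normal_purity: float = 1.0
    tumor_purity: float = 1.0
    min_avg_qual: float = 15.0
    p_value_thresh: float = 0.99
    somatic_p_value: float = 0.05
    error_rate: float = 0.01

    def validate(self) -> None:
        if not (0 < self.min_var_freq < self.min_freq_for_hom <= 1):
            raise ValueError("need 0 < min_var_freq < min_freq_for_hom <= 1")
        for p in (self.p_value_thresh, self.somatic_p_value):
            if not (0 < p <= 1):
                raise ValueError("p-value thresholds must be in (0, 1]")


@dataclass
class Genotype:
    call: str  # REF / HET / HOM / LOW_COVERAGE
    vaf: float

    @property
    def has_variant(self) -> bool:
        return self.call in (HET, HOM)


@dataclass
class VariantCall:
    """A candidate alternate allele at one site, with its audit trail."""

    key: SiteKey
    alt: str
    sample_case: str
    samples_control: tuple[str, ...]
    depth_case: int
    depth_controls: tuple[int, ...]
    alt_fwd_case: int
    alt_rev_case: int
    alt_controls: tuple[tuple[int, int], ...]
    vaf_case: float
    vaf_control: float
    p_somatic: float
    status: str
    filters_failed: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def alt_count_case(self) -> int:
        return self.alt_fwd_case + self.alt_rev_case


def call_genotype(p: SitePileup, alt: str, params: CallerParams,
                  role: str = "case") -> Genotype:
    """Genotype one sample at one alternate allele.

    LOW_COVERAGE below the per-role minimum depth; REF when support fails
    the read-count, strand-count, or minimum-fraction gates; HOM at or above
    ``min_freq_for_hom``; HET otherwise.
    """
    if alt == p.key.ref:
        raise ValueError("alt allele must differ from ref")
    depth = p.depth
    min_cov = params.min_coverage_case if role == "case" else params.min_coverage_normal
    if depth < min_cov:
        return Genotype(LOW_COVERAGE, p.vaf(alt))
    reads = p.allele_count(alt)
    vaf = reads / depth if depth else 0.0
    f, r = p.allele_strands(alt)
    strands = (f > 0) + (r > 0)
    if reads < params.min_reads2 or vaf < params.min_var_freq \
            or strands < params.min_strands2:
        return Genotype(REF, vaf)
    if vaf >= params.min_freq_for_hom:
        return Genotype(HOM, vaf)
    return Genotype(HET, vaf)


def fisher_somatic_p(case_ref: int, case_alt: int,
                     ctrl_ref: int, ctrl_alt: int) -> float:
    """One-sided Fisher exact p for the case alt-fraction exceeding the
    control's, on the 2x2 table [[ctrl_ref, ctrl_alt], [case_ref, case_alt]].

    Equals the upper hypergeometric tail P(X >= case_alt) with the table's
    margins fixed.  An all-zero table is degenerate and returns 1.
    """
    if min(case_ref, case_alt, ctrl_ref, ctrl_alt) < 0:
        raise ValueError("counts must be non-negative")
    N = case_ref + case_alt + ctrl_ref + ctrl_alt
    if N == 0:
        warnings.warn("all-zero contingency table", DegenerateTableWarning,
                      stacklevel=2)
        return 1.0
    K = case_alt + ctrl_alt
    n = case_ref + case_alt
    return float(min(1.0, hypergeom.sf(case_alt - 1, N, K, n)))


def fisher_somatic_p_many(case_ref, case_alt, ctrl_ref, ctrl_alt) -> np.ndarray:
    """Vectorised :func:`fisher_somatic_p` over aligned count arrays."""
    case_ref, case_alt, ctrl_ref, ctrl_alt = map(np.asarray,
                                                 (case_ref, case_alt, ctrl_ref, ctrl_alt))
    N = case_ref + case_alt + ctrl_ref + ctrl_alt
    K = case_alt + ctrl_alt
    n = case_ref + case_alt
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(case_alt - 1, N, K, n)
    p = np.where(N == 0, 1.0, p)
    return np.minimum(1.0, p)


def classify_paired(case_gt: Genotype, ctrl_gt: Genotype, p: float,
                    params: CallerParams) -> str:
    """Classify a paired observation given direction-appropriate Fisher p.

    GERMLINE when the variant is present in both tissues; SOMATIC when in
    the case only with p <= somatic_p_value; LOH when in the control only
    with p <= somatic_p_value; UNKNOWN otherwise.  Raises on LOW_COVERAGE —
    such sites are skipped upstream.
    """
    if LOW_COVERAGE in (case_gt.call, ctrl_gt.call):
        raise ValueError("cannot classify a LOW_COVERAGE genotype")
    in_case, in_ctrl = case_gt.has_variant, ctrl_gt.has_variant
    if in_case and in_ctrl:
        return GERMLINE
    if in_case and not in_ctrl:
        return SOMATIC if p <= params.somatic_p_value else UNKNOWN
    if in_ctrl and not in_case:
        return LOH if p <= params.somatic_p_value else UNKNOWN
    return UNKNOWN


def call_unpaired(p: SitePileup, params: CallerParams) -> list[VariantCall]:
    """Screen one sample's site without a control.

    Every alt allele passing the read-count/strand/fraction gates yields a
    call with status UNKNOWN carrying a one-sided Fisher exact p of the
    observed [ref, alt] split against the expectation under
    ``params.error_rate`` (expected table rounded to integer reads).
    """
    depth = p.depth
    if depth <= 0:
        return []
    out: list[VariantCall] = []
    for alt in _candidate_alleles(p):
        reads = p.allele_count(alt)
        vaf = reads / depth
        f, r = p.allele_strands(alt)
        strands = (f > 0) + (r > 0)
        if reads < params.min_reads2 or vaf < params.min_var_freq \
                or strands < params.min_strands2:
            continue
        exp_alt = int(round(depth * params.error_rate))
        exp_ref = depth - exp_alt
        pval = fisher_somatic_p(depth - reads, reads, exp_ref, exp_alt)
        out.append(VariantCall(
            key=p.key, alt=alt, sample_case=p.sample, samples_control=(),
            depth_case=depth, depth_controls=(),
            alt_fwd_case=f, alt_rev_case=r, alt_controls=(),
            vaf_case=vaf, vaf_control=0.0, p_somatic=pval, status=UNKNOWN,
        ))
    return out


def _candidate_alleles(p: SitePileup) -> list[str]:
    return [a for a, (f, r) in p.counts.items() if a != p.key.ref and f + r > 0]


def call_sample_set(pileup: MultiSamplePileup, case: str,
                    controls: tuple[str, ...] | list[str],
                    params: CallerParams) -> list[VariantCall]:
    """Paired calling of one case against one or two controls.

    Sites where any involved sample is LOW_COVERAGE are skipped.  With two
    controls, a SOMATIC call requires the variant absent from (and the
    contrast significant against) both; the variant present in any control
    makes the site GERMLINE.  Calls are returned in coordinate order.
    """
    params.validate()
    controls = tuple(controls)
    for s in (case, *controls):
        if s not in pileup.samples:
            raise KeyError(f"sample {s!r} not in pileup")
    if not controls:
        raise ValueError("paired calling requires at least one control")

    calls: list[VariantCall] = []
    for i in _candidate_sites(pileup, (case, *controls), params):
        p_case = pileup.pileup(case, i)
        p_ctrls = [pileup.pileup(c, i) for c in controls]
        alleles = set(_candidate_alleles(p_case))
        for pc in p_ctrls:
            alleles.update(_candidate_alleles(pc))
        for alt in sorted(alleles):
            gt_case = call_genotype(p_case, alt, params, role="case")
            gt_ctrls = [call_genotype(pc, alt, params, role="normal")
                        for pc in p_ctrls]
            if gt_case.call == LOW_COVERAGE or any(
                    g.call == LOW_COVERAGE for g in gt_ctrls):
                continue
            # prefilter: ignore alleles below presence gates everywhere
            if not gt_case.has_variant and not any(g.has_variant for g in gt_ctrls):
                continue
            in_case = gt_case.has_variant
            statuses = []
            pvals = []
            for pc, gt_c in zip(p_ctrls, gt_ctrls):
                ca = p_case.allele_count(alt)
                cta = pc.allele_count(alt)
                if in_case and not gt_c.has_variant:
                    pv = fisher_somatic_p(p_case.depth - ca, ca,
                                          pc.depth - cta, cta)
                elif gt_c.has_variant and not in_case:
                    # LOH direction: control enriched relative to case
                    pv = fisher_somatic_p(pc.depth - cta, cta,
                                          p_case.depth - ca, ca)
                else:
                    pv = fisher_somatic_p(p_case.depth - ca, ca,
                                          pc.depth - cta, cta)
                pvals.append(pv)
                statuses.append(classify_paired(gt_case, gt_c, pv, params))
            if GERMLINE in statuses:
                status = GERMLINE
            elif all(s == SOMATIC for s in statuses):
                status = SOMATIC
            elif all(s == LOH for s in statuses):
                status = LOH
            else:
                status = UNKNOWN
            p_somatic = max(pvals)  # consistency against every control
            f, r = p_case.allele_strands(alt)
            calls.append(VariantCall(
                key=p_case.key, alt=alt, sample_case=case,
                samples_control=controls,
                depth_case=p_case.depth,
                depth_controls=tuple(pc.depth for pc in p_ctrls),
                alt_fwd_case=f, alt_rev_case=r,
                alt_controls=tuple(pc.allele_strands(alt) for pc in p_ctrls),
                vaf_case=gt_case.vaf,
                vaf_control=max(g.vaf for g in gt_ctrls),
                p_somatic=p_somatic, status=status,
            ))
    calls.sort(key=lambda c: (c.key.chrom, c.key.pos, c.alt))
    return calls


def _candidate_sites(pileup: MultiSamplePileup, samples: tuple[str, ...],
                     params: CallerParams) -> np.ndarray:
    """Vectorised prefilter: sites where any sample shows a non-ref base
    allele with >= min_reads2 reads and >= min_var_freq fraction, or any
    indel allele at all."""
    n = pileup.n_sites
    mask = np.zeros(n, dtype=bool)
    ref_idx = np.array([_BASE_INDEX.get(r, -1) for r in pileup.sites["ref"]])
    for s in samples:
        c = pileup.base_counts(s).sum(axis=2)  # (n, 4)
        depth = pileup.depths(s)
        nonref = c.copy()
        rows = np.flatnonzero(ref_idx >= 0)
        nonref[rows, ref_idx[rows]] = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = nonref / np.maximum(depth, 1)[:, None]
        mask |= ((nonref >= params.min_reads2) & (frac >= params.min_var_freq)).any(axis=1)
        for i in pileup._indels[s]:
            mask[i] = True
    return np.flatnonzero(mask)
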