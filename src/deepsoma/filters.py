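"""Post-call quality filter cascade with a complete per-call audit trail.

After calling, candidate somatic variants pass through a fixed sequence of
hard filters that automate the manual winnowing such screens otherwise rely
on: minimum depth at the variant position, minimum variant support on both
strands, strict absence from the matched control tissue, a frequency window
(unpaired mode), rejection of alleles recurring at low fraction across many
samples (the cross-mapping artifact signature), and a read-evidence filter
that discards supporting reads with many mismatches, near read ends, or
near indels, then re-checks strand support.

Every filter is evaluated for every input call regardless of earlier
failures, so the audit table shows exactly which criteria each call met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .calling import LOH, SOMATIC, VariantCall
from .pileups import MultiSamplePileup, ReadEvidence

__all__ = [
    "FilterConfig", "FilterAudit",
    "depth_filter", "strand_filter", "control_absence_filter",
    "frequency_window_filter", "recurrence_artifact_filter",
    "read_evidence_filter", "run_cascade",
]

# cascade order (names are the VCF FILTER ids)
STATUS_GATE = "status_gate"
DEPTH = "depth"
STRAND = "strand"
CONTROL_ABSENCE = "control_absence"
FREQUENCY_WINDOW = "frequency_window"
RECURRENT_ARTIFACT = "RECURRENT_ARTIFACT"
READ_EVIDENCE = "read_evidence"


@dataclass
class FilterConfig:
    """Every threshold in the cascade.

    Depth minima are inclusive for paired designs (two-way: 300/300;
    three-way: 250 case, 300 per control); unpaired depth is a strict
    > 300.  Strand support requires >= 4 variant reads on each strand.
    Control absence is strict (0 alt reads) by default.  The unpaired
    frequency window has a 40% screening cut and a stricter 25% reporting
    cut, both exposed.  Recurrence flags alleles at <= 10% VAF seen in >= 3
    distinct samples.  Read evidence discards supporting reads with > 3
    mismatches, within 5 bp of a read end, or within 10 bp of an indel.
    """

    min_depth_case_2way: int = 300
    min_depth_control_2way: int = 300
    min_depth_case_3way: int = 250
    min_depth_control_3way: int = 300
    min_depth_unpaired: int = 300          # strict > for unpaired mode
    min_alt_per_strand: int = 4
    max_unpaired_freq: float = 0.40        # screening window
    report_unpaired_freq: float = 0.25     # stricter reporting window
    max_p_unpaired: float = 0.05
    control_absence_max_alt_reads: int = 0
    recurrence_min_samples: int = 3
    recurrence_max_vaf: float = 0.10
    max_read_mismatches: int = 3
    read_end_margin_bp: int = 5
    indel_margin_bp: int = 10

    def validate(self) -> None:
        for d in (self.min_depth_case_2way, self.min_depth_control_2way,
                  self.min_depth_case_3way, self.min_depth_control_3way):
            if d <= 0:
                raise ValueError("depth thresholds must be positive")
        if self.min_alt_per_strand < 0 or self.read_end_margin_bp < 0 \
                or self.indel_margin_bp < 0:
            raise ValueError("margins must be non-negative")
        for fq in (self.max_unpaired_freq, self.report_unpaired_freq,
                   self.max_p_unpaired):
            if not (0 < fq <= 1):
                raise ValueError("frequencies/p cutoffs must be in (0, 1]")


@dataclass
class AuditEntry:
    call_id: str
    filter: str
    passed: bool
    observed: float
    threshold: float


class FilterAudit:
    """Ordered per-call record of (filter, pass/fail, observed, threshold)."""

    def __init__(self) -> None:
        self.entries: list[AuditEntry] = []

    def add(self, call_id: str, filt: str, passed: bool,
            observed: float, threshold: float) -> None:
        self.entries.append(AuditEntry(call_id, filt, passed, observed, threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.call_id, e.filter, e.passed, e.observed, e.threshold)
             for e in self.entries],
            columns=["call_id", "filter", "pass", "observed", "threshold"])

    def passed(self, call_id: str) -> bool:
        ours = [e for e in self.entries if e.call_id == call_id]
        return bool(ours) and all(e.passed for e in ours)


def call_id(call: VariantCall) -> str:
    return f"{call.sample_case}:{call.key.chrom}:{call.key.pos}:{call.key.ref}>{call.alt}"


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def depth_filter(call: VariantCall, cfg: FilterConfig, n_controls: int,
                 unpaired: bool = False) -> tuple[bool, float, float]:
    """Inclusive depth minima for paired designs; strict > for unpaired.

    Returns (pass, observed, threshold); observed is the limiting depth.
    """
    if unpaired:
        return call.depth_case > cfg.min_depth_unpaired, float(call.depth_case), \
            float(cfg.min_depth_unpaired)
    if n_controls >= 2:
        min_case, min_ctrl = cfg.min_depth_case_3way, cfg.min_depth_control_3way
    else:
        min_case, min_ctrl = cfg.min_depth_case_2way, cfg.min_depth_control_2way
    ok = call.depth_case >= min_case and all(d >= min_ctrl for d in call.depth_controls)
    margin_case = call.depth_case - min_case
    margins = [margin_case] + [d - min_ctrl for d in call.depth_controls]
    worst = min(range(len(margins)), key=lambda j: margins[j])
    observed = float(call.depth_case if worst == 0 else call.depth_controls[worst - 1])
    threshold = float(min_case if worst == 0 else min_ctrl)
    return ok, observed, threshold


def strand_filter(call: VariantCall, cfg: FilterConfig) -> tuple[bool, float, float]:
    """Require >= min_alt_per_strand variant reads on each strand (inclusive)."""
    m = min(call.alt_fwd_case, call.alt_rev_case)
    return m >= cfg.min_alt_per_strand, float(m), float(cfg.min_alt_per_strand)


def control_absence_filter(call: VariantCall, controls, cfg: FilterConfig
                           ) -> tuple[bool, float, float]:
    """Strict absence of the variant allele from every control pileup.

    ``controls`` is a list of control SitePileups at the call site (None
    entries mean the control lacks the site and fail as MISSING_CONTROL).
    """
    thresh = float(cfg.control_absence_max_alt_reads)
    worst = 0
    for pc in controls:
        if pc is None:
            return False, math.inf, thresh
        worst = max(worst, pc.allele_count(call.alt))
    return worst <= cfg.control_absence_max_alt_reads, float(worst), thresh


def frequency_window_filter(call: VariantCall, cfg: FilterConfig,
                            window: float | None = None) -> tuple[bool, float, float]:
    """Unpaired screening window: keep case VAF strictly below the cut."""
    w = cfg.max_unpaired_freq if window is None else window
    return call.vaf_case < w, call.vaf_case, w


def recurrence_artifact_filter(calls: list[VariantCall], cfg: FilterConfig
                               ) -> set[tuple]:
    """Flag (site, alt) alleles seen at low VAF in many distinct samples.

    Returns the set of (chrom, pos, ref, alt) keys flagged RECURRENT_ARTIFACT;
    the same point substitution arising independently at low fraction in
    three or more samples is overwhelmingly a cross-mapping artifact.
    """
    seen: dict[tuple, set[str]] = {}
    for c in calls:
        if c.vaf_case <= cfg.recurrence_max_vaf and c.vaf_case > 0:
            k = (c.key.chrom, c.key.pos, c.key.ref, c.alt)
            seen.setdefault(k, set()).add(c.sample_case)
    return {k for k, samples in seen.items()
            if len(samples) >= cfg.recurrence_min_samples}


def read_evidence_filter(call: VariantCall, evidence: list[ReadEvidence] | None,
                         cfg: FilterConfig) -> tuple[bool, float, float, list[str]]:
    """Discard questionable supporting reads, then re-check strand support.

    Reads with more than ``max_read_mismatches`` mismatches, within
    ``read_end_margin_bp`` of a read end, or within ``indel_margin_bp`` of an
    indel are removed; the call fails if the surviving support no longer
    meets the per-strand minimum.  Calls without attached evidence pass with
    a NO_EVIDENCE flag (the filter has nothing to inspect).
    """
    if not evidence:
        m = min(call.alt_fwd_case, call.alt_rev_case)
        return True, float(m), float(cfg.min_alt_per_strand), ["NO_EVIDENCE"]
    surviving = [e for e in evidence
                 if e.mismatches <= cfg.max_read_mismatches
                 and e.dist_to_read_end > cfg.read_end_margin_bp
                 and e.dist_to_indel > cfg.indel_margin_bp]
    fwd = sum(1 for e in surviving if e.strand == "+")
    rev = len(surviving) - fwd
    m = min(fwd, rev)
    return m >= cfg.min_alt_per_strand, float(m), float(cfg.min_alt_per_strand), []


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def run_cascade(calls: list[VariantCall], pileup: MultiSamplePileup | None,
                cfg: FilterConfig, mode: str = "paired",
                n_controls: int = 1) -> tuple[list[VariantCall], FilterAudit]:
    """Apply the full cascade and return (survivors, audit).

    Order: status gate (paired keeps SOMATIC/LOH; unpaired keeps calls with
    p <= max_p_unpaired), depth, strand, control absence (paired) or
    frequency window (unpaired), recurrence, read evidence.  The audit is
    complete for every input call; survivors are the calls passing every
    stage.  Each call's ``filters_failed`` list is rewritten to match.
    """
    if mode not in ("paired", "unpaired"):
        raise ValueError(f"mode must be 'paired' or 'unpaired', got {mode!r}")
    cfg.validate()
    audit = FilterAudit()
    site_index: dict[tuple, int] = {}
    if pileup is not None:
        site_index = {(r.chrom, int(r.pos)): i
                      for i, r in enumerate(pileup.sites.itertuples(index=False))}
    recurrent = recurrence_artifact_filter(calls, cfg)
    survivors: list[VariantCall] = []
    for c in calls:
        cid = call_id(c)
        failed: list[str] = []

        if mode == "paired":
            ok = c.status in (SOMATIC, LOH)
            audit.add(cid, STATUS_GATE, ok, 1.0 if ok else 0.0, 1.0)
        else:
            ok = c.p_somatic <= cfg.max_p_unpaired
            audit.add(cid, STATUS_GATE, ok, c.p_somatic, cfg.max_p_unpaired)
        if not ok:
            failed.append(STATUS_GATE)

        ok, obs, thr = depth_filter(c, cfg, n_controls, unpaired=(mode == "unpaired"))
        audit.add(cid, DEPTH, ok, obs, thr)
        if not ok:
            failed.append(DEPTH)

        ok, obs, thr = strand_filter(c, cfg)
        audit.add(cid, STRAND, ok, obs, thr)
        if not ok:
            failed.append(STRAND)

        if mode == "paired":
            controls = _control_pileups(c, pileup, site_index)
            ok, obs, thr = control_absence_filter(c, controls, cfg)
            name = CONTROL_ABSENCE if obs != math.inf else "MISSING_CONTROL"
            audit.add(cid, name, ok, obs, thr)
            if not ok:
                failed.append(name)
        else:
            ok, obs, thr = frequency_window_filter(c, cfg)
            audit.add(cid, FREQUENCY_WINDOW, ok, obs, thr)
            if not ok:
                failed.append(FREQUENCY_WINDOW)

        k = (c.key.chrom, c.key.pos, c.key.ref, c.alt)
        ok = k not in recurrent
        audit.add(cid, RECURRENT_ARTIFACT, ok,
                  0.0 if ok else float(cfg.recurrence_min_samples),
                  float(cfg.recurrence_min_samples))
        if not ok:
            failed.append(RECURRENT_ARTIFACT)

        ev = _case_evidence(c, pileup, site_index)
        ok, obs, thr, flags = read_evidence_filter(c, ev, cfg)
        audit.add(cid, READ_EVIDENCE, ok, obs, thr)
        c.flags = sorted(set(c.flags) | set(flags))
        if not ok:
            failed.append(READ_EVIDENCE)

        c.filters_failed = failed
        if not failed:
            survivors.append(c)
    return survivors, audit


def _control_pileups(call: VariantCall, pileup, site_index):
    if pileup is None:
        # fall back to the counts recorded on the call itself
        return [_pseudo_control(call, j) for j in range(len(call.samples_control))]
    i = site_index.get((call.key.chrom, call.key.pos))
    out = []
    for s in call.samples_control:
        if i is None or s not in pileup.samples:
            out.append(None)
        else:
            out.append(pileup.pileup(s, i))
    return out


class _PseudoPileup:
    """Minimal control stand-in built from a call's recorded control counts."""

    def __init__(self, alt: str, fwd: int, rev: int) -> None:
        self._alt, self._f, self._r = alt, fwd, rev

    def allele_count(self, allele: str) -> int:
        return self._f + self._r if allele == self._alt else 0


def _pseudo_control(call: VariantCall, j: int) -> _PseudoPileup:
    f, r = call.alt_controls[j]
    return _PseudoPileup(call.alt, f, r)


def _case_evidence(call: VariantCall, pileup, site_index):
    if pileup is None:
        return None
    i = site_index.get((call.key.chrom, call.key.pos))
    if i is None:
        return None
    return pileup.evidence_for(call.sample_case, i, call.alt)
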