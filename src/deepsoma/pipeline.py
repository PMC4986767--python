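"""End-to-end orchestration: simulate -> call -> filter -> report.

One :class:`RunConfig` drives a deterministic run.  All randomness flows
from the single top-level seed; every output file records the seed and a
hash of the configuration, and rerunning the same config and seed
reproduces the summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .calling import (LOH, SOMATIC, CallerParams, call_sample_set,
                      call_unpaired)
from .filters import FilterConfig, run_cascade
from .pileups import MultiSamplePileup, read_counts_tsv, write_counts_tsv, write_vcf
from .simulate import SimConfig, simulate_pileups, write_truth_tsv

log = logging.getLogger("deepsoma")

LOW_VAF_CUTOFF = 0.25  # "low-allelic-fraction candidate" reporting cut


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``sim`` (a synthetic run) or ``counts_tsv`` (an observed counts
    table) supplies the input; ``case`` and ``controls`` name the design.
    With no controls the run is unpaired.
    """

    case: str
    controls: tuple[str, ...] = ()
    mode: str = "paired"
    caller: CallerParams = field(default_factory=CallerParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    sim: SimConfig | None = None
    counts_tsv: str | None = None
    out_dir: str = "deepsoma_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("paired", "unpaired"):
            raise ValueError("mode must be paired or unpaired")
        if self.mode == "paired" and not self.controls:
            raise ValueError("paired mode requires at least one control")
        if (self.sim is None) == (self.counts_tsv is None):
            raise ValueError("exactly one of sim / counts_tsv must be given")
        self.caller.validate()
        self.filters.validate()
        if self.sim is not None:
            self.sim.validate()
            missing = {self.case, *self.controls} - set(self.sim.samples)
            if missing:
                raise ValueError(f"design names not simulated: {sorted(missing)}")


def _config_hash(cfg: RunConfig) -> str:
    # hash the scientific configuration only — where outputs land and how
    # loudly we log must not change the run fingerprint
    def enc(o):
        if dataclasses.is_dataclass(o):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o
    payload = enc(cfg)
    payload.pop("out_dir", None)
    payload.pop("log_level", None)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute one run and write calls VCF, passed VCF, audit TSV and a
    summary JSON into ``cfg.out_dir``.  Returns the summary dict.

    The summary reports counts at each stage of the analysis: sites
    examined, putative variant calls, low-allelic-fraction candidates,
    calls with somatic status, and cascade survivors — monotone
    non-increasing along the cascade.
    """
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    header = [f"##deepsoma_version={__version__}",
              f"##deepsoma_seed={cfg.seed}",
              f"##deepsoma_config={chash}"]

    if cfg.sim is not None:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        log.info("simulating %d sites x %d samples (seed %d)",
                 sim.n_sites, len(sim.samples), cfg.seed)
        pileup, truth = simulate_pileups(sim)
        write_counts_tsv(pileup, out / "counts.tsv")
        write_truth_tsv(truth, out / "truth.tsv")
    else:
        pileup = read_counts_tsv(cfg.counts_tsv)

    for name, value in dataclasses.asdict(cfg.caller).items():
        log.info("caller threshold %s = %s", name, value)
    for name, value in dataclasses.asdict(cfg.filters).items():
        log.info("filter threshold %s = %s", name, value)

    if cfg.mode == "paired":
        calls = call_sample_set(pileup, cfg.case, cfg.controls, cfg.caller)
    else:
        calls = []
        for i in range(pileup.n_sites):
            calls.extend(call_unpaired(pileup.pileup(cfg.case, i), cfg.caller))

    write_vcf(calls, out / "calls.vcf", extra_header=header)
    survivors, audit = run_cascade(calls, pileup, cfg.filters, mode=cfg.mode,
                                   n_controls=len(cfg.controls))
    write_vcf(calls, out / "calls.annotated.vcf", extra_header=header)
    write_vcf(survivors, out / "passed.vcf", extra_header=header)
    audit_df = audit.to_frame()
    with open(out / "audit.tsv", "w") as fh:
        fh.write(f"# deepsoma_seed={cfg.seed} config={chash}\n")
        audit_df.to_csv(fh, sep="\t", index=False)

    n_somatic_status = sum(1 for c in calls if c.status in (SOMATIC, LOH))
    summary = {
        "deepsoma_version": __version__,
        "seed": cfg.seed,
        "config_hash": chash,
        "mode": cfg.mode,
        "case": cfg.case,
        "controls": list(cfg.controls),
        "stages": {
            "sites_examined": pileup.n_sites,
            "putative_variants": len(calls),
            "low_vaf_candidates": sum(1 for c in calls
                                      if c.vaf_case < LOW_VAF_CUTOFF),
            "somatic_status": n_somatic_status,
            "survivors": len(survivors),
        },
        "survivor_calls": [
            {"chrom": c.key.chrom, "pos": c.key.pos, "ref": c.key.ref,
             "alt": c.alt, "vaf_case": round(c.vaf_case, 6),
             "p_somatic": round(c.p_somatic, 10), "status": c.status}
            for c in survivors
        ],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
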