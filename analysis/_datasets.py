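"""Shared study-condition definitions for the numbered analysis scripts.

Three synthetic datasets mirror the screen's designs: a technical-replicate
aliquot pair (the false-positive control), a case/control tissue pair with
planted low-fraction clones, and a 39-sample cohort carrying a recurrent
cross-mapping artifact.
"""

from pathlib import Path

from deepsoma.simulate import ArtifactSite, PlantedVariant, SimConfig, simulate_pileups

SEED = 589
SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")

ALIQUOT = SimConfig(
    n_sites=20_000, mean_depth=1000.0, error_rate=0.001,
    germline_het_rate=0.001, germline_hom_rate=0.0005,
    samples=("aliquot_a", "aliquot_b"), seed=SEED)


def paired_with_plants() -> SimConfig:
    """Case/control pair with clones planted at 1-4% allele fraction."""
    probe, _ = simulate_pileups(SimConfig(
        n_sites=5_000, samples=("lens", "retina"), seed=SEED + 1))

    def alt(i):
        return "C" if probe.site_key(i).ref != "C" else "G"

    plants = [PlantedVariant(s, alt(s), v, ("lens",))
              for s, v in ((400, 0.0102), (1500, 0.011), (2600, 0.0272),
                           (3700, 0.0394))]
    return SimConfig(
        n_sites=5_000, mean_depth=1000.0, error_rate=0.0,
        germline_het_rate=0.001, germline_hom_rate=0.0005,
        samples=("lens", "retina"), somatic_plants=plants,
        attach_evidence=True, seed=SEED + 1)


def artifact_cohort() -> SimConfig:
    """39 samples sharing one low-fraction cross-mapping artifact allele."""
    probe, _ = simulate_pileups(SimConfig(n_sites=500, samples=("s0",),
                                          seed=SEED + 2))
    a = "C" if probe.site_key(250).ref != "C" else "G"
    return SimConfig(
        n_sites=500, mean_depth=1000.0, error_rate=0.0,
        samples=tuple(f"s{i}" for i in range(39)),
        artifact_sites=[ArtifactSite(250, a, 0.03, 35 / 39)], seed=SEED + 2)
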