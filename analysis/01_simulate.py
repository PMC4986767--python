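"""Simulate the three study datasets and record their ground truth.

Writes full counts tables (large) under scratch/analysis/ and a compact
truth summary under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

from _datasets import ALIQUOT, RESULTS, SCRATCH, artifact_cohort, paired_with_plants
from deepsoma.pileups import write_counts_tsv
from deepsoma.simulate import simulate_aliquot_pair, simulate_pileups, write_truth_tsv


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, cfg, sim in (
        ("aliquot_pair", ALIQUOT, simulate_aliquot_pair),
        ("planted_pair", paired_with_plants(), simulate_pileups),
        ("artifact_cohort", artifact_cohort(), simulate_pileups),
    ):
        pileup, truth = sim(cfg)
        write_counts_tsv(pileup, SCRATCH / f"{name}.counts.tsv")
        write_truth_tsv(truth, SCRATCH / f"{name}.truth.tsv")
        by_class = truth["klass"].value_counts().to_dict() if len(truth) else {}
        rows.append({"dataset": name, "n_sites": pileup.n_sites,
                     "n_samples": len(pileup.samples),
                     "mean_depth": cfg.mean_depth,
                     "error_rate": cfg.error_rate, **by_class})
        print(f"{name}: {pileup.n_sites} sites x {len(pileup.samples)} samples; "
              f"truth classes {by_class}")
    pd.DataFrame(rows).to_csv(RESULTS / "01_datasets.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
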