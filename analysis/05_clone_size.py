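"""Clone-size implications of a ~1% variant in the lens epithelium.

Takes the ddPCR-measured allele fraction from step 04 (falling back to the
canonical 1% figure), assumes the variant is heterozygous and the sample
covered half of a 0.5e6-cell epithelium at 5500 cells/mm^2, and derives the
mutant-cell fraction, clone cell count, and patch area.
"""

import dataclasses
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _datasets import RESULTS
from deepsoma.clone import CloneAssumptions, estimate_clone

ASSUMPTIONS = CloneAssumptions(
    zygosity="heterozygous", cells_total_epithelium=0.5e6,
    sampled_area_fraction=0.5, cell_density=5500.0)


def main() -> None:
    report = {}
    for label, vaf in (("nominal_1pct", 0.01), ("measured_ddpcr", None)):
        if vaf is None:
            ddpcr_path = RESULTS / "04_ddpcr_quant.json"
            if not ddpcr_path.exists():
                continue
            vaf = json.loads(ddpcr_path.read_text())["vaf"]
        est = estimate_clone(vaf, ASSUMPTIONS)
        entry = dataclasses.asdict(est)
        entry["assumptions"] = dataclasses.asdict(est.assumptions)
        report[label] = entry
        print(f"{label}: VAF {vaf:.4f} -> {est.cell_fraction:.2%} of cells, "
              f"{est.clone_cells} cells, {est.clone_area_mm2:.3f} mm^2 "
              f"(~{est.clone_area_mm2_rounded:g} mm^2)")
    with open(RESULTS / "05_clone_size.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
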