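"""Run the full filter cascade on both paired datasets.

Expected outcome: zero survivors on the technical-replicate null, and the
planted clones (plus nothing else) surviving in the case/control pair.  The
artifact cohort shows the recurrence filter flagging the shared allele.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

from _datasets import RESULTS, SCRATCH
from deepsoma.calling import CallerParams, call_sample_set, call_unpaired
from deepsoma.filters import FilterConfig, recurrence_artifact_filter, run_cascade
from deepsoma.pileups import read_counts_tsv, write_vcf


def main() -> None:
    rows = []
    for name, case, controls in (
        ("aliquot_pair", "aliquot_a", ("aliquot_b",)),
        ("planted_pair", "lens", ("retina",)),
    ):
        pileup = read_counts_tsv(SCRATCH / f"{name}.counts.tsv")
        calls = call_sample_set(pileup, case, controls, CallerParams())
        survivors, audit = run_cascade(calls, pileup, FilterConfig(),
                                       mode="paired", n_controls=len(controls))
        write_vcf(survivors, SCRATCH / f"{name}.passed.vcf")
        audit.to_frame().to_csv(SCRATCH / f"{name}.audit.tsv", sep="\t",
                                index=False)
        for c in survivors:
            rows.append({"dataset": name, "chrom": c.key.chrom,
                         "pos": c.key.pos, "ref": c.key.ref, "alt": c.alt,
                         "vaf_case": round(c.vaf_case, 4),
                         "p_somatic": c.p_somatic, "status": c.status})
        print(f"{name}: {len(survivors)}/{len(calls)} calls survive the cascade")

    pileup = read_counts_tsv(SCRATCH / "artifact_cohort.counts.tsv")
    calls = []
    for s in pileup.samples:
        for i in range(pileup.n_sites):
            calls.extend(call_unpaired(pileup.pileup(s, i), CallerParams()))
    flagged = recurrence_artifact_filter(calls, FilterConfig())
    print(f"artifact_cohort: {len(flagged)} recurrent artifact allele(s) flagged "
          f"across {len({c.sample_case for c in calls})} samples")

    pd.DataFrame(rows).to_csv(RESULTS / "03_survivors.tsv", sep="\t", index=False)
    with open(RESULTS / "03_recurrence_flags.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(flagged):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


if __name__ == "__main__":
    main()
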