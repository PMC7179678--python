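#!/usr/bin/env python
"""Apply the SNV filter cascade to the post-QC calls of run 1 and match
surviving variants against their genes' inheritance patterns.  Writes the
candidate table, the cascade attrition counts, and per-patient statuses."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_processed, outdir

from pidarray import vcfio


def main() -> None:
    cohort, r1, _r2 = load_processed()
    out = outdir("04_snv")

    cascade = r1.cascade
    cascade.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    cascade.diagnostic_variants.to_csv(out / "diagnostic_variants.tsv",
                                       sep="\t", index=False)
    vcfio.write_json({"attrition": cascade.attrition,
                      "n_unannotated_dropped": cascade.n_unannotated_dropped,
                      "statuses": cascade.statuses},
                     out / "cascade.json")

    print("cascade attrition (candidates surviving each filter):")
    for stage, n in cascade.attrition.items():
        print(f"  {stage:>16}: {n}")
    n_diag = sum(1 for v in cascade.statuses.values()
                 if v == "genetic_diagnosis")
    print(f"SNV-based diagnoses: {n_diag} of {len(cascade.statuses)} patients")
    flagged = int(cascade.candidates["flagged_for_review"].sum())
    print(f"candidates flagged for manual review: {flagged}")
    print(f"wrote SNV screen to {out}")


if __name__ == "__main__":
    main()
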