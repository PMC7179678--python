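#!/usr/bin/env python
"""Run the QC cascade on both runs: primary 97.5% call-rate filters,
Hardy-Weinberg exclusion (P < 1e-4), zCall-style recalling, and the
stricter post-recall 98% filters.  Writes post-QC VCFs and QC reports."""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_processed, outdir

from pidarray import vcfio


def main() -> None:
    cohort, r1, r2 = load_processed()
    out = outdir("03_qc")

    for res in (r1, r2):
        rid = res.run.run_id
        vcfio.write_vcf(res.postqc, cohort.manifest, out / f"{rid}_postqc.vcf")
        vcfio.write_json(res.qc_report.to_dict(), out / f"{rid}_qc.json")
        reasons = Counter(res.qc_report.excluded_probes.values())
        recalled = int((res.postqc.caller == 1).sum())
        print(f"{rid}: probes {res.qc_report.n_probes_in} -> "
              f"{res.qc_report.n_probes_out} "
              f"(excluded by reason: {dict(reasons) or 'none'}); "
              f"samples {res.qc_report.n_samples_in} -> "
              f"{res.qc_report.n_samples_out} "
              f"(excluded: {sorted(res.qc_report.excluded_samples) or 'none'})")
        print(f"{rid}: {recalled} genotypes rescued by recalling")
    print(f"wrote post-QC data to {out}")


if __name__ == "__main__":
    main()
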