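#!/usr/bin/env python
"""Generate the simulated screening cohort and write its inputs to disk:
probe manifest, variant annotation, truth genotypes, benign-CNV track and
the planted-event ledger.  Everything downstream reads from these study
conditions (95 patients + 56 controls, two runs)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_cohort, outdir

from pidarray import manifest as mf
from pidarray import vcfio


def main() -> None:
    cohort = load_cohort()
    out = outdir("01_cohort")

    mf.write_manifest(cohort.manifest, out / "manifest.csv")
    mf.write_annotation(cohort.annotation, out / "annotation.csv")
    mf.write_truth(cohort.truth, out / "truth_genotypes.csv")
    cohort.benign_track.df.to_csv(out / "benign_cnv_track.csv", index=False)
    led = cohort.ledger
    led.planted_snvs.to_csv(out / "planted_snvs.csv", index=False)
    vcfio.write_json({
        "causal_by_patient": led.causal_by_patient,
        "cnv_events": led.cnv_events,
        "lcsh_events": led.lcsh_events,
        "failed_samples": led.failed_samples,
        "failed_probes": led.failed_probes,
        "sexes": cohort.sexes,
    }, out / "ledger.json")

    counts = cohort.manifest.class_counts()
    print(f"cohort: {len(cohort.patient_ids)} patients, "
          f"{len(cohort.control_ids)} controls, two runs")
    print(f"manifest: {counts['custom']} custom probes "
          f"({counts.get('custom_pid_snv', 0)} SNV, "
          f"{counts.get('custom_pid_indel', 0)} INDEL), "
          f"{counts.get('backbone', 0)} backbone probes")
    print(f"planted SNVs: {len(led.planted_snvs)} "
          f"({int(led.planted_snvs['causal'].sum())} causal)")
    print(f"planted CNV events: {len(led.cnv_events)}; "
          f"LCSH regions: {len(led.lcsh_events)}")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
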