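#!/usr/bin/env python
"""Validation statistics of the simulated screen: genotype concordance of
controls against truth, variant sensitivity from the ledger, patient-level
diagnostic yield, inter-run reproducibility, and the screening cost model
evaluated at the measured yield."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_processed, outdir

from pidarray import evaluate, vcfio
from pidarray.evaluate import CostModel, cost_compare


def main() -> None:
    cohort, r1, r2 = load_processed()
    out = outdir("06_evaluation")

    conc = evaluate.concordance(r1.postqc, cohort.truth, cohort.manifest,
                                cohort.control_ids)
    print(f"concordance vs truth (controls, custom SNV probes): "
          f"{conc.n_matching}/{conc.n_compared} "
          f"= {conc.percent_concordance}%")

    # "known" variants are the planted causal diagnoses; incidental carrier
    # heterozygotes are not diagnostic targets (the recurrence filter is
    # designed to remove the recurrent ones)
    led = cohort.ledger.planted_snvs
    causal = led[led["causal"]]
    sens = evaluate.sensitivity_from_ledger(
        causal[["sample_id", "probe_id"]],
        r1.cascade.candidates[["sample_id", "probe_id"]],
        probe_ids_on_array=list(cohort.manifest.probe_ids),
        probes_passing_qc=list(r1.postqc.probe_ids))
    print(f"variant categories (causal planted): {sens.categories}")
    print(f"sensitivity (known variants, probe-covered): "
          f"{sens.sensitivity_known}%")

    statuses = {p: r1.statuses[p] for p in cohort.patient_ids}
    yld = evaluate.diagnostic_yield(statuses)
    print(f"diagnostic yield: {yld.n_diagnosed}/{yld.n_total_patients} "
          f"= {yld.yield_percent}%")

    repro = evaluate.reproducibility(r1.postqc, r2.postqc,
                                     cohort.ledger.causal_by_patient,
                                     r2.cascade.candidates, cohort.manifest)
    print(f"inter-run replication: {repro.n_patients_replicated}/"
          f"{repro.n_patients_compared} patients "
          f"= {repro.patient_percent}%; genotype discordance "
          f"{repro.n_genotypes_discordant}/{repro.n_genotypes_compared} "
          f"= {repro.genotype_discordance_percent}%")

    cost = cost_compare(CostModel(
        cohort_size=100,
        screen_yield_fraction=yld.n_diagnosed / yld.n_total_patients))
    print(f"cost per 100 patients at measured yield: array-first "
          f"EUR {cost.screen_then_sequence_total:,.0f} vs sequence-all "
          f"EUR {cost.sequence_all_total:,.0f} "
          f"(saving EUR {cost.saving:,.0f})")

    vcfio.write_json({
        "concordance": conc.to_dict(),
        "sensitivity": sens.to_dict(),
        "yield": yld.to_dict(),
        "reproducibility": repro.to_dict(),
        "cost_at_measured_yield": cost.to_dict(),
    }, out / "evaluation.json")
    print(f"wrote evaluation to {out}")


if __name__ == "__main__":
    main()
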