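"""Validation statistics and screening economics.

Covers: array-vs-truth genotype concordance (restricted to custom SNV
probes, the scope a sequencing comparison supports), variant-level
sensitivity, patient-level diagnostic yield, inter-run reproducibility, and
the two-arm screening cost model (array-screen-then-sequence versus
sequence-everyone).

All percentages are reported at the precision conventional for each
statistic (one decimal for concordance/reproducibility/validation rates,
integers for sensitivity and yield) using round-half-away-from-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .calling import GenotypeMatrix
from .manifest import ProbeManifest, TruthGenotypes


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (what a human does on paper; banker's
    rounding would print 94.8 for 37/39)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """Percentage of a count ratio at the stated precision."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)


@dataclass
class ConcordanceReport:
    n_compared: int
    n_matching: int
    n_nonref_calls: int
    n_nonref_mismatches: int
    excluded_probes: list[str]   # probes with any array/truth disagreement

    @property
    def percent_concordance(self) -> float:
        return percent(self.n_matching, self.n_compared, 1)

    @property
    def nonref_mismatch_rates(self) -> dict[str, float]:
        """Both defensible denominators for the non-reference mismatch rate
        are reported; neither is privileged."""
        out = {}
        if self.n_nonref_calls:
            out["vs_nonref_calls"] = round_half_away(
                100.0 * self.n_nonref_mismatches / self.n_nonref_calls, 2)
        if self.n_compared:
            out["vs_compared"] = round_half_away(
                100.0 * self.n_nonref_mismatches / self.n_compared, 2)
        return out

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_matching": self.n_matching,
            "percent_concordance": self.percent_concordance,
            "n_nonref_calls": self.n_nonref_calls,
            "n_nonref_mismatches": self.n_nonref_mismatches,
            "nonref_mismatch_rates": self.nonref_mismatch_rates,
            "excluded_probes": sorted(self.excluded_probes),
        }


def concordance(calls: GenotypeMatrix, truth: TruthGenotypes,
                manifest: ProbeManifest, sample_ids=None) -> ConcordanceReport:
    """Per-call comparison of array genotypes with truth genotypes over
    custom SNV probes (INDEL probes are excluded: the comparison frame of a
    sequencing truth set is only well-defined for SNVs)."""
    if sample_ids is None:
        sample_ids = list(calls.sample_ids)
    sample_ids = [s for s in sample_ids if s in set(calls.sample_ids)]
    truth_samples = set(truth.df["sample_id"])
    sample_ids = [s for s in sample_ids if s in truth_samples]
    if not sample_ids:
        raise ValueError("no overlapping samples between calls and truth")

    info = manifest.positions_of(calls.probe_ids)
    snv_mask = (info["probe_class"] == "custom_pid_snv").to_numpy()
    probe_ids = calls.probe_ids[snv_mask]
    srows = calls.sample_index(sample_ids)
    arr = calls.calls[np.ix_(srows, snv_mask)]
    tru = truth.to_codes(sample_ids, probe_ids)

    comparable = (arr >= 0) & (tru >= 0)
    match = comparable & (arr == tru)
    nonref = comparable & (arr > 0)
    mism_by_probe = (comparable & (arr != tru)).any(axis=0)

    return ConcordanceReport(
        n_compared=int(comparable.sum()),
        n_matching=int(match.sum()),
        n_nonref_calls=int(nonref.sum()),
        n_nonref_mismatches=int((nonref & (arr != tru)).sum()),
        excluded_probes=[str(p) for p in probe_ids[mism_by_probe]],
    )


VARIANT_CATEGORIES = ("replicated_known", "new_confirmed", "new_unconfirmable",
                      "missed_no_probe", "missed_probe_failed")


@dataclass
class YieldReport:
    """Variant-level sensitivity and patient-level diagnostic yield.

    ``categories`` partitions every assessed variant.  The sensitivity for
    known variants restricts the denominator to variants with a usable probe
    on the array; variants without a probe are counted separately, not as
    failures of the assay chemistry.
    """

    categories: dict[str, int]
    n_diagnosed: int = 0
    n_total_patients: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.categories) - set(VARIANT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown variant categories: {sorted(unknown)}")
        self.categories = {k: self.categories.get(k, 0)
                           for k in VARIANT_CATEGORIES}

    @property
    def sensitivity_known(self) -> float | None:
        num = self.categories["replicated_known"]
        den = num + self.categories["missed_probe_failed"]
        return percent(num, den) if den else None

    @property
    def sensitivity_overall(self) -> float | None:
        num = (self.categories["replicated_known"]
               + self.categories["new_confirmed"])
        den = (self.categories["replicated_known"]
               + self.categories["missed_probe_failed"]
               + self.categories["new_confirmed"]
               + self.categories["new_unconfirmable"])
        return percent(num, den) if den else None

    @property
    def yield_percent(self) -> float | None:
        if self.n_total_patients == 0:
            return None
        return percent(self.n_diagnosed, self.n_total_patients)

    def to_dict(self) -> dict:
        return {
            "categories": dict(self.categories),
            "sensitivity_known": self.sensitivity_known,
            "sensitivity_overall": self.sensitivity_overall,
            "n_diagnosed": self.n_diagnosed,
            "n_total_patients": self.n_total_patients,
            "yield_percent": self.yield_percent,
        }


def sensitivity_from_ledger(planted: pd.DataFrame, found: pd.DataFrame,
                            probe_ids_on_array, probes_passing_qc,
                            confirmable: dict | None = None) -> YieldReport:
    """Categorise planted (known) and newly-found variants.

    ``planted``/``found``: frames with sample_id + probe_id.  A planted
    variant replicates when found; planted variants at probes absent from
    the array are ``missed_no_probe``; at probes that failed QC,
    ``missed_probe_failed``.  Found variants not planted are new; they are
    confirmed by the truth lookup unless ``confirmable`` marks them
    untestable (emulating exhausted DNA).
    """
    on_array = set(probe_ids_on_array)
    passing = set(probes_passing_qc)
    found_keys = set(zip(found["sample_id"], found["probe_id"]))
    planted_keys = set(zip(planted["sample_id"], planted["probe_id"]))
    cats = dict.fromkeys(VARIANT_CATEGORIES, 0)
    for key in sorted(planted_keys):
        _s, p = key
        if p not in on_array:
            cats["missed_no_probe"] += 1
        elif key in found_keys:
            cats["replicated_known"] += 1
        else:
            cats["missed_probe_failed"] += 1
    confirmable = confirmable or {}
    for key in sorted(found_keys - planted_keys):
        if confirmable.get(key, True):
            cats["new_confirmed"] += 1
        else:
            cats["new_unconfirmable"] += 1
    return YieldReport(cats)


def diagnostic_yield(statuses: dict[str, str]) -> YieldReport:
    """Patient-level yield from per-patient diagnosis statuses."""
    n = len(statuses)
    d = sum(1 for v in statuses.values() if v == "genetic_diagnosis")
    return YieldReport(dict.fromkeys(VARIANT_CATEGORIES, 0),
                       n_diagnosed=d, n_total_patients=n)


@dataclass
class ReproducibilityReport:
    n_patients_compared: int
    n_patients_replicated: int
    n_genotypes_compared: int
    n_genotypes_discordant: int

    @property
    def patient_percent(self) -> float | None:
        if self.n_patients_compared == 0:
            return None
        return percent(self.n_patients_replicated, self.n_patients_compared, 1)

    @property
    def genotype_discordance_percent(self) -> float | None:
        if self.n_genotypes_compared == 0:
            return None
        return round_half_away(100.0 * self.n_genotypes_discordant
                               / self.n_genotypes_compared, 2)

    def to_dict(self) -> dict:
        return {
            "n_patients_compared": self.n_patients_compared,
            "n_patients_replicated": self.n_patients_replicated,
            "patient_percent": self.patient_percent,
            "n_genotypes_compared": self.n_genotypes_compared,
            "n_genotypes_discordant": self.n_genotypes_discordant,
            "genotype_discordance_percent": self.genotype_discordance_percent,
        }


def reproducibility(calls1: GenotypeMatrix, calls2: GenotypeMatrix,
                    causal_by_patient: dict[str, list[str]],
                    found2: pd.DataFrame, manifest: ProbeManifest
                    ) -> ReproducibilityReport:
    """Inter-run agreement.

    Patient level: fraction of patients whose run-1 causal variants all
    reappear among run 2's post-cascade candidates.  Genotype level:
    discordant calls over the custom probes and samples shared by both
    post-QC runs.
    """
    shared_samples = sorted(set(calls1.sample_ids) & set(calls2.sample_ids))
    if not shared_samples:
        raise ValueError("no overlapping samples between runs")
    shared_probes = np.array(sorted(set(calls1.probe_ids)
                                    & set(calls2.probe_ids)))
    info = manifest.positions_of(shared_probes)
    custom = info["probe_class"].str.startswith("custom").to_numpy()
    shared_probes = shared_probes[custom]

    a = calls1.calls[np.ix_(calls1.sample_index(shared_samples),
                            calls1.probe_index(shared_probes))]
    b = calls2.calls[np.ix_(calls2.sample_index(shared_samples),
                            calls2.probe_index(shared_probes))]
    comparable = (a >= 0) & (b >= 0)
    discordant = comparable & (a != b)

    found2_keys = set(zip(found2["sample_id"], found2["probe_id"]))
    sample_set2 = set(calls2.sample_ids)
    n_pat = n_rep = 0
    for pat, probes in sorted(causal_by_patient.items()):
        if pat not in sample_set2 or not probes:
            continue
        n_pat += 1
        if all((pat, p) in found2_keys for p in probes):
            n_rep += 1
    return ReproducibilityReport(n_pat, n_rep, int(comparable.sum()),
                                 int(discordant.sum()))


@dataclass(frozen=True)
class CostModel:
    array_cost_per_sample: float = 40.0     # EUR
    ngs_cost_per_sample: float = 1000.0     # EUR
    cohort_size: int = 100
    screen_yield_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.array_cost_per_sample <= 0 or self.ngs_cost_per_sample <= 0:
            raise ValueError("costs must be positive")
        if not 0.0 <= self.screen_yield_fraction <= 1.0:
            raise ValueError("yield fraction outside [0, 1]")


@dataclass
class CostComparison:
    initial_array_cost: float
    screen_then_sequence_total: float
    sequence_all_total: float
    saving: float

    def to_dict(self) -> dict:
        return {
            "initial_array_cost": self.initial_array_cost,
            "screen_then_sequence_total": self.screen_then_sequence_total,
            "sequence_all_total": self.sequence_all_total,
            "saving": self.saving,
        }


def cost_compare(model: CostModel) -> CostComparison:
    """Two-arm cost comparison: screen with the array and sequence only the
    undiagnosed remainder, versus sequencing every patient."""
    n = model.cohort_size
    initial = n * model.array_cost_per_sample
    undiagnosed = n * (1.0 - model.screen_yield_fraction)
    screen_total = initial + undiagnosed * model.ngs_cost_per_sample
    seq_all = n * model.ngs_cost_per_sample
    return CostComparison(initial, screen_total, seq_all,
                          seq_all - screen_total)
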