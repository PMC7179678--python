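"""Array quality control.

The cascade, in order: primary probe call-rate filter (97.5%), primary
sample call-rate filter (97.5%), Hardy-Weinberg exact-test exclusion
(P < 1e-4; autosomes on all retained samples, X on females only, Y never
tested), zCall-style rare-variant recalling, then the stricter post-recall
98% probe and sample call-rate filters.  Exclusion reasons record the first
failing rule per item.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import ClusterModel, GenotypeMatrix, zcall_recall
from .manifest import ProbeManifest


@dataclass(frozen=True)
class QcThresholds:
    snp_call_rate_primary: float = 0.975
    sample_call_rate_primary: float = 0.975
    hwe_p_cut: float = 1e-4
    snp_call_rate_post_zcall: float = 0.98
    sample_call_rate_post_zcall: float = 0.98

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_primary", "sample_call_rate_primary",
                     "snp_call_rate_post_zcall", "sample_call_rate_post_zcall"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if not 0.0 < self.hwe_p_cut < 1.0:
            raise ValueError("hwe_p_cut outside (0, 1)")


@dataclass
class QcReport:
    excluded_probes: dict[str, str] = field(default_factory=dict)
    excluded_samples: dict[str, str] = field(default_factory=dict)
    inferred_sex: dict[str, str] = field(default_factory=dict)
    n_probes_in: int = 0
    n_probes_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0

    def to_dict(self) -> dict:
        return {
            "excluded_probes": dict(sorted(self.excluded_probes.items())),
            "excluded_samples": dict(sorted(self.excluded_samples.items())),
            "inferred_sex": dict(sorted(self.inferred_sex.items())),
            "n_probes_in": self.n_probes_in,
            "n_probes_out": self.n_probes_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
        }


class EmptyCohortError(RuntimeError):
    """Every sample was excluded by QC."""


def call_rate(calls: np.ndarray, axis: int) -> np.ndarray:
    """Fraction of non-missing calls per probe (axis=0) or sample (axis=1)."""
    n = calls.shape[axis]
    if n == 0:
        return np.full(calls.shape[1 - axis], np.nan)
    return (calls >= 0).sum(axis=axis) / n


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed
    one's.  Uses the standard recurrence on the heterozygote count (the
    method family behind PLINK's ``--hwe``).  Monomorphic input returns 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # probabilities over het counts with the parity of n_rare, built from
    # the mode outward via the ratio recurrence
    mid = int(n_rare * (2 * n - n_rare) / (2.0 * n))
    if (mid % 2) != (n_rare % 2):
        mid += 1
    probs = {mid: 1.0}
    het = mid
    while het >= 2:
        # P(het-2) / P(het)
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        ratio = het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        probs[het - 2] = probs[het] * ratio
        het -= 2
    het = mid
    while het <= n_rare - 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        ratio = 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        probs[het + 2] = probs[het] * ratio
        het += 2

    total = sum(probs.values())
    obs = probs[n_ab] / total
    p = sum(v for v in probs.values() if v / total <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def infer_sex(calls: GenotypeMatrix, manifest: ProbeManifest,
              min_x_probes: int = 50,
              male_max_het: float = 0.05,
              female_min_het: float = 0.20) -> dict[str, str]:
    """Classify samples as male/female/ambiguous from X heterozygosity.

    The rate is computed over cohort-polymorphic X probes where possible:
    monomorphic custom probes carry no sex signal and would dilute the
    female heterozygosity rate towards the ambiguous band.
    """
    x_mask = manifest.positions_of(calls.probe_ids)["chromosome"].to_numpy() == "X"
    xc = calls.calls[:, x_mask]
    called_all = (xc >= 0).sum(axis=1)
    probe_called = np.maximum((xc >= 0).sum(axis=0), 1)
    informative = (xc == 1).sum(axis=0) / probe_called >= 0.05
    use = xc[:, informative] if informative.sum() >= 20 else xc
    called = (use >= 0).sum(axis=1)
    het = (use == 1).sum(axis=1)
    out = {}
    for i, s in enumerate(calls.sample_ids):
        if called_all[i] < min_x_probes or called[i] == 0:
            out[s] = "ambiguous"
            continue
        rate = het[i] / called[i]
        if rate < male_max_het:
            out[s] = "male"
        elif rate > female_min_het:
            out[s] = "female"
        else:
            out[s] = "ambiguous"
    return out


def _hwe_pvalues(calls: GenotypeMatrix, chroms: np.ndarray,
                 female_mask: np.ndarray) -> np.ndarray:
    """Per-probe HWE p: autosomes over all samples, X over females, Y = 1."""
    p = np.ones(calls.n_probes)
    c = calls.calls
    for j in range(calls.n_probes):
        if chroms[j] == "Y":
            continue
        col = c[female_mask, j] if chroms[j] == "X" else c[:, j]
        counts = (int((col == 0).sum()), int((col == 1).sum()),
                  int((col == 2).sum()))
        if sum(counts) == 0:  # e.g. X probe in an all-male cohort
            continue
        p[j] = hwe_exact_p(*counts)
    return p


def apply_qc(calls: GenotypeMatrix, model: ClusterModel,
             x: np.ndarray, y: np.ndarray, manifest: ProbeManifest,
             thresholds: QcThresholds = QcThresholds(),
             zcall_z: float = 7.0) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full QC cascade on a primary-called run.

    ``x``/``y`` are the raw channel matrices aligned with ``calls`` (needed
    by the recalling stage).  Returns the filtered, recalled matrix and a
    report of every exclusion with its first failing rule.
    """
    report = QcReport(n_probes_in=calls.n_probes, n_samples_in=calls.n_samples)
    chroms = manifest.positions_of(calls.probe_ids)["chromosome"].to_numpy()

    # stage 1: primary probe call rate
    pr = call_rate(calls.calls, axis=0)
    probe_keep = pr >= thresholds.snp_call_rate_primary
    for pid in calls.probe_ids[~probe_keep]:
        report.excluded_probes[pid] = "low_call_rate"

    # stage 2: primary sample call rate over retained probes
    sr = call_rate(calls.calls[:, probe_keep], axis=1)
    sample_keep = sr >= thresholds.sample_call_rate_primary
    for sid in calls.sample_ids[~sample_keep]:
        report.excluded_samples[sid] = "low_call_rate"
    if not sample_keep.any():
        raise EmptyCohortError("all samples failed the primary call-rate filter")

    sub = calls.subset(sample_keep, probe_keep)
    sub_x = x[np.ix_(sample_keep, probe_keep)]
    sub_y = y[np.ix_(sample_keep, probe_keep)]

    # stage 3: Hardy-Weinberg exclusion
    report.inferred_sex = infer_sex(sub, manifest)
    female = np.array([report.inferred_sex[s] == "female"
                       for s in sub.sample_ids])
    hwe_p = _hwe_pvalues(sub, chroms[probe_keep], female)
    hwe_keep = hwe_p >= thresholds.hwe_p_cut
    for pid in sub.probe_ids[~hwe_keep]:
        report.excluded_probes[pid] = "hwe"
    sub = sub.subset(probe_mask=hwe_keep)
    sub_x, sub_y = sub_x[:, hwe_keep], sub_y[:, hwe_keep]

    # stage 4: rare-variant recalling on the surviving matrix
    model_idx = {p: i for i, p in enumerate(model.probe_ids)}
    midx = np.array([model_idx[p] for p in sub.probe_ids])
    sub_model = ClusterModel(
        probe_ids=sub.probe_ids,
        centers=model.centers[midx], spreads=model.spreads[midx],
        counts=model.counts[midx], imputed=model.imputed[midx],
        median_total=model.median_total[midx],
        aa_y_mean=model.aa_y_mean[midx], aa_y_sd=model.aa_y_sd[midx],
        bb_x_mean=model.bb_x_mean[midx], bb_x_sd=model.bb_x_sd[midx],
        callable=model.callable[midx])
    sub = zcall_recall(sub_model, sub, sub_x, sub_y, z=zcall_z)

    # stage 5: stricter post-recall filters, probes then samples
    pr2 = call_rate(sub.calls, axis=0)
    keep_p2 = pr2 >= thresholds.snp_call_rate_post_zcall
    for pid in sub.probe_ids[~keep_p2]:
        report.excluded_probes[pid] = "post_zcall_rate"
    sub = sub.subset(probe_mask=keep_p2)
    sr2 = call_rate(sub.calls, axis=1)
    keep_s2 = sr2 >= thresholds.sample_call_rate_post_zcall
    for sid in sub.sample_ids[~keep_s2]:
        report.excluded_samples[sid] = "post_zcall_rate"
    if not keep_s2.any():
        raise EmptyCohortError("all samples failed the post-recall filter")
    sub = sub.subset(sample_mask=keep_s2)

    report.n_probes_out = sub.n_probes
    report.n_samples_out = sub.n_samples
    report.inferred_sex = {s: report.inferred_sex[s] for s in sub.sample_ids}
    return sub, report
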