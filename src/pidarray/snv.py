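"""SNV screening cascade: post-QC genotypes -> candidate diagnostic variants.

Filter order (the only order the screening design supports): pathogenicity
selection, population-frequency filter (strictly below 0.5% by default),
cohort recurrence filter (recurrent calls betray faulty probes), male
X-heterozygote exclusion, and an automated cluster-position/intensity check
standing in for manual SNP-graph review.  A final inheritance-matching step
turns each patient's surviving variants into a diagnosis status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import (DEFAULT_SPREAD, ClusterModel, GenotypeMatrix,
                      polar_transform)
from .manifest import ProbeManifest, VariantAnnotation
from .simulate import IntensityRun

DEFAULT_FREQ_CUTOFF = 0.005
DEFAULT_CLUSTER_K = 3.0

CANDIDATE_COLUMNS = ["sample_id", "probe_id", "chromosome", "gene",
                     "zygosity", "caller", "filter_trail",
                     "flagged_for_review"]


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(columns=CANDIDATE_COLUMNS)


def extract_candidates(calls: GenotypeMatrix,
                       manifest: ProbeManifest) -> pd.DataFrame:
    """Non-reference calls at custom probes become screening candidates."""
    custom_ids = set(manifest.df.loc[manifest.mask(custom=True), "probe_id"])
    pmask = np.isin(calls.probe_ids, list(custom_ids))
    info = manifest.positions_of(calls.probe_ids[pmask])
    rows = []
    sub = calls.calls[:, pmask]
    caller = calls.caller[:, pmask]
    for si, sid in enumerate(calls.sample_ids):
        nonref = np.flatnonzero(sub[si] > 0)
        for j in nonref:
            rows.append((sid, info["probe_id"].iloc[j],
                         info["chromosome"].iloc[j], info["gene"].iloc[j],
                         "het" if sub[si, j] == 1 else "hom",
                         "recalled" if caller[si, j] == 1 else "primary",
                         "", False))
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return df.sort_values(["sample_id", "probe_id"]).reset_index(drop=True)


def _stamp(df: pd.DataFrame, stage: str) -> pd.DataFrame:
    df = df.copy()
    sep = np.where(df["filter_trail"] == "", "", ">")
    df["filter_trail"] = df["filter_trail"] + sep + stage
    return df


def select_disease_causing(candidates: pd.DataFrame,
                           annotation: VariantAnnotation
                           ) -> tuple[pd.DataFrame, int]:
    """Keep candidates at probes annotated disease-causing.

    Unannotated probes are treated as not disease-causing; their dropped
    count is returned alongside for the attrition report.
    """
    ann = annotation.lookup(candidates["probe_id"])
    unannotated = ann["pathogenicity"].isna().to_numpy()
    keep = (ann["pathogenicity"] == "disease_causing").to_numpy()
    out = _stamp(candidates[keep], "disease_causing")
    return out.reset_index(drop=True), int(unannotated.sum())


def frequency_filter(candidates: pd.DataFrame, annotation: VariantAnnotation,
                     cutoff: float = DEFAULT_FREQ_CUTOFF) -> pd.DataFrame:
    """Keep candidates with population frequency strictly below ``cutoff``;
    a missing frequency is treated as 0 (retained)."""
    ann = annotation.lookup(candidates["probe_id"])
    freq = ann["pop_frequency"].fillna(0.0).to_numpy()
    keep = freq < cutoff
    return _stamp(candidates[keep], "rare").reset_index(drop=True)


def recurrence_filter(candidates: pd.DataFrame) -> pd.DataFrame:
    """Drop probe-level variants carried by two or more samples in the run —
    recurrence of a supposedly rare variant flags a faulty probe."""
    carriers = candidates.groupby("probe_id")["sample_id"].nunique()
    singleton = candidates["probe_id"].map(carriers) < 2
    return _stamp(candidates[singleton], "singleton").reset_index(drop=True)


def male_x_het_filter(candidates: pd.DataFrame, sexes: dict[str, str]
                      ) -> pd.DataFrame:
    """Drop male X-chromosome heterozygote calls (likely false positives);
    relabel male X homozygous-alt calls hemizygous.  Candidates of samples
    with ambiguous sex are retained but flagged for review."""
    sex = candidates["sample_id"].map(sexes).fillna("ambiguous")
    on_x = candidates["chromosome"] == "X"
    drop = (sex == "male") & on_x & (candidates["zygosity"] == "het")
    out = candidates[~drop].copy()
    sex = sex[~drop]
    hemi = (sex == "male") & (out["chromosome"] == "X") \
        & (out["zygosity"] == "hom")
    out.loc[hemi, "zygosity"] = "hemizygous"
    out.loc[(sex == "ambiguous") & (out["chromosome"] == "X"),
            "flagged_for_review"] = True
    return _stamp(out, "male_x_het").reset_index(drop=True)


def cluster_quality_check(candidates: pd.DataFrame, model: ClusterModel,
                          run: IntensityRun, calls: GenotypeMatrix,
                          k: float = DEFAULT_CLUSTER_K) -> pd.DataFrame:
    """Automated stand-in for manual SNP-graph review.

    A candidate is excluded when its angle lies more than ``k`` effective
    cluster spreads from the called cluster center (the effective spread is
    floored at the canonical cluster width: a cluster fitted to one or two
    carriers has no usable spread estimate), or when its total intensity is
    a dropout — below the probe's cohort 5th percentile *and* well below
    the probe median.  Borderline points are flagged for review instead.
    """
    if candidates.empty:
        return _stamp(candidates, "cluster_ok")
    angles, totals = polar_transform(run.x, run.y)
    p_idx = {p: i for i, p in enumerate(run.probe_ids)}
    s_idx = {s: i for i, s in enumerate(run.sample_ids)}
    m_idx = {p: i for i, p in enumerate(model.probe_ids)}
    c_pidx = {p: i for i, p in enumerate(calls.probe_ids)}
    c_sidx = {s: i for i, s in enumerate(calls.sample_ids)}

    keep = np.ones(len(candidates), dtype=bool)
    flag = candidates["flagged_for_review"].to_numpy().copy()
    gt_of_zyg = {"het": 1}
    for i, row in enumerate(candidates.itertuples(index=False)):
        pj, sj = p_idx[row.probe_id], s_idx[row.sample_id]
        mj = m_idx[row.probe_id]
        called = calls.calls[c_sidx[row.sample_id], c_pidx[row.probe_id]]
        cluster = int(called) if called >= 0 else gt_of_zyg.get(row.zygosity, 2)
        a = angles[sj, pj]
        d = abs(a - model.centers[mj, cluster])
        spread = max(model.spreads[mj, cluster], DEFAULT_SPREAD)
        col = totals[:, pj]
        ok_col = col[~np.isnan(col)]
        p5, p10 = np.percentile(ok_col, [5, 10])
        med = np.median(ok_col)
        tot = totals[sj, pj]
        # a dropout sits in the low tail AND far below the probe's typical
        # signal; the bottom of a healthy intensity distribution does not
        dropout = tot < p5 * (1 - 1e-9) and tot < 0.6 * med
        weak = tot < p10 * (1 - 1e-9) and tot < 0.75 * med
        if d > k * spread or dropout:
            keep[i] = False
        elif d > (k - 1) * spread or weak:
            flag[i] = True
    out = candidates[keep].copy()
    out["flagged_for_review"] = flag[keep]
    return _stamp(out, "cluster_ok").reset_index(drop=True)


def match_inheritance(candidates: pd.DataFrame, annotation: VariantAnnotation,
                      sexes: dict[str, str], patient_ids
                      ) -> tuple[dict[str, str], pd.DataFrame]:
    """Per-patient diagnosis from surviving variants vs inheritance pattern.

    AD gene: any non-reference variant; AR gene: a homozygote, or two
    distinct heterozygous variants in the same gene (assumed in trans);
    XL gene: a hemizygous male or homozygous female.
    """
    ann = annotation.lookup(candidates["probe_id"])
    cand = candidates.assign(inheritance=ann["inheritance"].to_numpy())
    statuses = {p: "no_diagnosis" for p in patient_ids}
    rows = []
    for (sid, gene), grp in cand.groupby(["sample_id", "gene"], sort=True):
        if sid not in statuses or gene == "":
            continue
        inh = grp["inheritance"].iloc[0]
        zyg = grp["zygosity"]
        diagnosed = False
        if inh == "AD":
            diagnosed = len(grp) >= 1
        elif inh == "AR":
            diagnosed = (zyg == "hom").any() or (zyg == "het").sum() >= 2
        elif inh == "XL":
            sex = sexes.get(sid, "ambiguous")
            diagnosed = ((zyg == "hemizygous").any()
                         or ((zyg == "hom").any() and sex == "female"))
        if diagnosed:
            statuses[sid] = "genetic_diagnosis"
            for r in grp.itertuples(index=False):
                rows.append((sid, gene, inh, r.probe_id, r.zygosity))
    detail = pd.DataFrame(rows, columns=["sample_id", "gene", "inheritance",
                                         "probe_id", "zygosity"])
    return statuses, detail


@dataclass
class CascadeResult:
    candidates: pd.DataFrame
    attrition: dict[str, int]
    statuses: dict[str, str]
    diagnostic_variants: pd.DataFrame
    n_unannotated_dropped: int


def run_snv_cascade(calls: GenotypeMatrix, manifest: ProbeManifest,
                    annotation: VariantAnnotation, sexes: dict[str, str],
                    model: ClusterModel, run: IntensityRun, patient_ids,
                    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
                    cluster_k: float = DEFAULT_CLUSTER_K) -> CascadeResult:
    """Apply the full cascade and match inheritance; records attrition."""
    cands = extract_candidates(calls, manifest)
    attrition = {"nonref_calls": len(cands)}
    cands, n_unannot = select_disease_causing(cands, annotation)
    attrition["disease_causing"] = len(cands)
    cands = frequency_filter(cands, annotation, cutoff=freq_cutoff)
    attrition["rare"] = len(cands)
    cands = recurrence_filter(cands)
    attrition["singleton"] = len(cands)
    cands = male_x_het_filter(cands, sexes)
    attrition["male_x_het"] = len(cands)
    cands = cluster_quality_check(cands, model, run, calls, k=cluster_k)
    attrition["cluster_ok"] = len(cands)
    statuses, detail = match_inheritance(cands, annotation, sexes, patient_ids)
    return CascadeResult(cands, attrition, statuses, detail, n_unannot)
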