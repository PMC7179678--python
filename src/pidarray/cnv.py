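"""Copy-number screening from log-R-ratio (LRR) and B-allele frequency (BAF).

LRR = log2(total intensity / cohort median at the probe) proxies copy
number; BAF is the normalised allelic fraction anchored at the fitted
AA/AB/BB cluster angles.  Small events come from change-point segmentation
of LRR (binary segmentation) with threshold classification; whole-chromosome
aneuploidy and runs of homozygosity (LCSH) are detected from chromosome-wide
LRR/BAF patterns.  Filters: disease-gene overlap, known-benign-CNV overlap
(0% tolerance for heterozygous events), and a once-in-the-cohort frequency
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import ClusterModel, GenotypeMatrix, polar_transform
from .manifest import AUTOSOMES, BenignCnvTrack, ProbeManifest
from .simulate import IntensityRun

EVENT_CLASSES = ("single_loss", "double_loss", "single_gain", "double_gain",
                 "lcsh", "trisomy", "monosomy")
HET_EVENTS = frozenset({"single_loss", "single_gain"})


@dataclass(frozen=True)
class CnvCallingParams:
    significance_p: float = 5e-6
    min_probes: int = 4
    max_probe_spacing_bp: int = 1_000_000
    log2_single_loss: float = -0.3
    log2_double_loss: float = -1.1
    log2_single_gain: float = 0.2
    log2_double_gain: float = 0.7
    het_known_overlap: float = 0.0
    # LCSH calling
    min_lcsh_bp: int = 5_000_000
    min_lcsh_probes: int = 50
    lcsh_error_interval: int = 50       # one miscall tolerated per this many
    # aneuploidy: fraction of the ideal LRR shift that must be reached
    aneuploidy_tolerance: float = 0.5
    # frequency filter: reciprocal overlap defining "the same CNV"
    reciprocal_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if not (self.log2_double_loss < self.log2_single_loss < 0
                < self.log2_single_gain < self.log2_double_gain):
            raise ValueError("log2 thresholds must be ordered "
                             "double_loss < single_loss < 0 < single_gain "
                             "< double_gain")


@dataclass
class BafLrrTrack:
    """Per-sample LRR/BAF matrices aligned with manifest probe order."""

    sample_ids: np.ndarray
    probe_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    lrr: np.ndarray   # NaN where unmeasured
    baf: np.ndarray   # NaN where unmeasured or uninformative


def compute_lrr_baf(run: IntensityRun, model: ClusterModel,
                    manifest: ProbeManifest) -> BafLrrTrack:
    """LRR against the cohort median total per probe; BAF by piecewise-linear
    interpolation of the angle between the fitted cluster centers."""
    angles, total = polar_transform(run.x, run.y)
    info = manifest.positions_of(run.probe_ids)
    expected = model.median_total
    with np.errstate(invalid="ignore", divide="ignore"):
        lrr = np.log2(total / expected[None, :])
    lrr = np.where(total > 0, lrr, np.nan)

    c = model.centers
    baf = np.empty_like(angles)
    lo, mid, hi = c[:, 0][None], c[:, 1][None], c[:, 2][None]
    below = angles <= mid
    with np.errstate(invalid="ignore", divide="ignore"):
        baf_lo = 0.5 * (angles - lo) / np.maximum(mid - lo, 1e-9)
        baf_hi = 0.5 + 0.5 * (angles - mid) / np.maximum(hi - mid, 1e-9)
    baf = np.where(below, baf_lo, baf_hi)
    baf = np.clip(baf, 0.0, 1.0)
    baf = np.where(np.isnan(angles), np.nan, baf)

    return BafLrrTrack(run.sample_ids, run.probe_ids,
                       info["chromosome"].to_numpy(),
                       info["position"].to_numpy(), lrr, baf)


def robust_noise_sd(lrr_row: np.ndarray) -> float:
    """Per-sample LRR noise: scaled MAD about the median (CNVs barely move
    it because they cover few probes)."""
    v = lrr_row[~np.isnan(lrr_row)]
    if len(v) < 10:
        return np.nan
    mad = np.median(np.abs(v - np.median(v)))
    return float(max(1.4826 * mad, 1e-6))


def _binary_segmentation(values: np.ndarray, sigma: float,
                         z_crit: float, min_len: int) -> list[tuple[int, int]]:
    """Recursive mean-shift change-point splits on a 1-D series.

    A split is accepted when the two-sample z statistic of the means exceeds
    ``z_crit``.  Returns half-open index intervals.
    """
    out: list[tuple[int, int]] = []
    stack = [(0, len(values))]
    while stack:
        a, b = stack.pop()
        n = b - a
        if n < 2 * 1:
            out.append((a, b))
            continue
        seg = values[a:b]
        csum = np.cumsum(seg)
        total = csum[-1]
        k = np.arange(1, n)
        mean_l = csum[:-1] / k
        mean_r = (total - csum[:-1]) / (n - k)
        z = np.abs(mean_l - mean_r) / (sigma * np.sqrt(1.0 / k + 1.0 / (n - k)))
        best = int(np.argmax(z))
        if z[best] > z_crit and 0 < best + 1 < n:
            stack.append((a, a + best + 1))
            stack.append((a + best + 1, b))
        else:
            out.append((a, b))
    return sorted(out)


def _classify(mean_log2: float, p: CnvCallingParams) -> str | None:
    if mean_log2 <= p.log2_double_loss:
        return "double_loss"
    if mean_log2 <= p.log2_single_loss:
        return "single_loss"
    if mean_log2 >= p.log2_double_gain:
        return "double_gain"
    if mean_log2 >= p.log2_single_gain:
        return "single_gain"
    return None


def segment(track: BafLrrTrack,
            params: CnvCallingParams = CnvCallingParams()) -> pd.DataFrame:
    """Segment each sample's LRR per chromosome and call threshold-crossing
    events.

    Adjacent probes farther apart than ``max_probe_spacing_bp`` can never
    share a segment.  A candidate segment becomes an event when it has at
    least ``min_probes`` probes, its mean log2 crosses a class threshold,
    and the two-sided Gaussian p-value of its mean against the sample's
    robust noise null is below ``significance_p``.
    """
    z_crit = float(stats.norm.isf(params.significance_p / 2))
    rows = []
    for si, sid in enumerate(track.sample_ids):
        sigma = robust_noise_sd(track.lrr[si])
        if np.isnan(sigma):
            continue
        for chrom in pd.unique(track.chromosomes):
            cmask = track.chromosomes == chrom
            pos = track.positions[cmask]
            vals = track.lrr[si, cmask]
            ok = ~np.isnan(vals)
            pos, vals = pos[ok], vals[ok]
            if len(vals) < params.min_probes:
                continue
            # hard breaks at over-long probe gaps
            gaps = np.flatnonzero(np.diff(pos) > params.max_probe_spacing_bp)
            blocks = np.split(np.arange(len(vals)), gaps + 1)
            for block in blocks:
                if len(block) < params.min_probes:
                    continue
                v = vals[block]
                for a, b in _binary_segmentation(v, sigma, z_crit,
                                                 params.min_probes):
                    n = b - a
                    if n < params.min_probes:
                        continue
                    m = float(v[a:b].mean())
                    event = _classify(m, params)
                    if event is None:
                        continue
                    zstat = abs(m) * np.sqrt(n) / sigma
                    pval = float(2 * stats.norm.sf(zstat))
                    if pval >= params.significance_p:
                        continue
                    idx = block[a:b]
                    rows.append((sid, chrom, int(pos[idx[0]]),
                                 int(pos[idx[-1]]) + 1, n, m, event, pval))
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "start",
                                       "end", "n_probes", "mean_log2",
                                       "event", "p_value"])


def detect_aneuploidy(track: BafLrrTrack,
                      params: CnvCallingParams = CnvCallingParams()
                      ) -> pd.DataFrame:
    """Whole-chromosome trisomy/monosomy from chromosome-wide LRR medians
    and the heterozygote BAF band pattern.

    Trisomy: median LRR at least ``tolerance`` of log2(3/2) with the het
    band split towards 1/3 and 2/3.  Monosomy: median LRR at most
    ``tolerance`` of log2(1/2) with the het band absent.  Conflicting
    evidence yields an event flagged discordant.
    """
    tri_lrr = params.aneuploidy_tolerance * np.log2(3 / 2)
    mono_lrr = params.aneuploidy_tolerance * np.log2(1 / 2)
    rows = []
    for si, sid in enumerate(track.sample_ids):
        for chrom in pd.unique(track.chromosomes):
            if chrom not in AUTOSOMES:
                continue
            cmask = track.chromosomes == chrom
            lrr = track.lrr[si, cmask]
            baf = track.baf[si, cmask]
            lrr = lrr[~np.isnan(lrr)]
            baf = baf[~np.isnan(baf)]
            if len(lrr) < 30 or len(baf) < 30:
                continue
            med = float(np.median(lrr))
            informative = baf[(baf > 0.15) & (baf < 0.85)]
            n_inf = len(informative)
            central = float(np.mean((informative > 0.44)
                                    & (informative < 0.56))) if n_inf else 0.0
            split = float(np.mean(((informative > 0.2) & (informative < 0.44))
                                  | ((informative > 0.56)
                                     & (informative < 0.8)))) if n_inf else 0.0
            het_frac = n_inf / len(baf)

            lrr_tri = med >= tri_lrr
            lrr_mono = med <= mono_lrr
            baf_tri = n_inf >= 10 and split > central
            baf_mono = het_frac < 0.05
            if lrr_tri or (baf_tri and n_inf >= 10 and med > 0):
                rows.append((sid, chrom, "trisomy", med, het_frac,
                             not (lrr_tri and baf_tri)))
            elif lrr_mono or (baf_mono and med < mono_lrr / 2):
                rows.append((sid, chrom, "monosomy", med, het_frac,
                             not (lrr_mono and baf_mono)))
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "event",
                                       "median_lrr", "het_fraction",
                                       "discordant"])


def detect_lcsh(track: BafLrrTrack, calls: GenotypeMatrix,
                params: CnvCallingParams = CnvCallingParams(),
                min_informative_het_rate: float = 0.05) -> pd.DataFrame:
    """Runs of homozygosity at normal copy number.

    Scans informative probes (cohort het rate above a floor) for maximal
    runs of homozygous calls (|BAF - 0.5| > 0.4), tolerating one discordant
    probe per ``lcsh_error_interval`` probes, and requires normal mean LRR
    to separate LCSH from deletion.
    """
    p_idx = {p: i for i, p in enumerate(track.probe_ids)}
    call_cols = np.array([p_idx.get(p, -1) for p in calls.probe_ids])
    het_rate = (calls.calls == 1).sum(axis=0) / np.maximum(
        (calls.calls >= 0).sum(axis=0), 1)
    informative_track = np.zeros(len(track.probe_ids), dtype=bool)
    valid = call_cols >= 0
    informative_track[call_cols[valid]] = het_rate[valid] >= \
        min_informative_het_rate

    s_idx = {s: i for i, s in enumerate(calls.sample_ids)}
    rows = []
    for ti, sid in enumerate(track.sample_ids):
        if sid not in s_idx:
            continue
        ci = s_idx[sid]
        # per-probe hom indicator on the track frame
        hom = np.full(len(track.probe_ids), -1, dtype=np.int8)  # -1 unknown
        call_row = np.full(len(track.probe_ids), -2, dtype=np.int8)
        call_row[call_cols[valid]] = calls.calls[ci][valid]
        baf_row = track.baf[ti]
        measurable = informative_track & (call_row >= 0) \
            & ~np.isnan(baf_row)
        hom_mask = measurable & (np.abs(baf_row - 0.5) > 0.4) \
            & (call_row != 1)
        het_mask = measurable & ~hom_mask

        for chrom in pd.unique(track.chromosomes):
            if chrom not in AUTOSOMES:
                continue  # hemizygous male X would read as one long run
            cmask = track.chromosomes == chrom
            idx = np.flatnonzero(cmask & measurable)
            if len(idx) < params.min_lcsh_probes:
                continue
            states = hom_mask[idx]  # True hom, False het/err
            pos = track.positions[idx]
            runs = _error_tolerant_runs(states, params.lcsh_error_interval)
            for a, b in runs:
                n = b - a
                span_start, span_end = int(pos[a]), int(pos[b - 1]) + 1
                if n < params.min_lcsh_probes or \
                        span_end - span_start < params.min_lcsh_bp:
                    continue
                seg_lrr = track.lrr[ti, idx[a:b]]
                seg_lrr = seg_lrr[~np.isnan(seg_lrr)]
                mean_lrr = float(seg_lrr.mean()) if len(seg_lrr) else np.nan
                # normal copy number required: not a deletion or gain
                if not (params.log2_single_loss < mean_lrr
                        < params.log2_single_gain):
                    continue
                rows.append((sid, chrom, span_start, span_end, n, mean_lrr,
                             "lcsh"))
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "start",
                                       "end", "n_probes", "mean_log2",
                                       "event"])


def _error_tolerant_runs(is_hom: np.ndarray, error_interval: int
                         ) -> list[tuple[int, int]]:
    """Maximal runs of True allowing one False per ``error_interval``
    elements of run length; runs are trimmed to end on True."""
    runs = []
    n = len(is_hom)
    i = 0
    while i < n:
        if not is_hom[i]:
            i += 1
            continue
        j = i
        errors = 0
        last_true = i
        while j < n:
            if is_hom[j]:
                last_true = j
            else:
                allowed = 1 + (last_true - i + 1) // error_interval
                if errors + 1 > allowed:
                    break
                errors += 1
            j += 1
        runs.append((i, last_true + 1))
        i = last_true + 1
    return runs


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def filter_cnvs(segments: pd.DataFrame, gene_track: pd.DataFrame,
                benign: BenignCnvTrack,
                params: CnvCallingParams = CnvCallingParams()) -> pd.DataFrame:
    """Disease-gene overlap, benign-track and cohort-frequency filters.

    Heterozygous (single-copy-change) events are dropped on any overlap
    (> ``het_known_overlap``, default 0%) with the known-benign track;
    homozygous/double events are exempt.  Events whose reciprocal-overlap
    match recurs in two or more samples are dropped as probe artifacts.
    """
    if segments.empty:
        return segments.copy()
    seg = segments.reset_index(drop=True)

    def hits_gene(r) -> bool:
        g = gene_track
        hit = ((g["chromosome"] == r.chromosome)
               & (g["start"] < r.end) & (g["end"] > r.start))
        return bool(hit.any())

    keep = np.array([hits_gene(r) for r in seg.itertuples(index=False)])
    seg = seg[keep].reset_index(drop=True)
    if seg.empty:
        return seg

    def benign_frac(r) -> float:
        d = benign.df
        hit = d[(d["chromosome"] == r.chromosome)
                & (d["start"] < r.end) & (d["end"] > r.start)]
        if hit.empty:
            return 0.0
        inter = (np.minimum(hit["end"], r.end)
                 - np.maximum(hit["start"], r.start)).clip(lower=0).sum()
        return float(inter / (r.end - r.start))

    keep = []
    for r in seg.itertuples(index=False):
        if r.event in HET_EVENTS:
            keep.append(benign_frac(r) <= params.het_known_overlap)
        else:
            keep.append(True)
    seg = seg[np.array(keep, dtype=bool)].reset_index(drop=True)
    if seg.empty:
        return seg

    # cohort frequency: the same event (same class, reciprocal overlap) in
    # >= 2 samples is a probe artifact
    drop = np.zeros(len(seg), dtype=bool)
    for i in range(len(seg)):
        ri = seg.iloc[i]
        carriers = {ri["sample_id"]}
        for j in range(len(seg)):
            if i == j:
                continue
            rj = seg.iloc[j]
            if rj["event"] != ri["event"] or \
                    rj["chromosome"] != ri["chromosome"]:
                continue
            ov = _reciprocal_overlap(ri["start"], ri["end"],
                                     rj["start"], rj["end"])
            if ov >= params.reciprocal_overlap:
                carriers.add(rj["sample_id"])
        if len(carriers) >= 2:
            drop[i] = True
    return seg[~drop].reset_index(drop=True)
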