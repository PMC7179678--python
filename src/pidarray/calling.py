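"""Genotype calling from two-channel array intensities.

Two stages, mirroring standard array practice:

1. *Primary* cluster-based calling.  Each probe's samples are transformed to
   polar coordinates (normalised angle = (2/pi)*arctan(y/x), total = x + y);
   a three-component 1-D Gaussian mixture is fitted on the angle axis and
   each sample is assigned to the nearest cluster with a confidence score.
2. *Rare-variant recalling* (zCall-style).  Rare probes have too few minor-
   allele carriers to fit a heterozygote cluster, so primary calling tends
   to no-call true heterozygotes.  Recalling derives per-channel decision
   thresholds from the homozygote cluster statistics (mean + z * sd of the
   null channel) and rescues no-calls that exceed them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

GT_CODE = {"AA": 0, "AB": 1, "BB": 2, "nocall": -1}
GT_NAME = {v: k for k, v in GT_CODE.items()}
CALLER_PRIMARY = 0
CALLER_RECALLED = 1

#: canonical normalised-angle positions for the AA / AB / BB clusters
CANONICAL_CENTERS = np.array([0.05, 0.5, 0.95])
DEFAULT_SPREAD = 0.05
MIN_SPREAD = 0.01
DEFAULT_NOCALL_THRESHOLD = 0.15
DEFAULT_ZCALL_Z = 7.0
RARE_MINOR_OCCUPANCY = 5
MIN_SAMPLES_FOR_FIT = 10


@dataclass
class GenotypeMatrix:
    """Dense called genotypes: ``calls`` int8 (samples x probes) with
    AA=0 AB=1 BB=2 nocall=-1; ``scores`` NaN exactly where nocall;
    ``caller`` 0=primary 1=recalled."""

    sample_ids: np.ndarray
    probe_ids: np.ndarray
    calls: np.ndarray
    scores: np.ndarray
    caller: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.probe_ids = np.asarray(self.probe_ids)
        shape = (len(self.sample_ids), len(self.probe_ids))
        if self.calls.shape != shape:
            raise ValueError(f"calls shape {self.calls.shape} != {shape}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def subset(self, sample_mask=None, probe_mask=None) -> "GenotypeMatrix":
        s = np.ones(self.n_samples, bool) if sample_mask is None else sample_mask
        p = np.ones(self.n_probes, bool) if probe_mask is None else probe_mask
        return GenotypeMatrix(
            self.sample_ids[s], self.probe_ids[p],
            self.calls[np.ix_(s, p)], self.scores[np.ix_(s, p)],
            self.caller[np.ix_(s, p)])

    def sample_index(self, sample_ids) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lut[s] for s in sample_ids])

    def probe_index(self, probe_ids) -> np.ndarray:
        lut = {p: i for i, p in enumerate(self.probe_ids)}
        return np.array([lut[p] for p in probe_ids])


def polar_transform(x, y):
    """Map channel intensities to (normalised angle in [0,1], total).

    angle = (2/pi) * arctan(y / x); points with x = y = 0 are unmeasured and
    get angle = NaN (downstream: no-call).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("channel intensities must be non-negative")
    total = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        angle = (2.0 / np.pi) * np.arctan2(y, x)
    angle = np.where(total > 0, angle, np.nan)
    return angle, total


@dataclass
class ClusterModel:
    """Per-probe three-cluster model on the angle axis plus the homozygote
    channel statistics needed for zCall-style recalling.

    Arrays are (n_probes, 3) for per-cluster quantities, ordered AA < AB < BB
    on the angle axis.  Clusters with no occupants are *imputed* at the
    canonical centers.  ``aa_y_mean/sd`` describe the null (B) channel of the
    AA cluster; ``bb_x_mean/sd`` the null (A) channel of the BB cluster;
    missing homozygote clusters inherit the observed one's null-channel
    statistics by symmetry of the two-colour chemistry.
    """

    probe_ids: np.ndarray
    centers: np.ndarray       # (P, 3) angles
    spreads: np.ndarray       # (P, 3) angular sd, >= MIN_SPREAD
    counts: np.ndarray        # (P, 3) hard-assignment occupancy
    imputed: np.ndarray       # (P, 3) bool
    median_total: np.ndarray  # (P,) cohort median total intensity
    aa_y_mean: np.ndarray
    aa_y_sd: np.ndarray
    bb_x_mean: np.ndarray
    bb_x_sd: np.ndarray
    callable: np.ndarray      # (P,) bool: enough measurable samples to fit

    def rare_probes(self, min_minor: int = RARE_MINOR_OCCUPANCY) -> np.ndarray:
        """Probes whose minor-cluster occupancy is below ``min_minor`` —
        the regime where recalling is applied."""
        major = self.counts.max(axis=1)
        minor = self.counts.sum(axis=1) - major
        return self.callable & (minor < min_minor)


def _em_fit(angles: np.ndarray, n_iter: int = 20):
    """Vectorised 3-component 1-D EM across probes.

    ``angles``: (n_samples, n_probes) with NaN for unmeasured points.
    Returns means, sds, weights, responsibilities-argmax assignments.
    """
    n_s, n_p = angles.shape
    obs = ~np.isnan(angles)
    a = np.where(obs, angles, 0.0)

    mu = np.tile(CANONICAL_CENTERS[:, None], (1, n_p))          # (3, P)
    sd = np.full((3, n_p), 0.08)
    w = np.full((3, n_p), 1.0 / 3.0)

    for _ in range(n_iter):
        # E step: responsibilities (3, S, P)
        z = (a[None] - mu[:, None]) / sd[:, None]
        log_pdf = -0.5 * z**2 - np.log(sd[:, None]) + np.log(w[:, None])
        log_pdf = np.where(obs[None], log_pdf, -np.inf)
        m = log_pdf.max(axis=0, keepdims=True)
        with np.errstate(invalid="ignore"):
            r = np.exp(log_pdf - m)
        tot = r.sum(axis=0, keepdims=True)
        r = np.where(obs[None], r / np.where(tot > 0, tot, 1.0), 0.0)

        # M step
        nk = r.sum(axis=1)                                       # (3, P)
        safe = np.where(nk > 0, nk, 1.0)
        mu_new = (r * a[None]).sum(axis=1) / safe
        var = (r * (a[None] - mu_new[:, None])**2).sum(axis=1) / safe
        mu = np.where(nk > 0, mu_new, mu)
        sd = np.where(nk > 0, np.sqrt(np.maximum(var, MIN_SPREAD**2)), sd)
        w = np.maximum(nk, 1e-3)
        w = w / w.sum(axis=0, keepdims=True)

        # ordering constraint: components stay AA < AB < BB on the angle axis
        order = np.argsort(mu, axis=0)
        mu = np.take_along_axis(mu, order, axis=0)
        sd = np.take_along_axis(sd, order, axis=0)
        w = np.take_along_axis(w, order, axis=0)

    # hard assignment for occupancy
    z = (a[None] - mu[:, None]) / sd[:, None]
    log_pdf = -0.5 * z**2 - np.log(sd[:, None]) + np.log(w[:, None])
    assign = np.argmax(log_pdf, axis=0)                          # (S, P)
    assign = np.where(obs, assign, -1)
    return mu, sd, w, assign


def fit_clusters(x: np.ndarray, y: np.ndarray, probe_ids,
                 min_samples: int = MIN_SAMPLES_FOR_FIT) -> ClusterModel:
    """Fit per-probe cluster models from channel matrices (samples x probes).

    Probes with fewer than ``min_samples`` measurable samples are flagged
    uncallable.  Empty clusters (e.g. no BB carriers at a rare variant) are
    imputed at the canonical centers with the default spread.
    """
    angles, total = polar_transform(x, y)
    obs = ~np.isnan(angles)
    n_obs = obs.sum(axis=0)
    callable_ = n_obs >= min_samples

    mu, sd, _w, assign = _em_fit(angles)
    raw_counts = np.stack([(assign == k).sum(axis=0) for k in range(3)], axis=1)

    # Components carry no genotype identity by themselves: merge components
    # that collapsed onto one cluster, map each observed cluster to the
    # genotype slot whose canonical center it is nearest, and impute the
    # empty slots at the canonical positions.
    n_p = angles.shape[1]
    centers = np.tile(CANONICAL_CENTERS, (n_p, 1))
    spreads = np.full((n_p, 3), DEFAULT_SPREAD)
    counts = np.zeros((n_p, 3), dtype=int)
    imputed = np.ones((n_p, 3), dtype=bool)
    # components closer than half the canonical cluster spacing describe the
    # same genotype cluster
    merge_tol = (CANONICAL_CENTERS[1] - CANONICAL_CENTERS[0]) / 2
    for j in range(n_p):
        comps = [(mu[k, j], sd[k, j], raw_counts[j, k])
                 for k in range(3) if raw_counts[j, k] > 0]
        comps.sort()
        merged: list[list[float]] = []
        for m, s, c in comps:
            if merged and m - merged[-1][0] < merge_tol:
                pm, ps, pc = merged[-1]
                tot = pc + c
                merged[-1] = [(pm * pc + m * c) / tot, max(ps, s), tot]
            else:
                merged.append([m, s, c])
        if not merged:
            continue
        k = len(merged)
        best, best_cost = None, np.inf
        for slots in combinations(range(3), k):
            cost = sum(abs(merged[i][0] - CANONICAL_CENTERS[slots[i]])
                       for i in range(k))
            if cost < best_cost:
                best, best_cost = slots, cost
        for i, slot in enumerate(best):
            centers[j, slot] = merged[i][0]
            spreads[j, slot] = max(merged[i][1], MIN_SPREAD)
            counts[j, slot] = merged[i][2]
            imputed[j, slot] = False

    # re-assign samples to genotype slots by nearest center (occupancy and
    # channel statistics must refer to slots, not raw EM components)
    d_slot = np.abs(angles[:, :, None] - centers[None])
    assign = np.argmin(d_slot, axis=2)
    assign = np.where(obs, assign, -1)
    counts = np.stack([(assign == k).sum(axis=0) for k in range(3)], axis=1)

    med_total = np.where(n_obs > 0,
                         np.nanmedian(np.where(obs, total, np.nan), axis=0),
                         np.nan)

    def _null_channel_stats(channel, cluster):
        """mean/sd of the null channel over members of a homozygote cluster."""
        member = (assign == cluster) & obs
        n = member.sum(axis=0)
        safe_n = np.maximum(n, 1)
        vals = np.where(member, channel, 0.0)
        mean = vals.sum(axis=0) / safe_n
        var = (np.where(member, (channel - mean[None]) ** 2, 0.0).sum(axis=0)
               / safe_n)
        mean = np.where(n > 0, mean, np.nan)
        sdev = np.where(n > 1, np.sqrt(var), np.nan)
        return mean, sdev

    aa_y_mean, aa_y_sd = _null_channel_stats(np.asarray(y, float), 0)
    bb_x_mean, bb_x_sd = _null_channel_stats(np.asarray(x, float), 2)

    # symmetry imputation: a missing homozygote cluster inherits the observed
    # one's null-channel statistics (two-colour chemistry is symmetric)
    bb_x_mean = np.where(np.isnan(bb_x_mean), aa_y_mean, bb_x_mean)
    bb_x_sd = np.where(np.isnan(bb_x_sd), aa_y_sd, bb_x_sd)
    aa_y_mean = np.where(np.isnan(aa_y_mean), bb_x_mean, aa_y_mean)
    aa_y_sd = np.where(np.isnan(aa_y_sd), bb_x_sd, aa_y_sd)
    # degenerate spread floor: fraction of the cluster mean signal
    floor = 0.01 * np.fmax(aa_y_mean, bb_x_mean)
    floor = np.where(np.isnan(floor), 1e-6, np.maximum(floor, 1e-6))
    aa_y_sd = np.where(np.isnan(aa_y_sd) | (aa_y_sd <= 0), floor, aa_y_sd)
    bb_x_sd = np.where(np.isnan(bb_x_sd) | (bb_x_sd <= 0), floor, bb_x_sd)

    return ClusterModel(np.asarray(probe_ids), centers, spreads, counts,
                        imputed, med_total, aa_y_mean, aa_y_sd,
                        bb_x_mean, bb_x_sd, callable_)


def primary_call(model: ClusterModel, x: np.ndarray, y: np.ndarray,
                 sample_ids,
                 nocall_threshold: float = DEFAULT_NOCALL_THRESHOLD
                 ) -> GenotypeMatrix:
    """Assign each point to the nearest cluster on the angle axis.

    The confidence score is 1 at the cluster center and falls linearly to 0
    at the decision boundary (midpoint to the adjacent center); calls with
    score below ``nocall_threshold`` become no-calls, as do unmeasured
    points and all points at uncallable probes.
    """
    angles, _total = polar_transform(x, y)
    c = model.centers                                  # (P, 3)
    d = np.abs(angles[:, :, None] - c[None])           # (S, P, 3)
    nearest = np.argmin(d, axis=2)                     # (S, P)
    d_center = np.take_along_axis(d, nearest[:, :, None], axis=2)[:, :, 0]

    # half-width of the called cluster: distance from its center to the
    # nearer decision boundary with an adjacent cluster
    mid_lo = (c[:, 0] + c[:, 1]) / 2                   # AA|AB boundary
    mid_hi = (c[:, 1] + c[:, 2]) / 2                   # AB|BB boundary
    half = np.empty(c.shape)
    half[:, 0] = mid_lo - c[:, 0]
    half[:, 1] = np.minimum(c[:, 1] - mid_lo, mid_hi - c[:, 1])
    half[:, 2] = c[:, 2] - mid_hi
    half = np.maximum(half, 1e-9)
    h = np.take_along_axis(half[None].repeat(angles.shape[0], 0),
                           nearest[:, :, None], axis=2)[:, :, 0]

    score = np.clip(1.0 - d_center / h, 0.0, 1.0)
    calls = nearest.astype(np.int8)
    nocall = (np.isnan(angles) | ~model.callable[None]
              | (score < nocall_threshold))
    calls[nocall] = -1
    score = np.where(nocall, np.nan, score)
    caller = np.zeros(calls.shape, dtype=np.int8)
    return GenotypeMatrix(np.asarray(sample_ids), model.probe_ids,
                          calls, score, caller)


def zcall_recall(model: ClusterModel, calls: GenotypeMatrix,
                 x: np.ndarray, y: np.ndarray,
                 z: float = DEFAULT_ZCALL_Z,
                 min_minor: int = RARE_MINOR_OCCUPANCY) -> GenotypeMatrix:
    """Rescue no-calls at rare probes using homozygote channel thresholds.

    Per probe, thresholds are set at (null-channel mean + z * sd) of each
    homozygote cluster: a point above both thresholds is a heterozygote;
    above exactly one, the corresponding homozygote; otherwise it stays a
    no-call.  Confident primary calls are never altered.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rare = model.rare_probes(min_minor)

    tx = model.bb_x_mean + z * model.bb_x_sd      # A-channel threshold
    ty = model.aa_y_mean + z * model.aa_y_sd      # B-channel threshold

    measurable = (x + y) > 0
    target = (calls.calls == -1) & measurable & rare[None] & model.callable[None]
    above_x = x > tx[None]
    above_y = y > ty[None]

    new_calls = calls.calls.copy()
    new_scores = calls.scores.copy()
    new_caller = calls.caller.copy()

    recall_ab = target & above_x & above_y
    recall_aa = target & above_x & ~above_y
    recall_bb = target & ~above_x & above_y
    new_calls[recall_ab] = 1
    new_calls[recall_aa] = 0
    new_calls[recall_bb] = 2
    recalled = recall_ab | recall_aa | recall_bb
    # nominal confidence for threshold-based calls: they carry no cluster
    # distance, so a fixed mid-scale score marks them as less certain
    new_scores[recalled] = 0.5
    new_caller[recalled] = CALLER_RECALLED

    return replace(calls, calls=new_calls, scores=new_scores,
                   caller=new_caller)
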