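"""Neural correlates of final-pitch prediction.

During the penultimate tone (pitch pinned at 440 Hz for every sequence),
windowed sensor activity is regressed onto the theoretically predicted final
pitch p34*; sensors where the group-level slope differs from zero form
"predictive processing" clusters (cluster-based permutation test, two-tailed).
Complementary views: the time course of the low- vs high-p34* ERF contrast
over the whole sequence, and an early-sensory spatial filter built from the
M100 evoked response (75-125 ms post tone onset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import butter, filtfilt

from . import cluster_perm
from .shi import WindowedActivity
from .synthetic_data import Recording

__all__ = [
    "PredictionRegression",
    "SpatialFilter",
    "TimeCourseContrast",
    "regress_prediction",
    "detect_predictive_clusters",
    "build_m100_filter",
    "erf_preprocess",
    "erf_contrast",
    "bin_activity_by_pstar",
]

PENULTIMATE = 33  # 1-based tone index carrying the prediction signal
M100_WINDOW = (0.075, 0.125)  # seconds post tone onset


@dataclass
class PredictionRegression:
    """Per-sensor/window OLS of tone-33 activity on p34* for one subject."""

    slope: np.ndarray  # (n_sensors, n_windows)
    intercept: np.ndarray
    resid_var: np.ndarray
    subject: int
    pstar: np.ndarray  # per-trial regressor actually used (Hz)


@dataclass
class SpatialFilter:
    """Nonnegative sensor weights summing to one (M100 contribution)."""

    weights: np.ndarray

    def apply(self, activity: np.ndarray, sensor_axis: int = 1) -> np.ndarray:
        """Weighted sum of (non-squared) sensor signals."""
        return np.tensordot(activity, self.weights, axes=([sensor_axis], [0]))


@dataclass
class TimeCourseContrast:
    """Group ERFs for low vs high p34* trials plus significant epochs."""

    erf_low: np.ndarray  # (n_samples,) group mean
    erf_high: np.ndarray
    times: np.ndarray  # seconds relative to sequence start
    sample_range: tuple[int, int]  # tested span (relative to `times`)
    clusters: list


def _slopes(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope/intercept of columns of y on x."""
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    slope = xc @ y / denom
    intercept = y.mean(axis=0) - slope * x.mean()
    return slope, intercept


def regress_prediction(
    wa: WindowedActivity,
    trials: pd.DataFrame,
    subject: int = 0,
    log_pstar: bool = False,
) -> PredictionRegression:
    """OLS of tone-33 windowed activity on p34* across trials.

    The regressor is p34* in Hz by default (``log_pstar`` switches to log
    Hz).  The pinned penultimate pitch itself is constant by design and
    therefore excluded.
    """
    sub = trials.set_index("trial_index").loc[wa.trial_index]
    x = sub["predicted_final"].to_numpy(dtype=float)
    if log_pstar:
        x = np.log(x)
    if np.ptp(x) == 0:
        raise ValueError("p34* is constant across trials: slope undefined")
    y = wa.data[:, :, PENULTIMATE - 1, :]  # (n_trials, S, W)
    n, s, w = y.shape
    slope, intercept = _slopes(y.reshape(n, s * w), x)
    resid = y.reshape(n, s * w) - np.outer(x, slope) - intercept
    return PredictionRegression(
        slope=slope.reshape(s, w),
        intercept=intercept.reshape(s, w),
        resid_var=resid.var(axis=0).reshape(s, w),
        subject=subject,
        pstar=x,
    )


def detect_predictive_clusters(
    was: list[WindowedActivity],
    trials: pd.DataFrame,
    adjacency,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    log_pstar: bool = False,
) -> dict[int, list[cluster_perm.ClusterResult]]:
    """Group predictive-processing clusters per time window.

    Per subject, per permutation, the across-trial pairing of activity and
    p34* is shuffled (identically for all sensors, independently across
    subjects) and the sensor-wise slope recomputed.  Group one-sample
    t-maps are thresholded at uncorrected p < alpha; same-sign connected
    clusters are scored by |sum t| against the pooled max-statistic null
    over all windows (two-tailed usage: report p, compare to alpha/2 tails
    via the 2.5th percentile convention at alpha = 0.05).
    """
    rng = np.random.default_rng(seed)
    n_subj = len(was)
    s, w = was[0].data.shape[1], was[0].data.shape[3]
    sw = s * w
    t_all = np.empty((n_perm + 1, n_subj, sw))
    for j, wa in enumerate(was):
        sub = trials.set_index("trial_index").loc[wa.trial_index]
        x = sub["predicted_final"].to_numpy(dtype=float)
        if log_pstar:
            x = np.log(x)
        n = len(x)
        y = wa.data[:, :, PENULTIMATE - 1, :].reshape(n, sw)
        perms = np.vstack([np.arange(n)] +
                          [rng.permutation(n) for _ in range(n_perm)])
        xp = x[perms]  # (n_perm+1, n)
        xc = xp - xp.mean(axis=1, keepdims=True)
        t_all[:, j, :] = (xc @ y) / (xc ** 2).sum(axis=1, keepdims=True)
    # group one-sample t over subjects, per permutation
    mean = t_all.mean(axis=1)
    sem = t_all.std(axis=1, ddof=1) / np.sqrt(n_subj)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(sem > 0, mean / sem, 0.0)
    pmap = 2 * stats.t.sf(np.abs(tmap), df=n_subj - 1)
    tmap = tmap.reshape(n_perm + 1, s, w)
    pmap = pmap.reshape(n_perm + 1, s, w)

    null_max = np.zeros(n_perm)
    for d in range(1, n_perm + 1):
        best = 0.0
        for wi in range(w):
            cs = cluster_perm.find_clusters(tmap[d, :, wi], pmap[d, :, wi],
                                            adjacency, signed=True,
                                            alpha=alpha)
            if cs:
                best = max(best, cs[0]["stat"])
        null_max[d - 1] = best
    out = {}
    for wi in range(w):
        cs = cluster_perm.find_clusters(tmap[0, :, wi], pmap[0, :, wi],
                                        adjacency, signed=True, alpha=alpha)
        out[wi] = cluster_perm.permutation_pvalues(cs, null_max, tail="two")
    return out


def build_m100_filter(rec: Recording) -> SpatialFilter:
    """Early-sensory spatial filter from the M100 evoked topography.

    The tone-locked ERF (averaged across all 34 tones and all trials) is
    squared and averaged over 75-125 ms post onset; sensor weights are the
    relative contributions, normalized to sum to one.
    """
    fs = rec.sample_rate
    a = int(round(M100_WINDOW[0] * fs))
    b = int(round(M100_WINDOW[1] * fs))
    n_samples = rec.activity.shape[2]
    segs = []
    for onset in rec.onset_samples:
        if onset + b <= n_samples:
            segs.append(rec.activity[:, :, onset + a:onset + b])
    erf = np.mean([s.mean(axis=0) for s in segs], axis=0)  # (S, win)
    power = (erf ** 2).mean(axis=1)
    total = power.sum()
    if total == 0:
        warnings.warn("all-zero M100 window: falling back to uniform weights")
        weights = np.full(rec.activity.shape[1], 1.0 / rec.activity.shape[1])
    else:
        weights = power / total
    return SpatialFilter(weights=weights)


def erf_preprocess(rec: Recording, lowpass_hz: float = 35.0,
                   order: int = 4) -> np.ndarray:
    """Zero-phase low-pass plus pre-sequence baseline correction.

    Returns trial-resolved activity filtered forward-backward with a
    Butterworth low-pass and baselined to the mean of the span preceding
    the first tone onset.
    """
    b, a = butter(order, lowpass_hz, fs=rec.sample_rate, btype="low")
    x = filtfilt(b, a, rec.activity.astype(np.float64), axis=2)
    base = x[:, :, : rec.onset_samples[0]].mean(axis=2, keepdims=True)
    return x - base


def erf_contrast(
    recs: list[Recording],
    trials: pd.DataFrame,
    target: np.ndarray | SpatialFilter,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    lowpass_hz: float = 35.0,
) -> TimeCourseContrast:
    """Low- vs high-p34* ERF contrast with temporal cluster correction.

    ``target`` is either a SpatialFilter (weighted sensor sum) or an array
    of cluster member sensor indices (plain mean).  Per subject the
    preprocessed trial ERFs are averaged within the low and high p34* trial
    groups; the paired differences are tested sample-wise (one-sample t
    across subjects) from the offset of the first tone to the start of the
    response window, with sign-flip permutations and contiguous-sample
    clusters.
    """
    rng = np.random.default_rng(seed)
    diffs, low_erfs, high_erfs = [], [], []
    for rec in recs:
        sub = trials.set_index("trial_index").loc[rec.trial_index]
        bins = sub["pstar_bin"].to_numpy()
        x = erf_preprocess(rec, lowpass_hz=lowpass_hz)
        if isinstance(target, SpatialFilter):
            ts = target.apply(x, sensor_axis=1)  # (n_trials, n_samples)
        else:
            ts = x[:, np.asarray(target, dtype=int), :].mean(axis=1)
        lo = ts[bins == "low"].mean(axis=0)
        hi = ts[bins == "high"].mean(axis=0)
        low_erfs.append(lo)
        high_erfs.append(hi)
        diffs.append(lo - hi)
    diffs = np.stack(diffs)  # (n_subj, n_samples)
    rec0 = recs[0]
    fs = rec0.sample_rate
    n_tone = rec0.onset_samples[1] - rec0.onset_samples[0]
    start = int(rec0.onset_samples[0] + n_tone)  # offset of the first tone
    stop = diffs.shape[1]  # through the gap preceding the response window
    seg = diffs[:, start:stop]
    n_subj, n_t = seg.shape

    signs = np.vstack([np.ones(n_subj)] +
                      [rng.choice([-1.0, 1.0], n_subj) for _ in range(n_perm)])
    # sign flips leave per-subject squares unchanged, so the permuted t-maps
    # follow from the flipped means and the fixed second moment
    m2 = (seg ** 2).mean(axis=0)
    mean = signs @ seg / n_subj
    var = (m2[None] - mean ** 2) * n_subj / (n_subj - 1)
    sem = np.sqrt(np.maximum(var, 0.0) / n_subj)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(sem > 0, mean / sem, 0.0)
    pmap = 2 * stats.t.sf(np.abs(tmap), df=n_subj - 1)
    chain = cluster_perm.chain_adjacency(n_t)
    clusters = cluster_perm.cluster_test(
        tmap[0], pmap[0], tmap[1:], pmap[1:], chain, signed=True,
        alpha=alpha, tail="two",
    )
    for c in clusters:  # report epochs relative to the recording
        c.members = c.members + start
    return TimeCourseContrast(
        erf_low=np.mean(low_erfs, axis=0),
        erf_high=np.mean(high_erfs, axis=0),
        times=(np.arange(diffs.shape[1]) - rec0.onset_samples[0]) / fs,
        sample_range=(start, stop),
        clusters=clusters,
    )


def bin_activity_by_pstar(wa: WindowedActivity,
                          trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Tone-33 activity averaged within low/medium/high p34* trial groups."""
    sub = trials.set_index("trial_index").loc[wa.trial_index]
    bins = sub["pstar_bin"].to_numpy()
    y = wa.data[:, :, PENULTIMATE - 1, :]
    return {b: y[bins == b].mean(axis=0) for b in ("low", "medium", "high")}
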