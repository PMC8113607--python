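"""Sensory-history integration (SHI): cross-validated k' estimation.

How many previous tone pitches explain windowed sensor activity?  Activity
N[s, w, i, n] (sensor, 50-ms window, tone, trial) during the second half of
a sequence (tones 16..32) is regressed onto the pitch of the current tone
and k' preceding tones,

    N = b0 + sum_{k=0}^{k'} b_{k+1} p_{i-k} + eps,    k' = 0..15,

and the winning k' is chosen by six-fold cross-validated test SSE, then
averaged across folds.  The null re-estimates k' after shuffling tone order
within each unique sequence in the training folds only (the current tone's
pitch is kept), 100 repetitions, preserving shuffle order across tone
duration conditions.

Implementation note: all 16 nested models over all (sensor, window) cells
are scored from per-sequence Gram matrices, so a full shuffled null costs
seconds, not hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import StimulusSet
from .synthetic_data import Recording

__all__ = [
    "WindowedActivity",
    "KPrimeMap",
    "KPrimeNull",
    "window_average",
    "fit_kprime",
    "fit_kprime_shuffled",
    "group_kprime_test",
]

#: pooled current-tone range (1-based, inclusive): second half of the
#: sequence, excluding the pinned 33rd and the independent 34th tone
TONE_LO, TONE_HI = 16, 32

WINDOW_MS = 50.0

#: relative tolerance for SSE ties; tied models resolve to the smallest k'
_TIE_RTOL = 1e-9


@dataclass
class WindowedActivity:
    """Raw (non-baseline-corrected) activity averaged in 50-ms tone windows."""

    data: np.ndarray  # (n_trials, n_sensors, 34, n_windows)
    tone_duration: int  # ms
    sequence_ids: np.ndarray  # (n_trials,)
    trial_index: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.data.shape[3]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]


@dataclass
class KPrimeMap:
    """Fold-averaged integration order per sensor and window."""

    kprime: np.ndarray  # (n_sensors, n_windows) float
    fold_winners: np.ndarray  # (folds, n_sensors, n_windows) int
    fold_assignment: np.ndarray  # (n_trials,) fold of each trial
    windows: np.ndarray  # window indices fitted
    tone_duration: int
    seed: int


@dataclass
class KPrimeNull:
    """Shuffled-tone-order null: fold-averaged k' per repetition."""

    kshuff: np.ndarray  # (n_sensors, n_windows, n_rep) float
    fold_assignment: np.ndarray
    windows: np.ndarray
    tone_duration: int
    seed: int
    shuffle_seed: int


def window_average(rec: Recording, trials: pd.DataFrame) -> WindowedActivity:
    """Average raw samples in nonoverlapping 50-ms windows of every tone.

    The number of windows per tone is tone_duration / 50 ms (3, 6, or 12).
    Uses nearest-sample binning when the rate does not divide 50 ms exactly.
    """
    sub = trials.set_index("trial_index").loc[rec.trial_index]
    win_samp = rec.sample_rate * WINDOW_MS / 1000.0
    n_windows = int(round(rec.tone_duration / WINDOW_MS))
    n_trials, n_sensors, n_samples = rec.activity.shape
    out = np.empty((n_trials, n_sensors, 34, n_windows), dtype=np.float64)
    for i, onset in enumerate(rec.onset_samples):
        for w in range(n_windows):
            a = onset + int(round(w * win_samp))
            b = onset + int(round((w + 1) * win_samp))
            if b > n_samples:
                raise IndexError(
                    f"tone {i + 1} window {w} extends past the recording "
                    f"(trial span {n_samples} samples)"
                )
            out[:, :, i, w] = rec.activity[:, :, a:b].mean(axis=2)
    return WindowedActivity(
        data=out,
        tone_duration=rec.tone_duration,
        sequence_ids=sub["sequence_id"].to_numpy(),
        trial_index=rec.trial_index.copy(),
    )


# ---------------------------------------------------------------------------
# Cross-validated model-order selection
# ---------------------------------------------------------------------------


def _fold_assignment(seq_ids: np.ndarray, folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Balanced folds: equal repetitions of each unique sequence per fold."""
    fold = np.empty(len(seq_ids), dtype=int)
    for u in np.unique(seq_ids):
        idx = np.flatnonzero(seq_ids == u)
        if len(idx) % folds != 0:
            raise ValueError(
                f"sequence {u!r} has {len(idx)} repetitions, not divisible "
                f"into {folds} balanced folds"
            )
        per = len(idx) // folds
        fold[idx[rng.permutation(len(idx))]] = np.repeat(np.arange(folds), per)
    return fold


def _design(logp: np.ndarray, perm: np.ndarray, k_max: int) -> np.ndarray:
    """Design rows for tones 16..32 of one unique sequence.

    Columns: [1, p_i, p_{i-1}, ..., p_{i-k_max}] (log pitch).  History
    columns are taken from the ``perm``-shuffled order of tones 1..32; the
    current tone's pitch always stays original.  Predictors p_{i-k} exist
    for every pooled row (i >= 16, k <= 15), so no padding is ever needed.
    """
    q = logp[:32][perm]
    i = np.arange(TONE_LO - 1, TONE_HI)  # 0-based current-tone indices
    hist_idx = i[:, None] - np.arange(1, k_max + 1)[None, :]
    assert hist_idx.min() >= 0
    return np.column_stack([np.ones(len(i)), logp[i], q[hist_idx]])


def _solve(g: np.ndarray, a: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(g, a)
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient design: using minimum-norm solve")
        return np.linalg.lstsq(g, a, rcond=None)[0]


def _select_orders(sse: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """argmin over models with tolerance ties resolved to the smallest k'.

    ``scale`` (per column, e.g. the test-fold energy sum y'y) sets the
    floating-point noise floor of the Gram-based SSE evaluation, so models
    that fit exactly (SSE = 0 up to rounding) tie and the smallest k' wins.
    """
    mins = sse.min(axis=0)
    ok = sse <= mins * (1 + _TIE_RTOL) + _TIE_RTOL * (np.abs(scale) + 1.0)
    return np.argmax(ok, axis=0)


class _CVEngine:
    """Precomputed fold/test-side quantities for repeated (shuffled) fits."""

    def __init__(self, wa: WindowedActivity, stimset: StimulusSet,
                 k_max: int, folds: int, seed: int,
                 windows: np.ndarray | None,
                 fold_assignment: np.ndarray | None = None):
        if k_max > TONE_LO - 1:
            raise ValueError(f"k_max must be <= {TONE_LO - 1}")
        self.k_max = k_max
        self.folds = folds
        self.seed = seed
        self.windows = (np.arange(wa.n_windows) if windows is None
                        else np.asarray(windows))
        self.n_models = k_max + 1

        self.seq_names = np.array(sorted(np.unique(wa.sequence_ids)))
        self.logp = {
            u: np.log(stimset.by_id(u).pitches) for u in self.seq_names
        }
        seq_of_trial = np.searchsorted(
            self.seq_names, wa.sequence_ids.astype(self.seq_names.dtype)
        )
        if fold_assignment is not None:
            self.fold_of_trial = np.asarray(fold_assignment, dtype=int)
        else:
            rng = np.random.default_rng(seed)
            self.fold_of_trial = _fold_assignment(wa.sequence_ids, folds, rng)

        # response matrix: rows (trial, pooled tone), columns (sensor, window)
        tones = np.arange(TONE_LO - 1, TONE_HI)
        y = wa.data[:, :, :, self.windows][:, :, tones, :]
        n_trials, n_sensors, n_tones, n_w = y.shape
        self.sw = n_sensors * n_w
        y = y.transpose(0, 2, 1, 3).reshape(n_trials, n_tones, self.sw)

        n_seq = len(self.seq_names)
        # per (sequence, fold): summed responses and trial counts
        self.ysum = np.zeros((n_seq, folds, n_tones, self.sw))
        self.count = np.zeros((n_seq, folds), dtype=int)
        self.yy_fold = np.zeros((folds, self.sw))
        for t in range(n_trials):
            u, f = seq_of_trial[t], self.fold_of_trial[t]
            self.ysum[u, f] += y[t]
            self.count[u, f] += 1
            self.yy_fold[f] += (y[t] ** 2).sum(axis=0)

        # fixed (unshuffled) test-side Gram quantities per fold
        ident = np.arange(32)
        self.x0 = np.stack([
            _design(self.logp[u], ident, k_max) for u in self.seq_names
        ])  # (n_seq, n_tones, p)
        p = self.x0.shape[2]
        self.g_test = np.zeros((folds, p, p))
        self.a_test = np.zeros((folds, p, self.sw))
        for f in range(folds):
            for u in range(n_seq):
                xu = self.x0[u]
                self.g_test[f] += self.count[u, f] * (xu.T @ xu)
                self.a_test[f] += xu.T @ self.ysum[u, f]
        self.n_seq = n_seq

    def fit_rep(self, perms_by_fold) -> np.ndarray:
        """One full CV pass; returns fold winners (folds, sensors*windows)."""
        winners = np.empty((self.folds, self.sw), dtype=int)
        p = self.x0.shape[2]
        for f in range(self.folds):
            g_tr = np.zeros((p, p))
            a_tr = np.zeros((p, self.sw))
            perms = perms_by_fold(f)
            for u in range(self.n_seq):
                xu = (self.x0[u] if perms is None
                      else _design(self.logp[self.seq_names[u]], perms[u],
                                   self.k_max))
                n_tr = self.count[u].sum() - self.count[u, f]
                ysum_tr = self.ysum[u].sum(axis=0) - self.ysum[u, f]
                g_tr += n_tr * (xu.T @ xu)
                a_tr += xu.T @ ysum_tr
            sse = np.empty((self.n_models, self.sw))
            for k in range(self.n_models):
                m = k + 2  # parameters: intercept + current + k history
                b = _solve(g_tr[:m, :m], a_tr[:m])
                gb = self.g_test[f][:m, :m] @ b
                sse[k] = (
                    self.yy_fold[f]
                    - 2.0 * np.einsum("ij,ij->j", b, self.a_test[f][:m])
                    + np.einsum("ij,ij->j", b, gb)
                )
            winners[f] = _select_orders(sse, self.yy_fold[f])
        return winners

    def reshape(self, flat: np.ndarray) -> np.ndarray:
        n_w = len(self.windows)
        return flat.reshape(flat.shape[:-1] + (self.sw // n_w, n_w))


def fit_kprime(
    wa: WindowedActivity,
    stimset: StimulusSet,
    k_max: int = 15,
    folds: int = 6,
    seed: int = 0,
    windows: np.ndarray | None = None,
    fold_assignment: np.ndarray | None = None,
) -> KPrimeMap:
    """Estimate k' per sensor/window by six-fold cross-validated SSE.

    All 16 nested regressions are fit on the training folds pooling tones
    16..32 across trials; the model minimizing test SSE wins in each fold
    (ties to the smallest k'), and k' is the across-fold mean.
    """
    eng = _CVEngine(wa, stimset, k_max, folds, seed, windows, fold_assignment)
    winners = eng.fit_rep(lambda f: None)
    return KPrimeMap(
        kprime=eng.reshape(winners.mean(axis=0)),
        fold_winners=eng.reshape(winners),
        fold_assignment=eng.fold_of_trial,
        windows=eng.windows,
        tone_duration=wa.tone_duration,
        seed=seed,
    )


def _shuffle_perm(shuffle_seed: int, seq_name: str, rep: int,
                  fold: int) -> np.ndarray:
    """Training-set tone-order permutation for one (sequence, rep, fold).

    Seeded by name, so the shuffle order of a unique sequence is identical
    across tone-duration conditions and across the 12 repetitions of the
    sequence, as required for valid cross-condition comparison.
    """
    key = [ord(c) for c in str(seq_name)] + [rep, fold]
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=shuffle_seed, spawn_key=tuple(key))
    )
    return rng.permutation(32)


def fit_kprime_shuffled(
    wa: WindowedActivity,
    stimset: StimulusSet,
    n_rep: int = 100,
    k_max: int = 15,
    folds: int = 6,
    seed: int = 0,
    shuffle_seed: int | None = None,
    windows: np.ndarray | None = None,
    fold_assignment: np.ndarray | None = None,
) -> KPrimeNull:
    """Shuffled-tone-order null distribution of k' (fold-averaged).

    Per repetition, tone order 1..32 is permuted within each unique sequence
    in the training folds only (current-tone pitch preserved in every design
    row; test folds untouched), and the full CV selection is repeated.  The
    100 fold-averaged values per cell summarize 600 pre-averaging winners.
    """
    shuffle_seed = seed if shuffle_seed is None else shuffle_seed
    eng = _CVEngine(wa, stimset, k_max, folds, seed, windows, fold_assignment)
    n_sens = eng.sw // len(eng.windows)
    kshuff = np.empty((n_sens, len(eng.windows), n_rep))
    for rep in range(n_rep):
        def perms_by_fold(f, _rep=rep):
            return [
                _shuffle_perm(shuffle_seed, u, _rep, f) for u in eng.seq_names
            ]
        winners = eng.fit_rep(perms_by_fold)
        kshuff[:, :, rep] = eng.reshape(winners.mean(axis=0))
    return KPrimeNull(
        kshuff=kshuff,
        fold_assignment=eng.fold_of_trial,
        windows=eng.windows,
        tone_duration=wa.tone_duration,
        seed=seed,
        shuffle_seed=shuffle_seed,
    )


# ---------------------------------------------------------------------------
# Group-level inference
# ---------------------------------------------------------------------------


def group_kprime_test(
    kmaps: list[KPrimeMap],
    knulls: list[KPrimeNull],
    n_draws: int = 1000,
    seed: int = 0,
) -> dict:
    """Across-subject k' vs a resampled shuffled null, one-tailed.

    The null consists of ``n_draws`` across-subject means, each drawing one
    shuffle repetition per subject (with replacement).  p[s, w] is the
    proportion of null means >= the observed group mean.
    """
    if len(kmaps) < 2 or len(kmaps) != len(knulls):
        raise ValueError("need k' maps and nulls for >= 2 matching subjects")
    obs = np.mean([m.kprime for m in kmaps], axis=0)
    nulls = np.stack([n.kshuff for n in knulls])  # (subj, s, w, rep)
    n_subj, _, _, n_rep = nulls.shape
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_rep, size=(n_draws, n_subj))
    null = np.empty((n_draws,) + obs.shape)
    for d in range(n_draws):
        null[d] = nulls[np.arange(n_subj), :, :, idx[d]].mean(axis=0)
    p = (null >= obs[None]).mean(axis=0)
    return {"group_kprime": obs, "null": null, "p": p}


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------


def save_kprime(path: str, kmap: KPrimeMap, knull: KPrimeNull | None = None) -> None:
    """Serialize a k' map (and optionally its shuffled null) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("kprime", data=kmap.kprime)
        f.create_dataset("fold_winners", data=kmap.fold_winners)
        f.create_dataset("fold_assignment", data=kmap.fold_assignment)
        f.create_dataset("windows", data=kmap.windows)
        f.attrs["tone_duration"] = kmap.tone_duration
        f.attrs["seed"] = kmap.seed
        if knull is not None:
            f.create_dataset("null", data=knull.kshuff)
            f.attrs["shuffle_seed"] = knull.shuffle_seed


def load_kprime(path: str) -> tuple[KPrimeMap, KPrimeNull | None]:
    import h5py

    with h5py.File(path, "r") as f:
        kmap = KPrimeMap(
            kprime=f["kprime"][()],
            fold_winners=f["fold_winners"][()],
            fold_assignment=f["fold_assignment"][()],
            windows=f["windows"][()],
            tone_duration=int(f.attrs["tone_duration"]),
            seed=int(f.attrs["seed"]),
        )
        knull = None
        if "null" in f:
            knull = KPrimeNull(
                kshuff=f["null"][()],
                fold_assignment=kmap.fold_assignment,
                windows=kmap.windows,
                tone_duration=kmap.tone_duration,
                seed=kmap.seed,
                shuffle_seed=int(f.attrs["shuffle_seed"]),
            )
    return kmap, knull
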