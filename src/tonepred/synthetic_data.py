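"""Synthetic multi-subject sessions with planted sensory-history ground truth.

Emulates a sensor-array (MEG-like) study: trials time-locked to 34-tone
sequences presented at 150/300/600 ms per tone, with sensors whose windowed
activity is a weighted linear function of the current and K preceding tone
pitches, a slowly accumulating non-baselined predictive signal proportional
to the running prediction of the final pitch, and trial-wise likelihood
ratings driven by the distance between the presented and the subject's
internally predicted final pitch.

Sensor roles
------------
``informational``  integrate a fixed number of tones (K_info) at every tone
                   duration, and carry the predictive build-up signal.
``temporal``       integrate a fixed time span T_int, i.e.
                   round(T_int / tone_duration) tones.
``sensory``        carry a pitch-modulated evoked response peaking ~100 ms
                   after each tone onset (an auditory M100 stand-in).
``noise``          no stimulus-driven signal.

All sensors receive additive white noise and a slowly varying, non-baselined
drift.  Roles live in spatially contiguous patches so that cluster-level
inference is meaningful.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial.distance import cdist

from .stimuli import (
    StimulusSet,
    autocovariance,
    blp_weights,
    make_semitone_grid,
)

__all__ = [
    "SensorLayout",
    "GroundTruth",
    "NoiseConfig",
    "Recording",
    "make_grid_layout",
    "make_ground_truth",
    "sequence_features",
    "simulate_session",
    "simulate_behavior",
    "simulate_study",
    "save_recording",
    "load_recording",
]

ROLES = ("informational", "temporal", "sensory", "noise")


@dataclass(frozen=True)
class SensorLayout:
    """Planar sensor array with role patches and a neighbor graph."""

    positions: np.ndarray  # (n_sensors, 2)
    roles: np.ndarray  # (n_sensors,) strings from ROLES
    neighbor_radius: float = 1.5

    @property
    def n_sensors(self) -> int:
        return len(self.roles)

    def role_idx(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)

    @property
    def adjacency(self) -> csr_matrix:
        """Symmetric sensor adjacency: Euclidean distance <= neighbor_radius."""
        d = cdist(self.positions, self.positions)
        a = (d <= self.neighbor_radius) & (d > 0)
        return csr_matrix(a)


def make_grid_layout(n_side: int = 12, neighbor_radius: float = 1.5) -> SensorLayout:
    """Square sensor grid split into four contiguous quadrant role patches.

    Quadrants (x, y from the grid center): lower-left informational,
    lower-right temporal, upper-left sensory, upper-right noise.
    """
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    pos = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    half = n_side / 2.0
    roles = np.empty(len(pos), dtype=object)
    left = pos[:, 0] < half
    low = pos[:, 1] < half
    roles[left & low] = "informational"
    roles[~left & low] = "temporal"
    roles[left & ~low] = "sensory"
    roles[~left & ~low] = "noise"
    return SensorLayout(positions=pos, roles=roles.astype(str),
                        neighbor_radius=neighbor_radius)


@dataclass
class GroundTruth:
    """Planted generative parameters for one subject.

    Per sensor: role-dependent gains; informational sensors integrate
    ``k_info`` tones at all durations, temporal sensors integrate
    round(t_int_ms / tone_duration) tones.  History weights decay
    geometrically: w_k = lam**k, k = 0..K-1.  Per subject: internal
    integration count ``k_subj`` and behavioral gain ``gamma``.
    """

    roles: np.ndarray
    k_info: int = 7
    t_int_ms: float = 1200.0
    lam: float = 0.7
    sensory_gain: float = 1.0
    history_gain: float = 1.0
    predictive_gain: float = 0.5
    k_subj: int = 7
    gamma: float = 1.0

    def history_weights(self, k: int) -> np.ndarray:
        return self.lam ** np.arange(k)

    def k_temporal(self, tone_duration_ms: float) -> int:
        k = int(round(self.t_int_ms / tone_duration_ms))
        if k < 1:
            warnings.warn(
                f"T_int={self.t_int_ms} ms < tone duration "
                f"{tone_duration_ms} ms: temporal sensors degenerate to K=1"
            )
            k = 1
        return k


def make_ground_truth(layout: SensorLayout, **kwargs) -> GroundTruth:
    return GroundTruth(roles=layout.roles.copy(), **kwargs)


@dataclass
class NoiseConfig:
    """Noise and scaling knobs of the generator (units of sensor activity)."""

    white_sd: float = 2.5  # per-sample white noise SD
    drift_sd: float = 0.3  # stationary SD of the slow drift
    drift_tau_s: float = 2.0  # drift autocorrelation time constant, seconds
    drift_knot_s: float = 0.5  # knot spacing of the drift process, seconds
    evoked_dc: float = 1.0  # pitch-independent part of the evoked response
    rating_scale: float = 1.5  # maps |z-prediction error| to rating units
    rating_noise_sd: float = 0.5
    sample_rate: float = 300.0  # Hz
    baseline_ms: float = 500.0  # pre-sequence span included in recordings
    gap_ms: float = 400.0  # post-sequence span before the response cue


@dataclass
class Recording:
    """Sensor-array activity for one subject and tone-duration condition."""

    subject: int
    tone_duration: int  # ms
    activity: np.ndarray  # (n_trials, n_sensors, n_samples), float32, raw
    sample_rate: float
    onset_samples: np.ndarray  # (34,) sample index of each tone onset
    trial_index: np.ndarray  # rows of the trial table this recording covers

    @property
    def n_trials(self) -> int:
        return self.activity.shape[0]


# ---------------------------------------------------------------------------
# Stimulus-derived features shared by the generator and the behavior model
# ---------------------------------------------------------------------------


def _z_standardizer(grid):
    logv = grid.log_values
    mu, sd = logv.mean(), logv.std()
    return lambda hz: (np.log(hz) - mu) / sd


def sequence_features(stimset: StimulusSet) -> dict:
    """Per-template standardized log pitches and running final-pitch predictions.

    Returns ``{seq_id: {"z": (33,), "zpred": (33,), "beta": float}}`` where
    ``zpred[i-1]`` is the best linear prediction of the (standardized) final
    pitch given tones 1..i under the synthesis autocovariance.
    """
    zfun = _z_standardizer(stimset.grid)
    out = {}
    weights_cache: dict[tuple[float, int], np.ndarray] = {}
    for seq in stimset.sequences:
        z = zfun(seq.pitches)
        r = autocovariance(seq.beta, 35)
        zpred = np.empty(33)
        for i in range(1, 34):
            key = (seq.beta, i)
            if key not in weights_cache:
                weights_cache[key] = blp_weights(r, n_obs=i, target=34)
            a = weights_cache[key]
            zi = z[:i]
            zpred[i - 1] = zi.mean() + a @ (zi - zi.mean())
        out[seq.seq_id] = {"z": z, "zpred": zpred, "beta": seq.beta}
    return out


def _evoked_kernel(sample_rate: float, peak_s: float = 0.1,
                   width_s: float = 0.025, span_s: float = 0.25) -> np.ndarray:
    """Evoked-response kernel: Gaussian bump peaking ~100 ms post onset."""
    t = np.arange(int(round(span_s * sample_rate))) / sample_rate
    return np.exp(-0.5 * ((t - peak_s) / width_s) ** 2)


def _history_values(z: np.ndarray, k: int, w: np.ndarray) -> np.ndarray:
    """Sum_k w_k z_{i-k} per tone (truncated at the sequence start)."""
    n = len(z)
    h = np.zeros(n)
    for kk in range(k):
        h[kk:] += w[kk] * z[: n - kk]
    return h


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------


def simulate_session(
    trials: pd.DataFrame,
    stimset: StimulusSet,
    layout: SensorLayout,
    truth: GroundTruth,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
    subject: int = 0,
) -> tuple[dict[int, Recording], pd.DataFrame]:
    """Generate recordings for every tone-duration condition plus behavior.

    Windowed means of the noiseless activity follow the generative model
    exactly: sensory sensors a*E(w)*(dc + z(p_i)); informational sensors
    b*sum_k w_k z(p_{i-k}) + c*zpred_i; temporal sensors the same sum with
    K = round(T_int/duration); noise sensors 0.  White noise and a
    non-baselined slow drift are added on top.  Deterministic given ``seed``.
    """
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    feats = sequence_features(stimset)
    zfun = _z_standardizer(stimset.grid)
    fs = noise.sample_rate
    kernel = _evoked_kernel(fs)
    s_idx = {role: layout.role_idx(role) for role in ROLES}

    recordings: dict[int, Recording] = {}
    for dur in sorted(trials["tone_duration"].unique()):
        sub = trials[trials["tone_duration"] == dur].reset_index(drop=True)
        n_trials = len(sub)
        n_base = int(round(noise.baseline_ms / 1000.0 * fs))
        n_tone = int(round(dur / 1000.0 * fs))
        n_gap = int(round(noise.gap_ms / 1000.0 * fs))
        n_samples = n_base + 34 * n_tone + n_gap
        onsets = n_base + np.arange(34) * n_tone

        act = np.zeros((n_trials, layout.n_sensors, n_samples), dtype=np.float32)

        # per-trial tone features
        z33 = np.stack([feats[s]["z"] for s in sub["sequence_id"]])  # (n, 33)
        zpred = np.stack([feats[s]["zpred"] for s in sub["sequence_id"]])
        z34 = zfun(sub["presented_final"].to_numpy())
        z_all = np.concatenate([z33, z34[:, None]], axis=1)  # (n, 34)

        # history sums per trial/tone for informational and temporal sensors
        k_info = truth.k_info
        k_temp = truth.k_temporal(dur)
        h_info = np.stack([
            _history_values(z_all[t], k_info, truth.history_weights(k_info))
            for t in range(n_trials)
        ])
        h_temp = np.stack([
            _history_values(z_all[t], k_temp, truth.history_weights(k_temp))
            for t in range(n_trials)
        ])
        # predictive build-up: hold the running prediction during each tone
        # epoch (tone 34 holds the complete prediction from tones 1..33)
        pred = np.concatenate([zpred, zpred[:, -1:]], axis=1)  # (n, 34)

        info, temp, sens = (s_idx["informational"], s_idx["temporal"],
                            s_idx["sensory"])
        for i in range(34):
            sl = slice(onsets[i], onsets[i] + n_tone)
            v_info = (truth.history_gain * h_info[:, i]
                      + truth.predictive_gain * pred[:, i])
            act[:, info, sl] += v_info[:, None, None]
            act[:, temp, sl] += (truth.history_gain * h_temp[:, i])[:, None, None]
            ev = slice(onsets[i], min(onsets[i] + len(kernel), n_samples))
            kseg = kernel[: ev.stop - ev.start]
            act[:, sens, ev] += (
                truth.sensory_gain
                * (noise.evoked_dc + z_all[:, i])[:, None, None]
                * kseg[None, None, :]
            )

        # white noise
        act += rng.standard_normal(act.shape, dtype=np.float32) * np.float32(
            noise.white_sd
        )
        # slow non-baselined drift: stationary Ornstein-Uhlenbeck process at
        # coarse knots (mirrors demeaned/detrended recordings, where slow
        # fluctuations have bounded variance), linearly interpolated via a
        # knot-to-sample matrix product
        n_knots = int(np.ceil(n_samples / (noise.drift_knot_s * fs))) + 1
        rho = np.float32(np.exp(-noise.drift_knot_s / noise.drift_tau_s))
        innov_sd = np.float32(noise.drift_sd * np.sqrt(1 - float(rho) ** 2))
        eps = rng.standard_normal((n_trials, layout.n_sensors, n_knots),
                                  dtype=np.float32)
        knots = np.empty_like(eps)
        knots[:, :, 0] = eps[:, :, 0] * np.float32(noise.drift_sd)
        for k in range(1, n_knots):
            knots[:, :, k] = rho * knots[:, :, k - 1] + innov_sd * eps[:, :, k]
        t_rel = np.arange(n_samples) / (noise.drift_knot_s * fs)
        i0 = np.minimum(t_rel.astype(int), n_knots - 2)
        frac = (t_rel - i0).astype(np.float32)
        interp = np.zeros((n_knots, n_samples), dtype=np.float32)
        interp[i0, np.arange(n_samples)] = 1 - frac
        interp[i0 + 1, np.arange(n_samples)] = frac
        act += (knots.reshape(-1, n_knots) @ interp).reshape(act.shape)

        recordings[int(dur)] = Recording(
            subject=subject,
            tone_duration=int(dur),
            activity=act,
            sample_rate=fs,
            onset_samples=onsets,
            trial_index=sub["trial_index"].to_numpy(),
        )

    behavior = simulate_behavior(trials, stimset, truth, noise=noise,
                                 seed=rng, subject=subject)
    return recordings, behavior


def simulate_behavior(
    trials: pd.DataFrame,
    stimset: StimulusSet,
    truth: GroundTruth,
    noise: NoiseConfig | None = None,
    seed: int | np.random.Generator | None = None,
    subject: int = 0,
) -> pd.DataFrame:
    """Trial-wise likelihood (1-5) and trend-strength (1-3) ratings.

    rating = clamp(round(5 - gamma * scale * |z(p34) - zhat34(K_subj)| +
    noise), 1, 5), where zhat34 uses only the last ``K_subj`` tones of the
    sequence.  Monotone decreasing in the prediction error before clamping;
    with gamma = 0 ratings are independent of the stimulus.
    """
    noise = noise or NoiseConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zfun = _z_standardizer(stimset.grid)
    # subject's internal prediction per template from the last K_subj tones
    internal = {}
    for seq in stimset.sequences:
        r = autocovariance(seq.beta, truth.k_subj + 2)
        a = blp_weights(r, n_obs=truth.k_subj, target=truth.k_subj + 1)
        z = zfun(seq.pitches)[-truth.k_subj:]
        internal[seq.seq_id] = float(z.mean() + a @ (z - z.mean()))
    zhat = trials["sequence_id"].map(internal).to_numpy()
    err = np.abs(zfun(trials["presented_final"].to_numpy()) - zhat)
    raw = (5.0 - truth.gamma * noise.rating_scale * err
           + rng.normal(0, noise.rating_noise_sd, size=len(trials)))
    rating = np.clip(np.round(raw), 1, 5).astype(int)
    # trend rating: noisy readout of the beta level (stored, never analyzed)
    beta_rank = trials["beta"].rank(method="dense").astype(int)
    trend = np.clip(
        beta_rank + rng.integers(-1, 2, size=len(trials)), 1, 3
    ).astype(int)
    return pd.DataFrame({
        "subject": subject,
        "trial_index": trials["trial_index"].to_numpy(),
        "tone_duration": trials["tone_duration"].to_numpy(),
        "pstar_bin": trials["pstar_bin"].to_numpy(),
        "predicted_final": trials["predicted_final"].to_numpy(),
        "presented_final": trials["presented_final"].to_numpy(),
        "likelihood_rating": rating,
        "trend_rating": trend,
    })


# ---------------------------------------------------------------------------
# Multi-subject studies
# ---------------------------------------------------------------------------


@dataclass
class Study:
    """A simulated multi-subject study (recordings generated lazily)."""

    trials: pd.DataFrame
    stimset: StimulusSet
    layout: SensorLayout
    truths: list[GroundTruth]
    noise: NoiseConfig
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.truths)

    def subject_session(self, subj: int) -> tuple[dict[int, Recording], pd.DataFrame]:
        return simulate_session(
            self.trials, self.stimset, self.layout, self.truths[subj],
            noise=self.noise, seed=self.seed + 1000 + subj, subject=subj,
        )


def simulate_study(
    stimset: StimulusSet,
    trials: pd.DataFrame,
    n_subjects: int = 12,
    layout: SensorLayout | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    couple_k_subj: bool = False,
    k_subj_range: tuple[int, int] = (4, 10),
    gamma: float = 1.0,
    **truth_kwargs,
) -> Study:
    """Assemble per-subject ground truths for a study.

    With ``couple_k_subj=False`` every subject shares the default truth
    (fixed K_info; used for parameter-recovery and geometry analyses).  With
    ``couple_k_subj=True`` each subject's internal integration count K_subj
    is drawn from ``k_subj_range``, informational sensors integrate that
    subject's K_subj tones, and the rating sharpness is gamma * 4 / K_subj —
    the planted negative coupling between neural integration length and the
    behavioral interaction effect.
    """
    layout = layout or make_grid_layout()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    truths = []
    for _ in range(n_subjects):
        if couple_k_subj:
            k = int(rng.integers(k_subj_range[0], k_subj_range[1] + 1))
            truths.append(make_ground_truth(
                layout, k_info=k, k_subj=k, gamma=gamma * 4.0 / k,
                **truth_kwargs,
            ))
        else:
            truths.append(make_ground_truth(layout, gamma=gamma, **truth_kwargs))
    return Study(trials=trials, stimset=stimset, layout=layout, truths=truths,
                 noise=noise, seed=seed)


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------


def save_recording(rec: Recording, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=rec.activity, compression="gzip")
        f.create_dataset("onsets", data=rec.onset_samples)
        f.create_dataset("trial_index", data=rec.trial_index)
        f.attrs["meta"] = json.dumps({
            "subject": rec.subject,
            "tone_duration": rec.tone_duration,
            "sample_rate": rec.sample_rate,
        })


def load_recording(path: str) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        return Recording(
            subject=meta["subject"],
            tone_duration=meta["tone_duration"],
            activity=f["activity"][()],
            sample_rate=meta["sample_rate"],
            onset_samples=f["onsets"][()],
            trial_index=f["trial_index"][()],
        )
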