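"""Naturalistic tone-sequence stimuli with 1/f^beta pitch statistics.

Sequences of 34 pure tones whose pitch fluctuates as a stationary Gaussian
process with temporal power spectrum P(f) ~ 1/f^beta, scaled onto a 25-value
semitone grid between 220 and 880 Hz. The penultimate (33rd) tone is pinned
at 440 Hz; the theoretically predicted final pitch p34* is the best linear
predictor (conditional mean) of element 34 given elements 1-33 under the
synthesis autocovariance. The presented final tone p34 is drawn independently
from six fixed pitches (+-4, 8, 12 semitones around 440 Hz).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_toeplitz, toeplitz
from scipy.signal import periodogram

__all__ = [
    "PitchGrid",
    "ToneSequence",
    "StimulusSet",
    "make_semitone_grid",
    "power_spectrum",
    "autocovariance",
    "synthesize_series",
    "fit_spectral_slope",
    "scale_and_discretize",
    "snap_to_grid",
    "blp_weights",
    "predict_final_pitch",
    "build_stimulus_set",
    "assign_final_tones",
    "render_wav",
    "PRESENTED_FINALS",
    "DURATIONS_MS",
    "BETAS",
]

#: presented final pitches, in Hz, at 4/8/12 semitones below/above 440 Hz
#: (printed to integer Hz as customary for these pitch values)
PRESENTED_FINALS = (220.0, 277.0, 349.0, 554.0, 699.0, 880.0)

#: tone durations in ms: fast / medium / slow presentation
DURATIONS_MS = (150, 300, 600)

#: temporal-dependence (spectral exponent) levels
BETAS = (0.5, 0.99, 1.5)

#: p34* bins as semitone indices on the default grid (base 220 Hz):
#: low [370, 392] Hz, medium [440] Hz, high [494, 523] Hz
PSTAR_BIN_STEPS = {"low": (9, 10), "medium": (12,), "high": (14, 15)}


@dataclass(frozen=True)
class PitchGrid:
    """Semitone-spaced pitch grid: values[j] = base * 2**(j/12)."""

    base: float
    n_steps: int
    values: np.ndarray = field(repr=False)

    @property
    def log_values(self) -> np.ndarray:
        return np.log(self.values)


def make_semitone_grid(base_hz: float = 220.0, n_steps: int = 25) -> PitchGrid:
    """Build a pitch grid of ``n_steps`` values spaced one semitone apart.

    The default grid spans 220-880 Hz (two octaves, 25 values).
    """
    if base_hz <= 0:
        raise ValueError(f"base_hz must be positive, got {base_hz}")
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    values = base_hz * 2.0 ** (np.arange(n_steps) / 12.0)
    return PitchGrid(base=base_hz, n_steps=n_steps, values=values)


# ---------------------------------------------------------------------------
# 1/f^beta process: spectrum, autocovariance, circulant-embedding synthesis
# ---------------------------------------------------------------------------


def power_spectrum(beta: float, m: int) -> np.ndarray:
    """Target power on the length-``m`` discrete frequency lattice.

    P_j = |f_j|^-beta with f_j = min(j, m-j)/m.  The zero-frequency power is
    set equal to the lowest nonzero-frequency power to avoid the 1/f
    divergence at DC (standard circulant-embedding practice).
    """
    if not 0 < beta < 2:
        raise ValueError(f"beta must lie in (0, 2), got {beta}")
    j = np.arange(m)
    f = np.minimum(j, m - j) / m
    f[0] = 1.0 / m  # DC power := power at the lowest nonzero frequency
    return f ** (-beta)


def autocovariance(beta: float, n_lags: int, embed_size: int = 4096) -> np.ndarray:
    """Autocovariance r(0..n_lags-1) of the synthesized process, r(0) = 1."""
    p = power_spectrum(beta, embed_size)
    r = np.fft.ifft(p).real
    return r[:n_lags] / r[0]


def _embed_size(length: int, embed_size: int | None) -> int:
    if embed_size is not None:
        return embed_size
    return max(4096, 2 ** math.ceil(math.log2(2 * length)))


def synthesize_series(
    beta: float,
    length: int,
    seed: int | np.random.Generator | None = None,
    embed_size: int | None = None,
) -> np.ndarray:
    """Sample a stationary Gaussian series with 1/f^beta power spectrum.

    Exact circulant-embedding synthesis: complex Gaussian coefficients with
    variance given by the lattice spectrum are inverse-transformed and the
    real part retained, so the finite-sample autocovariance is exactly the
    circulant one returned by :func:`autocovariance` (unit variance).
    """
    if length < 2:
        raise ValueError(f"length must be >= 2, got {length}")
    m = _embed_size(length, embed_size)
    p = power_spectrum(beta, m)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.sqrt(p) * (rng.standard_normal(m) + 1j * rng.standard_normal(m))
    x = np.fft.ifft(z).real * np.sqrt(m / 2.0)
    c0 = p.mean()  # r(0) of the un-normalized circulant covariance
    return x[:length] / np.sqrt(c0)


def _synthesize_batch(beta: float, length: int, n_series: int,
                      rng: np.random.Generator, embed_size: int) -> np.ndarray:
    """Vectorized circulant-embedding synthesis: (n_series, length) array.

    The spectrum is symmetric on the lattice, so the real and imaginary
    parts of each non-Hermitian draw are independent with the same
    covariance; both are kept, halving the FFT cost.
    """
    p = power_spectrum(beta, embed_size)
    half = (n_series + 1) // 2
    z = np.sqrt(p) * (
        rng.standard_normal((half, embed_size))
        + 1j * rng.standard_normal((half, embed_size))
    )
    y = np.fft.ifft(z, axis=1) * np.sqrt(embed_size / 2.0)
    x = np.concatenate([y.real, y.imag])[:n_series]
    return x[:, :length] / np.sqrt(p.mean())


def fit_spectral_slope(series: np.ndarray, f_lo: float | None = None,
                       f_hi: float = 0.25) -> float:
    """Least-squares slope of log power vs log frequency over the mid band.

    For a 1/f^beta series the expected slope is -beta.  The default band
    excludes the lowest resolvable frequencies (leakage-dominated) and the
    upper quarter of the spectrum.
    """
    n = len(series)
    f, pxx = periodogram(series, detrend="constant")
    if f_lo is None:
        f_lo = 8.0 / n
    sel = (f >= f_lo) & (f <= f_hi) & (pxx > 0)
    coef = np.polyfit(np.log(f[sel]), np.log(pxx[sel]), 1)
    return float(coef[0])


# ---------------------------------------------------------------------------
# Scaling / discretization onto the pitch grid
# ---------------------------------------------------------------------------


def scale_and_discretize(series: np.ndarray, grid: PitchGrid) -> np.ndarray:
    """Min-max map a series onto [log base, log top] and snap to the grid.

    The output spans the full grid range (min -> lowest grid pitch, max ->
    highest) and every element lies on a grid value.  A point exactly midway
    between two grid values snaps to the lower one.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = series.min(), series.max()
    if hi == lo:
        raise ValueError("constant series cannot be scaled onto the grid")
    logv = grid.log_values
    y = logv[0] + (series - lo) / (hi - lo) * (logv[-1] - logv[0])
    return _snap_log(y, grid)


def _snap_log(log_pitch: np.ndarray, grid: PitchGrid) -> np.ndarray:
    logv = grid.log_values
    mids = 0.5 * (logv[:-1] + logv[1:])
    # side='left': a value exactly at a midpoint resolves to the lower pitch
    idx = np.searchsorted(mids, log_pitch, side="left")
    return grid.values[idx]


def snap_to_grid(hz: float | np.ndarray, grid: PitchGrid) -> float | np.ndarray:
    """Nearest grid pitch in log space (ties to the lower value)."""
    out = _snap_log(np.log(np.atleast_1d(np.asarray(hz, dtype=float))), grid)
    return float(out[0]) if np.isscalar(hz) or np.ndim(hz) == 0 else out


# ---------------------------------------------------------------------------
# Optimal final-pitch predictor (best linear predictor under the 1/f^beta
# autocovariance, solved from the Toeplitz normal equations)
# ---------------------------------------------------------------------------


def blp_weights(r: np.ndarray, n_obs: int, target: int) -> np.ndarray:
    """Best-linear-predictor weights for element ``target`` given 1..n_obs.

    ``r`` is the process autocovariance (r[0] = variance); indices are
    1-based, target > n_obs.  Solves Sigma a = c with Sigma the n_obs x n_obs
    Toeplitz autocovariance and c_j = r(target - j).
    """
    if target <= n_obs:
        raise ValueError("target must come after the observed elements")
    col = r[:n_obs]
    c = r[target - np.arange(1, n_obs + 1)]
    try:
        return solve_toeplitz((col, col), c)
    except np.linalg.LinAlgError:
        warnings.warn("singular autocovariance; using ridge-regularized solve")
        sigma = toeplitz(col) + 1e-10 * np.eye(n_obs)
        return np.linalg.solve(sigma, c)


def predict_final_pitch(
    pitches: np.ndarray,
    beta: float,
    embed_size: int = 4096,
) -> tuple[float, np.ndarray]:
    """Theoretically predicted final (34th) tone pitch p34*, in Hz.

    The prediction is the conditional mean of element 34 of a zero-mean
    stationary Gaussian process with the synthesis 1/f^beta autocovariance,
    applied to the mean-centered log-pitch series and back-transformed:

        log p34* = mean(x) + a' (x - mean(x)),   Sigma a = c

    Returns the continuous prediction in Hz and the 33 predictor weights.
    """
    x = np.log(np.asarray(pitches, dtype=float))
    n = len(x)
    r = autocovariance(beta, n + 1, embed_size=embed_size)
    a = blp_weights(r, n_obs=n, target=n + 1)
    pred_log = x.mean() + a @ (x - x.mean())
    return float(np.exp(pred_log)), a


# ---------------------------------------------------------------------------
# Stimulus set and trial table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToneSequence:
    """A 33-tone template plus its theoretically predicted 34th pitch."""

    seq_id: str
    beta: float
    pitches: np.ndarray  # 33 grid pitches, Hz; pitches[32] == 440
    predicted_final: float  # p34* snapped to the grid (bin representative), Hz
    predicted_final_raw: float  # continuous p34*, Hz
    pstar_bin: str  # 'low' | 'medium' | 'high'


@dataclass(frozen=True)
class StimulusSet:
    """Nine templates (3 beta x 3 p34* bins) crossed with tone durations."""

    sequences: tuple[ToneSequence, ...]
    grid: PitchGrid
    durations: tuple[int, ...] = DURATIONS_MS
    n_blocks: int = 12
    seed: int | None = None

    def by_id(self, seq_id: str) -> ToneSequence:
        for s in self.sequences:
            if s.seq_id == seq_id:
                return s
        raise KeyError(seq_id)


def build_stimulus_set(
    seed: int,
    betas: tuple[float, ...] = BETAS,
    durations: tuple[int, ...] = DURATIONS_MS,
    n_blocks: int = 12,
    grid: PitchGrid | None = None,
    use_discretized: bool = True,
    max_attempts_per_cell: int = 1_000_000,
    embed_size: int = 4096,
) -> StimulusSet:
    """Rejection-sample templates for every (beta, p34* bin) design cell.

    Candidate 33-element series are synthesized, discretized, and kept when
    the penultimate pitch lands on 440 Hz and the grid-snapped p34* falls in
    the target bin (low [370, 392] / medium [440] / high [494, 523] Hz).
    ``use_discretized`` selects whether the predictor sees the discretized
    pitches (what the listener hears; default) or the raw scaled series.
    """
    grid = grid or make_semitone_grid()
    rng = np.random.default_rng(seed)
    bin_values = {
        name: {round(float(grid.values[j]), 6) for j in steps}
        for name, steps in PSTAR_BIN_STEPS.items()
    }
    p33_target = float(grid.values[12])  # 440 Hz on the default grid
    sequences: list[ToneSequence] = []
    for beta in betas:
        cells: dict[str, ToneSequence] = {}
        budget = max_attempts_per_cell * len(bin_values)
        r = autocovariance(beta, 34, embed_size=embed_size)
        a = blp_weights(r, n_obs=33, target=34)
        attempts = 0
        batch = 512
        while len(cells) < len(bin_values):
            if attempts >= budget:
                missing = sorted(set(bin_values) - set(cells))
                raise RuntimeError(
                    f"rejection budget exceeded for beta={beta}, "
                    f"unfilled p34* bin(s): {missing}"
                )
            attempts += batch
            raw = _synthesize_batch(beta, 33, batch, rng, embed_size)
            lo = raw.min(axis=1, keepdims=True)
            hi = raw.max(axis=1, keepdims=True)
            ok = (hi > lo).ravel()
            span = np.where(hi > lo, hi - lo, 1.0)
            logx = grid.log_values[0] + (raw - lo) / span * (
                grid.log_values[-1] - grid.log_values[0]
            )
            pitches_b = _snap_log(logx, grid)
            ok &= pitches_b[:, 32] == p33_target
            x = np.log(pitches_b) if use_discretized else logx
            pred_log = x.mean(axis=1) + (x - x.mean(axis=1, keepdims=True)) @ a
            pred_raw_b = np.exp(pred_log)
            pred_snap_b = _snap_log(pred_log, grid)
            for i in np.flatnonzero(ok):
                if len(cells) == len(bin_values):
                    break
                key = round(float(pred_snap_b[i]), 6)
                for name, vals in bin_values.items():
                    if name not in cells and key in vals:
                        cells[name] = ToneSequence(
                            seq_id=f"b{beta:g}_{name}",
                            beta=beta,
                            pitches=pitches_b[i],
                            predicted_final=float(pred_snap_b[i]),
                            predicted_final_raw=float(pred_raw_b[i]),
                            pstar_bin=name,
                        )
                        break
        sequences.extend(cells[name] for name in ("low", "medium", "high"))
    return StimulusSet(
        sequences=tuple(sequences), grid=grid, durations=tuple(durations),
        n_blocks=n_blocks, seed=seed,
    )


def assign_final_tones(
    stimset: StimulusSet,
    n_blocks: int | None = None,
    seed: int | None = None,
    balance: bool = True,
) -> pd.DataFrame:
    """Expand templates x durations x blocks into the full trial table.

    Each of the 27 distinct sequences (9 templates x 3 durations) appears
    once per block; across the ``n_blocks`` repetitions of each distinct
    sequence, the six presented final pitches are balanced (each twice for
    12 blocks).  Tone onsets are regular at the condition's tone duration;
    onset columns are 1-based (onset_01 .. onset_34, in ms from sequence
    start).
    """
    n_blocks = n_blocks if n_blocks is not None else stimset.n_blocks
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    finals = np.asarray(PRESENTED_FINALS)
    if balance and n_blocks % len(finals) != 0:
        raise ValueError(
            f"n_blocks={n_blocks} is not a multiple of {len(finals)}: "
            "presented-final balance impossible (pass balance=False to allow)"
        )
    rng = np.random.default_rng(seed if seed is not None else stimset.seed)
    combos = [(s, d) for s in stimset.sequences for d in stimset.durations]
    # presented-final schedule per distinct sequence, balanced across blocks
    schedule = {}
    for s, d in combos:
        if balance:
            pool = np.tile(finals, n_blocks // len(finals))
        else:
            pool = finals[rng.integers(0, len(finals), size=n_blocks)]
        schedule[(s.seq_id, d)] = rng.permutation(pool)
    rows = []
    trial = 0
    for block in range(n_blocks):
        order = rng.permutation(len(combos))
        for idx in order:
            s, dur = combos[idx]
            row = {
                "trial_index": trial,
                "block": block,
                "sequence_id": s.seq_id,
                "beta": s.beta,
                "tone_duration": dur,
                "pstar_bin": s.pstar_bin,
                "predicted_final": s.predicted_final,
                "presented_final": schedule[(s.seq_id, dur)][block],
            }
            onsets = np.arange(34) * dur
            row.update({f"onset_{i + 1:02d}": onsets[i] for i in range(34)})
            rows.append(row)
            trial += 1
    return pd.DataFrame(rows)


def render_wav(
    sequence: ToneSequence,
    tone_duration_ms: int,
    path: str,
    presented_final: float | None = None,
    sample_rate: int = 44_100,
    ramp_ms: float = 5.0,
) -> None:
    """Render a sequence as concatenated pure tones to a 16-bit PCM WAV.

    Each tone gets a raised-cosine on/off ramp to avoid clicks; the rendered
    audio never enters any analysis.
    """
    from scipy.io import wavfile

    pitches = list(sequence.pitches)
    if presented_final is not None:
        pitches.append(presented_final)
    n = int(round(sample_rate * tone_duration_ms / 1000.0))
    t = np.arange(n) / sample_rate
    n_ramp = int(round(sample_rate * ramp_ms / 1000.0))
    env = np.ones(n)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    audio = np.concatenate([env * np.sin(2 * np.pi * f * t) for f in pitches])
    wavfile.write(path, sample_rate, (audio * 0.8 * 32767).astype(np.int16))
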