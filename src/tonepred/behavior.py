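"""Behavioral prediction analyses and brain-behavior coupling.

Likelihood ratings (1-5) of the presented final tone are analyzed with
factorial ANOVAs over tone duration (3) x predicted final pitch p34* (3) x
presented final pitch p34 (6).  The p34* x p34 interaction F quantifies how
strongly a subject's rating depends on the sequence-derived prediction; it
serves as the per-subject behavioral index of sensory-history use.  Neural
k' values (cluster- and condition-averaged) are correlated with these F
statistics across subjects (Spearman), with FDR control across windows and
a sensor-wise cluster-permutation variant against the shuffled k' null.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert
from statsmodels.stats.multitest import multipletests

from . import cluster_perm
from .geometry import DURATION_AXES
from .shi import KPrimeMap, KPrimeNull

__all__ = [
    "factorial_anova",
    "subject_interaction_F",
    "group_rm_anova",
    "brain_behavior_correlation",
    "sensorwise_correlation_clusters",
]

FACTORS = ("tone_duration", "pstar_bin", "presented_final")
INTERACTION = ("pstar_bin", "presented_final")


def _cell_tensor(df: pd.DataFrame, dv: str, factors: tuple[str, ...]):
    """Cell means and replicate count of a balanced complete factorial."""
    levels = [np.sort(df[f].unique()) for f in factors]
    shape = tuple(len(l) for l in levels)
    counts = df.groupby(list(factors), observed=True)[dv].count()
    if len(counts) != np.prod(shape) or counts.nunique() != 1:
        missing = np.prod(shape) - len(counts)
        raise ValueError(
            f"unbalanced design: {missing} empty cell(s) or unequal "
            f"replicates per cell ({sorted(counts.unique())})"
        )
    means = (df.groupby(list(factors), observed=True)[dv].mean()
             .to_numpy().reshape(shape))
    return means, int(counts.iloc[0]), levels


def _effect_terms(m: np.ndarray) -> dict[tuple[int, ...], np.ndarray]:
    """Inclusion-exclusion decomposition of a cell-mean tensor.

    Returns, for every nonempty subset of axes, the effect array (marginal
    mean with all lower-order terms removed), broadcastable to m's shape.
    """
    nd = m.ndim
    grand = m.mean()
    terms: dict[tuple[int, ...], np.ndarray] = {(): np.asarray(grand)}
    for r in range(1, nd + 1):
        for axes in itertools.combinations(range(nd), r):
            other = tuple(a for a in range(nd) if a not in axes)
            marg = m.mean(axis=other, keepdims=True)
            e = marg.copy()
            for sub_r in range(r):
                for sub in itertools.combinations(axes, sub_r):
                    e = e - terms[sub]
            terms[axes] = e
    return terms


def factorial_anova(df: pd.DataFrame, dv: str = "likelihood_rating",
                    factors: tuple[str, ...] = FACTORS) -> pd.DataFrame:
    """Fixed-effects ANOVA on trial-level data of one subject.

    Balanced complete factorials only; sums of squares partition exactly
    (types I/II/III coincide).  Error is the within-cell (replicate)
    variation.
    """
    m, reps, levels = _cell_tensor(df, dv, factors)
    terms = _effect_terms(m)
    n_cells = m.size
    ss_cells = float(((df.groupby(list(factors), observed=True)[dv]
                       .transform("mean") - df[dv].mean()) ** 2).sum())
    ss_total = float(((df[dv] - df[dv].mean()) ** 2).sum())
    ss_error = ss_total - ss_cells
    df_error = len(df) - n_cells
    rows = []
    for axes, e in terms.items():
        if not axes:
            continue
        ss = reps * float((e ** 2).sum()) * np.prod(
            [m.shape[a] for a in range(m.ndim) if a not in axes])
        ddf = int(np.prod([m.shape[a] - 1 for a in axes]))
        mse = ss_error / df_error if df_error > 0 else np.nan
        f = (ss / ddf) / mse if df_error > 0 and mse > 0 else (
            0.0 if ss == 0 else np.inf)
        rows.append({
            "effect": ":".join(factors[a] for a in axes),
            "ss": ss, "df": ddf, "F": f,
            "p": stats.f.sf(f, ddf, df_error) if df_error > 0 else np.nan,
        })
    rows.append({"effect": "error", "ss": ss_error, "df": df_error,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def subject_interaction_F(behavior: pd.DataFrame,
                          dv: str = "likelihood_rating") -> float:
    """p34* x p34 interaction F from the single-subject three-way ANOVA.

    Constant ratings (zero within-cell variance and zero effect) give F = 0.
    """
    tab = factorial_anova(behavior, dv=dv, factors=FACTORS)
    name = ":".join(INTERACTION)
    f = float(tab.loc[tab["effect"] == name, "F"].iloc[0])
    return 0.0 if np.isnan(f) else f


# ---------------------------------------------------------------------------
# Group repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------


def group_rm_anova(behaviors: list[pd.DataFrame],
                   dv: str = "likelihood_rating",
                   factors: tuple[str, ...] = FACTORS) -> pd.DataFrame:
    """Within-subject three-way RM-ANOVA on per-subject cell means.

    For each effect, the error term is its interaction with subjects;
    Greenhouse-Geisser epsilon is estimated from the covariance of the
    orthonormal within-subject contrasts and applied whenever eps < 1.
    Reports F, uncorrected and GG-corrected p, epsilon, and partial eta^2.
    """
    cells = []
    levels0 = None
    for b in behaviors:
        m, _, levels = _cell_tensor(b, dv, factors)
        if levels0 is None:
            levels0 = [list(l) for l in levels]
        elif [list(l) for l in levels] != levels0:
            raise ValueError("subjects do not share the same cell structure")
        cells.append(m)
    y = np.stack(cells)  # (n_subj, L1, L2, L3)
    n_subj = y.shape[0]
    shape = y.shape[1:]
    nd = len(shape)

    # per-subject and group effect decompositions
    group_terms = _effect_terms(y.mean(axis=0))
    subj_terms = [_effect_terms(y[s]) for s in range(n_subj)]

    rows = []
    for r in range(1, nd + 1):
        for axes in itertools.combinations(range(nd), r):
            mult = np.prod([shape[a] for a in range(nd) if a not in axes])
            e = group_terms[axes]
            df1 = int(np.prod([shape[a] - 1 for a in axes]))
            ss = n_subj * mult * float((e ** 2).sum())
            dev = np.stack([subj_terms[s][axes] - e for s in range(n_subj)])
            ss_err = mult * float((dev ** 2).sum())
            df2 = (n_subj - 1) * df1
            ms, ms_err = ss / df1, ss_err / df2
            f = ms / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
            eps = _gg_epsilon(y, axes, shape)
            rows.append({
                "effect": ":".join(factors[a] for a in axes),
                "F": f, "df1": df1, "df2": df2,
                "p": stats.f.sf(f, df1, df2),
                "gg_eps": eps,
                "p_gg": stats.f.sf(f, eps * df1, eps * df2),
                "partial_eta_sq": ss / (ss + ss_err) if ss + ss_err > 0 else 0.0,
            })
    return pd.DataFrame(rows)


def _gg_epsilon(y: np.ndarray, axes: tuple[int, ...],
                shape: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for one within-subject effect."""
    n_subj = y.shape[0]
    other = tuple(a + 1 for a in range(len(shape)) if a not in axes)
    z = y.mean(axis=other) if other else y.copy()  # (n_subj, levels of axes)
    z = z.reshape(n_subj, -1)
    c = None
    for a in axes:
        h = helmert(shape[a], full=False)
        c = h if c is None else np.kron(c, h)
    w = z @ c.T
    if n_subj < 2:
        return 1.0
    sigma = np.cov(w, rowvar=False)
    sigma = np.atleast_2d(sigma)
    d = sigma.shape[0]
    tr = np.trace(sigma)
    tr2 = np.trace(sigma @ sigma)
    if tr2 <= 0:
        return 1.0
    eps = tr ** 2 / (d * tr2)
    return float(np.clip(eps, 1.0 / d, 1.0))


# ---------------------------------------------------------------------------
# Brain-behavior correlation
# ---------------------------------------------------------------------------


def _condition_averaged_kprime(kmaps: dict[int, list[KPrimeMap]],
                               windows: np.ndarray) -> np.ndarray:
    """(n_subj, S, W): k' averaged across the three duration conditions."""
    per_dur = [np.stack([km.kprime[:, windows] for km in kmaps[d]])
               for d in DURATION_AXES]
    return np.mean(per_dur, axis=0)


def brain_behavior_correlation(
    kmaps: dict[int, list[KPrimeMap]],
    members: np.ndarray,
    f_values: np.ndarray,
    windows: np.ndarray = np.arange(3),
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman rho between cluster-mean k' and interaction F per window.

    k' is averaged across the three tone-duration conditions and across the
    cluster's sensors for each subject; p-values are FDR-corrected
    (Benjamini-Hochberg) across the shared windows (0-150 ms).
    """
    f_values = np.asarray(f_values, dtype=float)
    if len(f_values) < 5:
        warnings.warn("fewer than 5 subjects: rank correlation is unstable")
    k = _condition_averaged_kprime(kmaps, windows)  # (subj, S, W)
    kc = k[:, np.asarray(members, dtype=int), :].mean(axis=1)  # (subj, W)
    rows = []
    for wi in range(kc.shape[1]):
        rho, p = stats.spearmanr(kc[:, wi], f_values)
        rows.append({"window": int(windows[wi]), "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], alpha=fdr_alpha,
                                 method="fdr_bh")[1]
    out["significant"] = out["p_fdr"] < fdr_alpha
    return out


def sensorwise_correlation_clusters(
    kmaps: dict[int, list[KPrimeMap]],
    knulls: dict[int, list[KPrimeNull]],
    f_values: np.ndarray,
    adjacency,
    windows: np.ndarray = np.arange(3),
    n_draws: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[int, list[cluster_perm.ClusterResult]]:
    """Sensor-wise k'-vs-F Spearman maps with cluster correction.

    The null draws one shuffle repetition per subject (condition-averaged
    k'_shuff), recomputes the sensor-wise correlation with the fixed F
    values, and repeats ``n_draws`` times.  Clusters of same-sign rho with
    two-tailed uncorrected p < alpha are scored by |sum rho| against the
    max-statistic null (top 2.5th percentile convention at alpha = 0.05).
    """
    f_values = np.asarray(f_values, dtype=float)
    n_subj = len(f_values)
    k = _condition_averaged_kprime(kmaps, windows)  # (subj, S, W)
    f_rank = stats.rankdata(f_values)

    null_stacks = []
    for d in DURATION_AXES:
        null_stacks.append(np.stack(
            [kn.kshuff[:, windows, :] for kn in knulls[d]]))
    null_k = np.mean(null_stacks, axis=0)  # (subj, S, W, rep)
    n_rep = null_k.shape[-1]
    rng = np.random.default_rng(seed)
    draw_idx = rng.integers(0, n_rep, size=(n_draws, n_subj))

    out = {}
    for wi in range(len(windows)):
        obs = _rank_corr_map(k[:, :, wi], f_rank)
        null = np.empty((n_draws, k.shape[1]))
        for d in range(n_draws):
            sample = null_k[np.arange(n_subj), :, wi, draw_idx[d]]
            null[d] = _rank_corr_map(sample, f_rank)
        out[int(windows[wi])] = cluster_perm.cluster_test_from_null_draws(
            obs, null, adjacency, tail="two", alpha=alpha)
    return out


def _rank_corr_map(x: np.ndarray, f_rank: np.ndarray) -> np.ndarray:
    """Spearman rho of each column of x (subj, S) with pre-ranked f."""
    rx = stats.rankdata(x, axis=0)
    rx = rx - rx.mean(axis=0)
    rf = f_rank - f_rank.mean()
    denom = np.sqrt((rx ** 2).sum(axis=0) * (rf ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = rf @ rx / denom
    return np.where(np.isfinite(rho), rho, 0.0)
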