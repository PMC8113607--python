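"""Hypothesis geometry: k' triples vs duration and information lines.

Integration orders estimated at the three tone durations form a vector
u = (k'_150, k'_300, k'_600) per sensor and time window.  A temporally fixed
integration span predicts u along the duration line v_dur = (4, 2, 1); a
fixed number of integrated items predicts the information line
v_info = (1, 1, 1).  Vectors are summarized by Euclidean norm and by the
angle to each orientation line, theta = atan2(||u x v||, u . v), and
compared against the shuffled-order null with one shuffle repetition drawn
per subject and condition.
"""

from __future__ import annotations

import numpy as np

from . import cluster_perm
from .shi import KPrimeMap, KPrimeNull

__all__ = [
    "V_DUR",
    "V_INFO",
    "plane_normal",
    "vector_norm",
    "vector_angle",
    "project_to_plane",
    "group_triples",
    "null_triples",
    "cluster_geometry_test",
    "arraywide_geometry_scan",
]

V_DUR = np.array([4.0, 2.0, 1.0])
V_INFO = np.array([1.0, 1.0, 1.0])

#: axis order of k' triples: (150 ms, 300 ms, 600 ms)
DURATION_AXES = (150, 300, 600)


def plane_normal() -> np.ndarray:
    """Normal of the plane spanned by the two orientation lines."""
    return np.cross(V_DUR, V_INFO)


def vector_norm(u: np.ndarray) -> np.ndarray:
    """Euclidean norm over the last axis; inputs must be finite."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite components in k' vector")
    return np.sqrt((u ** 2).sum(axis=-1))


def vector_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle in [0, pi] via the four-quadrant arctangent of cross and dot.

    atan2(||u x v||, u . v) is numerically stable near 0 and pi, unlike the
    arccos of the normalized dot product.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(vector_norm(u) == 0) or np.any(vector_norm(v) == 0):
        raise ValueError("angle undefined for zero vectors")
    cross = np.cross(u, v)
    return np.arctan2(np.sqrt((cross ** 2).sum(axis=-1)),
                      (u * v).sum(axis=-1))


def project_to_plane(u: np.ndarray, literal: bool = False) -> np.ndarray:
    """Nearest point on the duration-information plane.

    Default: signed orthogonal projection u - (u.N / N.N) N, idempotent and
    residual parallel to the normal.  ``literal=True`` applies an absolute
    value to the normal coefficient instead, a variant sometimes written for
    this correction that moves points with u.N > 0 away from the plane
    rather than onto it (exposed for comparison only).
    """
    u = np.asarray(u, dtype=float)
    n = plane_normal()
    nn = n @ n
    if nn == 0:
        raise ValueError("degenerate plane normal")
    coef = (0.0 - (u * n).sum(axis=-1)) / nn
    if literal:
        coef = np.abs(coef)
    return u + coef[..., None] * n


# ---------------------------------------------------------------------------
# Group-level triples and shuffle-null draws
# ---------------------------------------------------------------------------


def _check_conditions(maps: dict) -> None:
    if sorted(maps) != sorted(DURATION_AXES):
        raise ValueError(f"need maps for all of {DURATION_AXES}, got {sorted(maps)}")


def group_triples(kmaps: dict[int, list[KPrimeMap]],
                  windows: np.ndarray | None = None) -> np.ndarray:
    """Across-subject mean k' per sensor/window/condition: (S, W, 3).

    Only windows shared by all tone-duration conditions (0-150 ms, i.e. the
    first three 50-ms windows) are meaningful; ``windows`` restricts them.
    """
    _check_conditions(kmaps)
    out = []
    for dur in DURATION_AXES:
        m = np.mean([km.kprime for km in kmaps[dur]], axis=0)
        out.append(m if windows is None else m[:, windows])
    return np.stack(out, axis=-1)


def null_triples(
    knulls: dict[int, list[KPrimeNull]],
    n_draws: int = 1000,
    seed: int = 0,
    windows: np.ndarray | None = None,
    couple_reps: bool = False,
) -> np.ndarray:
    """Resampled null triples: (n_draws, S, W, 3).

    Each draw picks one shuffle repetition per subject and condition (with
    replacement) and averages across subjects.  By default repetition
    indices are drawn independently per condition, mirroring the fact that
    the observed k' values of the three conditions come from independent
    recordings; ``couple_reps=True`` reuses one repetition index across the
    three conditions (possible because shuffle orders are preserved across
    conditions, but it understates cross-condition null variability).
    """
    _check_conditions(knulls)
    n_subj = len(knulls[DURATION_AXES[0]])
    n_rep = knulls[DURATION_AXES[0]][0].kshuff.shape[-1]
    rng = np.random.default_rng(seed)
    if couple_reps:
        shared = rng.integers(0, n_rep, size=(n_draws, n_subj))
        idx = {dur: shared for dur in DURATION_AXES}
    else:
        idx = {dur: rng.integers(0, n_rep, size=(n_draws, n_subj))
               for dur in DURATION_AXES}
    stacks = {}
    for dur in DURATION_AXES:
        arr = np.stack([kn.kshuff for kn in knulls[dur]])  # (subj, S, W, rep)
        stacks[dur] = arr if windows is None else arr[:, :, windows, :]
    shape = stacks[DURATION_AXES[0]].shape[1:3]
    out = np.empty((n_draws,) + shape + (3,))
    subj_ix = np.arange(n_subj)
    for d in range(n_draws):
        for a, dur in enumerate(DURATION_AXES):
            out[d, :, :, a] = stacks[dur][subj_ix, :, :, idx[dur][d]].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def cluster_geometry_test(
    kmaps: dict[int, list[KPrimeMap]],
    knulls: dict[int, list[KPrimeNull]],
    members: np.ndarray,
    window: int,
    n_draws: int = 1000,
    seed: int = 0,
    project: bool = False,
    couple_reps: bool = False,
) -> dict:
    """Norm and angle statistics for one sensor cluster and window.

    Observed statistics are the cluster means of per-sensor norms and
    angles of the group-averaged triples (angle aggregation is the mean of
    per-sensor angles, not the angle of the mean vector).  One-tailed
    permutation p-values: norm significant when large (top tail), angle
    when small (bottom tail).  ``project=True`` computes all statistics on
    the 2-D in-plane embedding.
    """
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("empty cluster")
    obs_u = group_triples(kmaps)[members, window]  # (m, 3)
    null_u = null_triples(knulls, n_draws=n_draws, seed=seed,
                          couple_reps=couple_reps)[:, members, window]
    if project:
        obs_u = project_to_plane(obs_u)
        null_u = project_to_plane(null_u)
    obs_norm = vector_norm(obs_u).mean()
    null_norm = vector_norm(null_u).mean(axis=-1)
    res = {
        "norm": float(obs_norm),
        "norm_p": float((null_norm >= obs_norm).mean()),
        "triples": obs_u,
    }
    for name, line in (("info", V_INFO), ("duration", V_DUR)):
        obs_a = vector_angle(obs_u, line).mean()
        null_a = vector_angle(null_u, line).mean(axis=-1)
        res[f"angle_{name}"] = float(obs_a)
        res[f"angle_{name}_p"] = float((null_a <= obs_a).mean())
    return res


def arraywide_geometry_scan(
    kmaps: dict[int, list[KPrimeMap]],
    knulls: dict[int, list[KPrimeNull]],
    adjacency,
    line: str,
    window: int,
    n_draws: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    couple_reps: bool = False,
) -> dict:
    """Data-driven norm/angle cluster scan across the whole sensor array.

    ``line`` is 'info' or 'duration' for the angle scan, or 'norm'.  Angle
    clusters collect sensors whose angle is unusually SMALL relative to
    their own null (bottom tail); norm clusters unusually large (top tail).
    """
    obs_u = group_triples(kmaps)[:, window]  # (S, 3)
    null_u = null_triples(knulls, n_draws=n_draws, seed=seed,
                          couple_reps=couple_reps)[:, :, window]
    if line == "norm":
        obs = vector_norm(obs_u)
        null = vector_norm(null_u)
        clusters = cluster_perm.cluster_test_from_null_draws(
            obs, null, adjacency, tail="high", alpha=alpha)
    else:
        v = {"info": V_INFO, "duration": V_DUR}[line]
        obs = vector_angle(obs_u, v)
        null = vector_angle(null_u, v)
        clusters = cluster_perm.cluster_test_from_null_draws(
            obs, null, adjacency, tail="low", alpha=alpha)
    return {"map": obs, "clusters": clusters}


def export_triples_csv(path: str, triples: np.ndarray,
                       labels: list[str] | None = None) -> None:
    """Write (S, 3) k' triples as CSV (columns k150,k300,k600 [+ label])."""
    triples = np.atleast_2d(np.asarray(triples, dtype=float))
    with open(path, "w") as f:
        f.write("k150,k300,k600" + (",label\n" if labels else "\n"))
        for i, row in enumerate(triples):
            line = ",".join(f"{v:.6g}" for v in row)
            if labels:
                line += f",{labels[i]}"
            f.write(line + "\n")
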