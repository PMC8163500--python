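"""Permutation inference for paired condition comparisons.

Three tests, all built on the same exchangeability argument for paired
(within-participant) condition data:

* ``condition_permutation_test`` — a scalar per participant and condition;
  the null is built by re-running the paired t-test after swapping the
  condition labels of a random half of the participants (equivalently,
  flipping the sign of half of the paired differences).
* ``roi_global_permutation`` — values per region of interest; ROIs passing
  an uncorrected paired-t threshold contribute their t-values to a global
  sum, whose null distribution is built with the same half-swap scheme.
  Significance of the whole spatial pattern is assessed at once, which
  corrects for multiple comparisons across ROIs.
* ``cluster_permutation`` — a (unit × time) map per participant and
  condition; suprathreshold points of the paired-t map are grouped into
  spatio-temporally connected same-sign clusters and each cluster's mass
  (sum of t) is compared against the permutation distribution of the
  maximum cluster mass under per-participant sign flips.

All p-values use the add-one rule p = (1 + #{null ≥ observed}) / (1 + n_perm),
so the smallest attainable p is 1 / (n_perm + 1) and ties with the observed
statistic count against it (conservative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "PermutationResult",
    "RoiPermutationResult",
    "ClusterResult",
    "condition_permutation_test",
    "roi_global_permutation",
    "cluster_permutation",
    "windowed_roi_trf_test",
    "grid_adjacency",
]


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    null_distribution: np.ndarray
    p: float
    n_perm: int
    tail: str
    seed: int


@dataclass(frozen=True)
class RoiPermutationResult:
    roi_t: np.ndarray
    roi_p: np.ndarray
    suprathreshold: np.ndarray  # boolean mask over ROIs
    global_stat: float
    global_p: float
    null_distribution: np.ndarray
    n_perm: int
    seed: int
    hemisphere: str | None = None


@dataclass(frozen=True)
class ClusterResult:
    clusters: list = field(default_factory=list)  # {"members", "mass", "corrected_p"}
    threshold_p: float = 0.05
    n_perm: int = 0
    seed: int = 0

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c["corrected_p"] < alpha]


def _paired_t(diff: np.ndarray, axis: int = -1) -> np.ndarray:
    """t statistic of mean(diff) against 0; 0/0 (no difference at all) -> 0."""
    n = diff.shape[axis]
    mean = diff.mean(axis=axis)
    sd = diff.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        degenerate = np.where(np.asarray(mean) == 0, 0.0,
                              np.inf * np.where(np.asarray(mean) > 0, 1.0, -1.0))
    return np.where(np.asarray(sd) == 0, degenerate, t)


def _half_swap_signs(rng: np.random.Generator, n_perm: int, n: int,
                     scheme: str) -> np.ndarray:
    """(n_perm, n) sign matrix for the permutation null.

    ``half_swap``: exactly floor(n/2) participants have their condition
    labels swapped per permutation (literal reading of the published
    scheme).  ``bernoulli``: each participant is swapped independently
    with probability 1/2 (the FieldTrip-style convention).
    """
    if scheme == "half_swap":
        signs = np.ones((n_perm, n))
        k = n // 2
        for row in signs:
            row[rng.permutation(n)[:k]] = -1.0
        return signs
    if scheme == "bernoulli":
        return rng.choice([-1.0, 1.0], size=(n_perm, n))
    raise ValueError(f"unknown scheme {scheme!r}")


def _add_one_p(null: np.ndarray, observed: float, tail: str) -> float:
    if tail == "one_sided_greater":
        return float((1 + np.sum(null >= observed)) / (1 + null.size))
    if tail == "two_sided":
        return float((1 + np.sum(np.abs(null) >= abs(observed))) / (1 + null.size))
    raise ValueError(f"unknown tail {tail!r}")


def condition_permutation_test(values_a, values_b, n_perm: int = 1000,
                               tail: str = "one_sided_greater", seed: int = 0,
                               scheme: str = "half_swap") -> PermutationResult:
    """Paired-t permutation test of condition A vs condition B.

    Swapping a participant's condition labels flips the sign of their
    paired difference, so the null is generated directly on the
    differences.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be equal-length 1-D arrays")
    n = a.size
    if n < 4:
        raise ValueError(f"need at least 4 paired participants, got {n} "
                         "(permutation null too coarse)")
    diff = a - b
    observed = float(_paired_t(diff))
    rng = np.random.default_rng(seed)
    signs = _half_swap_signs(rng, n_perm, n, scheme)
    null = _paired_t(signs * diff[None, :], axis=1)
    return PermutationResult(observed_stat=observed, null_distribution=null,
                             p=_add_one_p(null, observed, tail),
                             n_perm=n_perm, tail=tail, seed=seed)


def roi_global_permutation(roi_values_a, roi_values_b, threshold_p: float = 0.05,
                           n_perm: int = 1000, seed: int = 0,
                           scheme: str = "half_swap", signed: bool = True,
                           hemisphere: str | None = None) -> RoiPermutationResult:
    """Sum-of-suprathreshold-t global statistic over ROIs, permutation-corrected.

    ROIs whose paired t passes an uncorrected two-sided threshold
    contribute their t to the global statistic (signed sum by default; set
    ``signed=False`` to sum |t| when no direction is predicted).  The
    pattern is significant when the observed global statistic falls in the
    top 5% of its half-swap permutation null.
    """
    a = np.asarray(roi_values_a, dtype=float)
    b = np.asarray(roi_values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("ROI inputs must be matching (participants x ROIs) arrays")
    n, n_roi = a.shape
    if n_roi < 2:
        raise ValueError("need at least 2 ROIs")
    diff = a - b
    df = n - 1
    t_crit = stats.t.ppf(1 - threshold_p / 2, df)

    def global_stat(d):
        # d: (..., n, n_roi); paired t per ROI along participant axis
        t = _paired_t(d, axis=-2)
        supra = np.abs(t) > t_crit
        contrib = t if signed else np.abs(t)
        return t, supra, np.sum(np.where(supra, contrib, 0.0), axis=-1)

    t_obs, supra_obs, g_obs = global_stat(diff)
    roi_p = 2 * stats.t.sf(np.abs(t_obs), df)
    rng = np.random.default_rng(seed)
    signs = _half_swap_signs(rng, n_perm, n, scheme)
    _, _, null = global_stat(signs[:, :, None] * diff[None, :, :])
    return RoiPermutationResult(
        roi_t=t_obs, roi_p=roi_p, suprathreshold=supra_obs,
        global_stat=float(g_obs), global_p=_add_one_p(null, float(g_obs),
                                                      "one_sided_greater"),
        null_distribution=null, n_perm=n_perm, seed=seed, hemisphere=hemisphere)


def grid_adjacency(n_rows: int, n_cols: int) -> np.ndarray:
    """Rook adjacency for channels laid out on an n_rows x n_cols grid."""
    n = n_rows * n_cols
    adj = np.zeros((n, n), dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                adj[i, i + 1] = adj[i + 1, i] = True
            if r + 1 < n_rows:
                adj[i, i + n_cols] = adj[i + n_cols, i] = True
    return adj


def _normalize_adjacency(adjacency, n_units: int) -> np.ndarray:
    adj = np.asarray(adjacency, dtype=bool)
    if adj.shape != (n_units, n_units):
        raise ValueError(f"adjacency must be ({n_units}, {n_units}), got {adj.shape}")
    adj = adj | adj.T
    np.fill_diagonal(adj, False)
    if np.any(~adj.any(axis=0)):
        warnings.warn("adjacency contains units with no neighbours; they are "
                      "treated as singleton-adjacent", stacklevel=3)
    return adj


def _find_clusters(tmap: np.ndarray, t_crit: float, unit_edges: np.ndarray):
    """Connected same-sign suprathreshold clusters of a (units x bins) t map.

    Connectivity: consecutive time bins within a unit, and identical time
    bins across adjacent units.  Returns (list of member-index arrays,
    masses).
    """
    n_units, n_bins = tmap.shape
    sign = np.where(tmap > t_crit, 1, np.where(tmap < -t_crit, -1, 0))
    supra = np.flatnonzero(sign)
    if supra.size == 0:
        return [], np.array([])
    flat_sign = sign.ravel()
    # temporal edges: (u, b) -- (u, b+1), same sign, both suprathreshold
    left = np.arange(n_units * n_bins).reshape(n_units, n_bins)[:, :-1].ravel()
    right = left + 1
    tmask = (flat_sign[left] != 0) & (flat_sign[left] == flat_sign[right])
    edges_i = [left[tmask]]
    edges_j = [right[tmask]]
    # spatial edges: (u, b) -- (v, b) for adjacent units, same sign
    if unit_edges.size:
        for u, v in unit_edges:
            iu = u * n_bins + np.arange(n_bins)
            iv = v * n_bins + np.arange(n_bins)
            smask = (flat_sign[iu] != 0) & (flat_sign[iu] == flat_sign[iv])
            edges_i.append(iu[smask])
            edges_j.append(iv[smask])
    ei = np.concatenate(edges_i)
    ej = np.concatenate(edges_j)
    n_nodes = n_units * n_bins
    graph = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n_nodes, n_nodes))
    n_comp, labels = connected_components(graph, directed=False)
    comp_of_supra = labels[supra]
    members, masses = [], []
    flat_t = tmap.ravel()
    for comp in np.unique(comp_of_supra):
        idx = supra[comp_of_supra == comp]
        members.append(idx)
        masses.append(flat_t[idx].sum())
    return members, np.asarray(masses)


def cluster_permutation(data_a, data_b, adjacency, threshold_p: float = 0.05,
                        n_perm: int = 1000, seed: int = 0) -> ClusterResult:
    """Spatio-temporal cluster permutation test for paired condition maps.

    ``data_a``/``data_b``: (participants, units, time_bins).  First-level
    paired t per point; suprathreshold points (|t| above the two-sided
    ``threshold_p`` quantile) are clustered by spatio-temporal
    connectivity, and cluster mass (sum of t) is referred to the
    permutation null of the maximum |mass| under per-participant condition
    sign flips.  Cluster members are reported as (unit, time_bin) pairs.
    """
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("inputs must be matching (participants, units, bins) arrays")
    n, n_units, n_bins = a.shape
    if n_bins < 2:
        raise ValueError("need at least 2 time bins")
    adj = _normalize_adjacency(adjacency, n_units)
    unit_edges = np.argwhere(np.triu(adj))
    diff = a - b
    df = n - 1
    t_crit = float(stats.t.ppf(1 - threshold_p / 2, df))

    members, masses = _find_clusters(_paired_t(diff, axis=0), t_crit, unit_edges)
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for k in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        _, perm_masses = _find_clusters(
            _paired_t(signs[:, None, None] * diff, axis=0), t_crit, unit_edges)
        null[k] = np.max(np.abs(perm_masses)) if perm_masses.size else 0.0

    order = np.argsort(-np.abs(masses))
    clusters = []
    for i in order:
        units, bins = np.unravel_index(members[i], (n_units, n_bins))
        clusters.append({
            "members": list(zip(units.tolist(), bins.tolist())),
            "mass": float(masses[i]),
            "corrected_p": _add_one_p(null, abs(float(masses[i])),
                                      "one_sided_greater"),
        })
    return ClusterResult(clusters=clusters, threshold_p=threshold_p,
                         n_perm=n_perm, seed=seed)


def windowed_roi_trf_test(trf_a, trf_b, times, adjacency,
                          window_len: float = 0.020,
                          analysis_window: tuple = (0.070, 0.180),
                          threshold_p: float = 0.05, n_perm: int = 1000,
                          seed: int = 0) -> ClusterResult:
    """Cluster test on ROI TRFs averaged in consecutive fixed-length windows.

    TRFs are averaged within consecutive ``window_len`` windows tiling
    ``analysis_window`` (a trailing window that does not fully fit is
    dropped), then passed to :func:`cluster_permutation` over
    ROIs x windows.  Cluster members are (roi, window_index) pairs.
    """
    a = np.asarray(trf_a, dtype=float)
    b = np.asarray(trf_b, dtype=float)
    times = np.asarray(times, dtype=float)
    if a.shape != b.shape or a.ndim != 3 or a.shape[2] != times.size:
        raise ValueError("TRF inputs must be (participants, ROIs, time) with a "
                         "matching time axis")
    lo, hi = analysis_window
    if times[0] > lo + 1e-9 or times[-1] < hi - 1e-9:
        raise ValueError(f"TRF time axis [{times[0]}, {times[-1]}] does not "
                         f"cover the analysis window [{lo}, {hi}]")
    dt = float(np.median(np.diff(times)))
    if abs(window_len / dt - round(window_len / dt)) > 1e-6:
        raise ValueError(f"window of {window_len} s is not a whole number of "
                         f"TRF samples (dt = {dt} s)")
    starts = []
    s = lo
    while s + window_len <= hi + 1e-9:
        starts.append(s)
        s += window_len
    wa, wb = [], []
    for s in starts:
        m = (times >= s - 1e-9) & (times < s + window_len - 1e-9)
        wa.append(a[:, :, m].mean(axis=2))
        wb.append(b[:, :, m].mean(axis=2))
    return cluster_permutation(np.stack(wa, axis=2), np.stack(wb, axis=2),
                               adjacency, threshold_p=threshold_p,
                               n_perm=n_perm, seed=seed)


def permutation_result_to_tsv(path, results: dict) -> None:
    """Write a table of named permutation results (stat, p, n_perm, seed)."""
    rows = [{"test": name, "stat": r.observed_stat if hasattr(r, "observed_stat")
             else r.global_stat,
             "p": r.p if hasattr(r, "p") else r.global_p,
             "n_perm": r.n_perm, "seed": r.seed}
            for name, r in results.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
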