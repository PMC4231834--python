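"""Cluster-based non-parametric permutation tests against baseline.

Group maps (one per participant, baseline-corrected so the null is zero)
are tested point-wise with one-sample t-tests; supra-threshold points of
equal sign are merged into clusters under an adjacency relation
(neighbouring time samples, neighbouring frequency bins in
time-frequency space, and neighbouring electrodes on the montage grid;
no diagonal connections).  The cluster mass is the signed sum of member
t-values.  The null distribution of the maximal |mass| is obtained by
repeatedly flipping the sign of randomly chosen participants' maps --
the sign-flip realization of exchanging evoked signal and baseline for
baseline-subtracted data -- and a cluster's p-value is the fraction of
permutation max-masses at least as large as its |mass| (the observed
statistic is not added to the null; p = 0 is reported as < 1/n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

#: t assigned to zero-variance points with nonzero mean.
T_SENTINEL = 1e6


@dataclass
class Cluster:
    """A connected set of supra-threshold points.

    ``indices`` are flat indices into the point space of shape ``shape``
    (last axis = electrodes; preceding axes time and, for time-frequency
    data, frequency).
    """

    indices: np.ndarray
    shape: tuple[int, ...]
    sign: int
    mass: float
    peak_index: int
    p_value: float | None = None
    p_ceiling: float | None = None   # set to 1/n_perm when p_value == 0
    significant: bool | None = None

    def member_coords(self) -> np.ndarray:
        """(n_members, ndim) array of point coordinates."""
        return np.stack(np.unravel_index(self.indices, self.shape), axis=1)


def pointwise_t(group: np.ndarray) -> np.ndarray:
    """One-sample t against zero at every point.

    group: (n_participants, *point_shape).  Zero-variance points get t = 0
    when their mean is zero, otherwise a signed large sentinel (logged).
    """
    group = np.asarray(group, dtype=float)
    n = group.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    m = group.mean(axis=0)
    sd = group.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var & (m != 0)):
        warnings.warn("zero-variance points with nonzero mean set to "
                      "sentinel t-values", stacklevel=2)
    t = np.where(zero_var, np.where(m == 0, 0.0, np.sign(m) * T_SENTINEL), t)
    return t


def t_threshold(df: int, alpha: float = 0.05) -> float:
    """Two-tailed point-wise threshold from the t distribution."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.t.ppf(1 - alpha / 2, df))


def _component_indices(mask: np.ndarray,
                       ch_adjacency: np.ndarray | None) -> list[np.ndarray]:
    """Connected components of True points.

    Grid axes (all but the last) connect +/-1 neighbours; the last axis
    connects electrode pairs marked in ``ch_adjacency`` (None = no
    cross-electrode connections).
    """
    if not mask.any():
        return []
    flat = np.arange(mask.size).reshape(mask.shape)
    heads, tails = [], []
    for ax in range(mask.ndim - 1):
        s1 = [slice(None)] * mask.ndim
        s2 = [slice(None)] * mask.ndim
        s1[ax], s2[ax] = slice(0, -1), slice(1, None)
        both = mask[tuple(s1)] & mask[tuple(s2)]
        heads.append(flat[tuple(s1)][both])
        tails.append(flat[tuple(s2)][both])
    if ch_adjacency is not None:
        a_idx, b_idx = np.where(np.triu(ch_adjacency, 1))
        for a, b in zip(a_idx, b_idx):
            both = mask[..., a] & mask[..., b]
            heads.append(flat[..., a][both])
            tails.append(flat[..., b][both])
    nodes = np.flatnonzero(mask)
    remap = np.full(mask.size, -1, dtype=np.int64)
    remap[nodes] = np.arange(nodes.size)
    if heads:
        h = remap[np.concatenate(heads)]
        t = remap[np.concatenate(tails)]
    else:
        h = t = np.empty(0, dtype=np.int64)
    graph = sparse.coo_matrix(
        (np.ones(h.size, dtype=np.int8), (h, t)),
        shape=(nodes.size, nodes.size))
    n_comp, labels = connected_components(graph, directed=False)
    return [nodes[labels == c] for c in range(n_comp)]


def form_clusters(t_map: np.ndarray, df: int, alpha: float = 0.05,
                  ch_adjacency: np.ndarray | None = None) -> list[Cluster]:
    """Clusters of supra-threshold points, separately per sign."""
    thr = t_threshold(df, alpha)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t_map) > thr
        for idx in _component_indices(mask, ch_adjacency):
            vals = t_map.ravel()[idx]
            peak = idx[int(np.argmax(sign * vals))]
            clusters.append(Cluster(
                indices=np.sort(idx), shape=t_map.shape, sign=sign,
                mass=float(vals.sum()), peak_index=int(peak)))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_mass(t_map: np.ndarray, df: int, alpha: float,
              ch_adjacency: np.ndarray | None) -> float:
    thr = t_threshold(df, alpha)
    best = 0.0
    flat_t = t_map.ravel()
    for sign in (1, -1):
        mask = (sign * t_map) > thr
        for idx in _component_indices(mask, ch_adjacency):
            best = max(best, abs(float(flat_t[idx].sum())))
    return best


def permutation_null(group: np.ndarray, n_perm: int, alpha: float = 0.05,
                     ch_adjacency: np.ndarray | None = None,
                     rng: np.random.Generator | int | None = None
                     ) -> np.ndarray:
    """Max-|mass| permutation distribution from per-participant sign flips.

    Each permutation multiplies every participant's map by an independent
    +/-1, recomputes the t-map and its clusters, and records the largest
    absolute cluster mass (0 when no point is supra-threshold).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    group = np.asarray(group, dtype=float)
    n = group.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    out = np.empty(n_perm)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    expand = (slice(None),) + (None,) * (group.ndim - 1)
    # the flipped t-map goes through the same code path as the observed
    # one, so a permutation reproducing the observed signs yields a
    # bit-identical mass (ties count as "same or larger")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_perm):
            t = pointwise_t(signs[k][expand] * group)
            out[k] = _max_mass(t, n - 1, alpha, ch_adjacency)
    return out


def score_clusters(clusters: list[Cluster], null: np.ndarray,
                   alpha: float = 0.05) -> list[Cluster]:
    """Attach permutation p-values: p = #(null >= |mass|) / n_perm."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    for c in clusters:
        # relative tolerance so numerically tied masses count as "same"
        p = float((null >= abs(c.mass) * (1 - 1e-12) - 1e-12).mean())
        c.p_value = p
        c.p_ceiling = 1.0 / null.size if p == 0 else None
        c.significant = p < alpha
    return clusters


def cluster_mean_amplitude(participant_map: np.ndarray,
                           cluster: Cluster) -> float:
    """Unweighted mean of one participant's values over the cluster's
    member points (the per-participant response magnitude used in
    brain-behaviour correlations)."""
    if cluster.indices.size == 0:
        raise ValueError("empty cluster")
    pm = np.asarray(participant_map, dtype=float)
    if pm.shape != cluster.shape:
        raise ValueError("participant map shape does not match cluster")
    return float(pm.ravel()[cluster.indices].mean())


def run_cluster_test(group: np.ndarray, n_perm: int = 1000,
                     alpha: float = 0.05,
                     ch_adjacency: np.ndarray | None = None,
                     rng: np.random.Generator | int | None = None
                     ) -> tuple[list[Cluster], np.ndarray]:
    """Point-wise t -> clusters -> permutation null -> scored clusters."""
    t_map = pointwise_t(group)
    clusters = form_clusters(t_map, group.shape[0] - 1, alpha, ch_adjacency)
    null = permutation_null(group, n_perm, alpha, ch_adjacency, rng)
    return score_clusters(clusters, null, alpha), null


def summarize_cluster(cluster: Cluster, times_ms: np.ndarray,
                      ch_names: tuple[str, ...], t_map: np.ndarray,
                      freqs: np.ndarray | None = None) -> dict:
    """Report-ready summary (start/end ms, peak electrode, peak t, peak
    time, frequency extent for time-frequency clusters)."""
    coords = cluster.member_coords()
    time_ax = 0 if freqs is None else 1
    t_members = coords[:, time_ax]
    peak = np.unravel_index(cluster.peak_index, cluster.shape)
    out = {
        "start_ms": float(times_ms[t_members.min()]),
        "end_ms": float(times_ms[t_members.max()]),
        "sign": "positive" if cluster.sign > 0 else "negative",
        "mass": cluster.mass,
        "p_value": cluster.p_value,
        "p_ceiling": cluster.p_ceiling,
        "significant": cluster.significant,
        "peak_electrode": ch_names[peak[-1]],
        "peak_t": float(np.asarray(t_map).ravel()[cluster.peak_index]),
        "peak_time_ms": float(times_ms[peak[time_ax]]),
        "n_points": int(cluster.indices.size),
    }
    if freqs is not None:
        out["min_freq_hz"] = float(freqs[coords[:, 0].min()])
        out["max_freq_hz"] = float(freqs[coords[:, 0].max()])
        out["peak_freq_hz"] = float(freqs[peak[0]])
    return out
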