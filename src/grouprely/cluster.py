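"""Cluster-based label-randomization test for condition effects on power.

The multiple-comparison problem over a (channel x frequency) grid is handled
by the max-statistic approach: a pointwise one-way F statistic is thresholded
at a parametric critical value, supra-threshold points are merged into
connected spatio-spectral clusters, and each observed cluster's mass (sum of
member F values) is compared against the distribution of the *maximum*
cluster mass obtained under random permutations of the condition labels.
Under the null hypothesis the trials of all conditions stem from the same
distribution, so labels are exchangeable.

Connectivity: two points are neighbors iff they sit on the same channel at
frequencies 1 Hz apart, or on spatially adjacent channels at the same
frequency.  Channel adjacency is a user-supplied distance graph — spatial
neighborhoods are montage-specific configuration, not something this module
hard-codes.

The permutation p-value includes the observed statistic,
``p = (#{null >= observed} + 1) / (n_perm + 1)``, so it can never be zero.

A note on naming: at the single-trial level the condition groups are
independent samples, so the pointwise statistic here is the ordinary one-way
(between-groups) F across trials.  An across-subject variant computes the
same F on per-subject condition means with condition labels permuted within
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .types import ChannelLayout, ValidationError

__all__ = [
    "StatMap",
    "Adjacency",
    "Cluster",
    "ClusterResult",
    "pointwise_f",
    "build_adjacency",
    "find_clusters",
    "cluster_permutation_test",
    "cluster_permutation_test_subjects",
]


@dataclass
class StatMap:
    """Pointwise one-way F statistics on a (channel, frequency) grid."""

    F: np.ndarray  # (n_channels, n_freqs)
    df_between: int
    df_within: int
    freqs_hz: np.ndarray | None = None  # integer grid; defaults to 0..n_freqs-1

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValidationError(f"F: expected 2 axes, got {self.F.ndim}")
        if np.any(self.F < 0):
            raise ValidationError("F: negative F statistic")
        if self.freqs_hz is None:
            self.freqs_hz = np.arange(self.F.shape[1])
        else:
            self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.int64)
            if self.freqs_hz.shape != (self.F.shape[1],):
                raise ValidationError("freqs_hz: length must match F columns")


@dataclass
class Adjacency:
    """Symmetric, irreflexive channel neighbor graph.

    Frequency adjacency is implicit: the 1 Hz chain on the integer grid.
    """

    channel_adj: np.ndarray  # (n_channels, n_channels) boolean

    def __post_init__(self) -> None:
        adj = np.asarray(self.channel_adj, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValidationError(f"channel_adj: expected square, got {adj.shape}")
        if not np.array_equal(adj, adj.T):
            raise ValidationError("channel_adj: must be symmetric")
        if np.any(np.diag(adj)):
            raise ValidationError("channel_adj: self-edges are not allowed")
        self.channel_adj = adj

    @property
    def n_channels(self) -> int:
        return self.channel_adj.shape[0]

    def neighbors(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.channel_adj[c])


@dataclass
class Cluster:
    """A connected set of supra-threshold (channel, frequency) points."""

    points: list[tuple[int, int]]  # (channel index, frequency Hz)
    mass: float
    p_value: float | None = None
    significant: bool = False


@dataclass
class ClusterResult:
    clusters: list[Cluster]  # sorted by mass, descending
    threshold: float
    n_perm: int
    seed: int
    alpha: float
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))
    stat_map: StatMap | None = None

    @property
    def min_p(self) -> float | None:
        return self.clusters[0].p_value if self.clusters else None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alpha": self.alpha,
            "clusters": [
                {
                    "points": [[int(c), int(f)] for c, f in cl.points],
                    "mass": cl.mass,
                    "p_value": cl.p_value,
                    "significant": cl.significant,
                }
                for cl in self.clusters
            ],
        }


def pointwise_f(power: np.ndarray, labels: np.ndarray,
                freqs_hz=None) -> StatMap:
    """One-way F statistic at every (channel, frequency) point.

    ``power`` is (n_trials, n_channels, n_freqs); ``labels`` assigns each
    trial to a condition.  Every condition needs at least 2 trials.
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 3:
        raise ValidationError(f"power: expected 3 axes, got {power.ndim}")
    labels = np.asarray(labels)
    if labels.shape != (power.shape[0],):
        raise ValidationError(
            f"labels: length {labels.shape} != {power.shape[0]} trials"
        )
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("labels: need at least 2 conditions")
    if np.any(counts < 2):
        small = classes[counts < 2].tolist()
        raise ValidationError(f"labels: condition(s) {small} have < 2 trials")
    n, n_ch, n_fr = power.shape
    Y = power.reshape(n, n_ch * n_fr)
    F = _f_stats_batch(Y, labels[None, :], classes, counts)[0]
    return StatMap(
        F=F.reshape(n_ch, n_fr),
        df_between=int(classes.size - 1),
        df_within=int(n - classes.size),
        freqs_hz=freqs_hz,
    )


def _f_stats_batch(
    Y: np.ndarray, label_rows: np.ndarray, classes: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """One-way F per point for a batch of label assignments.

    ``Y`` is (n, q); ``label_rows`` is (B, n), each row a relabeling with the
    same per-class counts.  Returns (B, q) F values.  Vectorized via indicator
    mat-muls so the permutation null costs B matrix products, not B loops.
    """
    n, q = Y.shape
    B = label_rows.shape[0]
    total = Y.sum(axis=0)  # (q,)
    sst = (Y**2).sum(axis=0) - total**2 / n
    ssb = np.zeros((B, q))
    for c, n_c in zip(classes, counts):
        M = (label_rows == c).astype(float)  # (B, n)
        gsum = M @ Y  # (B, q)
        ssb += gsum**2 / n_c
    ssb -= total**2 / n
    ssw = np.maximum(sst[None, :] - ssb, 0.0)
    dfb = classes.size - 1
    dfw = n - classes.size
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F[~np.isfinite(F)] = 0.0
    return np.maximum(F, 0.0)


def build_adjacency(layout: ChannelLayout, max_dist: float) -> Adjacency:
    """Channels are neighbors iff their Euclidean distance is <= ``max_dist``."""
    if max_dist <= 0:
        raise ValidationError(f"max_dist: must be positive, got {max_dist}")
    pos = layout.pos
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = d <= max_dist
    np.fill_diagonal(adj, False)
    return Adjacency(channel_adj=adj)


def _grid_neighbor_lists(n_ch: int, n_fr: int, adj: Adjacency) -> list[np.ndarray]:
    """Flat-index neighbor lists for the (channel x frequency) grid."""
    neighbors: list[np.ndarray] = []
    for c in range(n_ch):
        ch_nb = adj.neighbors(c)
        for f in range(n_fr):
            nb = []
            if f > 0:
                nb.append(c * n_fr + f - 1)
            if f < n_fr - 1:
                nb.append(c * n_fr + f + 1)
            nb.extend(ch_nb * n_fr + f)
            neighbors.append(np.asarray(nb, dtype=np.int64))
    return neighbors


def _connected_components(
    supra: np.ndarray, neighbors: list[np.ndarray]
) -> list[list[int]]:
    """Components of the supra-threshold node set (stack-based flood fill)."""
    comps = []
    seen = np.zeros(len(supra), dtype=bool)
    for start in np.flatnonzero(supra):
        if seen[start]:
            continue
        stack = [int(start)]
        seen[start] = True
        comp = []
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in neighbors[node]:
                if supra[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(int(nb))
        comps.append(comp)
    return comps


def find_clusters(
    stat_map: StatMap, threshold: float, adj: Adjacency
) -> list[Cluster]:
    """Partition supra-threshold points (F > threshold) into clusters.

    Points are connected along the frequency chain within a channel and
    across adjacent channels at equal frequency.  Returns clusters sorted by
    mass, descending; no supra-threshold point yields an empty list.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold: must be positive, got {threshold}")
    n_ch, n_fr = stat_map.F.shape
    if adj.n_channels != n_ch:
        raise ValidationError(
            f"adjacency: {adj.n_channels} channels but map has {n_ch}"
        )
    Fflat = stat_map.F.ravel()
    supra = Fflat > threshold
    neighbors = _grid_neighbor_lists(n_ch, n_fr, adj)
    clusters = []
    for comp in _connected_components(supra, neighbors):
        points = [
            (node // n_fr, int(stat_map.freqs_hz[node % n_fr])) for node in comp
        ]
        clusters.append(Cluster(points=points, mass=float(Fflat[comp].sum())))
    clusters.sort(key=lambda c: c.mass, reverse=True)
    return clusters


def _max_cluster_stat(
    Fflat: np.ndarray, threshold: float, neighbors: list[np.ndarray], stat: str
) -> float:
    supra = Fflat > threshold
    if not supra.any():
        return 0.0
    best = 0.0
    for comp in _connected_components(supra, neighbors):
        val = float(Fflat[comp].sum()) if stat == "mass" else float(len(comp))
        best = max(best, val)
    return best


def cluster_permutation_test(
    power: np.ndarray,
    labels: np.ndarray,
    adj: Adjacency,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    stat: str = "mass",
    freqs_hz=None,
    batch: int = 100,
) -> ClusterResult:
    """Max-cluster-mass randomization test on single-trial power.

    The cluster-forming threshold is the parametric F critical value at
    ``cluster_alpha`` for the map's degrees of freedom.  The null
    distribution is the maximum cluster statistic over each of ``n_perm``
    random relabelings (0 when a relabeling yields no supra-threshold
    cluster).  A cluster is significant iff its p-value is <= ``alpha``.
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm: must be >= 1, got {n_perm}")
    if stat not in ("mass", "size"):
        raise ValidationError(f"stat: expected mass|size, got {stat!r}")
    observed = pointwise_f(power, labels, freqs_hz=freqs_hz)
    threshold = float(
        scipy.stats.f.ppf(1 - cluster_alpha, observed.df_between, observed.df_within)
    )
    n, n_ch, n_fr = power.shape
    neighbors = _grid_neighbor_lists(n_ch, n_fr, adj)
    clusters = find_clusters(observed, threshold, adj)

    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    Y = np.asarray(power, dtype=float).reshape(n, n_ch * n_fr)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm_labels = np.stack([labels[rng.permutation(n)] for _ in range(b)])
        Fb = _f_stats_batch(Y, perm_labels, classes, counts)
        for i in range(b):
            null_max[done + i] = _max_cluster_stat(Fb[i], threshold, neighbors, stat)
        done += b

    for cl in clusters:
        obs = cl.mass if stat == "mass" else float(len(cl.points))
        cl.p_value = float((np.sum(null_max >= obs) + 1) / (n_perm + 1))
        cl.significant = cl.p_value <= alpha
    return ClusterResult(
        clusters=clusters,
        threshold=threshold,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        null_max_mass=null_max,
        stat_map=observed,
    )


def cluster_permutation_test_subjects(
    cond_means: np.ndarray,
    adj: Adjacency,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    stat: str = "mass",
    freqs_hz=None,
) -> ClusterResult:
    """Across-subject variant on per-subject condition means.

    ``cond_means`` is (n_subjects, n_conditions, n_channels, n_freqs): each
    subject contributes one mean power map per condition.  The pointwise F
    treats subject-condition means as observations grouped by condition;
    the null permutes condition labels *within each subject*, respecting the
    repeated-measures exchangeability structure.
    """
    cond_means = np.asarray(cond_means, dtype=float)
    if cond_means.ndim != 4:
        raise ValidationError(
            f"cond_means: expected 4 axes (subject, condition, channel, freq), "
            f"got {cond_means.ndim}"
        )
    n_subj, n_cond, n_ch, n_fr = cond_means.shape
    if n_subj < 2 or n_cond < 2:
        raise ValidationError("cond_means: need >= 2 subjects and >= 2 conditions")
    if n_perm < 1:
        raise ValidationError(f"n_perm: must be >= 1, got {n_perm}")
    power = cond_means.reshape(n_subj * n_cond, n_ch, n_fr)
    labels = np.tile(np.arange(n_cond), n_subj)
    observed = pointwise_f(power, labels, freqs_hz=freqs_hz)
    threshold = float(
        scipy.stats.f.ppf(1 - cluster_alpha, observed.df_between, observed.df_within)
    )
    neighbors = _grid_neighbor_lists(n_ch, n_fr, adj)
    clusters = find_clusters(observed, threshold, adj)

    classes, counts = np.unique(labels, return_counts=True)
    Y = power.reshape(n_subj * n_cond, n_ch * n_fr)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        perm = np.concatenate(
            [rng.permutation(n_cond) + s * n_cond for s in range(n_subj)]
        )
        F = _f_stats_batch(Y, labels[perm][None, :], classes, counts)[0]
        null_max[p] = _max_cluster_stat(F, threshold, neighbors, stat)

    for cl in clusters:
        obs = cl.mass if stat == "mass" else float(len(cl.points))
        cl.p_value = float((np.sum(null_max >= obs) + 1) / (n_perm + 1))
        cl.significant = cl.p_value <= alpha
    return ClusterResult(
        clusters=clusters,
        threshold=threshold,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        null_max_mass=null_max,
        stat_map=observed,
    )
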