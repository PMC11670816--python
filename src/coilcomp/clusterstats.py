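"""Spatiotemporal cluster-based permutation tests for paired designs.

Observed paired-t maps over channels x time are thresholded; maximal
connected components under (same channel, adjacent samples) union
(neighboring channels, same sample) connectivity form clusters, scored
by their summed t (mass). The null distribution of the maximal cluster
mass is built by per-subject condition swaps, i.e. sign flips of the
subject difference maps: random draws by default, falling back to
exhaustive enumeration of all 2^n sign patterns when the requested
number of permutations reaches or exceeds it. Monte-Carlo p-values use
the +1 correction; exhaustive p-values are exact proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import Montage


@dataclass
class NeighborGraph:
    """Symmetric channel adjacency without self-edges."""

    labels: tuple
    adjacency: np.ndarray  # (n, n) bool

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.labels):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-edges not allowed")
        self.adjacency = a

    @property
    def isolated(self) -> list:
        deg = self.adjacency.sum(axis=1)
        return [l for l, d in zip(self.labels, deg) if d == 0]

    def neighbor_lists(self) -> list:
        return [np.flatnonzero(row) for row in self.adjacency]


def build_neighbors(montage: Montage, max_angle: float = 0.6) -> NeighborGraph:
    """Channel adjacency: edge iff great-circle distance <= max_angle (rad)."""
    ang = np.arccos(montage.cosine_angles())
    adj = ang <= max_angle
    np.fill_diagonal(adj, False)
    return NeighborGraph(tuple(montage.labels), adj)


@dataclass(frozen=True)
class ClusterTestConfig:
    n_permutations: int = 256
    tail: str = "greater"  # 'greater', 'less', or 'two'
    cluster_forming_alpha: float = 0.05  # two-sided alpha for the t threshold
    analysis_window: tuple = (-400.0, 400.0)  # ms
    excluded_window: tuple | None = (-10.0, 20.0)  # ms, masked before clustering
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.tail not in ("greater", "less", "two"):
            raise ValueError("tail must be 'greater', 'less' or 'two'")
        if self.excluded_window is not None:
            lo, hi = self.analysis_window
            if self.excluded_window[0] < lo or self.excluded_window[1] > hi:
                raise ValueError("excluded window must lie inside the analysis window")


@dataclass
class Cluster:
    members: list  # (channel index, sample index) pairs
    mass: float  # signed sum of t over members
    p: float = float("nan")


@dataclass
class ClusterResult:
    clusters: list
    null_max_mass: np.ndarray
    n_permutations: int
    exhaustive: bool
    t_threshold: float

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p <= alpha]


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """Per channel-time paired t statistic (A - B) over subjects.

    Inputs are subjects x channels x samples. Cells with zero variance
    of the difference yield +/-inf (flagged degenerate) or 0 when the
    mean difference is also zero.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have the same shape")
    if a.shape[0] < 2:
        raise ValueError("need at least two subjects")
    return _t_from_diffs(a - b)


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    return t


def form_clusters(t_map: np.ndarray, threshold: float, graph: NeighborGraph) -> list:
    """Signed clusters of supra-threshold points.

    Positive clusters from t >= +threshold, negative from t <= -threshold;
    connectivity joins temporally adjacent samples of one channel and
    neighboring channels at the same sample.
    """
    if t_map.shape[0] != len(graph.labels):
        raise ValueError("t_map channel count does not match graph")
    nbrs = graph.neighbor_lists()
    clusters = []
    for sign in (+1, -1):
        mask = (sign * t_map) >= threshold
        clusters.extend(_components(mask, t_map, nbrs))
    return clusters


def _components(mask: np.ndarray, t_map: np.ndarray, nbrs) -> list:
    n_ch, n_samp = mask.shape
    seen = np.zeros_like(mask)
    out = []
    idx_ch, idx_s = np.nonzero(mask)
    for c0, s0 in zip(idx_ch, idx_s):
        if seen[c0, s0]:
            continue
        stack = [(c0, s0)]
        seen[c0, s0] = True
        members = []
        mass = 0.0
        while stack:
            c, s = stack.pop()
            members.append((int(c), int(s)))
            mass += t_map[c, s]
            if s > 0 and mask[c, s - 1] and not seen[c, s - 1]:
                seen[c, s - 1] = True
                stack.append((c, s - 1))
            if s + 1 < n_samp and mask[c, s + 1] and not seen[c, s + 1]:
                seen[c, s + 1] = True
                stack.append((c, s + 1))
            for c2 in nbrs[c]:
                if mask[c2, s] and not seen[c2, s]:
                    seen[c2, s] = True
                    stack.append((c2, s))
        out.append(Cluster(members=members, mass=float(mass)))
    return out


def _max_mass(t_map: np.ndarray, threshold: float, nbrs, tail: str) -> float:
    """Maximal cluster score of one (permuted) t map under the given tail."""
    best = 0.0
    if tail in ("greater", "two"):
        for cl in _components(t_map >= threshold, t_map, nbrs):
            best = max(best, cl.mass)
    if tail in ("less", "two"):
        # mass computed on -t_map, so it is already the positive score
        for cl in _components(-t_map >= threshold, -t_map, nbrs):
            best = max(best, cl.mass)
    return best


def _cluster_score(cluster: Cluster, tail: str) -> float:
    if tail == "greater":
        return cluster.mass
    if tail == "less":
        return -cluster.mass
    return abs(cluster.mass)


def _sign_matrix(n_subjects: int, config: ClusterTestConfig):
    """Sign-flip patterns: exhaustive when 2^n <= n_permutations requested."""
    n_total = 2 ** n_subjects
    if config.n_permutations >= n_total:
        bits = ((np.arange(n_total)[:, None] >> np.arange(n_subjects)) & 1)
        return 1 - 2 * bits.astype(float), True
    rng = np.random.default_rng(config.seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n_subjects))
    return signs, False


def permutation_test(cond_a: np.ndarray, cond_b: np.ndarray, graph: NeighborGraph,
                     config: ClusterTestConfig | None = None,
                     times: np.ndarray | None = None) -> ClusterResult:
    """Cluster-based Monte-Carlo permutation test for a paired design.

    ``cond_a``/``cond_b`` are subjects x channels x samples; ``times``
    (ms) enables analysis-window restriction and pulse-artifact masking
    before clustering. The cluster-forming threshold is the two-sided
    critical t at ``cluster_forming_alpha`` for n-1 degrees of freedom.
    """
    config = config or ClusterTestConfig()
    d = np.asarray(cond_a, dtype=float) - np.asarray(cond_b, dtype=float)
    if d.ndim != 3:
        raise ValueError("conditions must be subjects x channels x samples")
    n_sub = d.shape[0]
    if n_sub < 2:
        raise ValueError("need at least two subjects")
    if times is not None:
        keep = (times >= config.analysis_window[0]) & (times <= config.analysis_window[1])
        if config.excluded_window is not None:
            lo, hi = config.excluded_window
            keep &= ~((times >= lo) & (times <= hi))
        d = d[:, :, keep]
    df = n_sub - 1
    threshold = float(stats.t.ppf(1 - config.cluster_forming_alpha / 2, df))
    nbrs = graph.neighbor_lists()

    t_obs = _t_from_diffs(d)
    t_obs = np.nan_to_num(t_obs, posinf=0.0, neginf=0.0)
    if config.tail == "greater":
        observed = _components(t_obs >= threshold, t_obs, nbrs)
    elif config.tail == "less":
        observed = _components(-t_obs >= threshold, -t_obs, nbrs)
        for cl in observed:
            cl.mass = -cl.mass  # store the signed mass
    else:
        observed = form_clusters(t_obs, threshold, nbrs)

    signs, exhaustive = _sign_matrix(n_sub, config)
    # sign flips leave sum(d^2) invariant: vectorize mean/var over perms
    flat = d.reshape(n_sub, -1)
    ss = (flat ** 2).sum(axis=0)
    null = np.empty(signs.shape[0])
    for i, s in enumerate(signs):
        m = (s @ flat) / n_sub
        var = (ss - n_sub * m ** 2) / (n_sub - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = m / np.sqrt(var / n_sub)
        t_perm = np.nan_to_num(t_perm, posinf=0.0, neginf=0.0)
        null[i] = _max_mass(t_perm.reshape(d.shape[1:]), threshold, nbrs, config.tail)

    for cl in observed:
        score = _cluster_score(cl, config.tail)
        if exhaustive:
            cl.p = float((null >= score - 1e-12).mean())
        else:
            cl.p = float((1 + (null >= score - 1e-12).sum()) / (signs.shape[0] + 1))
    observed.sort(key=lambda c: c.p)
    return ClusterResult(clusters=observed, null_max_mass=null,
                         n_permutations=signs.shape[0], exhaustive=exhaustive,
                         t_threshold=threshold)


def gmfa_cluster_test(series_a: np.ndarray, series_b: np.ndarray,
                      config: ClusterTestConfig | None = None,
                      times: np.ndarray | None = None) -> ClusterResult:
    """Cluster permutation test on per-subject 1-D series (temporal adjacency only)."""
    a = np.asarray(series_a, dtype=float)[:, None, :]
    b = np.asarray(series_b, dtype=float)[:, None, :]
    graph = NeighborGraph(("gmfa",), np.zeros((1, 1), dtype=bool))
    return permutation_test(a, b, graph, config=config, times=times)
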