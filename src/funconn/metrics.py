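"""Signed weighted graph metrics for connectivity matrices.

Six metrics are computed per subject: three nodal (weighted degree, nodal
efficiency, nodal local efficiency) and three global (global efficiency,
network local efficiency, signed modularity Q).  Negative weights are
handled per-metric: absolute values for degree and the efficiencies,
preserved sign for modularity (with a zero-negatives confirmatory option).
Efficiencies are computed on a matrix whose unique-edge weights sum to 1,
so groups with different overall connectivity strength are comparable;
weighted degree stays on the unnormalized magnitudes.

Shortest paths treat an edge of weight w as having length 1/w (strong
connections are short); disconnected pairs contribute zero efficiency.

Modularity follows the signed variant in which the positive part of the
network is rewarded at scale 1/v+ and within-module negative weight is
penalized at scale 1/(v+ + v-), each sign against its own
configuration-model null (e_ij = s_i s_j / v computed per sign).  The
partition is found by a seeded Louvain-style greedy optimization; the
reported Q is always re-evaluated directly from the definition on the
final partition, independent of the optimizer's bookkeeping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .connectivity import ConnectivityMatrix

WEIGHT_POLICIES = ("absolute", "zero_negatives", "preserve")

NODAL_METRICS = ("weighted_degree", "nodal_efficiency", "nodal_local_efficiency")
GLOBAL_METRICS = ("global_efficiency", "network_local_efficiency", "modularity_q")


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, ConnectivityMatrix):
        return np.array(m.z, dtype=float)
    a = np.array(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square matrix")
    return a


def apply_weight_policy(m, policy: str) -> np.ndarray:
    """Resolve negative weights: ``absolute`` -> |w|, ``zero_negatives`` -> max(w, 0),
    ``preserve`` -> unchanged.  The diagonal stays zero."""
    if policy not in WEIGHT_POLICIES:
        raise ValueError(f"unknown weight policy {policy!r}; choose from {WEIGHT_POLICIES}")
    w = _as_matrix(m)
    if policy == "absolute":
        w = np.abs(w)
    elif policy == "zero_negatives":
        w = np.where(w < 0, 0.0, w)
    np.fill_diagonal(w, 0.0)
    return w


def normalize_total_weight(m) -> np.ndarray:
    """Divide every weight by the sum of |w| over unique edges (i < j).

    Afterwards the unique-edge absolute weights sum to exactly 1, making
    efficiency comparable across subjects whose total connectivity
    strength differs.
    """
    w = _as_matrix(m)
    iu = np.triu_indices(w.shape[0], k=1)
    total = float(np.abs(w[iu]).sum())
    if total == 0:
        raise ValueError("cannot normalize an all-zero matrix")
    return w / total


def weighted_degree(m) -> np.ndarray:
    """Node strength k_i = sum_j w_ij on a non-negative matrix."""
    w = _as_matrix(m)
    if (w < 0).any():
        raise ValueError(
            "weighted degree requires non-negative weights; apply a weight policy first"
        )
    return w.sum(axis=1)


def distance_matrix(m) -> np.ndarray:
    """All-pairs weighted shortest-path lengths with edge length 1/w.

    Zero-weight (absent) edges have infinite length; disconnected pairs
    stay at infinity.  Dijkstra per source on the sparse length graph.
    """
    w = _as_matrix(m)
    if (w < 0).any():
        raise ValueError("distances require non-negative weights; apply a weight policy first")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    # csgraph treats 0 as "no edge" in dense input only via masked arrays;
    # use the convention that np.inf marks absent edges.
    graph = np.where(np.isinf(lengths), 0.0, lengths)
    d = _csgraph_dijkstra(graph, directed=False, unweighted=False)
    # csgraph reads an explicit 0 off-diagonal as "no edge", which matches
    # our encoding (w=0 -> no edge); restore the zero diagonal.
    np.fill_diagonal(d, 0.0)
    return d


def nodal_efficiency(m) -> np.ndarray:
    """E_i = mean over j != i of 1/d_ij, with 1/inf = 0."""
    w = _as_matrix(m)
    n = w.shape[0]
    if n < 2:
        return np.zeros(n)
    d = distance_matrix(w)
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / d, 0.0)
    inv[np.isinf(d)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(m) -> float:
    """Mean nodal efficiency: the network's capacity for integration."""
    return float(nodal_efficiency(m).mean())


def nodal_local_efficiency(m) -> np.ndarray:
    """Efficiency of each node's neighborhood after removing the node.

    For node i, induce the subgraph on its neighbors (w_ij > 0, using the
    subgraph's own weights) and take that subgraph's global efficiency.
    Nodes with fewer than two neighbors score 0.
    """
    w = _as_matrix(m)
    if (w < 0).any():
        raise ValueError(
            "local efficiency requires non-negative weights; apply a weight policy first"
        )
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(sub)
    return out


def network_local_efficiency(m) -> float:
    """Mean nodal local efficiency across all nodes."""
    return float(nodal_local_efficiency(m).mean())


# ---------------------------------------------------------------------------
# Signed modularity
# ---------------------------------------------------------------------------


def _signed_parts(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    return wp, wn


def modularity_q(m, partition, resolution: float = 1.0) -> float:
    """Evaluate signed modularity Q of a partition, directly from the definition.

    Q = (1/v+) sum_ij (w+_ij - g s+_i s+_j / v+) delta_ij
        - (1/(v+ + v-)) sum_ij (w-_ij - g s-_i s-_j / v-) delta_ij

    where s are signed strengths, v signed total weights (double-counted
    sums over the full matrix), delta is co-membership and g the
    resolution.  A sign with zero total weight contributes nothing.
    """
    w = _as_matrix(m)
    labels = np.asarray(partition)
    if labels.shape[0] != w.shape[0]:
        raise ValueError("partition length does not match matrix size")
    delta = labels[:, None] == labels[None, :]
    np.fill_diagonal(delta, True)
    wp, wn = _signed_parts(w)
    q = 0.0
    vp = wp.sum()
    vn = wn.sum()
    if vp > 0:
        sp = wp.sum(axis=1)
        ep = resolution * np.outer(sp, sp) / vp
        q += ((wp - ep) * delta).sum() / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        en = resolution * np.outer(sn, sn) / vn
        q -= ((wn - en) * delta).sum() / (vp + vn)
    return float(q)


def _louvain_one_level(
    wp: np.ndarray,
    wn: np.ndarray,
    vp: float,
    vn: float,
    resolution: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Louvain level: greedy node moves until no gain.  Returns labels.

    Gains use each sign's configuration-model null; ties between equal
    gains are broken by the lowest community label for determinism.
    """
    n = wp.shape[0]
    labels = np.arange(n)
    sp = wp.sum(axis=1)
    sn = wn.sum(axis=1)
    # community strength sums
    comm_sp = sp.copy()
    comm_sn = sn.copy()
    improved = True
    sweeps = 0
    while improved and sweeps < 100:
        improved = False
        sweeps += 1
        order = rng.permutation(n)
        for i in order:
            ci = labels[i]
            # remove i from its community
            comm_sp[ci] -= sp[i]
            comm_sn[ci] -= sn[i]
            # weights from i to each community (exclude self-loop weight,
            # which moves with i and cancels in gain comparisons)
            kp = np.bincount(labels, weights=wp[i], minlength=n)
            kn = np.bincount(labels, weights=wn[i], minlength=n)
            kp[labels[i]] -= wp[i, i]
            kn[labels[i]] -= wn[i, i]
            gain = np.zeros(n)
            if vp > 0:
                gain += (kp - resolution * sp[i] * comm_sp / vp) / vp
            if vn > 0:
                gain -= (kn - resolution * sn[i] * comm_sn / vn) / (vp + vn)
            # candidate communities: neighbors' plus i's own
            best = int(np.flatnonzero(gain == gain.max())[0])
            stay = gain[ci]
            if gain[best] > stay + 1e-12:
                labels[i] = best
                improved = True
            comm_sp[labels[i]] += sp[i]
            comm_sn[labels[i]] += sn[i]
    return labels


def _aggregate(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    comms, inv = np.unique(labels, return_inverse=True)
    k = comms.size
    onehot = np.zeros((w.shape[0], k))
    onehot[np.arange(w.shape[0]), inv] = 1.0
    return onehot.T @ w @ onehot


def modularity_signed(
    m,
    seed: int = 0,
    n_restarts: int = 20,
    resolution: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Louvain-style optimization of signed modularity.

    Runs ``n_restarts`` seeded restarts with random sweep orders, keeps the
    best partition, and returns ``(labels, Q)`` with labels relabelled to
    contiguous integers from 0 and Q re-evaluated from the definition on
    the original matrix.
    """
    w = _as_matrix(m)
    wp, wn = _signed_parts(w)
    if wp.sum() == 0:
        raise ValueError("no positive weights: modularity is undefined")
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    best_labels = np.arange(n)
    best_q = -np.inf
    for _ in range(max(1, n_restarts)):
        cur = w
        mapping = np.arange(n)
        for _level in range(50):
            cwp, cwn = _signed_parts(cur)
            lv = _louvain_one_level(cwp, cwn, cwp.sum(), cwn.sum(), resolution, rng)
            _, lv = np.unique(lv, return_inverse=True)
            if lv.max() + 1 == cur.shape[0]:
                break  # no merge happened
            mapping = lv[mapping]
            cur = _aggregate(cur, lv)
            if cur.shape[0] == 1:
                break
        q = modularity_q(w, mapping, resolution=resolution)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = mapping
    _, best_labels = np.unique(best_labels, return_inverse=True)
    return best_labels.astype(int), float(best_q)


# ---------------------------------------------------------------------------
# Per-subject metric extraction
# ---------------------------------------------------------------------------


class GraphMetricsExtractor:
    """Transformer from connectivity matrices to graph-metric tables.

    For each subject matrix it computes weighted degree on the
    unnormalized |w| matrix, nodal/global/local efficiencies on the
    total-weight-normalized policy matrix, and signed modularity on the
    raw signed matrix (or the zero-negatives variant).

    Parameters
    ----------
    policy : negative-weight policy for degree and efficiencies
        (``absolute`` default, ``zero_negatives`` for confirmation).
    modularity_policy : ``preserve`` (default) or ``zero_negatives``.
    n_restarts, resolution, seed : Louvain controls.
    """

    def __init__(
        self,
        policy: str = "absolute",
        modularity_policy: str = "preserve",
        n_restarts: int = 20,
        resolution: float = 1.0,
        seed: int = 0,
    ):
        self.policy = policy
        self.modularity_policy = modularity_policy
        self.n_restarts = n_restarts
        self.resolution = resolution
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "policy": self.policy,
            "modularity_policy": self.modularity_policy,
            "n_restarts": self.n_restarts,
            "resolution": self.resolution,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "GraphMetricsExtractor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "GraphMetricsExtractor":
        if self.policy not in ("absolute", "zero_negatives"):
            raise ValueError("policy must be 'absolute' or 'zero_negatives'")
        if self.modularity_policy not in ("preserve", "zero_negatives"):
            raise ValueError("modularity_policy must be 'preserve' or 'zero_negatives'")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("expected an (n_subjects, N, N) array of matrices")
        self.n_nodes_ = X.shape[1]
        return self

    def subject_metrics(self, w: np.ndarray) -> tuple[dict[str, np.ndarray], dict[str, float]]:
        """Nodal vectors and global scalars for a single signed matrix."""
        pol = apply_weight_policy(w, self.policy)
        norm = normalize_total_weight(pol)
        k = weighted_degree(pol)
        e_nodal = nodal_efficiency(norm)
        e_local = nodal_local_efficiency(norm)
        w_mod = apply_weight_policy(w, self.modularity_policy)
        _, q = modularity_signed(
            w_mod, seed=self.seed, n_restarts=self.n_restarts, resolution=self.resolution
        )
        nodal = {
            "weighted_degree": k,
            "nodal_efficiency": e_nodal,
            "nodal_local_efficiency": e_local,
        }
        glob = {
            "global_efficiency": float(e_nodal.mean()),
            "network_local_efficiency": float(e_local.mean()),
            "modularity_q": q,
        }
        return nodal, glob

    def transform(self, X) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
        """Compute metrics for a stack of matrices.

        Returns ``(nodal, global_df)`` where ``nodal`` maps each nodal
        metric name to an (n_subjects, N) array and ``global_df`` has one
        row per subject and one column per global metric.
        """
        if not hasattr(self, "n_nodes_"):
            raise RuntimeError("GraphMetricsExtractor is not fitted")
        X = np.asarray(X, dtype=float)
        n_sub = X.shape[0]
        nodal = {name: np.zeros((n_sub, self.n_nodes_)) for name in NODAL_METRICS}
        glob_rows = []
        for s in range(n_sub):
            nv, gv = self.subject_metrics(X[s])
            for name in NODAL_METRICS:
                nodal[name][s] = nv[name]
            glob_rows.append(gv)
        return nodal, pd.DataFrame(glob_rows)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
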