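"""Functional connectivity: ROI time series -> signed Fisher-z matrices.

Connectivity between two regions is the Pearson correlation of their mean
time courses, variance-stabilized with Fisher's r-to-z transform
(z = atanh r).  Perfectly (anti)correlated pairs would map to +/-inf, so
|z| is capped at a configurable ceiling.  The matrix is symmetric with a
zero diagonal; weights keep their sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CLIP_Z = 6.0


@dataclass
class RoiTimeSeries:
    """A T x N matrix of region-mean signals for one subject.

    Parameters
    ----------
    values : (T, N) array of samples by regions.
    node_ids : region keys, one per column.
    sampling_interval : repetition time in seconds.
    """

    values: np.ndarray
    node_ids: list[str]
    sampling_interval: float = 2.5

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = [str(n) for n in self.node_ids]
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T, N) array")
        if self.values.shape[1] != len(self.node_ids):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.node_ids)} node ids"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Fisher-z connectivity matrix with zero diagonal."""

    z: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if not self.node_ids:
            self.node_ids = [str(i) for i in range(n)]
        self.node_ids = [str(v) for v in self.node_ids]
        if len(self.node_ids) != n:
            raise ValueError("node_ids length does not match matrix size")
        if not np.isfinite(self.z).all():
            raise ValueError("connectivity matrix contains non-finite entries")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.z), 0.0):
            raise ValueError("connectivity matrix diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.node_ids, columns=self.node_ids)

    def to_edge_list(self) -> pd.DataFrame:
        """Flat unique-edge table ``node_i, node_j, z`` (i < j)."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return pd.DataFrame(
            {
                "node_i": [self.node_ids[i] for i in iu],
                "node_j": [self.node_ids[j] for j in ju],
                "z": self.z[iu, ju],
            }
        )


def fc_matrix(ts: RoiTimeSeries, clip_z: float = DEFAULT_CLIP_Z) -> ConnectivityMatrix:
    """Pairwise Pearson correlations, Fisher r-to-z transformed.

    Off-diagonal entries are atanh(r); |r| = 1 (within machine tolerance)
    is capped at ``clip_z`` with the sign preserved, and every cap is
    logged.  The diagonal is zero.
    """
    if clip_z <= 0:
        raise ValueError("clip_z must be positive")
    if ts.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.node_ids[i] for i in dead]
        raise ValueError(f"zero-variance time series for node(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    near_one = np.abs(r) >= np.tanh(clip_z)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    z[near_one] = np.sign(r[near_one]) * clip_z
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(near_one, False)
    if near_one.any():
        logger.info(
            "capped %d edge(s) at |z| = %g (|r| at or above atanh ceiling)",
            int(near_one.sum()) // 2,
            clip_z,
        )
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z=z, node_ids=ts.node_ids)


def mean_fc(m: ConnectivityMatrix, absolute: bool = False) -> float:
    """Mean of the N(N-1)/2 unique off-diagonal weights (signed by default).

    The signed mean is the per-subject global connectivity-strength summary
    used as a nuisance covariate; set ``absolute=True`` for the magnitude
    variant.
    """
    if m.n_nodes < 2:
        raise ValueError("mean FC needs at least 2 nodes")
    iu = np.triu_indices(m.n_nodes, k=1)
    vals = m.z[iu]
    return float(np.abs(vals).mean() if absolute else vals.mean())


def aggregate_merged_series(ts: RoiTimeSeries, merge_map: dict[str, str]) -> RoiTimeSeries:
    """Average time-series columns that map to the same composite node.

    ``merge_map`` sends every original region id to its final node id
    (identity for unmerged regions).  Output column order follows first
    appearance of each target id, matching the merged node table.
    """
    missing = [n for n in ts.node_ids if n not in merge_map]
    if missing:
        raise KeyError(f"node id(s) missing from merge map: {missing}")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for idx, node in enumerate(ts.node_ids):
        target = merge_map[node]
        if target not in groups:
            groups[target] = []
            order.append(target)
        groups[target].append(idx)
    cols = [ts.values[:, groups[t]].mean(axis=1) for t in order]
    return RoiTimeSeries(
        values=np.column_stack(cols),
        node_ids=order,
        sampling_interval=ts.sampling_interval,
    )


class FisherZConnectivity:
    """Transformer from per-subject ROI time series to Fisher-z matrices.

    scikit-learn style: ``fit`` validates parameters and records the node
    set, ``transform`` maps a sequence of (T, N) arrays or
    :class:`RoiTimeSeries` to a stacked (n_subjects, N, N) array of signed
    Fisher-z matrices.

    Parameters
    ----------
    clip_z : cap on |z| applied where |r| reaches 1.
    """

    def __init__(self, clip_z: float = DEFAULT_CLIP_Z):
        self.clip_z = clip_z

    def get_params(self, deep: bool = True) -> dict:
        return {"clip_z": self.clip_z}

    def set_params(self, **params) -> "FisherZConnectivity":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_series(X) -> list[RoiTimeSeries]:
        out = []
        for x in X:
            out.append(x if isinstance(x, RoiTimeSeries) else RoiTimeSeries(
                values=np.asarray(x, dtype=float),
                node_ids=[str(i) for i in range(np.asarray(x).shape[1])],
            ))
        return out

    def fit(self, X, y=None) -> "FisherZConnectivity":
        if self.clip_z <= 0:
            raise ValueError("clip_z must be positive")
        series = self._as_series(X)
        if not series:
            raise ValueError("need at least one subject")
        self.node_ids_ = list(series[0].node_ids)
        self.n_nodes_ = len(self.node_ids_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "node_ids_"):
            raise RuntimeError("FisherZConnectivity is not fitted")
        mats = []
        for ts in self._as_series(X):
            if ts.node_ids != self.node_ids_:
                raise ValueError("subject node ids differ from the fitted node set")
            mats.append(fc_matrix(ts, clip_z=self.clip_z).z)
        return np.stack(mats)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
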