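"""Synthetic two-group cohorts of ROI time series with planted effects.

Subjects are drawn from zero-mean multivariate normal distributions whose
correlation matrices have a modular block structure (higher correlation
within modules than between), optional hub nodes with extra cross-module
correlation, and — for the patient group — a configurable deficit
subtracted from the population correlation on designated edges.  Planting
on population correlations (rather than on Fisher-z values directly)
mirrors the downstream measurement chain: time series -> Pearson r ->
Fisher z.

Covariates (age, sex, mean framewise displacement, psychosis history
among patients, IQ) are sampled per group; by default age and sex are
matched across groups so the group contrast is unconfounded, with an
optional group-dependent motion shift to exercise covariate adjustment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import RoiTimeSeries

logger = logging.getLogger(__name__)

PD_EIGEN_FLOOR = 1e-8


@dataclass
class GroupCovariates:
    """Per-group covariate sampling parameters."""

    age_mean: float
    age_sd: float
    p_male: float
    fd_mean: float
    fd_sd: float
    iq_mean: float
    iq_sd: float


@dataclass
class SimulationConfig:
    """Conditions for a simulated two-group resting-state cohort.

    Defaults emulate a 105-node network measured over 196 retained volumes
    in 67 controls and 40 patients, with five equal correlation modules,
    moderate within-module coupling, and 10 of 40 patients carrying a
    psychosis-history flag.
    """

    n_nodes: int = 105
    n_controls: int = 67
    n_patients: int = 40
    t_samples: int = 196
    module_sizes: list[int] = field(default_factory=lambda: [21, 21, 21, 21, 21])
    r_within: float = 0.4
    r_between: float = 0.1
    hub_nodes: list[int] = field(default_factory=list)
    r_hub: float = 0.15
    effect_edges: list[tuple[int, int]] = field(default_factory=list)
    effect_delta: float = 0.0
    control_covariates: GroupCovariates = field(
        default_factory=lambda: GroupCovariates(23.4, 3.7, 43 / 67, 0.15, 0.05, 107.3, 13.8)
    )
    patient_covariates: GroupCovariates = field(
        default_factory=lambda: GroupCovariates(23.2, 8.6, 17 / 40, 0.15, 0.05, 69.1, 13.0)
    )
    p_psychosis: float = 10 / 40
    fd_group_shift: float = 0.0  # optional patient FD mean shift (confound testing)
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)}, expected {self.n_nodes}"
            )
        if self.t_samples < self.n_nodes + 2:
            raise ValueError("t_samples must be at least n_nodes + 2")
        for r in (self.r_within, self.r_between):
            if not -1 < r < 1:
                raise ValueError("baseline correlations must lie in (-1, 1)")
        for i, j in self.effect_edges:
            if i == j or not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"invalid effect edge ({i}, {j})")
        for h in self.hub_nodes:
            if not 0 <= h < self.n_nodes:
                raise ValueError(f"hub index {h} out of range")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted group difference."""

    effect_edges: list[tuple[int, int]]
    effect_delta: float
    affected_nodes: list[int]
    control_corr: np.ndarray
    patient_corr: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "effect_edges": [list(e) for e in self.effect_edges],
                "effect_delta": self.effect_delta,
                "affected_nodes": self.affected_nodes,
            },
            indent=1,
        )


@dataclass
class CohortData:
    """Per-subject time series plus the covariate table.

    ``covariates`` columns: subject_id, group (0 control / 1 patient),
    age, sex (0 female / 1 male), psychosis, mean_fd, iq.
    """

    series: list[RoiTimeSeries]
    covariates: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.series)


def nearest_positive_definite(a: np.ndarray, floor: float = PD_EIGEN_FLOOR) -> np.ndarray:
    """Repair a symmetric matrix to positive definite by eigenvalue clipping.

    Eigenvalues below ``floor`` are raised to it and the matrix is rescaled
    back to unit diagonal.  Repairs are logged; an input that is already PD
    is returned unchanged.
    """
    sym = (a + a.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() > floor:
        return sym
    logger.info(
        "correlation matrix repaired to positive definite (min eigenvalue %.3g)",
        float(vals.min()),
    )
    clipped = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    out = clipped / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def build_population_covariance(cfg: SimulationConfig, group: str) -> np.ndarray:
    """Population correlation matrix for ``group`` (``control`` or ``patient``).

    Block structure with ``r_within`` inside modules and ``r_between``
    across, plus ``r_hub`` added on hub rows/columns (capped below 1); the
    patient matrix subtracts ``effect_delta`` on each planted edge.  The
    result is repaired to positive definite if needed.
    """
    if group not in ("control", "patient"):
        raise ValueError("group must be 'control' or 'patient'")
    cfg.validate()
    n = cfg.n_nodes
    corr = np.full((n, n), cfg.r_between)
    start = 0
    for size in cfg.module_sizes:
        corr[start : start + size, start : start + size] = cfg.r_within
        start += size
    for h in cfg.hub_nodes:
        boosted = np.minimum(corr[h] + cfg.r_hub, 0.95)
        corr[h, :] = boosted
        corr[:, h] = boosted
    if group == "patient" and cfg.effect_delta != 0.0:
        for i, j in cfg.effect_edges:
            corr[i, j] -= cfg.effect_delta
            corr[j, i] = corr[i, j]
    np.fill_diagonal(corr, 1.0)
    off_diag = corr[~np.eye(n, dtype=bool)]
    if off_diag.size and np.abs(off_diag).max() >= 1.0:
        raise ValueError("off-diagonal correlation magnitude reached 1; reduce deltas")
    corr = nearest_positive_definite(corr)
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValueError("population correlation matrix is not repairable to PD")
    return corr


def simulate_subject(ts_cov: np.ndarray, t_samples: int, seed: int) -> RoiTimeSeries:
    """Draw a T x N zero-mean multivariate normal series with the given correlation."""
    cov = np.asarray(ts_cov, dtype=float)
    n = cov.shape[0]
    if t_samples < n + 2:
        raise ValueError("t_samples must be at least n_nodes + 2")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((t_samples, n)) @ chol.T
    return RoiTimeSeries(values=x, node_ids=[str(i) for i in range(n)])


def generate_cohort(cfg: SimulationConfig) -> tuple[CohortData, SyntheticTruth]:
    """Simulate the full two-group cohort plus its ground truth."""
    cfg.validate()
    control_corr = build_population_covariance(cfg, "control")
    patient_corr = build_population_covariance(cfg, "patient")
    rng = np.random.default_rng(cfg.seed)

    series: list[RoiTimeSeries] = []
    rows = []
    groups = [0] * cfg.n_controls + [1] * cfg.n_patients
    for idx, grp in enumerate(groups):
        corr = patient_corr if grp else control_corr
        params = cfg.patient_covariates if grp else cfg.control_covariates
        sub_seed = int(rng.integers(0, 2**31 - 1))
        series.append(simulate_subject(corr, cfg.t_samples, sub_seed))
        age = rng.normal(params.age_mean, params.age_sd)
        sex = int(rng.random() < params.p_male)
        fd = abs(rng.normal(params.fd_mean + cfg.fd_group_shift * grp, params.fd_sd))
        psychosis = int(grp and rng.random() < cfg.p_psychosis)
        iq = rng.normal(params.iq_mean, params.iq_sd)
        rows.append(
            {
                "subject_id": f"sub-{idx + 1:03d}",
                "group": grp,
                "age": age,
                "sex": sex,
                "psychosis": psychosis,
                "mean_fd": fd,
                "iq": iq,
            }
        )
    covariates = pd.DataFrame(rows)
    effect_edges = list(cfg.effect_edges) if cfg.effect_delta != 0.0 else []
    affected = sorted({n for e in effect_edges for n in e})
    truth = SyntheticTruth(
        effect_edges=effect_edges,
        effect_delta=cfg.effect_delta if effect_edges else 0.0,
        affected_nodes=affected,
        control_corr=control_corr,
        patient_corr=patient_corr,
    )
    return CohortData(series=series, covariates=covariates), truth


def hub_deficit_config(
    n_hubs: int = 3,
    effect_delta: float = 0.3,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Convenience config: deficits on every edge incident to ``n_hubs`` hubs.

    The hubs are the first node of each module (spread across modules) and
    every edge touching them loses ``effect_delta`` of population
    correlation in the patient group.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    starts = np.cumsum([0] + cfg.module_sizes[:-1])
    hubs = [int(s) for s in starts[:n_hubs]]
    cfg.hub_nodes = hubs
    cfg.effect_delta = effect_delta
    cfg.effect_edges = [
        (h, j) for h in hubs for j in range(cfg.n_nodes) if j != h and j not in hubs[: hubs.index(h)]
    ]
    return cfg


def write_cohort(cohort: CohortData, truth: SyntheticTruth, out_dir: str | Path) -> None:
    """Write per-subject time-series TSVs, the covariate CSV and truth JSON."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for ts, sid in zip(cohort.series, cohort.covariates["subject_id"]):
        df = pd.DataFrame(ts.values, columns=ts.node_ids)
        df.to_csv(ts_dir / f"{sid}.tsv", sep="\t", index=False, float_format="%.10g")
    cohort.covariates.to_csv(out / "covariates.csv", index=False, float_format="%.10g")
    (out / "truth.json").write_text(truth.to_json())


def read_cohort(
    ts_dir: str | Path, covariates_path: str | Path, sampling_interval: float = 2.5
) -> CohortData:
    """Load a cohort from per-subject TSVs and a covariate CSV."""
    covariates = pd.read_csv(covariates_path)
    series = []
    for sid in covariates["subject_id"]:
        path = Path(ts_dir) / f"{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"time series for {sid} not found: {path}")
        df = pd.read_csv(path, sep="\t")
        series.append(
            RoiTimeSeries(
                values=df.to_numpy(dtype=float),
                node_ids=list(df.columns),
                sampling_interval=sampling_interval,
            )
        )
    return CohortData(series=series, covariates=covariates)
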