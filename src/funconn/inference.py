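"""Covariate-adjusted group contrasts with FDR control and effect sizes.

Each outcome (an edge's Fisher-z weight, a node's metric, a global metric,
or the subject-level mean connectivity) is regressed on
``[intercept, group, covariates...]`` by ordinary least squares; the group
coefficient's t statistic, two-sided p, Benjamini-Hochberg q within the
appropriate family, and a Cohen's-d-style effect size with 95% CI are
reported per unit.

The effect-size convention is d = 2 t / sqrt(n_total) with
SE_d = sqrt(4/n_total + d^2 / (2 n_total)), the standard conversion from a
t statistic of a two-group contrast; an unequal-group-size variant
(d = t sqrt(1/n1 + 1/n2)) is available separately.

Families for FDR: all unique edges form one family; each nodal metric's
node set forms one family; global metrics are reported uncorrected.

Edge-wise testing runs thousands of regressions that share one design
matrix, so the engine solves all outcomes in a single multi-column least
squares (one pseudoinverse, per-column residual variance); it is validated
against statsmodels OLS column by column in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

BASE_COVARIATES = ("age", "sex", "psychosis", "mean_fd")
KNOWN_COVARIATES = ("age", "sex", "psychosis", "mean_fd", "mean_fc", "iq")

RESULT_COLUMNS = ["unit_id", "t", "df", "p", "q", "d", "ci_low", "ci_high", "direction"]


@dataclass
class DesignSpec:
    """Which covariates enter the GLM and at what FDR level.

    ``contrast`` names the design column whose coefficient is tested:
    ``group`` for the patient-vs-control contrast, ``psychosis`` for the
    history-of-psychosis contrast within the same design.
    """

    covariates: tuple[str, ...] = BASE_COVARIATES
    contrast: str = "group"
    alpha: float = 0.05
    fdr: bool = True

    def __post_init__(self):
        unknown = [c for c in self.covariates if c not in KNOWN_COVARIATES]
        if unknown:
            raise ValueError(f"unknown covariate(s): {unknown}; allowed: {KNOWN_COVARIATES}")
        if self.contrast not in ("group",) + KNOWN_COVARIATES:
            raise ValueError(f"unknown contrast column {self.contrast!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def build_design_matrix(
    covariates: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, list[str], int]:
    """Assemble ``[intercept, group, covariates...]`` and locate the contrast column."""
    cols = ["group"] + [c for c in spec.covariates if c != "group"]
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing column(s): {missing}")
    x = np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(dtype=float) for c in cols]
    )
    names = ["intercept"] + cols
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        collinear = _collinear_columns(x, names)
        raise ValueError(f"rank-deficient design matrix; collinear column(s): {collinear}")
    if spec.contrast not in names:
        raise ValueError(f"contrast column {spec.contrast!r} not in design {names}")
    return x, names, names.index(spec.contrast)


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, x.shape[1]):
        sub = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(x):
            bad.append(names[j])
    return bad


def multi_ols_contrast(
    x: np.ndarray, y: np.ndarray, contrast_col: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS of each column of ``y`` on the shared design ``x``.

    Returns (t, p, df) for the contrast coefficient: one pseudoinverse of
    the design serves every outcome.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != x.shape[0]:
        y = y.T
    n, p_cols = x.shape
    df = n - p_cols
    if df < 1:
        raise ValueError(f"not enough subjects ({n}) for {p_cols} predictors")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[contrast_col, contrast_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[contrast_col] / np.where(se > 0, se, 1.0), np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, df


def glm_group_contrast(
    y: np.ndarray, covariates: pd.DataFrame, spec: DesignSpec | None = None
) -> tuple[float, float, int]:
    """Single-outcome GLM: t, two-sided p and residual df of the contrast."""
    spec = spec or DesignSpec()
    x, names, col = build_design_matrix(covariates, spec)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be one outcome vector; use multi_ols_contrast for many")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    y_var = y.var()
    if y_var > 0 and resid.var() <= 1e-12 * y_var:
        raise ValueError("outcome is collinear with the design (zero residual variance)")
    t, p, df = multi_ols_contrast(x, y[:, None], col)
    if not np.isfinite(t[0]):
        raise ValueError("outcome is collinear with the design (zero residual variance)")
    return float(t[0]), float(p[0]), df


def effect_size_from_t(t: float, n_total: int) -> tuple[float, float, float]:
    """Cohen's d and 95% CI from a two-group contrast t statistic.

    d = 2 t / sqrt(N); CI = d +/- 1.96 sqrt(4/N + d^2/(2N)).
    """
    if n_total < 4:
        raise ValueError("need at least 4 subjects")
    d = 2.0 * t / np.sqrt(n_total)
    se = np.sqrt(4.0 / n_total + d**2 / (2.0 * n_total))
    return float(d), float(d - 1.96 * se), float(d + 1.96 * se)


def effect_size_from_t_unequal(t: float, n1: int, n2: int) -> tuple[float, float, float]:
    """Unequal-group-size variant: d = t sqrt(1/n1 + 1/n2)."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    n = n1 + n2
    d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * n))
    return float(d), float(d - 1.96 * se), float(d + 1.96 * se)


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q values, reject mask at q <= alpha)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def _results_frame(
    unit_ids, t: np.ndarray, p: np.ndarray, df: int, n_total: int, alpha: float, fdr: bool
) -> pd.DataFrame:
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if fdr and p.size:
        q, _ = fdr_bh(p, alpha)
    else:
        q = p.copy()
    d = 2.0 * t / np.sqrt(n_total)
    se = np.sqrt(4.0 / n_total + d**2 / (2.0 * n_total))
    return pd.DataFrame(
        {
            "unit_id": list(unit_ids),
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "d": d,
            "ci_low": d - 1.96 * se,
            "ci_high": d + 1.96 * se,
            "direction": np.sign(t).astype(int),
        }
    )


class GroupContrastGLM:
    """Estimator for mass-univariate covariate-adjusted group contrasts.

    scikit-learn style: ``fit(X, y, covariates=...)`` where ``X`` is an
    (n_subjects, n_units) outcome matrix (edge weights, nodal metrics, or
    global metrics), ``y`` the 0/1 group labels, and ``covariates`` a
    DataFrame holding the nuisance columns named in the design spec.  FDR
    is applied across the units of ``X`` as one family.

    Fitted attributes: ``results_`` (per-unit table with t, df, p, q, d,
    CI, direction), ``df_resid_``, ``n_significant_``.
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = BASE_COVARIATES,
        contrast: str = "group",
        alpha: float = 0.05,
        fdr: bool = True,
    ):
        self.covariates = covariates
        self.contrast = contrast
        self.alpha = alpha
        self.fdr = fdr

    def get_params(self, deep: bool = True) -> dict:
        return {
            "covariates": self.covariates,
            "contrast": self.contrast,
            "alpha": self.alpha,
            "fdr": self.fdr,
        }

    def set_params(self, **params) -> "GroupContrastGLM":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _spec(self) -> DesignSpec:
        return DesignSpec(
            covariates=tuple(self.covariates),
            contrast=self.contrast,
            alpha=self.alpha,
            fdr=self.fdr,
        )

    def fit(self, X, y, covariates: pd.DataFrame, unit_ids=None) -> "GroupContrastGLM":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(covariates):
            raise ValueError("X rows must match the covariate table")
        spec = self._spec()
        cov = covariates.copy()
        cov["group"] = np.asarray(y, dtype=float)
        design, names, col = build_design_matrix(cov, spec)
        t, p, df = multi_ols_contrast(design, X, col)
        if unit_ids is None:
            unit_ids = [str(i) for i in range(X.shape[1])]
        self.design_columns_ = names
        self.df_resid_ = df
        self.results_ = _results_frame(
            unit_ids, t, p, df, X.shape[0], spec.alpha, spec.fdr
        )
        self.n_significant_ = int((self.results_["q"] <= spec.alpha).sum())
        return self

    def significant(self) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise RuntimeError("GroupContrastGLM is not fitted")
        return self.results_[self.results_["q"] <= self.alpha]


def edgewise_comparison(
    matrices: np.ndarray,
    covariates: pd.DataFrame,
    spec: DesignSpec | None = None,
    node_ids: list[str] | None = None,
) -> pd.DataFrame:
    """GLM per unique edge across subjects, FDR over the full edge family.

    ``matrices`` is (n_subjects, N, N) of Fisher-z weights.  Returns the
    per-edge results table with ``unit_id = "i|j"`` in node-id terms.
    """
    spec = spec or DesignSpec()
    matrices = np.asarray(matrices, dtype=float)
    n_sub, n = matrices.shape[0], matrices.shape[1]
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    y = matrices[:, iu, ju]
    est = GroupContrastGLM(
        covariates=spec.covariates, contrast=spec.contrast, alpha=spec.alpha, fdr=spec.fdr
    )
    unit_ids = [f"{node_ids[i]}|{node_ids[j]}" for i, j in zip(iu, ju)]
    est.fit(y, covariates["group"].to_numpy(), covariates, unit_ids=unit_ids)
    return est.results_


def nodal_comparison(
    nodal_values: np.ndarray,
    covariates: pd.DataFrame,
    spec: DesignSpec | None = None,
    node_ids: list[str] | None = None,
) -> pd.DataFrame:
    """GLM per node for one nodal metric; FDR across the node family."""
    spec = spec or DesignSpec()
    nodal_values = np.asarray(nodal_values, dtype=float)
    n = nodal_values.shape[1]
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    est = GroupContrastGLM(
        covariates=spec.covariates, contrast=spec.contrast, alpha=spec.alpha, fdr=spec.fdr
    )
    est.fit(nodal_values, covariates["group"].to_numpy(), covariates, unit_ids=node_ids)
    return est.results_


def global_comparison(
    global_df: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: DesignSpec | None = None,
) -> pd.DataFrame:
    """GLM per global metric, reported uncorrected (q = p)."""
    if spec is None:
        spec = DesignSpec()
    est = GroupContrastGLM(
        covariates=spec.covariates, contrast=spec.contrast, alpha=spec.alpha, fdr=False
    )
    est.fit(
        global_df.to_numpy(dtype=float),
        covariates["group"].to_numpy(),
        covariates,
        unit_ids=list(global_df.columns),
    )
    return est.results_


def classify_edges(
    edges: list[tuple[str, str]], node_table: pd.DataFrame
) -> dict[str, float]:
    """Percentage of edges per unordered lobe-pair category.

    Categories use the granularity frontal / temporal / parietal /
    occipital / cingulate / subcortical; any edge touching another lobe
    (insula, other) is pooled as ``remaining areas``.  Percentages sum to
    100 up to rounding; an empty edge list yields an empty map.
    """
    if not edges:
        return {}
    named = {"frontal", "temporal", "parietal", "occipital", "cingulate", "subcortical"}
    lobe_of = dict(zip(node_table["region_id"], node_table["lobe"]))
    counts: dict[str, int] = {}
    for a, b in edges:
        for node in (a, b):
            if str(node) not in lobe_of:
                raise KeyError(f"node {node!r} not in the node table")
        la, lb = lobe_of[str(a)], lobe_of[str(b)]
        if la in named and lb in named:
            cat = "-".join(sorted((la, lb)))
        else:
            cat = "remaining areas"
        counts[cat] = counts.get(cat, 0) + 1
    total = len(edges)
    return {c: 100.0 * k / total for c, k in sorted(counts.items(), key=lambda kv: -kv[1])}


def hub_ranking(
    control_degree_mean: np.ndarray,
    significant_nodes: set[str] | list[str],
    node_ids: list[str] | None = None,
    top_fraction: float = 0.2,
) -> tuple[pd.DataFrame, float]:
    """Rank nodes by control-group mean weighted degree; test hub enrichment.

    Returns the ranked table (rank 1 = strongest hub, with a flag for
    nodes significant in the patient contrast) and the hypergeometric
    probability of at least the observed overlap between significant nodes
    and the top ``top_fraction`` hubs.
    """
    deg = np.asarray(control_degree_mean, dtype=float)
    n = deg.size
    if n == 0:
        raise ValueError("empty degree vector")
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    order = np.argsort(-deg, kind="stable")
    sig = {str(s) for s in significant_nodes}
    table = pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "node_id": [node_ids[i] for i in order],
            "control_mean_degree": deg[order],
            "significant": [node_ids[i] in sig for i in order],
        }
    )
    k_top = max(1, int(round(top_fraction * n)))
    top_set = set(table["node_id"].iloc[:k_top])
    overlap = len(top_set & sig)
    if not sig:
        p_enrich = 1.0
    else:
        p_enrich = float(stats.hypergeom.sf(overlap - 1, n, k_top, len(sig)))
    return table, p_enrich


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Pooled-variance two-sample t (group 2 minus group 1), df = n1 + n2 - 2."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean2, sd2, n2, mean1, sd1, n1, equal_var=True)
    return float(res.statistic), n1 + n2 - 2


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table, df = 1."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
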