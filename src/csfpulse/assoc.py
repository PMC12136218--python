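"""Correlation, age-adjusted partial correlation, and residualization.

Implemented from first principles on top of numpy/scipy primitives:

* Spearman rho is the Pearson correlation of mid-ranks (ties averaged);
  p-values use the t approximation ``t = r sqrt((n-2)/(1-r^2))`` on n-2 df
  (two-sided).  An exact permutation p-value is available for tiny samples.
* Partial correlation of (x, y) given a control variable is computed two
  ways on every call — the closed form
  ``(r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))`` and the correlation of
  OLS residuals of x and y on the control — and the two routes are asserted
  to agree to 1e-10.  p uses ``t = r sqrt(df/(1-r^2))`` with df = n - 3.
* Residualization: stage 1 takes residuals of the flow metric on age;
  stage 2 regresses the biomarker on the residual with age retained in the
  model, and reports the residual's slope, SE, t and two-sided p on n - 3
  df.  Because the residual is orthogonal to age, this slope equals the
  metric's multiple-regression coefficient and its t-statistic is
  algebraically identical to the Pearson partial-correlation t — the reason
  the two procedures print identical p-values on the same data.

Missing data are handled by pairwise (matrix) or triple-wise (partial /
residualization) complete-case deletion; ``n_used`` is always reported and
cells with fewer than 4 complete cases are reported as missing, never as
zero.  Significance is assessed at p < 0.05 two-sided, uncorrected, by
default; Benjamini-Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MIN_COMPLETE = 4


# --------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p_value: float
    n_used: int
    method: str

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


@dataclass(frozen=True)
class PartialCorrelationResult:
    var_x: str
    var_y: str
    control: str
    rho_partial: float
    p_value: float
    df: int
    n_used: int
    method: str


@dataclass(frozen=True)
class ResidualizationResult:
    metric: str
    biomarker: str
    covariate: str
    estimate: float
    std_error: float
    t_value: float
    p_value: float
    n_used: int
    df: int


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix with p-values and per-cell n."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Boolean mask of cells significant at ``alpha`` (diagonal False)."""
        mask = self.p < alpha
        np.fill_diagonal(mask.values, False)
        return mask

    def masked_rho(self, alpha: float = 0.05) -> pd.DataFrame:
        """rho with non-significant off-diagonal cells blanked to NaN."""
        out = self.rho.where(self.significant(alpha))
        np.fill_diagonal(out.values, 1.0)
        return out

    def results(self) -> list[CorrelationResult]:
        """Upper-triangle cells as a flat list."""
        cols = list(self.rho.columns)
        out = []
        for i, j in itertools.combinations(range(len(cols)), 2):
            out.append(
                CorrelationResult(
                    var_x=cols[i],
                    var_y=cols[j],
                    rho=float(self.rho.iat[i, j]),
                    p_value=float(self.p.iat[i, j]),
                    n_used=int(self.n.iat[i, j]),
                    method=self.method,
                )
            )
        return out

    def bh_adjusted_p(self) -> pd.DataFrame:
        """Benjamini-Hochberg adjusted p-values over the upper triangle."""
        from statsmodels.stats.multitest import multipletests

        cols = list(self.p.columns)
        pairs = list(itertools.combinations(range(len(cols)), 2))
        raw = np.array([self.p.iat[i, j] for i, j in pairs])
        ok = np.isfinite(raw)
        adj = np.full_like(raw, np.nan)
        if ok.any():
            adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        out = pd.DataFrame(np.nan, index=cols, columns=cols)
        np.fill_diagonal(out.values, 0.0)
        for (i, j), v in zip(pairs, adj):
            out.iat[i, j] = out.iat[j, i] = v
        return out


# --------------------------------------------------------------------------
# primitives


def _ranks(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a zero-variance variable")
    return float(xc @ yc) / (sx * sy)


def _t_p_value(r: float, df: int) -> float:
    """Two-sided p for a correlation r on df degrees of freedom."""
    if df < 1:
        raise ValueError(f"needs df >= 1, got {df}")
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def _exact_p(x: np.ndarray, y: np.ndarray, method: str) -> float:
    """Exact permutation p-value by full enumeration (n <= 8)."""
    n = x.size
    if n > 8:
        raise ValueError(
            f"exact permutation p-value only supported for n <= 8, got n = {n}"
        )
    if method == "spearman":
        x, y = _ranks(x), _ranks(y)
    r_obs = abs(_pearson(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(_pearson(x, y[list(perm)])) >= r_obs - 1e-12:
            count += 1
    return count / total


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "spearman",
    p_mode: str = "tapprox",
) -> tuple[float, float, int]:
    """Correlation of two complete 1-D samples: (rho, two-sided p, n)."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < MIN_COMPLETE:
        raise ValueError(f"need >= {MIN_COMPLETE} complete pairs, got {n}")
    if p_mode == "exact":
        p = _exact_p(x, y, method)
        if method == "spearman":
            x, y = _ranks(x), _ranks(y)
        return _pearson(x, y), p, n
    if method == "spearman":
        x, y = _ranks(x), _ranks(y)
    r = _pearson(x, y)
    return r, _t_p_value(r, n - 2), n


def _complete(table: pd.DataFrame, cols: list[str]) -> np.ndarray:
    sub = table.loc[:, cols].apply(pd.to_numeric)
    return sub.dropna().to_numpy(dtype=float)


def correlation_matrix(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    method: str = "spearman",
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix over the given numeric columns.

    Cells with fewer than 4 complete pairs are reported as missing (NaN rho
    and p), never as zero.  The matrix is symmetric with a unit diagonal.
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c != "subject_id" and pd.api.types.is_numeric_dtype(table[c])
        ]
    k = len(columns)
    rho = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    n = pd.DataFrame(0, index=columns, columns=columns, dtype=int)
    for c in columns:
        n.loc[c, c] = int(table[c].notna().sum())
    for i, j in itertools.combinations(range(k), 2):
        data = _complete(table, [columns[i], columns[j]])
        if data.shape[0] < MIN_COMPLETE:
            r_ij, p_ij, n_ij = np.nan, np.nan, data.shape[0]
        else:
            r_ij, p_ij, n_ij = correlate(data[:, 0], data[:, 1], method=method)
        rho.iat[i, j] = rho.iat[j, i] = r_ij
        p.iat[i, j] = p.iat[j, i] = p_ij
        n.iat[i, j] = n.iat[j, i] = n_ij
    return CorrelationMatrix(rho=rho, p=p, n=n, method=method)


# --------------------------------------------------------------------------
# partial correlation (dual-route)


def _ols_residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def partial_correlation_arrays(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    method: str = "spearman",
) -> tuple[float, float, int]:
    """(rho_partial, p, df) of complete arrays x, y controlling z.

    Both the closed form and the residual-correlation route are computed and
    must agree to 1e-10 (a RuntimeError signals an internal defect).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if n < MIN_COMPLETE:
        raise ValueError(f"need >= {MIN_COMPLETE} complete triples, got {n}")
    if method == "spearman":
        x, y, z = _ranks(x), _ranks(y), _ranks(z)
    elif method != "pearson":
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")

    r_xy = _pearson(x, y)
    r_xz = _pearson(x, z)
    r_yz = _pearson(y, z)
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 1e-24:
        raise ValueError(
            "partial correlation undefined: a variable is collinear with the control"
        )
    r_closed = (r_xy - r_xz * r_yz) / math.sqrt(denom)

    design = np.column_stack([np.ones(n), z])
    r_resid = _pearson(_ols_residuals(x, design), _ols_residuals(y, design))

    if abs(r_closed - r_resid) > 1e-10:
        raise RuntimeError(
            f"partial-correlation routes disagree: closed {r_closed!r} vs "
            f"residual {r_resid!r}"
        )
    df = n - 3
    return r_closed, _t_p_value(r_closed, df), df


def partial_correlation(
    table: pd.DataFrame,
    var_x: str,
    var_y: str,
    control: str,
    method: str = "spearman",
) -> PartialCorrelationResult:
    """Partial correlation of two columns controlling a third (e.g. age)."""
    data = _complete(table, [var_x, var_y, control])
    n = data.shape[0]
    if n < MIN_COMPLETE:
        raise ValueError(
            f"need >= {MIN_COMPLETE} complete triples for "
            f"({var_x}, {var_y} | {control}), got {n}"
        )
    r, p, df = partial_correlation_arrays(
        data[:, 0], data[:, 1], data[:, 2], method=method
    )
    return PartialCorrelationResult(
        var_x=var_x,
        var_y=var_y,
        control=control,
        rho_partial=r,
        p_value=p,
        df=df,
        n_used=n,
        method=method,
    )


# --------------------------------------------------------------------------
# residualization


def residualization_arrays(
    metric: np.ndarray,
    biomarker: np.ndarray,
    covariate: np.ndarray,
    method: str = "pearson",
) -> tuple[float, float, float, float, int]:
    """(estimate, std_error, t, p, df) of the age-adjusted slope.

    Stage 1 residualizes the metric on the covariate; stage 2 regresses the
    biomarker on [1, covariate, residual] and reports the residual's
    coefficient on n - 3 df.  ``method='spearman'`` rank-transforms all
    three variables first.
    """
    m = np.asarray(metric, dtype=float)
    b = np.asarray(biomarker, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = m.size
    if n < MIN_COMPLETE:
        raise ValueError(f"need >= {MIN_COMPLETE} complete triples, got {n}")
    if method == "spearman":
        m, b, z = _ranks(m), _ranks(b), _ranks(z)
    elif method != "pearson":
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")

    stage1 = np.column_stack([np.ones(n), z])
    resid = _ols_residuals(m, stage1)
    if float(resid @ resid) <= 1e-24 * max(1.0, float(m @ m)):
        raise ValueError(
            "metric is (numerically) perfectly explained by the covariate; "
            "residuals have zero variance"
        )

    design = np.column_stack([np.ones(n), z, resid])
    coef, *_ = np.linalg.lstsq(design, b, rcond=None)
    fitted = design @ coef
    rss = float((b - fitted) @ (b - fitted))
    df = n - 3
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = math.sqrt(sigma2 * xtx_inv[2, 2])
    est = float(coef[2])
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return est, se, t, p, df


def residualization_fit(
    table: pd.DataFrame,
    metric: str,
    biomarker: str,
    covariate: str = "age_years",
    method: str = "pearson",
) -> ResidualizationResult:
    """Age-adjusted association of a flow metric with a biomarker."""
    data = _complete(table, [metric, biomarker, covariate])
    n = data.shape[0]
    if n < MIN_COMPLETE:
        raise ValueError(
            f"need >= {MIN_COMPLETE} complete triples for "
            f"({metric}, {biomarker} | {covariate}), got {n}"
        )
    est, se, t, p, df = residualization_arrays(
        data[:, 0], data[:, 1], data[:, 2], method=method
    )
    return ResidualizationResult(
        metric=metric,
        biomarker=biomarker,
        covariate=covariate,
        estimate=est,
        std_error=se,
        t_value=t,
        p_value=p,
        n_used=n,
        df=df,
    )


# --------------------------------------------------------------------------
# full report


@dataclass
class AssociationReport:
    """Assembled association analysis of one cohort table."""

    matrix: CorrelationMatrix
    adjusted: pd.DataFrame
    scatter: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        """Write CSV/JSON artifacts (rho, p, adjusted table, scatter data)."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.matrix.rho.to_csv(out / "correlation_rho.csv", float_format="%.10g")
        self.matrix.p.to_csv(out / "correlation_p.csv", float_format="%.10g")
        self.matrix.n.to_csv(out / "correlation_n.csv")
        self.adjusted.to_csv(out / "age_adjusted_table.csv", index=False,
                             float_format="%.10g")
        for name, df in self.scatter.items():
            df.to_csv(out / f"scatter_{name}.csv", index=False, float_format="%.10g")
        summary = {
            "method": self.matrix.method,
            "alpha": self.alpha,
            "notes": self.notes,
            "n_variables": int(len(self.matrix.rho.columns)),
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2))


def run_association_report(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    biomarkers: list[str] | None = None,
    covariate: str = "age_years",
    adjusted_biomarker: str = "csf_ab42_40_ratio",
    method: str = "spearman",
    adjusted_method: str = "pearson",
    alpha: float = 0.05,
) -> AssociationReport:
    """Full association analysis: matrix + age-adjusted table + scatter data.

    The matrix covers the covariate, the flow metrics and all biomarkers;
    the age-adjusted table holds, per metric, the partial correlation with
    ``adjusted_biomarker`` controlling the covariate and the matching
    residualization fit.  ``adjusted_method`` (default Pearson, i.e. a
    raw-data regression with raw-scale slopes) applies to both routes of the
    adjusted table, so their t-statistics and p-values coincide.
    Cell-level failures (too few complete cases,
    collinearity) become NaN rows annotated in ``notes``; the report is
    deterministic and invariant to row order.
    """
    from .cohort import METRIC_COLUMNS

    if metrics is None:
        metrics = [c for c in METRIC_COLUMNS if c in table.columns]
    if biomarkers is None:
        skip = {"subject_id", covariate, *metrics}
        biomarkers = [
            c
            for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        ]
    columns = [covariate, *metrics, *biomarkers]
    matrix = correlation_matrix(table, columns=columns, method=method)

    notes: list[str] = []
    rows = []
    scatter: dict[str, pd.DataFrame] = {}
    do_adjust = adjusted_biomarker is not None and adjusted_biomarker in table.columns
    for metric in metrics:
        row: dict[str, float | str] = {"metric": metric}
        if do_adjust:
            try:
                pc = partial_correlation(
                    table, metric, adjusted_biomarker, covariate,
                    method=adjusted_method,
                )
                # same method for both routes, so the twin columns agree
                rz = residualization_fit(
                    table, metric, adjusted_biomarker, covariate,
                    method=adjusted_method,
                )
                row.update(
                    partial_r=pc.rho_partial,
                    partial_p=pc.p_value,
                    estimate=rz.estimate,
                    std_error=rz.std_error,
                    t_value=rz.t_value,
                    resid_p=rz.p_value,
                    n_used=pc.n_used,
                )
            except ValueError as err:
                notes.append(f"{metric}: {err}")
                row.update(
                    partial_r=np.nan,
                    partial_p=np.nan,
                    estimate=np.nan,
                    std_error=np.nan,
                    t_value=np.nan,
                    resid_p=np.nan,
                    n_used=0,
                )
            sub = table.loc[:, [covariate, metric, adjusted_biomarker]].dropna()
            if len(sub) >= MIN_COMPLETE:
                design = np.column_stack([np.ones(len(sub)), sub[covariate]])
                resid = _ols_residuals(sub[metric].to_numpy(dtype=float), design)
                sc = sub.copy()
                sc[f"{metric}_age_residual"] = resid
                # sorted so the report is invariant to input row order
                sc = sc.sort_values([covariate, metric], kind="mergesort")
                scatter[metric] = sc.reset_index(drop=True)
        rows.append(row)

    adjusted = pd.DataFrame(rows)
    return AssociationReport(
        matrix=matrix, adjusted=adjusted, scatter=scatter, alpha=alpha, notes=notes
    )
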