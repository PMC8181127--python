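"""Definition of target populations of environments (TPEs).

Daily meteorological series are averaged over consecutive 20-day windows
starting from a planting-median calendar date (Nov 23 by default, six windows
= 120 days).  Windowed means plus static soil variables give one covariate
row per site (63 columns with the 9+9 default variable set).  Sites are then
ordinated by correlation-matrix PCA and grouped by Ward hierarchical
clustering on Euclidean distances of the standardized covariates.  A
thin-plate-spline surface can be fitted to interpolate cluster membership (or
any site-level response) over geographic coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CoverageError",
    "EnvCovariateTable",
    "TPEAssignment",
    "TPSModel",
    "window_aggregate",
    "pca_correlation",
    "hcluster",
    "site_proportions",
    "tps_fit",
    "tps_predict",
]


class CoverageError(ValueError):
    """A daily series does not span the requested windows."""


@dataclass(frozen=True)
class EnvCovariateTable:
    """Sites x covariates matrix; names carry variable and window index.

    Windowed meteorological columns are named ``<variable>_w<j>`` (j = 1..n)
    and static soil columns keep the bare variable name.
    """

    df: pd.DataFrame  # index: site_id

    @property
    def sites(self) -> list[str]:
        return list(self.df.index)

    @property
    def n_covariates(self) -> int:
        return self.df.shape[1]

    def standardized(self) -> pd.DataFrame:
        """Center/scale columns; zero-variance columns dropped with a warning."""
        mean = self.df.mean(axis=0)
        sd = self.df.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = list(self.df.columns[~keep])
            warnings.warn(f"dropping zero-variance covariate(s): {dropped}", stacklevel=2)
        return (self.df.loc[:, keep] - mean[keep]) / sd[keep]

    def to_long(self) -> pd.DataFrame:
        rows = []
        for col in self.df.columns:
            if "_w" in col and col.rsplit("_w", 1)[1].isdigit():
                var, window = col.rsplit("_w", 1)
                window = int(window)
            else:
                var, window = col, 0
            for site, value in self.df[col].items():
                rows.append((site, var, window, value))
        return pd.DataFrame(rows, columns=["site_id", "variable", "window", "value"])

    @classmethod
    def from_long(cls, long_df: pd.DataFrame) -> "EnvCovariateTable":
        df = long_df.copy()
        df["column"] = np.where(
            df["window"] > 0,
            df["variable"] + "_w" + df["window"].astype(str),
            df["variable"],
        )
        wide = df.pivot_table(index="site_id", columns="column", values="value", sort=False)
        wide.index.name = "site_id"
        wide.columns.name = None
        return cls(wide)


@dataclass(frozen=True)
class TPEAssignment:
    """Cluster membership of sites plus the clustering/ordination evidence."""

    labels: pd.Series  # index site_id, values 1..k
    linkage_matrix: np.ndarray
    variance_explained: np.ndarray | None = None

    @property
    def k(self) -> int:
        return int(self.labels.nunique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site_id": self.labels.index, "tpe": self.labels.values})


def window_aggregate(
    daily: pd.DataFrame,
    start_date: str = "11-23",
    window_days: int = 20,
    n_windows: int = 6,
    soil: pd.DataFrame | None = None,
) -> EnvCovariateTable:
    """Average daily meteorological series over consecutive calendar windows.

    Parameters
    ----------
    daily
        Long table (site_id, date, variable, value); dates parseable by
        pandas.  A "season" starts at ``start_date`` (``MM-DD``) of each year
        present; each site-season must cover ``window_days * n_windows`` days.
    soil
        Optional long table (site_id, variable, value) of static variables
        appended unchanged (averaged only if repeated per site).

    Multi-year data are windowed per season and then averaged over seasons,
    giving one row per site.
    """
    if window_days < 1 or n_windows < 1:
        raise ValueError("window_days and n_windows must be positive")
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    month, day = (int(x) for x in start_date.split("-"))
    span = window_days * n_windows

    # Map each record to the season whose start it falls in.
    def _starts(years: pd.Series | np.ndarray) -> pd.Series:
        return pd.to_datetime(
            pd.Series(years).astype(int).astype(str) + f"-{month:02d}-{day:02d}"
        ).set_axis(df.index)

    start_this_year = _starts(df["date"].dt.year)
    season_year = np.where(df["date"] >= start_this_year, df["date"].dt.year, df["date"].dt.year - 1)
    season_start = _starts(season_year)
    offset = (df["date"] - season_start).dt.days
    df["season"] = season_year
    df["window"] = offset // window_days + 1
    df["offset"] = offset
    df = df.loc[(df["offset"] >= 0) & (df["offset"] < span)]

    counts = df.groupby(["site_id", "variable", "season"])["value"].count()
    short = counts[counts < span]
    if len(short):
        site, var, season = short.index[0]
        raise CoverageError(
            f"daily series too short for {n_windows} windows of {window_days} d: "
            f"site {site}, variable {var}, season starting {season}-{start_date} "
            f"({int(short.iloc[0])}/{span} days)"
        )

    per_season = (
        df.groupby(["site_id", "variable", "window", "season"])["value"].mean().reset_index()
    )
    means = per_season.groupby(["site_id", "variable", "window"])["value"].mean().reset_index()
    means["column"] = means["variable"] + "_w" + means["window"].astype(str)
    wide = means.pivot_table(index="site_id", columns="column", values="value", sort=False)

    # Keep a stable variable-major, window-minor column order.
    variables = list(dict.fromkeys(daily["variable"]))
    ordered = [f"{v}_w{j}" for v in variables for j in range(1, n_windows + 1)]
    wide = wide.loc[:, ordered]

    if soil is not None:
        soil_wide = soil.pivot_table(index="site_id", columns="variable", values="value", sort=False)
        soil_vars = list(dict.fromkeys(soil["variable"]))
        wide = wide.join(soil_wide.loc[:, soil_vars], how="left")
        if wide.isna().any().any():
            missing = wide.index[wide.isna().any(axis=1)].tolist()
            raise CoverageError(f"missing soil covariates for site(s): {missing[:10]}")
    wide.index.name = "site_id"
    wide.columns.name = None
    return EnvCovariateTable(wide)


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def pca_correlation(X: EnvCovariateTable) -> PCAResult:
    """PCA on the correlation matrix of the covariates.

    Equivalent to an eigendecomposition of the correlation matrix of the
    columns; ``variance_explained`` sums to 1 and is non-increasing.
    """
    if len(X.df) < 2:
        raise ValueError("PCA needs at least 2 sites")
    Z = X.standardized()
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    explained = eigval / eigval.sum()
    comp = [f"PC{i + 1}" for i in range(len(eigval))]
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=Z.index, columns=comp)
    loadings = pd.DataFrame(eigvec, index=Z.columns, columns=comp)
    return PCAResult(scores=scores, loadings=loadings, variance_explained=explained)


def hcluster(
    X: EnvCovariateTable,
    k: int = 3,
    method: str = "ward",
    temperature_variable: str | None = "tavg",
) -> TPEAssignment:
    """Hierarchically cluster sites on Euclidean distances of standardized covariates.

    Ward linkage by default (single/average exposed).  Cluster labels are
    relabelled so cluster 1 has the lowest mean of the average-temperature
    covariates, giving a reproducible coolest-to-warmest numbering; when no
    temperature covariate is present, labels follow first appearance order.
    """
    n = len(X.df)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]; got {k}")
    Z = X.standardized()
    link = linkage(Z.to_numpy(), method=method, metric="euclidean")
    raw = fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=Z.index, name="tpe")

    temp_cols = (
        [c for c in X.df.columns if c == temperature_variable or c.startswith(f"{temperature_variable}_w")]
        if temperature_variable
        else []
    )
    if temp_cols:
        key = X.df[temp_cols].mean(axis=1).groupby(labels).mean().sort_values()
    else:
        key = pd.Series(
            {lab: i for i, lab in enumerate(dict.fromkeys(labels))}
        ).sort_values()
    remap = {old: new + 1 for new, old in enumerate(key.index)}
    labels = labels.map(remap)
    try:
        pca_var = pca_correlation(X).variance_explained
    except ValueError:
        pca_var = None
    return TPEAssignment(labels=labels, linkage_matrix=link, variance_explained=pca_var)


def site_proportions(assignment: TPEAssignment, decimals: int = 1) -> pd.Series:
    """Percentage of sites per cluster (sums to 100 within rounding)."""
    if len(assignment.labels) == 0:
        raise ValueError("empty assignment")
    counts = assignment.labels.value_counts().sort_index()
    return (100.0 * counts / counts.sum()).round(decimals)


# ---------------------------------------------------------------------------
# Thin plate splines (d = 2, m = 2): minimize ||y - g||^2 + lambda * J(g)


@dataclass(frozen=True)
class TPSModel:
    """Thin-plate-spline surface g(x) = P(x) @ beta + sum_i c_i phi(|x - x_i|)."""

    knots: np.ndarray
    coef_radial: np.ndarray
    coef_affine: np.ndarray
    smoothing: float
    penalty_order: int = 2
    dimension: int = 2
    gcv: float | None = None


def _tps_basis(r: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, r * r * np.log(r), 0.0)
    return out


def _tps_system(x: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[0]
    K = _tps_basis(squareform(pdist(x)))
    P = np.column_stack([np.ones(n), x])
    top = np.hstack([K + lam * np.eye(n), P])
    bottom = np.hstack([P.T, np.zeros((P.shape[1], P.shape[1]))])
    return np.vstack([top, bottom]), P


def tps_fit(
    y: np.ndarray,
    x: np.ndarray,
    smoothing: float | None = None,
    gcv_grid: np.ndarray | None = None,
) -> TPSModel:
    """Fit a thin-plate spline minimizing the penalized least-squares criterion.

    ``smoothing = 0`` interpolates the data; large values tend to the affine
    least-squares fit (affine surfaces are unpenalized).  When ``smoothing``
    is None, it is chosen by generalized cross-validation over ``gcv_grid``.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("y and x must have matching length")
    n, d = x.shape
    p = d + 1
    if n < p or np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < p:
        raise np.linalg.LinAlgError(
            "need at least d+1 affinely independent points to fit the spline"
        )

    if smoothing is None:
        grid = gcv_grid if gcv_grid is not None else np.logspace(-6, 4, 41)
        scores = [( _gcv_score(y, x, lam), lam) for lam in grid]
        _, smoothing = min(scores)
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")

    M, P = _tps_system(x, smoothing)
    rhs = np.concatenate([y, np.zeros(P.shape[1])])
    sol = np.linalg.solve(M, rhs)
    return TPSModel(
        knots=x.copy(),
        coef_radial=sol[:n],
        coef_affine=sol[n:],
        smoothing=float(smoothing),
        gcv=_gcv_score(y, x, smoothing) if smoothing > 0 else None,
    )


def _hat_matrix(x: np.ndarray, lam: float) -> np.ndarray:
    n = x.shape[0]
    M, P = _tps_system(x, lam)
    p = P.shape[1]
    E = np.vstack([np.eye(n), np.zeros((p, n))])
    sol = np.linalg.solve(M, E)
    K = _tps_basis(squareform(pdist(x)))
    return K @ sol[:n] + P @ sol[n:]


def _gcv_score(y: np.ndarray, x: np.ndarray, lam: float) -> float:
    n = x.shape[0]
    A = _hat_matrix(x, lam)
    resid = y - A @ y
    denom = (n - np.trace(A)) ** 2
    if denom <= 1e-12:
        return np.inf
    return float(n * (resid @ resid) / denom)


def tps_predict(model: TPSModel, x_new: np.ndarray) -> np.ndarray:
    """Evaluate a fitted thin-plate-spline surface at new coordinates."""
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    diff = x_new[:, None, :] - model.knots[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    B = _tps_basis(r)
    P = np.column_stack([np.ones(x_new.shape[0]), x_new])
    return B @ model.coef_radial + P @ model.coef_affine
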