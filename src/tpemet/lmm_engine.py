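"""Linear mixed models for multi-environment trial analysis.

Models are variance-component models: every random term is a grouping factor
(or interaction of factors, which also covers nesting) with identity
covariance, plus an IID residual.  Estimation is REML: the restricted
log-likelihood is profiled over the residual variance and the fixed effects
and maximized over the nonnegative variance ratios ``lambda_u =
sigma2_u / sigma2_e`` with a bound-constrained quasi-Newton search, so
boundary estimates come out exactly zero.  A Gibbs sampler over the same
models is provided as a cross-check.

Templates mirror the four trial models used for ESWYT-style data:

* ``eq3``  - by-year across sites: fixed environment; random replicate,
  replicate-within-environment, genotype, genotype x environment.
* ``eq4``  - across sites and TPEs: fixed TPE; random genotype,
  genotype x TPE, genotype x environment(TPE), environment(TPE),
  replicate(environment) and sub-block(environment x replicate).
* ``eq7``  - a single selection-environment trial: random replicate,
  sub-block(replicate), genotype.
* ``eq8``  - across selection environments: fixed SE; random replicate,
  replicate x sub-block(SE), genotype, genotype x SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ModelSpec",
    "RandomTerm",
    "VarianceComponents",
    "BlueTable",
    "ConvergenceError",
    "model_template",
    "prepare_trial_frame",
    "fit_reml",
    "fit_blues",
    "fit_gibbs",
    "heritability",
    "phenotypic_variance",
]


class ConvergenceError(RuntimeError):
    """REML failed to converge within the iteration budget."""


@dataclass(frozen=True)
class RandomTerm:
    """A random model term with identity covariance between its levels.

    ``factors`` names the columns whose value combinations define levels;
    alternatively ``design`` supplies an explicit n x q design matrix (used
    for correlated effects through a factored covariance, e.g. Z = Z_p L with
    A = L L').
    """

    name: str
    factors: tuple[str, ...] = ()
    design: np.ndarray | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Response, fixed factor terms and random terms of one mixed model."""

    response: str = "grain_yield"
    fixed: tuple[str, ...] = ()
    random: tuple[RandomTerm, ...] = ()
    template: str | None = None


_TEMPLATES: dict[str, ModelSpec] = {
    "eq3": ModelSpec(
        fixed=("env",),
        random=(
            RandomTerm("R", ("replicate",)),
            RandomTerm("R(E)", ("env", "replicate")),
            RandomTerm("G", ("genotype_id",)),
            RandomTerm("GE", ("genotype_id", "env")),
        ),
        template="eq3",
    ),
    "eq4": ModelSpec(
        fixed=("group_label",),
        random=(
            RandomTerm("G", ("genotype_id",)),
            RandomTerm("G*TPE", ("genotype_id", "group_label")),
            RandomTerm("G*E(TPE)", ("genotype_id", "env")),
            RandomTerm("E(TPE)", ("env",)),
            RandomTerm("R(E)", ("env", "replicate")),
            RandomTerm("SB(E*R)", ("env", "replicate", "sub_block")),
        ),
        template="eq4",
    ),
    "eq7": ModelSpec(
        fixed=(),
        random=(
            RandomTerm("R", ("replicate",)),
            RandomTerm("SB(R)", ("replicate", "sub_block")),
            RandomTerm("G", ("genotype_id",)),
        ),
        template="eq7",
    ),
    "eq8": ModelSpec(
        fixed=("group_label",),
        random=(
            RandomTerm("R", ("replicate",)),
            RandomTerm("R*SB(SE)", ("group_label", "replicate", "sub_block")),
            RandomTerm("G", ("genotype_id",)),
            RandomTerm("G*SE", ("genotype_id", "group_label")),
        ),
        template="eq8",
    ),
}


def model_template(name: str) -> ModelSpec:
    """Return one of the built-in model templates (eq3, eq4, eq7, eq8)."""
    try:
        return _TEMPLATES[name]
    except KeyError:
        raise KeyError(f"unknown model template {name!r}; choose from {sorted(_TEMPLATES)}")


def prepare_trial_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Add the derived ``env`` (site-year) column used by the templates."""
    out = df.copy()
    out["env"] = out["site_id"].astype(str) + "@" + out["cycle_year"].astype(str)
    return out


@dataclass
class VarianceComponents:
    """REML (or posterior-mean) variance estimates for one fitted model."""

    components: dict[str, float]
    residual: float
    loglik: float
    n_obs: int
    n_iterations: int
    converged: bool
    n_env: int | None = None
    n_rep: int | None = None
    phenotypic_variance: float | None = None
    heritability: float | None = None
    blups: dict[str, pd.Series] = field(default_factory=dict, repr=False)
    fixed_effects: pd.Series | None = field(default=None, repr=False)

    def __getitem__(self, name: str) -> float:
        if name in ("residual", "Residual"):
            return self.residual
        return self.components[name]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": k, "variance": v} for k, v in self.components.items()]
        rows.append({"component": "residual", "variance": self.residual})
        if self.phenotypic_variance is not None:
            rows.append({"component": "V_z", "variance": self.phenotypic_variance})
        if self.heritability is not None:
            rows.append({"component": "H2", "variance": self.heritability})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Design construction


def _factor_codes(df: pd.DataFrame, cols: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    key = df[list(cols)].astype(str).agg(":".join, axis=1)
    codes, levels = pd.factorize(key, sort=True)
    return codes, list(levels)


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _fixed_design(
    df: pd.DataFrame, fixed: tuple[str, ...], coding: str = "reference"
) -> tuple[np.ndarray, list[str]]:
    n = len(df)
    blocks = [np.ones((n, 1))]
    names = ["(Intercept)"]
    for term in fixed:
        cols = tuple(term.split(":"))
        codes, levels = _factor_codes(df, cols)
        g = len(levels)
        if g < 2:
            continue
        if coding == "sum":
            B = np.zeros((n, g - 1))
            for j in range(g - 1):
                B[codes == j, j] = 1.0
            B[codes == g - 1, :] = -1.0
        else:
            B = _indicator(codes, g)[:, 1:]
        blocks.append(B)
        names.extend(f"{term}={lev}" for lev in levels[1:])
    X = np.hstack(blocks)
    # Drop collinear columns (keeps the intercept).
    q, r, piv = _pivoted_qr(X)
    keep = sorted(piv[: np.sum(np.abs(np.diag(r)) > 1e-8 * max(1.0, abs(r[0, 0])))])
    return X[:, keep], [names[j] for j in keep]


def _pivoted_qr(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def _random_designs(
    df: pd.DataFrame, terms: tuple[RandomTerm, ...]
) -> tuple[list[RandomTerm], list[np.ndarray], list[list[str]]]:
    kept, Zs, levels_all = [], [], []
    for term in terms:
        if term.design is not None:
            Z = np.asarray(term.design, dtype=float)
            levels = [f"{term.name}[{j}]" for j in range(Z.shape[1])]
        else:
            codes, levels = _factor_codes(df, term.factors)
            if len(levels) < 2:
                warnings.warn(
                    f"random term {term.name!r} has <2 levels and is dropped", stacklevel=3
                )
                continue
            Z = _indicator(codes, len(levels))
        kept.append(term)
        Zs.append(Z)
        levels_all.append(levels)
    return kept, Zs, levels_all


# ---------------------------------------------------------------------------
# Profiled REML


class _REMLWorkspace:
    """Cross-products reused across likelihood evaluations."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray]):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.q_sizes = [Z.shape[1] for Z in Zs]
        Zfull = np.hstack(Zs) if Zs else np.zeros((self.n, 0))
        self.Zfull = Zfull
        self.ZtZ = Zfull.T @ Zfull
        self.ZtX = Zfull.T @ X
        self.Zty = Zfull.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.term_slices = []
        start = 0
        for q in self.q_sizes:
            self.term_slices.append(slice(start, start + q))
            start += q

    def _scale(self, lam: np.ndarray) -> np.ndarray:
        s = np.empty(sum(self.q_sizes))
        for sl, l in zip(self.term_slices, lam):
            s[sl] = np.sqrt(max(l, 0.0))
        return s

    def deviance(self, lam: np.ndarray) -> float:
        out = self._solve(lam)
        return out["deviance"]

    def _solve(self, lam: np.ndarray) -> dict:
        from scipy.linalg import cho_factor, cho_solve

        n, p = self.n, self.p
        s = self._scale(lam)
        K = np.outer(s, s) * self.ZtZ
        K[np.diag_indices_from(K)] += 1.0
        cK = cho_factor(K, lower=True)
        logdetH = 2.0 * np.log(np.diag(cK[0])).sum()

        SZtX = s[:, None] * self.ZtX
        SZty = s * self.Zty
        KiSZtX = cho_solve(cK, SZtX)
        KiSZty = cho_solve(cK, SZty)
        XtHiX = self.XtX - SZtX.T @ KiSZtX
        XtHiy = self.Xty - SZtX.T @ KiSZty
        yHiy = self.yty - SZty @ KiSZty
        cX = cho_factor(XtHiX, lower=True)
        logdetXtHiX = 2.0 * np.log(np.diag(cX[0])).sum()
        beta = cho_solve(cX, XtHiy)
        yPy = max(yHiy - XtHiy @ beta, 1e-300)
        dev = (n - p) * np.log(yPy) + logdetH + logdetXtHiX
        return {
            "deviance": float(dev),
            "beta": beta,
            "yPy": float(yPy),
            "logdetH": logdetH,
            "logdetXtHiX": logdetXtHiX,
            "cK": cK,
            "s": s,
        }


class _CollapsedWorkspace:
    """Profiled REML with the largest indicator term absorbed analytically.

    For an indicator term Z_b (one level per record cell), H = D + Zr Lr Zr'
    with D = I + lambda_b Z_b Z_b' block-diagonal: D^{-1} only reweights
    per-cell sums, so all cross-products can be corrected with per-cell-size
    aggregates and the Cholesky shrinks from q to q_rest.  Produces the same
    deviance as :class:`_REMLWorkspace` (tested), much faster when one term
    dominates q.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray], big: int):
        self.big = big
        self.n, self.p = X.shape
        Zb = Zs[big]
        codes = np.argmax(Zb, axis=1)
        m_of_cell = Zb.sum(axis=0)
        self.rest_idx = [i for i in range(len(Zs)) if i != big]
        Zr = (
            np.hstack([Zs[i] for i in self.rest_idx])
            if self.rest_idx
            else np.zeros((self.n, 0))
        )
        self.q_sizes = [Zs[i].shape[1] for i in self.rest_idx]
        self.term_slices = []
        start = 0
        for q in self.q_sizes:
            self.term_slices.append(slice(start, start + q))
            start += q
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtZ = Zr.T @ Zr
        self.ZtX = Zr.T @ X
        self.Zty = Zr.T @ y
        n_cells = Zb.shape[1]
        SX = np.zeros((n_cells, self.p))
        Sy = np.zeros(n_cells)
        np.add.at(SX, codes, X)
        np.add.at(Sy, codes, y)
        SZ = Zb.T @ Zr
        self.groups = []
        for m in np.unique(m_of_cell):
            sel = m_of_cell == m
            SXm, Sym, SZm = SX[sel], Sy[sel], SZ[sel]
            self.groups.append(
                {
                    "m": float(m),
                    "count": int(sel.sum()),
                    "ZZ": SZm.T @ SZm,
                    "ZX": SZm.T @ SXm,
                    "Zy": SZm.T @ Sym,
                    "XX": SXm.T @ SXm,
                    "Xy": SXm.T @ Sym,
                    "yy": float(Sym @ Sym),
                }
            )

    def _scale(self, lam_rest: list[float]) -> np.ndarray:
        s = np.empty(sum(self.q_sizes))
        for sl, l in zip(self.term_slices, lam_rest):
            s[sl] = np.sqrt(max(l, 0.0))
        return s

    def deviance(self, lam: np.ndarray) -> float:
        from scipy.linalg import cho_factor, cho_solve

        lam_b = max(float(lam[self.big]), 0.0)
        lam_rest = [float(lam[i]) for i in self.rest_idx]
        logdetD = 0.0
        ZtZ, ZtX, Zty = self.ZtZ.copy(), self.ZtX.copy(), self.Zty.copy()
        XtX, Xty, yty = self.XtX.copy(), self.Xty.copy(), self.yty
        for g in self.groups:
            w = lam_b / (1.0 + lam_b * g["m"])
            logdetD += g["count"] * np.log1p(lam_b * g["m"])
            if w:
                ZtZ -= w * g["ZZ"]
                ZtX -= w * g["ZX"]
                Zty -= w * g["Zy"]
                XtX -= w * g["XX"]
                Xty -= w * g["Xy"]
                yty -= w * g["yy"]
        s = self._scale(lam_rest)
        K = np.outer(s, s) * ZtZ
        K[np.diag_indices_from(K)] += 1.0
        cK = cho_factor(K, lower=True)
        logdetH = logdetD + 2.0 * np.log(np.diag(cK[0])).sum()
        SZtX = s[:, None] * ZtX
        SZty = s * Zty
        KiSZtX = cho_solve(cK, SZtX)
        KiSZty = cho_solve(cK, SZty)
        XtHiX = XtX - SZtX.T @ KiSZtX
        XtHiy = Xty - SZtX.T @ KiSZty
        yHiy = yty - SZty @ KiSZty
        cX = cho_factor(XtHiX, lower=True)
        beta = cho_solve(cX, XtHiy)
        yPy = max(yHiy - XtHiy @ beta, 1e-300)
        return float(
            (self.n - self.p) * np.log(yPy)
            + logdetH
            + 2.0 * np.log(np.diag(cX[0])).sum()
        )


def _pick_collapse(terms: list[RandomTerm], Zs: list[np.ndarray]) -> int | None:
    """Index of an indicator term worth absorbing analytically, if any."""
    q_total = sum(Z.shape[1] for Z in Zs)
    best, best_q = None, 0
    for i, (t, Z) in enumerate(zip(terms, Zs)):
        if t.design is None and Z.shape[1] > best_q:
            best, best_q = i, Z.shape[1]
    if best is not None and best_q >= 100 and best_q > 0.4 * q_total:
        return best
    return None


def fit_reml(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    include_checks: bool = False,
    max_iter: int = 500,
    tol: float = 1e-8,
    start: float = 0.1,
) -> VarianceComponents:
    """Fit a variance-component mixed model by REML.

    Parameters
    ----------
    data
        A trial frame (rows with missing response are dropped from the fit).
        Accepts a plain DataFrame or anything with a ``genetic_subset``
        method (a :class:`~tpemet.io_config.TrialTable`).
    spec
        A :class:`ModelSpec` or a template name (``eq3``/``eq4``/``eq7``/``eq8``).

    Returns
    -------
    VarianceComponents with nonnegative estimates (boundary solutions are
    exact zeros), the restricted log-likelihood at the optimum, and BLUPs for
    every retained random term.
    """
    from scipy.linalg import cho_solve

    if hasattr(data, "genetic_subset"):
        df = data.genetic_subset(include_checks=include_checks)
    else:
        df = data.copy()
    if isinstance(spec, str):
        spec = model_template(spec)
    needs_env = any("env" in t.factors for t in spec.random) or "env" in spec.fixed
    if needs_env and "env" not in df.columns:
        df = prepare_trial_frame(df)
    df = df.loc[df[spec.response].notna()]
    y = df[spec.response].to_numpy(dtype=float)
    X, fixed_names = _fixed_design(df, spec.fixed)
    terms, Zs, levels = _random_designs(df, spec.random)
    if not terms:
        raise ValueError("no random terms retained; nothing to estimate by REML")
    ws = _REMLWorkspace(y, X, Zs)
    collapse = _pick_collapse(terms, Zs)
    objective = _CollapsedWorkspace(y, X, Zs, collapse) if collapse is not None else ws

    U = len(terms)
    x0 = np.full(U, start)
    lam_max = 1e9  # ratio cap; hitting it means the residual variance is ~0
    res = optimize.minimize(
        objective.deviance,
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, lam_max)] * U,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success:
        # Flat-gradient aborts at a boundary still carry the optimum; only
        # genuine failures go through the derivative-free fallback.
        grad_ok = np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun))
        at_cap = np.any(res.x > 0.1 * lam_max)
        if not (grad_ok or at_cap):
            res_nm = optimize.minimize(
                lambda t: objective.deviance(np.clip(t, 0.0, lam_max)),
                res.x,
                method="Nelder-Mead",
                options={"maxiter": 200 * U, "fatol": tol, "xatol": 1e-10},
            )
            if res_nm.fun <= res.fun:
                res = res_nm
            if not res.success:
                raise ConvergenceError(f"REML did not converge: {res.message}; trace: {res}")
    lam = np.clip(res.x, 0.0, lam_max)
    lam[lam < 1e-10] = 0.0

    sol = ws._solve(lam)
    sigma2_e = sol["yPy"] / (ws.n - ws.p)
    unbounded = lam.max() > 1e3 and (
        ws.deviance(np.where(lam > 1e3, lam * 10.0, lam)) < sol["deviance"] - 0.5
    )
    if unbounded or sigma2_e < 1e-10 * max(float(np.var(y)), 1e-12):
        # Residual variance has collapsed: the restricted likelihood is
        # unbounded and the ratio parametrization degenerates.  Return the
        # continuity (ANOVA) limit: average replicate rows away and let the
        # finest random term play the residual of the collapsed model.
        degenerate = _fit_degenerate(df, spec, terms)
        if degenerate is not None:
            return degenerate
    components = {t.name: float(l * sigma2_e) for t, l in zip(terms, lam)}
    loglik = -0.5 * (
        (ws.n - ws.p) * np.log(2.0 * np.pi * sigma2_e)
        + sol["logdetH"]
        + sol["logdetXtHiX"]
        + (ws.n - ws.p)
    )

    # BLUPs: u_hat = lambda_u * Z_u' H^{-1} (y - X beta)
    e = y - X @ sol["beta"]
    Zte = ws.Zfull.T @ e
    s = sol["s"]
    HiZ_part = cho_solve(sol["cK"], s * Zte)
    # Z'H^{-1}e = Z'e - (Z'Ztilde) K^{-1} Ztilde'e with Z'Ztilde = ZtZ * s
    ZtHie = Zte - (ws.ZtZ * s[None, :]) @ HiZ_part
    blups = {}
    for t, sl, lev, l in zip(terms, ws.term_slices, levels, lam):
        u = l * ZtHie[sl]
        blups[t.name] = pd.Series(u, index=lev)

    ne = int(df["env"].nunique()) if "env" in df.columns else None
    nr = int(df["replicate"].nunique()) if "replicate" in df.columns else None
    return VarianceComponents(
        components=components,
        residual=float(sigma2_e),
        loglik=float(loglik),
        n_obs=ws.n,
        n_iterations=int(res.nit),
        converged=bool(res.success),
        n_env=ne,
        n_rep=nr,
        blups=blups,
        fixed_effects=pd.Series(sol["beta"], index=fixed_names),
    )


def _fit_degenerate(
    df: pd.DataFrame, spec: ModelSpec, terms: list[RandomTerm]
) -> VarianceComponents | None:
    """Continuity limit when the residual variance is exactly zero.

    Rows identical in every model factor are averaged; if some random term
    then indexes the collapsed rows uniquely, it takes the role of the
    residual and the remaining terms are re-estimated by REML.  Returns None
    when no term can absorb the residual (caller keeps the capped solution).
    """
    factor_terms = [t for t in terms if t.design is None]
    if len(factor_terms) != len(terms):
        return None
    cols: list[str] = []
    for t in spec.fixed:
        cols.extend(c for c in t.split(":") if c not in cols)
    for t in factor_terms:
        cols.extend(c for c in t.factors if c not in cols)
    collapsed = df.groupby(cols, as_index=False, sort=False)[spec.response].mean()
    n_rows = len(collapsed)
    finest = None
    for t in sorted(factor_terms, key=lambda t: -len(t.factors)):
        if collapsed[list(t.factors)].astype(str).agg(":".join, axis=1).nunique() == n_rows:
            finest = t
            break
    if finest is None:
        return None
    rest = tuple(t for t in factor_terms if t is not finest)
    if rest:
        inner = fit_reml(collapsed, ModelSpec(spec.response, spec.fixed, rest))
        components = dict(inner.components)
        components[finest.name] = inner.residual
        fixed_effects, loglik = inner.fixed_effects, inner.loglik
    else:
        y = collapsed[spec.response].to_numpy(dtype=float)
        X, fixed_names = _fixed_design(collapsed, spec.fixed)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        components = {finest.name: rss / (n_rows - X.shape[1])}
        fixed_effects = pd.Series(beta, index=fixed_names)
        loglik = float("inf")
    components = {t.name: components.get(t.name, 0.0) for t in terms}
    ne = int(df["env"].nunique()) if "env" in df.columns else None
    nr = int(df["replicate"].nunique()) if "replicate" in df.columns else None
    return VarianceComponents(
        components=components,
        residual=0.0,
        loglik=loglik,
        n_obs=len(df),
        n_iterations=0,
        converged=True,
        n_env=ne,
        n_rep=nr,
        fixed_effects=fixed_effects,
    )


# ---------------------------------------------------------------------------
# BLUEs (genotype fixed)


@dataclass(frozen=True)
class BlueTable:
    """Genotype BLUEs of grain yield per group (TPE-year or SE-year)."""

    df: pd.DataFrame  # columns: genotype_id, group, blue
    reference: str = "sum-to-zero genotype contrasts"

    def series(self, group: str | None = None) -> pd.Series:
        sub = self.df if group is None else self.df.loc[self.df["group"] == group]
        return sub.set_index("genotype_id")["blue"]

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


def fit_blues(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    group: str = "",
    include_checks: bool = False,
    genotype_col: str = "genotype_id",
) -> BlueTable:
    """Generalized-least-squares genotype means with genotype treated as fixed.

    The remaining random terms of ``spec`` keep their REML variance ratios;
    sum-to-zero contrasts make the BLUEs comparable means (intercept +
    genotype effect).  Genotypes absent from the data are flagged missing by
    omission rather than zero-filled.
    """
    if hasattr(data, "genetic_subset"):
        df = data.genetic_subset(include_checks=include_checks)
    else:
        df = data.copy()
    if isinstance(spec, str):
        spec = model_template(spec)
    if any("env" in t.factors for t in spec.random) or "env" in spec.fixed:
        if "env" not in df.columns:
            df = prepare_trial_frame(df)
    df = df.loc[df[spec.response].notna()]

    # Genotype (and its interactions) move to the fixed part.
    random_kept = tuple(
        t for t in spec.random if t.design is not None or genotype_col not in t.factors
    )
    y = df[spec.response].to_numpy(dtype=float)
    Xf, _ = _fixed_design(df, spec.fixed)
    codes, genos = _factor_codes(df, (genotype_col,))
    g = len(genos)
    if g < 2:
        raise ValueError("need at least two genotypes for BLUEs")
    B = np.zeros((len(df), g - 1))
    for j in range(g - 1):
        B[codes == j, j] = 1.0
    B[codes == g - 1, :] = -1.0
    X = np.hstack([Xf, B])

    terms, Zs, _ = _random_designs(df, random_kept)
    if terms:
        reml_spec = replace(spec, random=random_kept)
        vc = fit_reml(df, reml_spec)
        lam = np.array(
            [vc.components[t.name] / vc.residual if vc.residual > 0 else 0.0 for t in terms]
        )
        ws = _REMLWorkspace(y, X, Zs)
        sol = ws._solve(lam)
        beta = sol["beta"]
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    mu = beta[0]
    eff = np.append(beta[Xf.shape[1] :], -beta[Xf.shape[1] :].sum())
    blues = pd.DataFrame(
        {"genotype_id": genos, "group": group, "blue": mu + eff}
    )
    return BlueTable(df=blues)


# ---------------------------------------------------------------------------
# Heritability (entry-mean basis)


def phenotypic_variance(
    mode: str,
    *,
    V_g: float = 0.0,
    V_ge: float = 0.0,
    V_r: float = 0.0,
    ne: float = 1.0,
    nr: float = 1.0,
    V_g_tpe: float = 0.0,
) -> float:
    """Entry-mean phenotypic variance (the denominator of the H^2 formulas)."""
    if mode == "across_env":
        return V_g + V_ge / ne + V_r / (nr * ne)
    if mode == "across_tpe":
        return V_g + V_g_tpe + V_ge / ne + V_r / (nr * ne)
    raise ValueError(f"unknown mode {mode!r}")


def heritability(
    mode: str,
    *,
    V_g: float | None = None,
    V_ge: float | None = None,
    V_r: float | None = None,
    ne: float | None = None,
    nr: float | None = None,
    V_g_tpe: float = 0.0,
    V_g_total: float | None = None,
    V_z: float | None = None,
) -> float:
    """Broad-sense heritability on an entry-mean basis.

    Modes
    -----
    ``across_env``
        ``V_g / (V_g + V_ge/ne + V_r/(nr*ne))`` -- trials across environments
        within a group; for across-SE analyses pass the genotype x SE variance
        as ``V_ge`` and the number of SEs as ``ne``.
    ``across_tpe``
        ``(V_g + V_g_tpe) / (V_g + V_g_tpe + V_ge/ne + V_r/(nr*ne))`` where
        ``V_ge`` is the within-TPE GxE variance.
    ``plugin``
        ``V_g_total / V_z`` from already-aggregated quantities.
    """
    if mode == "plugin":
        if V_g_total is None or V_z is None:
            raise ValueError("plugin mode needs V_g_total and V_z")
        if V_z == 0:
            return float("nan")
        return V_g_total / V_z
    if ne is None or nr is None or ne < 1 or nr < 1:
        raise ValueError("ne and nr must be >= 1")
    vz = phenotypic_variance(mode, V_g=V_g, V_ge=V_ge, V_r=V_r, ne=ne, nr=nr, V_g_tpe=V_g_tpe)
    if vz == 0:
        return float("nan")
    num = V_g + V_g_tpe if mode == "across_tpe" else V_g
    return num / vz


# ---------------------------------------------------------------------------
# Gibbs cross-check


def fit_gibbs(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    n_iter: int = 3000,
    burn_in: int = 500,
    seed: int = 0,
    prior_df: float = 5.0,
    include_checks: bool = False,
) -> VarianceComponents:
    """Gibbs sampler over the same variance-component models as ``fit_reml``.

    Scaled-inverse-chi-squared priors (df=5) with scales implying an equal
    split of the sample phenotypic variance across components.  Intended as a
    cross-check of REML, not the default estimator.
    """
    if hasattr(data, "genetic_subset"):
        df = data.genetic_subset(include_checks=include_checks)
    else:
        df = data.copy()
    if isinstance(spec, str):
        spec = model_template(spec)
    if any("env" in t.factors for t in spec.random) or "env" in spec.fixed:
        if "env" not in df.columns:
            df = prepare_trial_frame(df)
    df = df.loc[df[spec.response].notna()]
    y = df[spec.response].to_numpy(dtype=float)
    X, _ = _fixed_design(df, spec.fixed)
    terms, Zs, _ = _random_designs(df, spec.random)
    rng = np.random.default_rng(seed)

    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    codes_list = [np.argmax(Z, axis=1) for Z in Zs]
    counts = [np.bincount(c, minlength=Z.shape[1]).astype(float) for c, Z in zip(codes_list, Zs)]

    U = len(terms)
    vy = float(np.var(y, ddof=1))
    S0 = vy / (U + 1) * (prior_df + 2) / prior_df  # prior mode = equal split
    sig2 = np.full(U, vy / (U + 1))
    sig2_e = vy / (U + 1)
    us = [np.zeros(Z.shape[1]) for Z in Zs]
    beta = XtX_inv @ (X.T @ y)

    keep_sig = np.zeros((n_iter - burn_in, U))
    keep_res = np.zeros(n_iter - burn_in)
    for it in range(n_iter):
        fitted_random = np.zeros(n)
        for u, c in zip(us, codes_list):
            fitted_random += u[c]
        # beta | rest
        r = y - fitted_random
        mean_b = XtX_inv @ (X.T @ r)
        Lb = np.linalg.cholesky(XtX_inv * sig2_e + 1e-12 * np.eye(p))
        beta = mean_b + Lb @ rng.standard_normal(p)
        resid = y - X @ beta - fitted_random
        # each random block | rest
        for k in range(U):
            c = codes_list[k]
            resid += us[k][c]
            tot = np.bincount(c, weights=resid, minlength=len(us[k]))
            prec = counts[k] / sig2_e + 1.0 / sig2[k]
            mean_u = (tot / sig2_e) / prec
            us[k] = mean_u + rng.standard_normal(len(us[k])) / np.sqrt(prec)
            resid -= us[k][c]
            df_post = prior_df + len(us[k])
            scale = (us[k] @ us[k] + prior_df * S0) / df_post
            sig2[k] = scale * df_post / rng.chisquare(df_post)
        df_post = prior_df + n
        scale = (resid @ resid + prior_df * S0) / df_post
        sig2_e = scale * df_post / rng.chisquare(df_post)
        if it >= burn_in:
            keep_sig[it - burn_in] = sig2
            keep_res[it - burn_in] = sig2_e

    comp = {t.name: float(m) for t, m in zip(terms, keep_sig.mean(axis=0))}
    return VarianceComponents(
        components=comp,
        residual=float(keep_res.mean()),
        loglik=float("nan"),
        n_obs=n,
        n_iterations=n_iter,
        converged=True,
        n_env=int(df["env"].nunique()) if "env" in df.columns else None,
        n_rep=int(df["replicate"].nunique()) if "replicate" in df.columns else None,
    )
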