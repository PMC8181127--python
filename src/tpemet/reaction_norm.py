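"""Pedigree reaction-norm prediction with Hadamard covariance kernels.

Three nested models over line-environment records:

* ``AE``            : y = mu + E + a + e
* ``AE-AxE``        : adds the line x environment interaction, with
  covariance (Z_p A Z_p') o (Z_E Z_E') -- the Hadamard (entrywise) product of
  the additive and the environment-membership kernels.
* ``AE-AxE-W-AxW``  : adds a covariate regression kernel W W'/q built from
  centered/scaled environmental covariates and its Hadamard interaction with
  the additive kernel.

Fitting is Bayesian via a Gibbs sampler on the eigenbases of the kernels
(scaled-inverse-chi-squared conjugate updates, df = 5, prior scales implying
an equal split of the phenotypic variance).  Held-out records are handled by
data augmentation; their posterior-mean predictions are reported.  With all
variances held fixed the model is Gaussian and the posterior mean is computed
in closed form instead of sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KernelSet",
    "PosteriorSummary",
    "MODELS",
    "build_kernels",
    "fit_gibbs",
    "gblup_solve",
    "pvt",
    "predictive_correlation",
]

MODELS = ("AE", "AE-AxE", "AE-AxE-W-AxW")
JITTER = 1e-8


class KernelError(ValueError):
    """Mapping or positive-semidefiniteness failures while building kernels."""


@dataclass(frozen=True)
class KernelSet:
    """Record-level covariance kernels for one reaction-norm model."""

    kernels: dict[str, np.ndarray]
    records: pd.DataFrame  # columns: line, env (row order = kernel order)
    model: str

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.kernels[name]


def _check_psd(name: str, K: np.ndarray, tol: float = 1e-6) -> None:
    w = np.linalg.eigvalsh((K + K.T) / 2.0)
    if w.min() < -tol * max(1.0, w.max()):
        raise KernelError(f"kernel {name} is not positive semidefinite (min eig {w.min():.3g})")


def build_kernels(
    A,
    records: pd.DataFrame,
    W: pd.DataFrame | None = None,
    model: str = "AE-AxE",
    check_psd: bool = True,
) -> KernelSet:
    """Materialize the covariance kernels needed by ``model``.

    Parameters
    ----------
    A
        A :class:`~tpemet.pedigree_kinship.RelationshipMatrix` (or a
        DataFrame indexed by line id).
    records
        One row per phenotypic record with columns ``line`` and ``env``.
    W
        Environment-level covariates (rows indexed by env label); required
        for the covariate model.  Columns are centered and scaled to unit
        variance at the record level; zero-variance columns are dropped.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    records = records.reset_index(drop=True)
    lines = records["line"].astype(str)
    envs = records["env"].astype(str)

    if hasattr(A, "submatrix"):
        known = set(A.ids)
        missing = sorted(set(lines) - known)
        if missing:
            raise KernelError(f"line(s) missing from pedigree: {missing[:10]}")
        K_a = A.submatrix(list(lines))
    else:
        missing = sorted(set(lines) - set(map(str, A.index)))
        if missing:
            raise KernelError(f"line(s) missing from pedigree: {missing[:10]}")
        K_a = A.loc[list(lines), list(lines)].to_numpy(dtype=float)

    env_codes, env_levels = pd.factorize(envs, sort=True)
    Z_E = np.zeros((len(records), len(env_levels)))
    Z_E[np.arange(len(records)), env_codes] = 1.0
    K_E = Z_E @ Z_E.T

    kernels: dict[str, np.ndarray] = {"a": K_a, "E": K_E}
    if model in ("AE-AxE", "AE-AxE-W-AxW"):
        kernels["aE"] = K_a * K_E
    if model == "AE-AxE-W-AxW":
        if W is None:
            raise KernelError("the covariate model needs an environment covariate matrix W")
        missing_env = sorted(set(envs) - set(map(str, W.index)))
        if missing_env:
            raise KernelError(f"environment(s) missing from W: {missing_env[:10]}")
        W_rec = W.loc[list(envs)].to_numpy(dtype=float)
        mu = W_rec.mean(axis=0)
        sd = W_rec.std(axis=0, ddof=0)
        keep = sd > 0
        W_std = (W_rec[:, keep] - mu[keep]) / sd[keep]
        q = W_std.shape[1]
        if q == 0:
            raise KernelError("all covariate columns are constant")
        K_w = (W_std @ W_std.T) / q
        kernels["W"] = K_w
        kernels["aW"] = K_a * K_w
    if check_psd:
        for name, K in kernels.items():
            _check_psd(name, K)
    return KernelSet(kernels=kernels, records=records[["line", "env"]].copy(), model=model)


@dataclass
class PosteriorSummary:
    """Posterior means/SDs of variance components plus predictions and diagnostics."""

    post_mean: dict[str, float]
    post_sd: dict[str, float]
    predictions: pd.Series = field(repr=False)
    fitted: pd.Series = field(repr=False)
    samples: pd.DataFrame = field(repr=False)
    diagnostics: pd.DataFrame = field(repr=False)
    n_chains: int = 1
    analytic: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": k, "post_mean": self.post_mean[k], "post_sd": self.post_sd.get(k, np.nan)}
            for k in self.post_mean
        ]
        return pd.DataFrame(rows)


def _eigenbases(kernels: dict[str, np.ndarray], tol: float = 1e-8):
    bases = {}
    for name, K in kernels.items():
        Kj = (K + K.T) / 2.0
        Kj[np.diag_indices_from(Kj)] += JITTER
        w, U = np.linalg.eigh(Kj)
        keep = w > tol * w.max()
        if not keep.any():
            raise KernelError(f"kernel {name} collapsed after jitter")
        bases[name] = (U[:, keep], w[keep])
    return bases


def gblup_solve(
    kernels: dict[str, np.ndarray] | KernelSet,
    variances: dict[str, float],
    resid_var: float,
    y: np.ndarray,
    train_mask: np.ndarray | None = None,
    mu: float | None = None,
) -> pd.Series | np.ndarray:
    """Closed-form posterior-mean predictions with the variances held fixed.

    Solves V = sum_m s2_m K_m[train, train] + s2_e I on the training records
    and propagates each kernel's effect to all records:
    ``g_m = s2_m K_m[:, train] V^{-1} (y_train - mu)``.  ``mu=None`` uses the
    GLS estimate of the grand mean; pass ``mu=0.0`` for a pure kernel-ridge
    solution.
    """
    kd = kernels.kernels if isinstance(kernels, KernelSet) else kernels
    y = np.asarray(y, dtype=float)
    n = len(y)
    if train_mask is None:
        train_mask = np.isfinite(y)
    tr = np.asarray(train_mask, dtype=bool)
    yt = y[tr]
    V = resid_var * np.eye(tr.sum())
    for name, s2 in variances.items():
        V += s2 * kd[name][np.ix_(tr, tr)]
    Vi = np.linalg.inv(V)
    if mu is None:
        ones = np.ones(tr.sum())
        mu = float(ones @ Vi @ yt / (ones @ Vi @ ones))
    alpha = Vi @ (yt - mu)
    pred = np.full(n, mu)
    for name, s2 in variances.items():
        pred += s2 * kd[name][:, tr] @ alpha
    return pred


def _split_rhat(chains: np.ndarray) -> float:
    # chains: (n_chains, n_draws)
    m, n = chains.shape
    if n < 4:
        return float("nan")
    half = n // 2
    split = chains[:, : 2 * half].reshape(2 * m, half)
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return float("nan")
    var_hat = (half - 1) / half * W + B / half
    return float(math.sqrt(var_hat / W))


def _ess(chains: np.ndarray) -> float:
    # Geyer initial-positive-sequence estimator, pooled over chains.
    m, n = chains.shape
    x = chains - chains.mean(axis=1, keepdims=True)
    var = x.var(axis=1, ddof=0).mean()
    if var <= 0:
        return float("nan")
    rho_sum = 0.0
    prev_rho = 0.0
    for lag in range(1, n):
        acov = np.mean([np.dot(x[c, :-lag], x[c, lag:]) / n for c in range(m)])
        rho = acov / var
        # Geyer: stop when an (odd, even) lag pair sums negative.
        if lag % 2 == 0 and rho + prev_rho < 0:
            break
        prev_rho = rho
        rho_sum += rho
    return float(m * n / (1.0 + 2.0 * rho_sum))


def fit_gibbs(
    y: np.ndarray | pd.Series,
    kernels: KernelSet,
    n_iter: int = 12_000,
    burn_in: int = 2_000,
    thin: int = 5,
    n_chains: int = 2,
    seed: int = 0,
    prior_df: float = 5.0,
    prior_scale: float | None = None,
    fixed_variances: dict[str, float] | None = None,
    fixed_resid: float | None = None,
    fixed_mu: float | None = None,
) -> PosteriorSummary:
    """Gibbs sampler for the kernel variance-component model.

    ``y`` may contain NaN for held-out records: they are imputed by data
    augmentation during sampling and their posterior-mean predictions are
    returned.  Seeded chains are reproducible bit-for-bit.

    When every variance (including the residual) is fixed the posterior over
    effects is Gaussian, so the exact posterior mean is returned via
    :func:`gblup_solve` and no sampling is performed.
    """
    y = np.asarray(pd.Series(y, dtype=float))
    n = kernels.n_records
    if len(y) != n:
        raise ValueError("response length does not match kernel dimension")
    train = np.isfinite(y)
    comp_names = list(kernels.kernels)

    if fixed_variances is not None and fixed_resid is not None and set(
        fixed_variances
    ) == set(comp_names):
        pred = gblup_solve(kernels, fixed_variances, fixed_resid, y, train, mu=fixed_mu)
        idx = _record_index(kernels)
        post = {**{k: float(v) for k, v in fixed_variances.items()}, "residual": float(fixed_resid)}
        return PosteriorSummary(
            post_mean=post,
            post_sd={k: 0.0 for k in post},
            predictions=pd.Series(pred[~train], index=idx[~train]),
            fitted=pd.Series(pred, index=idx),
            samples=pd.DataFrame(columns=list(post)),
            diagnostics=pd.DataFrame(columns=["component", "rhat", "ess"]),
            n_chains=0,
            analytic=True,
        )

    if (n_iter - burn_in) // thin < 100:
        raise ValueError("fewer than 100 post-burn-in samples; increase n_iter or lower thin")
    bases = _eigenbases(kernels.kernels)
    vy = float(np.var(y[train], ddof=1)) if train.sum() > 1 else 1.0
    vy = max(vy, 1e-8)  # constant responses must not zero the initial variances
    n_comp = len(comp_names) + 1
    # Default prior scale: mode of each scaled-inv-chi2(df, S) at an equal
    # split of the phenotypic variance (mode = df*S/(df+2)).  Pass a small
    # prior_scale for a weakly informative prior in recovery studies.
    S0 = prior_scale if prior_scale is not None else vy / n_comp * (prior_df + 2.0) / prior_df

    n_keep = (n_iter - burn_in) // thin
    all_samples = np.zeros((n_chains, n_keep, n_comp))
    pred_accum = np.zeros(n)
    pred_count = 0

    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        mu = float(np.mean(y[train]))
        y_aug = np.where(train, y, mu)
        sig2 = {
            name: (fixed_variances or {}).get(name, vy / n_comp) for name in comp_names
        }
        sig2_e = fixed_resid if fixed_resid is not None else vy / n_comp
        b = {name: np.zeros(bases[name][0].shape[1]) for name in comp_names}
        g = {name: np.zeros(n) for name in comp_names}
        kidx = 0
        for it in range(n_iter):
            # mean
            r = y_aug - sum(g.values())
            mu = rng.normal(r.mean(), math.sqrt(sig2_e / n))
            # kernel effects on their eigenbases
            for name in comp_names:
                U, d = bases[name]
                r = y_aug - mu - sum(g[m] for m in comp_names if m != name)
                proj = U.T @ r
                prec = 1.0 / sig2_e + 1.0 / (sig2[name] * d)
                mean_b = (proj / sig2_e) / prec
                b[name] = mean_b + rng.standard_normal(len(d)) / np.sqrt(prec)
                g[name] = U @ b[name]
                if fixed_variances is None or name not in fixed_variances:
                    df_post = prior_df + len(d)
                    scale = (np.sum(b[name] ** 2 / d) + prior_df * S0) / df_post
                    sig2[name] = scale * df_post / rng.chisquare(df_post)
            fitted = mu + sum(g.values())
            resid = y_aug - fitted
            if fixed_resid is None:
                df_post = prior_df + n
                scale = (resid @ resid + prior_df * S0) / df_post
                sig2_e = scale * df_post / rng.chisquare(df_post)
            # data augmentation for held-out records
            y_aug[~train] = fitted[~train] + rng.standard_normal((~train).sum()) * math.sqrt(
                sig2_e
            )
            if it >= burn_in and (it - burn_in) % thin == 0:
                all_samples[chain, kidx] = [sig2[m] for m in comp_names] + [sig2_e]
                pred_accum += fitted
                pred_count += 1
                kidx += 1

    names = comp_names + ["residual"]
    flat = all_samples.reshape(-1, n_comp)
    post_mean = {nm: float(flat[:, j].mean()) for j, nm in enumerate(names)}
    post_sd = {nm: float(flat[:, j].std(ddof=1)) for j, nm in enumerate(names)}
    diag = pd.DataFrame(
        {
            "component": names,
            "rhat": [_split_rhat(all_samples[:, :, j]) for j in range(n_comp)],
            "ess": [_ess(all_samples[:, :, j]) for j in range(n_comp)],
        }
    )
    pred = pred_accum / pred_count
    idx = _record_index(kernels)
    return PosteriorSummary(
        post_mean=post_mean,
        post_sd=post_sd,
        predictions=pd.Series(pred[~train], index=idx[~train]),
        fitted=pd.Series(pred, index=idx),
        samples=pd.DataFrame(flat, columns=names),
        diagnostics=diag,
        n_chains=n_chains,
    )


def _record_index(kernels: KernelSet) -> pd.Index:
    return pd.Index(
        kernels.records["line"].astype(str) + "|" + kernels.records["env"].astype(str)
    )


def pvt(components: dict[str, float] | PosteriorSummary) -> pd.Series:
    """Proportion of each component's variance relative to the total, in %."""
    comp = components.post_mean if isinstance(components, PosteriorSummary) else components
    vals = pd.Series({k: float(v) for k, v in comp.items()})
    if (vals < 0).any():
        raise ValueError("variance components must be nonnegative")
    total = vals.sum()
    if total == 0:
        raise ValueError("all components are zero; PVT undefined")
    return 100.0 * vals / total


def predictive_correlation(
    predictions: pd.Series | PosteriorSummary,
    observed: pd.Series,
    groups: pd.Series | None = None,
) -> float | pd.Series:
    """Pearson correlation of posterior-mean predictions vs held-out observations.

    With ``groups`` given (aligned to the observations), one correlation per
    group is returned.  Fewer than 3 pairs or zero-variance predictions give
    NaN.
    """
    if isinstance(predictions, PosteriorSummary):
        predictions = predictions.predictions
    joined = pd.concat(
        [predictions.rename("pred"), observed.rename("obs")], axis=1, join="inner"
    ).dropna()

    def _corr(sub: pd.DataFrame) -> float:
        if len(sub) < 3 or sub["pred"].std(ddof=1) == 0 or sub["obs"].std(ddof=1) == 0:
            return float("nan")
        return float(sub["pred"].corr(sub["obs"]))

    if groups is None:
        return _corr(joined)
    g = groups.reindex(joined.index)
    return joined.groupby(g).apply(_corr).rename("predictive_correlation")
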