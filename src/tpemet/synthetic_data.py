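"""Synthetic trial networks with known ground truth.

Generates pedigrees, site covariates (daily weather + static soil around
per-group means), and phenotypes whose variance structure matches what the
downstream mixed models assume, so every estimator can be scored against the
simulated truth.  Two generative modes are provided:

* ``anova`` - plot-level records following the across-TPE model (fixed TPE
  mean; random environment-within-TPE, replicate, sub-block, genotype,
  genotype x TPE, genotype x environment, residual) plus station trials in
  five selection environments.
* reaction-norm - line x environment records with effects drawn from the
  Hadamard-kernel covariances (additive, environment, additive x environment,
  covariate, additive x covariate).

All effects are zero-mean Gaussian and all draws go through a seeded
``numpy`` generator, so identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tpemet.io_config import SE_LABELS, TrialTable
from tpemet.pedigree_kinship import build_A
from tpemet.tpe_definition import EnvCovariateTable, window_aggregate

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SimulatedCovariates",
    "DesignError",
    "TPE_METEO_MEANS",
    "TPE_SOIL_MEANS",
    "simulate_pedigree",
    "simulate_covariates",
    "simulate_trials",
    "simulate_reaction_norm",
    "simulate_gain_blues",
]


class DesignError(ValueError):
    """Inconsistent trial-design settings (e.g. entries not divisible into sub-blocks)."""


#: Per-group means of the 9 meteorological variables (groups 1..3).
TPE_METEO_MEANS: dict[str, tuple[float, float, float]] = {
    "tavg": (15.82, 18.7, 21.43),
    "tmax": (24.26, 27.27, 30.69),
    "tmin": (9.5, 11.69, 13.72),
    "cdd": (16.88, 19.48, 22.2),
    "dewpoint": (0.65, 6.18, 4.24),
    "precip": (12.76, 7.83, 4.37),
    "rh2m": (38.29, 46.87, 35.77),
    "insolation": (-18.47, -13.12, 7.68),
    "wind": (1.59, 1.68, 1.86),
}

#: Per-group means of the 9 static soil variables.
TPE_SOIL_MEANS: dict[str, tuple[float, float, float]] = {
    "awc": (15.2, 13.12, 8.72),
    "awc_wilting": (20.4, 22.87, 27.5),
    "cec": (14.47, 18.75, 35.5),
    "coarse_frag": (5.467, 7.75, 15.4),
    "soc_density": (94.27, 118.37, 124.0),
    "ph_h2o": (7.53, 6.91, 7.43),
    "clay": (25.2, 30.0, 40.4),
    "sand": (37.4, 32.2, 32.3),
    "silt": (37.4, 38.0, 27.5),
}

#: Average SE yields (t/ha) used as simulated station means.
SE_MEANS: dict[str, float] = {"B5IR": 7.1, "B2IR": 4.8, "BLHT": 3.7, "F5IR": 6.7, "FDRT": 2.5}

#: Across-TPE variance components used as generative defaults (t/ha)^2.
ANOVA_COMPONENTS: dict[str, float] = {
    "E(TPE)": 1.6364,
    "G": 0.0311,
    "G*TPE": 0.0118,
    "G*E(TPE)": 0.1611,
    "R(E)": 0.0152,
    "SB(E*R)": 0.0504,
    "residual": 0.1967,
}

#: Across-SE variance components used for station trials (t/ha)^2.
SE_COMPONENTS: dict[str, float] = {
    "G*SE": 0.0447,
    "R*SB(SE)": 0.1164,
    "residual": 0.1531,
}

#: Reaction-norm variance components (scaled response).
RN_COMPONENTS: dict[str, float] = {
    "a": 0.05,
    "E": 1.0,
    "aE": 0.05,
    "W": 0.3,
    "aW": 0.02,
    "residual": 0.2,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters and design sizes of one simulated network."""

    n_cycles: int = 13
    start_year: int = 2004
    lines_per_cycle: int = 49
    replicates: int = 2
    sub_blocks: int = 5
    n_sites_per_tpe: tuple[int, ...] = (15, 8, 18)
    tpe_means: tuple[float, ...] = (5.1, 3.7, 4.7)
    se_means: dict[str, float] = field(default_factory=lambda: dict(SE_MEANS))
    anova_components: dict[str, float] = field(default_factory=lambda: dict(ANOVA_COMPONENTS))
    se_components: dict[str, float] = field(default_factory=lambda: dict(SE_COMPONENTS))
    rn_components: dict[str, float] = field(default_factory=lambda: dict(RN_COMPONENTS))
    site_year_dropout: float = 0.4
    missing_rate: float = 0.0
    include_se: bool = True
    n_founders: int = 60
    site_sd_frac: float = 0.25
    year_sd_frac: float = 0.05
    daily_sd_frac: float = 0.5
    n_weather_years: int = 3
    weather_start_year: int = 2003
    window_days: int = 20
    n_windows: int = 6
    n_env_covariates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for group in (self.anova_components, self.se_components, self.rn_components):
            bad = {k: v for k, v in group.items() if v < 0}
            if bad:
                raise ValueError(f"variances must be nonnegative: {bad}")
        if not 0 <= self.site_year_dropout < 1:
            raise ValueError("site_year_dropout must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def entries_per_trial(self) -> int:
        return self.lines_per_cycle + 1  # plus the site-specific local check

    @property
    def cycle_years(self) -> list[int]:
        return [self.start_year + c for c in range(self.n_cycles)]


@dataclass
class GroundTruth:
    """Everything needed to score downstream estimates of a simulated dataset."""

    line_effects: pd.Series
    env_effects: pd.Series
    tpe_labels: pd.Series
    components: dict[str, float]
    extras: dict = field(default_factory=dict)

    def to_tables(self) -> dict[str, pd.DataFrame]:
        return {
            "line_effects": self.line_effects.rename("effect").rename_axis("line").reset_index(),
            "env_effects": self.env_effects.rename("effect").rename_axis("env").reset_index(),
            "tpe_labels": self.tpe_labels.rename("tpe").rename_axis("site_id").reset_index(),
            "components": pd.DataFrame(
                [{"component": k, "variance": v} for k, v in self.components.items()]
            ),
        }


def _rng(spec_or_seed, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    seed = spec_or_seed.seed if isinstance(spec_or_seed, SimulationSpec) else spec_or_seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Pedigree


def simulate_pedigree(spec: SimulationSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Topologically ordered pedigree linking the trial cycles.

    Founders have unknown parents; cycle-1 lines are biparental crosses of
    founders and every later cycle crosses lines of the previous cycle, so
    the relationship matrix connects otherwise disconnected trial years.
    With ``n_cycles=0`` only the founders are returned.
    """
    if spec.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = _rng(spec, rng)
    rows = [(f"F{i + 1:03d}", "0", "0") for i in range(spec.n_founders)]
    parent_pool = [r[0] for r in rows]
    for year in spec.cycle_years:
        new = []
        for i in range(spec.lines_per_cycle):
            p1, p2 = rng.choice(parent_pool, size=2, replace=False)
            new.append((f"L{year}_{i + 1:02d}", p1, p2))
        rows.extend(new)
        parent_pool = [r[0] for r in new]
    return pd.DataFrame(rows, columns=["id", "parent1", "parent2"])


# ---------------------------------------------------------------------------
# Environmental covariates


@dataclass
class SimulatedCovariates:
    daily: pd.DataFrame       # site_id, date, variable, value
    soil: pd.DataFrame        # site_id, variable, value
    covariates: EnvCovariateTable
    tpe_labels: pd.Series     # site_id -> 1..k


def _site_ids(spec: SimulationSpec) -> tuple[list[str], pd.Series]:
    sites, labels = [], {}
    for k, n_sites in enumerate(spec.n_sites_per_tpe, start=1):
        for i in range(n_sites):
            sid = f"T{k}S{i + 1:02d}"
            sites.append(sid)
            labels[sid] = k
    return sites, pd.Series(labels, name="tpe")


def simulate_covariates(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> SimulatedCovariates:
    """Daily weather plus static soil variables around per-group means.

    Noise scales are fractions of the between-group standard deviation of
    each variable (``site_sd_frac``, ``year_sd_frac``, ``daily_sd_frac``);
    with all three at zero every site's windowed means equal its group means
    exactly.
    """
    rng = _rng(spec, rng)
    sites, labels = _site_ids(spec)
    n_days = spec.window_days * spec.n_windows
    years = [spec.weather_start_year + j for j in range(spec.n_weather_years)]

    daily_rows = []
    for var, means in TPE_METEO_MEANS.items():
        means = np.asarray(means, dtype=float)
        spread = float(np.std(means))
        for sid in sites:
            base = means[labels[sid] - 1] + rng.normal(0.0, spec.site_sd_frac * spread)
            for year in years:
                year_eff = rng.normal(0.0, spec.year_sd_frac * spread)
                dates = pd.date_range(f"{year}-11-23", periods=n_days, freq="D")
                values = base + year_eff + rng.normal(0.0, spec.daily_sd_frac * spread, n_days)
                daily_rows.append(
                    pd.DataFrame(
                        {"site_id": sid, "date": dates, "variable": var, "value": values}
                    )
                )
    daily = pd.concat(daily_rows, ignore_index=True)

    soil_rows = []
    for var, means in TPE_SOIL_MEANS.items():
        means = np.asarray(means, dtype=float)
        spread = float(np.std(means))
        for sid in sites:
            soil_rows.append(
                {
                    "site_id": sid,
                    "variable": var,
                    "value": means[labels[sid] - 1]
                    + rng.normal(0.0, spec.site_sd_frac * spread),
                }
            )
    soil = pd.DataFrame(soil_rows)

    covariates = window_aggregate(
        daily,
        start_date="11-23",
        window_days=spec.window_days,
        n_windows=spec.n_windows,
        soil=soil,
    )
    return SimulatedCovariates(daily=daily, soil=soil, covariates=covariates, tpe_labels=labels)


# ---------------------------------------------------------------------------
# Phenotypes: ANOVA mode


def _line_effects(
    spec: SimulationSpec,
    pedigree: pd.DataFrame | None,
    line_ids: list[str],
    sigma2: float,
    rng: np.random.Generator,
) -> pd.Series:
    """Genotype main effects: iid, or sigma2 * A-correlated when a pedigree is given."""
    if sigma2 == 0:
        return pd.Series(0.0, index=line_ids)
    if pedigree is None:
        return pd.Series(rng.normal(0.0, np.sqrt(sigma2), len(line_ids)), index=line_ids)
    A = build_A(pedigree, ordered=True)
    sub = A.submatrix(line_ids)
    L = np.linalg.cholesky(sub + 1e-8 * np.eye(len(line_ids)))
    return pd.Series(np.sqrt(sigma2) * (L @ rng.standard_normal(len(line_ids))), index=line_ids)


def _alpha_lattice(entries: list[str], sub_blocks: int, rng: np.random.Generator) -> list[int]:
    n = len(entries)
    if n % sub_blocks:
        raise DesignError(
            f"{n} entries cannot be split into {sub_blocks} equal sub-blocks"
        )
    size = n // sub_blocks
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.repeat(np.arange(1, sub_blocks + 1), size)
    return list(assignment)


def simulate_trials(
    spec: SimulationSpec,
    pedigree: pd.DataFrame | None = None,
    covariates: SimulatedCovariates | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TrialTable, GroundTruth]:
    """Plot-level phenotypes for the TPE network and the station SE trials.

    Each cycle uses a fresh line set (connectivity only through the pedigree,
    when given).  Site-year combinations drop out at rate
    ``site_year_dropout`` so the network is unbalanced; at least two sites
    per group are always retained.  Local checks are site-specific genotypes.
    """
    rng = _rng(spec, rng)
    if covariates is not None:
        tpe_labels = covariates.tpe_labels
        sites = list(tpe_labels.index)
    else:
        sites, tpe_labels = _site_ids(spec)

    ac, sc = spec.anova_components, spec.se_components
    records: list[dict] = []
    line_effect_all: dict[str, float] = {}
    env_effect_all: dict[str, float] = {}
    check_effects: dict[str, float] = {}

    def draw(sd2: float) -> float:
        return rng.normal(0.0, np.sqrt(sd2)) if sd2 > 0 else 0.0

    for year in spec.cycle_years:
        lines = [f"L{year}_{i + 1:02d}" for i in range(spec.lines_per_cycle)]
        g = _line_effects(spec, pedigree, lines, ac["G"], rng)
        line_effect_all.update(g.to_dict())
        g_tpe = {
            (line, k): draw(ac["G*TPE"])
            for line in lines
            for k in range(1, len(spec.n_sites_per_tpe) + 1)
        }

        # site-year dropout, keeping >=2 sites per group
        retained: list[str] = []
        for k in range(1, len(spec.n_sites_per_tpe) + 1):
            group_sites = [s for s in sites if tpe_labels[s] == k]
            keep = [s for s in group_sites if rng.random() >= spec.site_year_dropout]
            if len(keep) < 2:
                keep = list(rng.choice(group_sites, size=min(2, len(group_sites)), replace=False))
            retained.extend(keep)

        for site in retained:
            k = int(tpe_labels[site])
            env = f"{site}@{year}"
            e_eff = draw(ac["E(TPE)"])
            env_effect_all[env] = e_eff
            check_id = f"CHK_{site}"
            if check_id not in check_effects:
                check_effects[check_id] = draw(ac["G"])
            ge = {line: draw(ac["G*E(TPE)"]) for line in lines + [check_id]}
            for rep in range(1, spec.replicates + 1):
                r_eff = draw(ac["R(E)"])
                entries = lines + [check_id]
                sb_of = dict(zip(entries, _alpha_lattice(entries, spec.sub_blocks, rng)))
                sb_eff = {b: draw(ac["SB(E*R)"]) for b in range(1, spec.sub_blocks + 1)}
                for entry in entries:
                    is_check = entry == check_id
                    gen = check_effects[entry] if is_check else g[entry]
                    gt = 0.0 if is_check else g_tpe[(entry, k)]
                    yld = (
                        spec.tpe_means[k - 1]
                        + e_eff
                        + r_eff
                        + sb_eff[sb_of[entry]]
                        + gen
                        + gt
                        + ge[entry]
                        + draw(ac["residual"])
                    )
                    records.append(
                        {
                            "cycle_year": year,
                            "site_id": site,
                            "group_label": str(k),
                            "group_kind": "TPE",
                            "replicate": rep,
                            "sub_block": sb_of[entry],
                            "genotype_id": entry,
                            "is_local_check": is_check,
                            "grain_yield": yld,
                        }
                    )

        # Selection-environment trials at the single station.
        for se in SE_LABELS if spec.include_se else ():
            check_id = f"CHK_OBR_{se}"
            if check_id not in check_effects:
                check_effects[check_id] = draw(ac["G"])
            g_se = {line: draw(sc["G*SE"]) for line in lines + [check_id]}
            for rep in range(1, spec.replicates + 1):
                entries = lines + [check_id]
                sb_of = dict(zip(entries, _alpha_lattice(entries, spec.sub_blocks, rng)))
                sb_eff = {b: draw(sc["R*SB(SE)"]) for b in range(1, spec.sub_blocks + 1)}
                for entry in entries:
                    is_check = entry == check_id
                    gen = check_effects[entry] if is_check else g[entry]
                    yld = (
                        spec.se_means[se]
                        + sb_eff[sb_of[entry]]
                        + gen
                        + g_se[entry]
                        + draw(sc["residual"])
                    )
                    records.append(
                        {
                            "cycle_year": year,
                            "site_id": f"OBR_{se}",
                            "group_label": se,
                            "group_kind": "SE",
                            "replicate": rep,
                            "sub_block": sb_of[entry],
                            "genotype_id": entry,
                            "is_local_check": is_check,
                            "grain_yield": yld,
                        }
                    )

    df = pd.DataFrame.from_records(records)
    # Yields are measurements and cannot be negative; with the default means
    # the floor is touched by <1% of plots, with test-sized variances never.
    df["grain_yield"] = df["grain_yield"].clip(lower=0.0)
    if spec.missing_rate > 0:
        mask = rng.random(len(df)) < spec.missing_rate
        df.loc[mask, "grain_yield"] = np.nan
    truth = GroundTruth(
        line_effects=pd.Series(line_effect_all, name="effect"),
        env_effects=pd.Series(env_effect_all, name="effect"),
        tpe_labels=tpe_labels,
        components={**{k: v for k, v in ac.items()}, **{f"SE:{k}": v for k, v in sc.items()}},
        extras={"check_effects": check_effects},
    )
    return TrialTable(df), truth


# ---------------------------------------------------------------------------
# Phenotypes: reaction-norm mode


def simulate_reaction_norm(
    spec: SimulationSpec,
    pedigree: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    n_lines: int | None = None,
    n_envs: int | None = None,
    n_reps: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Line x environment records drawn from the Hadamard-kernel model.

    Returns ``(records, W, truth)``: records have columns line, env, y;
    ``W`` is the environment x covariate matrix (indexed by env).  Effects:
    environment main, additive (A-correlated when a pedigree is given),
    additive x environment (A-correlated within each environment), covariate
    regression t = W gamma and its interaction with the additive kernel.
    """
    rng = _rng(spec, rng)
    rc = spec.rn_components
    if pedigree is not None:
        ped_lines = [i for i in pedigree["id"] if not i.startswith("F")]
        lines = ped_lines if n_lines is None else ped_lines[:n_lines]
        A = build_A(pedigree, ordered=True).submatrix(lines)
    else:
        n_lines = n_lines or 100
        lines = [f"L{i + 1:03d}" for i in range(n_lines)]
        A = np.eye(n_lines)
    n_envs = n_envs or 20
    envs = [f"ENV{j + 1:02d}" for j in range(n_envs)]
    nl = len(lines)

    L = np.linalg.cholesky(A + 1e-8 * np.eye(nl))
    a = np.sqrt(rc["a"]) * (L @ rng.standard_normal(nl)) if rc["a"] > 0 else np.zeros(nl)
    E = rng.normal(0.0, np.sqrt(rc["E"]), n_envs) if rc["E"] > 0 else np.zeros(n_envs)

    q = spec.n_env_covariates
    W_env = rng.standard_normal((n_envs, q))
    W_env = (W_env - W_env.mean(axis=0)) / W_env.std(axis=0, ddof=0)

    # line x env interaction: A-correlated within each environment
    aE = np.zeros((nl, n_envs))
    if rc["aE"] > 0:
        aE = np.sqrt(rc["aE"]) * (L @ rng.standard_normal((nl, n_envs)))
    # covariate regression on the 1/sqrt(q)-scaled covariates
    t_env = np.zeros(n_envs)
    if rc["W"] > 0:
        gamma = rng.normal(0.0, np.sqrt(rc["W"] / q), q)
        t_env = W_env @ gamma
    at = np.zeros((nl, n_envs))
    if rc["aW"] > 0:
        U = np.sqrt(rc["aW"]) * (L @ rng.standard_normal((nl, q)))
        at = U @ (W_env.T / np.sqrt(q))

    rows = []
    for j, env in enumerate(envs):
        for i, line in enumerate(lines):
            signal = E[j] + a[i] + aE[i, j] + t_env[j] + at[i, j]
            for _ in range(n_reps):
                rows.append(
                    {
                        "line": line,
                        "env": env,
                        "y": signal + rng.normal(0.0, np.sqrt(rc["residual"])),
                    }
                )
    records = pd.DataFrame(rows)
    W = pd.DataFrame(W_env, index=envs, columns=[f"w{k + 1}" for k in range(q)])
    truth = GroundTruth(
        line_effects=pd.Series(a, index=lines, name="effect"),
        env_effects=pd.Series(E, index=envs, name="effect"),
        tpe_labels=pd.Series(dtype=int),
        components=dict(rc),
        extras={"aE": aE, "t_env": t_env, "at": at},
    )
    return records, W, truth


# ---------------------------------------------------------------------------
# BLUE-level data with a genetic trend (for gain-recovery experiments)


def simulate_gain_blues(
    spec: SimulationSpec,
    trend: float = 0.1,
    noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line yearly BLUEs carrying a linear genetic trend (t/ha per year).

    Returns ``(blues, pedigree)``; blues columns: genotype_id, cycle_year,
    group, blue.  Line means rise by ``trend`` per cycle on top of
    A-correlated deviations, with iid measurement noise.
    """
    rng = _rng(spec, rng)
    pedigree = simulate_pedigree(spec, rng)
    lines = [i for i in pedigree["id"] if not i.startswith("F")]
    A = build_A(pedigree, ordered=True).submatrix(lines)
    L = np.linalg.cholesky(A + 1e-8 * np.eye(len(lines)))
    sigma_a = np.sqrt(spec.rn_components["a"])
    dev = sigma_a * (L @ rng.standard_normal(len(lines)))
    year_of = {line: int(line[1:5]) for line in lines}
    y0 = spec.cycle_years[0]
    rows = []
    for i, line in enumerate(lines):
        year = year_of[line]
        bv = spec.tpe_means[0] + trend * (year - y0) + dev[i]
        rows.append(
            {
                "genotype_id": line,
                "cycle_year": year,
                "group": "1",
                "blue": bv + rng.normal(0.0, noise_sd),
            }
        )
    return pd.DataFrame(rows), pedigree
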