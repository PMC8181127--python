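"""Grain-yield gain per environment group.

Per-cycle genotype BLUEs are fed to a relationship-matrix mixed model
(y = mu + year + additive line effect, with the line effects distributed
N(0, sigma2_a A)); the resulting line-level predictions are regressed on the
trial year by OLS.  The slope, in kg/ha/year, is the estimated gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tpemet.lmm_engine import ModelSpec, RandomTerm, fit_reml
from tpemet.pedigree_kinship import RelationshipMatrix

__all__ = ["GainEstimate", "estimate_gain", "ols_slope"]


@dataclass(frozen=True)
class GainEstimate:
    """OLS slope of line-level predictions on year for one group."""

    group: str
    slope_kg_per_ha_year: float
    intercept_t_ha: float
    r_squared: float
    p_value: float
    slope_se_kg: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "slope_kg_per_ha_year": self.slope_kg_per_ha_year,
            "intercept_t_ha": self.intercept_t_ha,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "slope_se_kg": self.slope_se_kg,
            "n_points": self.n_points,
        }


def ols_slope(years: np.ndarray, values: np.ndarray) -> tuple[float, float, float, float, float]:
    """Plain OLS of values on (centered) years: slope, intercept, R^2, p, SE."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0.0:  # flat response: slope 0, nothing explained
        return 0.0, float(values.mean()), 0.0, 1.0, 0.0
    res = stats.linregress(years - years.mean(), values)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
        float(res.stderr),
    )


def estimate_gain(
    blues: pd.DataFrame,
    A: RelationshipMatrix,
    blup_kind: str = "fitted",
    weighted: bool = False,
) -> list[GainEstimate]:
    """Estimate the yearly yield gain for each group of BLUEs.

    Parameters
    ----------
    blues
        Columns genotype_id, cycle_year, group, blue (t/ha); one row per
        line per year per group.
    A
        Additive relationship matrix covering every genotype.
    blup_kind
        ``"fitted"`` regresses the model's line-level predictions
        (mean + year effect + additive value, i.e. yield-scale values); using
        ``"additive"`` regresses the additive values alone, which attributes
        to the trend only what the pedigree carries across cycles.
    weighted
        When True, regress yearly means instead of per-line values.
    """
    if blup_kind not in ("fitted", "additive"):
        raise ValueError("blup_kind must be 'fitted' or 'additive'")
    out = []
    for group, sub in blues.groupby("group", sort=False):
        sub = sub.dropna(subset=["blue"]).reset_index(drop=True)
        years = sub["cycle_year"].astype(int)
        if years.nunique() < 3:
            raise ValueError(
                f"group {group!r} has {years.nunique()} distinct years; need >= 3"
            )
        lines = list(dict.fromkeys(sub["genotype_id"].astype(str)))
        A_sub = A.submatrix(lines)
        L = np.linalg.cholesky(A_sub + 1e-8 * np.eye(len(lines)))
        line_pos = {g: i for i, g in enumerate(lines)}
        Zp = np.zeros((len(sub), len(lines)))
        Zp[np.arange(len(sub)), [line_pos[g] for g in sub["genotype_id"].astype(str)]] = 1.0

        frame = sub.assign(year_f=years.astype(str))
        spec = ModelSpec(
            response="blue",
            fixed=(),
            random=(
                RandomTerm("year", ("year_f",)),
                RandomTerm("a", design=Zp @ L),
            ),
        )
        vc = fit_reml(frame, spec)
        a_hat = L @ vc.blups["a"].to_numpy()
        mu = float(vc.fixed_effects.iloc[0])
        year_blup = vc.blups["year"]
        if blup_kind == "fitted":
            values = (
                mu
                + year_blup.reindex(frame["year_f"]).to_numpy()
                + a_hat[[line_pos[g] for g in sub["genotype_id"].astype(str)]]
            )
        else:
            values = a_hat[[line_pos[g] for g in sub["genotype_id"].astype(str)]]
        xs = years.to_numpy(dtype=float)
        if weighted:
            df_y = pd.DataFrame({"year": xs, "v": values}).groupby("year")["v"].mean()
            xs, values = df_y.index.to_numpy(), df_y.to_numpy()
        slope, intercept, r2, p, se = ols_slope(xs, values)
        out.append(
            GainEstimate(
                group=str(group),
                slope_kg_per_ha_year=1000.0 * slope,
                intercept_t_ha=intercept,
                r_squared=r2,
                p_value=p,
                slope_se_kg=1000.0 * se,
                n_points=len(values),
            )
        )
    return out
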