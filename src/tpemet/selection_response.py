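"""Genetic correlations and direct/correlated response to selection.

Given genotype BLUEs of two environment groups and their entry-mean
heritabilities:

* genetic correlation  r_ij = p_ij / sqrt(h2_i * h2_j)
* correlated response  CR = r_bar * sqrt(H2_SE / H2_TPE)
* direct response      DR = i * V_g_total / sqrt(V_z)   (i = 1 by default)

Raw genetic correlations may exceed 1 in magnitude; both the raw value (used
for CR) and a copy clamped to [-1, 1] are reported.
"""

from __future__ import annotations

import math
import warnings

import pandas as pd

__all__ = [
    "phenotypic_correlation",
    "genetic_correlation",
    "correlated_response",
    "direct_response",
    "response_table",
]

MIN_SHARED = 3


def phenotypic_correlation(blues_i: pd.Series, blues_j: pd.Series) -> float:
    """Pearson correlation of genotype BLUEs over shared genotypes.

    Pairwise complete: genotypes missing in either group are dropped.  Fewer
    than three shared genotypes, or a zero-variance vector, gives NaN with a
    warning.
    """
    merged = pd.concat([blues_i.rename("i"), blues_j.rename("j")], axis=1, join="inner").dropna()
    if len(merged) < MIN_SHARED:
        warnings.warn(
            f"only {len(merged)} shared genotypes (<{MIN_SHARED}); correlation undefined",
            stacklevel=2,
        )
        return float("nan")
    si, sj = merged["i"].std(ddof=1), merged["j"].std(ddof=1)
    if si == 0 or sj == 0:
        warnings.warn("zero-variance BLUE vector; correlation undefined", stacklevel=2)
        return float("nan")
    return float(merged["i"].corr(merged["j"]))


def genetic_correlation(p_ij: float, h2_i: float, h2_j: float) -> tuple[float, float]:
    """Genetic correlation from a phenotypic correlation and two heritabilities.

    Returns ``(raw, clamped)``: the raw value may exceed |1| when the plug-in
    inputs are noisy; the clamped copy is restricted to [-1, 1].  Either
    heritability at 0 gives NaN.
    """
    if not (0 < h2_i <= 1) or not (0 < h2_j <= 1):
        if h2_i == 0 or h2_j == 0:
            return float("nan"), float("nan")
        raise ValueError("heritabilities must lie in (0, 1]")
    if math.isnan(p_ij):
        return float("nan"), float("nan")
    raw = p_ij / math.sqrt(h2_i * h2_j)
    return raw, max(-1.0, min(1.0, raw))


def correlated_response(r_bar: float, h2_se: float, h2_tpe: float) -> float:
    """Relative efficiency of indirect selection: r_bar * sqrt(H2_SE / H2_TPE)."""
    if h2_tpe == 0:
        return float("nan")
    if h2_tpe < 0 or h2_se < 0:
        raise ValueError("heritabilities must be nonnegative")
    return r_bar * math.sqrt(h2_se / h2_tpe)


def direct_response(V_g_total: float, V_z: float, intensity: float = 1.0) -> float:
    """Expected direct response: i * V_g_total / sqrt(V_z).

    For across-TPE analyses ``V_g_total`` is the genotypic plus the
    genotype x TPE variance.  Nonpositive phenotypic variance gives NaN.
    """
    if V_z <= 0:
        return float("nan")
    return intensity * V_g_total / math.sqrt(V_z)


def response_table(
    per_year: pd.DataFrame,
    intensity: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-year/per-group response summary.

    Input columns: year, group, p (phenotypic correlation), h2_se, h2_tpe,
    V_g_total, V_z.  Output adds r, r_clamped, CR (from the raw per-year r)
    and DR; a ``Mean`` row per group averages the available years, matching
    the convention of computing r_bar as the arithmetic mean over years with
    data.
    """
    rows = []
    for rec in per_year.itertuples():
        raw, clamped = genetic_correlation(rec.p, rec.h2_se, rec.h2_tpe)
        rows.append(
            {
                "year": rec.year,
                "group": rec.group,
                "p": rec.p,
                "r": raw,
                "r_clamped": clamped,
                "h2_se": rec.h2_se,
                "h2_tpe": rec.h2_tpe,
                "cr": correlated_response(raw, rec.h2_se, rec.h2_tpe)
                if not math.isnan(raw)
                else float("nan"),
                "dr": direct_response(rec.V_g_total, rec.V_z, intensity),
            }
        )
    out = pd.DataFrame(rows)
    means = []
    for group, sub in out.groupby("group", sort=False):
        r_bar = sub["r"].mean(skipna=True)
        means.append(
            {
                "year": -1,
                "group": group,
                "p": sub["p"].mean(skipna=True),
                "r": r_bar,
                "r_clamped": max(-1.0, min(1.0, r_bar)) if not math.isnan(r_bar) else r_bar,
                "h2_se": sub["h2_se"].mean(skipna=True),
                "h2_tpe": sub["h2_tpe"].mean(skipna=True),
                "cr": correlated_response(
                    r_bar, sub["h2_se"].mean(skipna=True), sub["h2_tpe"].mean(skipna=True)
                )
                if not math.isnan(r_bar)
                else float("nan"),
                "dr": sub["dr"].mean(skipna=True),
            }
        )
    return pd.concat([out, pd.DataFrame(means)], ignore_index=True)
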