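"""Inferential layer for freezing effects.

Per-cell one-sample t-tests ask whether the mean log10 surrogate/original
ratio differs from zero; p-values are adjusted for multiplicity within small
families (by default the 6 joint x direction cells of one measure and
group, Holm step-down); group differences are assessed per cell with a
Type-II two-way ANOVA with factors Group and Lab (the lab factor absorbs the
acquisition-site confound), reporting the Group effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    n: int


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``.

    Uses the sample SD (n-1).  A zero-variance sample yields t=0, p=1 when
    its mean equals ``mu0``; otherwise the statistic is undefined and an
    error is raised.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("need a 1-D sample with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    n = x.shape[0]
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    df = n - 1
    if sd == 0.0:
        if np.isclose(mean, mu0):
            return TTestResult(0.0, df, 1.0, mean, n)
        raise ValueError("zero variance with mean != mu0: t undefined")
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), mean, n)


def adjust_p(pvals, method: str = "holm") -> np.ndarray:
    """Multiplicity-adjusted p-values.

    ``holm`` (step-down, default) or ``fdr_bh`` (Benjamini-Hochberg).
    Adjusted values are >= raw values and order preserving.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("holm", "fdr_bh"):
        raise ValueError(f"unsupported adjustment method {method!r}")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method=method)[1]


@dataclass(frozen=True)
class AnovaResult:
    F_group: float
    df_num: int
    df_den: int
    p_group: float


def anova_group_lab(
    effects: pd.DataFrame,
    value: str = "log10_ratio",
    group: str = "group",
    lab: str = "lab",
) -> AnovaResult:
    """Type-II two-way ANOVA of one cell's effects; Group main effect.

    The model is ``value ~ Group * Lab`` (interaction included); Type-II
    sums of squares are reported for the Group main effect.  Requires two
    levels per factor and at least one observation per occupied cell such
    that the Group effect is estimable.
    """
    data = effects[[value, group, lab]].dropna().rename(
        columns={value: "y", group: "g", lab: "l"}
    )
    if data["g"].nunique() < 2 or data["l"].nunique() < 2:
        raise ValueError("need >= 2 levels of both Group and Lab")
    with np.errstate(divide="ignore", invalid="ignore"):
        model = ols("y ~ C(g) * C(l)", data=data).fit()
        try:
            table = anova_lm(model, typ=2)
        except Exception as exc:  # non-estimable design (empty cells)
            raise ValueError(f"Type-II ANOVA not estimable: {exc}") from exc
    row = table.loc["C(g)"]
    resid = table.loc["Residual"]
    if not np.isfinite(row["F"]):
        raise ValueError("Group effect not estimable (empty cell?)")
    return AnovaResult(
        float(row["F"]), int(row["df"]), int(resid["df"]), float(row["PR(>F)"])
    )


def freezing_effect_stats(
    effects: pd.DataFrame,
    adjust_method: str = "holm",
    value: str = "log10_ratio",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level statistics over a tidy table of per-participant effects.

    Returns two tables:

    * one-sample tests: one row per (group, measure, joint, direction) with
      mean ratio, t, df, raw and adjusted p (family = the joint x direction
      cells of one group x measure);
    * group comparisons: one row per (measure, joint, direction) with the
      Type-II Group F and raw/adjusted p (family = the joint x direction
      cells of one measure).
    """
    t_rows = []
    for (grp, measure), block in effects.groupby(["group", "measure"]):
        for (joint, direction), cell in block.groupby(["joint", "direction"]):
            vals = cell[value].dropna().to_numpy()
            if vals.size < 2:
                log.warning("t-test skipped (n=%d): %s %s %s %s", vals.size, grp, measure, joint, direction)
                continue
            r = one_sample_t(vals)
            t_rows.append(
                {
                    "group": grp, "measure": measure, "joint": joint,
                    "direction": direction, "n": r.n, "mean_log10_ratio": r.mean,
                    "t": r.t, "df": r.df, "p": r.p,
                }
            )
    t_table = pd.DataFrame(t_rows)
    if not t_table.empty:
        t_table["p_adj"] = np.nan
        for _, idx in t_table.groupby(["group", "measure"]).groups.items():
            t_table.loc[idx, "p_adj"] = adjust_p(t_table.loc[idx, "p"], adjust_method)

    a_rows = []
    for (measure, joint, direction), cell in effects.groupby(["measure", "joint", "direction"]):
        try:
            r = anova_group_lab(cell, value=value)
        except ValueError as exc:
            log.warning("ANOVA skipped for %s %s %s: %s", measure, joint, direction, exc)
            continue
        a_rows.append(
            {
                "measure": measure, "joint": joint, "direction": direction,
                "F_group": r.F_group, "df_num": r.df_num, "df_den": r.df_den,
                "p": r.p_group,
            }
        )
    a_table = pd.DataFrame(a_rows)
    if not a_table.empty:
        a_table["p_adj"] = np.nan
        for _, idx in a_table.groupby("measure").groups.items():
            a_table.loc[idx, "p_adj"] = adjust_p(a_table.loc[idx, "p"], adjust_method)
    return t_table, a_table
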