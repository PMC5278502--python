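"""Drug-response statistics: two-way ANOVA with Sidak-corrected contrasts.

The pharmacology experiments compare normalized (fold-change) reporter
intensity across treatment groups over an hourly time course, separately
per neuron class. Following standard practice for such panels, a
fixed-effects two-way ANOVA (treatment x time) is fit per class, and each
treatment group is compared against a reference (vehicle) group at every
timepoint using the pooled residual variance, with Sidak correction for
the whole family of comparisons. Cells are the unit of observation;
within-cell repeated-measures correlation is deliberately ignored (a
documented limitation of this design, not an oversight of the code).

Significance tiers follow the usual star convention:
ns, * (<0.05), ** (<0.01), *** (<0.001), **** (<0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

TIER_THRESHOLDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_tier(p: float) -> str:
    for thr, tier in TIER_THRESHOLDS:
        if p < thr:
            return tier
    return "ns"


def sidak_adjust(p_raw: float, m: int) -> float:
    """Sidak familywise adjustment: 1 - (1 - p)^m, capped at 1.

    Monotone in both arguments and never smaller than ``p_raw``.
    """
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if p_raw == 1.0:
        return 1.0
    # -expm1(m*log1p(-p)) is exact for small p where (1-p)^m loses bits
    return float(min(1.0, -np.expm1(m * np.log1p(-p_raw))))


@dataclass(frozen=True)
class AnovaResult:
    """F tests of a two-way fixed-effects model."""

    tables: pd.DataFrame  # index: treatment/time/interaction; F, df, p
    residual_ms: float
    residual_df: float

    def f_statistic(self, factor: str) -> float:
        return float(self.tables.loc[factor, "F"])

    def p_value(self, factor: str) -> float:
        return float(self.tables.loc[factor, "p"])


def _check_design(df: pd.DataFrame, group_col: str, time_col: str) -> None:
    counts = df.groupby([group_col, time_col], observed=True).size()
    if df[group_col].nunique() < 2 or df[time_col].nunique() < 2:
        raise ValueError("need >= 2 levels per factor")
    full = pd.MultiIndex.from_product(
        [df[group_col].unique(), df[time_col].unique()])
    missing = full.difference(counts.index)
    if len(missing) > 0:
        raise ValueError(f"empty design cell(s): {list(missing)[:5]}")
    low = counts[counts < 2]
    if len(low) > 0:
        raise ValueError(f"design cell(s) with < 2 observations: {list(low.index)[:5]}")


def two_way_anova(table: pd.DataFrame, response: str = "intensity",
                  group_col: str = "group", time_col: str = "time_hr") -> AnovaResult:
    """Fixed-effects two-way ANOVA (treatment, time, interaction).

    Fit by OLS with sum-to-zero coding and marginal (Type-III) sums of
    squares, so unbalanced designs are handled; on balanced data this
    reduces to the textbook mean-squares ratios.
    """
    _check_design(table, group_col, time_col)
    df = table[[response, group_col, time_col]].copy()
    df.columns = ["y", "g", "t"]
    df["g"] = df["g"].astype(str)
    df["t"] = df["t"].astype(str)
    model = smf.ols("y ~ C(g, Sum) * C(t, Sum)", data=df).fit()
    aov = anova_lm(model, typ=3)
    out = pd.DataFrame({
        "F": [aov.loc["C(g, Sum)", "F"], aov.loc["C(t, Sum)", "F"],
              aov.loc["C(g, Sum):C(t, Sum)", "F"]],
        "df_num": [aov.loc["C(g, Sum)", "df"], aov.loc["C(t, Sum)", "df"],
                   aov.loc["C(g, Sum):C(t, Sum)", "df"]],
        "df_den": [aov.loc["Residual", "df"]] * 3,
        "p": [aov.loc["C(g, Sum)", "PR(>F)"], aov.loc["C(t, Sum)", "PR(>F)"],
              aov.loc["C(g, Sum):C(t, Sum)", "PR(>F)"]],
    }, index=["treatment", "time", "interaction"])
    resid_df = float(aov.loc["Residual", "df"])
    resid_ms = float(aov.loc["Residual", "sum_sq"] / resid_df)
    return AnovaResult(tables=out, residual_ms=resid_ms, residual_df=resid_df)


@dataclass(frozen=True)
class ResponseResult:
    """One group-vs-reference contrast at one timepoint in one class."""

    neuron_class: str
    time_hr: float
    group_pair: tuple[str, str]  # (group, reference)
    mean_difference: float
    F_statistics: dict  # factor -> (F, (df_num, df_den))
    p_raw: float
    p_sidak: float
    significance_tier: str


def normalize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each cell's intensities by its value at the first frame.

    Cells whose first-frame intensity is not > 0 are dropped (fold-change
    undefined); the returned table gains no columns.
    """
    def _norm(sub: pd.DataFrame) -> pd.DataFrame | None:
        sub = sub.sort_values("time_hr")
        first = sub["intensity"].iloc[0]
        if not np.isfinite(first) or first <= 0:
            return None
        sub = sub.copy()
        sub["intensity"] = sub["intensity"] / first
        return sub

    parts = [p for _, g in table.groupby("cell_id", sort=True)
             if (p := _norm(g)) is not None]
    return pd.concat(parts, ignore_index=True)


def per_timepoint_comparisons(table: pd.DataFrame, reference_group: str,
                              family: str = "panel",
                              by_class: bool = True) -> list[ResponseResult]:
    """Compare every group against the reference at every timepoint.

    Per neuron class (or once overall if ``by_class=False``): fit the
    two-way ANOVA, then at each timepoint test each non-reference group's
    mean against the reference using the pooled residual mean square
    (two-sided t on the residual df). Sidak family size is
    ``(n_groups - 1) * n_timepoints`` for ``family="panel"`` (the default
    reading of a whole time-course panel) or ``n_groups - 1`` for
    ``family="per_timepoint"``.
    """
    if family not in ("panel", "per_timepoint"):
        raise ValueError("family must be 'panel' or 'per_timepoint'")
    results: list[ResponseResult] = []
    strata = table.groupby("neuron_class", sort=True) if by_class else [("all", table)]
    for ncls, sub in strata:
        # fold-change tables have a degenerate baseline column (every cell
        # exactly 1 at t=0); zero-variance timepoints would deflate the
        # pooled residual MS and make every contrast anticonservative, so
        # they are excluded from the model and the comparisons
        variances = sub.groupby("time_hr")["intensity"].var()
        degenerate = set(variances[variances.fillna(0.0) <= 1e-24].index)
        if degenerate:
            sub = sub[~sub["time_hr"].isin(degenerate)]
        groups = sorted(sub["group"].unique())
        if reference_group not in groups:
            raise ValueError(f"reference group {reference_group!r} absent in class {ncls}")
        others = [g for g in groups if g != reference_group]
        times = sorted(sub["time_hr"].unique())
        aov = two_way_anova(sub)
        fstats = {factor: (aov.f_statistic(factor),
                           (float(aov.tables.loc[factor, "df_num"]),
                            float(aov.tables.loc[factor, "df_den"])))
                  for factor in ("treatment", "time", "interaction")}
        m_panel = len(others) * len(times)
        for t in times:
            at_t = sub[sub["time_hr"] == t]
            ref = at_t[at_t["group"] == reference_group]["intensity"]
            if len(ref) == 0:
                continue  # skipped timepoint: reference missing
            for g in others:
                cur = at_t[at_t["group"] == g]["intensity"]
                if len(cur) == 0:
                    continue
                diff = float(cur.mean() - ref.mean())
                se = np.sqrt(aov.residual_ms * (1.0 / len(cur) + 1.0 / len(ref)))
                tval = diff / se
                p_raw = float(2.0 * sps.t.sf(abs(tval), aov.residual_df))
                m = m_panel if family == "panel" else len(others)
                p_adj = sidak_adjust(p_raw, m)
                results.append(ResponseResult(
                    neuron_class=str(ncls), time_hr=float(t),
                    group_pair=(g, reference_group), mean_difference=diff,
                    F_statistics=fstats, p_raw=p_raw, p_sidak=p_adj,
                    significance_tier=significance_tier(p_adj),
                ))
    return results


def results_to_frame(results: list[ResponseResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "neuron_class": r.neuron_class, "time_hr": r.time_hr,
        "group": r.group_pair[0], "reference": r.group_pair[1],
        "mean_difference": r.mean_difference,
        "F_treatment": r.F_statistics["treatment"][0],
        "F_time": r.F_statistics["time"][0],
        "F_interaction": r.F_statistics["interaction"][0],
        "p_raw": r.p_raw, "p_sidak": r.p_sidak,
        "significance_tier": r.significance_tier,
    } for r in results])
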