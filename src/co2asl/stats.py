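"""Group statistics: mixed-design repeated-measures ANOVA and post-hoc tests.

The design is split-plot: stress group (unstressed vs stressed) is the
between-subject factor, CO2 concentration the within-subject factor, with one
metric value per subject x condition.  Post-hoc layers mirror common
practice: Holm-Sidak-adjusted between-group comparisons per concentration,
and Sidak-adjusted paired within-group tests for the 20 % vs post-removal
contrast.  Significance criterion: alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .image_io import CompletenessError, check_complete

ALPHA = 0.05


@dataclass
class FactorResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class AnovaResult:
    """Per-factor F statistics of the mixed two-way ANOVA."""

    stress: FactorResult
    concentration: FactorResult
    interaction: FactorResult
    metric: str
    alpha: float = ALPHA
    sphericity_correction: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("stress", "concentration", "interaction"):
            r: FactorResult = getattr(self, name)
            rows.append({"factor": name, "F": r.F, "df1": r.df1,
                         "df2": r.df2, "p": r.p})
        return pd.DataFrame(rows)


def _validate(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    required = {"subject", "group", "condition", metric}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    check_complete(table)
    counts = table.groupby("group")["subject"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 subjects per group")
    return table


def rm_two_way_anova(table: pd.DataFrame, metric: str,
                     correction: bool = False) -> AnovaResult:
    """Mixed-design ANOVA: concentration within-subject, stress between.

    ``correction=True`` applies the Greenhouse-Geisser correction to the
    within-subject p-values (off by default).  Factors with exactly zero
    between-level variation report F = 0, p = 1.
    """
    table = _validate(table, metric)
    aov = pg.mixed_anova(data=table, dv=metric, within="condition",
                         subject="subject", between="group",
                         correction=correction)
    aov = aov.set_index("Source")
    p_col = next(c for c in ("p_unc", "p-unc") if c in aov.columns)
    if correction:
        p_col = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns),
                     p_col)

    def factor(source: str) -> FactorResult:
        row = aov.loc[source]
        F, p = float(row["F"]), float(row[p_col])
        if not np.isfinite(F):  # zero sums of squares: no effect at all
            F, p = 0.0, 1.0
        if not np.isfinite(p):
            p = 1.0
        return FactorResult(F=F, df1=int(row["DF1"]), df2=int(row["DF2"]), p=p)

    return AnovaResult(stress=factor("group"),
                       concentration=factor("condition"),
                       interaction=factor("Interaction"),
                       metric=metric,
                       sphericity_correction=correction)


def holm_sidak_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Raw p-values are ordered ascending; the i-th (1-based) gets
    adjusted p = 1 - (1 - p_(i))^(m - i + 1), with monotone non-decreasing
    enforcement, mapped back to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    return multipletests(p, method="holm-sidak")[1]


def _safe_p(stat_p: float) -> float:
    # identical samples give a 0/0 t statistic; no evidence of a difference
    return 1.0 if not np.isfinite(stat_p) else float(stat_p)


def holm_sidak_posthoc(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Unstressed-vs-stressed comparison at each condition, Holm-Sidak adjusted.

    Two-sample t-tests per condition over subject-level metric values; the
    adjustment family is the set of conditions compared (all conditions
    present in the table).
    """
    table = _validate(table, metric)
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    rows = []
    for condition, sub in table.groupby("condition", sort=False):
        a = sub.loc[sub["group"] == groups[0], metric].to_numpy()
        b = sub.loc[sub["group"] == groups[1], metric].to_numpy()
        t, p = sps.ttest_ind(a, b)
        rows.append({"condition": condition, "t": float(t),
                     "p_raw": _safe_p(p),
                     "mean_" + groups[0]: a.mean(),
                     "mean_" + groups[1]: b.mean()})
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_sidak_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < ALPHA
    return out


def sidak_paired_removal(table: pd.DataFrame, metric: str,
                         cond_on: str = "20", cond_off: str = "post0"
                         ) -> pd.DataFrame:
    """Paired 20 %-CO2 vs post-removal comparison within each group.

    Per group, a paired t-test of the metric at ``cond_on`` against
    ``cond_off`` across subjects, Sidak-adjusted for the family of the
    within-group comparisons run (one per group):
    p_adj = 1 - (1 - p)^m.
    """
    table = _validate(table, metric)
    for cond in (cond_on, cond_off):
        if cond not in set(table["condition"]):
            raise ValueError(f"condition {cond!r} missing from the table")
    groups = sorted(table["group"].unique())
    m = len(groups)
    rows = []
    for group in groups:
        sub = table[table["group"] == group]
        wide = sub.pivot(index="subject", columns="condition", values=metric)
        on, off = wide[cond_on].to_numpy(), wide[cond_off].to_numpy()
        t, p = sps.ttest_rel(on, off)
        p = _safe_p(p)
        rows.append({"group": group, "n": len(on), "t": float(t),
                     "mean_on": on.mean(), "mean_off": off.mean(),
                     "p_raw": p,
                     "p_sidak": 1.0 - (1.0 - p) ** m,
                     "family_size": m})
    out = pd.DataFrame(rows)
    out["significant_decrease"] = (out["p_sidak"] < ALPHA) & (out["t"] > 0)
    return out
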