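"""Genotype x age group comparisons.

The comparison layer mirrors standard factorial practice for slice
electrophysiology cohorts: per-group ROUT-style robust outlier exclusion
(Q = 1%), a Shapiro-Wilk normality screen (reported, never used to switch
tests), a two-way ANOVA (genotype, age, interaction; Type-II sums of
squares for unbalanced cell counts), and per-age control-vs-disease
contrasts on the pooled residual variance with Holm-Sidak adjustment
across ages.

For single-group descriptive data the regression behind ROUT degenerates
to a robust location fit: residuals from the median, scaled by the
normalized MAD, tested with a Benjamini-Hochberg-style threshold at rate
Q. That simplification is flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .core import ParameterError

__all__ = [
    "CohortTable",
    "ComparisonResult",
    "normality_screen",
    "rout_outliers",
    "two_way_anova",
    "holm_sidak",
    "compare_groups",
]

REQUIRED_COLUMNS = ("value", "genotype", "age")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"cohort table missing columns: {missing}")
    if table[["genotype", "age"]].isna().any().any():
        raise ParameterError("cohort table has missing factor labels")
    return table


class CohortTable:
    """Per-cell metric values tagged with genotype x age factors.

    Thin wrapper over a DataFrame with columns ``value``, ``genotype``,
    ``age`` and optional ``animal_id``/``cell_id`` so either cells or
    animals can serve as the unit of analysis.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = _validate_table(pd.DataFrame(data).reset_index(drop=True))

    @classmethod
    def from_records(cls, records) -> "CohortTable":
        return cls(pd.DataFrame.from_records(records))

    def groups(self):
        return self.data.groupby(["genotype", "age"], sort=False, observed=True)

    def summary(self) -> pd.DataFrame:
        """Group means +/- SEM and n, Supplementary-Table style."""
        g = self.groups()["value"]
        out = g.agg(n="count", mean="mean", sem="sem").reset_index()
        return out


@dataclass
class ComparisonResult:
    """Two-way ANOVA + per-age Holm-Sidak contrasts with an audit trail."""

    anova: pd.DataFrame
    pairwise: pd.DataFrame
    normality: pd.DataFrame
    outliers_removed: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Two-way ANOVA (Type-II SS)", self.anova.to_string()]
        lines += ["", "Per-age contrasts (Holm-Sidak adjusted)", self.pairwise.to_string()]
        lines += ["", "Shapiro-Wilk normality screen", self.normality.to_string()]
        if self.outliers_removed:
            lines += ["", f"Outliers removed (ROUT): rows {self.outliers_removed}"]
        for note in self.notes:
            lines += ["", f"Note: {note}"]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "anova": self.anova.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "normality": self.normality.to_dict(orient="records"),
            "outliers_removed": list(self.outliers_removed),
            "notes": list(self.notes),
        }


def normality_screen(table: CohortTable | pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Shapiro-Wilk p per genotype x age group (reported, not acted on).

    Groups with n below ``min_n`` or zero variance are flagged instead of
    tested.
    """
    df = table.data if isinstance(table, CohortTable) else _validate_table(table)
    rows = []
    for (geno, age), grp in df.groupby(["genotype", "age"], sort=False, observed=True):
        vals = grp["value"].to_numpy(dtype=float)
        if vals.size < min_n:
            rows.append({"genotype": geno, "age": age, "n": vals.size,
                         "shapiro_p": np.nan, "flag": f"n < {min_n}"})
        elif np.ptp(vals) == 0:
            rows.append({"genotype": geno, "age": age, "n": vals.size,
                         "shapiro_p": np.nan, "flag": "degenerate (constant)"})
        else:
            rows.append({"genotype": geno, "age": age, "n": vals.size,
                         "shapiro_p": float(stats.shapiro(vals).pvalue), "flag": ""})
    return pd.DataFrame(rows)


def rout_outliers(values, q: float = 0.01) -> np.ndarray:
    """Robust outlier flags at FDR-like rate ``Q`` (default 1%).

    Residuals from the median, scaled by the normalized MAD, are turned
    into two-sided t tail probabilities (df = n - 1) and thresholded with
    a Benjamini-Hochberg step-up at rate Q. Returns a boolean mask; the
    input is never mutated. Fewer than 5 values, or zero spread, flags
    nothing.
    """
    x = np.asarray(values, dtype=float)
    flags = np.zeros(x.size, dtype=bool)
    if x.size < 5:
        return flags
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        return flags
    z = np.abs(x - med) / scale
    p = 2.0 * stats.t.sf(z, df=x.size - 1)
    order = np.argsort(p)
    thresh = q * (np.arange(1, x.size + 1)) / x.size
    below = p[order] <= thresh
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        flags[order[: k + 1]] = True
    return flags


def two_way_anova(table: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA (genotype, age, interaction), Type-II sums of squares.

    Requires >= 2 levels per factor and at least one observation per
    design cell; an empty cell is an error naming the cell.
    """
    df = table.data if isinstance(table, CohortTable) else _validate_table(table)
    genos = df["genotype"].unique()
    ages = df["age"].unique()
    if len(genos) < 2 or len(ages) < 2:
        raise ParameterError("two-way ANOVA needs >= 2 levels per factor")
    counts = df.groupby(["genotype", "age"], observed=True).size()
    for g in genos:
        for a in ages:
            if (g, a) not in counts.index:
                raise ParameterError(f"empty design cell: genotype={g!r}, age={a!r}")
    model = ols("value ~ C(genotype) * C(age)", data=df).fit()
    aov = anova_lm(model, typ=2)
    aov = aov.rename(index={
        "C(genotype)": "genotype",
        "C(age)": "age",
        "C(genotype):C(age)": "interaction",
        "Residual": "residual",
    })
    out = aov.reset_index().rename(columns={
        "index": "term", "sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p",
    })
    return out


def holm_sidak(raw_p) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, returned in input order.

    Sorted ascending, ``adj_i = max_{j<=i} 1 - (1 - p_(j))^(m - j + 1)``,
    clipped to 1.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def compare_groups(
    table: CohortTable | pd.DataFrame,
    *,
    control: str = "WT",
    q_outlier: float = 0.01,
    alpha: float = 0.05,
    exclude_outliers: bool = True,
    outlier_scope: str = "per_group",
) -> ComparisonResult:
    """Full comparison pipeline for one metric.

    Stages: ROUT(Q) exclusion (per design group by default,
    ``outlier_scope='pooled'`` to screen the pooled metric instead) ->
    Shapiro-Wilk screen (reported) -> two-way ANOVA -> per-age
    control-vs-disease t contrasts on the ANOVA residual variance,
    Holm-Sidak adjusted across ages. Excluded rows are listed by index in
    the result's audit trail.
    """
    if outlier_scope not in ("per_group", "pooled"):
        raise ParameterError("outlier_scope must be 'per_group' or 'pooled'")
    df = (table.data if isinstance(table, CohortTable) else _validate_table(table)).copy()
    notes = [f"ROUT applied {outlier_scope} as robust location (median/MAD) + BH cut at Q"]

    removed: list[int] = []
    if exclude_outliers:
        if outlier_scope == "pooled":
            chunks = [(None, df)]
        else:
            chunks = list(df.groupby(["genotype", "age"], sort=False, observed=True))
        for _, grp in chunks:
            flags = rout_outliers(grp["value"].to_numpy(dtype=float), q=q_outlier)
            removed.extend(grp.index[flags].tolist())
        df = df.drop(index=removed)
    clean = CohortTable(df)

    normality = normality_screen(clean)
    anova = two_way_anova(clean)
    resid = anova.loc[anova["term"] == "residual"].iloc[0]
    mse, dfr = float(resid["sum_sq"]) / float(resid["df"]), float(resid["df"])

    genos = [g for g in df["genotype"].unique() if g != control]
    if control not in set(df["genotype"]):
        raise ParameterError(f"control genotype {control!r} absent from table")
    if len(genos) != 1:
        raise ParameterError(f"expected exactly one non-control genotype, got {genos}")
    disease = genos[0]

    rows = []
    for age in df["age"].unique():
        a = df[(df["genotype"] == control) & (df["age"] == age)]["value"].to_numpy(float)
        b = df[(df["genotype"] == disease) & (df["age"] == age)]["value"].to_numpy(float)
        t = (b.mean() - a.mean()) / np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        p = 2.0 * stats.t.sf(abs(t), df=dfr)
        rows.append({
            "age": age, "n_control": a.size, "n_disease": b.size,
            "mean_control": a.mean(), "mean_disease": b.mean(),
            "t": float(t), "p_raw": float(p),
        })
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = holm_sidak(np.clip(pairwise["p_raw"].to_numpy(), 1e-15, 1.0))
    pairwise["significant"] = pairwise["p_adj"] < alpha
    return ComparisonResult(
        anova=anova, pairwise=pairwise, normality=normality,
        outliers_removed=removed, notes=notes,
    )
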