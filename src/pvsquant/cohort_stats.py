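"""Cohort-level descriptive and inferential statistics.

Nonparametric case-control analysis of a cohort table (pandas DataFrame,
one row per subject): medians with interquartile ranges and frequency
tables for descriptives; Mann-Whitney / Kruskal-Wallis for quantitative
group comparisons; chi-square or Fisher's exact for categorical ones;
Spearman correlation between MRI measurements; Shapiro-Wilk normality
checks. Significance level alpha = 0.05; no multiple-testing correction is
applied (none is part of the analysis design — a deliberate property, not
an omission).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class TestResult:
    """Outcome of a single statistical test."""

    method: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "group_sizes": list(self.group_sizes),
            "notes": self.notes,
            "significant": self.significant,
        }


# --------------------------------------------------------------------------
# Descriptives


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (Q1, Q3) by linear interpolation between order
    statistics — the convention used for every printed IQR."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return (float(med), float(q1), float(q3))


def percentage(count: int, denominator: int) -> float:
    """Relative frequency in percent, rounded to 1 decimal (half-up)."""
    if denominator == 0:
        return float("nan")
    import decimal

    d = decimal.Decimal(100 * count) / decimal.Decimal(denominator)
    return float(d.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def summarize_cohort(
    table: pd.DataFrame,
    group_variable: str = "group",
    quantitative: tuple[str, ...] = ("age_years", "pvs_volume_voxels"),
    categorical: tuple[str, ...] = (
        "sex",
        "severity",
        "adhd",
        "epilepsy",
        "insomnia",
        "intellectual_disability",
        "pvs_grade",
    ),
) -> pd.DataFrame:
    """Per-stratum summary: median (IQR) rows for quantitative variables,
    n (%) rows per level for categorical ones.

    Percentages are computed on non-missing denominators, and the
    denominator is printed with every row. Empty strata yield n=0 rows
    with a blank percentage.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    if group_variable not in table.columns:
        raise KeyError(f"unknown stratum variable {group_variable!r}")
    strata = ["all"] + [str(g) for g in table[group_variable].dropna().unique()]
    rows = []
    for var in quantitative:
        if var not in table.columns:
            raise KeyError(f"unknown variable {var!r}")
        for stratum in strata:
            sub = table if stratum == "all" else table[table[group_variable].astype(str) == stratum]
            med, q1, q3 = median_iqr(sub[var])
            rows.append(
                {
                    "variable": var,
                    "level": "",
                    "stratum": stratum,
                    "kind": "median_iqr",
                    "n": int(sub[var].notna().sum()),
                    "denominator": int(sub[var].notna().sum()),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "percent": np.nan,
                }
            )
    for var in categorical:
        if var not in table.columns:
            raise KeyError(f"unknown variable {var!r}")
        levels = sorted(table[var].dropna().unique(), key=str)
        for level in levels:
            for stratum in strata:
                sub = table if stratum == "all" else table[table[group_variable].astype(str) == stratum]
                denom = int(sub[var].notna().sum())
                n = int((sub[var] == level).sum())
                rows.append(
                    {
                        "variable": var,
                        "level": str(level),
                        "stratum": stratum,
                        "kind": "n_percent",
                        "n": n,
                        "denominator": denom,
                        "median": np.nan,
                        "q1": np.nan,
                        "q3": np.nan,
                        "percent": percentage(n, denom),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Group comparisons


def compare_quantitative(
    table: pd.DataFrame, variable: str, group_variable: str = "group"
) -> TestResult:
    """Mann-Whitney U (2 groups) or Kruskal-Wallis (>2 groups).

    Two-sided; the Mann-Whitney p uses the exact distribution for small
    tie-free samples and the tie-corrected normal approximation otherwise
    (scipy's automatic policy). All-tied data yields p = 1 with a note.
    """
    groups = []
    labels = []
    for g, sub in table.groupby(group_variable, observed=True):
        vals = np.asarray(sub[variable].dropna(), dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {g!r} has no observations for {variable!r}")
        groups.append(vals)
        labels.append(str(g))
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    sizes = tuple(len(g) for g in groups)
    if np.all(pooled == pooled[0]):
        return TestResult(
            method="mann-whitney" if len(groups) == 2 else "kruskal-wallis",
            statistic=float("nan"),
            p_value=1.0,
            group_sizes=sizes,
            notes="all values tied across groups",
        )
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return TestResult("mann-whitney", float(res.statistic), float(res.pvalue), sizes)
    res = stats.kruskal(*groups)
    return TestResult("kruskal-wallis", float(res.statistic), float(res.pvalue), sizes)


def contingency_table(
    table: pd.DataFrame, variable: str, group_variable: str = "group"
) -> pd.DataFrame:
    ct = pd.crosstab(table[variable], table[group_variable])
    if ct.size == 0:
        raise ValueError("empty contingency table")
    return ct


def compare_categorical(
    table: pd.DataFrame,
    variable: str,
    group_variable: str = "group",
    force: str | None = None,
) -> TestResult:
    """Chi-square or Fisher's exact on the variable-by-group table.

    Selection rule (``force=None``): Fisher's exact when any expected cell
    count is below 5 (2x2 tables only), otherwise Pearson chi-square
    without continuity correction. ``force`` may be ``"chisq"`` or
    ``"fisher"``. The rule outcome is recorded in ``notes``.
    """
    ct = contingency_table(table, variable, group_variable)
    return categorical_test_from_counts(ct.to_numpy(), force=force)


def categorical_test_from_counts(counts, force: str | None = None) -> TestResult:
    """As :func:`compare_categorical`, from a raw contingency array."""
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate contingency table (zero margin)")
    expected = stats.contingency.expected_freq(obs)
    min_expected = float(expected.min())
    sizes = tuple(int(s) for s in obs.sum(axis=0))
    if force == "fisher" or (force is None and min_expected < 5):
        if obs.shape != (2, 2):
            raise ValueError(
                "Fisher's exact test requires a 2x2 table; "
                f"got {obs.shape} with min expected count {min_expected:.2f}"
            )
        odds, p = stats.fisher_exact(obs.astype(int))
        note = (
            f"fisher (min expected {min_expected:.2f} < 5)"
            if force is None
            else "fisher (forced)"
        )
        return TestResult("fisher-exact", float(odds), float(p), sizes, note)
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    note = (
        f"chi-square, no continuity correction (min expected {min_expected:.2f})"
        if force is None
        else "chi-square (forced)"
    )
    return TestResult("chi-square", float(chi2), float(p), sizes, note)


def correlate_spearman(x, y) -> TestResult:
    """Spearman rank correlation with tie-corrected ranks; two-sided p."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    keep = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[keep], yv[keep]
    if xv.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("constant input: ranks undefined")
    rho, p = stats.spearmanr(xv, yv)
    return TestResult("spearman", float(rho), float(p), (int(xv.size),))


def normality_shapiro(x) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    v = np.asarray(pd.Series(x).dropna(), dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {v.size}")
    if np.all(v == v[0]):
        raise ValueError("constant vector: Shapiro-Wilk undefined")
    w, p = stats.shapiro(v)
    return TestResult("shapiro-wilk", float(w), float(p), (int(v.size),))


# --------------------------------------------------------------------------
# Report


def format_p(p: float) -> str:
    """p-values to 2 significant figures; '<0.0001' below 1e-4."""
    if np.isnan(p):
        return "NA"
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.2g}"


def build_report(
    table: pd.DataFrame,
    group_variable: str = "group",
    quantitative: tuple[str, ...] = ("age_years", "pvs_volume_voxels"),
    categorical: tuple[str, ...] = (
        "sex",
        "adhd",
        "epilepsy",
        "insomnia",
        "intellectual_disability",
        "pvs_grade",
    ),
    categorical_test: str | None = None,
) -> dict:
    """Case-control report: descriptive summary plus one test per variable.

    Returns a dict with a ``summary`` DataFrame (as records), a
    ``comparisons`` list of per-variable test results with significance
    flagged at alpha = 0.05, and the grade-volume Spearman correlation
    when both measurements are present. Deterministic for a fixed table.
    """
    summary = summarize_cohort(
        table,
        group_variable,
        quantitative=quantitative,
        categorical=tuple(
            c for c in set(categorical) | {"severity"} if c in table.columns
        ),
    )
    comparisons = []
    for var in quantitative:
        res = compare_quantitative(table, var, group_variable)
        comparisons.append({"variable": var, **res.to_dict(), "p_display": format_p(res.p_value)})
    for var in categorical:
        if var not in table.columns:
            continue
        try:
            res = compare_categorical(table, var, group_variable, force=categorical_test)
        except ValueError as exc:
            comparisons.append({"variable": var, "error": str(exc)})
            continue
        comparisons.append({"variable": var, **res.to_dict(), "p_display": format_p(res.p_value)})
    report: dict = {
        "alpha": ALPHA,
        "n_total": int(len(table)),
        "group_sizes": {
            str(g): int(n) for g, n in table[group_variable].value_counts().items()
        },
        "summary": summary.to_dict(orient="records"),
        "comparisons": comparisons,
    }
    if {"pvs_volume_voxels", "pvs_grade"} <= set(table.columns):
        sub = table[["pvs_volume_voxels", "pvs_grade"]].dropna()
        if len(sub) >= 3 and sub.nunique().min() > 1:
            res = correlate_spearman(sub["pvs_volume_voxels"], sub["pvs_grade"])
            report["grade_volume_spearman"] = {
                **res.to_dict(),
                "p_display": format_p(res.p_value),
            }
    return report
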