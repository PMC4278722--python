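"""Comparative statistics: Welch tests, category tables, cohort summaries.

Group comparisons use two-tailed unpooled (Welch) t-tests with
Satterthwaite degrees of freedom at a significance level of 0.001, with
no multiple-testing correction by default (an optional Holm correction
is available).  Category tables cross motion class (stationary /
dynamic-slow / dynamic-fast) with interaction class (interacting /
isolated) and report cell percentages of the grand total at one decimal,
half-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

MOTION_CLASSES = ("stationary", "dynamic-slow", "dynamic-fast")
INTERACTION_CLASSES = ("interacting", "isolated")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (7.65 -> 7.7), as printed tables use."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TestResult:
    """One Welch t-test: statistic, Satterthwaite df, two-tailed p."""

    t: float
    df: float
    p: float
    alpha: float
    significant: bool


def welch_ttest(group_a, group_b, alpha: float = 0.001) -> TestResult:
    """Two-tailed unpooled t-test between two samples.

    Raises ``ValueError`` for groups with fewer than two values or zero
    variance (the Welch statistic is undefined there).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; t-test undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return TestResult(t=t, df=df, p=p, alpha=alpha, significant=bool(p < alpha))


# ----------------------------------------------------------------------
# Category table
# ----------------------------------------------------------------------

@dataclass
class CategoryTable:
    """2x3 interaction x motion-class counts with percent-of-total cells."""

    counts: pd.DataFrame
    percentages: pd.DataFrame  # of the grand total, 1 decimal, half-up
    grand_total: int


def category_table_from_counts(counts: pd.DataFrame | dict) -> CategoryTable:
    """Build the table from a 2x3 count matrix.

    ``counts`` may be a DataFrame indexed (interacting, isolated) x
    (stationary, dynamic-slow, dynamic-fast) or a dict keyed by
    (interaction, motion) tuples.
    """
    if isinstance(counts, dict):
        df = pd.DataFrame(0, index=list(INTERACTION_CLASSES), columns=list(MOTION_CLASSES))
        for (inter, motion), v in counts.items():
            df.loc[inter, motion] = v
    else:
        df = counts.reindex(index=INTERACTION_CLASSES, columns=MOTION_CLASSES, fill_value=0)
    df = df.astype(int)
    total = int(df.to_numpy().sum())
    if total == 0:
        raise ValueError("category table is empty")
    pct = df.map(lambda c: round_half_up(100.0 * c / total, 1))
    return CategoryTable(counts=df, percentages=pct, grand_total=total)


def build_category_table(labels) -> CategoryTable:
    """Cross-tabulate (motion, interaction) label pairs.

    ``labels`` is an iterable of ``(motion_class, interaction_class)``
    pairs, one per organelle.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no labels to tabulate")
    counts = pd.DataFrame(0, index=list(INTERACTION_CLASSES), columns=list(MOTION_CLASSES))
    for motion, inter in labels:
        if motion not in MOTION_CLASSES or inter not in INTERACTION_CLASSES:
            raise ValueError(f"unknown label pair ({motion!r}, {inter!r})")
        counts.loc[inter, motion] += 1
    return category_table_from_counts(counts)


# ----------------------------------------------------------------------
# Per-category summaries
# ----------------------------------------------------------------------

def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def summarize_by_category(
    records: pd.DataFrame,
    category_col: str = "category",
    value_cols: tuple[str, ...] = ("area_um2", "norm_density"),
    alpha: float = 0.001,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category mean/SD tables plus all pairwise Welch tests.

    Categories with fewer than two members are excluded with a warning.
    No multiplicity correction is applied unless ``holm=True``.
    """
    cats = []
    for cat, grp in records.groupby(category_col, observed=True):
        if len(grp) < 2:
            warnings.warn(f"category {cat!r} has n={len(grp)} < 2; excluded", stacklevel=2)
            continue
        cats.append(cat)
    if len(cats) < 2:
        raise ValueError("need at least two categories with n >= 2")

    summary_rows = []
    for cat in cats:
        grp = records[records[category_col] == cat]
        row = {"category": cat, "n": len(grp)}
        for col in value_cols:
            row[f"{col}_mean"] = float(grp[col].mean())
            row[f"{col}_sd"] = float(grp[col].std(ddof=1))
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    test_rows = []
    for col in value_cols:
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                a = records.loc[records[category_col] == cats[i], col]
                b = records.loc[records[category_col] == cats[j], col]
                r = welch_ttest(a, b, alpha=alpha)
                test_rows.append(
                    {"value": col, "cat_a": cats[i], "cat_b": cats[j],
                     "t": r.t, "df": r.df, "p": r.p, "significant": r.significant}
                )
    tests = pd.DataFrame(test_rows)
    if holm and len(tests):
        tests["p_holm"] = holm_adjust(tests["p"].to_numpy())
        tests["significant"] = tests["p_holm"] < alpha
    return summary, tests


# ----------------------------------------------------------------------
# Cohort arithmetic
# ----------------------------------------------------------------------

def cohort_report(parts: dict[str, int], successes: int | None = None,
                  attempts: int | None = None) -> dict:
    """Totals and success-rate style summaries from printed counts.

    ``parts`` are per-cohort organelle counts; optionally a success /
    attempt pair yields a percentage (1 decimal, half-up).
    """
    if any(v < 0 for v in parts.values()):
        raise ValueError("counts must be non-negative")
    total = int(sum(parts.values()))
    out: dict = {"total": total, "parts": dict(parts)}
    if total > 0:
        out["part_pct"] = {k: round_half_up(100.0 * v / total, 1) for k, v in parts.items()}
    if successes is not None or attempts is not None:
        if not attempts:
            raise ValueError("attempts must be a positive whole for a success rate")
        if successes is None or successes < 0 or successes > attempts:
            raise ValueError("successes must be in [0, attempts]")
        out["success_rate_pct"] = round_half_up(100.0 * successes / attempts, 1)
        out["successes"] = successes
        out["attempts"] = attempts
    return out
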