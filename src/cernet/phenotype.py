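"""Group-comparison statistics for phenotype tables.

Works either from raw per-animal measurements (long format: trait, group,
animal, value) or directly from printed summaries (mean, SD, n), and
annotates each comparison with significance letters in the convention of
livestock tables: different lowercase letters mark p < 0.05, different
uppercase letters p < 0.01, a shared letter marks a non-significant
difference.  The group with the larger mean receives the first letter.

With equal group sizes the pooled and Welch t statistics coincide; only the
degrees of freedom (hence p) differ.  A Levene/Brown-Forsythe gate chooses
between them when raw data are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SUSPICIOUS_T = 50.0  # printed SDs implying |t| beyond this are flagged


@dataclass(frozen=True)
class GroupSummary:
    """A printed group summary: mean +/- SD with group size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("variance-based tests need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class ComparisonResult:
    trait: str
    t: float
    df: float
    p: float
    letters: tuple  # (letter for g1, letter for g2)
    suspicious: bool = False


def significance_letters(
    p: float, mean1: float, mean2: float, alpha: float = 0.05, alpha_strong: float = 0.01
) -> tuple:
    """Letter pair for two groups given their comparison p-value.

    ``("A", "B")``-style capitals below ``alpha_strong``, lowercase below
    ``alpha``, identical letters otherwise; the larger mean gets the first
    letter of the alphabet.
    """
    if p < alpha_strong:
        first, second = "A", "B"
    elif p < alpha:
        first, second = "a", "b"
    else:
        return ("a", "a")
    return (first, second) if mean1 >= mean2 else (second, first)


def t_test_from_summary(
    g1: GroupSummary, g2: GroupSummary, variant: str = "pooled", trait: str = ""
) -> ComparisonResult:
    """Two-sample t-test from printed summaries.

    ``variant='pooled'`` uses the classical equal-variance t with
    ``n1 + n2 - 2`` degrees of freedom; ``'welch'`` uses the Satterthwaite
    approximation.  Degenerate SD=0 summaries: equal means give p = 1,
    different means p = 0 with a warning.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if g1.sd == 0 and g2.sd == 0:
        equal = np.isclose(g1.mean, g2.mean)
        if not equal:
            warnings.warn(
                f"{trait or 'comparison'}: both SDs are zero with different means; p set to 0",
                stacklevel=2,
            )
        p = 1.0 if equal else 0.0
        t = 0.0 if equal else float("inf")
        df = float(g1.n + g2.n - 2)
        return ComparisonResult(trait, t, df, p, significance_letters(p, g1.mean, g2.mean))
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(g1.n + g2.n - 2)
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = float((v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1)))
    letters = significance_letters(p, g1.mean, g2.mean)
    return ComparisonResult(trait, float(t), df, float(p), letters, bool(abs(t) > SUSPICIOUS_T))


def levene_gate(*groups) -> str:
    """Choose the t variant from a Brown-Forsythe (median-centered Levene)
    test on raw data: ``'pooled'`` when variances look homogeneous
    (p >= 0.05), else ``'welch'``."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 observations")
    if all(np.ptp(a) == 0 for a in arrays):
        return "pooled"
    _, p = stats.levene(*arrays, center="median")
    return "pooled" if (np.isnan(p) or p >= 0.05) else "welch"


def one_way_anova(*groups) -> tuple:
    """Classical one-way ANOVA: returns ``(F, df1, df2, p)``.

    With exactly two groups, ``F`` equals the square of the pooled t
    statistic.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    if all(np.ptp(a) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        return 0.0, df1, df2, 1.0
    F, p = stats.f_oneway(*arrays)
    return float(F), df1, df2, float(p)


def annotate_summary_table(table: pd.DataFrame, variant: str = "pooled") -> pd.DataFrame:
    """Annotate a printed two-group summary table with t, p and letters.

    Expects columns trait, mean_high, sd_high, mean_low, sd_low, n; returns
    the table with t, df, p, letter_high, letter_low and a ``suspicious``
    flag for implausibly small printed SDs (|t| > 50).
    """
    rows = []
    for row in table.itertuples(index=False):
        res = t_test_from_summary(
            GroupSummary("high", row.mean_high, row.sd_high, row.n),
            GroupSummary("low", row.mean_low, row.sd_low, row.n),
            variant=variant,
            trait=row.trait,
        )
        rows.append(
            {
                "trait": row.trait,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "letter_high": res.letters[0],
                "letter_low": res.letters[1],
                "suspicious": res.suspicious,
            }
        )
    return pd.DataFrame(rows)
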