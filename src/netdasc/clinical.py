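"""Clinical-validation arithmetic: IHC H-score, 2×2 association, decile splits.

The H-score quantifies immunohistochemical staining on a tissue core as
H = 0·P0 + 1·P1 + 2·P2 + 3·P3 where P_x is the percentage of cells at
staining intensity x (0 none, 1 weak, 2 moderate, 3 strong), giving a
range of 0–300.  Marker high/low status versus a two-level phenotype is
tested on a 2×2 table with Pearson chi-square or Fisher's exact test; a
cohort can also be split into its extreme expression deciles for
downstream contrast analyses.

Survival modelling (Kaplan–Meier, log-rank, Cox) is deliberately out of
scope; :func:`survival_export` emits a tidy per-case table for external
survival tools instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import expected_freq

__all__ = [
    "IntensityProfile",
    "TwoByTwo",
    "AssociationResult",
    "h_score",
    "association_test",
    "dichotomize_extremes",
    "score_cases",
    "survival_export",
]


@dataclass(frozen=True)
class IntensityProfile:
    """Percentages of cells at staining intensities 0–3 (must total 100)."""

    p0: float
    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        vals = (self.p0, self.p1, self.p2, self.p3)
        for v in vals:
            if not 0 <= v <= 100:
                raise ValueError(f"intensity percentages must lie in [0, 100], got {v}")
        total = sum(vals)
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"intensity percentages must sum to 100, got {total}")


def h_score(profile: IntensityProfile) -> float:
    """H-score = 0·P0 + 1·P1 + 2·P2 + 3·P3, in [0, 300]."""
    return 0.0 * profile.p0 + 1.0 * profile.p1 + 2.0 * profile.p2 + 3.0 * profile.p3


@dataclass(frozen=True)
class TwoByTwo:
    """2×2 counts: rows = marker high/low, columns = group 1/group 2.

    The constructor order follows the printed-table reading (per-group
    column pairs): ``high_a, low_a`` for group 1 then ``high_b, low_b`` for
    group 2.
    """

    high_a: int
    low_a: int
    high_b: int
    low_b: int

    def __post_init__(self) -> None:
        for v in (self.high_a, self.low_a, self.high_b, self.low_b):
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"counts must be non-negative integers, got {v!r}")
        if self.total == 0:
            raise ValueError("2x2 table must have a positive total")

    @property
    def total(self) -> int:
        return self.high_a + self.low_a + self.high_b + self.low_b

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.high_a, self.high_b], [self.low_a, self.low_b]])

    @classmethod
    def from_flat(cls, counts: Sequence[int] | str) -> "TwoByTwo":
        if isinstance(counts, str):
            counts = [int(c) for c in counts.split(",")]
        a, b, c, d = (int(v) for v in counts)
        return cls(a, b, c, d)


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p: float
    odds_ratio: float
    high_proportions: tuple[float, float]  # percent high per column, full precision
    method: str
    expected: np.ndarray

    @property
    def high_proportions_display(self) -> tuple[float, float]:
        """Column percentages rounded to 1 decimal for display."""
        return tuple(round(v, 1) for v in self.high_proportions)


def association_test(t: TwoByTwo, method: str = "auto") -> AssociationResult:
    """Test marker-high status against a two-level group on a 2×2 table.

    ``auto`` selects Fisher's exact test when any expected count is below 5
    and the (uncorrected) Pearson chi-square otherwise; ``chi2_yates``
    applies the continuity correction.  The Fisher p-value is the two-sided
    hypergeometric enumeration (sum of conditional tables with probability
    at most that of the observed table).
    """
    tab = t.table
    expected = expected_freq(tab)
    if method == "auto":
        method = "fisher" if expected.min() < 5 else "chi2"
    if method in ("chi2", "chi2_yates"):
        res = stats.chi2_contingency(tab, correction=(method == "chi2_yates"))
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "fisher":
        statistic, p = (float(v) for v in stats.fisher_exact(tab, alternative="two-sided"))
    else:
        raise ValueError(f"unknown method {method!r}")
    num = t.high_a * t.low_b
    den = t.high_b * t.low_a
    odds = num / den if den else (math.inf if num else math.nan)
    col_a = t.high_a + t.low_a
    col_b = t.high_b + t.low_b
    props = (
        100.0 * t.high_a / col_a if col_a else math.nan,
        100.0 * t.high_b / col_b if col_b else math.nan,
    )
    return AssociationResult(
        statistic=statistic,
        p=p,
        odds_ratio=odds,
        high_proportions=props,
        method=method,
        expected=expected,
    )


def dichotomize_extremes(
    values: pd.Series | dict,
    fraction: float = 0.10,
) -> tuple[list[str], list[str]]:
    """Split the top and bottom ``fraction`` of samples into low/high groups.

    Group size is k = round-half-up(fraction · n); boundary ties are broken
    by stable sample order, and the two groups are guaranteed disjoint.
    Returns (low ids, high ids), each of length k.
    """
    s = pd.Series(values, dtype=float)
    if s.isna().any():
        raise ValueError("values must have no missing entries")
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = len(s)
    if n * fraction < 1:
        raise ValueError(f"n*fraction = {n * fraction:.3g} would give an empty group")
    k = math.floor(n * fraction + 0.5)
    if 2 * k > n:
        raise ValueError(f"groups of size {k} would overlap for n = {n}")
    order = np.argsort(s.to_numpy(), kind="stable")
    ids = s.index.to_numpy()
    low = [str(i) for i in ids[order[:k]]]
    high = [str(i) for i in ids[order[n - k:]]]
    return low, high


def score_cases(cases: pd.DataFrame) -> pd.DataFrame:
    """Add an ``h_score`` column from P0..P3 columns (case-insensitive names).

    Rows that already carry an ``h_score`` column are validated for range
    instead of recomputed.
    """
    df = cases.copy()
    colmap = {c.lower(): c for c in df.columns}
    if "h_score" in colmap:
        hs = df[colmap["h_score"]].astype(float)
        if ((hs < 0) | (hs > 300)).any():
            raise ValueError("h_score values must lie in [0, 300]")
        df["h_score"] = hs
        return df
    needed = ["p0", "p1", "p2", "p3"]
    if not all(c in colmap for c in needed):
        raise ValueError("cases table needs P0..P3 columns or a precomputed h_score column")
    df["h_score"] = [
        h_score(IntensityProfile(*[float(row[colmap[c]]) for c in needed]))
        for _, row in df.iterrows()
    ]
    return df


def survival_export(
    cases: pd.DataFrame,
    threshold: float,
    case_col: str = "case",
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Tidy per-case export (case id, H-score, high/low group, covariates)
    for external survival tools.  The high/low cut-off is user-supplied."""
    df = score_cases(cases)
    out = pd.DataFrame({
        "case": df[case_col] if case_col in df.columns else df.index,
        "h_score": df["h_score"],
        "group": np.where(df["h_score"] >= threshold, "high", "low"),
    })
    for cov in covariates:
        out[cov] = df[cov].to_numpy()
    return out
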