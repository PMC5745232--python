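"""Culture-establishment cohort statistics.

Success-rate tabulation for patient-derived culture attempts grouped by
tumor type (or sample type, media, ...), and exact two-sided Fisher
comparisons between groups computed by full hypergeometric enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd


def success_rate(finished: int, total: int, *, rounded: bool = False) -> float:
    """Percent of attempts that produced a finished culture.

    ``rounded=True`` applies round-half-away-from-zero to whole percent, the
    convention used for display; the raw value is the default.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= finished <= total:
        raise ValueError("need 0 <= finished <= total")
    pct = 100.0 * finished / total
    if rounded:
        return float(math.floor(pct + 0.5))
    return pct


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float  # (a*d)/(b*c); inf or nan when a zero cell intrudes
    zero_cell: bool
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Exact two-sided Fisher test of the 2x2 table [[a, b], [c, d]].

    Two-sidedness by the probability-mass rule: with margins fixed,
    enumerate the full hypergeometric support and sum the probabilities of
    every table whose probability does not exceed that of the observed
    table. All comparisons are exact integer arithmetic (the hypergeometric
    numerators share one denominator), so ties are handled without floating
    point slack. The odds ratio is the sample cross-product ratio; a zero
    cell is flagged rather than silently continuity-corrected.
    """
    counts = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in counts):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = (int(v) for v in counts)
    n = a + b + c + d
    if n == 0:
        raise ValueError("at least one margin must be positive")
    r1, r2, c1 = a + b, c + d, a + c
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    # P(table with a=k) = C(r1,k) C(r2,c1-k) / C(n,c1): compare numerators
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = sum(
        w
        for k in range(k_min, k_max + 1)
        if (w := math.comb(r1, k) * math.comb(r2, c1 - k)) <= w_obs
    )
    p = min(num / math.comb(n, c1), 1.0)

    zero_cell = 0 in counts
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return FisherResult(p_value=p, odds_ratio=odds, zero_cell=zero_cell,
                        table=((a, b), (c, d)))


@dataclass
class CohortTable:
    """Rows of finished/failed culture counts per group."""

    df: pd.DataFrame  # columns: group, finished, failed

    def __post_init__(self) -> None:
        required = {"group", "finished", "failed"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if (self.df[["finished", "failed"]] < 0).any().any():
            raise ValueError("counts must be non-negative")
        if self.df["group"].duplicated().any():
            raise ValueError("duplicate group labels")
        self.df = self.df.copy()
        self.df["total"] = self.df["finished"] + self.df["failed"]

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    @classmethod
    def bundled(cls) -> "CohortTable":
        """The packaged example cohort: culture success by tumor type."""
        with resources.files("ifscreen.data").joinpath(
            "culture_success_by_tumor_type.csv"
        ).open() as fh:
            return cls(pd.read_csv(fh))

    def row(self, group: str) -> pd.Series:
        hit = self.df[self.df["group"] == group]
        if hit.empty:
            raise KeyError(f"unknown group {group!r}")
        return hit.iloc[0]

    def rates(self, *, rounded: bool = False) -> pd.DataFrame:
        out = self.df.copy()
        out["percent_successful"] = [
            success_rate(f, t, rounded=rounded)
            for f, t in zip(out["finished"], out["total"])
        ]
        return out

    def overall(self, *, rounded: bool = False) -> float:
        """Success rate pooled over all groups."""
        return success_rate(
            int(self.df["finished"].sum()), int(self.df["total"].sum()),
            rounded=rounded,
        )


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    zero_cell: bool


def compare_groups(table: CohortTable, group_a: str, group_b: str) -> ComparisonResult:
    """Two-sided Fisher comparison of the success rates of two groups."""
    ra, rb = table.row(group_a), table.row(group_b)
    res = fisher_exact_2x2(
        int(ra["finished"]), int(ra["failed"]), int(rb["finished"]), int(rb["failed"])
    )
    return ComparisonResult(
        group_a=group_a, group_b=group_b, table=res.table,
        odds_ratio=res.odds_ratio, p_value=res.p_value, zero_cell=res.zero_cell,
    )


def all_pairwise(table: CohortTable) -> list[ComparisonResult]:
    """Fisher comparisons for every unordered pair of groups."""
    groups = list(table.df["group"])
    return [
        compare_groups(table, a, b)
        for i, a in enumerate(groups)
        for b in groups[i + 1:]
    ]
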