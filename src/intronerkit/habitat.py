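"""Habitat association: is Introner presence linked to an aquatic lifestyle?

Species carry two flags — habitat (aquatic / non-aquatic) and whether at
least one Introner family was detected in their genome.  The association is
a 2x2 contingency problem: a two-sided Fisher's exact test (summing all
tables with probability less than or equal to the observed one) plus the
per-habitat percentages and their ratio.  Percentages are rounded half-up to
one decimal and the headline ratio is computed from the rounded percentages;
the unrounded ratio is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or


@dataclass
class HabitatTable:
    """Counts: a=(aquatic, Introner+), b=(aquatic, Introner-),
    c=(non-aquatic, Introner+), d=(non-aquatic, Introner-)."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")
        if (self.a + self.b) == 0 or (self.c + self.d) == 0:
            raise ValueError("both habitat margins must be positive")

    @property
    def matrix(self):
        return [[self.a, self.b], [self.c, self.d]]


def tabulate(species: pd.DataFrame) -> HabitatTable:
    """Exact 2x2 counts from a species metadata table.

    Expects columns species, habitat ("aquatic"/"non-aquatic"), and
    introner_present (bool).  Species with a missing flag are excluded with
    a warning.
    """
    df = species.copy()
    ok = df["habitat"].isin(["aquatic", "non-aquatic"]) & df["introner_present"].notna()
    if (~ok).any():
        warnings.warn(f"excluding {int((~ok).sum())} species with missing flags")
        df = df[ok]
    aq = df["habitat"] == "aquatic"
    has = df["introner_present"].astype(bool)
    return HabitatTable(
        a=int((aq & has).sum()),
        b=int((aq & ~has).sum()),
        c=int((~aq & has).sum()),
        d=int((~aq & ~has).sum()),
    )


def fisher_exact(table: HabitatTable) -> tuple[float, float]:
    """Two-sided Fisher's exact p and the conditional-MLE odds ratio."""
    table.validate()
    if (table.a + table.c) == 0 and (table.b + table.d) == 0:
        raise ValueError("degenerate table")
    _, p = stats.fisher_exact(table.matrix, alternative="two-sided")
    orr = _conditional_or(table.matrix, kind="conditional")
    return float(p), float(orr.statistic)


def _round_percent(x: float) -> float:
    return float(Decimal(str(x * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def proportion_stats(table: HabitatTable, rounding: str = "one_decimal_percent") -> dict:
    """Per-habitat Introner percentages and their ratio.

    The headline ratio divides the rounded percentages (matching how such
    figures are typically quoted); `ratio_unrounded` uses full precision.
    A zero non-aquatic proportion leaves the ratio undefined (flagged None).
    """
    table.validate()
    p_aq = table.a / (table.a + table.b)
    p_na = table.c / (table.c + table.d)
    if rounding == "one_decimal_percent":
        pct_aq, pct_na = _round_percent(p_aq), _round_percent(p_na)
    else:
        pct_aq, pct_na = p_aq * 100, p_na * 100
    ratio = round(pct_aq / pct_na, 1) if pct_na > 0 else None
    return {
        "aquatic_percent": pct_aq,
        "nonaquatic_percent": pct_na,
        "ratio": ratio,
        "ratio_unrounded": (p_aq / p_na) if p_na > 0 else None,
    }


def habitat_report(species: pd.DataFrame) -> dict:
    """Counts, percentages, ratio and Fisher p for a species panel."""
    table = tabulate(species)
    p, orr = fisher_exact(table)
    stats_ = proportion_stats(table)
    return {
        "counts": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "fisher_p": p,
        "odds_ratio": orr,
        **stats_,
    }
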