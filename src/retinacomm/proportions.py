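"""Survival-normalized subclass composition.

Raw subclass percentages from a post-injury sample overstate survivors:
they are fractions of the cells that remain. Multiplying each subclass's
percentage by the sample's total survival rate (measured independently,
e.g. by immunostaining) puts all conditions on the pre-injury scale, so
a subclass's adjusted percentage is comparable across conditions. Sham
samples use a rate of 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class SubclassCounts:
    condition: str
    counts: Mapping[str, int]
    total_survival_rate: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("subclass counts must be nonnegative")
        rate = self.total_survival_rate
        if rate is not None and not (0 < rate <= 1):
            raise ValueError("survival rate must be in (0, 1]")


def normalize_by_survival(c: SubclassCounts) -> pd.Series:
    """Adjusted percentage per subclass:
    adjusted_i = count_i / sum(counts) * survival_rate * 100.

    The adjusted values sum to survival_rate * 100 exactly, and ratios
    between subclasses are untouched.
    """
    total = sum(c.counts.values())
    if total == 0:
        raise ValueError("zero total cell count")
    rate = 1.0 if c.total_survival_rate is None else c.total_survival_rate
    return pd.Series(
        {k: v / total * rate * 100.0 for k, v in c.counts.items()},
        name=c.condition,
    )


def load_subclass_counts(path) -> list[SubclassCounts]:
    """Read (condition, subclass, count, survival_rate) TSV rows."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for cond, grp in df.groupby("condition", sort=True):
        rates = grp["survival_rate"].dropna().unique()
        out.append(
            SubclassCounts(
                condition=str(cond),
                counts=dict(zip(grp["subclass"].astype(str), grp["count"].astype(int))),
                total_survival_rate=float(rates[0]) if len(rates) else None,
            )
        )
    return out
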