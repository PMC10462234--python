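"""Differential interaction statistic between high- and low-survival
receiver subclasses.

For a sender type and a ligand-receptor pair, each receiver subclass
contributes its maximum S_LR over the time course; D_SLR is the mean of
those maxima over the high-survival subclasses minus the mean over the
low-survival ones.  D_SLR > 0.25 calls the interaction *protective*
(stronger toward resilient receivers), D_SLR < -0.25 *depleted*; ties at
the cutoffs are neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, MissingDataError
from .scoring import ScoringParams, filter_pairs

HIGH_SURVIVAL_DEFAULT = ("ipRGC", "alphaRGC", "Gpr88RGC")
LOW_SURVIVAL_DEFAULT = ("T-RGC", "W-RGC", "N-RGC")


@dataclass(frozen=True)
class DifferentialParams:
    cutoff_hi: float = 0.25
    cutoff_lo: float = -0.25
    high_subclasses: tuple = HIGH_SURVIVAL_DEFAULT
    low_subclasses: tuple = LOW_SURVIVAL_DEFAULT

    def __post_init__(self) -> None:
        if self.cutoff_lo >= self.cutoff_hi:
            raise ConfigurationError("cutoff_lo must be below cutoff_hi")
        hi, lo = set(self.high_subclasses), set(self.low_subclasses)
        if not hi or not lo or hi & lo:
            raise ConfigurationError(
                "high/low subclass sets must be non-empty and disjoint"
            )


@dataclass(frozen=True)
class DifferentialRecord:
    sender: str
    ligand: str
    receptor: str
    subclass_max: dict
    mean_high: float
    mean_low: float
    dslr: float
    call: str  # protective | neutral | depleted


def _call(dslr: float, params: DifferentialParams) -> str:
    if dslr > params.cutoff_hi:
        return "protective"
    if dslr < params.cutoff_lo:
        return "depleted"
    return "neutral"


def dslr(
    table: pd.DataFrame,
    sender: str,
    pair: tuple[str, str],
    params: DifferentialParams = DifferentialParams(),
) -> DifferentialRecord:
    """D_SLR for one (sender, pair) from a subclass-resolution score table."""
    ligand, receptor = pair
    sel = table[
        (table["sender"] == sender)
        & (table["ligand"] == ligand)
        & (table["receptor"] == receptor)
    ]
    maxima = {}
    for subclass in (*params.high_subclasses, *params.low_subclasses):
        sub = sel[sel["receiver"] == subclass]
        if sub.empty:
            raise MissingDataError(
                f"no scores for subclass {subclass!r} "
                f"(sender {sender!r}, pair {ligand}-{receptor})"
            )
        maxima[subclass] = float(sub["score"].max())
    mean_high = sum(maxima[s] for s in params.high_subclasses) / len(
        params.high_subclasses
    )
    mean_low = sum(maxima[s] for s in params.low_subclasses) / len(
        params.low_subclasses
    )
    d = mean_high - mean_low
    return DifferentialRecord(
        sender=sender,
        ligand=ligand,
        receptor=receptor,
        subclass_max=maxima,
        mean_high=mean_high,
        mean_low=mean_low,
        dslr=d,
        call=_call(d, params),
    )


def qualify_pairs_for_differential(
    table: pd.DataFrame, scoring_params: ScoringParams = ScoringParams()
) -> pd.DataFrame:
    """Keep (sender, pair) keys passing the expression/score filter toward
    at least one receiver subclass, retaining all subclass rows so the
    subclass means stay evaluable."""
    kept = filter_pairs(table, scoring_params)
    if kept.empty:
        return kept
    keys = set(map(tuple, kept[["sender", "ligand", "receptor"]].drop_duplicates().values))
    mask = [
        tuple(k) in keys
        for k in table[["sender", "ligand", "receptor"]].itertuples(index=False)
    ]
    return table[mask].reset_index(drop=True)


def protective_table(
    table: pd.DataFrame, params: DifferentialParams = DifferentialParams()
) -> pd.DataFrame:
    """One differential record per (sender, pair), sorted by descending
    D_SLR within each sender."""
    records = []
    for sender, ligand, receptor in (
        table[["sender", "ligand", "receptor"]].drop_duplicates().itertuples(index=False)
    ):
        rec = dslr(table, sender, (ligand, receptor), params)
        records.append(
            {
                "sender": rec.sender,
                "ligand": rec.ligand,
                "receptor": rec.receptor,
                "mean_high": rec.mean_high,
                "mean_low": rec.mean_low,
                "dslr": rec.dslr,
                "call": rec.call,
            }
        )
    df = pd.DataFrame(
        records,
        columns=["sender", "ligand", "receptor", "mean_high", "mean_low", "dslr", "call"],
    )
    if df.empty:
        return df
    return df.sort_values(
        ["sender", "dslr", "ligand", "receptor"],
        ascending=[True, False, True, True],
        ignore_index=True,
    )


def aggregate_nonredundant(records: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Deduplicate protective records across senders by (ligand, receptor).

    Each pair keeps its maximum D_SLR; ranking is by that maximum, then by
    the number of supporting senders, then lexicographically; the list is
    truncated to top_n.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    prot = records[records["call"] == "protective"]
    if prot.empty:
        return pd.DataFrame(
            columns=["ligand", "receptor", "senders", "n_senders", "best_dslr"]
        )
    rows = []
    for (ligand, receptor), grp in prot.groupby(["ligand", "receptor"], sort=True):
        senders = sorted(grp["sender"].unique())
        rows.append(
            {
                "ligand": ligand,
                "receptor": receptor,
                "senders": ";".join(senders),
                "n_senders": len(senders),
                "best_dslr": float(grp["dslr"].max()),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["best_dslr", "n_senders", "ligand", "receptor"],
        ascending=[False, False, True, True],
        ignore_index=True,
    )
    return df.head(top_n).reset_index(drop=True)
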