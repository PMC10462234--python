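"""Temporal dynamics of interaction scores.

Covers three questions about a score trajectory over the time course:
does it *vary* (fold change between any two time points above a cutoff),
what temporal *shape* does it follow (hierarchical clustering of z-scored
trajectories into k groups), and — for protective interactions — was the
high-vs-low survival advantage *preset* before injury or *induced* by it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .differential import DifferentialParams
from .errors import MissingDataError

PSEUDOCOUNT = 0.05  # stabilises fold changes between scores on [0, 1]


def trajectories(
    table: pd.DataFrame, timepoints: list[str] | None = None
) -> pd.DataFrame:
    """Pivot a long score table to one row per (sender, receiver, ligand,
    receptor) with ordered time point columns."""
    if timepoints is None:
        timepoints = list(dict.fromkeys(table["timepoint"]))
    wide = table.pivot_table(
        index=["sender", "receiver", "ligand", "receptor"],
        columns="timepoint",
        values="score",
    )[timepoints]
    return wide.dropna()


def variable_interactions(
    trajs: pd.DataFrame, fc_min: float = 1.2, pseudocount: float = PSEUDOCOUNT
) -> pd.DataFrame:
    """Trajectories whose score fold change between some two time points
    exceeds fc_min: max over ordered pairs of
    (s_i + pseudocount) / (s_j + pseudocount) > fc_min (strict)."""
    vals = trajs.to_numpy(dtype=float) + pseudocount
    fc = vals.max(axis=1) / vals.min(axis=1)
    return trajs[fc > fc_min]


def cluster_trajectories(trajs: pd.DataFrame, k: int = 4) -> pd.Series:
    """Group z-scored trajectories by shape.

    Hierarchical agglomeration with correlation distance and average
    linkage, cut at k groups.  Constant trajectories (undefined
    correlation) are treated as maximally dissimilar from everything.
    The resulting partition does not depend on input row order.
    """
    if k < 1 or k > len(trajs):
        raise ValueError(f"k={k} must be in [1, {len(trajs)}]")
    if k == 1:
        return pd.Series(1, index=trajs.index, name="group")
    x = trajs.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.divide(x - mu, sd, out=np.zeros_like(x), where=sd > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = ssd.pdist(z, metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)
    labels = sch.fcluster(sch.linkage(dist, method="average"), k, criterion="maxclust")
    return pd.Series(labels, index=trajs.index, name="group")


def _group_diff(
    table: pd.DataFrame,
    sender: str,
    pair: tuple[str, str],
    params: DifferentialParams,
    timepoints: list[str],
    reduce_max: bool,
) -> float:
    """mean_high - mean_low of subclass scores over the given time points
    (per-subclass max when reduce_max, else the single time point)."""
    ligand, receptor = pair
    sel = table[
        (table["sender"] == sender)
        & (table["ligand"] == ligand)
        & (table["receptor"] == receptor)
        & (table["timepoint"].isin(timepoints))
    ]
    vals = {}
    for subclass in (*params.high_subclasses, *params.low_subclasses):
        sub = sel[sel["receiver"] == subclass]
        if sub.empty:
            raise MissingDataError(
                f"no scores for subclass {subclass!r} at {timepoints}"
            )
        vals[subclass] = float(sub["score"].max() if reduce_max else sub["score"].iloc[0])
    high = np.mean([vals[s] for s in params.high_subclasses])
    low = np.mean([vals[s] for s in params.low_subclasses])
    return float(high - low)


def preset_induced(
    table: pd.DataFrame,
    pair: tuple[str, str],
    sender: str,
    params: DifferentialParams = DifferentialParams(),
    delta: float = 0.25,
    pre_timepoint: str = "sham",
    post_timepoints: tuple = ("12h", "24h", "48h"),
) -> dict:
    """Classify a protective interaction's dynamics.

    pre_diff = high-low difference at the uninjured time point; post_diff
    = high-low difference of per-subclass maxima over post-injury time
    points.  preset when already above delta before injury; induced when
    it only crosses delta after; neither otherwise.
    """
    if not (table["timepoint"] == pre_timepoint).any():
        raise MissingDataError(f"no scores at pre-injury timepoint {pre_timepoint!r}")
    pre = _group_diff(table, sender, pair, params, [pre_timepoint], reduce_max=False)
    post = _group_diff(table, sender, pair, params, list(post_timepoints), reduce_max=True)
    if pre > delta:
        call = "preset"
    elif post > delta:
        call = "induced"
    else:
        call = "neither"
    return {"pre_diff": pre, "post_diff": post, "call": call}
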