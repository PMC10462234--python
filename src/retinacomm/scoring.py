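"""Ligand-receptor interaction scoring across cell groups and time points.

The interaction score S_LR for one pair between one sender group and one
receiver group at one time point combines three pieces of information:

1. Expression: the base score s0 is the geometric mean of the ligand's
   normalized mean expression in the sender and the receptor's in the
   receiver, each min-max scaled to [0, 1] per gene across all
   (group, time point) means in the dataset.  s0 is therefore a relative
   strength: 1 means both ends sit at their dataset-wide maximum.
2. Network context: cell-type-specific active subgraphs of the signaling/
   regulatory network (see :mod:`retinacomm.networks`) gate which
   feedback loops are considered.
3. Loops: when back pairs close a sender<->receiver feedback loop, the
   strongest back interaction raises the score multiplicatively,
   S_LR = min(1, s0 * (1 + beta * max(back scores))).

Candidate pairs are then filtered on two criteria: ligand and receptor
each detected in >= 10% of their group's cells, and S_LR >= 0.5 at at
least one time point (boundary inclusive).  The overall strength between
two groups is the sum of S_LR over surviving pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, UndefinedScoreError
from .io_qc import normalize_expression
from .networks import LRDatabase, active_subgraph, find_feedback_loops

GROUP_KEY = "comm_group"

SCORE_COLUMNS = [
    "sender", "receiver", "ligand", "receptor", "timepoint",
    "s0", "score", "det_ligand", "det_receptor", "n_sender", "n_receiver",
    "low_confidence",
]


@dataclass(frozen=True)
class ScoringParams:
    detect_min: float = 0.10     # min detection rate at both ends
    score_min: float = 0.5       # min of max-over-timepoints S_LR
    loop_bonus: float = 0.5      # beta, multiplicative loop reward
    loop_combine: str = "max"    # how multiple loops per pair combine
    max_path_len: int = 4        # receptor -> ... -> back-ligand path bound
    min_cells_confident: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.detect_min <= 1 and 0 <= self.score_min <= 1):
            raise ConfigurationError("detect_min and score_min must be in [0, 1]")
        if self.loop_bonus < 0:
            raise ConfigurationError("loop_bonus must be nonnegative")
        if self.loop_combine not in ("max", "sum"):
            raise ConfigurationError("loop_combine must be 'max' or 'sum'")


def annotate_groups(adata: ad.AnnData, key: str = GROUP_KEY) -> ad.AnnData:
    """Scoring group label: the RGC subclass where present, else the cell
    type — so receivers are scored at subclass resolution."""
    sub = adata.obs.get("subclass")
    ct = adata.obs["cell_type"].astype(str)
    if sub is None:
        adata.obs[key] = ct
    else:
        sub = sub.astype(str).replace({"nan": "", "None": ""})
        adata.obs[key] = np.where(sub != "", sub, ct)
    return adata


class GroupProfiles:
    """Per-(group, timepoint) mean normalized expression and detection.

    ``means``/``detection`` are DataFrames indexed by gene with a
    (group, timepoint) column MultiIndex; ``scaled`` is ``means`` min-max
    scaled per gene across all columns (constant genes scale to 0).
    """

    def __init__(self, adata: ad.AnnData, group_key: str = GROUP_KEY,
                 timepoint_key: str = "timepoint"):
        if group_key not in adata.obs:
            annotate_groups(adata, group_key)
        if "norm" not in adata.layers:
            normalize_expression(adata)
        norm = sp.csr_matrix(adata.layers["norm"])
        raw = sp.csr_matrix(adata.X)
        keys = list(
            zip(adata.obs[group_key].astype(str), adata.obs[timepoint_key].astype(str))
        )
        cols, means, dets, sizes = [], [], [], []
        for key in sorted(set(keys)):
            idx = np.array([i for i, k in enumerate(keys) if k == key])
            cols.append(key)
            means.append(np.asarray(norm[idx].mean(axis=0)).ravel())
            dets.append(raw[idx].getnnz(axis=0) / len(idx))
            sizes.append(len(idx))
        columns = pd.MultiIndex.from_tuples(cols, names=["group", "timepoint"])
        self.means = pd.DataFrame(
            np.column_stack(means), index=adata.var_names, columns=columns
        )
        self.detection = pd.DataFrame(
            np.column_stack(dets), index=adata.var_names, columns=columns
        )
        self.n_cells = pd.Series(sizes, index=columns)
        lo = self.means.min(axis=1)
        rng = self.means.max(axis=1) - lo
        scaled = self.means.sub(lo, axis=0).div(rng.where(rng > 0), axis=0)
        self.scaled = scaled.fillna(0.0)

    def require(self, group: str, timepoint: str) -> None:
        if (group, timepoint) not in self.means.columns:
            raise UndefinedScoreError(f"no cells for group {group!r} at {timepoint!r}")


def base_score(
    profiles: GroupProfiles,
    pair: tuple[str, str],
    sender: str,
    receiver: str,
    timepoint: str,
) -> float:
    """s0 = sqrt(scaled ligand mean in sender * scaled receptor mean in
    receiver) at one time point."""
    ligand, receptor = pair
    profiles.require(sender, timepoint)
    profiles.require(receiver, timepoint)
    l = profiles.scaled.at[ligand, (sender, timepoint)]
    r = profiles.scaled.at[receptor, (receiver, timepoint)]
    return float(np.sqrt(l * r))


def loop_adjusted_score(
    s0: float, back_scores: Sequence[float], beta: float = 0.5,
    combine: str = "max",
) -> float:
    """S_LR = min(1, s0 * (1 + beta * combine(back scores)))."""
    if back_scores:
        bonus = max(back_scores) if combine == "max" else sum(back_scores)
    else:
        bonus = 0.0
    return float(min(1.0, s0 * (1.0 + beta * bonus)))


def score_interactions(
    adata: ad.AnnData,
    lr: LRDatabase,
    senders: Sequence[str],
    receivers: Sequence[str],
    params: ScoringParams = ScoringParams(),
    graph: nx.DiGraph | None = None,
    group_key: str = GROUP_KEY,
    timepoints: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score every (sender, receiver, pair, timepoint) as a long table.

    When a signaling graph is given, feedback loops are searched per
    (sender, receiver, forward pair) on cell-type-specific active
    subgraphs, and back-pair base scores (receiver acting as sender)
    feed the loop adjustment; otherwise S_LR = s0.
    """
    annotate_groups(adata, group_key)
    profiles = GroupProfiles(adata, group_key=group_key)
    if timepoints is None:
        timepoints = list(dict.fromkeys(adata.obs["timepoint"].astype(str)))
    pairs = [
        (l, r)
        for l, r in lr.pairs
        if l in profiles.means.index and r in profiles.means.index
    ]

    subgraphs: dict[str, nx.DiGraph] = {}
    detected: dict[str, set] = {}
    if graph is not None:
        from .networks import detection_rates

        for g in set(senders) | set(receivers):
            mask = (adata.obs[group_key] == g).to_numpy()
            subgraphs[g] = active_subgraph(
                graph, adata, g, params.detect_min, group_key=group_key
            )
            det = detection_rates(adata, np.where(mask)[0])
            detected[g] = set(det.index[det >= params.detect_min])

    rows = []
    for sender in senders:
        for receiver in receivers:
            loop_cache: dict[tuple[str, str], list] = {}
            for ligand, receptor in pairs:
                loops = []
                if graph is not None:
                    key = (ligand, receptor)
                    if key not in loop_cache:
                        loop_cache[key] = find_feedback_loops(
                            (ligand, receptor, sender, receiver),
                            lr,
                            subgraphs[sender],
                            subgraphs[receiver],
                            max_path_len=params.max_path_len,
                            sender_detected=detected[sender],
                        )
                    loops = loop_cache[key]
                for tp in timepoints:
                    s0 = base_score(profiles, (ligand, receptor), sender, receiver, tp)
                    back = [
                        base_score(
                            profiles, (lp.back_ligand, lp.back_receptor),
                            receiver, sender, tp,
                        )
                        for lp in loops
                        if lp.back_ligand in profiles.means.index
                        and lp.back_receptor in profiles.means.index
                    ]
                    score = loop_adjusted_score(
                        s0, back, params.loop_bonus, params.loop_combine
                    )
                    n_s = int(profiles.n_cells[(sender, tp)])
                    n_r = int(profiles.n_cells[(receiver, tp)])
                    rows.append(
                        {
                            "sender": sender,
                            "receiver": receiver,
                            "ligand": ligand,
                            "receptor": receptor,
                            "timepoint": tp,
                            "s0": s0,
                            "score": score,
                            "det_ligand": profiles.detection.at[ligand, (sender, tp)],
                            "det_receptor": profiles.detection.at[
                                receptor, (receiver, tp)
                            ],
                            "n_sender": n_s,
                            "n_receiver": n_r,
                            "low_confidence": min(n_s, n_r)
                            < params.min_cells_confident,
                        }
                    )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


PAIR_KEY = ["sender", "receiver", "ligand", "receptor"]


def filter_pairs(
    table: pd.DataFrame, params: ScoringParams = ScoringParams()
) -> pd.DataFrame:
    """Two filter criteria per (sender, receiver, pair):

    both ends detected in >= detect_min of their cells at some time point,
    and max-over-timepoints S_LR >= score_min ("no less than", so the
    boundary is kept).  All time points of surviving keys are retained.
    """
    if table.empty:
        return table.copy()
    g = table.groupby(PAIR_KEY, sort=False)
    ok = (
        (g["det_ligand"].transform("max") >= params.detect_min)
        & (g["det_receptor"].transform("max") >= params.detect_min)
        & (g["score"].transform("max") >= params.score_min)
    )
    return table[ok].reset_index(drop=True)


def overall_score(
    table: pd.DataFrame, sender: str, receiver: str, timepoint: str
) -> float:
    """Sum of S_LR over (already filtered) pairs for one group pair and
    time point."""
    sel = table[
        (table["sender"] == sender)
        & (table["receiver"] == receiver)
        & (table["timepoint"] == timepoint)
    ]
    return float(sel["score"].sum())
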