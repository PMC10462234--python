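"""Ligand-receptor databases, signaling graphs, and feedback-loop search.

A feedback loop arises when a forward ligand-receptor pair (sender ->
receiver) triggers, through the receiver's intracellular signaling and
regulatory network, the transcription of a *back* ligand whose receptor
is present on the original sender — so the receiver answers the sender.
Loop search is a bounded directed-path query: the back pair (L2, R2)
qualifies when a path R1 -> ... -> L2 of length <= max_path_len exists in
the receiver's active subgraph and R2 is detected in the sender.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Iterable

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FormatError

EDGE_KINDS = ("signaling", "regulatory")


@dataclass(frozen=True)
class LRDatabase:
    """Deduplicated, order-preserving list of (ligand, receptor) pairs."""

    pairs: tuple

    def __post_init__(self) -> None:
        for l, r in self.pairs:
            if not l or not r:
                raise FormatError("empty gene label in ligand-receptor pair")
        if len(set(self.pairs)) != len(self.pairs):
            raise FormatError("duplicate ligand-receptor pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LRDatabase":
        if not {"ligand", "receptor"} <= set(df.columns):
            raise FormatError("ligand-receptor table needs ligand and receptor columns")
        seen, pairs = set(), []
        for l, r in zip(df["ligand"].astype(str), df["receptor"].astype(str)):
            if (l, r) not in seen:
                seen.add((l, r))
                pairs.append((l, r))
        return cls(pairs=tuple(pairs))


def load_lr_database(path) -> LRDatabase:
    """Read a ligand/receptor TSV; duplicate rows collapse to one pair."""
    df = pd.read_csv(path, sep="\t")
    return LRDatabase.from_frame(df)


def load_signaling_graph(path) -> nx.DiGraph:
    """Read a directed network TSV (source, target, kind) as a DiGraph.

    Edge kinds are restricted to "signaling" and "regulatory"; self-loops
    are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"source", "target"} <= set(df.columns):
        raise FormatError("network table needs source and target columns")
    if "kind" not in df.columns:
        df = df.assign(kind="signaling")
    return build_signaling_graph(
        zip(df["source"].astype(str), df["target"].astype(str), df["kind"].astype(str))
    )


def build_signaling_graph(edges: Iterable[tuple[str, str, str]]) -> nx.DiGraph:
    g = nx.DiGraph()
    for src, dst, kind in edges:
        if src == dst:
            raise FormatError(f"self-loop on {src!r}")
        if kind not in EDGE_KINDS:
            raise FormatError(f"edge kind {kind!r} not in {EDGE_KINDS}")
        g.add_edge(src, dst, kind=kind)
    return g


def detection_rates(
    adata: ad.AnnData, cells: np.ndarray | None = None
) -> pd.Series:
    """Fraction of (selected) cells with a nonzero count, per gene."""
    X = sp.csr_matrix(adata.X)
    if cells is not None:
        X = X[cells]
    if X.shape[0] == 0:
        return pd.Series(0.0, index=adata.var_names)
    frac = X.getnnz(axis=0) / X.shape[0]
    return pd.Series(frac, index=adata.var_names)


def active_subgraph(
    g: nx.DiGraph,
    adata: ad.AnnData,
    cell_type: str,
    detect_min: float = 0.10,
    group_key: str = "cell_type",
) -> nx.DiGraph:
    """Cell-type-specific subgraph: keep edges whose both endpoint genes
    reach detection rate >= detect_min in that type's cells."""
    mask = (adata.obs[group_key] == cell_type).to_numpy()
    if not mask.any():
        raise LookupError(f"no cells with {group_key} == {cell_type!r}")
    det = detection_rates(adata, np.where(mask)[0])
    sub = nx.DiGraph()
    for src, dst, attrs in g.edges(data=True):
        if det.get(src, 0.0) >= detect_min and det.get(dst, 0.0) >= detect_min:
            sub.add_edge(src, dst, **attrs)
    return sub


@dataclass(frozen=True)
class FeedbackLoop:
    ligand: str
    receptor: str
    sender: str
    receiver: str
    back_ligand: str
    back_receptor: str
    path_receiver: tuple  # witness gene path receptor -> ... -> back ligand
    path_sender: tuple = ()  # optional return path back_receptor -> ... -> ligand


def _witness_path(g: nx.DiGraph, src: str, dst: str, cutoff: int):
    """Shortest directed path src->dst of length <= cutoff; ties break
    lexicographically. None when no such path exists."""
    if src not in g or dst not in g:
        return None
    try:
        length = nx.shortest_path_length(g, src, dst)
    except nx.NetworkXNoPath:
        return None
    if length > cutoff or length == 0:
        return None
    best = min(tuple(p) for p in nx.all_shortest_paths(g, src, dst))
    return best


def find_feedback_loops(
    forward: tuple[str, str, str, str],
    lr: LRDatabase,
    g_sender: nx.DiGraph,
    g_receiver: nx.DiGraph,
    max_path_len: int = 4,
    sender_detected: Collection[str] | None = None,
) -> list[FeedbackLoop]:
    """Enumerate back pairs closing a loop on a forward interaction.

    ``forward`` is (ligand, receptor, sender, receiver).  A pair (L2, R2)
    from ``lr`` closes the loop when a directed path receptor -> L2 of
    length <= max_path_len exists in g_receiver and R2 is detected in the
    sender (membership in ``sender_detected`` if given, else in
    g_sender's node set).  A sender-side return path R2 -> ligand is
    recorded when present but never required.  Results are sorted by
    (back ligand, back receptor), so edge insertion order is irrelevant.
    """
    l1, r1, sender, receiver = forward
    if (l1, r1) not in set(lr.pairs):
        raise LookupError(f"forward pair ({l1}, {r1}) not in the LR database")
    detected = set(sender_detected) if sender_detected is not None else set(g_sender)
    loops = []
    for l2, r2 in sorted(set(lr.pairs)):
        if r2 not in detected:
            continue
        path = _witness_path(g_receiver, r1, l2, max_path_len)
        if path is None:
            continue
        back = _witness_path(g_sender, r2, l1, max_path_len)
        loops.append(
            FeedbackLoop(
                ligand=l1,
                receptor=r1,
                sender=sender,
                receiver=receiver,
                back_ligand=l2,
                back_receptor=r2,
                path_receiver=path,
                path_sender=back or (),
            )
        )
    return loops
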