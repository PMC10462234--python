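"""LR database parsing, active subgraphs, and loop search vs brute force."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import retinacomm as rc
from retinacomm.networks import LRDatabase, build_signaling_graph, find_feedback_loops

from conftest import make_adata


class TestLRDatabase:
    def test_duplicate_rows_collapse(self, tmp_path):
        p = tmp_path / "lr.tsv"
        p.write_text("ligand\treceptor\nBdnf\tNtrk2\nBdnf\tNtrk2\n")
        db = rc.load_lr_database(p)
        assert db.pairs == (("Bdnf", "Ntrk2"),)

    def test_order_preserved(self, tmp_path):
        rows = [(f"l{i}", f"r{i}") for i in range(5)]
        p = tmp_path / "lr.tsv"
        p.write_text(
            "ligand\treceptor\n" + "\n".join(f"{l}\t{r}" for l, r in rows) + "\n"
        )
        assert rc.load_lr_database(p).pairs == tuple(rows)

    def test_empty_file_gives_empty_scores(self, tmp_path, small_atlas):
        p = tmp_path / "lr.tsv"
        p.write_text("ligand\treceptor\n")
        db = rc.load_lr_database(p)
        _, atlas, _ = small_atlas
        adata = atlas[:500].copy()
        table = rc.score_interactions(adata, db, ["Astrocyte"], ["ipRGC"])
        assert table.empty

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "lr.tsv"
        p.write_text("from\tto\na\tb\n")
        with pytest.raises(rc.FormatError):
            rc.load_lr_database(p)


class TestSignalingGraph:
    def test_self_loop_rejected(self):
        with pytest.raises(rc.FormatError):
            build_signaling_graph([("a", "a", "signaling")])

    def test_unknown_kind_rejected(self):
        with pytest.raises(rc.FormatError):
            build_signaling_graph([("a", "b", "metabolic")])


class TestActiveSubgraph:
    def _fixture(self):
        # 6 genes, 4 cells of one type; detection = 1, 1, .5, .5, .25, 0
        counts = np.array(
            [
                [1, 2, 1, 0, 1, 0],
                [1, 1, 0, 1, 0, 0],
                [2, 1, 1, 0, 0, 0],
                [1, 3, 0, 1, 0, 0],
            ]
        )
        adata = make_adata(counts, genes=list("abcdef"),
                           obs={"cell_type": ["T"] * 4})
        g = build_signaling_graph(
            [
                ("a", "b", "signaling"),
                ("b", "c", "signaling"),
                ("c", "e", "regulatory"),
                ("e", "f", "regulatory"),
                ("d", "a", "signaling"),
            ]
        )
        return adata, g

    def test_detect_min_zero_keeps_everything(self):
        adata, g = self._fixture()
        sub = rc.active_subgraph(g, adata, "T", detect_min=0.0)
        assert set(sub.edges) == set(g.edges)

    def test_unexpressed_endpoint_removes_edge(self):
        adata, g = self._fixture()
        sub = rc.active_subgraph(g, adata, "T", detect_min=0.1)
        assert ("e", "f") not in sub.edges  # f never expressed

    def test_matches_per_edge_oracle(self):
        adata, g = self._fixture()
        det = {"a": 1, "b": 1, "c": 0.5, "d": 0.5, "e": 0.25, "f": 0.0}
        for dmin in (0.0, 0.25, 0.5, 0.75, 1.0):
            sub = rc.active_subgraph(g, adata, "T", detect_min=dmin)
            expected = {
                (u, v) for u, v in g.edges if det[u] >= dmin and det[v] >= dmin
            }
            assert set(sub.edges) == expected

    def test_monotone_in_detect_min(self):
        adata, g = self._fixture()
        prev = None
        for dmin in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            edges = set(rc.active_subgraph(g, adata, "T", detect_min=dmin).edges)
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_unknown_type_raises(self):
        adata, g = self._fixture()
        with pytest.raises(LookupError):
            rc.active_subgraph(g, adata, "NoSuchType")


def brute_force_loops(forward, lr, g_sender, g_receiver, max_path_len, detected):
    """Oracle: enumerate all simple paths R1 -> L2 up to max_path_len."""
    _, r1, _, _ = forward
    found = set()
    for l2, r2 in lr.pairs:
        if r2 not in detected:
            continue
        if r1 not in g_receiver or l2 not in g_receiver or r1 == l2:
            continue
        for path in nx.all_simple_paths(g_receiver, r1, l2, cutoff=max_path_len):
            found.add((l2, r2))
            break
    return found


class TestFeedbackLoops:
    def test_empty_receiver_graph_no_loops(self):
        lr = LRDatabase(pairs=(("L1", "R1"), ("L2", "R2")))
        loops = find_feedback_loops(
            ("L1", "R1", "s", "r"), lr, nx.DiGraph([("R2", "x")]), nx.DiGraph()
        )
        assert loops == []

    def test_bdnf_ntrk2_vegfa_flt1_relay(self):
        """A distress pair whose receptor drives a growth-factor ligand in
        the receiver, answered through a receptor on the sender."""
        lr = LRDatabase(pairs=(("Bdnf", "Ntrk2"), ("Vegfa", "Flt1")))
        g_receiver = build_signaling_graph(
            [("Ntrk2", "TFx", "signaling"), ("TFx", "Vegfa", "regulatory")]
        )
        g_sender = nx.DiGraph()
        loops = find_feedback_loops(
            ("Bdnf", "Ntrk2", "RGC", "MullerGlia"),
            lr,
            g_sender,
            g_receiver,
            sender_detected={"Flt1"},
        )
        assert len(loops) == 1
        assert (loops[0].back_ligand, loops[0].back_receptor) == ("Vegfa", "Flt1")
        assert loops[0].path_receiver == ("Ntrk2", "TFx", "Vegfa")

    def test_forward_pair_must_be_in_database(self):
        lr = LRDatabase(pairs=(("L1", "R1"),))
        with pytest.raises(LookupError):
            find_feedback_loops(("X", "Y", "s", "r"), lr, nx.DiGraph(), nx.DiGraph())

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_exhaustive_enumeration_on_random_graphs(self, trial):
        rng = np.random.default_rng(trial)
        nodes = [f"n{i}" for i in range(8)]
        edges = [
            (u, v, "signaling")
            for u, v in itertools.permutations(nodes, 2)
            if rng.random() < 0.18
        ]
        g_receiver = build_signaling_graph(edges) if edges else nx.DiGraph()
        pair_pool = list(itertools.permutations(nodes, 2))
        lr_pairs = tuple(
            pair_pool[i]
            for i in rng.choice(len(pair_pool), size=6, replace=False)
        )
        lr = LRDatabase(pairs=lr_pairs)
        forward = lr_pairs[0] + ("s", "r")
        detected = {n for n in nodes if rng.random() < 0.7}
        loops = find_feedback_loops(
            forward, lr, nx.DiGraph(), g_receiver,
            max_path_len=4, sender_detected=detected,
        )
        got = {(l.back_ligand, l.back_receptor) for l in loops}
        expected = brute_force_loops(forward, lr, None, g_receiver, 4, detected)
        assert got == expected
        for l in loops:  # witness paths are real and bounded
            assert 2 <= len(l.path_receiver) <= 5
            assert all(
                g_receiver.has_edge(a, b)
                for a, b in zip(l.path_receiver, l.path_receiver[1:])
            )

    def test_loop_set_invariant_to_edge_insertion_order(self):
        edges = [
            ("R1", "t1", "signaling"),
            ("t1", "L2", "regulatory"),
            ("R1", "t2", "signaling"),
            ("t2", "L3", "regulatory"),
        ]
        lr = LRDatabase(pairs=(("L1", "R1"), ("L2", "R2"), ("L3", "R3")))
        a = find_feedback_loops(
            ("L1", "R1", "s", "r"), lr, nx.DiGraph(), build_signaling_graph(edges),
            sender_detected={"R2", "R3"},
        )
        b = find_feedback_loops(
            ("L1", "R1", "s", "r"), lr, nx.DiGraph(),
            build_signaling_graph(edges[::-1]), sender_detected={"R2", "R3"},
        )
        assert a == b
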