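"""D_SLR arithmetic, protective calls, and non-redundant aggregation."""

import numpy as np
import pandas as pd
import pytest

import retinacomm as rc
from retinacomm.differential import (
    DifferentialParams,
    aggregate_nonredundant,
    dslr,
    protective_table,
)

PARAMS = DifferentialParams(
    high_subclasses=("h1", "h2"), low_subclasses=("l1", "l2")
)


def table_from_maxima(maxima, sender="s", ligand="L", receptor="R"):
    """Score table whose per-subclass max-over-time equals `maxima`;
    earlier timepoints carry a lower dummy score."""
    rows = []
    for subclass, peak in maxima.items():
        for tp, v in (("t0", peak / 2), ("t1", peak)):
            rows.append([sender, subclass, ligand, receptor, tp, v])
    return pd.DataFrame(
        rows, columns=["sender", "receiver", "ligand", "receptor",
                       "timepoint", "score"],
    )


class TestDslr:
    def test_hand_arithmetic(self):
        """high maxima {0.9, 0.7} vs low {0.2, 0.4} -> 0.8 - 0.3 = 0.5."""
        table = table_from_maxima({"h1": 0.9, "h2": 0.7, "l1": 0.2, "l2": 0.4})
        rec = dslr(table, "s", ("L", "R"), PARAMS)
        assert rec.mean_high == pytest.approx(0.8)
        assert rec.mean_low == pytest.approx(0.3)
        assert rec.dslr == pytest.approx(0.5)
        assert rec.call == "protective"

    def test_identical_trajectories_are_neutral(self):
        table = table_from_maxima({s: 0.6 for s in ("h1", "h2", "l1", "l2")})
        rec = dslr(table, "s", ("L", "R"), PARAMS)
        assert rec.dslr == pytest.approx(0.0)
        assert rec.call == "neutral"

    def test_swap_flips_sign_exactly(self):
        table = table_from_maxima({"h1": 0.9, "h2": 0.7, "l1": 0.2, "l2": 0.4})
        fwd = dslr(table, "s", ("L", "R"), PARAMS)
        swapped = DifferentialParams(
            high_subclasses=("l1", "l2"), low_subclasses=("h1", "h2")
        )
        rev = dslr(table, "s", ("L", "R"), swapped)
        assert rev.dslr == pytest.approx(-fwd.dslr)
        assert rev.call == "depleted"

    def test_tie_at_cutoff_is_neutral(self):
        table = table_from_maxima({"h1": 0.5, "h2": 0.5, "l1": 0.25, "l2": 0.25})
        rec = dslr(table, "s", ("L", "R"), PARAMS)
        assert rec.dslr == pytest.approx(0.25)
        assert rec.call == "neutral"

    def test_missing_subclass_raises(self):
        table = table_from_maxima({"h1": 0.9, "h2": 0.7, "l1": 0.2})
        with pytest.raises(rc.MissingDataError):
            dslr(table, "s", ("L", "R"), PARAMS)


class TestProtectiveTable:
    def test_all_zero_scores_all_neutral(self):
        frames = [
            table_from_maxima({s: 0.0 for s in ("h1", "h2", "l1", "l2")},
                              ligand=f"L{i}", receptor=f"R{i}")
            for i in range(3)
        ]
        out = protective_table(pd.concat(frames, ignore_index=True), PARAMS)
        assert (out["call"] == "neutral").all()

    def test_raising_cutoff_never_adds_calls(self):
        rng = np.random.default_rng(7)
        frames = []
        for i in range(30):
            maxima = {s: rng.random() for s in ("h1", "h2", "l1", "l2")}
            frames.append(
                table_from_maxima(maxima, ligand=f"L{i}", receptor=f"R{i}")
            )
        table = pd.concat(frames, ignore_index=True)
        calls = []
        for hi in (0.1, 0.25, 0.4):
            p = DifferentialParams(cutoff_hi=hi, cutoff_lo=-0.5,
                                   high_subclasses=("h1", "h2"),
                                   low_subclasses=("l1", "l2"))
            out = protective_table(table, p)
            calls.append(set(out[out["call"] == "protective"]["ligand"]))
        assert calls[2] <= calls[1] <= calls[0]

    def test_sorted_by_dslr_within_sender(self):
        frames = [
            table_from_maxima({"h1": v, "h2": v, "l1": 0.0, "l2": 0.0},
                              ligand=f"L{i}", receptor=f"R{i}")
            for i, v in enumerate((0.3, 0.9, 0.6))
        ]
        out = protective_table(pd.concat(frames, ignore_index=True), PARAMS)
        assert list(out["dslr"]) == sorted(out["dslr"], reverse=True)


class TestAggregateNonredundant:
    def records(self):
        return pd.DataFrame(
            [
                ["s1", "L1", "R1", 0.8, 0.1, 0.7, "protective"],
                ["s2", "L1", "R1", 0.6, 0.2, 0.4, "protective"],
                ["s3", "L1", "R1", 0.7, 0.3, 0.4, "protective"],
                ["s1", "L2", "R2", 0.6, 0.1, 0.5, "protective"],
                ["s2", "L3", "R3", 0.9, 0.2, 0.7, "protective"],
                ["s1", "L4", "R4", 0.3, 0.2, 0.1, "neutral"],
            ],
            columns=["sender", "ligand", "receptor", "mean_high", "mean_low",
                     "dslr", "call"],
        )

    def test_dedup_lists_supporting_senders(self):
        out = aggregate_nonredundant(self.records(), top_n=10)
        row = out[out["ligand"] == "L1"].iloc[0]
        assert row["n_senders"] == 3
        assert row["senders"] == "s1;s2;s3"
        assert row["best_dslr"] == pytest.approx(0.7)

    def test_top_n_truncates_and_large_n_returns_all(self):
        assert len(aggregate_nonredundant(self.records(), top_n=2)) == 2
        assert len(aggregate_nonredundant(self.records(), top_n=99)) == 3

    def test_order_matches_independent_sort(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(10):
            rows.append([f"s{i % 3}", f"L{i}", f"R{i}", 0.9, 0.1,
                         round(rng.random(), 3), "protective"])
        recs = pd.DataFrame(
            rows, columns=["sender", "ligand", "receptor", "mean_high",
                           "mean_low", "dslr", "call"],
        )
        out = aggregate_nonredundant(recs, top_n=10)
        expected = sorted(
            ((r[5], 1, r[1]) for r in rows), key=lambda t: (-t[0], -t[1], t[2])
        )
        assert list(out["ligand"]) == [e[2] for e in expected]

    def test_nonpositive_top_n_rejected(self):
        with pytest.raises(ValueError):
            aggregate_nonredundant(self.records(), top_n=0)


class TestPlantedRecovery:
    def test_planted_pairs_called_protective(self, scored_atlas):
        """All planted high-target pairs recovered; decoy false positives
        rare; no excess depleted calls when nothing targets low."""
        _, truth, table = scored_atlas
        q = rc.qualify_pairs_for_differential(table)
        diff = protective_table(q)
        prot = diff[diff["call"] == "protective"]
        hits = {(r.sender, r.ligand, r.receptor) for r in prot.itertuples()}
        planted = {
            (p["sender"], p["ligand"], p["receptor"])
            for p in truth["planted_pairs"]
        }
        assert planted <= hits
        decoys = set(map(tuple, truth["decoy_pairs"]))
        fp = sum((r.ligand, r.receptor) in decoys for r in prot.itertuples())
        assert fp <= 0.05 * 8 * len(decoys)

    def test_low_target_planting_is_called_depleted(self):
        cfg = rc.default_config(seed=21, n_planted=2, effect_size=4.0,
                                target="low")
        adata, truth = rc.generate_atlas(cfg)
        rc.compute_qc_metrics(adata)
        adata = rc.qc_filter(adata, rc.QC_PRESETS["whole_retina"])
        lr = rc.LRDatabase.from_frame(rc.lr_table(truth))
        table = rc.score_interactions(
            adata, lr, list(cfg.sender_types),
            [n for n, _ in cfg.receiver_subclasses],
        )
        q = rc.qualify_pairs_for_differential(table)
        diff = protective_table(q)
        for p in truth["planted_pairs"]:
            row = diff[(diff["sender"] == p["sender"])
                       & (diff["ligand"] == p["ligand"])]
            assert row["call"].iloc[0] == "depleted"
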