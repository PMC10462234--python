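"""End-to-end pipeline: QC -> scoring -> filtering -> differential ->
dynamics -> aggregation, with a reproducibility manifest.

A run is described by one :class:`PipelineConfig` (constructable from a
YAML/JSON document).  Inputs are either files (counts + metadata + LR
table + optional network) or the built-in synthetic atlas when no counts
path is given.  Every stage writes a TSV into the output directory; the
manifest records parameters, the seed, per-stage row counts and sha256
hashes of every output, so identical configs yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic
from .differential import (
    DifferentialParams,
    aggregate_nonredundant,
    protective_table,
    qualify_pairs_for_differential,
)
from .dynamics import preset_induced, trajectories, variable_interactions
from .errors import ConfigurationError
from .io_qc import (
    QC_PRESETS,
    QCThresholds,
    compute_qc_metrics,
    gene_filter,
    load_counts,
    qc_filter,
)
from .networks import LRDatabase, build_signaling_graph, load_lr_database, load_signaling_graph
from .scoring import ScoringParams, annotate_groups, score_interactions

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    counts_path: str | None = None  # None -> generate the synthetic atlas
    meta_path: str | None = None
    lr_path: str | None = None
    network_path: str | None = None
    qc_preset: str = "whole_retina"
    min_cells_per_gene: int = 5
    scoring: ScoringParams = field(default_factory=ScoringParams)
    differential: DifferentialParams = field(default_factory=DifferentialParams)
    delta: float = 0.25
    fc_min: float = 1.2
    top_n: int = 47
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        scoring = ScoringParams(**doc.pop("scoring", {}))
        diff = doc.pop("differential", {})
        for k in ("high_subclasses", "low_subclasses"):
            if k in diff:
                diff[k] = tuple(diff[k])
        return cls(scoring=scoring, differential=DifferentialParams(**diff), **doc)

    def validate(self) -> None:
        if self.qc_preset not in QC_PRESETS:
            raise ConfigurationError(f"unknown qc_preset {self.qc_preset!r}")
        if self.counts_path is not None:
            if self.lr_path is None:
                raise ConfigurationError(
                    "lr_path is required when counts_path is given"
                )
            for name in ("counts_path", "meta_path", "lr_path", "network_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"{name} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = {}

    if config.counts_path is None:
        cfg = synthetic.default_config(seed=config.seed, with_loops=True)
        adata, truth = synthetic.generate_atlas(cfg)
        lr = LRDatabase.from_frame(synthetic.lr_table(truth))
        graph = (
            build_signaling_graph(truth["network_edges"])
            if truth["network_edges"]
            else None
        )
    else:
        adata = load_counts(config.counts_path, meta_path=config.meta_path)
        lr = load_lr_database(config.lr_path)
        graph = (
            load_signaling_graph(config.network_path) if config.network_path else None
        )
        truth = None

    adata = compute_qc_metrics(adata)
    counts["cells_in"] = int(adata.n_obs)
    adata = qc_filter(adata, QC_PRESETS[config.qc_preset])
    adata = gene_filter(adata, config.min_cells_per_gene)
    counts["cells_qc"] = int(adata.n_obs)
    counts["genes_qc"] = int(adata.n_vars)
    qc_df = adata.obs.copy()
    qc_df.index.name = "cell_id"
    _write(qc_df, outdir / "qc_cells.tsv", index=True)

    annotate_groups(adata)
    receivers = sorted(
        set(adata.obs.loc[adata.obs["subclass"].astype(str) != "", "subclass"])
    )
    senders = sorted(
        set(adata.obs.loc[adata.obs["subclass"].astype(str) == "", "cell_type"])
    )
    if not receivers or not senders:
        raise ConfigurationError("need both sender types and receiver subclasses")

    table = score_interactions(
        adata, lr, senders, receivers, config.scoring, graph=graph
    )
    _write(table, outdir / "scores.tsv")
    counts["score_rows"] = len(table)

    qualified = qualify_pairs_for_differential(table, config.scoring)
    _write(qualified, outdir / "scores_filtered.tsv")
    counts["qualified_rows"] = len(qualified)

    diff = protective_table(qualified, config.differential)
    _write(diff, outdir / "differential.tsv")
    counts["differential_records"] = len(diff)

    agg = aggregate_nonredundant(diff, config.top_n)
    _write(agg, outdir / "aggregate_protective.tsv")
    counts["protective_pairs"] = len(agg)

    trajs = trajectories(table)
    variable = variable_interactions(trajs, fc_min=config.fc_min)
    _write(variable.reset_index(), outdir / "variable_interactions.tsv")
    counts["variable_trajectories"] = len(variable)

    pi_rows = []
    for rec in diff[diff["call"] == "protective"].itertuples(index=False):
        call = preset_induced(
            qualified, (rec.ligand, rec.receptor), rec.sender,
            config.differential, delta=config.delta,
        )
        pi_rows.append(
            {"sender": rec.sender, "ligand": rec.ligand, "receptor": rec.receptor,
             **call}
        )
    _write(
        pd.DataFrame(
            pi_rows, columns=["sender", "ligand", "receptor", "pre_diff",
                              "post_diff", "call"]
        ),
        outdir / "preset_induced.tsv",
    )

    manifest = {
        "package": "retinacomm",
        "seed": config.seed,
        "qc_preset": config.qc_preset,
        "scoring": asdict(config.scoring),
        "differential": asdict(config.differential),
        "delta": config.delta,
        "fc_min": config.fc_min,
        "top_n": config.top_n,
        "stage_counts": counts,
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
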