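"""Synthetic retinal atlas and RNAscope image generator.

Emulates the statistical structure of a multi-cell-type retinal scRNA-seq
time course around an optic-nerve injury: several sender cell types plus a
set of retinal-ganglion-cell (RGC) subclasses split into high- and
low-survival groups, profiled at one pre-injury (sham) and three
post-injury time points.  Counts follow a gamma-Poisson (negative
binomial) model with per-gene baseline abundances, per-(gene, cell type)
factors, and per-cell library sizes, so downstream QC metrics, detection
rates and group means have realistic spread.

Ligand-receptor interactions can be *planted*: the ligand is boosted in a
chosen sender type and the receptor in the receiver subclasses of a chosen
survival class, either at all time points ("preset") or only after injury
("induced").  Feedback loops can likewise be planted together with the
short signaling-network relay (receptor -> TF -> back-ligand) that makes
them discoverable.  The generator returns the full ground truth so every
downstream stage can be scored against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConfigurationError, PlacementError

TIMEPOINTS = ("sham", "12h", "24h", "48h")
POST_INJURY = ("12h", "24h", "48h")

DEFAULT_SENDER_TYPES = (
    "Astrocyte",
    "MullerGlia",
    "Microglia",
    "AmacrineGABA",
    "Bipolar",
    "Horizontal",
    "Photoreceptor",
    "Endothelial",
)
# Three resilient subclasses (the survivors of optic nerve crush) and three
# vulnerable ones.
DEFAULT_RECEIVER_SUBCLASSES = (
    ("ipRGC", "high"),
    ("alphaRGC", "high"),
    ("Gpr88RGC", "high"),
    ("T-RGC", "low"),
    ("W-RGC", "low"),
    ("N-RGC", "low"),
)


@dataclass(frozen=True)
class PlantedInteraction:
    """A ligand-receptor pair with a known, planted expression effect.

    ligand is boosted ``effect_size``-fold in ``sender``; receptor is
    boosted in the receiver subclasses belonging to
    ``target_survival_class`` ("high", "low" or "both").  "preset" dynamics
    apply the boost at every time point, "induced" only post-injury.
    """

    ligand: str
    receptor: str
    sender: str
    target_survival_class: str = "high"
    effect_size: float = 4.0
    dynamics: str = "preset"

    def __post_init__(self) -> None:
        if self.effect_size < 1:
            raise ConfigurationError("effect_size must be >= 1")
        if self.dynamics not in ("preset", "induced"):
            raise ConfigurationError(f"unknown dynamics {self.dynamics!r}")
        if self.target_survival_class not in ("high", "low", "both"):
            raise ConfigurationError(
                f"unknown target_survival_class {self.target_survival_class!r}"
            )


@dataclass(frozen=True)
class PlantedLoop:
    """A planted sender<->receiver feedback loop.

    The forward pair signals sender -> receiver; its receptor drives (via
    ``relay`` in the receiver's network) the back ligand, whose receptor is
    expressed on the original sender.
    """

    forward: PlantedInteraction
    back_ligand: str
    back_receptor: str
    relay: str = "TFrelay"


@dataclass
class SyntheticConfig:
    sender_types: tuple = DEFAULT_SENDER_TYPES
    receiver_subclasses: tuple = DEFAULT_RECEIVER_SUBCLASSES
    cells_per_type_per_timepoint: int = 60
    n_genes: int = 1200
    n_marker_genes_per_type: int = 5
    mito_gene_fraction: float = 0.05
    high_mito_cell_fraction: float = 0.03
    mito_boost: float = 8.0
    nb_mean: float = 0.5
    nb_dispersion: float = 0.5
    gene_mean_sigma: float = 1.0
    type_effect_sigma: float = 0.5
    libsize_sigma: float = 0.3
    target_numi: float = 2000.0
    marker_boost: float = 20.0
    planted_pairs: tuple = ()
    planted_loops: tuple = ()
    n_decoy_pairs: int = 50
    timepoints: tuple = TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_type_per_timepoint < 20:
            raise ConfigurationError("cells_per_type_per_timepoint must be >= 20")
        classes = {sc for _, sc in self.receiver_subclasses}
        if classes and classes != {"high", "low"}:
            raise ConfigurationError(
                "receiver subclasses must include both a high and a low survival group"
            )

    @property
    def all_groups(self) -> list[str]:
        return list(self.sender_types) + [n for n, _ in self.receiver_subclasses]


def default_config(
    seed: int = 0,
    n_planted: int = 5,
    effect_size: float = 4.0,
    dynamics: str = "preset",
    target: str = "high",
    with_loops: bool = False,
) -> SyntheticConfig:
    """Convenience factory: n_planted pairs spread over the sender types.

    Planted gene names are self-describing (``ligP1``/``recP1`` ...) and are
    injected into the gene universe by :func:`generate_atlas`.
    """
    senders = DEFAULT_SENDER_TYPES
    pairs = tuple(
        PlantedInteraction(
            ligand=f"ligP{i + 1}",
            receptor=f"recP{i + 1}",
            sender=senders[i % len(senders)],
            target_survival_class=target,
            effect_size=effect_size,
            dynamics=dynamics,
        )
        for i in range(n_planted)
    )
    loops = ()
    if with_loops and pairs:
        loops = (
            PlantedLoop(
                forward=pairs[0],
                back_ligand="ligBack1",
                back_receptor="recBack1",
                relay="TFrelay1",
            ),
        )
    return SyntheticConfig(planted_pairs=pairs, planted_loops=loops, seed=seed)


def _build_gene_universe(config: SyntheticConfig) -> dict:
    """Lay out marker, mitochondrial, planted and background gene names."""
    n = config.n_genes
    groups = config.all_groups
    markers: dict[str, list[str]] = {}
    names: list[str] = []
    for g in groups:
        ms = [f"mk_{g}_{i}" for i in range(config.n_marker_genes_per_type)]
        markers[g] = ms
        names.extend(ms)
    n_mito = int(round(config.mito_gene_fraction * n))
    mito = [f"mt-{i}" for i in range(n_mito)]
    names.extend(mito)
    planted_genes: list[str] = []
    for p in config.planted_pairs:
        for gene in (p.ligand, p.receptor):
            if gene not in names and gene not in planted_genes:
                planted_genes.append(gene)
    for lp in config.planted_loops:
        for gene in (lp.back_ligand, lp.back_receptor, lp.relay):
            if gene not in names and gene not in planted_genes:
                planted_genes.append(gene)
    names.extend(planted_genes)
    n_bg = n - len(names)
    if n_bg < 2 * config.n_decoy_pairs + 10:
        raise ConfigurationError(
            f"n_genes={n} leaves too few background genes "
            f"({n_bg}) for markers/mito/planted genes plus decoys"
        )
    background = [f"g{i:04d}" for i in range(n_bg)]
    names.extend(background)
    known = set(names)
    for p in config.planted_pairs:
        if p.sender not in config.sender_types:
            raise ConfigurationError(f"planted sender {p.sender!r} is not a sender type")
        for gene in (p.ligand, p.receptor):
            if gene not in known:
                raise ConfigurationError(f"planted gene {gene!r} absent from universe")
    return {
        "names": names,
        "markers": markers,
        "mito": mito,
        "planted_genes": planted_genes,
        "background": background,
    }


def _mean_tensor(config, universe, rng):
    """Expected expression per (gene, group, timepoint), before library size."""
    names = universe["names"]
    groups = config.all_groups
    tps = list(config.timepoints)
    gi = {g: i for i, g in enumerate(names)}
    n_genes, n_groups, n_tp = len(names), len(groups), len(tps)

    base = config.nb_mean * rng.lognormal(0.0, config.gene_mean_sigma, size=n_genes)
    type_factor = rng.lognormal(0.0, config.type_effect_sigma, size=(n_genes, n_groups))
    for t_idx, g in enumerate(groups):
        for m in universe["markers"][g]:
            type_factor[gi[m], t_idx] *= config.marker_boost
    # Planted genes sit on a flat cross-type baseline: the planted boost is
    # then the only systematic structure, so effect_size is an exact
    # sender/receiver-class contrast rather than one confounded by random
    # type-specific baselines.  Decoy genes keep the full type structure.
    planted_ref: set[str] = set()
    for p in config.planted_pairs:
        planted_ref.update((p.ligand, p.receptor))
    for lp in config.planted_loops:
        planted_ref.update((lp.back_ligand, lp.back_receptor, lp.relay))
    for gene in planted_ref:
        type_factor[gi[gene], :] = 1.0

    mean = base[:, None, None] * type_factor[:, :, None] * np.ones((1, 1, n_tp))

    survival_of = dict(config.receiver_subclasses)

    def boost(gene, group, dynamics, factor):
        cols = (
            range(n_tp)
            if dynamics == "preset"
            else [i for i, tp in enumerate(tps) if tp != "sham"]
        )
        for c in cols:
            mean[gi[gene], groups.index(group), c] *= factor

    for p in config.planted_pairs:
        boost(p.ligand, p.sender, p.dynamics, p.effect_size)
        targets = (
            [n for n, sc in config.receiver_subclasses]
            if p.target_survival_class == "both"
            else [n for n, sc in config.receiver_subclasses
                  if sc == p.target_survival_class]
        )
        for t in targets:
            boost(p.receptor, t, p.dynamics, p.effect_size)

    for lp in config.planted_loops:
        receivers = [
            n for n, sc in config.receiver_subclasses
            if lp.forward.target_survival_class in ("both", sc)
        ]
        for t in receivers:
            boost(lp.back_ligand, t, lp.forward.dynamics, lp.forward.effect_size)
            # the intracellular relay is constitutively present in receivers
            boost(lp.relay, t, "preset", lp.forward.effect_size)
        boost(lp.back_receptor, lp.forward.sender, "preset", lp.forward.effect_size)

    return mean, survival_of


def _loop_network_edges(config: SyntheticConfig) -> list[tuple[str, str, str]]:
    edges = []
    for lp in config.planted_loops:
        edges.append((lp.forward.receptor, lp.relay, "signaling"))
        edges.append((lp.relay, lp.back_ligand, "regulatory"))
    return edges


def generate_atlas(config: SyntheticConfig) -> tuple[ad.AnnData, dict]:
    """Sample a labeled synthetic atlas.

    Returns an AnnData (cells x genes, raw integer counts in ``.X``, labels
    in ``.obs``) and a ground-truth dict with the planted pairs/loops,
    decoy pairs, marker map, mitochondrial genes and planted network edges.
    Identical config (including seed) yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    universe = _build_gene_universe(config)
    names = universe["names"]
    groups = config.all_groups
    tps = list(config.timepoints)
    mean, survival_of = _mean_tensor(config, universe, rng)

    # global library scale so the typical cell hits ~target_numi UMIs;
    # computed once from the grand mean so planted boosts do not shift it
    lib_scale = config.target_numi / mean.mean(axis=(1, 2)).sum()
    mito_idx = np.array(
        [i for i, n in enumerate(names) if n.lower().startswith("mt-")], dtype=int
    )

    shape = 1.0 / config.nb_dispersion  # gamma shape; var = m + disp*m^2
    n_cells_grp = config.cells_per_type_per_timepoint

    blocks, obs_rows = [], []
    for g_idx, group in enumerate(groups):
        for tp in tps:
            t_idx = tps.index(tp)
            mu = mean[:, g_idx, t_idx] * lib_scale
            lib = rng.lognormal(0.0, config.libsize_sigma, size=n_cells_grp)
            lam = rng.gamma(shape, 1.0, size=(n_cells_grp, len(names)))
            lam *= (config.nb_dispersion * mu)[None, :] * lib[:, None]
            n_hi = rng.binomial(n_cells_grp, config.high_mito_cell_fraction)
            if n_hi and len(mito_idx):
                hi_cells = rng.choice(n_cells_grp, size=n_hi, replace=False)
                lam[np.ix_(hi_cells, mito_idx)] *= config.mito_boost
            counts = rng.poisson(lam)
            blocks.append(sp.csr_matrix(counts))
            is_receiver = group in survival_of
            for _ in range(n_cells_grp):
                obs_rows.append(
                    {
                        "cell_type": "RGC" if is_receiver else group,
                        "subclass": group if is_receiver else "",
                        "survival_class": survival_of.get(group, ""),
                        "timepoint": tp,
                        "condition": "sham" if tp == "sham" else "ONC",
                    }
                )

    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"c{i:05d}" for i in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(names, name="gene")))

    bg = universe["background"]
    perm = rng.permutation(len(bg))
    decoys = [
        (bg[perm[2 * i]], bg[perm[2 * i + 1]]) for i in range(config.n_decoy_pairs)
    ]

    ground_truth = {
        "planted_pairs": [asdict(p) for p in config.planted_pairs],
        "planted_loops": [
            {
                "forward": asdict(lp.forward),
                "back_ligand": lp.back_ligand,
                "back_receptor": lp.back_receptor,
                "relay": lp.relay,
            }
            for lp in config.planted_loops
        ],
        "decoy_pairs": decoys,
        "markers": universe["markers"],
        "mito_genes": universe["mito"],
        "network_edges": _loop_network_edges(config),
        "timepoints": tps,
        "groups": groups,
        "survival_of": survival_of,
    }
    return adata, ground_truth


def lr_table(ground_truth: dict) -> pd.DataFrame:
    """Planted + decoy pairs as a ligand/receptor table (scoring input)."""
    rows = [
        {"ligand": p["ligand"], "receptor": p["receptor"]}
        for p in ground_truth["planted_pairs"]
    ]
    for lp in ground_truth["planted_loops"]:
        rows.append({"ligand": lp["back_ligand"], "receptor": lp["back_receptor"]})
    rows += [{"ligand": l, "receptor": r} for l, r in ground_truth["decoy_pairs"]]
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


def write_atlas(adata: ad.AnnData, ground_truth: dict, outdir) -> None:
    """Write a 10x-style MTX triplet (genes x cells), metadata TSV and
    ground truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.csr_matrix(adata.X).T.tocoo())
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    meta = adata.obs.copy()
    meta.index.name = "cell_id"
    meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=1)


@dataclass
class DotField:
    """A 2-D fluorescence intensity field with background statistics."""

    intensity: np.ndarray
    background_mean: float
    detect_threshold: float
    pixel_area_unit: str = "px^2"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not np.all(np.isfinite(self.intensity)):
            raise ConfigurationError("intensity array must be finite")
        if self.detect_threshold < self.background_mean:
            raise ConfigurationError("detect_threshold must be >= background_mean")


def generate_dot_image(
    n_dots: int,
    dot_intensity: float,
    dot_area_px: int,
    background_level: float,
    image_shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    max_tries: int = 10_000,
) -> tuple[DotField, dict]:
    """Place n_dots uniform-intensity puncta on a flat background.

    Each dot occupies exactly ``dot_area_px`` pixels (filled row-major
    inside a minimal square patch); placements are rejection-sampled so
    dots never touch, even diagonally.  Returns the field plus ground
    truth (true count, per-dot integrated intensity, background).
    """
    rng = np.random.default_rng(seed)
    rows, cols = image_shape
    side = int(np.ceil(np.sqrt(dot_area_px))) if dot_area_px else 1
    img = np.full(image_shape, float(background_level))
    occupied = np.zeros(image_shape, dtype=bool)
    placed = []
    for _ in range(n_dots):
        for attempt in range(max_tries):
            r = rng.integers(1, rows - side - 1)
            c = rng.integers(1, cols - side - 1)
            # 1-px guard ring keeps dots disconnected under 8-connectivity
            if not occupied[r - 1 : r + side + 1, c - 1 : c + side + 1].any():
                break
        else:
            raise PlacementError(
                f"could not place {n_dots} dots of area {dot_area_px} "
                f"in {image_shape} without overlap"
            )
        filled = 0
        for dr in range(side):
            for dc in range(side):
                if filled == dot_area_px:
                    break
                img[r + dr, c + dc] += dot_intensity
                occupied[r + dr, c + dc] = True
                filled += 1
        placed.append((int(r), int(c)))
    field = DotField(
        intensity=img,
        background_mean=float(background_level),
        detect_threshold=float(background_level) + dot_intensity / 2.0,
    )
    truth = {
        "n_dots": n_dots,
        "dot_area_px": dot_area_px,
        "dot_integrated_intensity": dot_intensity * dot_area_px,
        "background_level": float(background_level),
        "positions": placed,
    }
    return field, truth
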