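"""Synthetic inputs with known ground truth.

Three generators emulate the study's raw materials so every downstream stage
can be tested end to end without external data:

* :func:`generate_eye_image` -- a grayscale micrograph of a compound fly eye:
  bright Gaussian ommatidial blobs on a hexagonal (offset-row) lattice with
  positional jitter, site dropout, dark necrotic disks, and sensor noise.
* :func:`generate_network` -- a weighted undirected gene-interaction graph
  with an optional planted module whose internal edge weights are scaled up,
  providing ground truth for connectivity-recovery tests.
* :func:`generate_universe` -- an annotated gene universe (e.g. an
  apoptosis-style boolean flag per gene) plus a candidate gene set whose
  annotation rate can be enriched relative to the background.

All generators are pure functions of their spec (which embeds a seed):
identical inputs yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import rng_from

__all__ = [
    "LatticeSpec",
    "NetworkSpec",
    "UniverseSpec",
    "generate_eye_image",
    "generate_network",
    "generate_universe",
    "hex_lattice_sites",
]

BLOB_AMPLITUDE = 0.75  # peak blob height as a fraction of full scale


@dataclass(frozen=True)
class LatticeSpec:
    """Parameters of a synthetic ommatidial lattice image.

    The hexagonal lattice is realized as offset rows: row pitch is
    ``spacing * sqrt(3)/2`` and alternate rows are shifted by ``spacing / 2``,
    so interior sites have six equidistant neighbors exactly as in true
    hexagonal packing.
    """

    n_rows: int = 10
    n_cols: int = 10
    spacing: float = 20.0  # px, center-to-center
    jitter_sigma: float = 0.0  # px, per-axis Gaussian positional noise
    dropout_fraction: float = 0.0
    blob_sigma: float = 2.5  # px, Gaussian blob width
    necrosis_disks: tuple[tuple[float, float, float], ...] = ()  # (cx, cy, r) px
    noise_sigma: float = 2.0  # intensity units of the declared bit depth
    image_margin: float = 20.0  # px
    background_level: float = 0.08  # pedestal, fraction of full scale
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice must have at least one row and column")
        if self.spacing <= 4.0 * self.blob_sigma:
            raise ValueError(
                "spacing must exceed 4*blob_sigma so that blobs are resolvable"
            )
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1]")
        if self.jitter_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not 0.0 <= self.background_level < 1.0:
            raise ValueError("background_level must lie in [0, 1)")


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of a synthetic weighted gene-interaction network.

    Background edges are Erdos-Renyi with weights drawn from a positive law
    (default: Exponential(mean 1) shifted by ``weight_shift``).  The planted
    module is a clique over ``planted_module`` whose edge weights are
    background draws scaled by ``module_weight_multiplier``; inter-module
    edges are never altered.
    """

    n_genes: int = 500
    background_edge_prob: float = 0.05
    background_weight_law: str = "exponential"  # only law currently implemented
    weight_mean: float = 1.0
    weight_shift: float = 1e-3
    planted_module: tuple[str, ...] = ()
    module_weight_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least two genes")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ValueError("background_edge_prob must lie in [0, 1]")
        if self.module_weight_multiplier <= 0:
            raise ValueError("module_weight_multiplier must be positive")
        if self.background_weight_law != "exponential":
            raise ValueError("only the 'exponential' weight law is implemented")
        if len(self.planted_module) > self.n_genes:
            raise ValueError("planted module larger than the gene universe")
        if len(set(self.planted_module)) != len(self.planted_module):
            raise ValueError("planted module contains duplicate genes")


@dataclass(frozen=True)
class UniverseSpec:
    """Parameters of an annotated gene universe with a candidate set.

    Every gene carries an independent boolean annotation at ``annotation_rate``
    (``annotation_rate * candidate_enrichment`` inside the candidate set).
    Defaults emulate a genome-scale universe with ~10% of genes carrying an
    apoptosis-style annotation and a disease candidate set of 756 genes.
    """

    n_genes: int = 18000
    annotation_rate: float = 0.1
    candidate_size: int = 756
    candidate_enrichment: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.annotation_rate <= 1.0:
            raise ValueError("annotation_rate must lie in [0, 1]")
        if self.candidate_size > self.n_genes:
            raise ValueError("candidate_size exceeds universe size")
        if self.annotation_rate * self.candidate_enrichment > 1.0:
            raise ValueError("enrichment pushes the candidate annotation rate above 1")


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def hex_lattice_sites(spec: LatticeSpec) -> np.ndarray:
    """Ideal (jitter-free) site coordinates, shape (n_rows*n_cols, 2) as (x, y)."""
    row_pitch = spec.spacing * np.sqrt(3.0) / 2.0
    xs, ys = [], []
    for r in range(spec.n_rows):
        shift = (spec.spacing / 2.0) if (r % 2 == 1) else 0.0
        for c in range(spec.n_cols):
            xs.append(spec.image_margin + c * spec.spacing + shift)
            ys.append(spec.image_margin + r * row_pitch)
    return np.column_stack([xs, ys])


def _image_shape(spec: LatticeSpec) -> tuple[int, int]:
    row_pitch = spec.spacing * np.sqrt(3.0) / 2.0
    width = (spec.n_cols - 1) * spec.spacing + spec.spacing / 2.0 + 2 * spec.image_margin
    height = (spec.n_rows - 1) * row_pitch + 2 * spec.image_margin
    return int(np.ceil(height)) + 1, int(np.ceil(width)) + 1


def generate_eye_image(spec: LatticeSpec):
    """Render a synthetic eye image; returns (EyeImage, true_centers).

    ``true_centers`` is an (n, 2) array of surviving blob centers in (x, y)
    pixel coordinates.  Dropout removes exactly ``round(f * n_sites)``
    uniformly chosen sites.  Necrotic disks are burned in last, setting
    intensity to the image minimum (0) so thresholded area is recoverable.
    """
    rng = rng_from(spec.seed)
    sites = hex_lattice_sites(spec)
    n_sites = sites.shape[0]

    n_drop = int(round(spec.dropout_fraction * n_sites))
    keep = np.ones(n_sites, dtype=bool)
    if n_drop > 0:
        keep[rng.choice(n_sites, size=n_drop, replace=False)] = False
    centers = sites[keep]

    if spec.jitter_sigma > 0:
        centers = centers + rng.normal(0.0, spec.jitter_sigma, size=centers.shape)

    h, w = _image_shape(spec)
    centers = np.column_stack(
        [np.clip(centers[:, 0], 0, w - 1), np.clip(centers[:, 1], 0, h - 1)]
    )

    maxval = 2**spec.bit_depth - 1
    img = np.full((h, w), spec.background_level * maxval, dtype=float)

    half = int(np.ceil(4 * spec.blob_sigma))
    for cx, cy in centers:
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        img[y0:y1, x0:x1] += (
            BLOB_AMPLITUDE * maxval * np.exp(-r2 / (2.0 * spec.blob_sigma**2))
        )

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    for cx, cy, r in spec.necrosis_disks:
        yy, xx = np.mgrid[0:h, 0:w]
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = 0.0

    img = np.clip(np.rint(img), 0, maxval)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    from .ommatidia_score import EyeImage  # local import to avoid a cycle

    return EyeImage(pixels=img.astype(dtype), bit_depth=spec.bit_depth), centers


def generate_network(spec: NetworkSpec):
    """Sample a weighted gene network; returns (edges DataFrame, module genes).

    The edge table has columns ``gene_a, gene_b, weight`` with ``gene_a <
    gene_b`` lexicographically, no self-edges and no duplicate pairs.
    """
    rng = rng_from(spec.seed)
    genes = _gene_names(spec.n_genes)
    module = list(spec.planted_module) if spec.planted_module else []
    unknown = set(module) - set(genes)
    if unknown:
        raise ValueError(f"planted module genes not in universe: {sorted(unknown)}")
    module_set = set(module)

    iu, ju = np.triu_indices(spec.n_genes, k=1)
    present = rng.random(iu.size) < spec.background_edge_prob
    weights = spec.weight_shift + rng.exponential(spec.weight_mean, size=iu.size)

    if module:
        idx = {g: k for k, g in enumerate(genes)}
        mod_idx = np.fromiter((idx[g] for g in module), dtype=int)
        in_module = np.zeros(spec.n_genes, dtype=bool)
        in_module[mod_idx] = True
        intra = in_module[iu] & in_module[ju]
        present = present | intra  # planted module is an intra-module clique
        weights = np.where(intra, weights * spec.module_weight_multiplier, weights)

    iu, ju, weights = iu[present], ju[present], weights[present]
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu],
            "gene_b": [genes[j] for j in ju],
            "weight": weights,
        }
    )
    return edges, module


def generate_universe(spec: UniverseSpec):
    """Sample an annotated universe; returns (universe DataFrame, candidate list).

    The DataFrame has columns ``gene, annotated`` (bool).  Candidate genes are
    drawn without replacement and annotated independently at
    ``annotation_rate * candidate_enrichment``; all other genes at
    ``annotation_rate``.
    """
    rng = rng_from(spec.seed)
    genes = _gene_names(spec.n_genes)
    candidate_idx = rng.choice(spec.n_genes, size=spec.candidate_size, replace=False)
    is_candidate = np.zeros(spec.n_genes, dtype=bool)
    is_candidate[candidate_idx] = True
    rate = np.where(
        is_candidate,
        spec.annotation_rate * spec.candidate_enrichment,
        spec.annotation_rate,
    )
    annotated = rng.random(spec.n_genes) < rate
    universe = pd.DataFrame({"gene": genes, "annotated": annotated})
    candidates = [genes[i] for i in sorted(candidate_idx)]
    return universe, candidates


# ---------------------------------------------------------------------------
# plain-text writers (TSV / one-gene-per-line), used by the pipeline stages


def write_centers_tsv(path, centers: np.ndarray) -> None:
    pd.DataFrame(centers, columns=["x", "y"]).to_csv(path, sep="\t", index=False)


def write_edges_tsv(path, edges: pd.DataFrame) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_universe_tsv(path, universe: pd.DataFrame) -> None:
    out = universe.copy()
    out["annotated"] = out["annotated"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def write_gene_list(path, genes) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
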