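"""Seeded generator of multi-slide Visium-like studies with known truth.

The generator emulates the structure of a multi-mouse brain Visium study:
each slide is one mouse section with ~constant spot count on a square
lattice, partitioned into anatomical regions (one white-matter strip plus
concentric bands around the section center). Counts are negative-binomial
with a per-spot library size, per-gene baseline proportion, region-specific
marker fold changes, (region, group)-specific signature effects, and
per-slide gene-wise batch factors:

    mean(spot, gene) = L_spot * w(spot, gene) / sum_g w(spot, g)
    w = p_gene * theta_marker(region, gene) * theta_effect(region, group, gene)
        * B(slide, gene)

so the expected total count of a spot equals its library size L_spot.
The planted layout, marker panel, effect table and batch factors are
returned as :class:`GroundTruth`, the recovery target for every downstream
stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_spatial import SpatialSlide, StudyDataset, assemble_study

__all__ = ["SyntheticSpec", "GroundTruth", "default_brain_spec", "simulate_study"]

REGION_NAMES = [
    "white matter",
    "upper cortex",
    "deep cortex",
    "hippocampus",
    "thalamus",
    "hypothalamus",
    "amygdala",
    "piriform area",
    "striatum",
    "dorsal striatum",
    "ventral striatum",
    "septal area",
    "olfactory area",
    "ventricle",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generator.

    ``marker_blocks`` maps region -> (marker genes, fold change on the mean);
    ``signature_blocks`` maps (region, group) -> (gene set, fold change),
    modelling e.g. an elevated reactive-glia signature in the TG group.
    ``batch_sigma`` is the sd of the per-slide gene-wise log-normal factor.
    """

    n_slides_per_group: int = 6
    groups: tuple[str, ...] = ("WT", "TG")
    n_regions: int = 9
    grid: tuple[int, int] = (25, 40)
    genes: int = 2000
    marker_blocks: dict[str, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    signature_blocks: dict[tuple[str, str], tuple[tuple[str, ...], float]] = field(
        default_factory=dict
    )
    library_size_meanlog: float = np.log(5000.0)
    library_size_sdlog: float = 0.25
    dispersion: float = 2.0  # NB size parameter r (var = m + m^2/r)
    batch_sigma: float = 0.1
    plane: str = "coronal"
    seed: int = 0

    def validate(self) -> None:
        if self.n_slides_per_group < 1 or self.genes < 1 or self.n_regions < 1:
            raise ValueError("sizes must be positive")
        if self.n_regions > self.grid[0] * self.grid[1]:
            raise ValueError("more regions than lattice spots")
        if self.dispersion <= 0:
            raise ValueError("NB size parameter must be > 0")
        if self.batch_sigma < 0:
            raise ValueError("batch_sigma must be >= 0")
        gene_set = set(gene_names(self.genes))
        for region, (genes_, theta) in self.marker_blocks.items():
            if theta < 0:
                raise ValueError(f"negative marker effect for {region}")
            if not set(genes_) <= gene_set:
                raise ValueError(f"unknown marker genes for {region}")
        for (region, group), (genes_, theta) in self.signature_blocks.items():
            if theta < 0:
                raise ValueError(f"negative effect for ({region}, {group})")
            if group not in self.groups:
                raise ValueError(f"effect group {group} not among {self.groups}")
            if not set(genes_) <= gene_set:
                raise ValueError(f"unknown signature genes for ({region}, {group})")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)

    @property
    def region_names(self) -> list[str]:
        return REGION_NAMES[: self.n_regions]


@dataclass
class GroundTruth:
    """Planted truth: per-spot regions, markers, effects and batch factors."""

    region: pd.Series  # indexed like StudyDataset.obs
    region_layout: np.ndarray  # per lattice spot, one slide's layout
    markers: dict[str, list[str]]
    effects: pd.DataFrame  # columns: region, group, theta, genes
    batch_factors: dict[str, np.ndarray]  # slide_id -> per-gene factor


def gene_names(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n)]


def region_layout(grid: tuple[int, int], n_regions: int) -> np.ndarray:
    """Deterministic partition of the lattice into regions.

    Region 0 ("white matter") is a vertical strip through the section
    center; the remaining regions are equal-size concentric bands by
    distance rank from the center, restricted to the non-strip spots.
    """
    rows, cols = grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    n_spots = rows * cols
    labels = np.full(n_spots, -1, dtype=int)

    if n_regions == 1:
        return np.zeros(n_spots, dtype=int)

    strip_width = max(1, cols // (2 * n_regions))
    mid = cols // 2
    strip = (cc >= mid - strip_width // 2) & (cc < mid - strip_width // 2 + strip_width)
    labels[strip] = 0

    rest = np.flatnonzero(~strip)
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    dist = np.hypot(rr[rest] - center[0], cc[rest] - center[1])
    order = rest[np.argsort(dist, kind="stable")]
    bands = np.array_split(order, n_regions - 1)
    for i, band in enumerate(bands, start=1):
        labels[band] = i
    return labels


def default_brain_spec(
    scale: Literal["tiny", "small", "paper_like"] = "small",
    n_markers: int = 10,
    theta_marker: float = 8.0,
    planted_effect: float = 4.0,
) -> SyntheticSpec:
    """Preset study conditions at three problem sizes.

    tiny: ~300 spots/slide, 500 genes, 4 regions; small: ~1,000 spots,
    2,000 genes, 9 regions; paper_like: ~3,000 spots, 15,000 genes,
    14 regions. Each region gets ``n_markers`` marker genes at fold change
    ``theta_marker``; the TG group carries a planted reactive-glia signature
    (10 genes, fold ``planted_effect``) in the white-matter region.
    """
    presets = {
        "tiny": dict(grid=(15, 20), genes=500, n_regions=4),
        "small": dict(grid=(25, 40), genes=2000, n_regions=9),
        "paper_like": dict(grid=(55, 55), genes=15000, n_regions=14),
    }
    if scale not in presets:
        raise ValueError(f"unknown scale {scale!r}")
    p = presets[scale]
    names = gene_names(p["genes"])
    regions = REGION_NAMES[: p["n_regions"]]
    marker_blocks = {}
    cursor = 0
    for region in regions:
        marker_blocks[region] = (tuple(names[cursor : cursor + n_markers]), theta_marker)
        cursor += n_markers
    sig_genes = tuple(names[cursor : cursor + 10])
    signature_blocks = {}
    if planted_effect != 1.0:
        signature_blocks[("white matter", "TG")] = (sig_genes, planted_effect)
    lib_meanlog = {"tiny": np.log(2000.0), "small": np.log(5000.0), "paper_like": np.log(20000.0)}
    return SyntheticSpec(
        grid=p["grid"],
        genes=p["genes"],
        n_regions=p["n_regions"],
        marker_blocks=marker_blocks,
        signature_blocks=signature_blocks,
        library_size_meanlog=lib_meanlog[scale],
    )


def reactive_glia_signature(spec: SyntheticSpec) -> list[str]:
    """The planted TG signature gene set (or the default slot if null)."""
    for (region, group), (genes_, _theta) in spec.signature_blocks.items():
        return list(genes_)
    n_marked = sum(len(g) for g, _ in spec.marker_blocks.values())
    return gene_names(spec.genes)[n_marked : n_marked + 10]


def simulate_study(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[StudyDataset, GroundTruth]:
    """Draw one study. Same (spec, seed) -> bit-identical counts."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    names = gene_names(spec.genes)
    gene_pos = {g: i for i, g in enumerate(names)}
    layout = region_layout(spec.grid, spec.n_regions)
    region_of_spot = np.asarray(layout)
    n_spots = region_of_spot.size
    regions = spec.region_names

    # Baseline gene proportions: heavy-tailed, shared by all slides.
    p_gene = rng.lognormal(mean=0.0, sigma=1.0, size=spec.genes)

    # Region x gene multiplier from marker blocks.
    theta_region = np.ones((spec.n_regions, spec.genes))
    for region, (genes_, theta) in spec.marker_blocks.items():
        r = regions.index(region)
        for g in genes_:
            theta_region[r, gene_pos[g]] = theta

    slides: list[SpatialSlide] = []
    batch_factors: dict[str, np.ndarray] = {}
    rr, cc = np.meshgrid(
        np.arange(spec.grid[0]), np.arange(spec.grid[1]), indexing="ij"
    )
    array_row, array_col = rr.ravel(), cc.ravel()
    barcodes = [f"BC{i:05d}-1" for i in range(n_spots)]

    for group in spec.groups:
        for k in range(spec.n_slides_per_group):
            slide_id = f"{group}_s{k}"
            theta = theta_region.copy()
            for (region, sig_group), (genes_, t_eff) in spec.signature_blocks.items():
                if sig_group == group:
                    r = regions.index(region)
                    for g in genes_:
                        theta[r, gene_pos[g]] *= t_eff
            if spec.batch_sigma > 0:
                batch = rng.lognormal(0.0, spec.batch_sigma, size=spec.genes)
            else:
                batch = np.ones(spec.genes)
            batch_factors[slide_id] = batch

            w = p_gene[None, :] * theta[region_of_spot] * batch[None, :]
            w /= w.sum(axis=1, keepdims=True)
            lib = rng.lognormal(spec.library_size_meanlog, spec.library_size_sdlog, n_spots)
            mean = lib[:, None] * w
            # NB(mean m, size r) as a gamma-Poisson mixture.
            lam = rng.gamma(shape=spec.dispersion, scale=mean / spec.dispersion)
            counts = rng.poisson(lam).astype(np.int64)

            slides.append(
                SpatialSlide(
                    slide_id=slide_id,
                    counts=sp.csr_matrix(counts),
                    gene_ids=list(names),
                    gene_names=list(names),
                    barcodes=list(barcodes),
                    array_row=array_row.copy(),
                    array_col=array_col.copy(),
                    pxl_row=array_row.astype(float) * 100.0,
                    pxl_col=array_col.astype(float) * 100.0,
                    in_tissue=np.ones(n_spots, dtype=bool),
                    mouse_id=f"m_{slide_id}",
                    group=group,
                    plane=spec.plane,
                )
            )

    study = assemble_study(slides)
    region_series = pd.Series(
        [regions[r] for _ in slides for r in region_of_spot],
        index=study.obs.index,
        name="region",
    )
    effects = pd.DataFrame(
        [
            {"region": region, "group": group, "theta": t, "genes": ",".join(genes_)}
            for (region, group), (genes_, t) in spec.signature_blocks.items()
        ],
        columns=["region", "group", "theta", "genes"],
    )
    truth = GroundTruth(
        region=region_series,
        region_layout=region_of_spot,
        markers={r: list(g) for r, (g, _t) in spec.marker_blocks.items()},
        effects=effects,
        batch_factors=batch_factors,
    )
    return study, truth
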