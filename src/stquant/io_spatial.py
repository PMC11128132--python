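"""Read/write Visium-style on-disk datasets and assemble multi-slide studies.

One capture area is a :class:`SpatialSlide`: a sparse (spot, gene) count
matrix plus spot geometry and slide-level metadata (mouse, group, section
plane). Several slides sharing a gene index form a :class:`StudyDataset`,
the container every downstream stage (normalization, integration,
clustering, scoring, differential expression) operates on.

On disk the layout is the standard 10x Genomics triplet — ``matrix.mtx``
(genes x spots, MatrixMarket), ``barcodes.tsv``, ``features.tsv`` — plus the
Space Ranger spot-geometry table ``tissue_positions_list.csv`` (headerless
dialect; the headered ``tissue_positions.csv`` dialect of Space Ranger >= 2.0
is accepted on read). In memory the convention is always (spot, gene).
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpatialSlide",
    "StudyDataset",
    "VisiumFormatError",
    "read_visium",
    "write_visium",
    "assemble_study",
    "read_study_manifest",
]

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row",
    "pxl_col",
]


class VisiumFormatError(ValueError):
    """Raised when an on-disk dataset violates the expected 10x layout."""


@dataclass
class SpatialSlide:
    """One Visium capture area with counts, geometry and metadata."""

    slide_id: str
    counts: sp.csr_matrix  # (n_spots, n_genes), non-negative integers
    gene_ids: list[str]
    gene_names: list[str]
    barcodes: list[str]
    array_row: np.ndarray
    array_col: np.ndarray
    pxl_row: np.ndarray
    pxl_col: np.ndarray
    in_tissue: np.ndarray
    mouse_id: str = ""
    group: str = ""
    plane: Literal["coronal", "sagittal"] = "coronal"

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        n, g = self.counts.shape
        if len(self.barcodes) != n or len(self.gene_ids) != g:
            raise ValueError(
                f"slide {self.slide_id}: counts shape {self.counts.shape} does "
                f"not match {len(self.barcodes)} barcodes / {len(self.gene_ids)} genes"
            )
        if len(set(self.barcodes)) != n:
            raise ValueError(f"slide {self.slide_id}: duplicate barcodes")
        if len(set(self.gene_ids)) != g:
            raise ValueError(f"slide {self.slide_id}: duplicate gene ids")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError(f"slide {self.slide_id}: counts must be non-negative integers")
        for name in ("array_row", "array_col", "pxl_row", "pxl_col", "in_tissue"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"slide {self.slide_id}: {name} length != n_spots")

    def subset_spots(self, mask: np.ndarray) -> "SpatialSlide":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[idx],
            barcodes=[self.barcodes[i] for i in idx],
            array_row=self.array_row[idx],
            array_col=self.array_col[idx],
            pxl_row=self.pxl_row[idx],
            pxl_col=self.pxl_col[idx],
            in_tissue=self.in_tissue[idx],
        )

    def subset_genes(self, genes: Sequence[str]) -> "SpatialSlide":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return replace(
            self,
            counts=sp.csr_matrix(self.counts[:, idx]),
            gene_ids=list(genes),
            gene_names=[self.gene_names[i] for i in idx],
        )


@dataclass
class StudyDataset:
    """Multiple slides stacked on a shared gene index (in-tissue spots only).

    ``obs`` carries one row per spot with columns ``slide_id, barcode,
    mouse_id, group, plane`` indexed by the global ``slide_id:barcode`` key.
    """

    counts: sp.csr_matrix  # (n_spots_total, n_shared_genes)
    shared_genes: list[str]
    gene_names: list[str]
    obs: pd.DataFrame
    slides: list[SpatialSlide] = field(default_factory=list)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def slide_mask(self, slide_id: str) -> np.ndarray:
        return (self.obs["slide_id"] == slide_id).to_numpy()

    @property
    def slide_ids(self) -> list[str]:
        return list(dict.fromkeys(self.obs["slide_id"]))


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_file(dir_path: Path, names: Sequence[str]) -> Path:
    for name in names:
        p = dir_path / name
        if p.exists():
            return p
    raise VisiumFormatError(
        f"missing file in {dir_path}: expected one of {', '.join(names)}"
    )


def read_visium(
    dir_path: str | os.PathLike,
    slide_id: str | None = None,
    mouse_id: str = "",
    group: str = "",
    plane: str = "coronal",
) -> SpatialSlide:
    """Read one capture area from a 10x-style directory.

    The matrix is stored genes x spots on disk and transposed to the
    in-memory (spot, gene) convention. Spot order follows the barcodes file;
    positions are joined by barcode.
    """
    d = Path(dir_path)
    mtx_path = _find_file(d, ["matrix.mtx", "matrix.mtx.gz"])
    bc_path = _find_file(d, ["barcodes.tsv", "barcodes.tsv.gz"])
    ft_path = _find_file(d, ["features.tsv", "features.tsv.gz"])
    pos_path = _find_file(d, ["tissue_positions_list.csv", "tissue_positions.csv"])

    mat = scipy.io.mmread(str(mtx_path))
    data = np.asarray(mat.data) if sp.issparse(mat) else np.asarray(mat).ravel()
    if data.size and np.any(data != np.round(data)):
        raise VisiumFormatError(f"{mtx_path}: matrix contains non-integer values")
    counts = sp.csr_matrix(mat.T.astype(np.int64) if sp.issparse(mat) else np.asarray(mat).T)

    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    gene_ids, gene_names = [], []
    with _open_maybe_gz(ft_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            gene_ids.append(parts[0])
            gene_names.append(parts[1] if len(parts) > 1 else parts[0])

    if counts.shape != (len(barcodes), len(gene_ids)):
        raise VisiumFormatError(
            f"{mtx_path}: matrix is {mat.shape} (genes x spots) but found "
            f"{len(gene_ids)} features and {len(barcodes)} barcodes"
        )

    # Headerless dialect (Space Ranger <2.0) vs headered tissue_positions.csv.
    if pos_path.stat().st_size == 0:
        pos = pd.DataFrame(columns=POSITION_COLUMNS).set_index("barcode")
    else:
        first = pd.read_csv(pos_path, header=None, nrows=1)
        has_header = isinstance(first.iloc[0, 1], str)
        pos = pd.read_csv(pos_path, header=0 if has_header else None)
        pos.columns = POSITION_COLUMNS
        pos = pos.set_index("barcode")

    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise VisiumFormatError(
            f"{pos_path}: barcodes missing from positions file: {', '.join(missing[:10])}"
        )
    extra = pos.index.difference(barcodes)
    if len(extra) and len(pos) != len(barcodes):
        # Space Ranger lists all 4,992 spots in positions; only warn for pure
        # supersets, error if the matrix has barcodes the positions lack
        # (handled above). Supersets are fine: restrict to matrix barcodes.
        pass
    pos = pos.loc[barcodes]

    slide = SpatialSlide(
        slide_id=slide_id or d.name,
        counts=counts,
        gene_ids=gene_ids,
        gene_names=gene_names,
        barcodes=barcodes,
        array_row=pos["array_row"].to_numpy(dtype=int),
        array_col=pos["array_col"].to_numpy(dtype=int),
        pxl_row=pos["pxl_row"].to_numpy(dtype=float),
        pxl_col=pos["pxl_col"].to_numpy(dtype=float),
        in_tissue=pos["in_tissue"].to_numpy(dtype=int).astype(bool),
        mouse_id=mouse_id,
        group=group,
        plane=plane,  # type: ignore[arg-type]
    )
    slide.validate()
    return slide


def write_visium(slide: SpatialSlide, dir_path: str | os.PathLike) -> Path:
    """Write a slide as matrix.mtx + barcodes.tsv + features.tsv + positions.

    The MatrixMarket file uses the 10x genes x spots orientation with 1-based
    coordinates; the positions file is the headerless dialect.
    """
    slide.validate()
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)

    scipy.io.mmwrite(
        str(d / "matrix.mtx"), sp.coo_matrix(slide.counts.T), field="integer"
    )
    with open(d / "barcodes.tsv", "w") as fh:
        fh.writelines(b + "\n" for b in slide.barcodes)
    with open(d / "features.tsv", "w") as fh:
        fh.writelines(
            f"{gid}\t{name}\tGene Expression\n"
            for gid, name in zip(slide.gene_ids, slide.gene_names)
        )
    pd.DataFrame(
        {
            "barcode": slide.barcodes,
            "in_tissue": slide.in_tissue.astype(int),
            "array_row": slide.array_row,
            "array_col": slide.array_col,
            "pxl_row": slide.pxl_row,
            "pxl_col": slide.pxl_col,
        }
    ).to_csv(d / "tissue_positions_list.csv", header=False, index=False)
    return d


def assemble_study(
    slides: Sequence[SpatialSlide],
    gene_policy: Literal["intersection", "union"] = "intersection",
) -> StudyDataset:
    """Stack slides on a shared gene index, keeping in-tissue spots only.

    Default policy keeps the genes common to every slide; ``union`` keeps
    all genes, zero-filling those absent from a slide.
    """
    if not slides:
        raise ValueError("assemble_study requires at least one slide")
    ids = [s.slide_id for s in slides]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate slide_id among {ids}")
    for s in slides:
        s.validate()

    if gene_policy == "intersection":
        shared = set(slides[0].gene_ids)
        for s in slides[1:]:
            shared &= set(s.gene_ids)
        if not shared:
            raise ValueError("gene intersection across slides is empty")
        # Keep the first slide's ordering for determinism.
        shared_genes = [g for g in slides[0].gene_ids if g in shared]
    elif gene_policy == "union":
        shared_genes = list(dict.fromkeys(g for s in slides for g in s.gene_ids))
    else:
        raise ValueError(f"unknown gene_policy {gene_policy!r}")

    name_of: dict[str, str] = {}
    for s in slides:
        for gid, gname in zip(s.gene_ids, s.gene_names):
            name_of.setdefault(gid, gname)

    blocks, obs_rows = [], []
    for s in slides:
        tissue = s.subset_spots(s.in_tissue.astype(bool))
        if gene_policy == "union":
            pos = {g: i for i, g in enumerate(tissue.gene_ids)}
            cols = sp.lil_matrix((tissue.n_spots, len(shared_genes)), dtype=np.int64)
            present = [(j, pos[g]) for j, g in enumerate(shared_genes) if g in pos]
            if present:
                jj, ii = zip(*present)
                cols[:, list(jj)] = tissue.counts[:, list(ii)]
            block = sp.csr_matrix(cols)
        else:
            block = tissue.subset_genes(shared_genes).counts
        blocks.append(block)
        for b in tissue.barcodes:
            obs_rows.append((s.slide_id, b, s.mouse_id, s.group, s.plane))

    obs = pd.DataFrame(
        obs_rows, columns=["slide_id", "barcode", "mouse_id", "group", "plane"]
    )
    obs.index = obs["slide_id"] + ":" + obs["barcode"]
    if obs.index.duplicated().any():
        raise ValueError("duplicate (slide_id, barcode) pairs in study")
    counts = sp.csr_matrix(sp.vstack(blocks))
    return StudyDataset(
        counts=counts,
        shared_genes=shared_genes,
        gene_names=[name_of[g] for g in shared_genes],
        obs=obs,
        slides=list(slides),
    )


def read_study_manifest(path: str | os.PathLike) -> StudyDataset:
    """Assemble a study from a TSV manifest.

    Columns: ``slide_id, path, mouse_id, group, plane``; ``path`` is the
    Visium directory, relative paths resolved against the manifest location.
    """
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    required = {"slide_id", "path", "mouse_id", "group", "plane"}
    if not required.issubset(manifest.columns):
        raise VisiumFormatError(
            f"study manifest must have columns {sorted(required)}"
        )
    base = Path(path).parent
    slides = []
    for row in manifest.itertuples(index=False):
        slide_dir = Path(row.path)
        if not slide_dir.is_absolute():
            slide_dir = base / slide_dir
        slides.append(
            read_visium(
                slide_dir,
                slide_id=row.slide_id,
                mouse_id=row.mouse_id,
                group=row.group,
                plane=row.plane,
            )
        )
    return assemble_study(slides)
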