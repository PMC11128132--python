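import numpy as np
import pytest
import scipy.sparse as sp

from stquant.io_spatial import SpatialSlide
from stquant.simdata import default_brain_spec, simulate_study


def make_slide(
    slide_id="s1", n_spots=6, n_genes=4, seed=0, group="WT", mouse_id="m1",
    counts=None, gene_ids=None,
):
    rng = np.random.default_rng(seed)
    if counts is None:
        counts = rng.integers(0, 20, size=(n_spots, n_genes))
    counts = np.asarray(counts)
    n_spots, n_genes = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    return SpatialSlide(
        slide_id=slide_id,
        counts=sp.csr_matrix(counts),
        gene_ids=list(gene_ids),
        gene_names=list(gene_ids),
        barcodes=[f"b{i}" for i in range(n_spots)],
        array_row=np.arange(n_spots),
        array_col=np.zeros(n_spots, dtype=int),
        pxl_row=np.arange(n_spots) * 100.0,
        pxl_col=np.zeros(n_spots),
        in_tissue=np.ones(n_spots, dtype=bool),
        mouse_id=mouse_id,
        group=group,
    )


@pytest.fixture
def slide_factory():
    return make_slide


@pytest.fixture(scope="session")
def tiny_study():
    """One seeded tiny study shared by read-only tests."""
    spec = default_brain_spec("tiny")
    return simulate_study(spec, seed=11)


@pytest.fixture(scope="session")
def tiny_spec():
    return default_brain_spec("tiny")
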