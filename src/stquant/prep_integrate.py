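"""Normalization, feature selection, embedding and anchor-based integration.

The preprocessing chain mirrors standard multi-slide spatial workflows:

1. per-spot log-normalization, ``log1p(count / total * 10,000)``;
2. per-slide highly-variable genes by variance-stabilizing-transform (vst)
   standardized variance (mean-variance trend on log10 scale, standardized
   counts clipped at sqrt(n_spots));
3. integration features ranked by the number of slides in which a gene is
   variable, ties broken by median variability rank;
4. per-gene scaling with the spot total count regressed out;
5. truncated PCA with a deterministic sign convention;
6. reciprocal-PCA (RPCA) integration: reference and query slides are
   projected into each other's PCA space, mutual nearest neighbors become
   anchors, and each query spot receives a kernel-weighted correction toward
   the reference built from its nearest anchors' feature differences.

Reference slides (wild-type mice, by default) pass through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_spatial import StudyDataset

__all__ = [
    "NormalizedMatrix",
    "Embedding",
    "AnchorSet",
    "log_normalize",
    "vst_standardized_variance",
    "select_hvg_vst",
    "select_integration_features",
    "scale_and_regress",
    "embed_pca",
    "integrate_rpca",
]


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, (spot, gene), log1p scale."""

    values: sp.csr_matrix
    scale_factor: float
    zero_total: np.ndarray  # spots whose raw total was 0 (all-zero rows)
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class Embedding:
    coordinates: np.ndarray  # (spot, n_pcs)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # (n_pcs, n_genes)
    mean: np.ndarray  # feature means used for centering
    n_pcs: int

    def project(self, scaled: np.ndarray) -> np.ndarray:
        return (scaled - self.mean) @ self.components.T


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor spot pairs between reference and one query."""

    pairs: pd.DataFrame  # columns: ref_index, query_index, score
    features: list[str]
    k_anchor: int
    k_score: int


def log_normalize(counts, scale_factor: float = 10000.0,
                  gene_ids: Sequence[str] | None = None) -> NormalizedMatrix:
    """``value = log1p(count / spot_total * scale_factor)`` per spot.

    Spots with zero total stay all-zero and are flagged; they carry no
    expression information and are excluded from integration/clustering.
    """
    X = sp.csr_matrix(counts, dtype=np.float64)
    if X.data.size and np.any(X.data < 0):
        raise ValueError("counts must be non-negative")
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    scale = np.divide(scale_factor, totals, out=np.zeros_like(totals), where=~zero)
    out = X.multiply(scale[:, None]).tocsr()
    np.log1p(out.data, out=out.data)
    return NormalizedMatrix(
        values=out,
        scale_factor=scale_factor,
        zero_total=zero,
        gene_ids=list(gene_ids) if gene_ids is not None else [],
    )


def vst_standardized_variance(counts, span: float = 0.3) -> np.ndarray:
    """Per-gene standardized variance after mean-variance trend removal.

    Raw-count mean and variance go on log10 scale; a lowess trend predicts
    the expected variance at each gene's mean; counts standardized by the
    expected sd are clipped at sqrt(n_spots) and their variance (around the
    raw mean, per the vst convention) is returned. Constant genes get 0.
    """
    X = sp.csc_matrix(counts, dtype=np.float64)
    n, g = X.shape
    if n < 2:
        raise ValueError("need at least 2 spots")
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).sum(axis=0)).ravel()
    var = (sq - n * mean**2) / (n - 1)
    # constant genes: guard against float cancellation leaving ~1e-16
    var[var <= 1e-10 * np.maximum(1.0, mean**2)] = 0.0

    out = np.zeros(g)
    ok = (var > 0) & (mean > 0)
    if ok.sum() < 2:
        return out
    lx, ly = np.log10(mean[ok]), np.log10(var[ok])
    fitted = lowess(ly, lx, frac=span, return_sorted=True)
    exp_var = np.zeros(g)
    exp_var[ok] = 10 ** np.interp(lx, fitted[:, 0], fitted[:, 1])
    sd = np.sqrt(exp_var)

    clip = np.sqrt(n)
    for j in np.flatnonzero(ok):
        col = X.data[X.indptr[j] : X.indptr[j + 1]]
        z_nz = np.minimum((col - mean[j]) / sd[j], clip)
        z_zero = -mean[j] / sd[j]  # negative, never clipped at the top
        total_sq = np.sum(z_nz**2) + (n - col.size) * z_zero**2
        out[j] = total_sq / (n - 1)
    return out


def select_hvg_vst(counts, gene_ids: Sequence[str], n_top: int = 2000,
                   span: float = 0.3) -> list[str]:
    """Top ``n_top`` genes by vst standardized variance, most variable first."""
    sv = vst_standardized_variance(counts, span=span)
    if n_top > len(gene_ids):
        warnings.warn(
            f"n_top={n_top} exceeds {len(gene_ids)} genes; returning all"
        )
        n_top = len(gene_ids)
    order = np.argsort(-sv, kind="stable")[:n_top]
    return [gene_ids[i] for i in order]


def rank_integration_features(
    hvg_lists: Sequence[Sequence[str]], genes: Sequence[str], n: int
) -> list[str]:
    """Sort genes by slide-frequency among HVG lists, then median rank.

    Primary key: descending number of lists (slides) in which the gene
    appears; tie-break: ascending median 1-based rank over the lists where
    it appears; final tie-break: gene order, for determinism. Genes in no
    list are excluded.
    """
    pos = {g: i for i, g in enumerate(genes)}
    counts_in = np.zeros(len(genes), dtype=int)
    ranks: list[list[float]] = [[] for _ in genes]
    for hvgs in hvg_lists:
        for rank, g in enumerate(hvgs, start=1):
            i = pos[g]
            counts_in[i] += 1
            ranks[i].append(rank)
    median_rank = np.array([np.median(r) if r else np.inf for r in ranks])
    order = sorted(
        range(len(genes)), key=lambda i: (-counts_in[i], median_rank[i], i)
    )
    return [genes[i] for i in order if counts_in[i] > 0][:n]


def select_integration_features(
    study: StudyDataset, n: int = 2000, n_hvg: int = 2000, span: float = 0.3
) -> list[str]:
    """Integration features: per-slide vst HVGs combined by slide-frequency
    then median variability rank (see :func:`rank_integration_features`)."""
    genes = study.shared_genes
    hvg_lists = [
        select_hvg_vst(study.counts[study.slide_mask(sid)], genes, n_top=n_hvg, span=span)
        for sid in study.slide_ids
    ]
    return rank_integration_features(hvg_lists, genes, n)


def scale_and_regress(
    values, covariate: np.ndarray | None = None, clip: float = 10.0
) -> np.ndarray:
    """Per-gene OLS residuals on a covariate, centered, unit variance, clipped.

    With ``covariate=None`` this is plain per-gene standardization. Genes
    with zero residual variance become all-zero columns.
    """
    Y = np.asarray(values.todense() if sp.issparse(values) else values, dtype=np.float64)
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    if covariate is not None:
        c = np.asarray(covariate, dtype=np.float64)
        if c.shape[0] != n:
            raise ValueError("covariate length must equal n_spots")
        cc = c - c.mean()
        ss = float(cc @ cc)
        if ss > 0:
            beta = (cc @ Yc) / ss
            Yc = Yc - np.outer(cc, beta)
            Yc -= Yc.mean(axis=0, keepdims=True)
    sd = Yc.std(axis=0, ddof=1)
    out = np.divide(Yc, sd[None, :], out=np.zeros_like(Yc), where=sd[None, :] > 0)
    np.clip(out, -clip, clip, out=out)
    return out


def embed_pca(scaled: np.ndarray, n_pcs: int = 30) -> Embedding:
    """Truncated PCA with the largest-magnitude loading of each PC positive."""
    X = np.asarray(scaled, dtype=np.float64)
    if n_pcs > min(X.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_spots, n_genes)={min(X.shape)}")
    solver = "covariance_eigh" if X.shape[1] <= 3000 else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=0)
    coords = pca.fit_transform(X)
    comps = pca.components_
    flip = np.sign(comps[np.arange(n_pcs), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    coords = coords * flip[None, :]
    return Embedding(
        coordinates=coords,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=comps,
        mean=pca.mean_,
        n_pcs=n_pcs,
    )


def _mnn_pairs(ref_proj, query_proj, k_anchor):
    """Mutual nearest neighbor (ref, query) index pairs in one projection."""
    k_r = min(k_anchor, len(ref_proj))
    k_q = min(k_anchor, len(query_proj))
    nn_ref = NearestNeighbors(n_neighbors=k_r).fit(ref_proj)
    nn_query = NearestNeighbors(n_neighbors=k_q).fit(query_proj)
    _, ref_of_query = nn_ref.kneighbors(query_proj)  # per query: k ref ids
    _, query_of_ref = nn_query.kneighbors(ref_proj)  # per ref: k query ids
    ref_sets = [set(row) for row in query_of_ref]
    pairs = set()
    for q, refs in enumerate(ref_of_query):
        for r in refs:
            if q in ref_sets[r]:
                pairs.add((int(r), int(q)))
    return pairs


def _anchor_scores(pairs, ref_proj, query_proj, k_score):
    """Shared-neighborhood overlap in the reference projection, in [0, 1]."""
    k = min(k_score, len(ref_proj), len(query_proj))
    nn_ref = NearestNeighbors(n_neighbors=k).fit(ref_proj)
    nn_query = NearestNeighbors(n_neighbors=k).fit(query_proj)
    _, ref_nbrs_of_ref = nn_ref.kneighbors(ref_proj)
    _, ref_nbrs_of_query = nn_ref.kneighbors(query_proj)
    _, query_nbrs_of_ref = nn_query.kneighbors(ref_proj)
    _, query_nbrs_of_query = nn_query.kneighbors(query_proj)
    scores = []
    for r, q in pairs:
        a = len(set(ref_nbrs_of_ref[r]) & set(ref_nbrs_of_query[q]))
        b = len(set(query_nbrs_of_ref[r]) & set(query_nbrs_of_query[q]))
        scores.append((a + b) / (2.0 * k))
    return np.array(scores)


def integrate_rpca(
    study: StudyDataset,
    reference_groups: set[str] | Sequence[str] = ("WT",),
    features: Sequence[str] | None = None,
    k_anchor: int = 5,
    k_weight: int = 100,
    k_score: int = 30,
    n_pcs: int = 30,
    scale_factor: float = 10000.0,
    feature_matrix: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, AnchorSet]]:
    """Correct query slides toward pooled reference slides via RPCA anchors.

    Returns the corrected log-normalized feature matrix over all study spots
    (reference rows unchanged) and one :class:`AnchorSet` per query slide.
    For each query slide, spots are projected into the pooled-reference PCA
    space and the reference into the query's PCA space; mutual nearest
    neighbors (within ``k_anchor``) in either projection are candidate
    anchors, scored by shared-neighborhood overlap, and each anchored query
    spot retains its closest pair. Query-spot corrections are Gaussian-kernel
    weighted means of the ``k_weight`` nearest anchors' (reference - query)
    feature differences, weighted additionally by anchor score.
    """
    reference_groups = set(reference_groups)
    if features is None:
        features = select_integration_features(study)
    features = list(features)
    fpos = {g: i for i, g in enumerate(study.shared_genes)}
    missing = [g for g in features if g not in fpos]
    if missing:
        raise ValueError(f"features absent from study: {missing[:5]}")
    fidx = np.array([fpos[g] for g in features])

    if feature_matrix is not None:
        F = np.asarray(feature_matrix, dtype=np.float64)
        if F.shape != (study.n_spots, len(features)):
            raise ValueError("feature_matrix must be (n_spots, n_features)")
    else:
        norm = log_normalize(study.counts, scale_factor=scale_factor)
        F = np.asarray(norm.values[:, fidx].todense())

    is_ref = study.obs["group"].isin(reference_groups).to_numpy()
    if not is_ref.any():
        raise ValueError(f"no reference slides with group in {sorted(reference_groups)}")
    ref_rows = np.flatnonzero(is_ref)
    query_slides = [
        sid
        for sid in study.slide_ids
        if not study.obs.loc[study.slide_mask(sid), "group"].iloc[0] in reference_groups
    ]

    # Per-slide standardization of the feature block before any projection.
    S = np.zeros_like(F)
    for sid in study.slide_ids:
        m = study.slide_mask(sid)
        S[m] = scale_and_regress(F[m])

    corrected = F.copy()
    anchor_sets: dict[str, AnchorSet] = {}
    if not query_slides:
        return corrected, anchor_sets

    ref_S = S[ref_rows]
    npc_ref = min(n_pcs, ref_S.shape[0] - 1, ref_S.shape[1])
    ref_pca = embed_pca(ref_S, n_pcs=npc_ref)

    for sid in query_slides:
        qmask = study.slide_mask(sid)
        q_rows = np.flatnonzero(qmask)
        if len(q_rows) < k_anchor or len(ref_rows) < k_anchor:
            raise ValueError(f"slide {sid}: fewer than k_anchor={k_anchor} spots")
        q_S = S[q_rows]

        # Reciprocal projections.
        ref_in_ref = ref_pca.coordinates
        query_in_ref = ref_pca.project(q_S)
        npc_q = min(n_pcs, q_S.shape[0] - 1, q_S.shape[1])
        q_pca = embed_pca(q_S, n_pcs=npc_q)
        query_in_q = q_pca.coordinates
        ref_in_q = q_pca.project(ref_S)

        pairs = _mnn_pairs(ref_in_ref, query_in_ref, k_anchor)
        pairs |= _mnn_pairs(ref_in_q, query_in_q, k_anchor)
        if not pairs:
            raise ValueError(f"no anchors found for query slide {sid}")
        pair_list = sorted(pairs)
        scores = _anchor_scores(pair_list, ref_in_ref, query_in_ref, k_score)

        # Keep, per anchored query spot, the closest pair (summed over both
        # projections); guarantees zero-distance twins win on identical data.
        d = np.array(
            [
                np.linalg.norm(ref_in_ref[r] - query_in_ref[q])
                + np.linalg.norm(ref_in_q[r] - query_in_q[q])
                for r, q in pair_list
            ]
        )
        best: dict[int, int] = {}
        for i, (r, q) in enumerate(pair_list):
            j = best.get(q)
            if j is None or (d[i], pair_list[i][0]) < (d[j], pair_list[j][0]):
                best[q] = i
        keep = sorted(best.values())
        anchors = [pair_list[i] for i in keep]
        a_scores = scores[keep]

        a_ref = np.array([r for r, _ in anchors])
        a_query = np.array([q for _, q in anchors])
        diffs = F[ref_rows[a_ref]] - F[q_rows[a_query]]

        # Weighted correction per query spot in the query PCA space.
        k_use = min(k_weight, len(anchors))
        nn = NearestNeighbors(n_neighbors=k_use).fit(query_in_q[a_query])
        dist, idx = nn.kneighbors(query_in_q)
        bw = np.maximum(dist[:, -1], 1e-12)
        w = np.exp(-(dist**2) / (2.0 * (bw[:, None] / 3.0) ** 2))
        w *= np.maximum(a_scores[idx], 1e-6)
        w /= w.sum(axis=1, keepdims=True)
        correction = np.einsum("ik,ikj->ij", w, diffs[idx])
        corrected[q_rows] = F[q_rows] + correction

        anchor_sets[sid] = AnchorSet(
            pairs=pd.DataFrame(
                {
                    "ref_index": ref_rows[a_ref],
                    "query_index": q_rows[a_query],
                    "score": np.clip(a_scores, 0.0, 1.0),
                }
            ),
            features=features,
            k_anchor=k_anchor,
            k_score=k_score,
        )
    return corrected, anchor_sets
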