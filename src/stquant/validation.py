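"""Validation experiments: recovery of planted truth on synthetic studies.

Each function runs one self-contained experiment — exact-statistic
cross-checks against enumeration oracles, null calibration of the hurdle
model, segmentation/integration/marker/signature/DE recovery — and returns
plain numbers. The test suite asserts on them; the acceptance script
reports them.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import kstest, rankdata
from sklearn.metrics import adjusted_rand_score

from . import simdata
from .diffexpr import bh_adjust, classify_degs, fit_hurdle_gene, run_de
from .markers import minimal_combination, rank_candidates_rf
from .pipeline import PipelineConfig, run_study
from .prep_integrate import (
    embed_pca,
    integrate_rpca,
    log_normalize,
    scale_and_regress,
    select_hvg_vst,
)
from .scoring import wilcoxon_rank_sum
from .segment import cluster_snn_louvain

__all__ = [
    "wilcoxon_vs_enumeration",
    "hypergeom_vs_enumeration",
    "bh_vs_direct",
    "null_expression_study",
    "hurdle_null_calibration",
    "segmentation_recovery",
    "integration_batch_experiment",
    "marker_recovery",
    "signature_effect_experiment",
    "de_recovery",
]


# ---------------------------------------------------------------- oracles

def exact_wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of rank assignments.

    Valid for tie-free samples: counts the fraction of the C(n, n_a)
    equally likely rank assignments whose U statistic deviates from its
    null mean at least as much as the observed one.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, n = len(a), len(a) + len(b)
    ranks = rankdata(np.concatenate([a, b]))
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    m = na * (n - na) / 2.0
    dev = abs(u_obs - m)
    hits = total = 0
    all_ranks = np.arange(1, n + 1)
    for idx in combinations(range(n), na):
        u = all_ranks[list(idx)].sum() - na * (na + 1) / 2
        hits += abs(u - m) >= dev - 1e-9
        total += 1
    return hits / total


def wilcoxon_vs_enumeration(n_instances: int = 1000, seed: int = 0) -> dict:
    """Max |p - p_enum| over random tie-free instances with n_A+n_B <= 8."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        na = int(rng.integers(1, 7))
        nb = int(rng.integers(1, 9 - na))
        vals = rng.permutation(100)[: na + nb].astype(float)
        a, b = vals[:na], vals[na:]
        _, p = wilcoxon_rank_sum(a, b)
        worst = max(worst, abs(p - exact_wilcoxon_p(a, b)))
    return {"max_abs_diff": worst, "n": n_instances}


def hypergeom_vs_enumeration(n_max: int = 15) -> dict:
    """Exhaustive check of the upper-tail hypergeometric p for N <= n_max.

    The oracle sums C(K, j) C(N-K, n-j) / C(N, n) over j >= k directly.
    """
    from scipy.stats import hypergeom

    worst = 0.0
    count = 0
    for N in range(1, n_max + 1):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                lo, hi = max(0, n - (N - K)), min(K, n)
                for k in range(lo, hi + 1):
                    p_oracle = sum(
                        comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1)
                    ) / comb(N, n)
                    p = float(hypergeom.sf(k - 1, N, K, n))
                    worst = max(worst, abs(p - p_oracle))
                    count += 1
    return {"max_abs_diff": worst, "n": count}


def bh_direct(p: np.ndarray) -> np.ndarray:
    """Independent step-up Benjamini-Hochberg implementation."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        out[order[i]] = running
    return out


def bh_vs_direct(n_instances: int = 200, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        p = rng.uniform(size=rng.integers(1, 60))
        worst = max(worst, float(np.max(np.abs(bh_adjust(p) - bh_direct(p)))))
    return {"max_abs_diff": worst, "n": n_instances}


# ------------------------------------------------------ hurdle calibration

def null_expression_study(
    n_spots: int = 200, n_genes: int = 2000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NB-derived log-normalized matrix with a random, effect-free group split.

    Gene means are log-normal around 2 counts/spot so most genes have both
    detected and undetected spots — the regime the hurdle model addresses.
    """
    rng = np.random.default_rng(seed)
    mean_g = rng.lognormal(np.log(2.0), 0.8, size=n_genes)
    lib = rng.lognormal(0.0, 0.25, size=n_spots)
    m = lib[:, None] * mean_g[None, :]
    r = 2.0
    counts = rng.poisson(rng.gamma(r, m / r))
    group = np.zeros(n_spots)
    group[rng.permutation(n_spots)[: n_spots // 2]] = 1.0
    norm = log_normalize(counts)
    Y = np.asarray(norm.values.todense())
    cdr = (counts > 0).mean(axis=1)
    return Y, group, cdr - cdr.mean()


def hurdle_null_calibration(
    n_spots: int = 200, n_genes: int = 2000, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Type-I error and KS uniformity of the hurdle LRT p under the null."""
    Y, group, cdr = null_expression_study(n_spots, n_genes, seed)
    pvals = []
    for j in range(Y.shape[1]):
        fit = fit_hurdle_gene(Y[:, j], group, cdr)
        if fit is not None and fit.df > 0:
            pvals.append(fit.p)
    pvals = np.asarray(pvals)
    ks = kstest(pvals, "uniform").statistic
    return {
        "type1": float(np.mean(pvals < alpha)),
        "ks_stat": float(ks),
        "ks_crit_1pct": 1.628 / np.sqrt(len(pvals)),
        "n": int(len(pvals)),
    }


# ----------------------------------------------------- recovery experiments

def _cluster_study(study, seed: int, n_features: int = 500, resolution: float = 0.15):
    """Normalize -> HVG -> scale (total-count regressed) -> PCA -> SNN+Louvain."""
    norm = log_normalize(study.counts)
    features = select_hvg_vst(
        study.counts, study.shared_genes, n_top=min(n_features, study.n_genes)
    )
    fidx = [study.shared_genes.index(g) for g in features]
    totals = np.asarray(study.counts.sum(axis=1)).ravel()
    scaled = scale_and_regress(norm.values[:, fidx], covariate=totals)
    emb = embed_pca(scaled, n_pcs=min(30, min(scaled.shape) - 1))
    return cluster_snn_louvain(emb, resolution=resolution, seed=seed)


def segmentation_recovery(seed: int = 0) -> dict:
    """ARI of SNN+Louvain at resolution 0.15 vs 9 planted regions, no batch."""
    spec = simdata.default_brain_spec("small").with_(
        n_slides_per_group=1, batch_sigma=0.0
    )
    study, truth = simdata.simulate_study(spec, seed=seed)
    labels = _cluster_study(study, seed=seed)
    return {
        "ari": float(adjusted_rand_score(truth.region.to_numpy(), labels)),
        "n": study.n_spots,
    }


def integration_batch_experiment(seed: int = 0, batch_sigma: float = 0.5) -> dict:
    """Two-slide study with a strong gene-wise batch factor and no biology.

    Measures the reduction of mean per-gene between-batch differences on the
    integration features after RPCA correction, whether clustering recovery
    (ARI vs planted regions) survives correction, and the identity no-op
    (query = bit-identical copy of the reference).
    """
    spec = simdata.default_brain_spec("small", planted_effect=1.0).with_(
        n_slides_per_group=1, batch_sigma=batch_sigma
    )
    study, truth = simdata.simulate_study(spec, seed=seed)
    features = select_hvg_vst(study.counts, study.shared_genes, n_top=500)
    fidx = [study.shared_genes.index(g) for g in features]
    norm = log_normalize(study.counts)
    F = np.asarray(norm.values[:, fidx].todense())
    is_ref = (study.obs["group"] == "WT").to_numpy()

    def batch_diff(M):
        return float(np.mean(np.abs(M[is_ref].mean(0) - M[~is_ref].mean(0))))

    corrected, _ = integrate_rpca(study, {"WT"}, features=features)

    def ari_of(M):
        totals = np.asarray(study.counts.sum(axis=1)).ravel()
        scaled = scale_and_regress(M, covariate=totals)
        emb = embed_pca(scaled, n_pcs=30)
        labels = cluster_snn_louvain(emb, resolution=0.15, seed=seed)
        return float(adjusted_rand_score(truth.region.to_numpy(), labels))

    before, after = batch_diff(F), batch_diff(corrected)

    # Identity no-op: query slide is a bit-identical copy of the reference.
    ref = study.slides[0]
    twin = simdata.SpatialSlide(
        slide_id="copy",
        counts=ref.counts.copy(),
        gene_ids=list(ref.gene_ids),
        gene_names=list(ref.gene_names),
        barcodes=list(ref.barcodes),
        array_row=ref.array_row,
        array_col=ref.array_col,
        pxl_row=ref.pxl_row,
        pxl_col=ref.pxl_col,
        in_tissue=ref.in_tissue,
        mouse_id="copy",
        group="TG",
        plane=ref.plane,
    )
    from .io_spatial import assemble_study

    twin_study = assemble_study([ref, twin])
    corrected_twin, _ = integrate_rpca(twin_study, {"WT"}, features=features)
    F_twin = np.asarray(
        log_normalize(twin_study.counts).values[:, fidx].todense()
    )
    identity_max = float(np.max(np.abs(corrected_twin - F_twin)))

    return {
        "batch_diff_before": before,
        "batch_diff_after": after,
        "reduction_pct": 100.0 * (1.0 - after / before),
        "ari_uncorrected": ari_of(F),
        "ari_corrected": ari_of(corrected),
        "identity_max_correction": identity_max,
        "n": study.n_spots,
    }


def marker_recovery(
    n_seeds: int = 100, seed0: int = 0, n_trees: int = 100
) -> dict:
    """Fraction of seeds where the minimal combination is within the planted
    3-gene marker set of a type with F-beta >= 0.95, at tiny scale.

    Marker selection operates on reference expression profiles (in practice
    cell-type-labeled scRNAseq atlases, where marker genes are close to
    on/off per cell type), so the planted data use a strong marker contrast
    (fold 30) and mild overdispersion (NB size 10) rather than the noisier
    Visium-spot defaults.
    """
    spec = simdata.default_brain_spec("tiny", n_markers=3, theta_marker=30.0).with_(
        n_slides_per_group=1, dispersion=10.0
    )
    regions = spec.region_names
    hits = 0
    for s in range(n_seeds):
        study, truth = simdata.simulate_study(spec, seed=seed0 + s)
        norm = log_normalize(study.counts)
        X = np.asarray(norm.values.todense())
        labels = truth.region.to_numpy()
        target = regions[s % len(regions)]
        cands = rank_candidates_rf(
            X, labels, target, study.shared_genes,
            n_trees=n_trees, n_top=15, seed=seed0 + s,
        )
        genes, fb = minimal_combination(
            cands, X, labels, target, study.shared_genes, max_genes=6
        )
        if set(genes) <= set(truth.markers[target]) and fb >= 0.95:
            hits += 1
    return {"recovery_rate": hits / n_seeds, "n": n_seeds}


def signature_effect_experiment(
    n_runs: int = 50, seed0: int = 0, null: bool = False, scale: str = "tiny"
) -> dict:
    """Full-pipeline recovery of one planted (region, group) signature effect.

    A run succeeds when the planted white-matter TG effect is the unique
    Bonferroni-significant (adjusted p < 0.05) region for the signature.
    With ``null=True`` the effect is absent and any significant region
    counts as a family-wise false positive.
    """
    effect = 1.0 if null else 4.0
    spec = simdata.default_brain_spec(scale, planted_effect=effect)
    unique_hits = any_hit = 0
    for s in range(n_runs):
        cfg = PipelineConfig.from_mapping(
            {"seed": seed0 + s, "simulate": {"spec": spec}}
        )
        res = run_study(cfg)
        rows = res.comparison.rows
        sig = rows[rows["p_adjusted"] < 0.05]
        if null:
            any_hit += int(len(sig) > 0)
        else:
            unique_hits += int(
                len(sig) == 1 and sig.iloc[0]["region"] == "white matter"
            )
    if null:
        return {"familywise_fp_rate": any_hit / n_runs, "n": n_runs}
    return {"unique_detection_rate": unique_hits / n_runs, "n": n_runs}


def de_recovery(seed: int = 0, theta: float = 3.0, n_de_genes: int = 50) -> dict:
    """Sensitivity and empirical FDR for planted fold-change genes in one region.

    Batch factors are off here so that non-planted genes are truly null:
    per-slide batch shifts are real spot-level expression differences
    (confounded with group in a two-group design), which integration — not
    DE — is responsible for; including them would measure the design
    confound, not the method's error rate.
    """
    base = simdata.default_brain_spec("small")
    names = simdata.gene_names(base.genes)
    planted = tuple(names[100 : 100 + n_de_genes])
    spec = base.with_(
        signature_blocks={("thalamus", "TG"): (planted, theta)},
        n_slides_per_group=3,
        batch_sigma=0.0,
    )
    study, truth = simdata.simulate_study(spec, seed=seed)
    from .segment import RegionAssignment

    regions = sorted(set(truth.region))
    idx = {r: i for i, r in enumerate(regions)}
    assignment = RegionAssignment(
        cluster_id=np.array([idx[r] for r in truth.region]),
        region_name_map={i: r for r, i in idx.items()},
        resolution=0.15,
        n_clusters=len(regions),
    )
    result = run_de(study, assignment, "thalamus", "TG", "WT")
    up, down = classify_degs(result)
    passes = set(up) | set(down)
    planted_set = set(planted)
    sens = len(passes & planted_set) / len(planted_set)
    fdr = len(passes - planted_set) / len(passes) if passes else 0.0
    return {
        "sensitivity": sens,
        "empirical_fdr": fdr,
        "n_passes": len(passes),
        "n": study.n_spots,
    }
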