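"""Control-gene-normalized signature scores and per-mouse group comparison.

The signature (module) score of a gene set in a spot is the mean
log-normalized expression of the set minus the mean of pooled control
genes drawn from expression-matched bins: all genes are split into
``n_bins`` equal-frequency bins by dataset-wide average expression and each
set gene contributes ``n_ctrl`` controls from its own bin. The score is a
proxy for the abundance of a cell type/state in a spot; it is zero in
expectation for a random gene set.

The statistical unit for group comparison is the mouse: spot scores are
averaged per (mouse, region) and groups are compared per region with the
two-sided Wilcoxon rank-sum test, Bonferroni-corrected over the declared
family (by default, the regions tested for a signature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from .io_spatial import StudyDataset
from .prep_integrate import NormalizedMatrix
from .segment import UNASSIGNED, RegionAssignment

__all__ = [
    "SignatureTable",
    "GroupComparison",
    "module_score",
    "score_signatures",
    "aggregate_scores",
    "compare_groups",
]


@dataclass
class SignatureTable:
    spot_scores: pd.DataFrame  # one column per signature, indexed like obs
    aggregates: pd.DataFrame  # mouse_id, group, region, signature, mean_score, n_spots
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0


@dataclass
class GroupComparison:
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    family_size: int = 0


def _expression_bins(avg: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin id per gene (bin sizes differ by at most 1)."""
    order = np.argsort(avg, kind="stable")
    bins = np.empty(avg.size, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def module_score(
    norm: NormalizedMatrix | sp.spmatrix | np.ndarray,
    gene_set,
    gene_ids=None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-spot signature score with binned control genes.

    Controls are drawn uniformly without replacement from the set gene's
    expression bin (with replacement when the bin holds fewer than
    ``n_ctrl`` genes); the score is mean(set) - mean(pooled controls).
    Genes absent from the matrix are dropped with a warning.
    """
    if isinstance(norm, NormalizedMatrix):
        X = norm.values
        gene_ids = gene_ids if gene_ids is not None else norm.gene_ids
    else:
        X = norm
    if gene_ids is None or not len(gene_ids):
        raise ValueError("gene_ids required")
    X = sp.csc_matrix(X, dtype=np.float64)
    pos = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in gene_set if g in pos]
    missing = [g for g in gene_set if g not in pos]
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent, dropped: {missing[:5]}")
    if not present:
        raise ValueError("no signature genes present in the matrix")

    avg = np.asarray(X.mean(axis=0)).ravel()
    bins = _expression_bins(avg, n_bins)
    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for g in present:
        i = pos[g]
        pool = np.flatnonzero(bins == bins[i])
        replace = pool.size < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    controls = np.concatenate(ctrl_idx)

    set_idx = np.array([pos[g] for g in present])
    set_mean = np.asarray(X[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, controls].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


def score_signatures(
    norm: NormalizedMatrix,
    gene_sets: dict[str, list[str]],
    obs_index=None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score several signatures; one seeded control draw per signature."""
    cols = {}
    for j, (name, genes) in enumerate(sorted(gene_sets.items())):
        cols[name] = module_score(
            norm, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + j
        )
    return pd.DataFrame(cols, index=obs_index)


def aggregate_scores(
    scores: pd.DataFrame,
    assignment: RegionAssignment,
    study: StudyDataset,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> SignatureTable:
    """Mean score per (mouse, region, signature) with spot counts.

    Spots without a region (unassigned) are excluded; a mouse lacking a
    region contributes no row for it rather than a zero.
    """
    region = assignment.region
    df = scores.copy()
    df["mouse_id"] = study.obs["mouse_id"].to_numpy()
    df["group"] = study.obs["group"].to_numpy()
    df["region"] = region
    n_dropped = int((df["region"] == UNASSIGNED).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} spots without region excluded from aggregates")
    df = df[df["region"] != UNASSIGNED]
    long = df.melt(
        id_vars=["mouse_id", "group", "region"],
        var_name="signature",
        value_name="score",
    )
    agg = (
        long.groupby(["mouse_id", "group", "region", "signature"], observed=True)
        .agg(mean_score=("score", "mean"), n_spots=("score", "size"))
        .reset_index()
    )
    return SignatureTable(
        spot_scores=scores, aggregates=agg, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
    )


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) statistic and p-value.

    Exact null distribution when n_a + n_b <= 10 with no ties; normal
    approximation with tie correction (and continuity correction)
    otherwise. All-tied small samples return p = 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    method = "exact" if (len(a) + len(b) <= 10 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    table: SignatureTable,
    group_a: str,
    group_b: str,
    family: str | int = "per_signature_regions",
) -> GroupComparison:
    """Wilcoxon rank-sum on per-mouse aggregates, Bonferroni-adjusted.

    ``family`` is either ``"per_signature_regions"`` (the number of regions
    tested for each signature) or an explicit integer family size; the
    family used is recorded in the output.
    """
    agg = table.aggregates
    rows = []
    for signature, sub in agg.groupby("signature", observed=True):
        per_region = []
        for region, r_sub in sub.groupby("region", observed=True):
            va = r_sub.loc[r_sub["group"] == group_a, "mean_score"].to_numpy()
            vb = r_sub.loc[r_sub["group"] == group_b, "mean_score"].to_numpy()
            if len(va) == 0 or len(vb) == 0:
                continue
            stat, p = wilcoxon_rank_sum(va, vb)
            diff = np.median(va) - np.median(vb)
            per_region.append(
                dict(
                    region=region,
                    signature=signature,
                    group_A=group_a,
                    group_B=group_b,
                    n_A=len(va),
                    n_B=len(vb),
                    W=stat,
                    p_raw=p,
                    direction=int(np.sign(diff)),
                )
            )
        m = len(per_region) if family == "per_signature_regions" else int(family)
        for row in per_region:
            row["family_m"] = m
            row["p_adjusted"] = min(1.0, m * row["p_raw"])
            rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "region", "signature", "group_A", "group_B", "n_A", "n_B",
            "W", "p_raw", "p_adjusted", "direction", "family_m",
        ],
    )
    fam = int(df["family_m"].max()) if len(df) else 0
    return GroupComparison(rows=df, family_size=fam)
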