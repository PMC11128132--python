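"""Minimal marker-gene combination selection and panel curation.

The selection procedure is NSForest-style: genes are first ranked for a
target cluster by random-forest importance (one-vs-rest), the top
candidates are re-ranked by a binary expression score, and the minimal
combination of genes whose conjunction of per-gene expression thresholds
best recovers the cluster (by F-beta, precision-weighted beta=0.5 by
default) becomes the marker set.

Curation applies the reproducible counterparts of visual panel cleanup:
blocklist patterns (ribosomal ``Rpl*``/``Rps*`` and similar), explicit
cross-expression maps (genes shared with major cell types, e.g. microglial
genes contaminating a T-cell panel), removal of genes absent from the
dataset, and flagging of ubiquitously detected genes.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MarkerEntry",
    "MarkerPanel",
    "binary_scores",
    "rank_candidates_rf",
    "minimal_combination",
    "apply_curation",
    "build_panel",
]

ACTIVE = "active"
REMOVED_BLOCKLIST = "removed-blocklist"
REMOVED_CROSSEXPR = "removed-crossexpression"
REMOVED_ABSENT = "removed-absent"
REMOVED_MANUAL = "removed-manual"


@dataclass
class MarkerEntry:
    genes: list[str]
    fbeta: float
    provenance: dict[str, str] = field(default_factory=dict)  # gene -> source
    status: dict[str, str] = field(default_factory=dict)  # gene -> status
    reasons: dict[str, str] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)  # ubiquitous, kept pending review

    def __post_init__(self):
        for g in self.genes:
            self.provenance.setdefault(g, "nsforest")
            self.status.setdefault(g, ACTIVE)

    @property
    def active_genes(self) -> list[str]:
        return [g for g in self.genes if self.status.get(g) == ACTIVE]


@dataclass
class MarkerPanel:
    entries: dict[str, MarkerEntry] = field(default_factory=dict)

    def gene_sets(self) -> dict[str, list[str]]:
        return {ct: e.active_genes for ct, e in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_type": ct,
                "gene": g,
                "provenance": e.provenance.get(g, "nsforest"),
                "status": e.status.get(g, ACTIVE),
                "reason": e.reasons.get(g, ""),
                "fbeta": e.fbeta,
            }
            for ct, e in self.entries.items()
            for g in e.genes
        ]
        return pd.DataFrame(rows, columns=["cell_type", "gene", "provenance", "status", "reason", "fbeta"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        obj = {
            ct: {
                "genes": e.genes,
                "fbeta": e.fbeta,
                "provenance": e.provenance,
                "status": e.status,
                "reasons": e.reasons,
                "flagged": e.flagged,
            }
            for ct, e in self.entries.items()
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def read_json(cls, path) -> "MarkerPanel":
        obj = json.loads(Path(path).read_text())
        entries = {
            ct: MarkerEntry(
                genes=v["genes"],
                fbeta=v.get("fbeta", float("nan")),
                provenance=v.get("provenance", {}),
                status=v.get("status", {}),
                reasons=v.get("reasons", {}),
                flagged=v.get("flagged", []),
            )
            for ct, v in obj.items()
        }
        return cls(entries=entries)


def _as_dense(expr) -> np.ndarray:
    return np.asarray(expr.todense() if sp.issparse(expr) else expr, dtype=np.float64)


def binary_scores(expr, labels, target) -> np.ndarray:
    """Per-gene specificity for the target cluster, in [0, 1].

    ``score(g) = 1 - mean_c min(1, median_c(g) / median_target(g))`` over
    non-target clusters c; genes not expressed in the target median get 0.
    A gene whose median expression is exclusive to the target scores 1.
    """
    X = _as_dense(expr)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("binary_scores needs at least two clusters")
    if target not in clusters:
        raise ValueError(f"target {target!r} not among cluster labels")
    med_target = np.median(X[labels == target], axis=0)
    others = [c for c in clusters if c != target]
    ratios = np.zeros((len(others), X.shape[1]))
    for i, c in enumerate(others):
        med_c = np.median(X[labels == c], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(med_target > 0, med_c / med_target, np.inf)
        ratios[i] = np.minimum(1.0, r)
    score = 1.0 - ratios.mean(axis=0)
    score[med_target <= 0] = 0.0
    return np.clip(score, 0.0, 1.0)


def rank_candidates_rf(
    expr,
    labels,
    target,
    gene_ids: Sequence[str],
    n_trees: int = 1000,
    n_top: int = 15,
    seed: int = 0,
) -> list[str]:
    """Top candidate markers: RF importance filter, then binary-score order."""
    X = _as_dense(expr)
    labels = np.asarray(labels)
    y = (labels == target).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("degenerate labels: target must be a proper subset")
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, max_features="sqrt"
    )
    rf.fit(X, y)
    imp = rf.feature_importances_
    top = np.argsort(-imp, kind="stable")[:n_top]
    bscores = binary_scores(X[:, top], labels, target)
    order = np.argsort(-bscores, kind="stable")
    return [gene_ids[top[i]] for i in order]


def _stump_threshold(x: np.ndarray, y: np.ndarray) -> float:
    """Split value of a depth-1 decision stump for target-vs-rest."""
    tree = DecisionTreeClassifier(max_depth=1, random_state=0)
    tree.fit(x.reshape(-1, 1), y)
    thr = tree.tree_.threshold[0]
    if thr == -2.0:  # no split found (constant feature)
        return np.inf
    return float(thr)


def fbeta_score_binary(pred: np.ndarray, truth: np.ndarray, beta: float) -> float:
    tp = float(np.sum(pred & truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    denom = (1 + beta**2) * tp + beta**2 * fn + fp
    return (1 + beta**2) * tp / denom if denom > 0 else 0.0


def minimal_combination(
    candidates: Sequence[str],
    expr,
    labels,
    target,
    gene_ids: Sequence[str],
    max_genes: int = 6,
    beta: float = 0.5,
    tol: float = 1e-9,
) -> tuple[list[str], float]:
    """Smallest gene combination whose threshold conjunction best marks the target.

    Every combination of 1..max_genes candidates is scored: a spot is
    predicted positive when all genes exceed their per-gene stump
    thresholds; the F-beta against target membership is the combination
    score. The smallest combination within ``tol`` of the best score wins,
    ties broken by candidate rank order.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    X = _as_dense(expr)
    labels = np.asarray(labels)
    truth = labels == target
    pos = {g: i for i, g in enumerate(gene_ids)}
    cand_idx = [pos[g] for g in candidates]
    above = np.zeros((len(candidates), X.shape[0]), dtype=bool)
    for j, gi in enumerate(cand_idx):
        thr = _stump_threshold(X[:, gi], truth.astype(int))
        above[j] = X[:, gi] > thr

    results = []  # (k, rank_tuple, score, combo)
    for k in range(1, min(max_genes, len(candidates)) + 1):
        for combo in combinations(range(len(candidates)), k):
            pred = np.all(above[list(combo)], axis=0)
            score = fbeta_score_binary(pred, truth, beta)
            results.append((k, combo, score))
    best_score = max(r[2] for r in results)
    eligible = [r for r in results if r[2] >= best_score - tol]
    k_min = min(r[0] for r in eligible)
    winner = min((r for r in eligible if r[0] == k_min), key=lambda r: r[1])
    return [candidates[i] for i in winner[1]], winner[2]


def build_panel(
    expr,
    labels,
    gene_ids: Sequence[str],
    targets: Sequence | None = None,
    n_trees: int = 1000,
    n_top: int = 15,
    max_genes: int = 6,
    beta: float = 0.5,
    seed: int = 0,
) -> MarkerPanel:
    """Run candidate ranking + minimal combination for each target cluster."""
    labels = np.asarray(labels)
    if targets is None:
        targets = list(np.unique(labels))
    panel = MarkerPanel()
    for t in targets:
        cands = rank_candidates_rf(
            expr, labels, t, gene_ids, n_trees=n_trees, n_top=n_top, seed=seed
        )
        genes, fb = minimal_combination(
            cands, expr, labels, t, gene_ids, max_genes=max_genes, beta=beta
        )
        panel.entries[str(t)] = MarkerEntry(genes=genes, fbeta=fb)
    return panel


def apply_curation(
    panel: MarkerPanel,
    dataset_genes: Sequence[str],
    blocklist: Sequence[str] = (),
    crossexpr: dict[str, str] | None = None,
    manual_remove: dict[str, Sequence[str]] | None = None,
    max_detect_frac: float = 0.5,
    expr=None,
) -> MarkerPanel:
    """Apply curation filters, recording a removal reason per gene.

    Order: blocklist patterns, cross-expression map, absence from the
    dataset, manual per-cell-type removals. If ``expr`` (study matrix,
    spot x dataset_genes) is given, active genes detected in more than
    ``max_detect_frac`` of spots are flagged for review (not removed).
    An entry left without active genes raises, naming the cell type.
    """
    crossexpr = crossexpr or {}
    manual_remove = manual_remove or {}
    gene_set = set(dataset_genes)
    detect_frac = None
    if expr is not None:
        X = expr
        nz = (X > 0).sum(axis=0)
        detect_frac = dict(
            zip(dataset_genes, np.asarray(nz).ravel() / X.shape[0])
        )

    for ct, entry in panel.entries.items():
        for g in entry.genes:
            if any(fnmatch.fnmatch(g, pat) for pat in blocklist):
                entry.status[g] = REMOVED_BLOCKLIST
                entry.reasons[g] = "blocklist pattern"
            elif g in crossexpr:
                entry.status[g] = REMOVED_CROSSEXPR
                entry.reasons[g] = crossexpr[g]
            elif g not in gene_set:
                entry.status[g] = REMOVED_ABSENT
                entry.reasons[g] = "absent from dataset"
            elif g in manual_remove.get(ct, ()):
                entry.status[g] = REMOVED_MANUAL
                entry.reasons[g] = "manual curation"
        if detect_frac is not None:
            entry.flagged = [
                g
                for g in entry.active_genes
                if detect_frac.get(g, 0.0) > max_detect_frac
            ]
        if not entry.active_genes:
            raise ValueError(f"curation removed every gene for cell type {ct!r}")
    return panel
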