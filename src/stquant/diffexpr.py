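"""Hurdle-model differential expression and gene-set overrepresentation.

Spot-level expression after log-normalization is zero-inflated and roughly
continuous where detected, so each gene is modelled with a two-part
(hurdle) model: a logistic regression for detection (y > 0) and a Gaussian
linear model for the positive values, both with the group label and the
centered cellular detection rate (CDR; fraction of genes detected per spot)
as covariates. The group effect is tested jointly across the two parts by a
likelihood-ratio chi-square with df = number of parts where the group term
is estimable.

DEG classification applies FDR-adjusted p < 0.05, |logFC| > 0.25 (natural
log scale), and an abundance guard on the detection fraction.
Overrepresentation of gene sets among DEGs uses the upper-tail
hypergeometric test with Benjamini-Hochberg correction and reports the
count ratio (DEG-proportion over universe-proportion of each term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2, hypergeom
from statsmodels.stats.multitest import multipletests

from .io_spatial import StudyDataset
from .prep_integrate import log_normalize
from .segment import RegionAssignment

__all__ = [
    "HurdleFit",
    "DEResult",
    "ORAResult",
    "fit_hurdle_gene",
    "run_de",
    "classify_degs",
    "run_ora",
    "read_gmt",
    "bh_adjust",
]


@dataclass
class HurdleFit:
    gene: str
    discrete_coef: np.ndarray | None  # (intercept, group, cdr)
    continuous_coef: np.ndarray | None
    residual_var: float
    lrt_chi2: float
    df: int
    p: float
    converged: bool = True


@dataclass
class DEResult:
    region: str
    group_a: str
    group_b: str
    table: pd.DataFrame  # gene, log_fc, pct_A, pct_B, mean_count_A/B, p_raw, p_fdr, passes


@dataclass
class ORAResult:
    table: pd.DataFrame  # term_id, term_name, k_overlap, n_degs, K_term, N_universe, count_ratio, p_raw, p_bh, genes


def _logistic_loglik(X, y, beta):
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_logistic(X, y, ridge: float = 0.0, max_iter: int = 50, tol: float = 1e-10):
    """Newton-IRLS logistic fit; returns (beta, loglik, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, _logistic_loglik(X, y, beta), False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, _logistic_loglik(X, y, beta), True
        if np.max(np.abs(beta)) > 1e3:
            return beta, _logistic_loglik(X, y, beta), False
    return beta, _logistic_loglik(X, y, beta), False


def _logistic_lrt(X_full, X_null, y, ridge_fallback: float = 1e-4):
    beta_f, ll_f, ok_f = _fit_logistic(X_full, y)
    if not ok_f or np.max(np.abs(beta_f)) > 30:
        # perfect or quasi-separation: ridge-stabilized refit
        beta_f, ll_f, _ = _fit_logistic(X_full, y, ridge=ridge_fallback)
        beta_n, ll_n, _ = _fit_logistic(X_null, y, ridge=ridge_fallback)
        return beta_f, max(0.0, 2.0 * (ll_f - ll_n)), False
    _, ll_n, _ = _fit_logistic(X_null, y)
    return beta_f, max(0.0, 2.0 * (ll_f - ll_n)), True


def _gaussian_lrt(X_full, X_null, y):
    """OLS LRT with MLE variance: chi2 = n * log(RSS_null / RSS_full)."""
    n = y.size
    beta_f, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_f = float(np.sum((y - X_full @ beta_f) ** 2))
    beta_n, _, _, _ = np.linalg.lstsq(X_null, y, rcond=None)
    rss_n = float(np.sum((y - X_null @ beta_n) ** 2))
    if rss_f <= 0:
        return beta_f, 0.0, 0.0
    return beta_f, rss_f / n, max(0.0, n * np.log(rss_n / rss_f))


def fit_hurdle_gene(
    y: np.ndarray, group: np.ndarray, cdr: np.ndarray, gene: str = ""
) -> HurdleFit | None:
    """Two-part hurdle fit and joint likelihood-ratio test of the group term.

    ``y`` is log-normalized expression, ``group`` a binary indicator and
    ``cdr`` the centered per-spot detection fraction. Returns None for
    all-zero genes (no detected spots). A part where the group coefficient
    is not estimable (all spots detected / none, or positives confined to
    one group, or fewer than 3 positives) contributes no degree of freedom.
    """
    y = np.asarray(y, float)
    group = np.asarray(group, float)
    cdr = np.asarray(cdr, float)
    detected = (y > 0).astype(float)
    if detected.sum() == 0:
        return None

    X_full = np.column_stack([np.ones_like(y), group, cdr])
    X_null = np.column_stack([np.ones_like(y), cdr])

    chi2_stat, df = 0.0, 0
    disc_coef, cont_coef, resid_var = None, None, np.nan
    converged = True

    if 0 < detected.sum() < y.size:
        disc_coef, stat, ok = _logistic_lrt(X_full, X_null, detected)
        chi2_stat += stat
        df += 1
        converged &= ok

    pos = y > 0
    if pos.sum() >= 3 and np.unique(group[pos]).size > 1:
        cont_coef, resid_var, stat = _gaussian_lrt(X_full[pos], X_null[pos], y[pos])
        chi2_stat += stat
        df += 1

    if df == 0:
        return HurdleFit(gene, disc_coef, cont_coef, resid_var, 0.0, 0, 1.0, converged)
    p = float(chi2.sf(chi2_stat, df))
    return HurdleFit(gene, disc_coef, cont_coef, resid_var, chi2_stat, df, p, converged)


def run_de(
    study: StudyDataset,
    assignment: RegionAssignment,
    region: str,
    group_a: str,
    group_b: str,
    scale_factor: float = 10000.0,
    genes: Sequence[str] | None = None,
) -> DEResult:
    """Hurdle-model DE between two groups within one region's spots.

    Spots are pooled across slides; log fold change is the difference of
    mean log-normalized expression (A - B); detection fractions and mean
    raw counts are reported per group; BH adjustment is across the genes
    tested within the region.
    """
    regions = assignment.region
    in_region = regions == region
    grp = study.obs["group"].to_numpy()
    mask_a = in_region & (grp == group_a)
    mask_b = in_region & (grp == group_b)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(
            f"region {region!r} lacks spots for group "
            f"{group_a if mask_a.sum() == 0 else group_b!r}"
        )
    sel = mask_a | mask_b
    counts = study.counts[sel]
    norm = log_normalize(counts, scale_factor=scale_factor)
    Y = np.asarray(norm.values.todense())
    group_ind = (grp[sel] == group_a).astype(float)
    cdr = np.asarray((counts > 0).sum(axis=1)).ravel() / counts.shape[1]
    cdr = cdr - cdr.mean()

    gene_list = list(study.shared_genes) if genes is None else list(genes)
    pos_of = {g: i for i, g in enumerate(study.shared_genes)}

    rows = []
    a_rows, b_rows = group_ind == 1, group_ind == 0
    for g in gene_list:
        j = pos_of[g]
        y = Y[:, j]
        fit = fit_hurdle_gene(y, group_ind, cdr, gene=g)
        if fit is None:
            continue
        rows.append(
            dict(
                region=region,
                gene=g,
                log_fc=float(y[a_rows].mean() - y[b_rows].mean()),
                pct_A=float((y[a_rows] > 0).mean()),
                pct_B=float((y[b_rows] > 0).mean()),
                mean_count_A=float(counts[a_rows][:, j].mean()),
                mean_count_B=float(counts[b_rows][:, j].mean()),
                p_raw=fit.p,
                lrt_chi2=fit.lrt_chi2,
                df=fit.df,
            )
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_fdr"] = bh_adjust(table["p_raw"].to_numpy())
    else:
        table["p_fdr"] = []
    return DEResult(region=region, group_a=group_a, group_b=group_b, table=table)


def classify_degs(
    result: DEResult,
    fdr_thr: float = 0.05,
    lfc_thr: float = 0.25,
    min_pct: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Split passing genes into up/down lists.

    A gene passes iff p_fdr < fdr_thr, |log_fc| > lfc_thr and
    max(pct_A, pct_B) >= min_pct (the abundance criterion).
    """
    t = result.table
    if not len(t):
        return [], []
    passes = (
        (t["p_fdr"] < fdr_thr)
        & (t["log_fc"].abs() > lfc_thr)
        & (t[["pct_A", "pct_B"]].max(axis=1) >= min_pct)
    )
    t = t.assign(passes=passes)
    result.table = t
    up = t.loc[passes & (t["log_fc"] > 0), "gene"].tolist()
    down = t.loc[passes & (t["log_fc"] < 0), "gene"].tolist()
    return up, down


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """GMT gene-set collection: term_id -> (description, genes)."""
    out: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        out[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return out


def run_ora(
    degs: Sequence[str],
    universe: Sequence[str],
    gene_sets: dict[str, tuple[str, list[str]]],
    min_overlap: int = 1,
) -> ORAResult:
    """Upper-tail hypergeometric overrepresentation of each term among DEGs.

    k = |degs ∩ term|, p = P(X >= k) with X ~ Hypergeom(N=|universe|,
    K=|term ∩ universe|, n=|degs|); count_ratio = (k/n)/(K/N); BH across
    the tested terms. Terms with k < min_overlap (or empty intersection
    with the universe) are skipped.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    deg_in = [g for g in dict.fromkeys(degs) if g in universe_set]
    dropped = len(set(degs)) - len(deg_in)
    if dropped:
        warnings.warn(f"{dropped} DEGs outside the universe dropped")
    if not deg_in:
        raise ValueError("no DEGs within the universe")
    N, n = len(universe_set), len(deg_in)
    deg_set = set(deg_in)

    rows = []
    for term_id, (name, genes_) in gene_sets.items():
        term_genes = set(genes_) & universe_set
        K = len(term_genes)
        if K == 0:
            continue
        overlap = sorted(deg_set & term_genes)
        k = len(overlap)
        if k < min_overlap:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            dict(
                term_id=term_id,
                term_name=name,
                k_overlap=k,
                n_degs=n,
                K_term=K,
                N_universe=N,
                count_ratio=(k / n) / (K / N),
                p_raw=p,
                genes=",".join(overlap),
            )
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_bh"] = bh_adjust(table["p_raw"].to_numpy())
        table = table.sort_values("p_raw", kind="stable").reset_index(drop=True)
    return ORAResult(table=table)
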