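"""OLS machinery for guide-level interaction and discrepancy statistics.

Three small fixed-effects models carry the audit:

* the delta coefficient — mean LFC difference between a guide of interest
  and the clean guides targeting the same gene, across cell lines, from the
  model y_ij = alpha + beta_i + delta * 1(j = guide of interest) + r_ij with
  sum-to-zero cell effects;
* the additivity test — a three-group means model for guides targeting gene
  A only, gene B only, or both, with a t test of the linear contrast
  beta_A + beta_B - beta_AB = 0 (synthetic lethality drives it negative);
* the design-system solver — OLS gene scores from an arbitrary guide x gene
  incidence matrix, reporting the score covariance the design induces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import GuideAlignmentSummary
from .stats import benjamini_hochberg, pearson_with_p

__all__ = [
    "DeltaModelFit",
    "AdditivityFit",
    "DesignFit",
    "delta_coefficient",
    "additivity_test",
    "expected_min_lfc",
    "solve_design_ols",
    "coessentiality_edges",
    "self_expression_screen",
]


@dataclass(frozen=True)
class DeltaModelFit:
    delta: float
    se_delta: float
    t_delta: float
    p_value: float
    alpha: float
    cell_effects: np.ndarray
    n_cells: int
    n_guides: int
    residuals: np.ndarray  # n_cells x n_guides


def delta_coefficient(y: np.ndarray) -> DeltaModelFit:
    """Delta coefficient of the first-column guide against clean guides.

    ``y`` is an n_cells x n_guides matrix of LFCs; column 0 is the guide of
    interest and columns 1.. are clean guides for the same gene. The model
    y_ij = alpha + beta_i + delta * 1(j=0) + r_ij is fit by OLS with
    sum-to-zero cell effects; delta is invariant to that identifiability
    choice and equals the across-cell mean of (guide LFC - clean-guide mean).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("delta_coefficient: y must be 2-D (cells x guides)")
    n, n_g = y.shape
    if n < 2:
        raise ValueError("delta_coefficient: need at least 2 cell lines")
    if n_g < 2:
        raise ValueError("delta_coefficient: need at least one clean guide")
    # Design: intercept, n-1 effect-coded cell columns, delta indicator.
    obs = y.ravel()  # cell-major
    cells = np.repeat(np.arange(n), n_g)
    is_interest = np.tile(np.arange(n_g) == 0, n).astype(float)
    X = np.zeros((n * n_g, 1 + (n - 1) + 1))
    X[:, 0] = 1.0
    for i in range(n - 1):
        X[cells == i, 1 + i] = 1.0
        X[cells == n - 1, 1 + i] = -1.0
    X[:, -1] = is_interest
    beta, *_ = np.linalg.lstsq(X, obs, rcond=None)
    fitted = X @ beta
    resid = obs - fitted
    dof = n * n_g - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(X.T @ X)
    delta = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    t = delta / se if se > 0 else float("nan")
    p = 2 * float(sps.t.sf(abs(t), dof)) if dof > 0 else float("nan")
    cell_eff = np.append(beta[1:-1], -np.sum(beta[1:-1]))
    return DeltaModelFit(
        delta=delta,
        se_delta=se,
        t_delta=t,
        p_value=p,
        alpha=float(beta[0]),
        cell_effects=cell_eff,
        n_cells=n,
        n_guides=n_g,
        residuals=resid.reshape(n, n_g),
    )


@dataclass(frozen=True)
class AdditivityFit:
    beta_a: float
    beta_b: float
    beta_ab: float
    se: tuple[float, float, float]
    p_values: tuple[float, float, float]
    contrast: float  # beta_a + beta_b - beta_ab
    se_contrast: float
    t_contrast: float
    p_contrast: float
    n_obs: tuple[int, int, int]


def additivity_test(
    y_a: Sequence[float],
    y_b: Sequence[float],
    y_ab: Sequence[float],
    cell_ids: tuple[Sequence, Sequence, Sequence] | None = None,
) -> AdditivityFit:
    """Test whether the digenic knockout effect is the sum of the single ones.

    Pools guide x cell observations per class as exchangeable replicates and
    fits the three-group means model by OLS; the additivity hypothesis
    beta_A + beta_B = beta_AB is tested with a two-sided t test on the
    contrast. When ``cell_ids`` is given, cluster-robust (by cell line)
    standard errors replace the classical ones, since observations from the
    same cell line share its knockout context.
    """
    ya = np.asarray(y_a, dtype=float)
    yb = np.asarray(y_b, dtype=float)
    yab = np.asarray(y_ab, dtype=float)
    if min(ya.size, yb.size, yab.size) == 0:
        raise ValueError("additivity_test: every guide class must be non-empty")
    means = (float(ya.mean()), float(yb.mean()), float(yab.mean()))
    ns = (ya.size, yb.size, yab.size)
    n_total = sum(ns)
    dof = n_total - 3
    rss = sum(float(((v - m) ** 2).sum()) for v, m in zip((ya, yb, yab), means))
    sigma2 = rss / dof if dof > 0 else float("nan")

    if cell_ids is None:
        var_means = tuple(sigma2 / n for n in ns)
    else:
        # Cluster-robust variance of each class mean (clusters = cell lines).
        var_means = []
        for v, m, cid in zip((ya, yb, yab), means, cell_ids):
            cid = np.asarray(cid)
            resid = v - m
            cluster_sums = np.array([resid[cid == c].sum() for c in np.unique(cid)])
            g = cluster_sums.size
            corr = g / (g - 1) if g > 1 else 1.0
            var_means.append(corr * float((cluster_sums**2).sum()) / v.size**2)
        var_means = tuple(var_means)

    se = tuple(np.sqrt(v) for v in var_means)
    p_each = tuple(
        2 * float(sps.t.sf(abs(m / s), dof)) if s > 0 else float("nan")
        for m, s in zip(means, se)
    )
    contrast = means[0] + means[1] - means[2]
    se_c = float(np.sqrt(sum(var_means)))
    t_c = contrast / se_c if se_c > 0 else float("nan")
    p_c = 2 * float(sps.t.sf(abs(t_c), dof)) if dof > 0 else float("nan")
    return AdditivityFit(
        beta_a=means[0],
        beta_b=means[1],
        beta_ab=means[2],
        se=se,
        p_values=p_each,
        contrast=contrast,
        se_contrast=se_c,
        t_contrast=t_c,
        p_contrast=p_c,
        n_obs=ns,
    )


def expected_min_lfc(y_a: float, y_b: float) -> float:
    """Minimum LFC expected from two knockouts without genetic interaction."""
    if not (np.isfinite(y_a) and np.isfinite(y_b)):
        raise ValueError("expected_min_lfc: inputs must be finite")
    return min(y_a, y_b, y_a + y_b)


@dataclass(frozen=True)
class DesignFit:
    scores: pd.Series  # per-gene estimates; NaN where unidentifiable
    cov: pd.DataFrame  # score covariance on the identifiable genes
    unidentifiable: tuple[str, ...]
    rank: int
    residual_var: float


def solve_design_ols(incidence: pd.DataFrame, y: pd.Series) -> DesignFit:
    """OLS gene scores from a guide x gene incidence matrix.

    Minimizes sum over guides of (y_g - sum_genes incidence * beta)^2.
    Genes with a component in the design null space are reported
    unidentifiable (NaN score) and the remaining columns are re-solved; the
    returned covariance exposes the correlation structure the guide design
    induces between gene scores.
    """
    X = incidence.loc[y.index].to_numpy(dtype=float)
    genes = list(incidence.columns)
    yv = y.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    unident: list[str] = []
    if rank < len(genes):
        _, s, vt = np.linalg.svd(X)
        null_space = vt[rank:]
        involved = np.any(np.abs(null_space) > 1e-8, axis=0)
        unident = [g for g, bad in zip(genes, involved) if bad]
        keep = [g for g in genes if g not in unident]
        X = incidence.loc[y.index, keep].to_numpy(dtype=float)
        if keep and np.linalg.matrix_rank(X) < len(keep):
            raise np.linalg.LinAlgError("design still rank-deficient after null-space removal")
    else:
        keep = genes
    scores = pd.Series(np.nan, index=genes, dtype=float)
    if keep:
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        scores.loc[keep] = beta
        resid = yv - X @ beta
        dof = yv.size - len(keep)
        sigma2 = float(resid @ resid) / dof if dof > 0 else float("nan")
        xtx_inv = np.linalg.inv(X.T @ X)
        cov = pd.DataFrame(sigma2 * xtx_inv, index=keep, columns=keep)
    else:
        sigma2 = float("nan")
        cov = pd.DataFrame()
    return DesignFit(
        scores=scores,
        cov=cov,
        unidentifiable=tuple(unident),
        rank=int(rank),
        residual_var=sigma2,
    )


def coessentiality_edges(scores: pd.DataFrame, r_cutoff: float = 0.35) -> pd.DataFrame:
    """Undirected edges between genes whose score profiles correlate.

    ``scores`` is genes x cell lines; an edge joins every pair with Pearson
    r >= ``r_cutoff``. Constant rows are excluded with a warning.
    """
    import warnings

    if scores.shape[1] < 3:
        raise ValueError("coessentiality_edges: need at least 3 cell lines")
    variable = scores.std(axis=1) > 0
    if (~variable).any():
        warnings.warn(
            f"coessentiality_edges: excluding constant genes {list(scores.index[~variable])}"
        )
    sub = scores.loc[variable]
    corr = np.corrcoef(sub.to_numpy(dtype=float))
    genes = list(sub.index)
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if corr[i, j] >= r_cutoff:
                rows.append({"gene_a": genes[i], "gene_b": genes[j], "r": float(corr[i, j])})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])


def self_expression_screen(
    gene_scores: pd.DataFrame,
    expression: pd.DataFrame,
    summaries: Mapping[str, GuideAlignmentSummary],
    guide_to_gene: Mapping[str, str | None],
) -> pd.DataFrame:
    """Rank genes by anticorrelation of their essentiality score with their
    own expression, annotating mismatch-tolerant off-target candidates.

    Genes essential only where expressed correlate negatively; when such a
    gene also has a guide with a single-mismatch alignment in another gene's
    exon, the apparent dependency may instead be driven by the off-target
    (the confounding pattern this audit is after). Returns one row per gene
    with r, raw p, BH q, the off-target flag and the off-target gene ids.
    """
    import logging

    log = logging.getLogger(__name__)
    offtargets: dict[str, set[str]] = {}
    for gid, s in summaries.items():
        gene = guide_to_gene.get(gid)
        if gene is None:
            continue
        hit = {g for g in s.genes_hit_1mm if g != gene}
        if hit:
            offtargets.setdefault(gene, set()).update(hit)
    rows = []
    cells = gene_scores.columns.intersection(expression.columns)
    for gene in gene_scores.index:
        if gene not in expression.index:
            log.info("self_expression_screen: %s absent from expression, dropped", gene)
            continue
        score = gene_scores.loc[gene, cells].to_numpy(dtype=float)
        expr = expression.loc[gene, cells].to_numpy(dtype=float)
        try:
            r, p = pearson_with_p(score, expr)
        except ValueError:
            continue
        ot = sorted(offtargets.get(gene, ()))
        rows.append(
            {
                "gene_id": gene,
                "r_self_expression": r,
                "p_value": p,
                "has_exonic_1mm_offtarget": bool(ot),
                "offtarget_genes": ",".join(ot),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "r_self_expression",
            "p_value",
            "has_exonic_1mm_offtarget",
            "offtarget_genes",
        ],
    )
    if not table.empty:
        table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
        table = table.sort_values("r_self_expression").reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
    return table
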