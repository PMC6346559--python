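"""End-to-end audit pipeline: align, summarize, model, and flag.

``run_audit`` chains the stages over one input bundle: guide alignment and
annotation, toxicity-curve fitting and adjustment, per-guide off-target
delta coefficients, the self-expression confounder screen, SNP
genotype-LFC analysis, and the double-mismatch problem-guide screen. Each
stage is a pure function of its inputs and the configuration; all
randomness (permutation nulls, the delta null band) is seeded.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .alignment import (
    Alignment,
    ExonAnnotation,
    Genome,
    GuideAlignmentSummary,
    GuideRecord,
    annotate_alignment,
    find_alignments,
    gene_summary_table,
    is_clean,
    summarize_guide,
)
from .interactions import delta_coefficient, self_expression_screen
from .snp import (
    SNPRecord,
    classify_snp_effect,
    intersect_snps_with_targets,
    permutation_null,
    position_stratified_correlations,
)
from .toxicity import adjust_for_toxicity, fit_toxicity_curve

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AuditReport", "run_audit", "align_library", "select_problematic_double_mm"]

ALL_STAGES = ("align", "toxicity", "delta", "self_expression", "snp", "double_mm")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for the audit stages.

    Thresholds follow the audit's conventions: a guide is highly active at
    LFC <= -0.5, an off-target delta coefficient below -0.25 is substantial,
    and a gene counts as expressed at log2(rpkm+1) >= 4.
    """

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    clean_level: str = "1mm"
    max_mm: int = 2
    substantial_delta: float = -0.25
    high_activity_lfc: float = -0.5
    expression_threshold: float = 4.0
    permutation_B: int = 100
    cn_knots: int = 4
    toxicity_n_max: int = 8
    flag_top_fraction: float = 0.1
    double_mm_min_alignments: int = 5
    double_mm_first_position: int = 20
    null_band_genes: int = 1000

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages {sorted(unknown)}")


@dataclass
class AuditReport:
    config: PipelineConfig
    alignments: pd.DataFrame | None = None
    guide_summaries: dict[str, GuideAlignmentSummary] = field(default_factory=dict)
    gene_table: pd.DataFrame | None = None
    toxicity_curves: pd.DataFrame | None = None
    lfc_adjusted: pd.DataFrame | None = None
    delta_table: pd.DataFrame | None = None
    self_expression: pd.DataFrame | None = None
    flagged_genes: pd.DataFrame | None = None
    snp_pairs: pd.DataFrame | None = None
    snp_position_comparison: dict | None = None
    double_mm_table: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "alignments.csv": self.alignments,
            "gene_summary.csv": self.gene_table,
            "toxicity_curves.csv": self.toxicity_curves,
            "lfc_adjusted.csv": self.lfc_adjusted,
            "delta_table.csv": self.delta_table,
            "self_expression.csv": self.self_expression,
            "flagged_genes.csv": self.flagged_genes,
            "snp_pairs.csv": self.snp_pairs,
            "double_mm_table.csv": self.double_mm_table,
        }
        for name, df in tables.items():
            if df is not None:
                df.to_csv(out / name, index=(name == "lfc_adjusted.csv"))
        with open(out / "config.txt", "w") as fh:
            fh.write(repr(self.config) + "\n")


def align_library(
    genome: Genome,
    guides: Sequence[GuideRecord],
    annotation: ExonAnnotation | None = None,
    max_mm: int = 2,
) -> dict[str, list[Alignment]]:
    """Alignments (annotated when gene models are given) per guide."""
    out: dict[str, list[Alignment]] = {}
    for g in guides:
        alns = find_alignments(genome, g.spacer, max_mm, guide_id=g.guide_id)
        if annotation is not None:
            alns = [annotate_alignment(a, annotation) for a in alns]
        out[g.guide_id] = alns
    return out


def _gene_scores(
    lfc: pd.DataFrame, guide_to_gene: Mapping[str, str | None], exclude: set[str] = frozenset()
) -> pd.DataFrame:
    """Mean guide LFC per intended gene (the audit's simple gene score)."""
    rows = {}
    by_gene: dict[str, list[str]] = {}
    for gid, gene in guide_to_gene.items():
        if gene is not None and gid in lfc.index and gid not in exclude:
            by_gene.setdefault(gene, []).append(gid)
    for gene, gids in by_gene.items():
        rows[gene] = lfc.loc[gids].mean(axis=0)
    return pd.DataFrame(rows).T


def _delta_screen(
    lfc: pd.DataFrame,
    summaries: Mapping[str, GuideAlignmentSummary],
    guide_to_gene: Mapping[str, str | None],
    clean_level: str,
    substantial: float,
    qualifies,
) -> pd.DataFrame:
    """Delta coefficient of each qualifying guide against its gene's clean guides."""
    clean_by_gene: dict[str, list[str]] = {}
    for gid, s in summaries.items():
        gene = guide_to_gene.get(gid)
        if gene is not None and is_clean(s, clean_level) and gid in lfc.index:
            clean_by_gene.setdefault(gene, []).append(gid)
    rows = []
    for gid, s in summaries.items():
        gene = guide_to_gene.get(gid)
        if gene is None or gid not in lfc.index or not qualifies(s):
            continue
        clean = [c for c in clean_by_gene.get(gene, []) if c != gid]
        if not clean:
            continue
        y = lfc.loc[[gid] + clean].T.to_numpy(dtype=float)
        fit = delta_coefficient(y)
        rows.append(
            {
                "guide_id": gid,
                "gene_id": gene,
                "delta": fit.delta,
                "se": fit.se_delta,
                "p_value": fit.p_value,
                "n_clean_guides": len(clean),
                "substantial": fit.delta < substantial,
            }
        )
    return pd.DataFrame(
        rows, columns=["guide_id", "gene_id", "delta", "se", "p_value", "n_clean_guides", "substantial"]
    )


def select_problematic_double_mm(
    lfc: pd.DataFrame,
    summaries: Mapping[str, GuideAlignmentSummary],
    guide_to_gene: Mapping[str, str | None],
    min_alignments: int = 5,
    first_position: int = 20,
    substantial: float = -0.25,
    n_null_genes: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Screen guides whose double-mismatch promiscuity predicts off-target toxicity.

    Qualifying guides have one unique on-target, no single-mismatch
    alignment, and at least ``min_alignments`` double-mismatch alignments
    carrying a mismatch at the most PAM-distal position; each needs a clean
    guide (no 1- or 2-mm alignments) for the same gene. Their delta
    coefficients are compared against a 95% null band of deltas for genes
    targeted by clean guides only.
    """
    rng = np.random.default_rng(seed)
    lfc_mat = lfc

    def qualifies(s: GuideAlignmentSummary) -> bool:
        if s.n_perfect != 1 or s.n_1mm != 0:
            return False
        n_qual = sum(first_position in pos for pos in s.mismatch_positions_2mm)
        return n_qual >= min_alignments

    table = _delta_screen(lfc_mat, summaries, guide_to_gene, "2mm", substantial, qualifies)

    # Null band: genes targeted by clean guides only; one clean guide plays
    # the guide-of-interest against the rest.
    clean_only_genes = []
    by_gene: dict[str, list[str]] = {}
    for gid, s in summaries.items():
        gene = guide_to_gene.get(gid)
        if gene is not None:
            by_gene.setdefault(gene, []).append(gid)
    for gene, gids in by_gene.items():
        present = [g for g in gids if g in lfc_mat.index]
        if len(present) >= 2 and all(is_clean(summaries[g], "2mm") for g in present):
            clean_only_genes.append(gene)
    null_deltas = []
    if clean_only_genes:
        choices = rng.choice(len(clean_only_genes), size=n_null_genes, replace=True)
        for ci in choices:
            gids = [g for g in by_gene[clean_only_genes[ci]] if g in lfc_mat.index]
            k = int(rng.integers(len(gids)))
            order = [gids[k]] + [g for i, g in enumerate(gids) if i != k]
            y = lfc_mat.loc[order].T.to_numpy(dtype=float)
            null_deltas.append(delta_coefficient(y).delta)
    if null_deltas:
        band = (float(np.quantile(null_deltas, 0.025)), float(np.quantile(null_deltas, 0.975)))
    else:
        band = (float("nan"), float("nan"))
    if not table.empty:
        table["below_null_band"] = table["delta"] < band[0]
        table["outside_null_band"] = (table["delta"] < band[0]) | (table["delta"] > band[1])
    return table, band


def run_audit(
    genome: Genome,
    annotation: ExonAnnotation,
    guides: Sequence[GuideRecord],
    lfc: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    snps: Sequence[SNPRecord] | None = None,
    genotypes: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
    exclude_guides: set[str] = frozenset(),
) -> AuditReport:
    """Run the configured audit stages over one screen.

    ``lfc`` is guides x cell lines (processed/averaged). ``exclude_guides``
    removes guides from every analysis (used to re-score a gene after
    dropping its mismatch-tolerant guides).
    """
    report = AuditReport(config=config)
    guides = [g for g in guides if g.guide_id not in exclude_guides]
    lfc = lfc.loc[[g for g in lfc.index if g not in exclude_guides]]
    guide_to_gene = {g.guide_id: g.intended_gene for g in guides}

    if "align" not in config.stages:
        return report
    aln_map = align_library(genome, guides, annotation, max_mm=config.max_mm)
    summaries = {
        g.guide_id: summarize_guide(aln_map[g.guide_id], guide_id=g.guide_id)
        for g in guides
        if g.intended_gene is not None
    }
    report.guide_summaries = summaries
    report.alignments = sio.alignments_to_frame(a for alns in aln_map.values() for a in alns)
    gene_rows = gene_summary_table(list(summaries.values()), guide_to_gene, config.clean_level)
    report.gene_table = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_guides": r.n_guides,
                "n_clean_guides": r.n_clean_guides,
                "all_guides_multitarget": r.all_guides_multitarget,
            }
            for r in gene_rows
        ]
    )

    lfc_used = lfc
    if "toxicity" in config.stages:
        # the alignment-count support is cell-independent; check it once
        support = {
            min(s.n_perfect, config.toxicity_n_max)
            for s in summaries.values()
            if s.n_1mm == 0 and s.n_perfect >= 1
        }
        curves = {}
        curve_rows = []
        if len(support) < 3:
            log.warning(
                "toxicity stage skipped: only %d distinct on-target alignment counts", len(support)
            )
        else:
            for cell in lfc.columns:
                curve = fit_toxicity_curve(
                    lfc[cell], summaries, "on_target", cell_line=cell, n_max=config.toxicity_n_max
                )
                curves[cell] = curve
                curve_rows.append(
                    {"cell_line": cell, "c0": curve.coef[0], "c1": curve.coef[1], "c2": curve.coef[2], "n_guides": curve.n_guides}
                )
        report.toxicity_curves = pd.DataFrame(curve_rows)
        if len(curves) == len(lfc.columns):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lfc_used = adjust_for_toxicity(lfc, summaries, curves)
            report.lfc_adjusted = lfc_used

    if "delta" in config.stages:
        report.delta_table = _delta_screen(
            lfc_used,
            summaries,
            guide_to_gene,
            config.clean_level,
            config.substantial_delta,
            qualifies=lambda s: s.n_perfect == 1 and s.n_1mm >= 1 and s.n_2mm == 0,
        )

    if "self_expression" in config.stages and expression is not None:
        scores = _gene_scores(lfc_used, guide_to_gene)
        table = self_expression_screen(scores, expression, summaries, guide_to_gene)
        report.self_expression = table
        if not table.empty:
            top_n = max(1, int(np.ceil(config.flag_top_fraction * len(table))))
            flagged = table[(table["rank"] <= top_n) & table["has_exonic_1mm_offtarget"]]
            report.flagged_genes = flagged.reset_index(drop=True)

    if "snp" in config.stages and snps and genotypes is not None:
        all_alns = [a for alns in aln_map.values() for a in alns]
        pairs = intersect_snps_with_targets(all_alns, list(snps))
        snp_by_id = {s.snp_id: s for s in snps}
        rows = []
        classified = []
        rng = np.random.default_rng(config.seed)
        for pair, aln in pairs:
            pair = classify_snp_effect(pair, aln, snp_by_id[pair.snp_id])
            if pair.guide_id not in lfc_used.index or pair.snp_id not in genotypes.index:
                continue
            gt = genotypes.loc[pair.snp_id].reindex(lfc_used.columns).to_numpy(dtype=float)
            y = lfc_used.loc[pair.guide_id].to_numpy(dtype=float)
            try:
                perm = permutation_null(y, gt, B=config.permutation_B, seed=rng)
            except ValueError as err:
                log.info("SNP pair (%s, %s) skipped: %s", pair.snp_id, pair.guide_id, err)
                continue
            pair = dataclasses.replace(
                pair,
                r_genotype_lfc=perm.r_observed,
                p_permutation=perm.p_two_sided,
                significant_positive=perm.significant_positive,
                significant_negative=perm.significant_negative,
            )
            classified.append(pair)
            rows.append(
                {
                    "snp_id": pair.snp_id,
                    "guide_id": pair.guide_id,
                    "site_role": pair.site_role,
                    "position_class": pair.position_class,
                    "pam_relative_position": pair.pam_relative_position,
                    "category": pair.category,
                    "r_genotype_lfc": pair.r_genotype_lfc,
                    "p_permutation": pair.p_permutation,
                    "significant_positive": pair.significant_positive,
                    "significant_negative": pair.significant_negative,
                }
            )
        report.snp_pairs = pd.DataFrame(rows)
        report.snp_position_comparison = position_stratified_correlations(classified)

    if "double_mm" in config.stages:
        table, band = select_problematic_double_mm(
            lfc_used,
            summaries,
            guide_to_gene,
            min_alignments=config.double_mm_min_alignments,
            first_position=config.double_mm_first_position,
            substantial=config.substantial_delta,
            n_null_genes=config.null_band_genes,
            seed=config.seed + 1,
        )
        report.double_mm_table = table
        report.double_mm_band = band  # type: ignore[attr-defined]

    return report
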