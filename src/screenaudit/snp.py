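"""SNP effects on guide activity: genotype-LFC association with permutation nulls.

A SNP inside a protospacer or its PAM changes the match between a guide and
one cell line's genome. Depending on where it falls, the minor allele can
reduce on-target cutting (a protospacer mismatch), abolish it entirely (a
PAM guanine destroyed), turn a single-mismatch off-target into a perfect
on-target (SNP at the mismatch position with the minor allele matching the
spacer base), or demote it to a double-mismatch site. Each case predicts the
sign of the Pearson correlation between minor-allele dosage (0/1/2) and the
guide's LFC across cell lines; significance is assessed against a
genotype-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import PAM_LEN, SPACER_LEN, Alignment, revcomp
from .stats import pearson_with_p

__all__ = [
    "SNPRecord",
    "SNPGuidePair",
    "PermutationResult",
    "intersect_snps_with_targets",
    "classify_snp_effect",
    "genotype_lfc_correlation",
    "permutation_null",
    "position_stratified_correlations",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SiteRole = Literal["on_target", "off_target_1mm"]
PositionClass = Literal["protospacer_pam_proximal", "protospacer_pam_distal", "PAM_N", "PAM_G2", "PAM_G3"]
EffectCategory = Literal["efficiency_loss", "pam_destroying", "offtarget_to_ontarget", "mm1_to_mm2"]


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP; the A allele is the reference-genome base."""

    snp_id: str
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    maf: float = float("nan")

    def __post_init__(self):
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"SNP {self.snp_id}: identical alleles")


@dataclass(frozen=True)
class SNPGuidePair:
    snp_id: str
    guide_id: str
    site_role: SiteRole
    position_class: PositionClass
    pam_relative_position: int | None  # 1..20 within protospacer, None for PAM
    category: EffectCategory | None = None
    r_genotype_lfc: float = float("nan")
    p_permutation: float = float("nan")
    significant_positive: bool = False
    significant_negative: bool = False


def _spacer_orientation_allele(base: str, strand: str) -> str:
    """A forward-strand allele read in the protospacer's spacer orientation."""
    return base.upper() if strand == "+" else _COMP[base.upper()]


def _locate_snp(aln: Alignment, snp: SNPRecord) -> tuple[PositionClass, int | None] | None:
    """Position class of a SNP relative to one alignment, or None if outside."""
    if snp.contig != aln.contig:
        return None
    pos = snp.position
    if aln.start <= pos <= aln.end:
        if aln.strand == "+":
            idx_5p = pos - aln.start + 1
        else:
            idx_5p = aln.end - pos + 1
        pam_rel = SPACER_LEN + 1 - idx_5p
        cls = "protospacer_pam_proximal" if pam_rel <= 10 else "protospacer_pam_distal"
        return cls, pam_rel
    pam_lo, pam_hi = aln.pam_interval()
    if pam_lo <= pos <= pam_hi:
        if aln.strand == "+":
            offset = pos - pam_lo  # 0 = N, 1 = G2, 2 = G3
        else:
            offset = pam_hi - pos
        return ("PAM_N", "PAM_G2", "PAM_G3")[offset], None
    return None


def intersect_snps_with_targets(
    alignments: Sequence[Alignment],
    snps: Sequence[SNPRecord],
) -> list[tuple[SNPGuidePair, Alignment]]:
    """All (SNP, guide alignment) overlaps, with the position class computed.

    Only perfect (on-target) and single-mismatch alignments are considered,
    the two site roles whose genotype-LFC behaviour the audit models.
    Returns each pair alongside the alignment it came from so the effect can
    be classified downstream.
    """
    out: list[tuple[SNPGuidePair, Alignment]] = []
    for aln in alignments:
        if aln.n_mismatches > 1:
            continue
        role: SiteRole = "on_target" if aln.n_mismatches == 0 else "off_target_1mm"
        for snp in snps:
            loc = _locate_snp(aln, snp)
            if loc is None:
                continue
            cls, pam_rel = loc
            out.append(
                (
                    SNPGuidePair(
                        snp_id=snp.snp_id,
                        guide_id=aln.guide_id,
                        site_role=role,
                        position_class=cls,
                        pam_relative_position=pam_rel,
                    ),
                    aln,
                )
            )
    return out


def classify_snp_effect(pair: SNPGuidePair, aln: Alignment, snp: SNPRecord) -> SNPGuidePair:
    """Deterministic effect category of a SNP on a guide's target site.

    PAM G2/G3 minor alleles always break NGG (pam_destroying). At a
    single-mismatch off-target, a SNP at the mismatch position whose minor
    allele (read in spacer orientation) equals the spacer base converts the
    off-target into an on-target; any other protospacer SNP there adds a
    second mismatch (mm1_to_mm2). On an on-target, a protospacer SNP (or the
    inert PAM N position) degrades cutting efficiency (efficiency_loss).
    """
    if pair.position_class in ("PAM_G2", "PAM_G3"):
        return replace(pair, category="pam_destroying")
    if pair.position_class == "PAM_N":
        return replace(pair, category="efficiency_loss")
    if pair.site_role == "off_target_1mm":
        (mm_pos,) = aln.mismatch_positions
        ((spacer_base, _ref_base),) = aln.substitutions
        minor_in_spacer_orientation = _spacer_orientation_allele(snp.alt, aln.strand)
        if pair.pam_relative_position == mm_pos and minor_in_spacer_orientation == spacer_base:
            return replace(pair, category="offtarget_to_ontarget")
        return replace(pair, category="mm1_to_mm2")
    return replace(pair, category="efficiency_loss")


def genotype_lfc_correlation(lfc: Sequence[float], genotype: Sequence[float]) -> float:
    """Pearson r between minor-allele dosage and LFC over complete pairs."""
    lfc = np.asarray(lfc, dtype=float)
    gt = np.asarray(genotype, dtype=float)
    keep = np.isfinite(lfc) & np.isfinite(gt)
    lfc, gt = lfc[keep], gt[keep]
    if lfc.size < 3:
        raise ValueError("genotype_lfc_correlation: need >=3 complete pairs")
    if np.ptp(gt) == 0:
        raise ValueError("genotype_lfc_correlation: no allele variation")
    if np.ptp(lfc) == 0:
        raise ValueError("genotype_lfc_correlation: constant LFC")
    r, _ = pearson_with_p(lfc, gt)
    return r


@dataclass(frozen=True)
class PermutationResult:
    r_observed: float
    r_null: np.ndarray
    p_two_sided: float
    p_one_sided_greater: float
    significant_positive: bool
    significant_negative: bool
    quantile: float
    B: int


def permutation_null(
    lfc: Sequence[float],
    genotype: Sequence[float],
    B: int = 100,
    seed: int | np.random.Generator = 0,
    quantile: float = 0.95,
) -> PermutationResult:
    """Genotype-permutation null for the genotype-LFC correlation.

    Cell-line genotype labels are permuted ``B`` times with a seeded
    generator. The empirical two-sided p uses the add-one correction
    p = (1 + #{|r_null| >= |r_obs|}) / (B + 1). Tail calls compare the
    observed r against the configurable null quantile in each direction.
    """
    if B < 1:
        raise ValueError("permutation_null: B >= 1 required")
    lfc = np.asarray(lfc, dtype=float)
    gt = np.asarray(genotype, dtype=float)
    keep = np.isfinite(lfc) & np.isfinite(gt)
    lfc, gt = lfc[keep], gt[keep]
    r_obs = genotype_lfc_correlation(lfc, gt)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = lfc.size
    perms = np.array([rng.permutation(gt) for _ in range(B)])  # B x n
    # Vectorized Pearson r of lfc against each permuted genotype row.
    lc = lfc - lfc.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((lc @ lc) * np.sum(pc * pc, axis=1))
    r_null = (pc @ lc) / denom
    p_two = (1 + np.sum(np.abs(r_null) >= abs(r_obs))) / (B + 1)
    p_one = (1 + np.sum(r_null >= r_obs)) / (B + 1)
    # conservative order statistics: exceeding the "higher" 95% order
    # statistic of B null draws has probability floor(B*(1-q))+... ~ (1-q)
    hi = float(np.quantile(r_null, quantile, method="higher"))
    lo = float(np.quantile(r_null, 1 - quantile, method="lower"))
    return PermutationResult(
        r_observed=r_obs,
        r_null=r_null,
        p_two_sided=float(p_two),
        p_one_sided_greater=float(p_one),
        significant_positive=bool(r_obs > hi),
        significant_negative=bool(r_obs < lo),
        quantile=quantile,
        B=B,
    )


def position_stratified_correlations(pairs: Sequence[SNPGuidePair]) -> dict:
    """Compare genotype-LFC correlations between PAM-proximal and PAM-distal SNPs.

    Returns the two stratum distributions and a Wilcoxon rank-sum test
    (exact for small samples, normal approximation otherwise).
    """
    prox = [p.r_genotype_lfc for p in pairs if p.position_class == "protospacer_pam_proximal" and np.isfinite(p.r_genotype_lfc)]
    dist = [p.r_genotype_lfc for p in pairs if p.position_class == "protospacer_pam_distal" and np.isfinite(p.r_genotype_lfc)]
    out = {
        "proximal_r": np.asarray(prox),
        "distal_r": np.asarray(dist),
        "proximal_mean": float(np.mean(prox)) if prox else float("nan"),
        "distal_mean": float(np.mean(dist)) if dist else float("nan"),
        "p_value": float("nan"),
    }
    if len(prox) >= 2 and len(dist) >= 2:
        method = "exact" if (len(prox) + len(dist)) <= 16 else "asymptotic"
        res = sps.mannwhitneyu(prox, dist, alternative="two-sided", method=method)
        out["p_value"] = float(res.pvalue)
    return out
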