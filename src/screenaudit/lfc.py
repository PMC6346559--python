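"""Log-fold-change processing for pooled CRISPR knockout screens.

Two standard processing chains are supported. The count-based chain starts
from raw read counts: guides under-represented in the plasmid library are
dropped, LFC = log2(sample + pc) - log2(plasmid + pc). The normalization
chain then centers each replicate at its median and scales by the median
absolute deviation, rescales so guides targeting known essential genes sit
near -1, averages replicates per cell line, and finally removes the
copy-number dependence of LFC per cell line with a continuous
piecewise-linear spline anchored at diploid-normal copy number 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "LFCMatrix",
    "compute_raw_lfc",
    "normalize_median_mad",
    "scale_by_essentials",
    "average_replicates",
    "correct_copy_number",
    "correct_copy_number_matrix",
]

STAGES = ("raw", "normalized", "scaled", "averaged", "cn_corrected", "toxicity_adjusted")


@dataclass
class CountMatrix:
    """Guide x sample read counts with the plasmid column identified."""

    counts: pd.DataFrame  # guides x samples, non-negative integers
    plasmid: str
    sample_map: Mapping[str, tuple[str, str]] | None = None  # sample -> (cell line, replicate)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.plasmid not in self.counts.columns:
            raise ValueError(f"plasmid column {self.plasmid!r} missing")


@dataclass
class LFCMatrix:
    """Guide x sample (or cell line) log-fold changes with a stage flag.

    Stages only move forward along the processing chain; attempting to move
    backwards raises, which catches out-of-order pipeline wiring.
    """

    values: pd.DataFrame
    stage: str = "raw"
    sample_map: Mapping[str, tuple[str, str]] | None = None
    essential_genes: frozenset[str] = frozenset()
    nonessential_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def advanced(self, values: pd.DataFrame, stage: str, **kw) -> "LFCMatrix":
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage cannot move backwards: {self.stage} -> {stage}")
        out = replace(self, values=values, stage=stage)
        for k, v in kw.items():
            setattr(out, k, v)
        return out

    @property
    def guides(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def compute_raw_lfc(
    counts: CountMatrix,
    min_plasmid_reads: int = 30,
    pseudocount: float = 1.0,
) -> LFCMatrix:
    """Per-sample LFC against the plasmid library.

    Guides with fewer than ``min_plasmid_reads`` reads in the plasmid column
    are dropped before the log transform.
    """
    keep = counts.counts[counts.plasmid] >= min_plasmid_reads
    if not keep.any():
        raise ValueError("all guides fail the plasmid read filter")
    kept = counts.counts.loc[keep]
    plasmid = np.log2(kept[counts.plasmid] + pseudocount)
    samples = [c for c in kept.columns if c != counts.plasmid]
    lfc = np.log2(kept[samples] + pseudocount).sub(plasmid, axis=0)
    return LFCMatrix(values=lfc, stage="raw", sample_map=counts.sample_map)


def normalize_median_mad(
    lfc: LFCMatrix,
    center: Literal["median", "nonessential_median"] = "median",
    guide_to_gene: Mapping[str, str | None] | None = None,
) -> LFCMatrix:
    """Center each replicate column and scale it by its MAD.

    The default centers on the column median; ``nonessential_median``
    centers on the median of guides targeting the recorded non-essential
    reference genes instead (the count-based chain's convention).
    """
    vals = lfc.values.copy()
    for col in vals.columns:
        x = vals[col]
        finite = x.dropna()
        if finite.size < 2:
            raise ValueError(f"replicate {col!r}: fewer than 2 finite values")
        if center == "nonessential_median":
            if guide_to_gene is None or not lfc.nonessential_genes:
                raise ValueError("nonessential_median centering needs guide_to_gene and gene set")
            ref = finite[[guide_to_gene.get(g) in lfc.nonessential_genes for g in finite.index]]
            med = float(ref.median())
        else:
            med = float(finite.median())
        mad = float((finite - med).abs().median())
        if mad == 0:
            raise ValueError(f"replicate {col!r}: zero MAD, cannot scale")
        vals[col] = (x - med) / mad
    return lfc.advanced(vals, "normalized")


def scale_by_essentials(
    lfc: LFCMatrix,
    essential_genes: Sequence[str],
    guide_to_gene: Mapping[str, str | None],
    statistic: Literal["mean_abs", "median"] = "mean_abs",
) -> LFCMatrix:
    """Rescale so guides targeting essential genes sit near -1.

    ``mean_abs`` divides by the absolute mean LFC of essential-gene guides
    across all columns; ``median`` divides by the absolute median instead.
    """
    ess = frozenset(essential_genes)
    if not ess:
        raise ValueError("essential gene set is empty")
    mask = [guide_to_gene.get(g) in ess for g in lfc.values.index]
    block = lfc.values.loc[mask].values
    block = block[np.isfinite(block)]
    if block.size == 0:
        raise ValueError("no essential-gene guides present in the library")
    if statistic == "mean_abs":
        scale = abs(float(np.mean(block)))
    elif statistic == "median":
        scale = abs(float(np.median(block)))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if scale < 1e-12:
        raise ValueError("essential-guide scaling statistic is ~0")
    return lfc.advanced(lfc.values / scale, "scaled", essential_genes=ess)


def average_replicates(lfc: LFCMatrix, sample_map: Mapping[str, tuple[str, str]] | None = None) -> LFCMatrix:
    """Arithmetic mean over replicate columns, one column per cell line."""
    sm = sample_map or lfc.sample_map
    if sm is None:
        raise ValueError("average_replicates: no sample -> (cell line, replicate) map")
    groups: dict[str, list[str]] = {}
    for sample, (cell, _rep) in sm.items():
        if sample in lfc.values.columns:
            groups.setdefault(cell, []).append(sample)
    cols = {cell: lfc.values[samples].mean(axis=1) for cell, samples in sorted(groups.items())}
    return lfc.advanced(pd.DataFrame(cols), "averaged")


def _pwl_basis(cn: np.ndarray, knots: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(cn), cn]
    for k in knots:
        cols.append(np.clip(cn - k, 0, None))
    return np.column_stack(cols)


def correct_copy_number(
    lfc: pd.Series,
    cn: pd.Series,
    knots: int = 4,
) -> tuple[pd.Series, np.ndarray]:
    """Remove the copy-number dependence of one cell line's LFCs.

    Fits LFC on relative copy number with a continuous piecewise-linear
    spline whose interior knots sit at CN quantiles, then subtracts the
    fitted effect relative to its value at CN = 1 so diploid-normal guides
    are untouched. Guides with missing CN pass through unchanged. Returns
    the corrected series and the fitted spline coefficients.
    """
    common = lfc.index.intersection(cn.dropna().index)
    corrected = lfc.copy()
    x = cn.loc[common].to_numpy(dtype=float)
    y = lfc.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, idx = x[ok], y[ok], common[ok]
    if x.size == 0:
        return corrected, np.zeros(2)
    if np.unique(x).size < 10:
        if np.unique(x).size >= 2:
            warnings.warn("correct_copy_number: <10 distinct CN values, falling back to linear fit")
        knot_vals = np.array([])
    else:
        qs = np.linspace(0, 1, knots + 2)[1:-1]
        knot_vals = np.unique(np.quantile(x, qs))
    X = _pwl_basis(x, knot_vals)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    at_one = _pwl_basis(np.array([1.0]), knot_vals) @ beta
    corrected.loc[idx] = y - (fitted - at_one[0])
    return corrected, beta


def correct_copy_number_matrix(
    lfc: LFCMatrix,
    cn: pd.DataFrame,
    knots: int = 4,
) -> LFCMatrix:
    """Per-cell-line copy-number correction of an averaged LFC matrix.

    ``cn`` is guides (or loci) x cell lines relative copy number; columns
    missing from ``cn`` pass through unchanged.
    """
    vals = lfc.values.copy()
    for cell in vals.columns:
        if cell in cn.columns:
            vals[cell], _ = correct_copy_number(vals[cell], cn[cell], knots=knots)
    return lfc.advanced(vals, "cn_corrected")
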