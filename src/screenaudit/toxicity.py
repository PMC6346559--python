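"""Cell-line-specific cleavage toxicity from multi-target guides.

Guides that cut the genome at several loci deplete in proportion to the
number of double-strand breaks, independently of which genes they hit. The
effect is modelled per cell line as a second-degree polynomial of mean LFC
on the number of alignments, separately for perfect alignments (on-target
toxicity) and single-mismatch alignments (off-target toxicity). Subtracting
the fitted curve relative to its value at one alignment yields
toxicity-adjusted LFCs that leave single-target guides untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import GuideAlignmentSummary
from .stats import JonckheereResult, jonckheere

__all__ = [
    "ToxicityCurve",
    "ToxicityMetric",
    "fit_toxicity_curve",
    "adjust_for_toxicity",
    "toxicity_metric",
    "stratified_mismatch_table",
    "single_mismatch_position_table",
    "trend_over_alignment_count",
]

TargetKind = Literal["on_target", "off_target_1mm"]


@dataclass(frozen=True)
class ToxicityCurve:
    """Quadratic fit of guide LFC on alignment count for one cell line."""

    cell_line: str
    target_kind: TargetKind
    coef: tuple[float, float, float]  # (c0, c1, c2): y = c0 + c1*n + c2*n^2
    coef_se: tuple[float, float, float]
    n_guides: int
    n_min: int
    n_max: int

    def predict(self, n: float | np.ndarray, clamp: bool = True) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        if clamp:
            out_of_domain = (n < self.n_min) | (n > self.n_max)
            if np.any(out_of_domain):
                warnings.warn(
                    f"toxicity curve for {self.cell_line}: alignment counts outside "
                    f"fit domain [{self.n_min}, {self.n_max}] clamped"
                )
            n = np.clip(n, self.n_min, self.n_max)
        c0, c1, c2 = self.coef
        return c0 + c1 * n + c2 * n * n


@dataclass(frozen=True)
class ToxicityMetric:
    """Mean LFC at four alignments, a per-cell summary of cleavage toxicity."""

    cell_line: str
    on_target_at_4: float
    off_target_at_4: float
    n_on: int
    n_off: int


def _counts_for_kind(
    summaries: Mapping[str, GuideAlignmentSummary],
    target_kind: TargetKind,
) -> dict[str, int]:
    """Guide -> alignment count after the kind-specific exclusions.

    On-target fits exclude guides with any single-mismatch alignment (their
    off-targets would confound the curve); off-target fits are restricted to
    guides with exactly one perfect alignment so the on-target count is held
    fixed.
    """
    out: dict[str, int] = {}
    for gid, s in summaries.items():
        if target_kind == "on_target":
            if s.n_1mm == 0 and s.n_perfect >= 1:
                out[gid] = s.n_perfect
        elif target_kind == "off_target_1mm":
            if s.n_perfect == 1:
                out[gid] = s.n_1mm
        else:
            raise ValueError(f"unknown target_kind {target_kind!r}")
    return out


def fit_toxicity_curve(
    lfc: pd.Series,
    summaries: Mapping[str, GuideAlignmentSummary],
    target_kind: TargetKind = "on_target",
    cell_line: str = "",
    n_max: int = 8,
) -> ToxicityCurve:
    """Least-squares quadratic of one cell line's guide LFCs on alignment count.

    Counts above ``n_max`` are pooled into the ``n_max`` bin (tail bins are
    sparse). Requires at least 3 distinct alignment-count values.
    """
    counts = _counts_for_kind(summaries, target_kind)
    guides = [g for g in lfc.index if g in counts and np.isfinite(lfc[g])]
    x = np.clip(np.array([counts[g] for g in guides], dtype=float), None, n_max)
    y = lfc.loc[guides].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise ValueError(
            f"fit_toxicity_curve({cell_line or '?'}): need >=3 distinct alignment counts"
        )
    X = np.column_stack([np.ones_like(x), x, x * x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(x.size - 3, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return ToxicityCurve(
        cell_line=cell_line,
        target_kind=target_kind,
        coef=tuple(float(b) for b in beta),
        coef_se=tuple(float(s) for s in se),
        n_guides=x.size,
        n_min=int(x.min()),
        n_max=int(x.max()),
    )


def adjust_for_toxicity(
    lfc: pd.DataFrame,
    summaries: Mapping[str, GuideAlignmentSummary],
    curves: Mapping[str, ToxicityCurve],
) -> pd.DataFrame:
    """Subtract each cell line's fitted multi-target toxicity from its LFCs.

    For a guide with n perfect alignments in cell line c the adjustment is
    f_c(n) - f_c(1), so guides with a single perfect alignment are unchanged.
    The adjustment is linear in the input matrix.
    """
    out = lfc.copy()
    n_perfect = pd.Series({g: s.n_perfect for g, s in summaries.items()})
    common = out.index.intersection(n_perfect.index)
    for cell in out.columns:
        curve = curves.get(cell)
        if curve is None:
            raise KeyError(f"no toxicity curve for cell line {cell!r}")
        n = n_perfect.loc[common].to_numpy(dtype=float)
        shift = curve.predict(n) - curve.predict(1.0)
        out.loc[common, cell] = out.loc[common, cell] - shift
    return out


def toxicity_metric(
    lfc: pd.Series,
    summaries: Mapping[str, GuideAlignmentSummary],
    cell_line: str = "",
    at: int = 4,
    min_guides: int = 5,
) -> ToxicityMetric:
    """Mean LFC of guides with ``at`` perfect / single-mismatch alignments."""
    on = _counts_for_kind(summaries, "on_target")
    off = _counts_for_kind(summaries, "off_target_1mm")
    on_vals = lfc[[g for g in lfc.index if on.get(g) == at]].dropna()
    off_vals = lfc[[g for g in lfc.index if off.get(g) == at]].dropna()
    return ToxicityMetric(
        cell_line=cell_line,
        on_target_at_4=float(on_vals.mean()) if on_vals.size >= min_guides else float("nan"),
        off_target_at_4=float(off_vals.mean()) if off_vals.size >= min_guides else float("nan"),
        n_on=int(on_vals.size),
        n_off=int(off_vals.size),
    )


def _position_class(positions: Sequence[int]) -> str:
    if all(1 <= p <= 10 for p in positions):
        return "pam_proximal"
    if all(11 <= p <= 20 for p in positions):
        return "pam_distal"
    return "mixed"


def stratified_mismatch_table(
    lfc_mean: pd.Series,
    summaries: Mapping[str, GuideAlignmentSummary],
    max_n_1mm: int = 4,
) -> pd.DataFrame:
    """Median LFC by (number of 1-mm alignments, PAM region) for single-target guides.

    Guides with exactly one perfect alignment are stratified by their number
    of single-mismatch alignments and by whether all the mismatch positions
    fall in the PAM-proximal half (positions 1-10) or the PAM-distal half
    (11-20). Each (count, proximal vs distal) pair gets a two-sample t test.
    """
    rows = []
    groups: dict[tuple[int, str], list[float]] = {}
    for gid, s in summaries.items():
        if s.n_perfect != 1 or gid not in lfc_mean.index:
            continue
        val = lfc_mean[gid]
        if not np.isfinite(val):
            continue
        n1 = min(s.n_1mm, max_n_1mm)
        if n1 == 0:
            groups.setdefault((0, "none"), []).append(val)
            continue
        pos = [p for aln in s.mismatch_positions_1mm for p in aln]
        groups.setdefault((n1, _position_class(pos)), []).append(val)
    for (n1, cls), vals in sorted(groups.items()):
        rows.append(
            {
                "n_1mm": n1,
                "position_class": cls,
                "n_guides": len(vals),
                "median_lfc": float(np.median(vals)) if vals else float("nan"),
            }
        )
    table = pd.DataFrame(rows, columns=["n_1mm", "position_class", "n_guides", "median_lfc"])
    pvals = []
    for _, row in table.iterrows():
        if row["position_class"] != "pam_distal":
            pvals.append(float("nan"))
            continue
        other = groups.get((row["n_1mm"], "pam_proximal"))
        this = groups.get((row["n_1mm"], "pam_distal"))
        if not other or not this or len(other) < 2 or len(this) < 2:
            pvals.append(float("nan"))
        else:
            pvals.append(float(sps.ttest_ind(this, other, equal_var=False).pvalue))
    table["p_vs_proximal"] = pvals
    return table


def single_mismatch_position_table(
    lfc_mean: pd.Series,
    summaries: Mapping[str, GuideAlignmentSummary],
) -> pd.DataFrame:
    """Median LFC by single-mismatch position for 1-perfect/1-mm guides."""
    groups: dict[int, list[float]] = {}
    for gid, s in summaries.items():
        if s.n_perfect != 1 or s.n_1mm != 1 or gid not in lfc_mean.index:
            continue
        val = lfc_mean[gid]
        if not np.isfinite(val):
            continue
        (positions,) = s.mismatch_positions_1mm
        if len(positions) == 1:
            groups.setdefault(positions[0], []).append(val)
    rows = [
        {"position": pos, "n_guides": len(vals), "median_lfc": float(np.median(vals))}
        for pos, vals in sorted(groups.items())
    ]
    return pd.DataFrame(rows, columns=["position", "n_guides", "median_lfc"])


def trend_over_alignment_count(
    lfc_mean: pd.Series,
    summaries: Mapping[str, GuideAlignmentSummary],
    target_kind: TargetKind = "on_target",
    alternative: str = "decreasing",
    n_max: int = 8,
) -> JonckheereResult:
    """Jonckheere trend of guide LFC over ordered alignment-count groups."""
    counts = _counts_for_kind(summaries, target_kind)
    by_n: dict[int, list[float]] = {}
    for gid, n in counts.items():
        if gid in lfc_mean.index and np.isfinite(lfc_mean[gid]):
            by_n.setdefault(min(n, n_max), []).append(float(lfc_mean[gid]))
    ordered = [by_n[k] for k in sorted(by_n) if by_n[k]]
    if len(ordered) < 3:
        raise ValueError("trend_over_alignment_count: need >=3 ordered groups")
    return jonckheere(ordered, alternative=alternative)
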