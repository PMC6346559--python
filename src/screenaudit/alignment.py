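"""Mismatch-tolerant alignment of 20-nt sgRNA spacers to small genomes.

The search is an exhaustive sliding-window scan on both strands: a genomic
window aligns to a spacer when it differs at no more than ``max_mm``
positions and the adjacent 3-nt PAM matches canonical NGG. Coordinates are
1-based inclusive; for minus-strand hits the stored start is the
forward-strand 5' coordinate of the 20-nt window, and the PAM is read 3' of
the protospacer in spacer orientation. Mismatch positions are PAM-relative:
position 1 is the spacer nucleotide adjacent to the PAM, position 20 the
most PAM-distal one.

This is deliberately a brute-force aligner: the synthetic genomes used in
the audit are kilobases, not gigabases, and exhaustiveness is what the
downstream guarantees rest on.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

SPACER_LEN = 20
PAM_LEN = 3
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DEC = "ACGTN"
_COMP = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "Genome",
    "GuideRecord",
    "Alignment",
    "GuideAlignmentSummary",
    "GeneTargetSummary",
    "ExonAnnotation",
    "find_alignments",
    "mismatch_profile",
    "annotate_alignment",
    "summarize_guide",
    "classify_guide",
    "is_clean",
    "gene_summary_table",
    "apply_genotype",
    "revcomp",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.uint8)
    for base, code in _ENC.items():
        out[arr == ord(base)] = code
    return out


def _validate_spacer(spacer: str) -> str:
    spacer = spacer.upper()
    if len(spacer) != SPACER_LEN or any(b not in "ACGT" for b in spacer):
        raise ValueError(f"invalid spacer {spacer!r}: need 20 nt over A/C/G/T")
    return spacer


class Genome:
    """A set of named contigs; sequences are uppercased on access."""

    def __init__(self, contigs: Mapping[str, str]):
        if len(set(contigs)) != len(list(contigs)):
            raise ValueError("contig names must be unique")
        self.contigs: dict[str, str] = {name: seq.upper() for name, seq in contigs.items()}

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def with_substitutions(self, subs: Iterable[tuple[str, int, str]]) -> "Genome":
        """Return a copy with single-base substitutions applied.

        ``subs`` holds (contig, 1-based position, new base).
        """
        mutable = {name: bytearray(seq.encode()) for name, seq in self.contigs.items()}
        for contig, pos, base in subs:
            mutable[contig][pos - 1] = ord(base.upper())
        return Genome({name: arr.decode() for name, arr in mutable.items()})


@dataclass(frozen=True)
class GuideRecord:
    """A library guide; ``intended_gene`` None marks a non-targeting control."""

    guide_id: str
    spacer: str
    intended_gene: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "spacer", _validate_spacer(self.spacer))


@dataclass(frozen=True)
class Alignment:
    guide_id: str
    contig: str
    start: int  # 1-based forward-strand 5' coordinate of the 20-nt window
    strand: str  # "+" or "-"
    n_mismatches: int
    mismatch_positions: tuple[int, ...]  # PAM-relative, strictly increasing
    substitutions: tuple[tuple[str, str], ...]  # (spacer base -> reference base)
    pam_seq: str
    genes: tuple[str, ...] = ()  # exonic gene ids; empty = intergenic
    heterozygous: bool = False

    @property
    def region(self) -> str:
        return "exonic" if self.genes else "intergenic"

    @property
    def end(self) -> int:
        return self.start + SPACER_LEN - 1

    def pam_interval(self) -> tuple[int, int]:
        """Forward-strand 1-based inclusive interval of the PAM."""
        if self.strand == "+":
            return (self.end + 1, self.end + PAM_LEN)
        return (self.start - PAM_LEN, self.start - 1)


def mismatch_profile(spacer: str, protospacer: str) -> tuple[list[int], list[tuple[str, str]]]:
    """PAM-relative mismatch positions and spacer->reference substitutions.

    Both sequences are given in spacer orientation (5'->3', PAM 3' of the
    protospacer). PAM-relative position = 21 - (1-based 5' index), so the
    base next to the PAM is position 1. Positions are returned in strictly
    increasing PAM-relative order; each substitution is the spacer base
    followed by the reference (protospacer) base it faces, the direction
    library alignment tables print.
    """
    spacer = spacer.upper()
    protospacer = protospacer.upper()
    if len(spacer) != SPACER_LEN or len(protospacer) != SPACER_LEN:
        raise ValueError("mismatch_profile: both sequences must be 20 nt")
    pairs = [
        (SPACER_LEN - i, (spacer[i], protospacer[i]))
        for i in range(SPACER_LEN)
        if spacer[i] != protospacer[i]
    ]
    pairs.sort(key=lambda t: t[0])
    return [p for p, _ in pairs], [s for _, s in pairs]


def _scan_strand(
    enc: np.ndarray,
    spacer_enc: np.ndarray,
    max_mm: int,
    require_pam: bool = True,
) -> list[tuple[int, int]]:
    """Return (0-based window start, n_mismatches) on one encoded strand.

    Windows containing N, or whose PAM contains N, are excluded; the PAM is
    the 3 bases 3' of the window and must match NGG when ``require_pam``.
    """
    n = enc.size
    n_windows = n - SPACER_LEN - PAM_LEN + 1
    if n_windows <= 0:
        return []
    win = np.lib.stride_tricks.sliding_window_view(enc, SPACER_LEN)[:n_windows]
    mm = np.count_nonzero(win != spacer_enc, axis=1)
    ok = ~np.any(win == 4, axis=1)
    pam_n = enc[SPACER_LEN : SPACER_LEN + n_windows]
    pam_g2 = enc[SPACER_LEN + 1 : SPACER_LEN + 1 + n_windows]
    pam_g3 = enc[SPACER_LEN + 2 : SPACER_LEN + 2 + n_windows]
    ok &= (pam_n != 4) & (pam_g2 != 4) & (pam_g3 != 4)
    if require_pam:
        ok &= (pam_g2 == 2) & (pam_g3 == 2)
    ok &= mm <= max_mm
    return [(int(i), int(mm[i])) for i in np.nonzero(ok)[0]]


def find_alignments(
    genome: Genome,
    spacer: str,
    max_mm: int = 2,
    guide_id: str = "",
    alignment_cap: int | None = 10_000,
) -> list[Alignment]:
    """Every genomic position on either strand matching the spacer.

    A hit is a 20-nt window differing from the spacer at no more than
    ``max_mm`` positions whose adjacent PAM matches NGG. Results are sorted
    by (contig, start, strand).
    """
    spacer = _validate_spacer(spacer)
    if not 0 <= max_mm <= 2:
        raise ValueError("max_mm must be 0, 1 or 2")
    if len(genome) == 0:
        raise ValueError("empty genome")
    spacer_enc = _encode(spacer)
    hits: list[Alignment] = []
    for contig in genome:
        seq = genome[contig]
        L = len(seq)
        enc_fwd = _encode(seq)
        for pos0, n_mm in _scan_strand(enc_fwd, spacer_enc, max_mm):
            protospacer = seq[pos0 : pos0 + SPACER_LEN]
            positions, subs = mismatch_profile(spacer, protospacer)
            hits.append(
                Alignment(
                    guide_id=guide_id,
                    contig=contig,
                    start=pos0 + 1,
                    strand="+",
                    n_mismatches=n_mm,
                    mismatch_positions=tuple(positions),
                    substitutions=tuple(subs),
                    pam_seq=seq[pos0 + SPACER_LEN : pos0 + SPACER_LEN + PAM_LEN],
                )
            )
        rc = revcomp(seq)
        enc_rev = _encode(rc)
        for pos0, n_mm in _scan_strand(enc_rev, spacer_enc, max_mm):
            # window occupies forward positions [L - pos0 - 20, L - pos0 - 1] 0-based
            start = L - pos0 - SPACER_LEN + 1
            protospacer = rc[pos0 : pos0 + SPACER_LEN]
            positions, subs = mismatch_profile(spacer, protospacer)
            hits.append(
                Alignment(
                    guide_id=guide_id,
                    contig=contig,
                    start=start,
                    strand="-",
                    n_mismatches=n_mm,
                    mismatch_positions=tuple(positions),
                    substitutions=tuple(subs),
                    pam_seq=rc[pos0 + SPACER_LEN : pos0 + SPACER_LEN + PAM_LEN],
                )
            )
    hits.sort(key=lambda a: (a.contig, a.start, a.strand))
    if alignment_cap is not None and len(hits) > alignment_cap:
        warnings.warn(
            f"guide {guide_id or spacer}: {len(hits)} alignments exceed cap {alignment_cap}"
        )
    return hits


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

class ExonAnnotation:
    """Exon intervals (1-based inclusive) carrying gene ids."""

    def __init__(self, exons: Iterable[tuple[str, int, int, str]] = ()):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._genes: set[str] = set()
        for contig, start, end, gene_id in exons:
            self.add(contig, start, end, gene_id)

    def add(self, contig: str, start: int, end: int, gene_id: str) -> None:
        if end < start:
            raise ValueError("exon end < start")
        # interval tree is half-open; store [start, end+1)
        self._trees[contig][start : end + 1] = gene_id
        self._genes.add(gene_id)

    @classmethod
    def from_bed(cls, rows: Iterable[tuple[str, int, int, str]]) -> "ExonAnnotation":
        """From 0-based half-open BED rows (chrom, chromStart, chromEnd, name)."""
        return cls((c, s + 1, e, g) for c, s, e, g in rows)

    def genes(self) -> set[str]:
        return set(self._genes)

    def overlapping(self, contig: str, start: int, end: int) -> list[str]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = sorted({iv.data for iv in tree.overlap(start, end + 1)})
        return hits

    def gene_intervals(self, gene_id: str) -> list[tuple[str, int, int]]:
        out = []
        for contig, tree in self._trees.items():
            for iv in tree:
                if iv.data == gene_id:
                    out.append((contig, iv.begin, iv.end - 1))
        return sorted(out)


def annotate_alignment(aln: Alignment, annotation: ExonAnnotation) -> Alignment:
    """Fill the exonic-gene annotation of an alignment.

    The alignment is exonic for every gene whose exons overlap the 20-nt
    protospacer by at least one base; with no overlap it is intergenic.
    """
    genes = tuple(annotation.overlapping(aln.contig, aln.start, aln.end))
    return replace(aln, genes=genes)


# ---------------------------------------------------------------------------
# Guide and gene summaries
# ---------------------------------------------------------------------------

CleanLevel = Literal["1mm", "2mm"]


@dataclass(frozen=True)
class GuideAlignmentSummary:
    guide_id: str
    n_perfect: int
    n_1mm: int
    n_2mm: int
    n_exonic_1mm: int
    genes_hit_perfect: frozenset[str]
    genes_hit_1mm: frozenset[str]
    label: str
    mismatch_positions_1mm: tuple[tuple[int, ...], ...] = ()
    mismatch_positions_2mm: tuple[tuple[int, ...], ...] = ()

    @property
    def is_double_target(self) -> bool:
        return self.n_perfect == 2


def summarize_guide(alignments: Sequence[Alignment], guide_id: str | None = None) -> GuideAlignmentSummary:
    """Tally a guide's alignments by mismatch count and compute its label."""
    ids = {a.guide_id for a in alignments}
    if len(ids) > 1:
        raise ValueError(f"summarize_guide: mixed guide ids {sorted(ids)}")
    if guide_id is None:
        guide_id = next(iter(ids)) if ids else ""
    n_perfect = sum(a.n_mismatches == 0 for a in alignments)
    n_1mm = sum(a.n_mismatches == 1 for a in alignments)
    n_2mm = sum(a.n_mismatches == 2 for a in alignments)
    n_exonic_1mm = sum(a.n_mismatches == 1 and bool(a.genes) for a in alignments)
    genes_perfect = frozenset(g for a in alignments if a.n_mismatches == 0 for g in a.genes)
    genes_1mm = frozenset(g for a in alignments if a.n_mismatches == 1 for g in a.genes)
    pos_1mm = tuple(sorted(a.mismatch_positions for a in alignments if a.n_mismatches == 1))
    pos_2mm = tuple(sorted(a.mismatch_positions for a in alignments if a.n_mismatches == 2))
    summary = GuideAlignmentSummary(
        guide_id=guide_id,
        n_perfect=n_perfect,
        n_1mm=n_1mm,
        n_2mm=n_2mm,
        n_exonic_1mm=n_exonic_1mm,
        genes_hit_perfect=genes_perfect,
        genes_hit_1mm=genes_1mm,
        label="",
        mismatch_positions_1mm=pos_1mm,
        mismatch_positions_2mm=pos_2mm,
    )
    return replace(summary, label=classify_guide(summary))


def classify_guide(summary: GuideAlignmentSummary, clean_level: CleanLevel = "1mm") -> str:
    """Deterministic guide class from its alignment tallies.

    ``clean_level`` decides whether double-mismatch alignments disqualify a
    single-target guide from being "clean": at "1mm" they do not (such a
    guide is labelled double_mm_only), at "2mm" they do as well.
    """
    np_, n1, n2 = summary.n_perfect, summary.n_1mm, summary.n_2mm
    if np_ == 0 and n1 == 0 and n2 == 0:
        return "no_target"
    if np_ == 0:
        return "mismatch_only"
    if np_ == 1:
        if n1 > 0:
            return "single_mm_offtarget"
        if n2 > 0:
            return "double_mm_only"
        return "clean_single"
    # multi-target guides
    if n1 > 0:
        return "multi_target_with_offtargets"
    return "double_target" if np_ == 2 else "multi_target"


def is_clean(summary: GuideAlignmentSummary, clean_level: CleanLevel = "1mm") -> bool:
    """One perfect alignment and no single-mismatch alignments; at level
    "2mm" additionally no double-mismatch alignments."""
    if clean_level not in ("1mm", "2mm"):
        raise ValueError("clean_level must be '1mm' or '2mm'")
    clean = summary.n_perfect == 1 and summary.n_1mm == 0
    if clean_level == "2mm":
        clean = clean and summary.n_2mm == 0
    return clean


@dataclass(frozen=True)
class GeneTargetSummary:
    gene_id: str
    n_guides: int
    n_clean_guides: int
    all_guides_multitarget: bool
    guide_summaries: tuple[GuideAlignmentSummary, ...]


def gene_summary_table(
    summaries: Sequence[GuideAlignmentSummary],
    guide_to_gene: Mapping[str, str | None],
    clean_level: CleanLevel = "1mm",
) -> list[GeneTargetSummary]:
    """One row per intended gene, flagging genes with no clean guide."""
    by_gene: dict[str, list[GuideAlignmentSummary]] = defaultdict(list)
    for s in summaries:
        gene = guide_to_gene.get(s.guide_id)
        if gene is not None:
            by_gene[gene].append(s)
    out = []
    for gene in sorted(by_gene):
        rows = by_gene[gene]
        n_clean = sum(is_clean(s, clean_level) for s in rows)
        out.append(
            GeneTargetSummary(
                gene_id=gene,
                n_guides=len(rows),
                n_clean_guides=n_clean,
                all_guides_multitarget=(n_clean == 0),
                guide_summaries=tuple(rows),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Genotype-aware alignment
# ---------------------------------------------------------------------------

def _apply_haplotype(genome: Genome, snps, carry: set[str]) -> Genome:
    subs = []
    for snp in snps:
        ref_base = genome[snp.contig][snp.position - 1]
        if ref_base != snp.ref.upper():
            raise ValueError(
                f"SNP {snp.snp_id}: reference allele {snp.ref} disagrees with genome base {ref_base}"
            )
        if snp.snp_id in carry:
            subs.append((snp.contig, snp.position, snp.alt))
    return genome.with_substitutions(subs)


def apply_genotype(
    genome: Genome,
    snps: Sequence,
    genotype: Mapping[str, int],
    spacer: str,
    max_mm: int = 2,
    guide_id: str = "",
) -> list[Alignment]:
    """Effective alignments of one guide in one cell line's genome.

    ``snps`` are biallelic records (snp_id, contig, position, ref, alt) with
    the A allele equal to the reference base; ``genotype`` codes minor-allele
    dosage 0/1/2 per snp_id. Homozygous-minor sites substitute the minor
    base before alignment. Heterozygous sites are evaluated on both
    haplotypes; each alignment is reported at its fewest-mismatch haplotype
    and flagged heterozygous when the two haplotypes disagree there.
    """
    hom = {s.snp_id for s in snps if genotype.get(s.snp_id, 0) == 2}
    het = {s.snp_id for s in snps if genotype.get(s.snp_id, 0) == 1}
    g_ref = _apply_haplotype(genome, snps, hom)
    if not het:
        return find_alignments(g_ref, spacer, max_mm, guide_id=guide_id)
    g_alt = _apply_haplotype(genome, snps, hom | het)
    aln_ref = {(a.contig, a.start, a.strand): a for a in find_alignments(g_ref, spacer, max_mm, guide_id=guide_id)}
    aln_alt = {(a.contig, a.start, a.strand): a for a in find_alignments(g_alt, spacer, max_mm, guide_id=guide_id)}
    merged: list[Alignment] = []
    for key in sorted(set(aln_ref) | set(aln_alt)):
        a, b = aln_ref.get(key), aln_alt.get(key)
        if a is not None and b is not None:
            best = a if a.n_mismatches <= b.n_mismatches else b
            differs = (a.n_mismatches, a.mismatch_positions) != (b.n_mismatches, b.mismatch_positions)
            merged.append(replace(best, heterozygous=differs))
        else:
            merged.append(replace(a or b, heterozygous=True))
    return merged
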