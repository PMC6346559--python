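"""Aligner, annotation, summary and genotype-aware alignment tests.

The central guarantee is exhaustiveness: on small genomes the vectorized
aligner must return exactly the alignment set of a naive scan over every
window on both strands.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from screenaudit.alignment import (
    Alignment,
    ExonAnnotation,
    Genome,
    GuideRecord,
    annotate_alignment,
    apply_genotype,
    classify_guide,
    find_alignments,
    gene_summary_table,
    is_clean,
    mismatch_profile,
    revcomp,
    summarize_guide,
)
from screenaudit.snp import SNPRecord

from conftest import random_seq


def brute_force_alignments(genome: Genome, spacer: str, max_mm: int) -> set:
    """Naive window-by-window oracle, independent of the implementation."""
    out = set()
    for contig in genome:
        seq = genome[contig]
        L = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(L - 22):
                win, pam = s[i : i + 20], s[i + 20 : i + 23]
                if "N" in win or "N" in pam:
                    continue
                if pam[1] == "G" and pam[2] == "G":
                    mm = sum(a != b for a, b in zip(win, spacer))
                    if mm <= max_mm:
                        start = i + 1 if strand == "+" else L - i - 19
                        out.add((contig, start, strand, mm))
    return out


class TestFindAlignments:
    def test_unique_embedded_site(self, rng):
        site = random_seq(rng, 20)
        genome = Genome({"c": random_seq(rng, 500) + site + "AGG" + random_seq(rng, 480)})
        hits = find_alignments(genome, site, max_mm=0)
        assert len(hits) == 1
        assert hits[0].start == 501 and hits[0].n_mismatches == 0 and hits[0].strand == "+"

    def test_sox9_sox10_pattern(self, table1_genome):
        """The paralog protospacer pair yields one perfect and one 1-mm hit."""
        genome, spacers = table1_genome
        hits = find_alignments(genome, spacers["A3"], max_mm=2, guide_id="A3")
        assert [h.n_mismatches for h in hits] == [0, 1]
        perfect, mm = hits
        assert perfect.contig == "chr17" and mm.contig == "chr22"
        assert mm.mismatch_positions == (7,)
        assert mm.substitutions == (("C", "G"),)

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_matches_brute_force_oracle(self, rng, max_mm):
        for _ in range(10):
            genome = Genome({"c": random_seq(rng, 1500)})
            spacer = random_seq(rng, 20)
            got = {(a.contig, a.start, a.strand, a.n_mismatches) for a in find_alignments(genome, spacer, max_mm)}
            assert got == brute_force_alignments(genome, spacer, max_mm)

    def test_revcomp_genome_flips_strands(self, rng):
        seq = random_seq(rng, 800)
        spacer = random_seq(rng, 20)
        fwd = find_alignments(Genome({"c": seq}), spacer, 2)
        rev = find_alignments(Genome({"c": revcomp(seq)}), spacer, 2)
        L = len(seq)
        remapped = {(L - a.start - 19, {"+": "-", "-": "+"}[a.strand], a.n_mismatches, a.mismatch_positions) for a in rev}
        original = {(a.start, a.strand, a.n_mismatches, a.mismatch_positions) for a in fwd}
        assert remapped == original

    def test_n_bases_excluded(self):
        spacer = "ACGT" * 5
        genome = Genome({"c": "T" * 30 + spacer + "AGG" + "T" * 30})
        assert len(find_alignments(genome, spacer, 0)) == 1
        # N inside the window
        genome_n = Genome({"c": "T" * 30 + spacer[:10] + "N" + spacer[11:] + "AGG" + "T" * 30})
        assert find_alignments(genome_n, spacer, 2) == []
        # N inside the PAM
        genome_pam_n = Genome({"c": "T" * 30 + spacer + "ANG" + "T" * 30})
        assert find_alignments(genome_pam_n, spacer, 0) == []

    def test_pam_required(self):
        spacer = "ACGT" * 5
        genome = Genome({"c": "T" * 30 + spacer + "ATT" + "T" * 30})
        assert find_alignments(genome, spacer, 0) == []

    def test_minus_strand_coordinates(self):
        spacer = "ACCGTAGGTTCACGATAGCA"
        # embed the reverse complement with the PAM's revcomp ("CCT") 5'-ward
        insert = "CCT" + revcomp(spacer)
        genome = Genome({"c": "T" * 40 + insert + "T" * 40})
        hits = find_alignments(genome, spacer, 0)
        assert len(hits) == 1
        (h,) = hits
        assert h.strand == "-"
        assert h.start == 44  # window occupies positions 44..63
        assert h.pam_seq == "AGG"

    def test_invalid_spacer(self):
        with pytest.raises(ValueError):
            find_alignments(Genome({"c": "A" * 100}), "ACGT", 0)
        with pytest.raises(ValueError):
            find_alignments(Genome({"c": "A" * 100}), "N" * 20, 0)

    def test_deterministic_order(self, rng):
        genome = Genome({"b": random_seq(rng, 400), "a": random_seq(rng, 400)})
        spacer = random_seq(rng, 20)
        hits = find_alignments(genome, spacer, 2)
        keys = [(a.contig, a.start, a.strand) for a in hits]
        assert keys == sorted(keys)


class TestMismatchProfile:
    def test_table1_examples(self):
        pos, subs = mismatch_profile("GCACCTGGCTGACCGCCTCG", "GCACCTGGCTGACGGCCTCG")
        assert pos == [7] and subs == [("C", "G")]
        pos, subs = mismatch_profile("GCTGGTACTTGTAGTCCGGG", "GCTGGTACTTGTAGTCGGGG")
        assert pos == [4] and subs == [("C", "G")]

    def test_identity(self):
        assert mismatch_profile("A" * 20, "A" * 20) == ([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mismatch_profile("A" * 19, "A" * 20)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_revcomp_invariance(self, seed):
        """Reverse-complementing both sequences maps 5' index i -> 21-i,
        leaving PAM-relative positions defined from the other end; the
        number of mismatches is invariant and positions map accordingly."""
        rng = np.random.default_rng(seed)
        s = random_seq(rng, 20)
        p = list(s)
        k = rng.integers(1, 4)
        idx = rng.choice(20, size=k, replace=False)
        for i in idx:
            p[i] = "ACGT"[(("ACGT".index(p[i])) + 1) % 4]
        p = "".join(p)
        pos_fwd, _ = mismatch_profile(s, p)
        pos_rc, _ = mismatch_profile(revcomp(s), revcomp(p))
        assert sorted(21 - q for q in pos_rc) == pos_fwd


class TestAnnotation:
    def test_exonic_and_boundary(self):
        ann = ExonAnnotation([("c", 100, 200, "GENE1")])
        aln = Alignment("g", "c", 120, "+", 0, (), (), "AGG")
        assert annotate_alignment(aln, ann).genes == ("GENE1",)
        # 1-bp overlap at the exon end still counts as exonic
        edge = Alignment("g", "c", 200, "+", 0, (), (), "AGG")
        assert annotate_alignment(edge, ann).region == "exonic"
        outside = Alignment("g", "c", 201, "+", 0, (), (), "AGG")
        assert annotate_alignment(outside, ann).region == "intergenic"

    def test_multiple_overlapping_genes(self):
        ann = ExonAnnotation([("c", 100, 200, "A"), ("c", 150, 300, "B")])
        aln = Alignment("g", "c", 160, "+", 0, (), (), "AGG")
        assert annotate_alignment(aln, ann).genes == ("A", "B")

    def test_matches_interval_oracle(self, rng):
        intervals = [("c", int(s), int(s) + int(l), f"G{i}") for i, (s, l) in
                     enumerate(zip(rng.integers(1, 5000, 20), rng.integers(10, 300, 20)))]
        ann = ExonAnnotation(intervals)
        for _ in range(100):
            start = int(rng.integers(1, 5200))
            aln = Alignment("g", "c", start, "+", 0, (), (), "AGG")
            end = start + 19
            expected = sorted({g for (_, s, e, g) in intervals if s <= end and e >= start})
            assert list(annotate_alignment(aln, ann).genes) == expected

    def test_bed_conversion(self):
        ann = ExonAnnotation.from_bed([("c", 99, 200, "G")])
        assert ann.gene_intervals("G") == [("c", 100, 200)]


def _aln(guide, mm, positions=(), genes=()):
    return Alignment(guide, "c", 1, "+", mm, tuple(positions), tuple(("A", "C") for _ in positions), "AGG", genes=tuple(genes))


class TestSummaries:
    def test_empty_list_is_no_target(self):
        s = summarize_guide([], guide_id="g")
        assert s.n_perfect == 0 and s.label == "no_target"

    def test_clean_single(self):
        s = summarize_guide([_aln("g", 0)])
        assert s.label == "clean_single"
        assert is_clean(s, "1mm") and is_clean(s, "2mm")

    def test_multi_target_with_offtargets(self):
        alns = [_aln("g", 0)] * 2 + [_aln("g", 1, [5])] * 3
        s = summarize_guide(alns)
        assert (s.n_perfect, s.n_1mm, s.n_2mm) == (2, 3, 0)
        assert s.label == "multi_target_with_offtargets"
        assert s.is_double_target

    def test_double_target_iff_two_perfect(self):
        assert summarize_guide([_aln("g", 0)] * 2).label == "double_target"
        assert summarize_guide([_aln("g", 0)] * 3).label == "multi_target"

    def test_double_mm_only_and_clean_levels(self):
        s = summarize_guide([_aln("g", 0), _aln("g", 2, [3, 17])])
        assert s.label == "double_mm_only"
        assert is_clean(s, "1mm") and not is_clean(s, "2mm")

    def test_mixed_guide_ids_rejected(self):
        with pytest.raises(ValueError):
            summarize_guide([_aln("a", 0), _aln("b", 0)])

    def test_order_independence(self, rng):
        alns = [_aln("g", 0)] * 2 + [_aln("g", 1, [4])] + [_aln("g", 2, [1, 20])]
        perm = [alns[i] for i in rng.permutation(len(alns))]
        assert summarize_guide(alns) == summarize_guide(perm)

    def test_classify_examples(self):
        assert classify_guide(summarize_guide([], guide_id="g")) == "no_target"
        assert classify_guide(summarize_guide([_aln("g", 0), _aln("g", 1, [9])])) == "single_mm_offtarget"


class TestGeneSummaryTable:
    def test_flags(self):
        clean = [summarize_guide([_aln(f"g{i}", 0)], guide_id=f"g{i}") for i in range(4)]
        multi = [summarize_guide([_aln(f"m{i}", 0)] * 2, guide_id=f"m{i}") for i in range(2)]
        mapping = {f"g{i}": "GOOD" for i in range(4)} | {f"m{i}": "BAD" for i in range(2)}
        table = gene_summary_table(clean + multi, mapping)
        rows = {r.gene_id: r for r in table}
        assert not rows["GOOD"].all_guides_multitarget and rows["GOOD"].n_clean_guides == 4
        assert rows["BAD"].all_guides_multitarget and rows["BAD"].n_clean_guides == 0

    def test_flags_match_recomputation(self, rng):
        summaries, mapping = [], {}
        for i in range(30):
            gid = f"g{i}"
            n_perfect = int(rng.integers(1, 4))
            n_1mm = int(rng.integers(0, 3))
            alns = [_aln(gid, 0)] * n_perfect + [_aln(gid, 1, [5])] * n_1mm
            summaries.append(summarize_guide(alns, guide_id=gid))
            mapping[gid] = f"GENE{i % 10}"
        table = gene_summary_table(summaries, mapping, "1mm")
        for row in table:
            expected = sum(
                s.n_perfect == 1 and s.n_1mm == 0
                for s in summaries
                if mapping[s.guide_id] == row.gene_id
            )
            assert row.n_clean_guides == expected
            assert row.all_guides_multitarget == (expected == 0)


class TestApplyGenotype:
    def _setup(self, rng):
        spacer = random_seq(rng, 20)
        offtarget = spacer[:12] + ("A" if spacer[12] != "A" else "C") + spacer[13:]
        genome = Genome(
            {"c": random_seq(rng, 50) + spacer + "AGG" + random_seq(rng, 30) + offtarget + "AGG" + random_seq(rng, 30)}
        )
        return spacer, offtarget, genome

    def test_reference_genotype_unchanged(self, rng):
        spacer, _, genome = self._setup(rng)
        snps = [SNPRecord("rs1", "c", 55, genome["c"][54], "T" if genome["c"][54] != "T" else "A")]
        base = find_alignments(genome, spacer, 2)
        eff = apply_genotype(genome, snps, {"rs1": 0}, spacer, 2)
        assert [(a.start, a.n_mismatches) for a in eff] == [(a.start, a.n_mismatches) for a in base]

    def test_offtarget_becomes_ontarget(self, rng):
        spacer, offtarget, genome = self._setup(rng)
        # SNP at the mismatched base of the off-target; minor allele = spacer base
        ot_start = 50 + 20 + 3 + 30 + 1  # 1-based start of the off-target window
        snps = [SNPRecord("rs1", "c", ot_start + 12, offtarget[12], spacer[12])]
        eff = apply_genotype(genome, snps, {"rs1": 2}, spacer, 2)
        by_start = {a.start: a for a in eff}
        assert by_start[ot_start].n_mismatches == 0

    def test_pam_destroyed(self, rng):
        spacer, _, genome = self._setup(rng)
        pam_g2 = 50 + 20 + 2  # second PAM base of the on-target site
        snps = [SNPRecord("rs1", "c", pam_g2, "G", "A")]
        eff = apply_genotype(genome, snps, {"rs1": 2}, spacer, 2)
        assert all(a.start != 51 for a in eff)

    def test_heterozygous_best_haplotype_flagged(self, rng):
        spacer, _, genome = self._setup(rng)
        pam_g2 = 50 + 20 + 2
        snps = [SNPRecord("rs1", "c", pam_g2, "G", "A")]
        eff = apply_genotype(genome, snps, {"rs1": 1}, spacer, 2)
        on = [a for a in eff if a.start == 51]
        assert len(on) == 1 and on[0].heterozygous

    def test_ref_mismatch_raises(self, rng):
        spacer, _, genome = self._setup(rng)
        wrong = "A" if genome["c"][54] != "A" else "C"
        snps = [SNPRecord("rs1", "c", 55, wrong, "G" if wrong != "G" else "T")]
        with pytest.raises(ValueError, match="disagrees"):
            apply_genotype(genome, snps, {"rs1": 2}, spacer, 2)


def test_guide_record_validation():
    with pytest.raises(ValueError):
        GuideRecord("g", "ACGT")
    ntc = GuideRecord("ntc", "A" * 20, None)
    assert ntc.intended_gene is None
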