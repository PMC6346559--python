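"""Synthetic pooled CRISPR screens with planted ground truth.

The generator builds a small genome (kilobases, one contig) in which every
guide target site is planted deliberately: background single-target genes,
paralog families whose members differ at chosen PAM-relative positions,
pseudogene copies, readthrough constructs spanning two genes, guides with
extra perfect or single/double-mismatch copies in intergenic DNA, and SNPs
placed at chosen positions of protospacers and PAMs.

Screen log-fold changes follow the generative model

    y(g,c) = a_c * tau(N(g,c)) + sum_G d_G(g,c) * e(G,c)
             + sum_(A,B) d_A d_B * i(A,B,c) + gamma_c * (CN(g,c) - 1) + eps

where eta(site,c) is the cutting efficiency of one alignment (product of
position-specific mismatch-tolerance weights w(pos), zero when the genotype
destroys the PAM), N(g,c) = sum of eta over the guide's alignments is the
expected number of cut loci, tau(n) = t1*(n-1) + t2*(n-1)^2 is cleavage
toxicity (tau(1) = 0), d_G = 1 - prod(1 - eta) is knockout dosage of gene G,
e(G,c) is the (possibly expression-dependent) gene essentiality effect,
i(A,B,c) is a context-dependent interaction (synthetic lethality when a
redundant partner gene is not expressed), gamma_c scales a copy-number
artifact and eps is Gaussian noise. Non-targeting controls receive noise
only. Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    Alignment,
    ExonAnnotation,
    Genome,
    GuideRecord,
    SPACER_LEN,
    annotate_alignment,
    find_alignments,
    mismatch_profile,
    revcomp,
    summarize_guide,
)
from .snp import SNPRecord, _locate_snp, _spacer_orientation_allele

__all__ = [
    "MismatchToleranceWeights",
    "EffectParameters",
    "ParalogFamilySpec",
    "ReadthroughSpec",
    "MultiTargetSpec",
    "OffTargetSpec",
    "DoubleMismatchSpec",
    "SNPPlacementSpec",
    "GenomeSpec",
    "SimulationConfig",
    "SimBundle",
    "SyntheticTruth",
    "generate_genome",
    "simulate_screen",
    "simulate",
    "make_fixture",
    "FIXTURE_NAMES",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MismatchToleranceWeights:
    """Position-specific single-mismatch cutting-efficiency weights w(pos).

    PAM-proximal (seed) mismatches are poorly tolerated, PAM-distal ones
    increasingly so, with maximal tolerance at position 20. Defaults: 0.05
    for positions 1-10, a linear ramp 0.2 -> 0.8 over 11-19, 0.9 at 20.
    Multiple mismatches multiply their weights.
    """

    proximal: float = 0.05
    ramp_start: float = 0.2
    ramp_end: float = 0.8
    position_20: float = 0.9

    def w(self, pos: int) -> float:
        if not 1 <= pos <= 20:
            raise ValueError("mismatch position must be in 1..20")
        if pos <= 10:
            return self.proximal
        if pos == 20:
            return self.position_20
        return self.ramp_start + (self.ramp_end - self.ramp_start) * (pos - 11) / 8.0

    def efficiency(self, positions: Sequence[int]) -> float:
        out = 1.0
        for p in positions:
            out *= self.w(p)
        return out


@dataclass(frozen=True)
class EffectParameters:
    """Planted effect sizes; tau(n) = t1*(n-1) + t2*(n-1)^2 so tau(1) = 0."""

    t1: float = -0.05
    t2: float = -0.01
    cas9_activity_range: tuple[float, float] = (0.2, 1.0)
    essential_fraction: float = 0.25
    essential_effect: float = -1.0
    sigma: float = 0.1
    cn_log2_sd: float = 0.25
    gamma_range: tuple[float, float] = (-0.35, -0.15)
    expressed_fraction: float = 0.7
    expr_high: tuple[float, float] = (6.0, 1.0)  # mean, sd of log2(rpkm+1) when expressed
    expr_low: tuple[float, float] = (0.7, 0.4)
    expression_threshold: float = 4.0
    tolerance: MismatchToleranceWeights = field(default_factory=MismatchToleranceWeights)

    def tau(self, n: np.ndarray | float) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.t1 * (n - 1) + self.t2 * (n - 1) ** 2


@dataclass(frozen=True)
class ParalogFamilySpec:
    """A family of near-identical genes sharing guide target sites.

    Shared sites are sequence copies differing between members at the given
    PAM-relative positions; with no mismatch positions the members share the
    exact protospacer and a single multi-target guide is created per shared
    site. The last ``pseudogene_members`` members are annotated but carry no
    essentiality effect and get no guides of their own.
    """

    name: str
    n_members: int = 2
    n_shared_sites: int = 2
    n_private_sites: int = 1
    mismatch_positions: tuple[int, ...] = ()
    effect_mode: Literal["none", "constant", "expression_dependent"] = "none"
    expression_mode: Literal["independent", "mutually_exclusive"] = "independent"
    pseudogene_members: int = 0

    def member_ids(self) -> list[str]:
        return [f"{self.name}_{chr(ord('A') + i)}" for i in range(self.n_members)]


@dataclass(frozen=True)
class ReadthroughSpec:
    """Two adjacent genes plus a readthrough transcript spanning both.

    ``n_a_sites`` guides hit gene A and the readthrough, ``n_b_shared_sites``
    hit gene B and the readthrough, and ``n_b_only_sites`` hit gene B alone —
    the incidence structure that makes additive gene scores design-coupled.
    """

    name: str
    n_a_sites: int = 4
    n_b_shared_sites: int = 3
    n_b_only_sites: int = 1
    effect_a: float = -0.5
    effect_b: float = -0.3
    effect_fusion: float = -0.3

    @property
    def gene_a(self) -> str:
        return f"{self.name}_A"

    @property
    def gene_b(self) -> str:
        return f"{self.name}_B"

    @property
    def fusion(self) -> str:
        return f"{self.name}_AB"


@dataclass(frozen=True)
class MultiTargetSpec:
    """Guides with extra perfect copies of their protospacer in intergenic DNA.

    ``counts`` maps a total perfect-alignment count n to the number of guides
    planted with that count; each such guide targets its own non-essential
    single-site gene plus n-1 intergenic copies (pure cleavage toxicity).
    """

    counts: Mapping[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class OffTargetSpec:
    """Guides with intergenic single-mismatch copies at given positions.

    Each entry (k, positions) plants guides with one on-target site and k
    single-mismatch intergenic copies whose PAM-relative mismatch positions
    cycle through ``positions``.
    """

    entries: tuple[tuple[int, tuple[int, ...], int], ...] = ()  # (k, positions, n_guides)


@dataclass(frozen=True)
class DoubleMismatchSpec:
    """Guides with several double-mismatch intergenic copies.

    Plants ``n_guides`` guides, each targeting its own gene that also has
    ``n_clean_extra`` clean guides, with ``n_copies`` intergenic copies
    mismatched at PAM-relative positions (first_pos, second cycling through
    ``second_positions``).
    """

    n_guides: int = 0
    n_copies: int = 6
    first_pos: int = 20
    second_positions: tuple[int, ...] = (19, 18, 17)
    n_clean_extra: int = 2


@dataclass(frozen=True)
class SNPPlacementSpec:
    """How many SNPs to plant in each position class.

    On-target classes pick distinct background-gene guides; the off-target
    classes require guides from an OffTargetSpec with a single 1-mm copy.
    """

    n_proximal: int = 0
    n_distal: int = 0
    n_pam_n: int = 0
    n_pam_g2: int = 0
    n_off_to_on: int = 0  # SNP at the off-target mismatch, minor allele = spacer base
    n_off_elsewhere: int = 0  # SNP elsewhere in the off-target window
    maf: float = 0.3

    @property
    def total(self) -> int:
        return (
            self.n_proximal + self.n_distal + self.n_pam_n + self.n_pam_g2
            + self.n_off_to_on + self.n_off_elsewhere
        )


@dataclass(frozen=True)
class GenomeSpec:
    n_background_genes: int = 20
    guides_per_gene: int = 3
    n_ntc: int = 5
    site_pad: int = 5
    intergenic_length: int = 40
    paralog_families: tuple[ParalogFamilySpec, ...] = ()
    readthroughs: tuple[ReadthroughSpec, ...] = ()
    multi_target: MultiTargetSpec = field(default_factory=MultiTargetSpec)
    off_target: OffTargetSpec = field(default_factory=OffTargetSpec)
    double_mismatch: DoubleMismatchSpec = field(default_factory=DoubleMismatchSpec)
    snps: SNPPlacementSpec = field(default_factory=SNPPlacementSpec)


@dataclass(frozen=True)
class InteractionSpec:
    """Synthetic lethality between two genes gated on a redundant partner.

    i(A,B,c) = ``effect`` in cells where the partner gene's expression is
    below ``threshold`` (no backup, the double knockout is lethal), else 0.
    """

    gene_a: str
    gene_b: str
    partner: str
    effect: float = -1.0
    threshold: float = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_cells: int = 100
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    effects: EffectParameters = field(default_factory=EffectParameters)
    interactions: tuple[InteractionSpec, ...] = ()
    gene_effect_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimulationConfig: seed is mandatory")
        for p in (self.effects.essential_fraction, self.effects.expressed_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def _rand_protospacer(rng: np.random.Generator) -> str:
    return _rand_seq(rng, SPACER_LEN)


def _mutate(rng: np.random.Generator, proto: str, pam_relative_positions: Sequence[int]) -> str:
    """Copy of a protospacer substituted at the given PAM-relative positions."""
    seq = list(proto)
    for pos in pam_relative_positions:
        i = SPACER_LEN - pos  # 0-based 5' index of PAM-relative position pos
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = rng.choice(choices)
    return "".join(seq)


class _Builder:
    """Accumulates sequence segments and 1-based annotation on one contig."""

    def __init__(self, rng: np.random.Generator, contig: str = "chr1"):
        self.rng = rng
        self.contig = contig
        self.parts: list[str] = []
        self.cursor = 0  # 0-based length so far
        self.exons: list[tuple[str, int, int, str]] = []
        self.site_starts: dict[str, int] = {}  # site key -> 1-based protospacer start

    def pad(self, n: int) -> None:
        self.parts.append(_rand_seq(self.rng, n))
        self.cursor += n

    def add_site(self, protospacer: str, key: str | None = None) -> int:
        start = self.cursor + 1  # 1-based
        self.parts.append(protospacer + "AGG")
        self.cursor += SPACER_LEN + 3
        if key is not None:
            self.site_starts[key] = start
        return start

    def add_gene(self, gene_id: str, protospacers: Sequence[str], keys: Sequence[str | None] | None = None, pad: int = 5) -> tuple[int, int]:
        gene_start = self.cursor + 1
        self.pad(pad)
        for i, proto in enumerate(protospacers):
            key = keys[i] if keys else None
            self.add_site(proto, key=key)
            self.pad(pad)
        gene_end = self.cursor
        self.exons.append((self.contig, gene_start, gene_end, gene_id))
        return gene_start, gene_end

    def finish(self) -> tuple[Genome, ExonAnnotation]:
        genome = Genome({self.contig: "".join(self.parts)})
        return genome, ExonAnnotation(self.exons)


@dataclass
class SimBundle:
    """Everything a screen audit consumes, plus the planted truth."""

    config: SimulationConfig
    genome: Genome
    annotation: ExonAnnotation
    guides: list[GuideRecord]
    gene_meta: dict[str, dict]
    snps: list[SNPRecord]
    paralog_pairs: list[tuple[str, str]]
    lfc: pd.DataFrame | None = None  # guides x cells
    expression: pd.DataFrame | None = None  # genes x cells
    cn: pd.DataFrame | None = None  # genes x cells
    genotypes: pd.DataFrame | None = None  # snps x cells
    truth: "SyntheticTruth | None" = None

    @property
    def guide_to_gene(self) -> dict[str, str | None]:
        return {g.guide_id: g.intended_gene for g in self.guides}


@dataclass
class SyntheticTruth:
    """Planted parameters and derived per-guide quantities."""

    cas9_activity: pd.Series  # per cell
    tau_coefficients: tuple[float, float]
    gene_effects: pd.DataFrame  # genes x cells effective e(G, c)
    gamma: pd.Series
    tolerance: MismatchToleranceWeights
    interactions: tuple[InteractionSpec, ...]
    cut_counts: pd.DataFrame  # guides x cells N(g, c)
    dosage: dict[tuple[str, str], np.ndarray]  # (guide, gene) -> per-cell d
    affected_guides: dict[str, str]  # snp_id -> guide_id of the planted pair
    snp_categories: dict[str, str]  # snp_id -> planted position/effect class


def generate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimBundle:
    """Build genome, annotation, guide library, SNPs and paralog pairs."""
    rng = rng or np.random.default_rng(config.seed)
    gs = config.genome
    b = _Builder(rng)
    guides: list[GuideRecord] = []
    gene_meta: dict[str, dict] = {}
    snps: list[SNPRecord] = []
    paralog_pairs: list[tuple[str, str]] = []
    snp_guides: dict[str, str] = {}
    snp_classes: dict[str, str] = {}

    b.pad(gs.intergenic_length)

    essential_draws = rng.random(gs.n_background_genes)
    background_ids = []
    for i in range(gs.n_background_genes):
        gid = f"G{i:03d}"
        background_ids.append(gid)
        protos = [_rand_protospacer(rng) for _ in range(gs.guides_per_gene)]
        keys = [f"{gid}_g{k}" for k in range(gs.guides_per_gene)]
        b.add_gene(gid, protos, keys=keys, pad=gs.site_pad)
        b.pad(gs.intergenic_length)
        for k, proto in enumerate(protos):
            guides.append(GuideRecord(f"{gid}_g{k}", proto, gid))
        essential = essential_draws[i] < config.effects.essential_fraction
        gene_meta[gid] = {
            "role": "background",
            "effect_mode": "constant" if essential else "none",
            "expression_mode": "independent",
        }

    # Guides with extra perfect intergenic copies (pure toxicity).
    idx = 0
    for n_targets, count in sorted(gs.multi_target.counts.items()):
        for _ in range(count):
            gid = f"MT{idx:03d}"
            proto = _rand_protospacer(rng)
            b.add_gene(gid, [proto], keys=[f"{gid}_g0"], pad=gs.site_pad)
            b.pad(gs.site_pad)
            for _copy in range(n_targets - 1):
                b.add_site(proto)
                b.pad(gs.site_pad)
            b.pad(gs.intergenic_length)
            guides.append(GuideRecord(f"{gid}_g0", proto, gid))
            gene_meta[gid] = {"role": "multi_target", "effect_mode": "none", "expression_mode": "independent"}
            idx += 1

    # Guides with single-mismatch intergenic copies.
    idx = 0
    offtarget_guide_ids: list[str] = []
    for k_copies, positions, n_guides in gs.off_target.entries:
        for j in range(n_guides):
            gid = f"OT{idx:03d}"
            proto = _rand_protospacer(rng)
            b.add_gene(gid, [proto], keys=[f"{gid}_g0"], pad=gs.site_pad)
            b.pad(gs.site_pad)
            for c in range(k_copies):
                pos = positions[c % len(positions)]
                b.add_site(_mutate(rng, proto, [pos]), key=f"{gid}_ot{c}")
                b.pad(gs.site_pad)
            b.pad(gs.intergenic_length)
            guides.append(GuideRecord(f"{gid}_g0", proto, gid))
            gene_meta[gid] = {"role": "off_target", "effect_mode": "none", "expression_mode": "independent"}
            if k_copies == 1:
                offtarget_guide_ids.append(f"{gid}_g0")
            idx += 1

    # Guides with several double-mismatch intergenic copies.
    dm = gs.double_mismatch
    for j in range(dm.n_guides):
        gid = f"DM{j:03d}"
        protos = [_rand_protospacer(rng) for _ in range(1 + dm.n_clean_extra)]
        keys = [f"{gid}_g{k}" for k in range(len(protos))]
        b.add_gene(gid, protos, keys=keys, pad=gs.site_pad)
        b.pad(gs.site_pad)
        for c in range(dm.n_copies):
            second = dm.second_positions[c % len(dm.second_positions)]
            b.add_site(_mutate(rng, protos[0], [dm.first_pos, second]))
            b.pad(gs.site_pad)
        b.pad(gs.intergenic_length)
        for k, proto in enumerate(protos):
            guides.append(GuideRecord(f"{gid}_g{k}", proto, gid))
        gene_meta[gid] = {"role": "double_mismatch", "effect_mode": "none", "expression_mode": "independent"}

    # Paralog families.
    for fam in gs.paralog_families:
        members = fam.member_ids()
        shared = [_rand_protospacer(rng) for _ in range(fam.n_shared_sites)]
        functional = members[: fam.n_members - fam.pseudogene_members]
        for m, member in enumerate(members):
            if m == 0:
                member_sites = list(shared)
            else:
                member_sites = [_mutate(rng, s, fam.mismatch_positions) for s in shared]
            privates = [_rand_protospacer(rng) for _ in range(fam.n_private_sites)]
            protos = member_sites + privates
            keys = [f"{member}_s{k}" for k in range(len(protos))]
            b.add_gene(member, protos, keys=keys, pad=gs.site_pad)
            b.pad(gs.intergenic_length)
            is_pseudo = member not in functional
            gene_meta[member] = {
                "role": "pseudogene" if is_pseudo else "paralog",
                "family": fam.name,
                "effect_mode": "none" if is_pseudo else fam.effect_mode,
                "expression_mode": fam.expression_mode,
                "family_index": m,
            }
            if is_pseudo:
                continue
            # Shared-site guides: with no planted mismatches all members share
            # the same spacer, so only the first member contributes a guide
            # (it targets every member perfectly).
            for k, proto in enumerate(member_sites):
                if fam.mismatch_positions or m == 0:
                    guides.append(GuideRecord(f"{member}_g{k}", proto, member))
            for k, proto in enumerate(privates):
                guides.append(GuideRecord(f"{member}_p{k}", proto, member))
        for a in functional:
            for c in functional:
                if a < c:
                    paralog_pairs.append((a, c))

    # Readthrough constructs.
    for rt in gs.readthroughs:
        a_protos = [_rand_protospacer(rng) for _ in range(rt.n_a_sites)]
        b_shared = [_rand_protospacer(rng) for _ in range(rt.n_b_shared_sites)]
        b_only = [_rand_protospacer(rng) for _ in range(rt.n_b_only_sites)]
        fusion_start = b.cursor + 1
        b.add_gene(rt.gene_a, a_protos, keys=[f"{rt.gene_a}_g{k}" for k in range(rt.n_a_sites)], pad=gs.site_pad)
        b.pad(gs.site_pad)
        shared_start = b.cursor + 1
        b.pad(gs.site_pad)
        for k, proto in enumerate(b_shared):
            b.add_site(proto, key=f"{rt.gene_b}_g{k}")
            b.pad(gs.site_pad)
        fusion_end = b.cursor
        for k, proto in enumerate(b_only):
            b.add_site(proto, key=f"{rt.gene_b}_only{k}")
            b.pad(gs.site_pad)
        b_end = b.cursor
        b.exons.append((b.contig, shared_start, b_end, rt.gene_b))
        b.exons.append((b.contig, fusion_start, fusion_end, rt.fusion))
        b.pad(gs.intergenic_length)
        for k, proto in enumerate(a_protos):
            guides.append(GuideRecord(f"{rt.gene_a}_g{k}", proto, rt.gene_a))
        for k, proto in enumerate(b_shared + b_only):
            guides.append(GuideRecord(f"{rt.gene_b}_g{k}", proto, rt.gene_b))
        for gid, eff in ((rt.gene_a, rt.effect_a), (rt.gene_b, rt.effect_b), (rt.fusion, rt.effect_fusion)):
            gene_meta[gid] = {"role": "readthrough", "effect_mode": "constant", "effect": eff, "expression_mode": "independent"}

    b.pad(gs.intergenic_length)
    genome, annotation = b.finish()
    contig_seq = genome["chr1"]

    # --- SNP placement -----------------------------------------------------
    sp = gs.snps
    snp_idx = 0

    def place(coord: int, alt: str, cls: str, guide_id: str) -> None:
        nonlocal snp_idx
        ref = contig_seq[coord - 1]
        snp = SNPRecord(f"rs{snp_idx:04d}", "chr1", coord, ref, alt, maf=sp.maf)
        snps.append(snp)
        snp_guides[snp.snp_id] = guide_id
        snp_classes[snp.snp_id] = cls
        snp_idx += 1

    def other_base(rng, base, forbid=()):
        choices = [x for x in "ACGT" if x != base and x not in forbid]
        return rng.choice(choices)

    # on-target classes use distinct background-gene guides
    on_target_keys = [f"{gid}_g0" for gid in background_ids]
    need_on = sp.n_proximal + sp.n_distal + sp.n_pam_n + sp.n_pam_g2
    if need_on > len(on_target_keys):
        raise ValueError("not enough background genes for the requested on-target SNPs")
    ki = 0
    for n, cls in ((sp.n_proximal, "proximal"), (sp.n_distal, "distal"), (sp.n_pam_n, "pam_n"), (sp.n_pam_g2, "pam_g2")):
        for _ in range(n):
            key = on_target_keys[ki]
            ki += 1
            start = b.site_starts[key]
            if cls == "proximal":
                pos = int(rng.integers(1, 11))
                coord = start + SPACER_LEN - pos
            elif cls == "distal":
                pos = int(rng.integers(11, 21))
                coord = start + SPACER_LEN - pos
            elif cls == "pam_n":
                coord = start + SPACER_LEN
            else:  # pam_g2
                coord = start + SPACER_LEN + 1
            alt = other_base(rng, contig_seq[coord - 1])
            place(coord, alt, cls, key)

    need_off = sp.n_off_to_on + sp.n_off_elsewhere
    if need_off > len(offtarget_guide_ids):
        raise ValueError("not enough single-copy off-target guides for the requested SNPs")
    for j in range(sp.n_off_to_on):
        guide_id = offtarget_guide_ids[j]
        gid = guide_id.rsplit("_", 1)[0]
        ot_start = b.site_starts[f"{gid}_ot0"]
        spacer = next(g.spacer for g in guides if g.guide_id == guide_id)
        ot_seq = contig_seq[ot_start - 1 : ot_start - 1 + SPACER_LEN]
        positions, subs = mismatch_profile(spacer, ot_seq)
        mm_pos = positions[0]
        coord = ot_start + SPACER_LEN - mm_pos
        place(coord, subs[0][0], "off_to_on", guide_id)  # minor allele = spacer base
    for j in range(sp.n_off_to_on, need_off):
        guide_id = offtarget_guide_ids[j]
        gid = guide_id.rsplit("_", 1)[0]
        ot_start = b.site_starts[f"{gid}_ot0"]
        spacer = next(g.spacer for g in guides if g.guide_id == guide_id)
        ot_seq = contig_seq[ot_start - 1 : ot_start - 1 + SPACER_LEN]
        positions, _ = mismatch_profile(spacer, ot_seq)
        mm_pos = positions[0]
        # the added mismatch sits PAM-proximally so the demotion from one to
        # two mismatches actually silences the site
        pos = mm_pos
        while pos == mm_pos:
            pos = int(rng.integers(1, 11))
        coord = ot_start + SPACER_LEN - pos
        # minor allele must not equal the spacer base there (stays a mismatch)
        spacer_base = spacer[SPACER_LEN - pos]
        alt = other_base(rng, contig_seq[coord - 1], forbid=(spacer_base,))
        place(coord, alt, "off_elsewhere", guide_id)

    # NTC guides: spacers absent from the genome (rejection-sampled).
    for k in range(gs.n_ntc):
        while True:
            sp20 = _rand_protospacer(rng)
            if sp20 not in contig_seq and sp20 not in revcomp(contig_seq):
                break
        guides.append(GuideRecord(f"NTC{k:02d}", sp20, None))

    bundle = SimBundle(
        config=config,
        genome=genome,
        annotation=annotation,
        guides=guides,
        gene_meta=gene_meta,
        snps=snps,
        paralog_pairs=paralog_pairs,
    )
    bundle._snp_guides = snp_guides  # type: ignore[attr-defined]
    bundle._snp_classes = snp_classes  # type: ignore[attr-defined]
    return bundle


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------

def _eta_profiles(
    aln: Alignment,
    snps_in_window: list[SNPRecord],
    tol: MismatchToleranceWeights,
) -> tuple[float, float, float]:
    """Cutting efficiency of one site under genotype 0/1/2 of its (single) SNP.

    Heterozygous cells average the two haplotype efficiencies. Sites with no
    overlapping SNP return a flat profile.
    """
    base = tol.efficiency(aln.mismatch_positions)
    if not snps_in_window:
        return (base, base, base)
    snp = snps_in_window[0]  # placement guarantees at most one per window
    loc = _locate_snp(aln, snp)
    assert loc is not None
    cls, pam_rel = loc
    if cls in ("PAM_G2", "PAM_G3"):
        eta_alt = 0.0
    elif cls == "PAM_N":
        eta_alt = base
    else:
        spacer_idx = SPACER_LEN - pam_rel  # 0-based 5' index
        minor = _spacer_orientation_allele(snp.alt, aln.strand)
        positions = set(aln.mismatch_positions)
        # reconstruct the spacer base at that position from the alignment
        sub_at = {p: s for p, (s, _r) in zip(aln.mismatch_positions, aln.substitutions)}
        if pam_rel in positions:
            spacer_base = sub_at[pam_rel]
            if minor == spacer_base:
                positions.discard(pam_rel)  # mismatch resolved: off-target -> on-target
            # else still a mismatch at that position (different base, same weight)
        else:
            # matched position acquires a mismatch unless minor equals spacer base
            positions.add(pam_rel)
        eta_alt = tol.efficiency(sorted(positions))
    return (base, 0.5 * (base + eta_alt), eta_alt)


def simulate_screen(bundle: SimBundle, rng: np.random.Generator | None = None) -> SimBundle:
    """Simulate per-cell LFCs (and covariates) for a generated genome bundle."""
    config = bundle.config
    eff = config.effects
    rng = rng or np.random.default_rng(config.seed + 1)
    n_cells = config.n_cells
    cells = [f"C{i:03d}" for i in range(n_cells)]
    genes = sorted(bundle.gene_meta)

    # cell-level parameters
    a_c = rng.uniform(*eff.cas9_activity_range, size=n_cells)
    gamma_c = rng.uniform(*eff.gamma_range, size=n_cells)

    # expression
    expr = pd.DataFrame(index=genes, columns=cells, dtype=float)
    mutually_exclusive_draw: dict[str, np.ndarray] = {}
    for gene in genes:
        meta = bundle.gene_meta[gene]
        if meta["expression_mode"] == "mutually_exclusive":
            fam = meta["family"]
            if fam not in mutually_exclusive_draw:
                mutually_exclusive_draw[fam] = rng.random(n_cells)
            u = mutually_exclusive_draw[fam]
            m = meta["family_index"]
            expressed = (u >= m * 0.4) & (u < (m + 1) * 0.4) if m < 2 else np.zeros(n_cells, bool)
        else:
            expressed = rng.random(n_cells) < eff.expressed_fraction
        hi = rng.normal(eff.expr_high[0], eff.expr_high[1], n_cells)
        lo = rng.normal(eff.expr_low[0], eff.expr_low[1], n_cells)
        expr.loc[gene] = np.clip(np.where(expressed, hi, lo), 0, None)

    # gene effects e(G, c)
    e = pd.DataFrame(0.0, index=genes, columns=cells)
    for gene in genes:
        meta = bundle.gene_meta[gene]
        effect = config.gene_effect_overrides.get(gene, meta.get("effect", eff.essential_effect))
        if meta["effect_mode"] == "constant":
            e.loc[gene] = effect
        elif meta["effect_mode"] == "expression_dependent":
            mask = expr.loc[gene].to_numpy(dtype=float) >= eff.expression_threshold
            e.loc[gene] = np.where(mask, effect, 0.0)

    # copy number
    if eff.cn_log2_sd > 0:
        cn = pd.DataFrame(
            2.0 ** rng.normal(0.0, eff.cn_log2_sd, size=(len(genes), n_cells)),
            index=genes,
            columns=cells,
        )
    else:
        cn = pd.DataFrame(1.0, index=genes, columns=cells)

    # genotypes
    genotypes = pd.DataFrame(
        {
            cell: {s.snp_id: int(rng.binomial(2, s.maf)) for s in bundle.snps}
            for cell in cells
        },
        dtype=int,
    ) if bundle.snps else pd.DataFrame(index=pd.Index([], name="snp_id"), columns=cells)

    # alignments and per-site efficiency profiles
    guide_ids = [g.guide_id for g in bundle.guides]
    lfc = pd.DataFrame(0.0, index=guide_ids, columns=cells)
    cut_counts = pd.DataFrame(0.0, index=guide_ids, columns=cells)
    dosage: dict[tuple[str, str], np.ndarray] = {}
    snp_by_id = {s.snp_id: s for s in bundle.snps}

    interactions = config.interactions
    for guide in bundle.guides:
        noise = rng.normal(0.0, eff.sigma, n_cells)
        if guide.intended_gene is None:
            lfc.loc[guide.guide_id] = noise
            continue
        alns = [
            annotate_alignment(a, bundle.annotation)
            for a in find_alignments(bundle.genome, guide.spacer, max_mm=2, guide_id=guide.guide_id)
        ]
        # per-site efficiency per cell
        eta = np.zeros((len(alns), n_cells))
        for si, aln in enumerate(alns):
            window_snps = [
                s
                for s in bundle.snps
                if s.contig == aln.contig
                and (aln.start <= s.position <= aln.end or aln.pam_interval()[0] <= s.position <= aln.pam_interval()[1])
            ]
            profile = _eta_profiles(aln, window_snps, eff.tolerance)
            if window_snps:
                gt = genotypes.loc[window_snps[0].snp_id].to_numpy(dtype=int)
                eta[si] = np.asarray(profile)[gt]
            else:
                eta[si] = profile[0]
        n_cuts = eta.sum(axis=0)
        cut_counts.loc[guide.guide_id] = n_cuts
        y = a_c * eff.tau(n_cuts)
        # knockout dosage per gene hit by this guide
        genes_hit = sorted({g for aln in alns for g in aln.genes})
        d_by_gene: dict[str, np.ndarray] = {}
        for gene in genes_hit:
            rows = [si for si, aln in enumerate(alns) if gene in aln.genes]
            d = 1.0 - np.prod(1.0 - eta[rows], axis=0)
            d_by_gene[gene] = d
            dosage[(guide.guide_id, gene)] = d
            y = y + d * e.loc[gene].to_numpy(dtype=float)
        for inter in interactions:
            if inter.gene_a in d_by_gene and inter.gene_b in d_by_gene:
                gate = expr.loc[inter.partner].to_numpy(dtype=float) < inter.threshold
                y = y + d_by_gene[inter.gene_a] * d_by_gene[inter.gene_b] * inter.effect * gate
        # copy-number artifact: highest CN among perfectly-hit genes
        perfect_genes = sorted({g for aln in alns if aln.n_mismatches == 0 for g in aln.genes})
        if perfect_genes:
            cn_guide = cn.loc[perfect_genes].max(axis=0).to_numpy(dtype=float)
        else:
            cn_guide = np.ones(n_cells)
        y = y + gamma_c * (cn_guide - 1.0)
        lfc.loc[guide.guide_id] = y + noise

    truth = SyntheticTruth(
        cas9_activity=pd.Series(a_c, index=cells),
        tau_coefficients=(eff.t1, eff.t2),
        gene_effects=e,
        gamma=pd.Series(gamma_c, index=cells),
        tolerance=eff.tolerance,
        interactions=interactions,
        cut_counts=cut_counts,
        dosage=dosage,
        affected_guides=getattr(bundle, "_snp_guides", {}),
        snp_categories=getattr(bundle, "_snp_classes", {}),
    )
    bundle.lfc = lfc
    bundle.expression = expr
    bundle.cn = cn
    bundle.genotypes = genotypes
    bundle.truth = truth
    return bundle


def simulate(config: SimulationConfig) -> SimBundle:
    """Generate a genome and simulate a screen from one config and seed."""
    rng = np.random.default_rng(config.seed)
    bundle = generate_genome(config, rng)
    return simulate_screen(bundle, rng)


def counts_from_lfc(
    lfc: pd.DataFrame,
    plasmid_reads: int = 500,
    dispersion: float = 0.1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Overdispersed read counts consistent with an LFC matrix.

    Counts are negative-binomial with mean plasmid * 2^LFC and dispersion
    ``dispersion`` (variance mu + dispersion * mu^2); a plasmid column is
    appended. LFC-level output remains the primary path; this is for
    exercising the count-based processing chain.
    """
    rng = rng or np.random.default_rng(0)
    mu = plasmid_reads * np.power(2.0, lfc.to_numpy(dtype=float))
    if dispersion > 0:
        n_param = 1.0 / dispersion
        p = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p)
    else:
        counts = rng.poisson(mu)
    out = pd.DataFrame(counts, index=lfc.index, columns=lfc.columns)
    out["plasmid"] = plasmid_reads
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "myl12_like",
    "sox9_sox10_like",
    "tmed7_ticam2_like",
    "snp_pam_like",
    "double_mm_like",
)


def make_fixture(name: str, seed: int = 2024, n_cells: int | None = None) -> SimBundle:
    """Deterministic input bundles reproducing the audit's study designs.

    myl12_like: two non-essential paralogs share perfect-match guide sites;
    a redundant third gene is expressed in ~60% of cells and the double
    knockout is lethal only where it is silent (context-dependent synthetic
    lethality; the additivity test should reject).

    sox9_sox10_like: two expression-dependent essential paralogs expressed
    in disjoint cell subsets; three of four guides for the first carry a
    tolerated PAM-distal single-mismatch off-target into the second, which
    confounds the self-expression screen.

    tmed7_ticam2_like: a readthrough spanning two genes with the 4/3/1
    shared-guide incidence whose OLS solution is design-coupled.

    snp_pam_like: background guides overlapping planted SNPs in every
    position class, plus guides whose single off-target contains a SNP.

    double_mm_like: guides with >= 5 double-mismatch intergenic copies with
    one mismatch at position 20, next to clean-guide genes for a null band.
    """
    if name == "myl12_like":
        cfg = SimulationConfig(
            seed=seed,
            n_cells=n_cells or 100,
            genome=GenomeSpec(
                n_background_genes=20,
                guides_per_gene=3,
                paralog_families=(
                    ParalogFamilySpec(
                        name="MYL12",
                        n_members=2,
                        n_shared_sites=2,
                        n_private_sites=2,
                        mismatch_positions=(),
                        effect_mode="none",
                    ),
                ),
            ),
            effects=EffectParameters(expressed_fraction=0.6, cn_log2_sd=0.0),
            interactions=(
                InteractionSpec("MYL12_A", "MYL12_B", partner="G000", effect=-1.0),
            ),
        )
        return simulate(cfg)
    if name == "sox9_sox10_like":
        cfg = SimulationConfig(
            seed=seed,
            n_cells=n_cells or 120,
            genome=GenomeSpec(
                n_background_genes=25,
                guides_per_gene=3,
                paralog_families=(
                    ParalogFamilySpec(
                        name="SOXF",
                        n_members=2,
                        n_shared_sites=3,
                        n_private_sites=1,
                        mismatch_positions=(18,),
                        effect_mode="expression_dependent",
                        expression_mode="mutually_exclusive",
                    ),
                ),
            ),
            effects=EffectParameters(cn_log2_sd=0.0, essential_fraction=0.2),
        )
        return simulate(cfg)
    if name == "tmed7_ticam2_like":
        cfg = SimulationConfig(
            seed=seed,
            n_cells=n_cells or 50,
            genome=GenomeSpec(
                n_background_genes=10,
                readthroughs=(ReadthroughSpec(name="RT"),),
            ),
            effects=EffectParameters(cn_log2_sd=0.0, sigma=0.1),
        )
        return simulate(cfg)
    if name == "snp_pam_like":
        cfg = SimulationConfig(
            seed=seed,
            n_cells=n_cells or 150,
            genome=GenomeSpec(
                n_background_genes=40,
                guides_per_gene=1,
                # first entry: PAM-proximal mismatch, silent until a SNP turns
                # the off-target into an on-target; second entry: tolerated
                # position-20 mismatch, active until a SNP adds a second one
                off_target=OffTargetSpec(entries=((1, (5,), 10), (1, (20,), 10))),
                snps=SNPPlacementSpec(
                    n_proximal=8,
                    n_distal=8,
                    n_pam_n=4,
                    n_pam_g2=8,
                    n_off_to_on=10,
                    n_off_elsewhere=10,
                    maf=0.3,
                ),
            ),
            effects=EffectParameters(cn_log2_sd=0.0, essential_fraction=1.0),
        )
        return simulate(cfg)
    if name == "double_mm_like":
        cfg = SimulationConfig(
            seed=seed,
            n_cells=n_cells or 80,
            genome=GenomeSpec(
                n_background_genes=40,
                guides_per_gene=3,
                double_mismatch=DoubleMismatchSpec(n_guides=8, n_copies=6),
            ),
            effects=EffectParameters(cn_log2_sd=0.0, essential_fraction=0.2),
        )
        return simulate(cfg)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
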