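# Methods

## Alignment model

A guide aligns to a genomic site when the 20-nt window differs from its
spacer at no more than `max_mm ∈ {0,1,2}` positions and the 3 nt
immediately 3′ of the protospacer (in spacer orientation) match NGG. The
search is an exhaustive sliding-window scan of both strands — correctness,
not throughput, is the point here, and the synthetic genomes are kilobases.
Genome-scale screens would use an indexed aligner; the brute-force contract
is what the test suite's oracle equivalence rests on.

Conventions, stated once:

* Coordinates are 1-based inclusive everywhere; the BED reader converts
  from 0-based half-open.
* For minus-strand hits, `start` is the forward-strand 5′ coordinate of the
  window; the PAM then occupies `start−3 .. start−1` on the forward strand.
* Mismatch positions are PAM-relative: position 1 is the spacer base next
  to the PAM (5′ index 20), position 20 the most PAM-distal base.
  Positions 1–10 are "PAM-proximal" (the seed), 11–20 "PAM-distal".
* Substitutions are recorded spacer base → reference base, the direction
  library alignment tables print.
* Windows or PAMs containing N are excluded. No alignment-count cap is
  enforced; a warning fires above a configurable threshold (default 10,000).
* Exon overlap of ≥1 bp makes an alignment exonic for that gene; all
  overlapping genes are recorded.
* "Clean" is parameterized: level `1mm` means one perfect alignment and no
  single-mismatch alignments; level `2mm` additionally requires no
  double-mismatch alignments. The off-target delta screen and the
  double-mismatch screen use `2mm`; guide classification tables default to
  `1mm`.
* Genotype-aware alignment substitutes the minor allele for homozygous
  carriers before aligning. Heterozygous sites are evaluated on both
  haplotypes; an alignment is reported at its fewest-mismatch haplotype and
  flagged. (Downstream correlation analyses treat heterozygotes as dosage
  1 of 2; the alignment layer itself does not average.)

## LFC processing

The count chain: drop guides with fewer than 30 plasmid reads (default),
LFC = log2(counts + 1) − log2(plasmid + 1); the pseudocount default of 1 is
shared by both chains and configurable. Normalization centers each
replicate at its median (optionally at the median of non-essential-gene
guides) and divides by the raw MAD (no 1.4826 consistency factor — the
target is MAD 1, not an SD estimate). Scaling divides by the absolute mean
(or median) LFC of guides targeting a supplied essential-gene reference set
so that −1 ≈ essential. Replicates are averaged arithmetically per cell
line.

Copy-number correction fits, per cell line, a continuous piecewise-linear
spline of LFC on relative CN with 4 interior knots at CN quantiles
{0.2, 0.4, 0.6, 0.8}, and subtracts the fitted effect relative to its value
at CN = 1, so diploid-normal guides are untouched and within-CN rankings
are preserved. With fewer than 10 distinct CN values it degrades to a
linear fit with a warning. The knot scheme is our choice; published
CN-correction models use linear splines without printing their knots, so we
document ours rather than guess theirs. Multi-target guides use the
maximum CN across their perfectly matched loci.

## Toxicity model

Per cell line, mean LFC is modelled as a degree-2 polynomial of alignment
count n over n ∈ [1, 8]; counts above 8 are pooled (tail bins are sparse),
and the fit is unweighted per guide. On-target fits exclude guides with any
single-mismatch alignment (their off-targets would confound the curve);
off-target fits condition on exactly one perfect alignment. Adjustment
subtracts f_c(n) − f_c(1), so single-target guides are fixed points and the
operation is linear in the LFC matrix; counts outside the fit domain are
clamped to it with a warning. The per-cell summary metric is the mean LFC
of guides with four perfect (resp. four single-mismatch) alignments,
reported only when at least 5 guides occupy the bin.

## Interaction models

**Delta coefficient.** y_ij = α + β_i + δ·1(j=1) + r_ij over cells i and
guides j (guide 1 of interest, the rest clean). Identifiability is fixed by
sum-to-zero cell effects; δ̂ is invariant to that choice and equals
mean_i(y_i1 − clean-mean_i) exactly (the OLS normal equations collapse to
it), which the tests assert to 1e-10. Classical SEs from the residual
variance. Thresholds follow the audit's conventions: δ < −0.25 is
substantial off-target activity, LFC ≤ −0.5 is high guide activity.

**Additivity test.** Guide×cell observations are pooled per class as
exchangeable replicates — the model is a three-group means model, and the
contrast β_A + β_B − β_AB is tested with a two-sided t. Because
observations within a class share cell lines, cluster-robust (by cell) SEs
are available as an option; the default matches the pooled fit. The
no-interaction reference point for a double knockout is
min(y_A, y_B, y_A + y_B).

**Design OLS.** Gene scores minimize ‖y − Xβ‖² for a guide×gene incidence
X. Rank-deficient designs are not silently pseudo-inverted: genes with a
null-space component are reported unidentifiable (NaN) and the rest
re-solved. The score covariance σ²(XᵀX)⁻¹ is part of the result because the
design-induced correlation between scores (e.g. a readthrough's gene
hanging off a single guide) is itself a finding, not a nuisance.

**Screens.** Coessentiality edges connect genes with Pearson r ≥ 0.35
across cell lines. The self-expression screen ranks genes by the
correlation of their score with their own expression (ascending), flags
genes whose guides carry exonic single-mismatch off-targets into other
genes, and reports raw p plus Benjamini–Hochberg q. The audit flags a gene
when it sits in the top decile of anticorrelation *and* carries such an
off-target.

## SNP effects

SNPs are intersected with protospacers and PAMs of perfect and
single-mismatch alignments. Effect categories are deterministic:
PAM G2/G3 minor alleles destroy NGG; a SNP at a single-mismatch position
whose minor allele (read in spacer orientation) equals the spacer base
turns the off-target into an on-target; any other off-target protospacer
SNP adds a second mismatch; on-target protospacer SNPs (and the inert PAM
N) degrade efficiency. Genotype–LFC association is Pearson r on 0/1/2
dosage with pairwise deletion of missing genotypes; a constant genotype is
an error, not r = 0. Significance uses B = 100 seeded genotype
permutations with the add-one empirical p, (1 + #{|r_null| ≥ |r_obs|})/(B+1)
(the correction avoids p = 0; both one- and two-sided modes exist). Tail
calls compare r_obs against the "higher"/"lower" order statistic of the B
null draws rather than an interpolated quantile: with B = 100 the
interpolated 95% quantile yields an exceedance rate near 6/101, while the
order-statistic rule attains the nominal ~5%.

## Bespoke statistics

**Jonckheere–Terpstra.** J sums, over ordered group pairs, concordant
observation pairs with half credit for ties. The default p is the normal
approximation with the tie-corrected variance; totals ≤ 12 switch to exact
enumeration of all group assignments. For two groups J reduces to the
Mann–Whitney U, which the suite checks. Which tie variant any given
reference implementation uses is rarely stated; ours is the standard
tie-corrected form and is documented as such.

**Fisher 2×2.** The two-sided p sums hypergeometric point probabilities no
larger than the observed table's (the `fisher.test` convention; a
double-one-sided mode is not provided because nothing downstream needs it).
The odds ratio is the conditional MLE: ψ solving E_ψ[X] = x under Fisher's
noncentral hypergeometric distribution, found by bracketed root-finding in
log ψ with log-space weights; boundary tables return 0 or ∞. scipy's
independent implementation serves as a cross-check in the tests, never as
the implementation.

## The simulator

The generator plants every structure the audit looks for, on a single
contig with AGG PAMs and (by construction) plus-strand sites; strandedness
of the *aligner* is exercised separately by the oracle tests. Screens
follow

y(g,c) = a_c·τ(N) + Σ_G d_G·e(G,c) + Σ d_A d_B·i(A,B,c) + γ_c·(CN−1) + ε

with τ(n) = t1(n−1) + t2(n−1)² (defaults t1 = −0.05, t2 = −0.01, so
τ(1) = 0), per-cell Cas9 activity a_c ~ U(0.2, 1), cutting efficiency
η = Π w(pos) over a site's mismatches (0 if the genotype destroys the PAM),
cut count N = Σ_sites η, knockout dosage d_G = 1 − Π(1 − η) capped at 1 by
the complementary product, expression-gated essentiality e (essential
genes −1; "expression-dependent" genes essential only where expressed,
log2(rpkm+1) ≥ 4), synthetic lethality i = −1 gated on a redundant partner
gene's silence, a CN artifact with slope γ_c ~ U(−0.35, −0.15), and
ε ~ N(0, 0.1). Mismatch-tolerance weights w are 0.05 at positions 1–10, a
linear ramp 0.2→0.8 over 11–19, and 0.9 at position 20; double-mismatch
efficiency is multiplicative in the two weights (an assumption — measured
double-mismatch data would refine it). Heterozygous SNP carriers get the
mean of the two haplotype efficiencies. Non-targeting controls receive
noise only, yet their median LFC drifts positive after median-centering a
lethal screen — the relative-abundance artifact emerges rather than being
planted. Read counts, when requested, are negative-binomial around
plasmid·2^LFC with dispersion 0.1; the LFC-level output is the primary
path.

What the simulator does not emulate: real sequence composition and repeat
structure, chromatin or repair-pathway effects on cutting, guide-intrinsic
activity variation, indels and structural variants, and bulge-tolerant
(indel) alignment. Passing tests therefore demonstrate that the estimators
recover the planted generative structure — not that real screens obey it.

Default study conditions: 100–150 cell lines, 20–40 background genes with
3 guides each, essential fraction 0.2–0.25, MAF 0.3 for planted SNPs,
σ = 0.1. Two fixture choices deserve a note: the off-target-to-on-target
SNP vignette plants its single-mismatch off-target PAM-proximally
(weight 0.05), because the mechanism — a silent site activated by the minor
allele — requires the reference site to be uncut; conversely the
mismatch-adding vignette plants a tolerated position-20 off-target that the
SNP's PAM-proximal second mismatch silences. Sample sizes in the tests and
the acceptance script (e.g. 2000 guides for toxicity recovery, 1000 pairs
for permutation calibration, 60–100 oracle cases) are chosen so that each
check is decisively powered at these effect sizes.

## Known limitations

The pipeline's gene score is the mean guide LFC per gene (plus the design
OLS where an incidence is supplied); it does not re-implement iterative
guide-activity/offset estimation, which published scoring models layer on
top of the same additive core. The double-mismatch screen's null band uses
resampled clean-guide genes from the same screen, so very small libraries
give wide bands. LOWESS is delegated to statsmodels and used only for
visual trend fits.
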