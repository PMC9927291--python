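# Methods

This note documents the models implemented in gcpanorama, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that affect results.

## Base-composition decomposition

For each genome, GC is the fraction of G+C among unambiguous bases
(A/C/G/T); N and IUPAC ambiguity letters are excluded from both numerator
and denominator (the number excluded is recorded in the profile), so a
scaffolded assembly does not dilute its GC estimate. GC_CDS is computed over
the union of CDS intervals — overlapping CDS count each base once, and
strand is irrelevant for a base count — and GC_NCS over the complement;
"noncoding" therefore includes RNA genes, which are not annotated
separately. When no ambiguity letters are present, GC is exactly the
length-weighted mean of GC_CDS and GC_NCS.

Codon counting processes each CDS independently (reverse-complemented on the
minus strand, frame 0), drops 1–2 trailing bases of CDS whose length is not
a multiple of three (counted and logged), skips triplets containing
ambiguity letters, and excludes stop codons from both codon and amino-acid
tallies, since the decomposition formulas range over the 20 amino acids.
Translation table 11 (bacterial) is the default and can be overridden.

GC_AA weights each amino acid's dataset-independent mean codon GC (*AC_i*,
the unweighted mean of *C_j* over its synonymous codons) by the genome's
amino-acid frequencies; it is invariant to synonymous codon choice by
construction. GC_Codon holds the amino-acid mix fixed at the across-genome
mean (*AA_i*, the unweighted mean of per-genome frequencies) and weights
codon GC by the genome's within-amino-acid codon preferences *R_j*; an amino
acid never observed in a genome contributes *AA_i*·*AC_i* (the uniform-usage
limit), keeping the sum over all 20 amino acids defined. When synonymous
usage is exactly uniform, GC_Codon collapses to GC_AA of the dataset mean —
an identity the tests exercise.

The bundled amino-acid property table uses standard published scales —
Kyte–Doolittle hydrophobicity, Grantham polarity, average residue molecular
weights, van der Waals side-chain volumes, free-amino-acid isoelectric
points, and nitrogen counts / N-to-C atom ratios from the molecular
formulas. Property means are linear in composition, so any other scale can
be substituted as a TSV without code changes.

## Taxonomy variance partitioning

At a rank with groups g, SS_W = Σ_g Σ_i (x_gi − x̄_g)² and
SS_T = Σ (x − x̄)². The output reports both 1 − SS_W/SS_T under the column
`explained` and SS_W/SS_T under `unexplained`; the two sum to one whenever
SS_T > 0, and for nested labels SS_W can only shrink as ranks get finer.
Genomes lacking a label are excluded per rank, not globally. Constant traits
leave the fractions undefined (NaN) rather than zero.

Rank-sum comparisons use the exact null distribution (exhaustive
enumeration) when both groups have ≤ 12 observations and no cross-sample
ties, and the normal approximation with continuity and tie correction
otherwise; the Bonferroni multiplicity is the number of comparisons in the
invoked batch and is recorded in the output.

## Phylogenetic comparative methods

All statistics build on the BM tip covariance C (shared root-to-MRCA path
lengths). Likelihood work is ML throughout (variance denominators n, not
n − p) so likelihood-ratio tests across nested transforms share one
likelihood; PGLS t-tests are the one exception, using the bias-corrected
residual variance as regression software conventionally does. Linear
algebra goes through Cholesky factorizations — no covariance matrix is
inverted explicitly — and singular covariances (duplicated tips,
zero-length cherries) raise immediately with a pointer to collapse them.

Transforms: λ multiplies off-diagonal covariances (bounded to [0, 1], the
conventional estimator range); κ raises each branch length to a power before
C is rebuilt; δ raises node depths — equivalently each entry of C — to a
power, with depths measured from the root (non-ultrametric input is allowed
with a warning, since the depth convention then matters). κ and δ are
searched in [1e-6, 3]. Each ML fit runs bounded Brent minimization from 5
multistart brackets plus explicit endpoint evaluation, which is robust to
the multimodal profiles that occasionally arise. λ's p-value is a
likelihood-ratio test against λ = 0 using the ½·χ²₁ boundary mixture; κ and
δ are tested against their neutral value 1 with an ordinary χ²₁.

Blomberg's K uses the observed ratio of the tip variance about the GLS mean
to the GLS mean square, divided by its BM expectation
(tr C − n/(1′C⁻¹1))/(n − 1); K = 1 identically on star trees. Significance
is a one-tailed tip-permutation test, p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1)
with a user seed (default n_perm = 999); the permutation p is invariant to
affine transformations of the trait.

Independent contrasts follow Felsenstein's pruning pass; polytomies are
resolved into zero-length bifurcations (warned, with the count), which
leaves the contrast set valid but the extra contrasts arbitrary in sign.

PGLS always includes an intercept, reports R² = 1 − RSS_gls/TSS_gls with
TSS from the GLS intercept-only fit (so R² ∈ [0, 1]), and offers either a
fixed BM correlation structure or joint ML estimation of λ by profile
likelihood; the default is BM, with ML-λ as an explicit option, since
published analyses differ in which they use. Rank-deficient designs are
rejected with the collinear columns named.

Ancestral states are conditional (kriging) expectations of each internal
node's BM state given all tips, with the root fixed at the GLS mean; the
reported standard errors include the uncertainty of the estimated root mean
(universal-kriging variance). Note that a cherry's conditional mean is
shrunk toward the rest of the tree and can lie outside its two tips' range —
this matches phytools::fastAnc exactly and is the expected behaviour of the
marginal conditional mean, not an artifact.

Trees must arrive rooted; a basal trifurcation is rejected with a pointer to
the explicit midpoint-rooting utility rather than silently rerooted.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the estimators assume:
pure-birth (Yule) time trees (ultrametric; simpler than birth–death and
sufficient as an estimator test bed); traits drawn from
N(root·1, σ²·transform(C)) via Cholesky, so transform-parameter truths are
exact; KO presence as independent Bernoulli draws with
logit p = α_j + β_j·z (z the standardized trait), with the per-KO α, β and
effect group recorded in a truth table; and genomes whose CDS are sense
codons drawn from an exponentially GC-tilted distribution
(w_j ∝ exp(θ·g_j), θ solved by bisection so the expected per-base GC equals
the target — one-parameter, monotone, invertible), separated by iid
intergenic spacers at the target GC. Nested taxonomy labels are cut from
the tree at per-rank height thresholds.

Defaults were chosen once as field-realistic desk-scale conditions: the
end-to-end screen uses 500 genomes and 300 KOs (one third positive, one
third negative, one third null couplings at |β| = 2, intercepts N(0, 1));
recovery experiments use 20 replicates of 200-tip trees; the demo pipeline
uses 120 genomes, 120 KOs and 8 sequence-level genomes of 60 CDS × 300 bp.
The trait scale for "GC percent" simulations is root 50, σ² = 60, matching
the spread of bacterial genomic GC (roughly 16–77%).

What passing these tests does *not* show about real data: KO presences here
are conditionally independent given the trait (no gene-gain/loss process on
the tree, no HGT, no correlated pathway structure), genomes contain no RNA
genes, repeats, or assembly artifacts, codon usage within a genome is
homogeneous, and taxonomy is perfectly nested because it is cut from the
true tree. Real screens face phylogenetic pseudo-replication that the
Pearson screen does not correct (that is what the PGLS and PIC routes are
for) and annotation noise that binarization only partly absorbs.

## Numerical choices and degenerate inputs

- GC of a sequence with no unambiguous base is NaN (missing), never 0; the
  same convention marks empty distance-curve bins, zero-variance features in
  the correlation screen, and undefined GC_CDS/GC_NCS.
- GC-difference bins are half-open [k, k+1) percentage points; a pair
  exactly on an edge belongs to the band whose lower edge it sits on.
- The "present in more than 3 families" predictor screen is implemented as
  conservation > 0 in ≥ 4 clades (literal reading of "more than 3").
- Newick serialization uses 12 significant digits, making round trips exact
  to well below 1e-9.
- BM trait draws add a relative 1e-12 diagonal jitter before Cholesky so
  that λ = 0 and duplicated-depth covariances remain factorizable; this is
  below any tolerance used in the tests.
- Exact rank-sum enumeration is limited to both n ≤ 12 (4,900 tables at
  worst); beyond that the tie- and continuity-corrected normal
  approximation takes over.

## Known limitations

- δ (node-depth power) is weakly identified on pure-birth trees of a few
  hundred tips: node depths concentrate near the present, so the expected
  Fisher information is low — the Cramér–Rao bound for δ̂ at 200 tips is a
  standard deviation of roughly 0.26–0.63 across truths 0.5–2. The
  implementation is consistent (mean absolute error ≈ 0.13 by 500 tips) and
  matches dense grid search, but single-tree δ̂ values at desk scale carry
  wide uncertainty and the 200-tip recovery experiment reflects that bound
  rather than an implementation defect.
- K's permutation test, not the analytic variance, is the supported
  significance route; n_perm bounds the attainable p at 1/(n_perm + 1).
- PGLS assumes the predictor matrix is error-free; conservation fractions
  from small clades are noisy predictors and no errors-in-variables
  correction is attempted.
- The pipeline's `compose` stage holds all contig strings in memory; it is
  sized for desk-scale synthetic genomes, not thousands of real assemblies
  at once (the underlying functions stream genome-by-genome if called
  directly).
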