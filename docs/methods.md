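# Methods

This note documents the models, conventions and design choices behind
`tumorevo`, stage by stage in pipeline order.

## Variant filtering and reinterrogation

A cohort is a long table of per-sample variant observations with alt/ref
read counts, an impact annotation (HIGH/MODERATE/LOW/MODIFIER), and one
PASS flag per somatic caller (three callers by default). Conventions:

* **MAF** (mutant allele frequency) is alt/(alt+ref); undefined at zero
  depth (an error for the scalar accessor, NaN in tables).
* **pass_all** means PASS in *every* caller, optionally additionally
  gated on a quality score exceeding a configurable threshold (default 0,
  i.e. disabled — no principled default exists for a cross-caller score).
* MAF thresholds are strict (`> 0.05`), sharing counts inclusive
  (`>= 2`, `>= 3`), following the usual phrasing "greater than 5%" /
  "at least N tumors". Boundary rows (MAF exactly 5%, depth exactly 20)
  are therefore excluded.
* **Reinterrogation**: the union of per-sample high-quality variants
  (pass_all and MAF > 5%) is re-queried in every sample; any observation
  of such a variant with at least one alt read (configurable floor;
  nothing deeper is defensible without base-quality data) is marked
  rescued regardless of caller flags or MAF. Rescue never removes rows,
  so downstream shared-variant sets can only grow — a property the tests
  assert rather than assume.
* Variant counting for per-sample mutation burden (coding impact, MAF >
  5%) uses initial calls by default; a flag includes rescues, since it is
  genuinely ambiguous which convention a given figure uses.
* The recurrent-variant selection intersects three variant-level
  predicates — observed (called or rescued) in ≥ 3 tumors, MAF > 5% in at
  least one observed sample, RNA-expressed (≥ 1 supporting read in any
  tumor RNA sample; floor configurable) — and is order-independent. An
  optional impact restriction (HIGH/MODERATE = coding) is exposed for
  nonsynonymous-only selections.
* Copy-neutral (for the MAF-vs-purity correlation) means total copy
  number exactly 2 at the locus.

## From read counts to clones

Cellular prevalence converts a VAF into the fraction of tumor cells
carrying the mutation under the standard mixture model of tumor (purity
ρ, local total copy number C_T, mutation on m copies) and diploid normal
cells:

    CP = VAF · (ρ·C_T + 2(1 − ρ)) / (ρ·m),  clamped to [0, 1].

Multiplicity defaults to 1 (the mutation sits on one copy) — the
conservative choice when phasing is unavailable; major-copy multiplicity
can be supplied instead.

**Clustering input filter**: depth strictly above 20 in *all* samples
(missing observations fail), MAF strictly above 0.15 in *any* sample, and
a copy-number segment covering the locus in *every* sample.

**Clone model.** Variants are clustered by a multi-sample binomial
mixture: clone k has a CP vector C_k over samples, and a variant's
likelihood under clone k is ∏_s Binomial(alt_s | depth_s, VAF(C_ks)),
with VAF(·) the inverse of the CP transform above. This is a deliberate
stand-in for variational clonal-deconvolution tools with the same
input/output contract (counts + purity + copy number in; assignments and
a clone × sample CP matrix out); it drops their beta-binomial
overdispersion, which the synthetic data do not generate. Fitting is EM:

* E-step responsibilities from binomial log-likelihoods (expected VAF
  clipped to [1e-7, 1−1e-7]);
* M-step: per clone and sample, the CP MLE. Where the VAF coefficient
  a = ρm/(ρC_T + 2(1−ρ)) is constant within a sample (uniform copy
  number), the weighted moment estimator Σr·alt / Σr·depth·a is exact;
  otherwise the unique root of the monotone score function is found by
  50 bisection steps.
* Initialization: one warm start from k-means centroids on the empirical
  per-variant CP matrix plus `n_restarts` random-variant starts. The warm
  start removes most local optima at the true K; the random restarts
  guard the warm start.
* Convergence at relative log-likelihood change < 1e-6 (cap 200
  iterations); clone count chosen by minimum BIC over a K range, with
  K·S + (K−1) free parameters; empty clusters are dropped after hard
  assignment. Everything is seeded; identical seeds give identical fits.

Clones are relabeled clone_0, clone_1, … by decreasing mean CP, so the
truncal clone is clone_0.

## Sample phylogeny, seeding, founders

Each sample's clone-prevalence column is normalized to a probability
distribution (an error if all-zero). Pairwise sample distance is the
Jensen-Shannon divergence computed with base-2 logarithms, reported as
the divergence itself (not its square root), so values live in [0, 1]
bits; 0·log 0 ≡ 0. Base and root conventions differ between software
ecosystems; base-2/no-root was chosen for the bounded, interpretable
scale and is asserted by tests (symmetry, bound, zero-iff-equal).

Trees are built with canonical Saitou–Nei neighbor joining:
Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k); ties in Q are broken at
the lowest (row, column) pair for determinism; the reduced matrix uses
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2; negative branch lengths are clamped to
zero after the raw values are stored in the tree's diagnostics. Output is
an unrooted tree (trifurcating root node), serialized as Newick with
6-significant-digit branch lengths and single-quoted labels where needed.
On additive inputs NJ reproduces all pairwise path lengths exactly, which
the tests check against a least-squares fit over every topology.

**Seeding**: a sample is monoclonal iff exactly one clone has CP at or
above a presence threshold (default 0.1, configurable — no published rule
exists for this cutoff, so it is this package's construction and the
synthetic generator guarantees an unambiguous margin around it).
**Founding clone**: per sample, the clone of maximal CP above the
threshold (ties to the lowest clone id); the cohort founder is the modal
per-sample founder.

## Repertoires, neoantigens, expression

* Horn's modified Morisita index is computed on relative abundances:
  MH = 2Σp_i q_i / (Σp_i² + Σq_i²) over the union clonotype universe —
  1 for identical compositions, 0 for disjoint supports, invariant to
  scaling either count vector.
* The pre/post contrast partitions off-diagonal matrix entries into
  pre–pre, pre–post and post–post pairs and contrasts post–post against
  pre–post with a two-sided Student's t test; pair classes with fewer
  than two values are flagged insufficient instead of tested (two
  pretreatment samples give a single pre–pre pair).
* Neoantigen burden counts distinct peptides with binding percentile rank
  ≤ a cutoff (weak-binder convention 2.0; strong 0.5 — the standard MHC-I
  rank conventions, configurable). Intersample overlap is plain set
  intersection, displayed as log10(count+1) to admit zeros. Overlap uses
  all predicted peptides by default; a rank cutoff can restrict it to
  binders.
* Signature scores are unweighted means of the signature genes present in
  the matrix (absent genes are dropped and the used-gene count reported);
  an optional flag takes the mean on log2(x+1). The raw scale is the
  default because signature matrices arrive in unknown normalizations.
* DE threshold filtering is strict: up means FC > 1.5, p_adj < 0.05,
  base mean > 10; down uses FC < 1/1.5. Preranked gene scores are
  −log10(p)·log2(FC), with p floored at 1e-300 (warning) to keep scores
  finite.

## Statistical toolkit

Student's t test uses the pooled-variance (classical) statistic with
df = n1+n2−2 — Welch is available behind a flag but is not the default
because the pooled form is what "Student's t test" names. Pearson
correlation p-values use the t transform on n−2 df. BH-FDR is the
standard step-up (via statsmodels), asserted against a hand-worked
example. Two-way ANOVA uses type-II sums of squares (statsmodels OLS +
anova_lm) — a defensible default for unbalanced designs when no
convention is stated. Degenerate inputs (zero variance, no residual df)
raise typed errors rather than returning NaN.

## Synthetic cohorts

The generator produces what the analysis consumes, with full ground
truth. Defaults mirror the motivating design: 4 pre + 13 post samples,
8 clones × 50 mutations (shared subclones under ~150 mutations), 200×
Poisson depth floored at 20 (so the depth filter is exercised but rarely
binding), purity uniform on [0.6, 0.9], multiplicity 1, copy number 2
(whole-chromosome SEG segments; a gain fraction is available).

Construction rules and what they guarantee:

* The clone tree is random with clone i's parent uniform on earlier
  clones; the root is truncal (CP 1 in every sample). Each sample
  activates an ancestor-closed clone subset, so the tree sum condition
  (children's CPs sum ≤ parent's) holds by construction.
* Active clones get CP ≥ 0.12 (rejection sampling over Dirichlet
  stick-breaks), inactive clones exactly 0, so seeding labels at the 0.1
  presence threshold are unambiguous and the seeding truth is recoverable
  exactly.
* Every clone is active in at least one sample, and each non-root clone
  has a "home" sample where its CP reaches 0.5: a clone tree in a real
  analysis only contains clones that clustering detected somewhere, and
  0.5 puts the expected VAF at the MAF-0.15 detection boundary at the
  lowest simulated purity. Without this, simulated clones can be
  undetectable *in principle*, which would test the generator rather
  than the method.
* Read counts: alt ~ Binomial(depth, VAF(CP)) at Poisson depth. Caller
  flags: each of three callers independently misses a called variant with
  probability `caller_dropout` (default 0.1), rising to 0.7 below 5% MAF
  — the situation reinterrogation exists to repair.
* Pre and post samples prefer disjoint root-child subtrees
  (`phase_divergence`, default 0.8), giving the phylogeny a real pre/post
  signal to find.
* Repertoires: a shared clonotype pool of size overlap·n plus private
  clonotypes, lognormal counts; expected Morisita-Horn rises
  monotonically with the overlap parameter and is exactly 0 at overlap 0.
* Neoantigens: a fixed fraction of mutations yields a peptide; a sample
  carries a peptide iff the source clone is present; binding ranks are
  drawn per peptide (an HLA property), with `binder_fraction` below the
  weak-binder rank 2.0.
* Expression: lognormal baselines with a known set of genes shifted in
  post samples (half up, half down), plus small gene-set definitions for
  signature scoring.

Everything derives from one seed through spawned generator streams;
identical configurations give byte-identical serialized outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error and strand artifacts (caller
dropout is the only miscall mechanism), subclonal copy number and
multi-copy mutations, beta-binomial overdispersion of read counts, clone
trees violating the infinite-sites assumption, repertoire clonality
structure beyond a shared/private split, and any realistic peptide-MHC
binding model. Results on real cohorts depend on upstream calling,
copy-number and purity quality in ways these tests cannot certify.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the recovery benchmark at
K = 4 clones × 150 mutations over 10 samples at 200× depth (10 seeds),
toy filter cohorts of ≤ 20 variants × ≤ 6 samples (50 draws), 1,000
random distribution pairs for divergence properties, 20 repertoire
overlap settings at 800 clonotypes, and 10,000 null replicates for type-I
calibration — sizes at which every check completes in seconds to a few
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances.

## Package layout

One module per stage: `synthetic` (generator), `filtering` (caller merge,
rescue, selections), `phylogeny` (CP transform, clustering, JSD, NJ,
seeding), `immuno` (repertoire/neoantigen/signature/DE), `stats`
(toolkit), `io` (MAF/SEG/VCF/GMT/Newick/TSV dialects), `pipeline`
(config, stage reports, demo orchestration), `cli` (one subcommand per
stage). Standard statistics go through scipy/statsmodels; trees are
scikit-bio `TreeNode` objects (the NJ construction itself is implemented
here for deterministic tie-breaking and clamp diagnostics, and is
cross-checked against scikit-bio's NJ in the tests); VCF ingest uses
cyvcf2.

## Known limitations

* The clone clustering assumes one CP per clone per sample with binomial
  counts; overdispersed or copy-number-confounded real data will
  fragment clones (no beta-binomial option yet).
* Neighbor joining is unrooted; no outgroup rooting or bootstrap support.
* The two-way ANOVA is fixed-effects only.
* Clone-ancestry (mutation-tree) inference is out of scope beyond
  founding-clone reporting; the clone tree is known only in simulation.
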