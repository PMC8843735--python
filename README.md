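# tumorevo

Multi-region tumor evolution and immunogenomics analysis for rapid-autopsy
style cohorts: many tumor samples from one patient, taken before and after
a targeted therapy, profiled by whole-exome and RNA sequencing.

The package answers the questions such a cohort poses:

* Which somatic mutations are real and shared? Calls from three somatic
  callers are merged with per-caller PASS flags; high-quality variants
  (PASS in all callers, mutant allele frequency > 5%) are *reinterrogated*
  across every tumor, rescuing calls missed at low allele frequency; shared
  variants are cross-referenced against RNA support.
* How are the tumors clonally related? Read counts are corrected for tumor
  purity and local copy number to give each mutation a cellular prevalence
  (CP) — the fraction of tumor cells carrying it:

      CP = VAF · (ρ·C_T + 2(1 − ρ)) / (ρ·m)

  with purity ρ, tumor copy number C_T and multiplicity m. Variants are
  clustered into clones by a multi-sample binomial mixture fitted with EM
  and model selection by BIC (the same input/output contract as
  variational clonal-deconvolution tools). Each sample's clone-prevalence
  column is normalized to a probability distribution; samples are compared
  by the Jensen-Shannon divergence (base 2, bounded by 1 bit) and a
  phylogeny is built with Saitou–Nei neighbor joining. Each tumor is then
  classified as monoclonally or polyclonally seeded, and founding clones
  are reported.
* How did the immune context change? Repertoire similarity between samples
  uses Horn's modified Morisita index on clonotype abundances; neoantigen
  burden and intersample overlap are counted at an MHC binding-rank
  cutoff; immune gene signatures are scored as mean expression;
  differential-expression lists use strict fold-change / adjusted-p /
  base-mean thresholds, with preranked gene scores −log10(p)·log2(FC).
* Inference uses a small shared toolkit: pooled-variance Student's t test,
  Pearson correlation, Benjamini-Hochberg FDR, two-way ANOVA (type II).

Patient data of the motivating study design are controlled-access, so the
package ships a synthetic cohort generator (`tumorevo.synthetic`) that
emulates the cohort shape — 4 pretreatment and 13 posttreatment samples,
~200× exome depth, a clone tree with per-sample prevalences, purity in
[0.6, 0.9], repertoires with controlled overlap — with full ground truth,
so every stage has a recoverable answer.

## Worked example

```bash
tumorevo demo --seed 42 --outdir demo_out
```

simulates one patient (17 tumor samples, 8 clones, 400 mutations) and runs
the full chain. `demo_out/results/summary.json` from this exact command:

```json
{
  "cohort_founding_clone": "clone_0",
  "n_de_down": 7,
  "n_de_up": 20,
  "n_recurrent_variants": 130,
  "neoantigen_burden_pre_vs_post_p": 0.0839672881672424,
  "selected_K": 7,
  "seeding": {"pre_0": "polyclonal", "...": "..."}
}
```

Reading: 130 mutations survive the recurrent-variant filter (shared by ≥3
tumors, MAF > 5%, expressed in RNA); clustering selects 7 clones out of
the 8 simulated (low-prevalence clones below the detectability filter
merge into their parents); the truncal clone `clone_0` is the founding
clone of every sample; most samples are polyclonally seeded; 20 genes up-
and 7 down-regulated post-treatment pass the DE thresholds, and the
pre-vs-post neoantigen burden contrast has p ≈ 0.084. Per-stage tables (CP matrix, JSD distances, Newick
tree, overlap matrices, signature scores) are written under
`demo_out/results/`; `demo_out/inputs/` holds the simulated MAF-style,
SEG-style, clonotype, neoantigen and expression tables plus the ground
truth.

The same stages are available individually (`tumorevo simulate | filter |
cluster | tree | seeding | overlap | neoantigen | signatures`) and as
library functions.

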