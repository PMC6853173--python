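# Methods

## Problem and approach

`xsub` implements a cross-species transcriptomic subtyping analysis for
colorectal cancer (CRC). Genetically engineered mouse models (GEMMs) of
intestinal cancer — genotype codes combining KrasG12D (K), Trp53 loss (P),
Notch1 intracellular domain (N) and Apc mutation (A), e.g. KPN, KP, APN —
produce tumor transcriptomes whose differential-expression (DE) profiles can
be compared with the human consensus molecular subtypes (CMS1–4) and CRC
intrinsic subtypes (CRIS-A–E). The package covers:

1. **Subtype templates.** For each human subtype, a one-vs-rest DE table is
   reduced to its top `n` most significantly up-regulated genes under a
   strict log-fold-change threshold (defaults: n = 75, logFC > 0.75). The
   template is the union gene list with one weight column per subtype (that
   subtype's logFC on its selected genes, 0 elsewhere). Both the per-subtype
   selection sum (4 × 75 = 300, 5 × 75 = 375) and the union size are
   reported, since overlapping selections make them differ.
2. **Cross-species mapping.** Mouse DE tables are translated into the human
   namespace with an orthology table; for one-to-many mappings the partner
   with the highest homology percentage wins. Ties at equal homology break
   by ascending partner id, and post-translation many-to-one collisions keep
   the row with the smallest adjusted p — both rules chosen for determinism
   and auditability, since no canonical convention exists. Unmapped genes
   are counted, never silently dropped.
3. **Model–subtype correlation.** Each model's logFC vector is Pearson-
   correlated with each template column over the template genes present in
   the model's table (per-cell gene count recorded). Two independent
   correlations are compared with Fisher's r-to-z:
   z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)), two-sided normal p.
4. **Patient scoring.** Two families:
   *z-sum panel scores* (NOTCH-, WNT-, KPN/KP-score): per-gene z-scores
   across the cohort (sample sd, ddof = 1) summed over a fixed panel;
   stratification at the (optionally within-stratum) median, strictly-above
   = high. *Signature-correlation scores*: expression restricted to the
   signature genes and mean-centred gene-wise; each sample scored by the
   Pearson correlation of its centred profile with the signature's logFC
   weights; classification at a threshold of 0.1 (two-group high/low by
   default; a three-group ±0.1 positive/negative/unassigned mode exists —
   the two conventions both occur in practice, so the mode is explicit).
5. **Survival.** Kaplan-Meier product-limit curves per group and the
   unweighted k-sample log-rank test (hypergeometric variance-covariance,
   χ² with k−1 df). Deaths are processed before censorings at tied times.
   No confidence bands are computed.
6. **Auxiliaries.** Marker-mean infiltration scores (mean log expression of
   a cell type's markers, then z-standardized per cell type across samples;
   marker sets are user-supplied GMT files), per-genotype metastasis
   incidence with a 2×2 chi-square (no continuity correction by default),
   qPCR relative expression 2^(−ΔCT), and an IUPAC motif scanner for
   putative RBPJ binding sites (default core consensus `TGGGAA`, always a
   parameter) reporting both strands in 1-based forward coordinates.

## DE engine

Differential expression for synthetic cohorts uses a per-gene Welch
(unequal-variance) t-test on log-scale expression, with logFC = difference
of group means and Benjamini-Hochberg adjustment. This is deliberately a
simple, pluggable engine: DE tables produced by any external tool are
accepted as first-class input, and the selection/correlation machinery is
agnostic to their origin. Genes with zero variance in both groups get
p = 1 with the logFC as computed.

## Synthetic data: what it emulates and what it does not

The generator produces the minimal structure the analysis assumes, directly
on the log scale (no count layer — downstream math only ever sees log
expression):

* **Cohort.** Per-gene baseline ~ N(7, 1); i.i.d. Gaussian noise
  (`noise_sd`, default 1.0 log-units); each subtype up-regulates a disjoint
  block of genes (`genes_per_subtype_block`, default 150) by `block_effect`
  (default 1.5 log-units). Disjoint blocks make template sizes and expected
  classifications analytically checkable. Optional additive per-(gene,
  batch) offsets ~ N(0, `batch_effect_sd`) emulate platform effects, which
  the simple per-batch gene-wise centering (global gene means preserved)
  removes exactly.
* **Survival.** Exponential event times with administrative censoring at
  `censor_time` (default 1825 days, a five-year recurrence horizon).
  Log-hazard = `hazard_beta` (default 0.8) × the cohort-standardized mean
  expression of the *last* subtype's block — the poorest-prognosis,
  mesenchymal-like analogue — with the baseline rate set so median baseline
  survival is `censor_time`/2. This is the simplest model exposing a
  score–hazard link for log-rank power checks.
* **Mouse profiles.** A model targeting subtype S plants
  `round(overlap_fraction × block size)` of S's block genes as strongly
  up-regulated (logFC ≥ 1.5 × `lfc_scale`, adjusted p ≤ 1e-7); decoy
  up-regulated genes drawn from outside every block keep the up-set size
  constant, and all other genes get null logFC ~ N(0, 0.3 × `lfc_scale`)
  with uniform p.
* **Orthology.** Every human gene gets one partner (homology ~ U(80, 100));
  exactly `round(frac_one_to_many × n)` genes get a second, strictly
  lower-homology partner, exercising the highest-homology rule.

Not emulated: count-level noise (negative binomial/overdispersion), tumor
purity and stromal admixture, correlated co-expression modules,
non-proportional hazards, informative censoring, real marker biology.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted signal under idealized conditions — not
performance on real cohorts.

Default effect sizes and noise levels are calibration choices for a
clearly-detectable regime (block_effect/noise_sd = 1.5 gives essentially
complete block recovery by Welch DE at n = 500), not estimates of any real
dataset, which is also why the cohort defaults (500 samples, 2000 genes)
are desk-scale rather than transcriptome-scale.

## Numerical conventions

* Standardization always uses the sample standard deviation (ddof = 1);
  zero-variance rows standardize to 0 with a warning rather than NaN.
* Selection ranks by ascending adjusted p, ties by descending |logFC|, then
  ascending gene id; logFC thresholds are strict (>). Selection is invariant
  to input row order.
* Missing panel/signature/marker genes are dropped with warnings, never
  imputed; fewer than 3 overlapping genes is an error for any correlation.
* Log-rank singular variance matrices fall back to a pseudoinverse;
  time-unit rescaling leaves the statistic unchanged.
* `median_stratify` sends scores equal to the median to "low"
  (strictly-above = high), so an all-tied group is all "low".
* Readers reject rather than coerce: non-finite expression values, duplicate
  identifiers, out-of-range probabilities/homologies and unknown subtype
  labels are errors naming the offender.
* All simulation randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global state. Pipeline re-runs with the
  same config produce byte-identical artifacts.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use desk-scale instances chosen
for quick feedback: cohorts of 200–500 samples × 600–5000 genes, 100-seed
recovery sweeps, 500–2000-replicate null calibrations for the log-rank and
Welch engines (both land within 0.05 ± 0.015 at α = 0.05), and randomized
oracle comparisons up to a few thousand elements.

## Known limitations

* The Welch engine is not a substitute for count-based DE models when raw
  counts are available; supply external DE tables in that case.
* Infiltration scoring is marker-set averaging; it does not reproduce any
  specific published deconvolution method's marker lists or normalisation.
* The motif scanner is consensus-matching only (no PWM scores); overlapping
  and palindromic matches are all reported.
* CMS/CRIS labels are inputs; no classifier is bundled.
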