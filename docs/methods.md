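# Methods

## The measurement model

A pooled MRE screen compares each variant's frequency across amplicon
libraries drawn from the same transfected pool. The quantities computed are
ratios of multinomial frequencies:

- **Transcript abundance**: `f_cDNA(v) / f_pDNA(v)`. Dividing by the
  plasmid frequency cancels the (heavily skewed) library composition, so
  the ratio estimates steady-state transcript output per template.
- **Normalised expression**: abundance divided by the abundance of a
  non-targeted control site (complementary to a *C. elegans* miRNA with no
  mammalian counterpart). The control defines 1.0 = unrepressed; its own
  normalised expression is exactly 1 by construction.
- **Translational efficiency (TE)**: `f_heavy(v) / f_monosome(v)` over
  polysome-gradient fractions.
- **Knock-in expression**: `(f_cDNA(v)/f_gDNA(v))` normalised to a
  scrambled-MRE donor; repression = 1 − expression. Normalising to gDNA
  allele frequency removes HDR-efficiency differences between donors,
  which the test suite verifies by rescaling all donor frequencies and
  checking the estimates are unchanged within sampling error.

Counting is exact: reads are trimmed by locating the 5′ flank verbatim and
the following L bases must match an enumerated variant exactly. There is no
error-tolerant assignment; a sequencing error either moves a read to a
neighbouring enumerated variant or into the `other` bucket. Frequencies are
normalised to total retained reads *including* `other` (configurable via
pseudocount; default pseudocount is 0 and unobserved pDNA variants are
reported missing, never imputed).

## Coordinates and naming

Positions are 1-based from the miRNA 5′ end; the seed is nt 2–8 and the
supplementary region nt 13–16. The MRE is stored as DNA 5′→3′ in mRNA
orientation, so miRNA position *i* pairs with MRE string index *L − i*.
Variant ids are `p<pos><altbase>` tokens joined with `+` (e.g.
`p5A+p14G`), ordered by position then base; all ranking ties are broken on
that canonical order so outputs are byte-stable across runs.

Pairing classes: the four canonical Watson–Crick pairs; G:U wobbles for
miRNA G against MRE T and miRNA U against MRE G; everything else is a
mismatch. Flanking bases beyond the L-nt window are ignored for pairing.

## The synthetic-data generator

The generator reproduces the screen's design conditions so that every
estimator has a known answer:

- **Pool composition**: each position carries the complementary base with
  probability 0.91 and each alternative with 0.03. Variants with up to two
  substitutions are enumerated individually (1 + 69 + 2277 categories);
  the k ≥ 3 design mass (~34%) is pooled into an `other` category, since
  enumerating 4^23 sequences is neither tractable nor analysed.
- **Ground truth**: expression(v) = min(1, perfect_level · Π(1 + gᵢ)) with
  one relief factor per substitution,
  gᵢ = wᵢ · base_modifier(alt) · seed_boost^[seed] · wobble_relief^[wobble].
  Defaults: perfect_level 0.1; region weights 2.0 (seed, supplementary) and
  0.5 (elsewhere) with a fixed deterministic per-position jitter
  (×0.75–1.25, rng seed 170817); seed_boost 2.5; wobble_relief 0.5; base
  modifiers A 1.0 / C 0.9 / G 1.15 / T 1.05. The jitter and distinct base
  modifiers make all 69 single-variant truths distinct — real per-position
  effect maps are idiosyncratic, and exact ties would make rank-recovery
  checks ill-posed. These defaults put the simulated mean single-nt fold
  derepression near 3× and seed mismatches above non-seed ones, with
  wobbles always milder than non-pairing substitutions at the same
  position. The model is multiplicative and capped at 1, hence monotone:
  adding a substitution never lowers expression.
- **Libraries**: pDNA counts are multinomial over the enumerated
  categories, a non-targeted spike-in (default 1% of reads; the real
  amplicon share of the co-transfected control is not knowable from the
  design, so it is a parameter) and `other`. cDNA probabilities are pDNA
  design frequency × expression, renormalised; monosome likewise; the
  heavy-polysome library additionally multiplies by expression^te_gamma so
  the per-variant heavy/monosome ratio is expression^γ up to a global
  constant (γ = 1 by default, i.e. transcript loss and translational
  repression move together). The `other` bucket's expression defaults
  to 0.7: under the multiplicative model most deep variants are largely or
  fully derepressed.
- **Reads**: flank5 + variant + flank3, padded/truncated to 150 nt, with
  independent per-base substitution errors (default 1e-3) and constant
  Q40 qualities. `other` reads are random sequence (they carry no
  enumerated variant, so they must not match the flank by construction —
  collisions are vanishingly unlikely at 150 nt).
- **Knock-in pools**: gDNA alleles are 18 donors plus wild type (intact
  SacI site); digestion removes a configurable fraction (default all) of
  wild-type amplicons from both libraries; cDNA probabilities are allele
  frequency × expression with scrambled = wild type = 1. The 2× tandem
  perfect site's expression is a simulator parameter, never predicted from
  the single-site model.

What the generator does *not* emulate: PCR duplicates/jackpotting,
quality-score-dependent error profiles, paired-end overlap, indel (NHEJ)
alleles, cell-to-cell variation, or any biology linking sequence to
repression beyond the stated model. Passing recovery tests therefore
demonstrates that the estimator chain is unbiased and correctly scaled
against its own sampling process — not that the ground-truth model is the
biology of any particular miRNA.

## Numerical and design choices

- **Seeds** are mandatory for every stochastic operation (no wall-clock
  seeding); a fixed seed reproduces count tables and downstream TSVs
  byte for byte.
- **Replicate aggregation** uses the sample s.d. (n−1); a single replicate
  reports an undefined (NaN) s.d. rather than 0. Missing values are
  excluded with the usable-replicate count recorded.
- **Mean fold derepression** across the 69 singles reports a
  normal-approximation 95% CI (1.96·sd/√n).
- **Dictionary**: expression is rescaled to % of the chosen subset's
  maximum mean (configurable to the non-targeted control); adjacent-step
  quartiles use linear interpolation. Panel selection minimises
  |expression − target| with ties to the higher-expression variant; the
  selection error is bounded by half the largest adjacent step for targets
  inside the dictionary's range.
- **Di-nucleotide matrix** cells are the mean over the ≤9 base combinations
  per position pair (the aggregation is not uniquely determined by the
  figure it mirrors; the mean is the obvious symmetric choice). The matrix
  is symmetric with an undefined diagonal.
- **OLS** (`cross_context_fit`) hand-computes the normal equations so that
  a constant response returns slope 0 and R² = 0 instead of an undefined
  correlation; the slope p-value uses the t distribution with n − 2 df.
- **Donor design**: SacI (GAGCTC) is ablated by a single substitution of
  the site's final base (→ GAGCTT), outside the MRE insert; NheI (GCTAGC)
  rides along with every insert; homology arms (default 45 nt) are taken
  verbatim from the locus and validated to be identical across donors.
  Site searches run on both strands (both sites are palindromic, but the
  check is general). The tandem-site spacer defaults to `ACT`. The
  scrambled donor is a fixed permutation of the perfect site, validated to
  introduce neither restriction site.
- **Degenerate inputs**: empty count tables, missing controls, zero-variance
  regressors, loci without the expected restriction site and non-nucleotide
  characters all raise with specific messages rather than propagating NaNs
  (except where the contract is to flag-and-continue: zero pDNA/monosome/
  gDNA frequencies mark that variant missing).

## Problem sizes used in the test and acceptance runs

Simulated screens for recovery checks use pDNA/cDNA depths of 1.7 million
reads × 3 replicates × 5 seeds, which places every single-nt variant above
the 6000-read minimum pDNA coverage observed in the assay this emulates
(0.91²² × 0.03 × 0.99 × 1.7e6 ≈ 6300). Recovery is assessed as
|pooled mean − truth| ≤ 3 × the per-replicate sampling s.d. (measured
across the 15 simulated replicates), plus mean Spearman rank correlation
≥ 0.95 across seeds. Read-level round trips use 40k reads per library;
knock-in pools use 500k reads per library with 2% HDR frequency per donor,
and compare against the delta-method sampling s.d. implied by the
multinomial model (`knockin.expected_repression_sd`) — with only three
replicates an empirical s.d. has two degrees of freedom and is too
unstable to serve as a yardstick.

## Known limitations

- Substitution-only libraries: no insertions/deletions, no thermodynamic
  (ΔG) modelling, no genome-wide target prediction.
- Dictionary rank order is context-dependent in reality (it can change
  between cell types); the package fits cross-context regressions but does
  not predict strength in new contexts.
- Multi-site (2×/4×) controls are carried as panel members with measured,
  not modelled, expression.
- Statistics that are properties of the original biological dataset (the
  published fold-derepression, step-size medians, R² values and repression
  ranges) require the original sequencing data; the pipeline computes all
  of them from any real FASTQ/count input with the same code paths used on
  synthetic data.
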