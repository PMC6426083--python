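# Methods

## The model

dtukit tests for differential transcript usage (DTU): a between-condition
change in the proportions p_i = c_i / Σ_j c_j that a gene's isoforms
contribute to its total expression. The data are per-replicate transcript
abundance estimates (counts, or TPM rescaled to pseudo-counts), optionally
with bootstrap re-quantifications capturing read-assignment uncertainty.

Both tests operate on counts summed across a condition's replicates and use
the G-test of independence without continuity correction:

    G = 2 Σ_cells O ln(O / E),   E_ij = (row_i total)(col_j total) / N

with the convention 0·ln(0/E) = 0, rows whose total is zero dropped before
df = (rows − 1)(cols − 1), and p from the upper tail of the chi-squared
distribution. Tables may be real-valued (TPM-rescaled counts are not
rounded); G is computed on them unchanged. The gene-level test uses the
isoforms × 2 table; the transcript-level test uses the 2×2 table of one
transcript versus its pooled siblings. For a 2-isoform gene the two tables
coincide up to row order, so the two tests return identical statistics — a
property the test suite checks.

Summing replicates discards between-replicate variance, which makes the raw
G-test anticonservative under biological overdispersion. That is deliberate:
stability of the calls is restored not by a dispersion model but by the two
reproducibility filters below, which measure call stability directly.

## Pipeline stages and parameters

1. **Eligibility.** A transcript is *detected* in a condition when its mean
   count across that condition's replicates is ≥ `abundance_threshold`
   (default 5 in routine use; 0, i.e. no pre-filter, in all validation
   experiments here). Applying the threshold to the mean keeps detection
   invariant to replication level. A gene is eligible when ≥ 2 of its
   isoforms are detected in at least one condition (the union reading, so
   complete gains/losses of an isoform — genuine DTU — remain testable) and
   its summed expression is nonzero in both conditions; a transcript is
   eligible when its gene is and it is detected somewhere. Each ineligible
   feature records the first failing reason in the order unannotated →
   absent_in_a_condition → single_isoform → below_abundance_threshold.
   A gene that passes these detection-based rules but has fewer than two
   isoform rows with nonzero summed counts would give a degenerate table; it
   is marked untested (`ineligible`) rather than raising.
2. **Testing and correction.** Gene-level and transcript-level G-tests as
   above; Benjamini–Hochberg within each level's tested family,
   independently (the two levels produce independent result tables).
3. **Effect size.** Dprop = prop_B − prop_A per transcript; a gene's effect
   is max |Dprop| over its isoforms. Significant features with effect below
   `dprop_threshold` (default 0.2) are rejected as `small_effect`. The
   filter is applied after BH and does not shrink the correction family.
4. **Quantification reproducibility.** `n_quant_draws` (default 100) times,
   one bootstrap iteration index is drawn uniformly with replacement per
   replicate, and stages 1–3 are re-run on the drawn counts (eligibility is
   recomputed from the drawn counts; BH is performed within the draw, at the
   same α and Dprop threshold). The Qrep fraction is the share of draws with
   a positive provisional call; a provisional positive must exceed
   `qrep_threshold` (default 0.95). Skipped with a warning when any
   replicate lacks bootstraps.
5. **Inter-replicate reproducibility.** Stages 1–3 are re-run for every
   one-vs-one cross-condition replicate pair (all n_a × n_b pairings; 9 for
   3 vs 3). The Rrep fraction must exceed `rrep_threshold` (default 0.85).
   Skipped with a warning when either condition has < 2 replicates, leaving
   calls unchanged.

Filters only demote: final positives are always a subset of provisional
positives, and relaxing the thresholds through their explored ranges
(0.8–0.95 for Qrep, 0.55–0.85 for Rrep) can only grow the call set. The
first failing criterion becomes the rejection cause, quantification before
inter-replicate.

All randomness (bootstrap draws) flows from the single `seed` in the run
configuration, which is recorded verbatim — along with every threshold and
input checksums — in `provenance.json`, so identical inputs and
configuration reproduce byte-identical result tables.

## The synthetic-data generator

`simulate_experiment` emulates a replicated two-condition experiment at the
count level:

* per-gene mean expression ~ LogNormal(`mean_log`, `sd_log`) (defaults
  ln 100 and 1.0, a typical bulk RNA-seq spread), split across 1–6 isoforms
  by a symmetric Dirichlet(1);
* replicate counts per transcript ~ negative binomial with
  var = m + φm², φ = `dispersion` (default 0.1, bulk-scale biological
  overdispersion; φ = 0 gives the Poisson limit, so the coefficient of
  variation at mean m is √(1/m + φ) and never falls below the Poisson floor
  1/√m);
* bootstrap iterations by multinomial resampling of each replicate's counts
  at its exact library size (each iteration's column sum equals the
  replicate's library size);
* DTU injection: for `n_dtu_genes` randomly chosen candidate genes (≥ 2
  isoforms, condition-A gene mean ≥ `well_expressed_min_mean`, default 100,
  and swap effect ≥ `min_injected_dprop`), the means of the two most
  abundant isoforms (by condition-A mean, ties broken by transcript ID) are
  swapped in condition B. The injected |Dprop| is (m₁ − m₂)/Σm, recorded in
  the truth registry together with the gene and the swapped pair.

What the generator does *not* emulate: read-level simulation and hence
quantifier misattribution between similar isoforms, length biases,
library-preparation artifacts, or correlated isoform usage across genes.
Passing the validation suite therefore demonstrates the statistical
machinery's error control under the stated count model, not robustness to
quantifier-specific biases on real reads.

`null_split` builds a null comparison by sampling two disjoint groups
without replacement from a single-condition replicate pool — any DTU call
between them is a false positive by construction.

## Validation designs and problem sizes

* **Null false-positive control** (the quantity `scripts/acceptance.py`
  recomputes): 50 simulations of 2,000 genes (1–6 isoforms), φ = 0.1,
  100 bootstrap iterations, n = 3 per group drawn from one shared
  condition; caller at defaults with no abundance pre-filter. Reported:
  the median over simulations of the fraction of tested features called
  DTU, at each level; both medians sit far below 0.05.
* **Injection recovery**: 2,000 genes with means centred at 1,000 counts
  (sd_log 0.5) — the smallest round design in which ≥ 200 genes qualify for
  a |Dprop| ≥ 0.5 swap under Dirichlet(1) proportions — with 200 injected
  swaps, n = 3, scored at the gene level against the truth registry without
  reproducibility filters. Replicate noise is set to read-sampling scale
  (φ = 0.01), mirroring benchmark designs in which the replicates of a
  simulated dataset are re-sampled reads from fixed transcript abundances
  and carry technical rather than biological variance. Under bulk-scale
  biological noise (φ = 0.1) the same design still recovers every injected
  swap (sensitivity 1.0, asserted in the suite), but the *unfiltered* FDR
  fluctuates around 0.05–0.10 — precisely the anticonservativeness of the
  summed-count G-test that the reproducibility filters exist to remove,
  and the reason they are on by default.
* Sizes were chosen so the full suite and the acceptance run each complete
  in a few minutes on a single CPU while keeping ≥ 1,600 tested features
  per simulation.

## Numerical choices and edge cases

* G is computed with `scipy.special.rel_entr` and clipped at 0 to absorb
  rounding residue on proportional columns; the vectorized batch engine is
  asserted (in tests) to agree with the scalar definitions to 1e-9.
* BH adjustment delegates to `scipy.stats.false_discovery_control` after
  validating inputs to [0, 1].
* Zero column totals (a gene absent from a condition) are an eligibility
  failure, never a division: proportions are only formed where column sums
  are positive.
* Dominant-isoform switch detection breaks proportion ties by lexicographic
  transcript ID and flags the tie.
* Transcript IDs are matched as exact strings; no version-suffix stripping.
  Transcripts quantified but missing from the annotation are dropped with a
  logged count (recorded in provenance), not an error.
* TPM rescaling multiplies point and bootstrap values by library_size/10⁶
  and leaves them unrounded.

## Known limitations

* Two conditions only; no paired or multi-factor designs.
* No dispersion modelling or proportion shrinkage — call stability is
  enforced empirically via the reproducibility filters, so experiments
  without bootstraps and with < 2 replicates per condition lose both
  filters and inherit the raw G-test's anticonservativeness.
* Salmon's compressed binary bootstrap archives are not parsed; bootstraps
  are accepted as a plain TSV matrix per sample (transcripts × iterations)
  or inside Kallisto's HDF5.
* The inter-replicate filter uses one-vs-one pairs only; larger subsets are
  not explored.
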