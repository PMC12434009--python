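# Methods

This note documents the models and procedures implemented in `trophomode`,
the parameters that matter, the design choices that were genuinely open, and
what the synthetic benchmark does and does not demonstrate.

## Profile construction

The unit of analysis is the species bin: all contigs in one metatranscriptome
sample sharing a closest species-level taxonomic annotation. Expression is
normalized *within* each (bin, sample): per-contig reads-per-kilobase are
divided by the bin-and-sample RPK total over 10^6, so per-contig TPM always
sums to one million regardless of how abundant the bin is in the sample.
This makes profiles comparable between a rare bin in a metatranscriptome
and a cultured transcriptome, which is what lets a model trained on
cultures be applied to environmental bins at all. Consequences worth
remembering: TPM is invariant to multiplying all counts by a constant, and
to expressing length in nt or kb (both asserted in tests); and an all-zero
bin yields an all-zero profile rather than an error, since environmental
samples legitimately lack bins.

Pfam annotation uses the best-bitscore hit per contig among hits with
e-value strictly below 1e-5. Bitscore ties are broken by lexicographically
smallest accession — the choice is arbitrary but must be deterministic, and
ties at identical bitscore are almost always the same domain model family.

Training transcriptomes must pass three quality gates: ≥ 1,200 total
sequences, ≥ 500 assigned Pfam domains, contamination < 50%. Contamination
is consumed as precomputed metadata; recomputing it from ribosomal-protein
taxonomy is out of scope.

## Scaling

Features are min-max scaled to [0, 1] with parameters fitted on the
training profiles. Two open choices were resolved as follows:

* *Constant features* (min = max) map to 0.
* *Environmental profiles* are scaled with the training-fitted parameters
  and clipped to [0, 1]. Refit-per-dataset is available
  (`RunConfig.scaler_mode = "refit"`), but the default treats the training
  scale as part of the model: an environmental Pfam expressed beyond the
  training range saturates rather than extrapolating.

A binarized variant (TPM > 0 → 1) is supported end to end via
`RunConfig.binarize`.

## Classifier and training protocol

The classifier is XGBoost with a three-class softmax. Default
hyperparameters are the mid-grid values (`n_estimators=100, max_depth=10,
learning_rate=0.1, gamma=0.5, reg_lambda=0.5`); `grid_search` evaluates the
full 324-combination Cartesian grid by mean weighted F1 over stratified
5-fold CV, with ties broken by first-in-grid order.

The training corpus is heavily imbalanced (258 phototrophic, 85 mixotrophic,
44 heterotrophic profiles), so feature selection runs on four undersampled
versions of the dataset with 50, 80, 100 and 120 phototrophs (all
mixotrophs and heterotrophs retained). Per version, permutation importance
is computed over 10 random 70/30 splits: fit, score weighted F1 on the
held-out 30%, then per feature shuffle its held-out values, re-predict, and
take `(F1 − F1_shuffled)/F1`, defined as 0 when the baseline F1 is 0.

Resolved ambiguities, recorded here as package conventions:

* **Sign convention.** A feature whose shuffling *degrades* F1 scores
  positive, and positive-mean features are retained
  (`IMPORTANCE_RETAIN_SIGN` in config). Retention in ≥ 1 of the 4
  undersampled datasets suffices, making selection liberal and monotone in
  the number of datasets.
* **Which F1.** Weighted multiclass F1 throughout, including inside
  feature selection.
* **Shuffle scope.** The held-out partition only, without refitting —
  standard permutation importance.
* **Exact shortcut.** A feature the booster never splits on cannot change
  any prediction when shuffled, so its importance is identically 0 and no
  re-prediction is performed for it. This is an identity, not an
  approximation, and is verified against a naive per-feature loop in the
  test suite.

Evaluation uses stratified shuffle-split cross-validation: 6 random
83/17 splits preserving class proportions (not a partition), reporting
per-mode and weighted F1 with standard errors across splits. A split whose
test side misses a class is redrawn under a new sub-seed and logged. The
learning curve subsamples the training side of each split (stratified) to
25/50/75/100% against a fixed test side.

All randomness flows from one top-level seed through named sub-streams
(undersampling, splits, shuffles, fits), so every run is bit-reproducible.

## Environmental application

Three safeguards order the application of the model to environmental bins:

1. **Completeness gate.** A bin must have nonzero TPM for ≥ 70% (inclusive)
   of the Core Transcribed Genes in a sample. With the 605-Pfam reference
   list, 424 expressed CTGs (69.92…% < 70.08…%) is the boundary: 424 pass,
   423 do not. Ineligible bins are emitted flagged, never silently dropped.
2. **Split-prediction exclusion.** Within a grouping unit — cruise+latitude
   for surface transects, latitude+depth for profiles,
   latitude+treatment+timepoint for incubations, date for diel studies —
   all of a bin's predictions are excluded when phototrophy and
   heterotrophy each account for strictly more than 25% of them, since a
   bin cannot plausibly be both under one set of conditions. The rule is
   applied after the CTG gate and before capability aggregation.
3. **Agreement.** The modal-mode fraction across replicates and size
   fractions within each grouping unit quantifies prediction uncertainty.

## Capability calls

Predictions (non-excluded, across all dataset kinds) are aggregated per
bin. Mixotrophic capability requires ≥ 23% (inclusive) of predictions
diverging from the dominant mode, *and* that divergence not be purely a
replicate/size-fraction split; alternatively > 77% (strict) mixotrophy
predictions suffice. Dominant-mode ties break by fixed precedence
heterotrophy > mixotrophy > phototrophy.

The replicate-split caveat is the vaguest rule in the procedure and is
operationalized as: the divergence is *only* a replicate split iff no
grouping unit is unanimous for a single non-dominant mode — i.e. every
divergent prediction co-occurs in its unit with a dominant-mode prediction.
A unanimous unit, even a singleton, counts as evidence of a genuine shift.

One edge the rules leave open: a mixotrophy-dominant bin that triggers
neither branch (e.g. 77% mixotrophy exactly, with the rest a replicate
split). There is no mixotrophic-specialist class, so such a bin is called
mixotrophic-capable — dominance in mixotrophy is itself evidence of the
capability.

## Transcript abundance

The internal-standard estimator
`T/L = (bin reads / standard reads) × standard copies added / volume (L)`
is the standard spike-in accounting; the upstream read merging and mapping
that produce the counts are external to this package. Size fractions from
the same sample are summed (replicate structure preserved), dinoflagellate
concentrations are divided by 6.4 (a named config constant in a per-taxon
correction table) to offset their higher transcript content per unit
carbon, and trophic-group totals are summed across the group's bins within
each replicate and then averaged across replicates, with per-location group
proportions. A sample with zero standard reads is unquantifiable and
raises; a location with zero total abundance yields missing proportions.

## Synthetic benchmark

The generator emulates what the pipeline assumes about real data, nothing
more. Pfams belong to archetypes: photosynthesis-like (15), motility-like
(21), phagocytosis-like (10), housekeeping (605, doubling as the CTG list)
and mode-independent noise (the remainder of 2,000). Expression is drawn
log-normally (log-sd 0.8) with a per-feature mean offset (sd 0.5) drawn
once per Pfam, zero-inflated, and renormalized to the 10^6 TPM simplex.

Each profile also draws a per-sample *activity level* per archetype that
interpolates expression between the archetype's off and on levels.
Phototrophs run photosynthesis at 0.7–1.0 and phagotrophic machinery near
zero; heterotrophs the reverse; mixotrophs run both anywhere in 0.3–1.0.
This produces a continuum of borderline profiles — a mixotroph barely
running its phagocytosis machinery looks nearly phototrophic — which is the
confusion structure observed in real culture transcriptomes, and it makes
each signal Pfam individually informative rather than a redundant copy of
its archetype. Without this mechanism the planted features are mutually
redundant and permutation importance is structurally blind to most of them.

Default class counts are 258/85/44, matching the culture training corpus
composition. At this size (387 profiles × 2,000 Pfams, seed 1) the
benchmark yields cross-validated weighted F1 ≈ 0.95 with mixotrophy the
weakest class, ≈ 130 selected features, and recovery of ≈ 98% of the 46
planted signal Pfams — the same qualitative regime as real training
corpora. These sizes are the package's benchmark conditions; tests and the
acceptance script run at them on a single CPU in a few minutes.

What passing the benchmark does **not** show about real data: the generator
draws profiles independently (no phylogenetic correlation between training
transcriptomes of related species), archetypes are disjoint (real Pfams
serve several roles), expression is log-normal (real TPM tails are
heavier), and environmental bins are simulated from the same expression
model as training profiles (no assembly artifacts, chimeric bins, or
cross-mapping). Accuracy numbers on the benchmark therefore bound
implementation correctness, not field performance.

Mock environmental scenarios name stations, replicates and size fractions;
bins can shift mode along the transect (the `gradient-shift` scenario), CTG
dropout exercises the completeness gate, and spike-in read counts are
generated by inverting the abundance estimator so concentration recovery is
exact up to floating point.

## Numerical conventions

* Probability vectors from the booster are renormalized in float64 so they
  sum to 1 within 1e-9.
* Comparisons follow stated strictness exactly: e-value < 1e-5; QC
  contamination < 50%; CTG coverage ≥ 0.70; exclusion fractions > 0.25;
  capability divergence ≥ 0.23; mixotrophy override > 0.77.
* Degenerate cases: all-zero count groups give all-zero TPM; F1 = 0 before
  shuffling gives importance 0; empty prediction sets are errors for
  dominant-mode and capability calls.
* Sub-seeds are SHA-256 hashes of `"{seed}:{stream}"` reduced mod 2^31,
  so named streams are independent and reproducible across platforms.
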