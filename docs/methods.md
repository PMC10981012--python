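# Methods

This note records the models, conventions and design choices behind
`mirtransfer`, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Duplex model

The duplex scorer is a base-pair-scoring dynamic program, not a
nearest-neighbour thermodynamic model. Pairs score GC=+3, AU=+2, GU=+1;
a run of `L` unpaired nucleotides *between* two pairs on either strand
costs `2 + (L−1)` (affine: opening −2, extension −1); dangling ends are
free, so the empty structure scores 0 and no duplex scores negative.
The miRNA is indexed 1-based 5'→3' and the site is read antiparallel
(site positions decrease along the pair list). The scalar path
(`predict_duplex`) is a suffix DP over "first pair" cells followed by a
greedy front-to-back reconstruction, which returns the exact
lexicographically smallest co-optimal pair set; the batched
sliding-window path (`window_scores`) is a three-state affine DP
(pair / miRNA-gap / site-gap) vectorised across windows, value-identical
to the scalar DP (cross-checked in tests against exhaustive enumeration
of all non-crossing matchings). The scorer is pluggable: anything
producing a `DuplexStructure` can replace it, e.g. an adapter around an
external hybridisation engine.

Trade-off: the simple scoring scheme is exactly verifiable and fast, but
it does not produce free energies in kcal/mol and ignores intramolecular
structure and site accessibility. Scores are comparable within this
package only.

## Seed typing

Windows 2–7 and 3–8 are checked independently; the better verdict wins
(canonical > non-canonical > other). Canonical requires every window
position to be Watson–Crick paired to consecutive site bases. For
non-canonical, GU wobbles are allowed and at most one defect is
tolerated, where the defects between two neighbouring paired positions
count as `max(miRNA gap, site gap)` — an unpaired miRNA base facing a
skipped site base is a single mismatch, not two defects. Unpaired
positions at the window edges count one each.

## Negative generation

A negative is a uniform permutation (Fisher–Yates) of the positive's
miRNA, redrawn (up to `max_attempts = 1000`) until its 6-mers at
positions 2–7 and 3–8 equal no catalogue miRNA's corresponding 6-mers —
exact string equality, same window against same window, which is the
strictest reading and prevents seed-mimicking negatives. Its site is the
most favourable UTR window (length = miRNA length + 5, step 1, ties to
the leftmost). Negatives' sites may overlap positive sites in the same
UTR; nothing forbids it. Pairs that exhaust the shuffle budget are
dropped with a warning, which unbalances the dataset and is surfaced to
the caller.

## Features

45 features spanning four families: seed-status indicators per window,
Watson–Crick/GU/unpaired counts in miRNA regions 1–8 (seed), 9–12
(central) and 13–end (3'-compensatory), duplex score and pairing totals,
site mono- and di-nucleotide composition with AU/GC content, site
relative position in the UTR, and miRNA composition. Order and names are
pinned by `feature_schema_v1.json`; extraction is pure. The set is a
deliberately compact stand-in for the much larger catalogues used with
real CLIP/CLASH data — the transfer and explanation machinery only needs
a rich, fixed tabular input.

## Splits and chunks

Datasets are split 72/8/20 (train/validation/test; the validation share
is 10% of the 80% training portion), stratified at the miRNA level, ten
repeats. miRNAs with a single interaction go entirely to the test set so
every model must score unseen miRNAs. Integer allocation rounds each
miRNA's fractional shares to floor or ceil (never more than one row from
the ideal) with running global deficits deciding the rounding direction,
so the global 72/8/20 totals also land within one row. Transfer chunks
are cumulative nested draws of 100..500 training rows, label-balanced
50/50 (the fine-tuning signal stays balanced like the full data); chunk
nesting matches the way transfer curves are reported per cumulative
count — independent redraws per point would confound the curve.

## Models and transfer mechanisms

The dense network is implemented in numpy: ReLU hidden layers, sigmoid
output trained with binary cross-entropy (with-logits form), inverted
dropout, L2 weight decay, Adam, minibatches of 64, optional early
stopping with best-weights restoration. Features are standardised with
training-set statistics stored in the model. Default architecture
64→32→1 with dropout 0.2 — a funnel sized for this package's feature
count; every element is configurable. Transfer freezes a configurable
set of dense layers (default: all but the last two, i.e. the input layer
for the default depth); frozen layers are simply excluded from updates,
so they remain bitwise identical, and the fine-tuned copy re-uses the
source scaler so frozen weights keep their meaning. Fine-tuning
early-stops on the *target validation split* when one is supplied: the
split design reserves a fixed 8% validation share, and stopping on
target-domain loss catches the best adaptation point before the chunk is
overfitted and the source knowledge forgotten. The mix
(source-plus-chunk, no transfer) configuration instead validates on the
source validation split, because its training set is source-dominated
and the validation share is defined as a fraction of the training set.

XGBoost transfer is boosting continuation: the source ensemble is copied
verbatim and `n_new_trees` (default 50 per 100-observation chunk call)
additional trees are fitted on the chunk starting from the source
margins, with the learning rate halved — small chunks need low-variance
updates. Source hyperparameters are otherwise re-used in the transfer
phase. Determinism: exact tree method, single thread, explicit seeds.

With zero target observations both mechanisms are the identity: the
transfer model *is* the source model.

## Synthetic data

Two generation modes feed the same table type. **Sequence mode** builds
miRNA catalogues (20–24 nt), 3'UTRs, and positives whose embedded sites
classify (by rejection sampling against the package's own classifier) as
canonical or non-canonical, never "other". The divergence knob δ
perturbs the non-canonical fraction multiplicatively (so a zero fraction
stays zero), lowers site/UTR GC content, and raises flank AU content.
miRNA multiplicities are geometric, so singleton miRNAs arise naturally;
the multiplicity law of real catalogues is not characterised here and
the geometric choice is a stand-in.

**Feature mode** draws labels Bernoulli(sigmoid(w_s · x)) from a shared
logistic rule with per-species deviations, balanced to exactly 1:1 by
resampling, with the species logit centred empirically so prevalence
stays near one half under any displacement. A species at divergence δ
may carry: additive weight deltas on its subset of rule features, mean
and spread displacement of those features, a compositional signature
(small mean offsets across *all* features), and a spread profile.
Features outside the declared deviation set keep identical marginals
across species. A shared set of pairwise product terms (interactions)
can make the backbone nonlinear. Deviation features can be
*lineage-specific* (zero shared base weight — new rules) or
*recalibrations* of shared-weight features.

Two named condition sets pin the experiments:

- `study_conditions` (transfer-curve and merging experiments): 200
  features, base weights N(0, 0.18²) — a weak signal spread thinly, so
  learning the shared rule from a few hundred rows is genuinely hard and
  a pre-trained source model carries real value — with per-species
  recalibration of a 6-feature subset (weight deltas 0.75δ, mean shifts
  0.5δ) and a compositional signature of sd 0.5δ per feature.
- `explanation_conditions` (TransferSHAP recovery): 20 features,
  base weights N(0,1), each species owning 4 lineage-specific rule
  features with unit-δ weights and a pronounced 2.5δ mean displacement —
  the regime in which the transfer step has a crisp planted answer.
  Each `<source,target>` run draws its own chunk of the target training
  split, so any same-target grouping of importance vectors is driven by
  the planted divergence, not by shared fine-tuning data (with a single
  shared chunk per target, same-target grouping appears even at δ=0).
  Boosting continuation uses 250 new trees here, matching the cumulative
  five-chunk budget of the curve experiments.

What passing tests show — and what they do not: the generators plant
linear(-plus-products) logistic structure with Gaussian features. Real
CLIP/CLASH data have correlated, heavy-tailed features, label noise from
chimera calling, and rule differences far richer than weight shifts.
The synthetic experiments validate the *machinery* (mechanisms,
identities, recovery of planted structure at realistic effect sizes),
not the biological accuracy of any particular trained model.

## Metrics and experiment harnesses

ACC, F1 = TP/(TP + 0.5(FP+FN)), MCC with the zero convention when any
denominator factor vanishes, and AUC as the Mann–Whitney rank statistic
(ties count one half; undefined and reported missing for single-class
labels). Binarisation threshold 0.5, recorded in every result. Reported
aggregates are means over split repeats. The cross-species harness
reproduces the intra-species harness exactly when source and target are
the same table (same splits, same model seeds). The transfer-curve
harness evaluates every configuration on the fixed target test set,
asserts that no test id ever enters a chunk, and reports the full-data
baselines as constants across chunk sizes. The target-only
configuration is undefined at chunk 0 (no training data) and is emitted
for sizes ≥ 100 only.

## TransferSHAP

Shapley matrices use the positive-class sign convention. Back-ends:
exact coalition enumeration (≤ 12 features; satisfies local accuracy to
numerical precision), an unbiased permutation-sampling estimator with
recorded draw count and seed, and xgboost's path-dependent TreeSHAP for
the tree family (contributions in margin space — consistent within a
family, which is all the differencing requires; note the two phases of
one continued ensemble differ exactly by the new trees' contributions).
The background distribution defaults to the evaluation table; the
recovery experiment passes the source training sample for the source
phase and a chunk-augmented sample for the target phase. Evaluation
observations are the target pair's test set: aligned rows are required
by the subtraction, and the purpose is explaining target-domain
behaviour.

`transfershap` aggregates `Σ_obs |φ_target − φ_source|` per feature —
elementwise absolute difference of one signed matrix per phase; a
class-split variant is future work. Importances are MinMax-normalised
per vector (a no-op ahead of the rank-based correlation, kept for
interpretability of the reported vectors); pairs are compared by
Spearman ρ with average-rank ties, clustered with average linkage on
1 − ρ. The evaluation-set and linkage choices are conventions, not
claims.

The recovery experiment trains all ordered species pairs, reports each
pair's top-k recall of its planted deviation features (k = size of the
union of source and target subsets), the pair-correlation matrix, the
dendrogram cut at the species count, and the adjusted Rand index against
the same-target partition, with a label-permutation p-value available
for null controls. With three species and six ordered pairs the
permutation null has only 15 distinct partitions, so attainable p-values
are bounded below by about 0.067.

## Numerical and procedural conventions

- All randomness flows through explicit `numpy.random.Generator` seeds;
  no global state. Identical inputs and seeds give byte-identical
  outputs, including FASTA serialisations.
- Degenerate inputs fail loudly: single-class training labels,
  all-layers-frozen transfer, empty chunks, schema mismatches, dangling
  sequence references and impossible species specifications raise with
  the offending name in the message.
- Grid search is exhaustive with first-in-declared-order tie-breaking.
- Experiment problem sizes (3000 observations per species, 10 seeds for
  curve and clustering experiments, 250 evaluation observations for
  tree-based Shapley matrices, 80 for sampling-based ones) are the
  package's reference desk-scale settings; all are parameters.

## Known limitations

- The duplex model is not thermodynamic; seed typing is purely
  structural.
- The dense network is CPU-bound numpy; architectures beyond
  feed-forward and calibrated probabilities are out of scope.
- TransferSHAP is binary-class only, and the ANN family's same-target
  clustering is markedly weaker than the tree family's in the reference
  experiments (the importance vectors still recover the planted
  features; their pairwise rank correlations organise less cleanly).
- Feature-mode data are Gaussian and independent per feature; sequence
  mode does not simulate read-level artefacts or expression.
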