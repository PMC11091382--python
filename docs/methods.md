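# Methods

`errmir` implements a marker-discovery strategy for multi-center small-RNA
sequencing studies in which the predictive features are *within-sample
expression ratios* of miRNA pairs connected through a transcription-factor
(TF)-mediated regulatory network, rather than individual miRNA abundances.
This note records the models, the numerical choices, and what the bundled
synthetic data generator does and does not emulate.

## The interaction network

miRNAs repress TFs by binding their 3'UTRs; TFs activate or repress miRNA
transcription. Composing a miRNA→TF layer with a TF→miRNA layer yields
directed miRNA→miRNA influences: edge (a, b) exists iff some TF t has a→t
in the first layer and t→b in the second, and each edge stores the exact
set of mediating TFs. Self-loops are dropped; reciprocal edges (a, b) and
(b, a) are kept as distinct directed edges. Because the two database
families name miRNAs at different maturity levels (miRNA→target resources
use mature ids, TF→miRNA resources use precursors), precursor endpoints
are expanded through an explicit precursor→mature table: each precursor
edge expands to the cross-product of its mature forms, mediator sets of
edges that collapse onto one mature pair are merged by union.

Two readings of the composition rule exist: the a→TF→b chain used here
(the only reading that consumes both collected layers) and a co-targeting
relation (a and b regulate the same TF). Both are implemented
(`join_mode={"chain", "co_target"}`); chain is the default.

Topology metrics (degree histogram, clustering, average shortest path) are
computed on the undirected projection, path metrics on its largest
connected component. The power-law exponent is the negated OLS slope of
log count vs log degree over observed degrees ≥ 1 — a deliberately simple,
reproducible tail summary, not a maximum-likelihood power-law fit.

## Ratio features

For a network edge (a, b) and RPM-scale expression,

    ERRmiR(a, b) = expr(a) / (expr(b) + 1),

the +1 keeping the divisor positive when b is undetected. The formula's
typography admits a second reading ((a/b) + 1); the stated purpose of the
offset — avoiding a zero divisor — singles out a/(b+1), which is what is
implemented. miRNAs whose median training RPM falls below 100 are removed
before feature construction (aggregation configurable to mean or min; the
filter is computed on training samples only and frozen, to avoid
information leakage into test or validation data).

The batch-robustness mechanism is scale cancellation: multiplying a sample
by a library factor c moves log2 ERRmiR by log2((b+1)/(b+1/c)), which is
at most ≈ 0.05 for b ≥ 100 and c ∈ [1/4, 4], while raw log2 expression
moves by the full |log2 c| (up to 2). The stability report quantifies this
on data: per-feature absolute spread of per-batch medians on the log2
scale (log2(x+1) for raw expression, log2(ratio) for features) plus
per-batch quartiles. Note that with the log2(x+1) raw transform a 2×
scaling of values ≥ 100 shifts raw medians by ≈ 0.993, not exactly 1.

Downstream statistics operate on log2(ratio + ε) with ε = 2⁻²⁰, so
zero-valued ratios (undetected numerator) remain finite.

## Screening

Univariate stage: per feature, log2 fold change of group means on the log2
scale, a two-sided Mann–Whitney U test (Welch's t available; the rank test
is preferred because ratio features are right-skewed), and
Benjamini–Hochberg FDR control. Candidates require q < α (default 0.05)
and |log2FC| ≥ fc_min (default 1.0). Constant features get p = 1 by
convention. A practical note on the gate: a fold-change threshold placed
exactly at the expected effect size has ~50% power per feature, because
the estimate is centred on the gate. Screens that target k-fold effects
should therefore gate at roughly half that effect; the bundled experiments
against 2-fold planted signals use fc_min = 0.5 for this reason.

Wrapper stage: a genetic algorithm over binary feature masks. Fitness is
the mean stratified k-fold cross-validated AUC (or accuracy) of the
downstream SVC pipeline on the masked features, minus
`max_subset_penalty × |subset| / n_features`; the empty mask scores 0.
Operators: tournament selection (size 3), uniform crossover (p = 0.8),
per-bit mutation (1/L), elitism (1), population 50, 40 generations by
default. The population is initialised sparsely (expected 8 bits set), the
conventional choice for wrapper feature selection. Fitness values are
memoised per chromosome within a run. With elitism ≥ 1 the best-so-far
fitness trace is non-decreasing.

The GA is repeated n times (default 100) with seeds seed+0 … seed+n−1,
and a feature's *appearance frequency* counts the runs whose final optimal
subset contains it (once per run, not per generation). The CV split inside
the fitness function is re-randomised per run: with a shared split all
repeats converge to near-identical optima and the frequency table
degenerates to an indicator; re-randomisation makes the frequency measure
the sampling stability of each feature, which is what the repeated-run
design is for. Markers are the top-k features by (count desc, id asc);
the lexicographic tie-break keeps the selection deterministic.

The subset-size penalty deserves a note: it exists to break ties among
AUC-equivalent subsets toward parsimony and must stay well below
meaningful AUC differences. At 0.05 the per-feature cost is ≈ 0.002 for
30 candidates; larger values (≥ 0.2) were found to exceed the marginal
AUC contribution of genuinely informative features once a few strong ones
are already selected, pruning true signal. Default is 0 (pure CV score);
the bundled experiments use 0.05.

## Classifier and evaluation

Pipeline: log2(x+ε) → per-feature standardisation (training statistics) →
RBF-kernel C-SVC (C = 1, kernel width by the "scale" convention). Risk
scores are Platt-calibrated probabilities: a sigmoid fitted to
out-of-fold decision values from an internal stratified 5-fold CV. All
fitted quantities are plain arrays — transform statistics, support
vectors, dual coefficients, sigmoid parameters, threshold — so models
serialise to JSON and re-score bit-identically; scoring is an own
numpy implementation of the RBF decision function plus sigmoid.

Train/test split: stratified 0.75:0.25, seed-reproducible (total train
size floor(0.75·n), per-class allocation as close to proportional as
rounding allows — 100 balanced samples give exactly 75/25). Evaluation:
ROC over all thresholds with midrank tie handling, AUC by trapezoid
(hence exactly the Mann–Whitney concordance probability on tie-free
scores), and sensitivity/specificity at an operating threshold fixed on
training data — Youden's J maximiser by default, fixed 0.5 as an
alternative. Validation of a frozen panel computes marker ratios directly
on the external matrix without re-applying the abundance filter (a
deployed panel is fixed). Learning curves report train vs CV AUC at
increasing stratified subsample sizes.

## Synthetic data generator

The generator emulates the structure of two-group, multi-batch RPM
matrices with network-connected ratio signals:

    log2 x[i, j] = baseline[j] + N(0, bio_sd)
                 + label[i] · effect[j]
                 + log2 library_factor[i]
                 + protocol_bias[j, batch(i)]

with per-miRNA baselines N(10, 2) on the log2 scale (median ≈ 1000 RPM,
~95% of miRNAs clearing the 100-RPM filter), biological noise sd 0.5,
per-sample library factors log-uniform on [1/4, 4] (these cancel in
ratios), and per-miRNA per-batch protocol bias N(0, 0.1) (these do not).
The two batch components mirror the two faces of real library-preparation
effects. Networks are two independent Bernoulli layers (defaults: 200
miRNAs, 40 TFs, edge probability 0.015 per layer, chosen to give mean
degree ≈ 3.5 — the empirical density of large TF-mediated networks scaled
down to this node count); the TF→miRNA layer names precursors with a 1:1
precursor→mature map, so the emitted tables exercise the full
composition+mapping path.

Planted signals: `planted_pairs` network edges receive a group effect
totalling `effect_size_log2` on the log2 ratio. Two constructions are
available. The default ("split") applies +e/2 to the numerator and −e/2
to the denominator; the alternative ("numerator") applies the full shift
to the numerator alone. The default exists because ratio features leak:
a shift on endpoint m makes *every* ratio involving m differential, so
under numerator-only shifts the planted pair is statistically
indistinguishable from any sibling ratio sharing its numerator and
"recover the planted pair" is not a well-posed benchmark. Splitting the
effect makes the planted pair the uniquely strongest feature (siblings
carry half the effect). For the same reason pairs are planted on edges
whose endpoints have minimal additional connectivity, and planted
endpoints have baselines floored at log2(100)+2 so the abundance filter
cannot remove the signal by construction. Ground truth (pairs, library
factors, biases) is serialisable JSON.

What the generator does *not* emulate: count-level sampling noise
(abundances are log-normal, not negative-binomial — planted log2 effects
stay exact and the stability bounds analytic), correlated miRNA programs,
sequencing-depth-dependent dropout, and any specific public dataset's
values. Passing tests therefore demonstrate the mechanism — ratio
cancellation of per-sample scale, GA-based frequency screening, cross-batch
transfer — not performance on any real cohort.

## Experiment scales

The bundled end-to-end experiments run at desk scale: recovery uses 200
miRNAs, 5 planted pairs, 60 samples/group and a reduced GA (population 30,
15 generations, 10 repeats); the cross-batch contrast trains on one batch
of 30/group and validates on the other with a further reduced GA
(population 20, 10 generations, 5 repeats); the GA-vs-exhaustive check
uses 10-feature instances at 20 samples/group. These sizes keep full runs
in the minutes range while leaving the statistical contrasts
well-resolved.

## Known limitations

- Exact-pair identifiability degrades with network density; in dense
  networks several ratios of a planted endpoint are near-equivalent
  markers, and the frequency table ranks whichever the data favour.
- The power-law exponent is a descriptive OLS fit, not an MLE, and is
  reported as absent for degree distributions with fewer than two distinct
  positive degrees.
- Platt calibration at very small n falls back to in-sample decision
  values and can be optimistic.
- The univariate screen tests features marginally; strongly correlated
  candidate sets can enter the GA, which handles redundancy only through
  the subset-size penalty.
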