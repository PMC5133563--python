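# Methods

## Problem and model

Given a protein sequence, every lysine is a candidate malonylation site.
The predictor models a site by its local sequence context: a window of
ξ = 6 residues upstream and η = 9 downstream of the central K (length 16),
chosen to cover the flanking context observed in proteomics-derived
malonyl-peptides.  Positions outside the protein are padded with the dummy
residue X, giving a fixed 21-letter alphabet (20 amino acids + X).

Each window is encoded as a 687-component vector in a fixed layout:

| block | content | size |
|---|---|---|
| A | 1-gram occurrence counts, codes 1–21 | 21 |
| B | adjacent 2-gram counts, lexicographic by code pair | 441 |
| C | residue code at each flanking position (−6…−1, +1…+9) | 15 |
| D | 14 physicochemical values per flanking position (position-major) | 210 |

Residue codes number the native amino acids 1–20 alphabetically by
one-letter code, with X = 21.  The invariant center K is excluded from
blocks C and D (it carries no information), which is what makes those
blocks 15- rather than 16-positional.  Block A always sums to 16 and block
B to 15 — useful invariants exploited by the tests.

k-gram values are occurrence counts rather than binary presence flags
(`binary_kgrams` switches to indicators); counts are the standard k-gram
spectrum.  Block C is ordinal integer codes, not one-hot: the 15-D total is
only consistent with one code per position.

### Physicochemical table

Block D uses 14 per-residue property scales: hydrophobicity
(Kyte–Doolittle), polarity (Grantham), polarizability (Charton–Charton),
solvent-accessible surface area, net charge index of side chains, molecular
weight, α-amino and α-carboxyl pKa, melting point, specific optical
rotation, entropy of formation, heat capacity, absolute entropy, and a
configurable 14th slot defaulting to Hopp–Woods hydrophilicity.  The scale
*identities* behind published predictors of this family are ambiguous (13
names are listed where 14 values are used), so the table ships as curated
literature defaults in an editable 20×14 TSV; a trained model records a
checksum of the table it was fitted with, and X is defined as 0 for every
property.  Swapping tables changes block D only; no result in this package
depends on the exact values.

## Pipeline

Training fits, in order, on the training data only:

1. **Constant-feature mask** — features taking a single value across all
   training rows (both classes pooled) are dropped; the mask is refit per
   cross-validation fold.
2. **mRMR selection** — greedy forward selection of n = 50 features.
   Relevance and redundancy are plug-in mutual-information estimates (nats)
   on discretized columns.  The difference form MID,
   score(f) = I(f;y) − |S|⁻¹ Σ_{s∈S} I(f;s), is the default; the quotient
   form MIQ is available.  Ties break toward the lowest feature index, so
   selection is fully deterministic.
3. **Min-max scaling** of the 50 selected features to [0, 1], fitted on the
   training fold.
4. **RBF-SVM** with γ = 0.0125, C = 1.0, Platt sigmoid probability
   calibration (the LIBSVM mechanism), fixed random seed recorded in the
   model.

Prediction applies the identical chain; a window is called positive when
Pr(y=1|P) > θ = 0.5, and a probability exactly equal to θ is classified
negative (conservative positive calls).

### Discretization for mutual information

Mutual information needs discrete variables.  Columns that are already
non-negative integers (k-gram counts, position codes) pass through
unchanged; real-valued columns (block D) are discretized to three states at
mean ± α·σ (α = 1, population σ), the conventional default of the original
mRMR program for continuous data.  Equal-frequency binning is available as
an alternative.  A zero-variance column maps to a single label — valid, MI
0 with everything.

### Why scaling is on by default

The raw blocks span four orders of magnitude (counts 0–16 versus molecular
weights ~75–204 and melting points ~178–344).  At γ = 0.0125 the RBF kernel
of unscaled vectors is ≈ 0 off the diagonal, the SVM memorizes its support
vectors, and the calibrated probabilities are degenerate (train AUC
collapses).  γ = 0.0125 is only meaningful for features on a common scale —
LIBSVM practice runs `svm-scale` first — so the pipeline min-max scales the
*selected* features before the SVM.  Scaling is applied after mRMR so the
discretizer sees the natural integer-valued columns.  `scale=False`
restores raw features.

The soft-margin cost C is not fixed by the reference protocol; C = 1.0 is
the default, recorded in every model, and `grid_search_c` tunes it
explicitly by stratified k-fold AUC when wanted.

## Evaluation protocol

Leave-one-out and stratified k-fold cross-validation (k = 6, 8, 10),
repeated with reshuffled folds.  The full chain (mask, mRMR, scaler, SVM)
is refit per fold — no selection leakage; whole-dataset selection before CV
would mimic a leaky protocol and is deliberately not the default.  Per
repeat, fold scores are pooled into a single ROC/AUC; the mean of per-fold
AUCs is reported alongside because conventions in the literature differ.
Repeat-averaged ROC curves are vertically averaged on a 101-point FPR grid.
All resampling derives from a single master seed (per-repeat seeds from a
seed sequence, kept below 2³¹), making every reported number reproducible.

Metrics: Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/N,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Zero denominators
yield NaN plus an explicit `undefined` marker, except MCC which reports 0
with the marker (common convention, surfaced rather than hidden).  AUC is
computed two ways — trapezoidal integration of the threshold-sweep ROC and
the normalized Mann–Whitney rank statistic with ties counted ½ — and the
two agree to 1e−12 by construction; the tests enforce this.

## Redundancy filtering

Benchmarks are deduplicated at ≥ 40% pairwise identity.  Identity between
equal-length ungapped windows is Hamming identity (exact position matches /
length, X an ordinary symbol) — the only alignment-free reading.  The
filter is a greedy single pass in input order: a window is removed if its
identity to any *previously retained* window reaches the threshold, so the
earlier window always wins and the result is deterministic and idempotent.
Retained pairs are only guaranteed non-redundant against the retained
prefix; this greedy semantics is documented and tested explicitly.  Scope
is configurable (whole set or within-class).  Note that strict 40% Hamming
identity on 16-mers sharing a central K is an aggressive criterion; the
threshold and scope are configuration, not constants.

## Negative-set construction

Experiments report modified sites only, so when a site table contains no
explicit negatives, every non-annotated lysine in the annotated proteins
becomes a negative window — the standard construction for PTM benchmarks.
Explicit negative annotations disable auto-generation.  Non-standard input
residues (B, J, O, U, Z, *) map to X with a logged warning; coordinates are
1-based in all I/O and 0-based internally.

## Synthetic data: what it emulates, and what it does not

The generator draws 16-mers with a central K, flanks uniform over the 20
amino acids, then applies per-class enrichment rules "residue r at position
p with probability q".  Defaults are the study conditions: 458 positives
with G planted at −3/−1/+2 (q = 0.30), 3,974 negatives with K planted at
+1/+2/+8 (q = 0.25), and 5% of windows with one randomly sized terminal
X-pad (sites near protein ends).  The expected planted-residue frequency is
q + (1−q)/20 ≈ 0.335 against a 0.05 background — a weak, realistic signal,
not a crisp motif.  The proteome generator embeds the same windows in
random proteins (padded windows become their own short proteins) with exact
annotations, so window extraction recovers the planted labels exactly.

What the generator does **not** emulate: homology structure between
windows (real benchmarks need the redundancy filter; uniform random
windows are almost never 40% identical), non-uniform amino-acid background
composition (an empirical background can be supplied), correlated
positions, and any property-scale signal beyond what the planted residues
imply.  Passing tests therefore demonstrate that the pipeline recovers
positional composition signal under realistic imbalance — not that it
reaches any particular accuracy on real proteomes.

## Problem sizes used in tests and the acceptance script

Cross-validation refits the whole chain per fold, so the suite scales
problem sizes to what the protocol needs rather than running everything at
full size: k-fold runs use the full 458+3,974 benchmark (6-fold × 5
repeats; 8- and 10-fold × 3), while LOO — 4,432 refits at full size — runs
on a 400-window stratified subsample preserving the class ratio; the
protocol-consistency test uses an 80+320 benchmark for all four schemes so
their AUCs are comparable.  The null (label-shuffled) check uses an
800-window subsample.  These are the package's chosen study sizes and are
fixed in the code, not tunable by tests.

## Known limitations

* The probability calibration uses the deprecated-but-functional
  `SVC(probability=True)` path to match the LIBSVM mechanism; its internal
  5-fold CV makes calibrated probabilities (not the decision ranking)
  mildly sensitive to the seed, which is why the seed is recorded.
* MCC and the swap-symmetry of calibrated probabilities hold only
  approximately at very small n (< ~100 samples).
* The mRMR implementation is O(n·f) per selection step via flat
  histograms; for matrices far wider than ~10⁴ features a different
  strategy would be needed.
* Model archives are Python pickles: reload them only from trusted sources.
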