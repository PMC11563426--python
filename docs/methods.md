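# Methods

This note documents the models and procedures pepstack implements, the
defaults it ships, and the choices made where the design was genuinely open.

## Feature encoders

All encoders are pure functions from a residue string (canonical 20-letter
alphabet, alphabetical order A,C,D,…,Y fixed everywhere) to a named,
fixed-length vector. Default vector lengths: AAC 20, DPC 400, TPC 8000,
CKSAAP 1600, PAAC 22, APAAC 24, CTDC 39, conjoint triad 343, Moran 2,
reduced-alphabet composition 4.

**Plain compositions.** AAC divides residue counts by length *L*; DPC and
TPC divide ordered adjacent pair/triple counts by *L*−1 and *L*−2. CKSAAP
counts ordered pairs at separations 0…`gap_max` (default 3, giving
4 × 400 = 1600 features), each gap block normalised by its own position
count so each block sums to 1.

**Pseudo-amino-acid composition.** PAAC augments the 20 frequencies with λ
sequence-order factors θ_d (default λ = 2, weight w = 0.05): θ_d averages,
over residue pairs d apart, the mean squared difference of three
standardized physicochemical properties (hydrophobicity, hydrophilicity,
side-chain mass; tables bundled in `_property_tables.py`, standardized to
zero mean and unit population variance over the 20 residues). All 20 + λ
components share the denominator 1 + w·Σθ, so the vector sums to 1 and
collapses exactly to AAC at λ = 0. APAAC replaces θ with 2λ separate
correlation chains — products of standardized hydrophobicity
(τ₁, τ₃, …) and hydrophilicity (τ₂, τ₄, …) at each lag.

**CTD composition.** Thirteen standard physicochemical properties (seven
hydrophobicity scales, van der Waals volume, polarity, polarizability,
charge, secondary structure, solvent accessibility), each partitioning the
alphabet into three groups; features are the per-group residue fractions
(3 × 13 = 39).

**Conjoint triad.** Residues map to seven classes grouped by dipole and
side-chain volume; every window of three consecutive class labels
increments one of 7³ = 343 bins. Default normalisation is the descriptor's
original (count − min)/max over the bins; a frequency mode
(counts/(L−2)) is available.

**Moran autocorrelation.** I(d) = [(1/(L−d)) Σᵢ(xᵢ−x̄)(xᵢ₊d−x̄)] /
[(1/L) Σᵢ(xᵢ−x̄)²] of a standardized residue property at lags 1…nlag.
Default is a single property (hydrophobicity) with nlag = 2, giving the
2-feature vector; which property drives a 2-feature Moran descriptor is not
standardised anywhere, so the choice is configurable and recorded in the
feature names. Zero-variance sequences (homopolymers) return 0 at every lag
rather than 0/0.

**Reduced-alphabet composition.** Cluster frequencies over a fixed 4-cluster
partition — charged (DEHKR), polar (CNQST), aromatic/large hydrophobic
(FILMWY), small hydrophobic (AGPV). The partition is a documented,
swappable convention; nothing downstream depends on its specifics.

TPC is implemented but excluded from the default combined feature set,
which is AAC+DPC (420 columns) — the combination that performs best among
the composition descriptors and keeps fitting fast.

## Oversampling

ADASYN and SMOTE share the interpolation rule s = x_i + λ(x_k − x_i),
λ ~ U(0,1), x_k drawn uniformly from the k (default 5) nearest
minority-class neighbours of minority point x_i. The total synthetic count
is G = N_maj·target_ratio − N_min (default ratio 1.0, i.e. exact balance).
SMOTE allots G uniformly across minority points; ADASYN allots
proportionally to r_i = (majority members among x_i's k nearest neighbours
in the full data)/k, so boundary points receive more. Per-point allotments
use largest-remainder rounding so Σg_i = G exactly. If every r_i is zero
(no minority point has majority neighbours) ADASYN falls back to uniform
allotment rather than generating nothing.

Distances are Euclidean on the raw encoded features — composition features
are already commensurate in [0,1] — with an optional min-max scaling of the
neighbour-search space, off by default. Synthetic rows carry their
generating pair indices and λ values, so the interpolation contract is
auditable after the fact, and every resampled dataset records seed and
method. The λ = 0 and λ = 1 endpoints reproduce x_i and x_k bit-for-bit.

Oversampling runs **inside each training fold** by default. Balancing before
splitting lets synthetic points (interpolants of training points) appear in
test folds and inflates every metric; the global mode exists behind an
explicit flag for comparison with studies that balanced first.

## Stacking ensemble

Five default base learners: random forest (max_depth 30, min_samples_split
5, 300 trees), decision tree (entropy criterion, min_samples_split 5,
random splitter), SVM (RBF kernel, library defaults, probabilities via
internal cross-validated Platt calibration), k-NN (k = 5), LightGBM
(library defaults). XGBoost is available as an optional sixth. The RF and
DT settings are tuned constants; hyperparameter search is out of scope.

Meta-features are out-of-fold base-learner positive-class probabilities:
stratified 5-fold cross-fitting produces one meta-feature column per
enabled base learner with no row ever predicted by a model trained on it.
The meta-learner is L2-regularised logistic regression (C = 1). A
hard-label meta-feature mode exists for comparison. After the meta-learner
is fitted, base learners are refitted on the full training data for use at
predict time; the decision threshold is fixed at 0.5, with score
granularity available via the ROC export.

Seeds: every stochastic component receives a seed spawned deterministically
from one master seed via `numpy.random.SeedSequence` in learner order, so a
refit with the same seed reproduces predictions exactly, and persisted
models (config + column names + seeds + fitted state in one joblib
artifact) reload to bit-identical scores. Prediction realigns input columns
to the training columns by name and refuses mismatches explicitly.

The meta-learner's regularisation and the SVM kernel are this package's
documented defaults, not values taken from elsewhere.

## Evaluation

Sn, Sp, ACC and MCC are computed from the confusion table as fractions
(MCC in [−1,1]); a percent presentation is display-only. Undefined Sn/Sp
(empty class) are NaN; a zero MCC denominator yields 0 by the usual
convention. AUC is the Mann–Whitney rank formulation with ties counted
half. Stratified k-fold (default 10) keeps per-fold class counts within one
of proportional; the hold-out protocol is a stratified 80/20 split.
Aggregation across folds defaults to the unweighted mean of per-fold
metrics (fold sizes are near-equal); pooled-confusion aggregation is an
option since either convention is defensible.

## Synthetic data generator

The generator emulates the *shape* of a curated MHC-II binder benchmark:
two classes of 8–25-residue peptides at a 394:848 imbalance (the defaults),
with a class signal that is purely compositional. A shared baseline
(natural amino-acid background frequencies) is shifted by ±delta of total
probability mass on a designated residue subset (default the charged
residues DEHKR — a biologically plausible axis, though nothing depends on
the choice); each peptide draws its composition from a
Dirichlet(concentration × class propensity) and samples residues i.i.d.
per position.

Defaults: delta 0.1 (a moderate, learnable-but-imperfect signal),
concentration 50 (within-class dispersion of a 0.05-frequency component is
roughly ±0.03, comparable between classes and within them). delta = 0 makes
the classes exchangeable — the basis of the null-calibration and
label-permutation checks — and large delta (≈0.3) makes them nearly
separable from AAC features alone.

A compositional (rather than motif-based) signal was chosen deliberately:
every in-scope encoder is composition-driven, so signal present in the
generator is provably visible to the encoders and its strength is graded by
a single parameter. Consequences for interpretation: passing tests show the
pipeline recovers compositional class differences at realistic sizes and
imbalance and invents nothing under the null; they do **not** show
performance on real epitope data, where signal may be positional,
motif-like, or entangled with MHC binding — no claim of biological realism
is made beyond composition. Position-dependent encoders (TPC, CKSAAP at
large gaps, Moran) carry no extra signal here beyond what composition
induces.

## Problem sizes and numerics

The acceptance computations run at the reference scale (1,242 peptides),
with AAC+DPC features for the cross-validated stack and AAC features for
the five-seed stack-versus-base comparison (held-out 80/20 per seed) —
sizes at which the full pipeline completes in about two minutes on one CPU.
Composition block sums are asserted to 1e−9; bit-exactness is required only
where the contract states it (CSV round-trip, persistence, seed
determinism, interpolation endpoints). Degenerate inputs are defined, not
errors, where a convention exists (homopolymer Moran = 0) and errors where
silence would corrupt data (non-canonical residues under the default strict
policy, encoder length preconditions, single-class fits).

## Known limitations

* No hyperparameter search; the tuned constants above are fixed.
* No feature selection; the encoders' full vectors are used as-is.
* The generator cannot produce motif- or position-based signal, so it
  cannot stress-test the sequence-order encoders specifically.
* Sn/Sp NaN-propagation in fold means: a fold with an empty class (only
  possible without stratification) propagates NaN into the aggregate by
  design, to avoid silently averaging over undefined values.
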