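# Methods

## Problem and pipeline

The package detects ventricular arrhythmias (VT, PVC, ST change) against
normal sinus rhythm from fixed-length ECG epochs.  One run executes:
segment (or simulate) epochs → thin the epoch population 1-in-20 →
embed each class's epoch vectors into a low-dimensional space → select a
fixed-size, maximally separable subset of epochs by metaheuristic search
→ train one of seven classifiers (optionally with tuned
hyperparameters) → score by stratified 10-fold cross-validation.

Epoch geometry is class-specific: arrhythmia classes are 360 samples at
360 Hz (1 s), NSR is 128 samples at 128 Hz (1 s).  Because the two
classes of a disease pair therefore live in different ambient
dimensions, the embeddings are computed per class and the coordinates
stacked afterwards; the per-class epoch counts after decimation
(ceil(n/20)) are the quantities the bookkeeping preserves.  A
consequence worth knowing: per-class spectral embeddings carry no
common alignment, so the classifiers discriminate on the shape and
scale of the embedded clouds rather than on a shared coordinate frame
— absolute accuracies on synthetic data are correspondingly moderate
in the untuned baseline cells, which is the regime the selection and
tuning stages are designed to improve.

## Synthetic data generator

There is no public generator for the original ambulatory recordings,
so the package simulates ECG-like epochs with a sum-of-Gaussians beat
template (P wave, Q/R/S deflections, T wave) on a periodic beat phase:

- **NSR**: 75 beats/min, full P-QRS-T morphology;
- **VT**: 190 beats/min, absent P wave, wide high-amplitude merged
  QRS-T complexes;
- **PVC**: sinus base rhythm plus one early, wide, large ectopic
  complex with inverted T per epoch at a random position;
- **ST**: 80 beats/min with an elevated segment (+0.25 of the R
  amplitude) between ventricular depolarization and repolarization.

Per epoch the beat phase is uniformly randomized, rate jittered by 5%
and amplitude by 10%; white measurement noise (sd 0.05, R amplitude
normalized to 1) is added.  A fraction `artifact_frac` (default 0.15)
of epochs additionally receives a superimposed motion artifact —
0.3-amplitude baseline wander at 0.3–1.5 Hz plus broadband noise of
sd 0.3 — emulating the noisy stretches of real Holter recordings.
The artifact is superimposed rather than substituted so artifact
epochs remain class-bearing but much harder, which is exactly the
structure the epoch-selection stage exploits.  Generation is a pure
function of the config including its seed.

What the generator does *not* emulate: inter-patient morphology
variation, baseline drift within an epoch, beat-to-beat heart-rate
variability structure, lead placement effects, or annotated beat
alignment (epochs are contiguous slices, not R-peak-centred — the
provenance string records this choice).  Passing tests on synthetic
data therefore demonstrate correctness and qualitative behaviour of
the pipeline, not clinical-grade accuracy on real recordings; the
original study's headline accuracies require the external PhysioNet
recordings and unpublished settings, and are out of scope.

## Dimensionality reduction

All three methods act on raw epoch sample vectors with Euclidean
distances.  Defaults (all overridable, all recorded in the result's
`params`): LLE k = 12 neighbours, target dimension 10, local-Gram
regularizer 1e−3 (scaled by the Gram trace); diffusion maps σ = median
pairwise distance, t = 1, h = 10; Laplacian eigenmaps m = 12, σ =
median pairwise distance, dimension 10.  Eigenvector sign is fixed by
making the first nonzero entry positive.  LLE coordinates are scaled by
√n so the embedding's second-moment matrix is the identity.  The
diffusion-map eigenproblem is solved through the symmetric conjugate
D^{-1/2} K D^{-1/2} for numerical stability; the trivial λ = 1
eigenvector is dropped.  Laplacian eigenmaps reject disconnected
neighbourhood graphs (listing component sizes) since the embedding is
ill-defined across components.

The 1-in-20 epoch thinning keeps the first epoch of every block of 20
within each class, reproducing ceil(n/20) exactly (43 333 → 2 167,
57 778 → 2 889, 84 000 → 4 200, 141 750 → 7 088).

## Epoch selection

Both metaheuristics optimize a continuous vector in [0,1]^n (one score
per candidate epoch); the retained subset is the per-class top-k by
score with ties broken toward lower indices, which makes the decoding
deterministic and the kept counts exactly equal to the requested
targets (default fractions mirror the reference retention ratios,
about 15–20% per class).  The fitness is the negated Fisher
separability — between-class variance of class means over within-class
variance, summed over embedding coordinates — of the decoded subset; a
custom fitness (e.g. a wrapper classifier error) can be passed in.

Cuckoo search: Lévy-flight proposals with Mantegna steps scaled by
0.01·γ·(xᵢ − x_best), greedy replacement of a random nest, and
re-seeding of the worst `fa` fraction each generation.  The default
Lévy exponent β = 0.2 is retained from the source method even though it
lies below the Mantegna scheme's usual (0.3, 2) validity range; a
runtime warning notes the extreme tails.  Harmony search: memory size
20, memory-considering rate 0.9, pitch-adjusting rate 0.3, bandwidth
0.05, replace-worst-if-better.  Both clip to bounds at every iterate
and are deterministic given their seed.

## Classifiers

All families share one contract: real-valued score per row, hard label
= score ≥ threshold, boundary ties resolved toward the arrhythmia
class.  Decision rules that their classical formulations leave open are
completed minimally:

- **GMM** — one diagonal-covariance mixture per class fitted by EM
  (log-likelihood trace is monotone; weights renormalize each M-step);
  classification by class-conditional log-likelihood plus log-prior.
  Diagonal covariances suffice because mixtures of diagonal components
  can model correlated densities.
- **EM** — a per-class Gaussian density fitted by
  expectation-maximization over missing feature entries (NaNs); with
  complete data the first M-step is the closed-form fit.  This is a
  declared completion: the classical presentation of this family mixes
  unit-vector and Gaussian sufficient statistics inconsistently, so the
  package implements the coherent Gaussian special case.
- **NLR** — saturation response g(a) = γ₁a/(γ₂+a) least-squares fitted
  to 0/1 labels on a pooled-variance-scaled discriminant projection of
  the features, thresholded at 0.5.
- **LR** — ridge-penalized logistic regression by Newton/IRLS with step
  halving; the penalized deviance −2(ln H(γ) − α/2‖γ‖²) decreases every
  accepted step.
- **BDLC** — linear discriminant with pooled covariance and configurable
  priors; positive iff s_m(g) − s_n(g) ≥ M (default M = 0).
- **DFA** — the per-epoch scaling exponent (slope of log RMS fluctuation
  of the polynomially detrended cumulative profile against log scale)
  thresholded at the midpoint of the training class means; the sign is
  flipped automatically if arrhythmia exponents are smaller.  Because a
  10-dimensional embedded row is too short for fluctuation analysis,
  the pipeline feeds DFA the raw epoch samples (truncated to the
  shorter class's length when the pair mixes 360- and 128-sample
  epochs); the library still allows DFA on any sufficiently long row.
- **Firefly** — the swarm optimizer (attractiveness α(p) = α_min +
  (α₀−α_min)e^{−βp²}, randomization γ(rand−½)·scale with geometric
  cooling) fits a centroid pair plus threshold minimizing training
  error.

## Hyperparameter tuning

Tuned hyperparameters all live in [0,1] and act as scalar reshapers of
internally fitted quantities — mixture weights are tempered by the
exponent, class means shrunk toward the grand mean, covariances
multiplied (floored at 1e−3 to avoid degeneracy) — because literally
freezing a mixture mean at a scalar in [0,1] is ill-posed.  Tuned sets:
GMM {weight, mean, covariance scales}, EM {covariance scale}, BDLC
{mean, covariance scales}, firefly {γ, α_min, scale, α₀}.

Grid search evaluates every grid point by stratified k-fold error
(default 11 points per axis, capped so total evaluations ≤ 500; failed
fits score worst rather than aborting; ties break lexicographically).
Adam tuning alternates: cross-validated error → secant gradient
(first step e/g_init; later (e−e_prev)/(g−g_prev) elementwise, stalled
coordinates contributing 0) → Adam update with l = 0.0009, R1 = 0.74,
R2 = 0.82, ε = 1e−7 → clip to [0,1]; the best point seen anywhere in
the trace is returned, so the result is never worse than the start.
Tuning uses a fold seed distinct from the final evaluation's folds so
the reported metrics are not selected on.  Reference tuned values
reported for the original recordings ship in
`ecgdetect.tuning.REFERENCE_TUNED` as documentation only.

## Evaluation

Stratified 10-fold cross-validation distributes each class across folds
with per-fold counts differing by at most one; K = n degenerates to
leave-one-out.  The metric suite is computed from the pooled confusion
matrix in exact rational arithmetic, with half-up rounding to the
reported precision (two decimals for the percentage metrics, four for
MCC).  MCC is implemented on its true range [−1, 1].  A zero MCC or GDR
denominator yields 0 with a degeneracy flag rather than an error.  MSE
compares hard 0/1 decisions against 0/1-coded labels; the historical
recording-index target coding is not used because it makes MSE
incomparable across classes.

The shipped reference tables are integer-rounded fold-average confusion
matrices, so their printed metrics do not always recompute exactly from
the printed counts: across the 333 fixture rows, 89 overall-accuracy
values recompute to the printed digit and the rest deviate in the last
digit or two, with one published block internally inconsistent (its
printed perfect matrix sits beside non-perfect metrics).  The tests
assert the exactly recomputable fields and track the match counts.

## Problem sizes and numerical choices

Tests and examples run the pipeline at 2 000 simulated epochs per class
(→ 100 per class after decimation), embedding dimension 8, selection
budgets of tens of optimizer generations and Adam tuning for 20
iterations over 5 folds — sizes chosen so a full run takes seconds on
one core while leaving every stage's behaviour observable.  The library
defaults for the optimizer-heavy components (firefly population 40 and
1 000 iterations, grid cap 500 evaluations, Adam cap 300) match the
reference settings and can be restored through the config objects.

Degenerate inputs are handled explicitly: constant sequences have zero
ApEn/variance; a singular local Gram matrix in LLE raises with advice
to increase the regularizer; kernels that underflow to the identity
warn; infeasible selection targets, single-class training sets,
non-finite features and objectives, and dimension mismatches all raise
with specific messages.

## Known limitations

Real-recording ingestion (the standard physiological waveform format)
is not included; the synthetic generator is the only data source, and
the CSV epoch format is the interchange surface.  Multiclass (>2)
decision rules, probability calibration, out-of-sample embedding
extension and ROC analysis are out of scope.  The per-class embedding
choice means absolute synthetic accuracies should not be read as
estimates of performance on real ECG.
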