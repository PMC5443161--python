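# Methods

## The problem and the signal model

A trial consists of continuous multichannel EEG during which a participant
hears a lateralized auditory cue ("left"/"right") and, at a moment of their
own choosing at least 2 s later, presses a key with the corresponding index
finger. Two 500 ms epochs are cut per valid trial: an *idle* epoch ending at
the cue, and a *movement* epoch ending 130 ms before the press — early enough
to exclude movement execution, late enough to contain the lateralized late
readiness potential (RP). Trials with a press within 2 s of the cue
(reactive, not self-initiated), with a press before the cue, or with multiple
presses are screened out. Each kept trial therefore contributes one idle and
one movement epoch, giving the dataset its characteristic ~2:1:1
idle:left:right imbalance.

Epoching and windows use half-open sample intervals `[start, end)` with
round-half-away-from-zero time-to-sample conversion; a 500 ms epoch is
exactly `round(0.5·fs)` samples, so at the 100 Hz working rate an epoch is
T = 50 samples of N = 34 channels.

## Feature extraction (PSTF)

Working order: anti-aliased decimation from the acquisition rate (1 kHz) to
100 Hz → EOG regression → cascaded zero-phase Butterworth low-pass and
high-pass filters (order 4 per pass, forward-backward, reflect padding of one
epoch length) → Fisher beamformer → window averaging.

*EOG regression.* Regression weights b = Cov(EOG)⁻¹ Cov(EOG, EEG) are fitted
on the demeaned, concatenated training epochs and frozen; cleaned EEG is
EEG − bᵀ·EOG. A singular EOG covariance is jittered with `1e-10·trace·I`
rather than failing, so degenerate synthetic inputs cannot abort a grid
search. Because both the band filters and the regression subtraction are
linear operators, fitting the regression once per training set and
re-filtering per grid point is observationally equivalent to re-running the
whole chain per grid point; the grid search exploits this by caching the
EOG-cleaned signals.

*Beamformer.* With class means M_i, grand mean M and empirical priors
p_i = K_i/K,

    S_b = Σ_i p_i (M_i − M)(M_i − M)ᵀ,
    S_w = Σ_i Σ_k (X_ik − M_i)(X_ik − M_i)ᵀ   (raw pooled scatter,
                                               no count normalization),

and W is the unit-norm leading eigenvector of (S_w + γI)⁻¹S_b, solved on the
symmetric-definite form (`scipy.linalg.eigh(S_b, S_w + γI)`, Cholesky
whitening internally) for stability. Sign is fixed by making the
largest-magnitude entry of W positive. Only the first filter is used. γ = 0
on a singular S_w raises a numerical error during direct fitting; inside the
grid search such combinations score 0 instead of aborting.

*Window averaging.* The beamformed time course is averaged over consecutive
non-overlapping windows of w samples, T′ = floor(T/w) features, trailing
remainder dropped. The standard grids (w ∈ {5, 10, 25}) all divide T = 50.

*Grid search.* All (low-pass, high-pass, γ, w) combinations are scored by
seeded, stratified inner 5-fold CV: the beamformer and the downstream
classifier are refitted on every inner-training fold and scored on the held
fold. Ties break deterministically toward lower low-pass, then no/lower
high-pass, then lower γ, then larger window (stronger smoothing and
regularization preferred at equal accuracy). Fold assignment is a pure
function of (labels, fold count, seed), making `fit_pstf` bit-reproducible.
For decompositions the PSTF is fitted per binary sub-problem in its binary
form; the direct ternary classifier uses the three-class scatter matrices.

## Classification algorithms

All five candidates expose calibrated posteriors behind one contract; the
routing and fusion layers never branch on the algorithm identity.

| id | model | probability rule | notes |
|----|-------|------------------|-------|
| LPGM | Gaussian class-conditionals, pooled covariance | Bayes posterior | covariance ridge `1e-6·trace/d·I` guards degenerate folds |
| SVM | RBF kernel, C = 1 | Platt calibration | kernel width from the median pairwise-distance heuristic, avoiding a second hyperparameter grid |
| FLDA | 1-D Fisher projection | LPGM on the projected scalars | by construction limited to one discriminant axis |
| LR | logistic regression | logistic link | scikit-learn, seeded |
| RLS | one-vs-rest ridge on ±1 targets | softmax of scores | λ by internal stratified 5-fold CV over {0, 0.5, 1, 10, 10²…10⁵}, ties to the larger λ (favour shrinkage) |

The RLS probability mapping (softmax) is a design choice: ridge regression
defines no posterior, but the fusion rule consumes posteriors from every
algorithm. Equal-duplication of one sample per class leaves empirical priors
unchanged, so posteriors are stable under that perturbation.

## Ternary strategies and fusion

Class labels are R (right), I (idle), L (left); the canonical order (R, I, L)
resolves every probability tie deterministically, with the earlier class
winning. Binary training sets are balanced by seeded subsampling of the
larger side without replacement; the pooled "All"/"movement" sides are first
subsampled class-proportionally so no constituent class dominates. Test
epochs are never subsampled.

- **MCS**: one ternary classifier; training classes balanced to the minimum
  count.
- **OAO**: nodes R-I, R-L, I-L; per-pair posteriors r_ij combined by the
  Wu–Lin–Weng second method — minimize Σ_{i<j}(r_ji p_i − r_ij p_j)² on the
  simplex via its KKT linear system.
- **OAA**: nodes R-A, I-A, L-A; label = highest target-class probability.
- **DBT**: root idle-vs-movement, leaf left-vs-right.
- **DDAG**: for node order [c1, c2, c3] the root compares c1 vs c3,
  eliminates the loser, and the survivor meets c2 ("RIL" ⇒ root R-vs-L).
  This is the standard DDAG construction; all three orders are available and
  RIL is the default reporting structure.

**ODCS.** Per node, each candidate algorithm's validation accuracy (VA) is
its mean over seeded stratified 5-fold CV on the node's training features —
one estimate used both for ordering and as the fusion weight, mirroring the
inner-CV style used everywhere else rather than a single arbitrary holdout.
Prediction fuses the top-m posteriors with softmax-of-VA weights; m = 1
reduces exactly to best-algorithm selection, equal VAs to plain averaging.
The layer is scheme-agnostic although the reference configuration pairs it
with the DDAG. During ODCS runs the PSTF grid search needs a single scoring
classifier before the per-node ranking exists; FLDA is used (the strongest
single algorithm in this family of pipelines). For single-algorithm runs the
grid search scores with that same algorithm.

## Evaluation protocol

Trials are split into 10 disjoint chunks, equal to ±1 trial, contiguous in
chronological order by default (conservative under slow nonstationarity; a
seeded shuffle is available). Chunking is at the *trial* level so a trial's
idle and movement epochs always share a chunk. Per fold, every stage — EOG
regression, PSTF grid search, classifier training, ODCS ranking — sees only
the 9 training chunks; a guard validates the fold plan (disjointness,
coverage, balance) and aborts on any train/test trial overlap. Cohen's kappa
is computed per fold from the integer confusion matrix; the headline
statistic is the mean of fold kappas, with the pooled-confusion kappa
reported alongside (the two differ in general). Per-class accuracy
(diagonal over row marginal) and overall accuracy are by-products.

## The synthetic generator

`simulate_dataset` emulates the structure of the key-press experiment: 200
trials per side at 1 kHz, 34 EEG + 4 EOG channels, cue at U(1, 2) s, press
latency truncated-normal (mean 4.76 s, SD 1.98 s, min 2 s), with 1.5% planted
reactive and 1% double-press trials reproducing a ~390/400 retention rate.
The RP is a piecewise-linear ramp from 0 at press−1.5 s to −10 µV at the
press with 300 ms recovery (an optional two-slope variant models the
early/late RP distinction), projected through unit-norm spatial patterns
loading on {C1, C3, CP1, CP3} vs {C2, C4, CP2, CP4} with contralateral
dominance 2:1. Noise is per-channel 1/f-amplitude-shaped ("pink") noise plus
a 50%-weight shared common-mode term (default 1.8 µV), an 8–12 Hz alpha
component (0.8 µV), and blink artifacts: 300 ms raised-cosine deflections at
0.3 expected blinks/trial, ~100 µV on the EOG channels, mixed into the EEG
through a fixed frontal-weighted matrix so the EOG regression has an exactly
recoverable planted target. Everything is a pure function of the seed, which
is expanded per trial through a hashed tag scheme.

**What the defaults mean.** The noise amplitudes are calibrated so that the
planted classes are clearly separable (fused-DDAG mean kappa ≈ 0.92 under
the 10-fold protocol with the reduced grid). This is a synthetic validation
regime — it demonstrates that the pipeline recovers planted structure, not
that real single-trial RPs are this separable. Real recordings carry far
lower single-trial SNR, volume-conducted spatial correlation, oscillatory
(ERD) components, nonstationarity across a session, and artifact families
(EMG, line noise) the generator does not model; passing tests here therefore
validate the machinery, not clinical-grade performance. Setting
`lateralization_ratio=1` makes left and right patterns identical, collapsing
the L-R node to chance while idle-vs-movement stays easy — mirroring the
qualitative error structure expected of real RP data, where most left/right
errors are lateral confusions.

## Numerical and design choices

- Filtering 500 ms epochs with sub-Hz high-pass cut-offs is close to an
  identity (the filter's time constant exceeds the epoch); infra-slow drift
  therefore survives preprocessing and is handled downstream by the
  beamformer and by classifier contrasts across window features. This is a
  property of epoch-wise filtering generally, and the reason the simulation's
  pink-noise level, not the high-pass grid, governs task difficulty.
- Probability vectors are renormalized after clipping at 1e-300; coupling
  solutions clip tiny negative components and renormalize.
- Deterministic seeds: a single run seed expands via SHA-256 of a tag path
  (`fold/3/pstf/R-L/…`) into independent child seeds below 2³¹, so adding a
  component never shifts the streams of the others; identical configs give
  byte-identical outputs.
- Degenerate inputs: constant feature columns are absorbed by covariance
  ridges; a γ = 0 beamformer on singular scatter raises a clear error
  outside the grid and scores 0 inside it; an empty epoch container
  round-trips as empty.

## Known limitations

- FLDA uses a single discriminant axis by definition; with three
  non-collinear class clusters it cannot be exact (visible in its ternary
  behaviour), which is also why it is used in binary form within the
  decompositions.
- One-vs-rest RLS inherits the masking weakness of least-squares
  classification for middle classes; its λ grid cannot repair geometry.
- The generator does not model volume conduction, realistic head geometry,
  or oscillatory desynchronization; group-level inferential statistics
  across participants are out of scope (the per-fold CSV export is the
  intended interface to external stats tools).
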