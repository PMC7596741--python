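# Methods

This note documents the models implemented in `m1decode`, the assumptions
behind them, the synthetic data they are validated on, and the numerical
choices that were genuinely open. It states no result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Session model and preprocessing

A *session* bundles per-unit spike event times (seconds), hand position
(cm) on a uniform sampling grid, and a chronological table of
non-overlapping trials. Sessions are stored in a single HDF5 container
(`/units/<k>`, `/hand/{t,x,y}`, `/trials`); dataset timestamps are disabled
so identical sessions produce byte-identical files.

Preprocessing order is fixed: spike counts in non-overlapping 50 ms bins →
firing rates (counts / 0.05 s) → elementwise square root → Gaussian kernel
smoothing. The square root is the standard variance stabilizer for
near-Poisson counts; note it only reduces skewness once the mean count is
comfortably above zero (at a mean of 4 counts per bin it overcorrects — the
test suite demonstrates the stabilization at mean 9). The smoothing kernel
(default SD 80 ms for center-out-style sessions, 140 ms for
sequential-reach-style ones) is truncated at ±4 SD and renormalized near
the series edges, so constants pass through unchanged and < 1e-4 of kernel
mass is lost.

Kinematics: hand position is averaged within each bin and differenced,
v_i = (p_i − p_{i−1}) / 0.05 s; the first bin of each trial uses a forward
difference so no cross-trial motion leaks in. Speed is the Euclidean norm,
giving the kinematic vector x = (v_x, v_y, ‖v‖). Bins are assigned to the
trial containing their center; bins outside all trials are dropped.

Unit inclusion is gated by the velocity-form cosine tuning model
z_k = β₀ + β₁ᵀv + β₂‖v‖ + ε fitted by OLS on the *training* trials only;
units with r² > 0.01 are kept (threshold configurable). The preferred
direction is atan2(β₁y, β₁x). Trial splitting is chronological with
floor(0.75 · n) training trials — floor gives 131/44 and 372/124
train/test counts for 175- and 496-trial sessions.

## Synthetic reaching sessions

The generator emulates the structure of center-out (8 targets, 45°
spacing) and sequential-target reaching sessions. Trajectories are
minimum-jerk reaches, the standard smooth-reach model, whose analytic peak
speed 1.875·d/T anchors several tests; each leg's final sample lands
exactly on the target so trials begin and end at rest. Unit rates follow
the rectified cosine model λ = max(0, b + d·(v·û(φ)) + g‖v‖); a
configurable fraction of units additionally squash λ through
λmax·tanh(λ/λmax) with λmax at ~60% of the unit's dynamic peak
("nonlinear" units). Spikes are drawn from an inhomogeneous Poisson
process by thinning at the unit's peak rate. Default tuning ranges
(baselines 5–15 Hz, depths 0.4–1.2 Hz/(cm/s), speed gains 0–0.3, half the
units saturating) give 10–30 Hz modulation at 25 cm/s peak reach speed —
typical of well-isolated arm-area units. One seed drives targets, tuning
parameters, and spikes, and is recorded in the session metadata.

What the generator does *not* emulate: shared (correlated) noise across
units, spike sorting artifacts, non-stationarity within a session, reaction
and hold periods, or neurons tuned to variables other than velocity and
speed. Passing tests therefore demonstrate correctness of the pipeline
under velocity-tuned Poisson populations, not performance on real
recordings.

## Unsupervised representations

* **PCA** — eigendecomposition of the training covariance (all rank
  components retained); component scores are re-smoothed with the session
  kernel before decoding, since projection can reintroduce bin-level noise.
* **FA** — EM for loadings plus diagonal uniquenesses; factor scores are
  posterior means. The per-iteration log-likelihood is stored and is
  non-decreasing.
* **LDS** — EM for a linear-Gaussian state space with diagonal observation
  noise (uniqueness-style, matching the FA noise model); the E-step uses a
  Kalman filter/RTS smoother with information-form updates so only q×q
  matrices are inverted. Initialization is deterministic (PCA-scaled
  loadings, A = 0.9 I), so fits are reproducible without restarts. Latent
  states for decoding are *causally filtered*, not smoothed, because they
  feed a real-time-style decoder.

**Dimensionality selection** scans a candidate grid (step 5; PCA up to m,
FA/LDS up to min(m, 40)) and minimizes *leave-neuron-out* reconstruction
MAE on the test set: each unit is predicted from latents inferred from the
other units. Plain projection reconstruction is monotone non-increasing in
q for PCA and cannot exhibit a minimum; the cross-validated error turns up
once extra dimensions fit unit-private noise, so its argmin identifies the
shared dimensionality. (Plain reconstruction remains available and is used
for the full-basis exactness check.) For LDS the selection uses the static
observation model — uniform machinery across methods; the dynamics matter
for state estimation, not for detecting the shared rank.

## Linear CCA

Both views are centered; each covariance gets a ridge (default 1e-8) and
is inverted via its symmetric eigendecomposition; the SVD of the whitened
cross-covariance yields the canonical coefficients and correlations. The
SVD route is numerically stabler than the generalized eigenproblem it is
equivalent to; the test suite verifies agreement with the
generalized-eigenvalue route to 1e-8 over 100 random instances. Signs are
fixed by the SVD convention (training correlations ≥ 0). A singular
covariance without ridge raises an explicit error naming the remedy.

## Deep CCA

Two feedforward encoders (sigmoidal hidden layers, linear 3-unit output —
the output width is pinned to the number of kinematic variables, which
caps the canonical pairing at 3) are trained by full-batch or minibatch
Adam on

    maximize  Σ_k σ_k(Σ̂₁₁^{−1/2} Σ̂₁₂ Σ̂₂₂^{−1/2})
              − λ·(recon_Z + recon_X) − L2·‖W‖²,

where Σ̂ᵢᵢ are output covariances regularized by rcov·I, the σ_k are
singular values (the total canonical correlation), and recon terms are the
MSE of mirror decoder networks reconstructing the standardized inputs from
the encoder outputs. The gradient of the singular-value sum with respect
to the output batches uses the standard matrix-calculus form for whitened
cross-covariances. Hidden layers are initialized by greedy layerwise
denoising-autoencoder pretraining with masking noise. After training, a
linear CCA on the network outputs (tiny fixed ridge 1e-8, so the stored ρ
equal the Pearson correlations of the rotated outputs) orders the pairs.

Defaults were calibrated to the regime where the method is trustworthy:
heavy covariance regularization (rcov = 0.04), reconstruction trade-off
λ = 0.01, L2 ≈ 5e-4, and full-batch gradients. Two findings from
development are worth recording. First, with light regularization and
small minibatches the deep representation is *noisier* than the linear one
on modestly sized sessions, and any advantage disappears into estimation
variance. Second, the training objective itself is an imperfect proxy for
downstream decodability: the kinematic-side network can warp velocity
(chasing corr(f(z), g(x)) with a nonlinear g), which raises total
correlation while *hurting* a linear-in-velocity observation model —
selecting restarts by training objective degraded Kalman decoding and is
deliberately not done; a single seeded fit is used.

Hyperparameter search is a budgeted random search (default 50 draws) over
the documented ranges (nodes 2⁴–2¹⁰, 1–4 layers, batch 2⁵–2⁸, learning
rate 1e-5–1e-2, rcov/L2/λ 1e-6–1e-1), scored by total canonical
correlation on a chronological inner validation split; deterministic given
its seed.

**Inversion baseline.** Velocity can be reconstructed through the CCA maps
alone: per-pair regressions X_k = a₀ + a₁Z_k on training canonical
variables, then inversion of the kinematic-side map — pseudo-inverse for
the linear model; for the deep model, inverse output rotation followed by
layerwise inversion (logit of clipped activations, pseudo-inverse of the
weights). This is an expected-worse baseline than a proper decoder and is
exposed for completeness.

## Decoders

**Steady-state linear Kalman filter.** State x = (v_x, v_y, ‖v‖). The
transition and observation models are affine least-squares fits
(x_t ≈ A x_{t−1} + a₀, o ≈ H x + h₀ — the offsets absorb the nonzero mean
of speed), with residual covariances Q and V. The steady-state gain is the
fixed point of the Riccati recursion, iterated until the gain moves < 1e-10
in max norm (max 10⁴ iterations, with spectral diagnostics on failure).
Decoding runs the constant-gain filter with the state reset to zero at
every trial start (reaches begin at rest); the speed component is dropped
from the output. A time-varying reference filter is included for the
agreement check.

**Neural dynamical filter.** For LDS latent states — which already carry
their own dynamics — the decoder is a ridge regression from states to
kinematics; a second dynamical model on top would be redundant.

**LSTM.** A single LSTM layer (sigmoid gates, tanh cell/output squashing)
with a linear velocity readout, trained per-trial (hidden state restarts
at trial boundaries, matching the Kalman resets) with Adam — gradient
decay 0.95, squared-gradient decay 0.99 — squared-error loss, trial
minibatches reshuffled every epoch, global gradient-norm clipping at 5,
and early stopping on an inner-validation plateau (patience 10, default
100 epochs). Inputs are standardized with training statistics. The "rcov"
hyperparameter is an L2 penalty on the weight matrices. The forward
gate arithmetic is verified against a pure-scalar reference to 1e-10.

## Evaluation

Per-trial decoding error is the mean Euclidean distance between true and
predicted velocity within the trial; positions are reconstructed by
cumulating decoded velocity from the trial's true start position
(p(t_i) = p_start + Σ_{k≤i} v̂_k·Δ, with p_start the position at trial
*onset*, before the first bin's displacement — the convention that makes
integration the exact inverse of the first-difference kinematics on trial
interiors). Per-axis Pearson correlations are reported over all test bins
and per trial.

Method comparison uses the Friedman test across trials (methods as the
repeated factor) with pairwise Wilcoxon signed-rank post hocs,
Bonferroni-corrected; rank-sum statistics are reported alongside. With
exactly two methods the signed-rank test is the main test (Friedman
degenerates). Decoder and representation effects are tested as two
separate one-way analyses; Friedman has no interaction term.

## The representation-ordering property

On sessions with nonlinear tuned units, the expected ordering of Kalman
velocity errors is Z_DCV ≤ Z_LCV ≤ Z_E-FR. Two subtleties, both verified
by the test suite:

1. **LCV ties E-FR exactly.** With OLS-fitted observation models the
   canonical variables span the same subspace as the linear regression
   E[x|z], i.e. they are a sufficient statistic of the fitted Gaussian
   model, so the Kalman posterior — and the decoded velocity — is
   identical for the full rates and their three canonical variables. The
   ordering tests therefore compare with a 1e-6 relative tolerance so this
   analytic tie counts as "≤". The compression from m units to 3 variables
   is free, which is itself the argument for CCA in front of a Kalman
   filter.

2. **Where the deep advantage lives.** Under mildly saturating mixed
   populations, averaging over many units with diverse preferred
   directions linearizes the velocity code; the deep model's gain then
   concentrates in the *speed* pair, which velocity-only error ignores,
   and DCV ties LCV. The ordering benchmark therefore uses the regime
   where a linear readout is genuinely suboptimal: a small ensemble
   (14 units), all tuned units saturating, low baselines (2–6 Hz) and
   strong modulation (2–4 Hz/(cm/s)), making units nearly binary direction
   detectors. Under these conditions (fixed in `m1decode.benchmarks`) the
   deep canonical variables decode velocity strictly better in 10/10
   seeded runs of the acceptance suite.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately reduced problem sizes
chosen as the smallest at which each property is stable: 100 random
5–20-unit instances for the CCA oracle, n = 20 000 bins for the nonlinear
two-view benchmark, n = 50 000 for Kalman parameter recovery, 10 seeded
120-trial sessions for the ordering property, ~500 s sessions for tuning
recovery. Other fixed choices: whitening ridge 1e-8; FA uniqueness floor
1e-6; LDS state-noise jitter 1e-9 with a warning at transition spectral
radius > 1.05; sigmoid inputs clipped at ±60; logit-inversion clipping at
(1e-6, 1−1e-6) with a count of clipped activations; zero-variance
regressands define r² = 0; candidate-grid ties in dimensionality selection
break toward smaller q.

## Known limitations

The simulator's independence across units means FA and LDS have little
shared variability to exploit beyond kinematic drive, so their
representations are validated for correctness rather than expected to win
comparisons. Deep-CCA results depend on optimization quality; the
defaults favor reproducibility (single seeded fit, full-batch gradients)
over squeezing out the last few percent. The LSTM is a single layer and
CPU-bound; it is sized for benchmark sessions, not for hundreds of units
at thousands of trials. The CCA-only velocity inversion is a diagnostic
baseline, not a decoder. None of the numbers produced on synthetic
sessions are claims about any particular recorded dataset.
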