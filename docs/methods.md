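# Methods

`eegconn` implements a complete analysis chain for directed, band-limited
cortical connectivity during response inhibition: synthetic data generation
with planted ground truth, EEG-style preprocessing, source reconstruction by
minimum-variance beamforming with density-based node clustering, and a
neural-network estimator of the nonlinear multivariate autoregressive
(nMVAR) model that splits directed information transfer into linear (LC) and
nonlinear (NC) components, tested against time-shifted surrogates.  This
note records the models, the defaults and why they were chosen, and the
limits of what the synthetic validation shows.

## The nMVAR model and the network estimator

The node signals x(n) ∈ R^M are modeled as

    x(n) = f(x_p) + σ(n),      x_p = [x₁(n−1), …, x_M(n−1), …, x_M(n−p)]ᵀ

where f is an arbitrary smooth function of the p past samples of all M
channels and σ is the innovation.  f is fit by a multilayer perceptron with
one hidden tanh layer of H = 10 units (no input–output shortcut), trained by
per-sample ("incremental") gradient descent with momentum α = 0.9, an
adaptive learning rate, early stopping, and 10-fold permuted cross-validation
with 80/10/10 train/validation/test splits.  Channels are standardized
before training, so MSE and R² live on a common scale across datasets.
Weights initialize uniformly in (−0.5, 0.5).

Training defaults and rationale:

- learning rate 0.005, grown ×1.05 after an epoch that reduced training
  error and capped at 0.02 (the cap bounds the steady-state SGD weight
  noise); an epoch that raises training error by more than 4% is rejected
  and the rate shrinks ×0.7 with the momentum buffer cleared — the classic
  adaptive-rate backpropagation rules.
- early stopping with patience 30 over at most 1000 epochs.  Patience
  matters more than usual here: per-sample SGD converges slowly along
  weakly determined weight directions (lags and channels collinear with the
  true predictors), and stopping too early leaves weight mass spread across
  null edges.  At patience 10 the null entries of LC sit near 0.05; at 30
  they approach the least-squares floor (~0.02–0.03) at about twice the
  cost.
- divergence policy: one restart at a tenth of the learning rate, then
  failure.

The model reported after cross-validation is **one further early-stopped fit
on a fresh permuted split** — exactly the protocol of each fold and of every
surrogate fit.  An un-early-stopped refit (e.g., for a fixed epoch count on
all rows) systematically develops larger weights than early-stopped fits and
therefore a positively biased |Jacobian|; since surrogate significance
compares the observed connectivity against surrogate fits by rank, observed
and null models must be statistically exchangeable under the null, which
identical protocols guarantee.

## LC/NC decomposition

The fitted predictor is split as f = f_lin + f_nonlin, with f_lin the
first-order Taylor expansion of the network at the origin of the
standardized input space.  With J(x) = ∂f/∂x_p the network Jacobian and
J₀ = J(0) = W_o · diag(1 − tanh²(b_h)) · W_h:

    LC[i→j] = (1/p) Σ_k |J₀[j, (i,k)]|
    NC[i→j] = mean_x (1/p) Σ_k |J(x)[j, (i,k)] − J₀[j, (i,k)]|

where the NC mean runs over a fixed random subsample of ≤ 2000 training rows
(fixed by the training seed).  A linear map has J(x) = J₀ everywhere, so NC
isolates input-dependent (curvature) sensitivity; a purely even coupling
such as z² − 1 of a standardized parent has no first-order term at the
origin and surfaces only in NC.  Jacobians are validated against central
finite differences to 10⁻⁵ relative in the test suite.

Known floors of these functionals, measured on a purely linear 3-channel
system at L = 8000:

- lag-averaging absolute values inflates entries whose per-lag coefficients
  are mostly zero by an E|noise| term.  Against the least-squares (OLS)
  oracle the entry-wise agreement of LC plateaus around 30–45% relative —
  the SGD noise scale exceeds the OLS one and tanh curvature adds bias —
  while the qualitative structure (which edges dominate) matches exactly.
- NC has a noise floor near 0.03–0.05 from residual curvature even on
  linear data.  That floor does not scale with edge strength; it stays
  around half the lag-averaged LC of a moderate true edge, but well below
  (less than half) the NC of a genuinely nonlinear edge of comparable
  strength, which is the comparison that matters for interpretation.

## Surrogate significance

Null data are built by circularly shifting each channel independently by an
offset uniform on [0.1 L, 0.9 L] in the concatenated-trial index space:
per-channel marginals and autocorrelation are preserved exactly while
cross-channel temporal alignment — hence any directed transfer — is
destroyed.  Every surrogate is fit with the identical architecture and
training protocol (a single 80/10/10 early-stopped fit; cross-validating
each of 100 surrogates would multiply cost tenfold without changing the
connectivity functional).  One-sided empirical p-values use the +1 rank
correction, p = (1 + #{surrogate ≥ observed})/(1 + n_surrogates); an edge is
significant at p < α with self-connections excluded.

Two statistical points worth noting for small surrogate counts:

- with 25 surrogates, p < 0.05 requires the observed value to exceed every
  surrogate, a brittle max-statistic; 50 surrogates tolerate one exceedance
  at the same α and are markedly more robust.
- narrowband signals have heavy spurious-correlation tails (a 10 Hz carrier
  with pole radius 0.95 has an effective sample count near L/30), so the
  null distribution is wide at short L; benchmark validation uses L = 8000.

## The synthetic benchmark

The 3-channel benchmark drives everything quantitative.  Channel 0 is an
AR(2) oscillation (pole radius 0.95 at 10 Hz for 256 Hz sampling; the AR(2)
coefficients follow a1 = 2r·cos(2πf/fs), a2 = −r²).  Channel 1 receives
0.80·z₀(n−1) linearly and channel 2 receives 0.60·(z₀(n−1)² − 1), where z₀
is channel 0 standardized by its own post-burn-in moments; both children
keep 0.55 self-feedback and innovation SD 0.12 (channel 0 has SD 1), with a
1000-sample burn-in.  Standardized parents make the signal-to-innovation
ratio — hence the attainable R²/MSE — a function of the coefficients alone,
and the centered-even nonlinearity gives a sharp LC/NC separation test.
Cross-channel couplings must form a DAG; channels are generated
exogenous-first so a standardized parent exists before its children.

On this benchmark (L = 8000, order p = 10 selected by information criteria,
full cross-validation protocol) the network reaches mean held-out R² ≈ 0.99
and mean held-out MSE ≈ 0.009 on the standardized scale, and the surrogate
test flags the linear 0→1 edge in LC and the nonlinear 0→2 edge in NC while
edges with no coupling stay at the nominal false-positive rate.  Genuine
leakage above the nominal rate appears only on "proxy-parent" edges —
channel 1 is a smoothed copy of the common driver, so sensitivity for
predicting channel 2 can load on it — a known behavior of regression-based
directed connectivity with collinear regressors.

## Source reconstruction

The spatial filter per voxel is the unit-gain minimum-variance solution
w = (LᵀC⁻¹L)⁻¹LᵀC⁻¹ with C regularized by λI, λ defaulting to 5% of the mean
sensor variance.  For free-orientation lead fields the scalar orientation is
the dominant eigenvector of the constrained power matrix (LᵀC⁻¹L)⁺ — the
pseudoinverse restricts the search to orientations the lead field can
express.  Voxels are ranked by the neural activity index
NAI = (wᵀCw)/(σ²·wᵀw) with σ² the smallest covariance eigenvalue (the
white-noise-floor estimate), which cancels the depth-dependent growth of the
filter norm.  The top 2% of labeled voxels are clustered by DBSCAN
(Euclidean metric, eps = 1.5 × voxel edge, minimum 2 voxels; ties in the
top-k broken toward lower voxel index), and each cluster's node signal is
the plain mean time course of its member voxels.

The synthetic grid stands in for an anatomical template: a regular lattice
(default 10×10×10 voxels, 10 mm edge) with region labels partitioning the
grid into slabs, 64 sensors on a deterministic Fibonacci-spiral hemisphere
above it, and gains falling off as 1/(1 + (d/d₀)²) with d₀ = 1.5 voxel
edges — smooth enough that neighboring voxels have correlated lead-field
columns, which is what makes beamformer leakage form spatial clusters.  It
deliberately has no volume-conduction physics, no noise correlations across
sensors, and no inhomogeneous head geometry; passing the recovery tests
shows the algorithm chain is correct, not that it would resolve real
cortical anatomy.

A genuine limitation surfaced by the benchmark: its linear coupling makes
sources 0 and 1 correlate at ~0.88, and a unit-gain minimum-variance filter
partially cancels correlated sources — in the noiseless limit the filter
output is the partialized source (the Σ⁻¹-weighted direction), not the raw
one.  At any regularization that preserves the three-cluster structure the
correlated pair's reconstruction correlation plateaus near 0.5, while the
uncorrelated source exceeds 0.9; with the couplings removed all three
sources reconstruct above 0.85.  The tests assert exactly these achievable
levels.  High regularization (≥ 5× the mean sensor variance) restores
time-course fidelity above 0.95 but merges the activity blobs into a single
cluster — the classic trade-off for correlated sources.

## Preprocessing

Broadband conditioning is a two-pass 4th-order recursive band-pass
(0.5–40 Hz, 48 dB/octave as a two-pass convention) plus a 50 Hz notch;
resampling to 256 Hz uses polyphase filtering with its built-in anti-alias
stage.  Band extraction (theta 4–7 Hz, alpha 8–12 Hz) uses Hamming-windowed
sinc FIR filters designed by the window method with transition width 25% of
the lower band edge, applied forward–backward for exactly zero phase; the
tap count is capped so the two-pass filter remains valid on 4-second
epochs.  Epochs span [−2000, 2000) ms around stimulus onset (half-open in
samples, 0-based internally).  Amplitude rejection removes trials with any
channel exceeding 200 μV peak-to-peak within a sliding 200 ms window, or
falling below 0.5 μV span within 100 ms — the span reading of the
minimum-amplitude rule, since a literal signed minimum would reject every
zero-crossing signal.  In the pipeline, rejection runs on raw sensor epochs
*before* re-referencing (a single-channel dropout is no longer flat after
the common average is subtracted back into it), then the common average
reference and band extraction follow; rejection always precedes narrowband
filtering.

## Behavioral layer

The task generator reproduces the blocked Go/Nogo × congruency design with
exact integer cell counts per block (default 720 trials, 70% Go, 50%
congruent, six blocks, inter-trial interval uniform on 1300–1700 ms).
Responses code as hit/error/miss (Go) and correct omission/false alarm
(Nogo) against a 0–1700 ms window, and the Simon Nogo effect is the accuracy
difference Nogo-congruent minus Nogo-incongruent.  The behavioral simulator
draws per-trial correctness from condition-specific probabilities and adds a
reaction-time shift for incongruent Go trials; its defaults (e.g., 0.82
versus 0.90 Nogo accuracy, 30 ms Simon shift) are plausible fixture values
for exercising the statistics and are not estimates of any studied
population.  Group comparisons use nonparametric rank tests (paired
signed-rank within group or condition, rank-sum between groups), reported
uncorrected with the α exposed.

## Pipeline problem sizes

The demo pipeline runs a deliberately small study — tens of trials per
condition, a 1000-voxel grid, and a configurable surrogate count — so a
full run stays in minutes on one core; the benchmark validations use
L = 8000 samples, 3 seeds × 50 surrogates for edge recovery and 50
replicates × 20 surrogates for the type-I calibration.  These sizes are the
package's validation conditions; scaling any of them up is a config change,
not a code change.

## Known limitations

- Correlated-source cancellation bounds beamformer time-course fidelity
  (above); any conclusions about strongly coupled deep sources inherit it.
- LC/NC magnitudes carry the estimator floors quantified above; compare
  them against surrogate nulls or across conditions, not as absolute
  coupling strengths.
- Directed estimates can leak onto proxy-parent edges when one channel is
  nearly a linear copy of another's driver.
- No time-varying (sliding-window) variant of the estimator; the fit is one
  stationary model per condition and band.
- The synthetic lead field has no volume conduction; EDF/BrainVision
  writers are minimal (16-bit EDF, float32 BrainVision) and exist for round
  trips and interchange, not archival fidelity.
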