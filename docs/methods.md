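# Methods

`manowave` analyzes spatiotemporal quasiperiodic pressure recordings — the
motivating application is high-resolution colonic manometry — in two
stages: a spectral decomposition that turns each recording into a small
number of response functions, and a Bayesian functional mixed-effects
model that compares those responses across experimental groups and
conditions.

## Preprocessing

Raw recordings are channels x time matrices of pressures (mmHg) sampled at
~10 Hz from sensors spaced ~1 cm apart. Three steps precede any spectral
analysis, in this order:

1. **Baseline removal.** A per-channel running median (default window
   120 s) is subtracted. The window is a stand-in for the baseline model
   of the upstream acquisition pipeline; the analyses here are not
   sensitive to its exact width because the analysis band (1/16–16
   cycles/min, cpm) sits well above typical drift rates.
2. **Synchronous pressure-increase removal.** Samples where *every*
   channel rises by at least `min_rise` (default 5 mmHg) within
   `rise_window_s` (default 2 s) are flagged — these are typically
   strain/cough artifacts, since genuine motor patterns rarely span all
   sensors at once. Flagged samples are excluded from all downstream
   time averages; for the wavelet transform, which needs a gapless
   signal, they are filled by per-channel linear interpolation. Pressure
   waves spanning only a subset of channels are untouched.
3. **Clamp and log.** Pressures below 1 mmHg are clamped to 1 mmHg and
   natural-log transformed, so rare high-amplitude events do not drown
   the low-amplitude cyclic activity of interest.

## Spectral decomposition

Each channel x(t) is decomposed with the continuous wavelet transform,
evaluated in the frequency domain via the convolution theorem:
w(t,s) = ifft[X(omega) sqrt(s) Psi*(s omega)], over logarithmically spaced
scales (16 voices per octave spanning the analysis band). The mother
wavelet is an analytic Morlet with shape parameter omega0 = 6 — a standard
admissible choice for quasiperiodic physiological signals; it is zero-mean
in practice, so constant offsets are annihilated. Signals are mean-removed
and zero-padded to the next power of two; the padded region is discarded.
An optional *harmonic clip* hook can transform w(t,s) before reassignment
(for harmonic-artifact suppression algorithms such as the MesaClip family);
the default is the identity.

**Synchrosqueezing** maps scale to frequency: the instantaneous frequency
(1/2pi) d/dt unwrap(angle w(t,s)) is estimated by central differences
(one-sided at the edges), and w(t,s)/s is accumulated into the geometric
frequency bin containing it (half-open membership [edge, next_edge)).
Coefficients mapping outside the band, including negative estimates, are
discarded. An alternative s^(-3/2) dlog(s) weighting common elsewhere in
the synchrosqueezing literature is available behind
`normalization="density"`.

The **1D response** is the log global wavelet power: |v(t,f)|^2 averaged
over unmasked samples and over channels (channels are flattened into one
long time axis so every retained sample counts equally), then logged. The
default grid is K = 33 bins over 1/16–16 cpm. Bins that received no power
are floored at 1e-12 of the maximum bin before the log so the response is
finite everywhere.

The **2D response** comes from cross-wavelet transforms
v_ab = v_a conj(v_b) of all adjacent sensor pairs (proximal sensor first,
so positive phase difference = antegrade propagation). For each frequency,
|v_ab| is averaged within each of M = 18 equal phase-difference bins over
(-pi, pi] (K = 17 frequency bins by default), pairs flattened before
averaging. Samples with exactly zero cross-amplitude — frequency bins the
reassignment left empty — carry no information and are not counted; this
also makes the histogram exactly mirror-symmetric under swapping the two
sensors. The per-bin *mean* amplitude (not the amplitude-weighted sum) is
used; a squared-amplitude variant is available behind `weight="power"`.
Empty bins are floored as in 1D; the response is the log.

Phase difference phi at frequency f over sensor separation d maps to an
apparent propagation velocity u = d·2·pi·f/phi (cm/s); its sign encodes
direction. For synchronous (phase-locked) activity phi = 0 the *pace*
1/u = phi/(d·2·pi·f) = 0 is the stable quantity.

## The functional mixed-effects model

Each observation i (one subject x region x meal period) contributes a
response function y_i on the frequency grid (1D) or frequency x phase grid
(2D):

    y_i(x)      ~ GP(eta_i(x), omega_i(x) omega_i(x') (k_sigma(x,x') + sigma_eps^2))
    eta_i       = X_i beta + Z_i b + o
    log omega_i = W_i gamma + U_i u

X and W are fixed-effect design matrices from formula notation (default
mean formula `group*region*meal + (region*meal|subject)`, scale formula
`group*region*meal + nchan`; treatment coding with healthy / descending /
preprandial references; the channel count nchan enters the scale model
standardized, because fewer sensors mean noisier averages). Z contains one
block of within-subject effect functions per subject; U defaults to empty
(with no repeated measurements a within-subject scale effect is not
identified). The offset o defaults to the grand mean of all responses.

Kernels: a squared-exponential in log frequency,
k(f,f') = tau^2 exp(-|ln f - ln f'|^2 / (2 lambda^2)), and for 2D its
product with a periodic phase kernel
exp(-2 sin^2(|phi-phi'|/2)/lambda_phi^2), whose Gram matrix on the product
grid is a Kronecker product of the two axis matrices. Population effects
(beta_p, gamma_q) use covariance kernels with free tau; subject effects
use correlation kernels (tau = 1) with their variance carried by a shared
E x E between-function covariance Sigma_b = diag(sd) R diag(sd),
block-diagonal over subjects. Because the between-function notation leaves
the cross-function kernel open, all subject-effect functions share one
lengthscale — the reading that keeps the matrix-normal structure exact.

Standardizing residuals by omega_i reduces the likelihood to one zero-mean
GP shared by all observations: the 1D path does a single Cholesky of
C = K_sigma + sigma_eps^2 I per posterior evaluation; the 2D path
separates the Kronecker kernel from the white-noise term through
eigendecompositions of the two factors (C's eigenvalues are
lf_i·lh_j + sigma_eps^2), using (SF kron SH)^-1 = SF^-1 kron SH^-1.

**Priors.** lambda ~ Lognormal(0,1) for all effect kernels;
lambda_sigma ~ Lognormal(-0.7,1) constrained below the smallest effect
lengthscale by the rejection-free reparameterization
lambda_sigma = min(lambda) · sigmoid(zeta) (log-density plus transform
Jacobian), so the structured noise is always rougher than the effects it
sits under; tau ~ Gamma(2,1); sigma_eps and the Sigma_b standard
deviations ~ Half-Normal(1) on the omega-standardized scale (weakly
informative for responses standardized near unit scale); the Sigma_b
correlation ~ LKJ(2). In the 2D model one rho ~ Beta(2,2) correlates each
kernel's log lambda_f with its log lambda_phi through a Gaussian copula
(non-centered bivariate-normal latents), which preserves the Lognormal
marginals exactly.

**Inference.** All latent functions are sampled non-centered (whitened
through the kernel Cholesky factors, or the per-axis factors in 2D), and
the whole posterior — latents plus hyperparameters on their unconstrained
scales — is sampled with an in-package No-U-Turn sampler: multiplicative
stepsize adaptation by dual averaging toward an 0.9 acceptance target,
windowed diagonal mass-matrix estimation, zero-initialized chains, and a
divergence threshold of 1000 on the Hamiltonian error. Points where the
posterior is numerically unevaluable (overflow, factorization failure)
return -inf and register as divergences rather than aborting. The
gradient comes from a small reverse-mode automatic-differentiation engine
written for this package (elementwise ops, batched matrix products,
Cholesky, triangular solves, symmetric eigendecompositions); its adjoints
are verified against finite differences in the test suite. The reference
sampler configuration is 8 chains x (500 warmup + 500 sampling) = 4000
draws with adapt_delta 0.9 and maximum tree depth 10. Convergence is
summarized by split R-hat and effective sample size (ArviZ) plus
divergence and tree-depth counts.

This posterior is genuinely expensive: trajectories routinely reach tree
depths of 7–10 because the hyperparameter–latent coupling is stiff even
after whitening (the original Stan-based analyses of such models report
hours of sampling at full scale). The package's tests and acceptance
script therefore run deliberately reduced configurations — a parameter
recovery study with 20 observations on a 9-bin grid at 4 chains x (250 +
250) with tree depth capped at 7, and a 4-observation smoke model at the
full 8 x 500 draw count — chosen as the smallest problems that still
exercise every model component.

## Grid refinement

Sampling runs on the coarse grid; each posterior draw of each effect
function is then refined by the GP conditional mean
y* = Sigma(x*,x) Sigma(x,x)^{-1} y, which preserves the covariance between
locations and reproduces the inputs exactly at the original nodes. The
frequency axis refines in endpoint mode (K -> q(K-1)+1: 33 -> 129 at
factor 4, 17 -> 97 at factor 6), the periodic phase axis in periodic mode
(M -> qM: 18 -> 108). Refinement uses each draw's own kernel
hyperparameters, preserving joint posterior uncertainty; 2D grids refine
separably per axis via the Kronecker inverse identity. All kernel Gram
matrices carry a relative diagonal jitter of 1e-8·tau^2 before
factorization.

## Contrasts

Because responses are log power, differences of condition-cell means are
log power *ratios*. Contrast weights are assembled from cell-mean rows of
the fixed-effect coding (not raw coefficients), which makes every contrast
invariant to the coding scheme. Bands are pointwise equal-tailed 95%
credible intervals (highest-density intervals behind `method="hpd"`); a
grid point is *significant* when its band excludes ratio 1. No additional
multiple-comparison correction is applied: the GP prior over locations is
the model's correlation/smoothing mechanism, and the bands are read
pointwise exactly as the envelope plots are.

## Synthetic data

The recording generator emulates what the analysis consumes: Gaussian-
envelope bursts of pressure waves (default 3 cycles per burst recurring
every ~3 min, echoing the clustered cyclic motor patterns seen around
2–4 cpm) propagating along the array with per-channel lag
channel·spacing/velocity, over a ~20 mmHg resting baseline with optional
linear drift, all-channel step artifacts, and white noise; defaults are
30 channels, 1 cm spacing, 10 Hz, 1 h. It does **not** model colonic
electrophysiology (slow waves, ICC dynamics), amplitude gradients along
the array, non-stationary frequency drift within a burst, or realistic
artifact morphology — so passing tests demonstrate that the pipeline
recovers known spectral/propagation structure and known regression
effects, not that it is validated on clinical recordings.

The response generator runs the statistical model forward from known
effect functions and is the ground truth for the parameter-recovery and
moment tests. Study-design defaults follow the motivating application:
11 healthy + 12 patient subjects, descending and sigmoid regions,
pre/postprandial periods (the generator exposes the counts as parameters,
and supports dropping cells for incomplete designs).

## Numerical choices and degenerate inputs

- Frequency-bin membership is half-open; +pi wraps into the last phase
  bin, so the circle is covered exactly once.
- Empty spectrum/histogram bins are floored (1e-12 of the maximum)
  before logs; all-masked inputs are rejected with an error.
- Kernel jitter 1e-8·tau^2; non-positive-definite covariances raise with
  the offending smallest eigenvalue.
- The eigendecomposition adjoint masks (near-)degenerate eigenvalue
  pairs; this is exact for the rotation-invariant objectives used here
  (the periodic kernel's Gram matrix has repeated eigenvalues by
  symmetry).
- Ties in the lengthscale minimum take the first argument's subgradient.
- The intercept of the scale model trades off against the overall level
  of k_sigma (the model is scale-redundant along that ridge); the priors
  keep the posterior proper, but very small datasets show the expected
  wide, correlated posteriors on tau_sigma, sigma_eps and gamma's
  intercept. Fits with no scale predictors can drop omega entirely
  (scale formula "0").

## Known limitations

- Simulation-based calibration is exercised only as a reduced prior-
  predictive check (prior-only sampling reproduces the tau prior's
  marginal second moment); a full SBC sweep is beyond the intended test
  runtime.
- The 2D model is implemented and tested for correctness of its
  likelihood and gradients, but full-scale 2D fits (97 x 108 refined
  grids, dozens of observations) are long-running by design.
- Wavelet coherence, cone-of-influence masking, and red-noise
  significance testing of spectra are out of scope.
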