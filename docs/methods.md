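# Methods

## Scientific setting

The package models effective connectivity in a five-node auditory
network during passive listening to consonant-vowel (CV) syllables:
medial and lateral auditory cortex (AC) in each hemisphere plus the left
planum temporale (PT).  The experimental factor of interest is the
consonant's place of articulation (PoA: alveolar /d,t/ vs bilabial
/b,p/); voice-onset time (VOT: short vs long) is the second factor of
the 2x2 stimulus design.  Because no ROI time-series data are deposited
for this paradigm, every analysis runs on synthetic data generated from
a known ground truth with the study's exact block design, which turns
the pipeline into a measurable object: recovery of the generating
parameters and of the generating model is what the validation
experiments quantify.

## Neural model

Node activity follows the bilinear state equation

    dz/dt = (A + sum_j u_j B_j) z + C u

with `A` (Hz) the fixed coupling (row = target, column = source), `B_j`
the change in coupling under modulator `u_j`, and `C` the weights of the
driving input.  The driving "phonetic input" is a boxcar over every
non-target stimulus (700 ms); the PoA modulator is the +-1 condition
code, mean-centred over the stimulus support.  Structure is enforced by
boolean masks; the connectivity rule permits medial<->lateral links
within each hemisphere, homolog links across hemispheres, and links
between every AC node and PT - 16 directed connections.  The modulation
model space has one member per connection, carrying the modulator on
that connection alone; all members share the A- and C-structure (driving
input to the four AC nodes).

Self-connections are parameterized as `A_ii = -0.5 * exp(theta_i)` so
that negativity (and hence nominal stability) is structural.  Priors are
weakly informative, zero-centred Gaussians: off-diagonal A and B entries
N(0, 0.25), C entries N(0, 1), log self-decay N(0, 0.0625).

## Observation model

Neural trajectories are mapped to BOLD by linear convolution with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1 s,
peak:undershoot 6, length 32 s, peak-normalized) and sampled at the
volume grid (TR = 2 s).  A full nonlinear balloon model is deliberately
not used: the linear observation model keeps the inversion fast and
analytically checkable, shares its kernel with the GLM, and suffices
for data generated under the same assumption.  This is a stated
simplification - on real data the hemodynamic nonlinearity is a known
source of bias.

## Integration

Inputs are piecewise constant on the micro-time grid (dt = TR/16 =
0.125 s), so within every step the system is linear time-invariant.  The
integrator therefore uses the exact one-step transition obtained from
the matrix exponential of the augmented generator [[M, Cu], [0, 0]]
(computed once per distinct input combination - there are only a
handful: silence, alveolar stimulation, bilabial stimulation).  This is
exact for the sampled inputs, so step-halving changes trajectories only
through input requantization, and the single-node closed form is matched
to machine precision.  The neural state restarts at rest at every run
boundary (runs are separate acquisitions), and HRF convolution is
likewise run-wise.

Parameter sensitivities (the Jacobian of the predicted BOLD) chain the
Frechet derivatives of the same matrix exponentials.  Every free
parameter perturbs the augmented generator in a single entry, so the
derivative is evaluated spectrally: with `X = V diag(lam) V^-1`,
`dexpm(X)[D] = V ((V^-1 D V) * Phi) V^-1` where `Phi` is the
divided-difference table of `exp(lam)`.  When the eigenbasis is
ill-conditioned (cond(V) > 1e6, e.g. exactly defective triangular test
systems), the code falls back to scaling-and-squaring `expm_frechet`.
The Jacobian is exact up to that conditioning guard; a finite-difference
cross-check is part of the test suite.

## Inversion and model evidence

`invert_model` maximizes a Laplace free energy

    F = accuracy - complexity
    accuracy   = log p(y | theta)   (Gaussian, per-node variance profiled)
    complexity = KL[ N(mu, Sigma) || N(mu0, Sigma0) ]

by damped Gauss-Newton from the prior means (fully deterministic).
Per-node noise variances are profiled at sigma^2 = SSE/(T - K) with a
small floor (1e-8 of the data variance) so noiseless data remain
finite.  Nuisance structure - intercept, run-baseline indicators for
runs 2..R, and the 256-s discrete-cosine high-pass basis - is projected
out of data and predictions, the flat-prior limit for those
coefficients; `T - K` accounts for the projected dimensions.  The
posterior covariance is the inverse curvature `(J' Lambda J + Pi0)^-1`,
ridge-regularized with a warning if singular.

Damping follows Levenberg-Marquardt: a candidate step is accepted only
if F increases (so the recorded F history is non-decreasing by
construction); on rejection the damping factor doubles (with a floor of
1e-3 when re-raised from very small values); on a well-predicted accept
(gain ratio > 0.5) it relaxes by 4.  Iteration stops when an accepted
step improves F by less than 1e-4 nats, when the Newton decrement
`g' Sigma g / 2` falls below the same tolerance, or after 128
iterations (`converged=False` in that case).  Temporal autocorrelation
is ignored in the likelihood - the simulator's AR(1) component is mild
(rho = 0.3) and largely whitened by the high-pass projection; an exact
treatment would use a GLS whitening matrix.

## Model selection and averaging

Fixed-effects BMS sums log evidences over subjects and applies a softmax
under a uniform model prior; it is invariant to common shifts, and a
280-nat lead maps to a posterior probability of 1.0 at double precision.
Random-effects BMS implements the variational Dirichlet scheme over
population model frequencies (alpha0 = 1), with exceedance probabilities
estimated from 20,000 seeded Dirichlet draws.  Family comparison
aggregates evidence mass (log-sum-exp within family, fixed effects) or
expected frequencies (random effects) over a partition of the model
list.  BMA averages connection-wise posterior means weighted by model
probability; connections absent from a model contribute zero, and a
sampling mode (model index ~ pP, then parameters from each model's
Gaussian posterior) is available when posterior spread should propagate.

## Synthetic data

Each subject receives an independent seeded realization of the block
design: per run, 12 ON blocks of 20 s (3 per PoA x VOT cell; 10 trials
of 700 ms whose inter-trial silences are a flat Dirichlet split of the
13-s slack) alternating with 16-s OFF blocks, 220 volumes per run; one
trial per block is a monaural target (10% of trials), modelled as a
separate nuisance regressor and excluded from the phonetic input.
Subject-level heterogeneity is Gaussian jitter (sd 0.05 Hz) on the
unmasked A/B/C entries, redrawn (up to 10 times) until the effective
coupling is stable for every input combination.

Noise at the volume grid is AR(1)-filtered Gaussian (rho = 0.3,
stationary scaling) plus a slow cosine drift (period 300 s, random
phase, amplitude equal to the noise sd).  SNR is defined as sd(clean
stimulus-locked signal)/sd(AR+white noise) per node at the volume grid;
the noise sd is set from the target SNR (default 2), and the realized
ratio is within sampling error of the target.  What the generator does
not emulate: physiological (cardiac/respiratory) noise, motion, scanner
spikes, hemodynamic nonlinearity and regional HRF variability, BOLD
responses to the target trials, and spatial/voxel structure of any kind.
Passing tests therefore demonstrate internal consistency of the
estimation machinery, not robustness to these real-data phenomena.

The `paper_poa` scenario fixes the ground truth to the qualitative sign
pattern of the winning model: excitatory within-hemisphere, homolog and
AC->PT coupling (+0.2/+0.25 Hz), inhibitory PT->AC feedback and
left-to-right lateral homolog link (-0.2 Hz), driving input 0.4 to the
four AC nodes, and a PoA modulation of -|strength| (default -0.4 Hz) on
R-lateral-AC -> PT alone.  A consequence worth stating: because the
alveolar code is +1 and the modulated AC->PT coupling is excitatory, the
preset *reduces* the PT response to alveolar blocks while *increasing*
the AC responses (via reduced PT-mediated inhibition), more strongly on
the left - i.e. the left-lateralized alveolar activation pattern emerges
in the AC nodes, not in PT.  The tests assert these oracle-computed
directions.

## GLM and group statistics

The first-level design matrix treats the concatenated runs as one
session: HRF-convolved phonetic, PoA, VOT and interaction regressors
(modulators mean-centred before convolution), a target-trial regressor,
run-baseline indicators for runs 2..R, and the DCT high-pass basis
(K = floor(2*T*TR/256 + 1) components, k = 0 serving as intercept).
Rest is implicit, so the phonetic beta is an increase over baseline.
Estimation is OLS per ROI; serial correlation is ignored at the default
(see above).  One caveat documented here because it is easy to
mis-state: a truncated DCT basis removes basis-aligned slow components
exactly but leaves spectral leakage for off-grid frequencies - a 300-s
cosine on 2200 s of data loses >75% of its energy but is not nulled.

Condition cells are reconstructed per AC node by inverting the modulator
parameterization, `cell = phonetic + p*poa + v*vot + p*v*inter` with
p, v the +-1 codes, giving the subjects x 2x2x2x2 array (Hemisphere x
ROI x PoA x VOT; PT is not part of the factorial grid).  The
repeated-measures ANOVA projects the cell array onto orthonormal effect
contrasts; F is the ratio of effect to within-subject contrast variance
and the Greenhouse-Geisser epsilon comes from the eigenspectrum of the
contrast-score covariance - identically 1 for the all-2-level design,
where each F equals the squared paired t.  Fisher-LSD post hocs are
uncorrected pairwise paired t-tests on marginal cell means.  A
sign-flipping permutation option (seeded, default 10,000 permutations)
backs the one-sample group test nonparametrically.

## Problem sizes and seeds

The recovery experiments use a scaled-down acquisition of 2 runs per
subject (440 volumes) with the full 10-subject group: parameter
recovery inverts 160 models, model recovery 10 replicate groups x 160
models, and the ANOVA power experiment uses 20 replicate groups at the
GLM level.  All randomness flows from explicit integer seeds through
numpy `SeedSequence` spawning, so every experiment is exactly
reproducible; one master seed fans out to per-subject design and noise
seeds.

## Known limitations

Beyond the simulator gaps listed above: the likelihood assumes
independent Gaussian noise per node; the linear observation model
cannot capture saturation of large responses; model evidence is a
Laplace approximation whose complexity term inherits the Gauss-Newton
curvature; random-effects BMS exceedance probabilities are Monte-Carlo
estimates; and the A/C-family pre-analysis is exposed as a recipe whose
outcome on synthetic data depends on the structure the data were
generated from.
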