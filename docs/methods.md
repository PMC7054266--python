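# Methods

## The model

`sessm` implements an accuracy-coded sequential sampling model of the
Simon effect (SE-SSM).  Within a trial, a decision variable x
accumulates noisy evidence

    dx = v (1 + c b d) dt + s ξ1 √dt,

starting from x0 = x_b (1 − 2c), until |x| reaches the threshold x_th;
the upper bound codes the correct response.  c ∈ {0, 1} flags conflict
trials, d is elapsed decision time in seconds.  The observed response
time adds a non-decision component t_eff = t + ξ2 s_t with ξ2 uniform
on [−1/2, 1/2] — s_t is the *range* of the jitter, the standard
convention for non-decision-time variability (the alternative,
half-range scaling, would halve the meaning of fitted s_t; we state the
convention here because it is not identifiable from a single fit).

Two parameters are conflict-specific.  The starting bias x_b displaces
the accumulator toward the error bound on conflict trials (an automatic
response channel), producing slower, more error-prone conflict
responses and, in particular, fast conflict errors.  The counteraction
gain b ramps the drift linearly within a conflict trial, compensating
the bias late in the trial and *shrinking* the conflict RT spread.
The noise scale s is fixed at 1 and sets the evidence unit.

Parameter invariants enforced throughout: v, x_th, t > 0; s_t, b,
x_b ≥ 0; x_b < x_th; t − s_t/2 > 0.

## First-passage engine

The SE-SSM has no closed-form RT density (the drift is time-varying on
conflict trials), so defective first-passage densities are computed by
propagating a discretized decision-variable distribution through
Gaussian single-step transition kernels with absorbing bounds.  Because
the drift does not depend on x, every transition matrix is a
convolution, evaluated in O(m·k) per step (m interior cells, k kernel
taps).  An optional numba JIT accelerates the step loop; a pure-numpy
path produces identical results.

Numerical choices:

* **Edge-aligned cells.**  The interior (−x_th, x_th) is tiled by m
  cells of width 2·x_th/m (m chosen so the width is closest to the
  nominal resolution dx), so the absorbing boundary coincides exactly
  with ±x_th.  Placing grid *points* on the threshold instead would put
  the effective barrier half a cell inside the bounds, a bias of order
  dx/2 that measurably distorts choice probabilities at dx = 0.01.
* **Cell-integrated kernels.**  Transition weights are Gaussian CDF
  differences over destination cells (mean drift·dt, sd s·√dt), with
  the far tails folded into the end taps; each column sums to one, so
  interior probability is conserved exactly before absorption
  accounting.
* **Initial condition.**  Unit mass split linearly between the two cell
  centers bracketing x0 (keeps the symmetric case exactly symmetric and
  makes P(correct) continuous in x_b).
* **Defaults.**  dt = 1 ms; dx = 0.01 for the coarse fitting pass and
  0.005 for the refinement; horizon t_max = 5 s with a mass-leak
  warning at 1e−3; density floor 1e−10 in the log-likelihood (guards
  against −∞ from outlier RTs); boundary pad 5·s·√dt.
* **RT domain.**  Densities are shifted by t and convolved with the
  discretized uniform jitter kernel; the defective CDFs are convolved
  with the same kernel directly (the CDF of a sum), avoiding a
  differentiate-then-integrate roundtrip that costs ~0.01 sup-norm
  accuracy at steep rises.  Likelihoods interpolate the RT-domain
  density linearly at each observed RT.

Accuracy: against a 1e5-trial simulation at the same dt, defective CDFs
agree to < 0.01 sup-norm.  Against the *continuum* closed form (b = 0),
the discrete-time process carries the usual boundary-overshoot bias of
order 0.58·s·√dt (≈ +0.008 in P(correct) at dt = 1 ms); refining to
dt = 0.25 ms, dx = 0.005 brings the closed-form error below 0.005.  The
engine is validated in both regimes: equivalence with the simulator at
the shared default resolution, convergence to the analytic limit at
refined resolution.

## Simulator

Euler–Maruyama at dt = 1 ms, threshold crossing recorded at the first
sample with |x| ≥ x_th (no within-step bridge correction; the
discretization bias is shared with the engine and below all test
tolerances).  Trials still running at t_max = 5 s are flagged censored
and excluded from RT summaries with a warning.  Traces, when kept, are
float32 and end at the crossing sample.

## Fitting

Per subject, the joint choice–RT negative log-likelihood (correct *and*
error trials) is minimized by a bounded compass (generalized pattern)
search: poll ±1 mesh step per free parameter, move on improvement,
halve the mesh after a failed poll; converged when the mesh is below
1/256 of the initial poll scale (about one prior sd per parameter) and
the last contraction improved the NLL by < 1e−3 nats.  Five restarts
(default) are drawn from fixed initialization distributions — v ~
Gamma(mean 3, sd 1), x_th ~ G(0.6, 0.15), t ~ G(0.3, 0.075), x_b ~
G(0.1, 0.06) (moment matching: shape (m/sd)², scale sd²/m), b ~
half-normal(sd 2.5), s_t ~ U(0, 0.15) — at the coarse grid resolution,
followed by one refinement pass at the fine resolution from the best
candidate.  Box bounds (v ≤ 20, x_th ∈ (0.05, 5], t ∈ (0.05, 1.5],
s_t ≤ min(0.5, 2t − 0.01), b ≤ 20, x_b ≤ 0.95·x_th) enclose the
initialization distributions with wide margins; the two coupled caps
keep every polled point a valid parameter set.  Fits are deterministic
given the seed; evaluations are cached.

The candidate family: M1 (basic model, 4 free parameters), M2 (+b), M3
(+x_b), M4 (both, 6 free).  Model comparison uses AIC = 2k + 2·NLL and
Akaike weights; winners tie-break toward fewer parameters.  When the
whole family is fitted together, each larger model additionally starts
its refinement from the nested submodels' solutions, which makes the
nesting inequality NLL(M4) ≤ min(NLL(M2), NLL(M3)) ≤ NLL(M1) hold by
construction rather than up to optimizer noise.

## Expected decision variable and BOLD regressors

For each real trial, simulated trials of the same condition and
correctness whose RT falls in a 25 ms bin centered on the observed RT
(|ΔRT| ≤ 12.5 ms) are aligned at their threshold crossing and averaged
backwards wherever at least half of them have samples (avoids artifacts
from the shortest traces).  Trials with fewer than 10 matches are
excluded rather than matched more loosely, keeping the estimator's
definition uniform.  Mean DV amplitudes are taken in 50 ms windows
centered −25, −75, … ms before the response (8 windows by default;
windows reaching before a trace's start are missing).  Amplitudes are
z-scored across trials (population sd); missing values are imputed as 0
after z-scoring — mean imputation, chosen over trial exclusion to keep
the event count constant across windows.  An optional condition split
z-scores the two conditions separately into a pair of regressor
vectors.  Window-to-scanner-time mapping places the crossing at the
observed response time, absorbing the motor part of the non-decision
component into the alignment; DV regressor events are 100 ms long,
centered on their extraction time.

The default pool size is 7.5e5 traces (split between conditions), but tests and the acceptance script use 1e5–2e5:
measured stability shows pool-doubling moves the mean window amplitude
by far less than the across-trial spread, while per-trial values for
tail-RT trials always retain matching noise of the order of that spread
(few matchable traces exist at any pool size).

## First-level GLM

Designs are built as boxcars at 0.1 s microtime resolution × parametric
amplitude, convolved with a canonical double-gamma HRF (response gamma
shape 6, undershoot shape 16, unit dispersions, undershoot ratio 1/6,
peak-normalized; the FSL variant differs slightly — the difference is
absorbed by the tolerance of every check that involves the HRF) and
sampled at k·TR.  High-pass filtering (0.01 Hz) is implemented as
discrete-cosine drift columns with a 100 s cutoff added to the design
rather than pre-filtering the data; motion-style confounds are accepted
as unconvolved numeric columns.  Standard designs: simple (all stimuli
+ incongruent stimuli), RT (all stimuli + log-transformed z-scored RT
amplitudes), DV (correct-trial events, 1 s by convention, + 100 ms DV
events).  Estimation is OLS with t = c'β̂/√(σ̂² c'(X'X)⁻¹c) and z via
the t tail probability.  Sessions combine by inverse-variance fixed
effects; subjects by a one-sample t-test (a full mixed-effects level is
out of scope); clusters are reported above z = 2.5 by 26-connected
components, without random-field p-values.

## Group statistics

Per masked voxel, the Pearson correlation between subject GLM weights
and a scalar covariate is Fisher z-transformed (|r| capped at 1−1e−12;
constant voxels get z = 0 with a warning).  TFCE integrates
extent^E·height^H (E = 0.5, H = 2) over thresholds with step
max|map|/100 (midpoint rule; positive and negative parts enhanced
separately and recombined with sign; 26-connectivity).  Significance
uses the permutation distribution of the image-wide maximum |TFCE|
under covariate shuffling: p = (1 + #{null max ≥ observed})/(1 + n_perm),
split by observed sign into positive/negative one-tailed maps with the
complementary voxels set to 1.  When n_perm reaches n! the permutations
are enumerated exactly.  Permuting the covariate rather than the maps
is equivalent under exchangeability and cheaper.

## Synthetic data

The behavioral generator reproduces a typical two-session Simon-task fMRI protocol: 21 subjects,
2 sessions, each with 48 congruent + 48 incongruent + 24 null trials of
2.5 s on a fixed onset grid (null positions uniformly random), TR 2 s,
151 volumes/session.  Subject parameters are drawn from a population
with the initialization marginals but a Gaussian-copula-coupled
conflict pair (b, x_b) (ρ = 0.5, Spearman ≈ 0.48, the level of
across-subject correlation typically seen between fitted conflict
parameters in this task) and a
population counteraction scale b ~ HN(1.5) — weaker than the
optimizer's initialization prior, reflecting that in practice roughly half
of subjects show little or no counteraction.  This population was
calibrated once against standard behavioral benchmarks for the task
(conflict RT cost ≈ 26 ms; accuracies ≈ 97%/96%) and then frozen; with it, synthetic
cohorts show the Simon RT cost (Wilcoxon p < 0.05 in ~97% of seeds),
the b-driven reduction of conflict RT spread, and minimum accuracy in
the fastest conflict RT quintile.  An *uncoupled* population fails to
produce the RT cost in most cohorts, because counteraction alone speeds
conflict trials.

BOLD fixtures are white-noise series/maps with planted HRF-convolved
responses or covariate-linked regions.  What passing tests show, and
what they do not: the fixtures validate estimator correctness and
calibration against a matched generative model; they contain no
autocorrelated scanner noise, motion, anatomy, registration error, or
conflict-history structure, so they say nothing about preprocessing
robustness on real data.

## Validation problem sizes

The test-suite and acceptance-script runs use: 5 random parameter sets
× 1e5 trials for engine/simulator equivalence; a 3×3 (v, x_th) grid for
the closed-form limit; 8–10 subjects × 2000 trials/condition with 3
restarts for parameter recovery; 6–10 replicates × 1000 trials/condition
with 2 restarts per model for model recovery; 10 cohort seeds for the
Simon signatures; 200 null runs × 199 permutations for FWER
calibration; 1e5-trace pools and 10 noise seeds for the DV-GLM checks.
These sizes were chosen so the full validation runs on a single CPU in
tens of minutes while keeping Monte-Carlo error well inside each
check's tolerance.

## Known limitations

* Fitted s_t is interpretable only under the uniform-range convention
  stated above.
* The engine and simulator share the discrete-time crossing bias; fitted
  parameters are defined at dt = 1 ms, not in the continuum limit.
* No hierarchical/Bayesian estimation; subjects are fitted
  independently.
* The GLM stack assumes preprocessed, aligned inputs (no registration,
  smoothing, slice timing, prewhitening).
* Across-trial sequential (conflict-history) effects are outside the
  model.
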