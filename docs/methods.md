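# Methods

## The model

Gamble value is *synthesized*, not received: a two-layer network maps a
50/50 gamble's prospective gain G and loss L (both positive magnitudes)
onto a scalar value signal V read out from a population of integration
units,

    x(i,j) = f(u(i); mu_x(i,j), sigma_x(i,j))     attribute sublayers
    v(k)   = sum_ij C(i,j,k) x(i,j)               integration inputs
    z(k)   = f(v(k); mu_z(k), sigma_z(k))         integration outputs
    V      = sum_k w(k) z(k)                      linear population readout

with f the logistic sigmoid f(u) = 1/(1 + exp((mu − u)/sigma)).  The
bounded (saturating) response of every unit is the biological constraint
the whole account rests on: a unit cannot discriminate inputs that land
in its saturated tails.  The model is agnostic about within-trial
temporal dynamics; a "trial" is one presentation of a (G, L) pair.

Money is mapped onto a canonical [0, 1] domain by dividing by $40 (the
largest amount in either study design).  Attribute units tile that
domain: thresholds evenly spaced on [0, 1], slope equal to half the
spacing; they are fixed, not fitted.  Integration units are homogeneous
(mu_z = 0, sigma_z = 1); the adapted quantity is the location and scale
of their *inputs*, set by the connectivity C.  Defaults: 8 units per
attribute sublayer, 16 integration units.  Initial connectivity entries
are i.i.d. N(0, (c/sqrt(16))^2) with c = 3, which makes initial
integration inputs sample the saturating range.

Choice: p(accept) = sigmoid(b + V) with unit slope.  There is no
separate temperature parameter — the readout weights absorb behavioral
temperature — and the value readout itself has no intercept; the
decision bias b plays that role, mirroring the intercept of the choice
logistic regression.

## The plasticity rule

At the small-noise limit, the information the integration layer loses
about its inputs decomposes into (minus) the entropy of the integration
inputs v and (minus) the mean log-steepness of the activation functions.
Descending the *local* part of this objective's gradient with respect to
C — the non-local entropy term couples all connections and is
biologically implausible, so it is dropped from the rule — and replacing
the expectation with an exponentially weighted moving average over
trials gives

    dC_t(i,j,k) = alpha (1 − beta) dC_{t−1}(i,j,k)
                  + alpha beta (1/sigma_z(k)) (1 − 2 z_t(k)) x_t(i,j).

The rule is local (only the connected pair's outputs enter),
self-organized (no teaching signal), and anti-Hebbian (a connection
weakens when x > 0 and z > 1/2).  alpha scales the magnitude of
plasticity and beta its time scale; alpha = 0 or beta = 0 recovers
*static* value synthesis exactly.  Note the 1/sigma_z placement: the
derivative chain for this sigmoid parameterization (f' = f(1−f)/sigma)
forces division by sigma_z; a multiplicative shorthand sometimes seen
for this rule coincides with ours at sigma_z = 1, the default.

Two empirical notes from our implementation, both visible in the test
suite:

* The rule provably ascends the log-steepness term, and does so in
  100/100 seeded runs.  The *total* information loss under the Gaussian
  log-det entropy approximation is roughly flat over an adaptation run:
  the entropy of v shrinks about as fast as the steepness gain, because
  the dropped non-local term is exactly the part that would preserve
  input variance.  The approximation is also numerically fragile here —
  attribute patterns live on a two-dimensional manifold, so C S C^T is
  near-singular for realistic layer sizes (a ridge is applied and
  flagged).
* Plasticity magnitude matters qualitatively.  Large steps (alpha around
  0.5) collapse integration responses onto z = 1/2 within a session,
  destroying the value signal.  The Monte-Carlo experiments use
  alpha = beta = 0.1: self-organization reaches a steady state well
  within a 256-trial session (mean update norms fall by more than half
  from the first to the last 32 trials) while units keep responsive
  variability spanning their output range — the regime in which apparent
  value range adaptation is observable at all.

## Monte-Carlo range-adaptation experiments

A condition is a factorial design: n_levels x n_levels (default 16 x 16
= 256) gain/loss combinations, each presented once, order shuffled per
run.  "Narrow" ranges span [0, 0.5] and "wide" [0, 1] on the unit
domain; range-grid sweeps use upper bounds {0.4, 0.6, 0.8, 1.0} with all
ranges starting at 0.  Per run: draw a fresh random C, train the readout
w to output EV = (G − L)/2 by least squares over the condition's grid
(R^2 > 0.999 in all of 100 seeds), freeze w, and let C self-organize
over the trial sequence.  Analyses of the adapted network re-evaluate it
statically on the same design (steady-state responses, uncontaminated by
the early transient).

Summary statistics per run: the fraction of integration inputs within
mu_z ± 2 sigma_z (responsive-range focusing); EV-binned mean response
curves per unit sign class (units classed by the sign of their
across-trial correlation with EV; 9 equal-width bins within the realized
EV range; units with response variance < 1e−8 excluded); neural encoding
strengths (below); and behavioral sensitivities, the OLS gradients of
the value landscape per unit gain and per unit loss over the condition
grid, whose ratio is the loss-aversion ratio.  At the condition level
the ratio is computed from run-mean sensitivities — per-run ratios are
heavy-tailed when adapted sensitivities are small.

Defaults are 1000 runs; the analysis scripts, acceptance checks and test
suite use 100 runs per condition (50 for the scenario contrast), which
is where the Monte-Carlo means stabilize to the precision the
qualitative assertions need.

## Neural encoding strengths and RSA

The trial-pair representational dissimilarity matrix (RDM) is
1 − Pearson correlation between multivariate activity patterns
(integration-unit vectors, or voxel vectors for synthetic "neural"
data); it is invariant to affine transformations of the patterns.
Confound corrections, in the order session-mean projection on the
pattern matrix, then RDM computation, then per-delay detrending
(subtracting the mean dissimilarity at each inter-trial index
difference; delays use the concatenated trial index across sessions).
Corrected entries may be negative.

Encoding strength of gains and losses: OLS of the vectorized strict
lower triangle on |dG| and |dL| jointly plus an intercept; EV strength
from a separate single-regressor fit to avoid collinearity.  Standard
errors are nominal (trial pairs sharing a trial are dependent) and are
used only descriptively.  Binned RDMs average trial-pair dissimilarities
within level pairs (robust to unequal bin counts).  Model-data
comparison: Pearson r between lower triangles, Fisher z = atanh(r), and
a one-sample t-test on subjects' z values for group inference.

## Synthetic study generator

Two designs emulate the re-analyzed two-group gamble studies: "narrow"
(gains and losses $5–$20 in $1 steps) and "wide" (gains $10–$40 in $2
steps — the narrow gain levels doubled — losses unchanged), 16 x 16
= 256 trials, every combination once, shuffled per subject, 4 contiguous
64-trial sessions.  The EV range common to both designs is [−5, 7.5]$.

Ground-truth choosers are the model itself: a network with a fresh
random C, readout trained to EV over its own design grid and scaled by a
temperature of 40 (about 0.5 logit per dollar, which puts simulated
balanced accuracies in the high 80s, the regime of the original
participants), plus the plasticity rule.  Two generator-design points
deserve note:

* Agent readouts are constrained to sum to zero.  Adaptation recenters
  all unit activities toward z = 1/2; with an unconstrained readout that
  drift enters V as a spurious bias that saturates late-session choices.
  A sum-zero readout is drift-invariant and costs nothing in EV fit
  (R^2 = 0.9997).
* Behavioral-pattern cohorts draw alpha ~ U[0.08, 0.16] and
  beta ~ U[0.1, 0.2] (the effective, non-collapsing regime; bias
  ~ N(0, 0.3)).  Parameter-recovery cohorts use the wider spread
  alpha ~ U[0.05, 0.6], beta ~ U[0.05, 0.5] to probe identifiability
  across regimes.

With these defaults the synthetic two-group study reproduces the
qualitative group pattern: the wide-gain group develops loss aversion
over the session (group-mean final-window lambda about 0.7) while the
narrow group stays near neutral, and within the common EV range the
wide group gambles about 25 percentage points *less* — the context
effect, with the same sign as (and larger than) the one reported for
the original cohorts.

Synthetic "voxel" patterns mix integration activity through a random
matrix, add per-session voxel offsets and AR(1) trial noise scaled to a
target SNR.  What the generator does *not* emulate: hemodynamics, motion
artifacts, spatial autocorrelation, inter-subject anatomical
variability, or trait heterogeneity in loss aversion.  Passing tests
therefore show the pipeline recovers its own generative structure under
realistic noise, session and autocorrelation confounds — not that the
original neuroimaging conclusions are reproduced.

A four-level response vocabulary (strongly/weakly accept/reject, plus
no-response) is written and read in a BIDS-like events-TSV format,
including the deposited dataset's column dialect (per-run files with a
`participant_response` column); analyses binarize to accept vs reject
and drop missing responses.

## Fitting the network to choices

MAP estimation of p(accept)_t = sigmoid(b + V_t), V_t from the
sequential forward/plasticity pass.  Free parameters: bias b (prior
N(0, 2^2)); the readout w, parameterized in an orthonormal basis of the
sum-zero subspace (prior N(0, 2^2) per coordinate) — a uniform readout
component is redundant with b on stationary activity and converts
adaptation's recentering into a spurious drift otherwise; one
multiplicative input gain per attribute (log-normal prior, sd 0.5); and,
for the plastic variant only, logit-alpha and logit-beta (priors
N(logit 0.1, 2^2)).  The initial connectivity C_0 is a fixed draw from a
subject-specific seed, never fitted, and never the generating agent's —
too many degrees of freedom otherwise.  The static variant pins
alpha = beta = 0 and is exactly nested in the plastic one.

Optimization: deterministic seeded multi-start (default 8; the cohort
analyses use 4) L-BFGS with numerical gradients, warm-started at a
static EV-landscape solution (readout trained to EV, temperature from a
quick logistic fit of choices on EV).  Only MAP points and the negative
log joint are reported; no posterior approximation is attempted.

Postdiction = model predictions on the fitted data (balanced accuracy;
variance explained defined as 100 · corr(p, choice)^2).  Counterfactual
prediction resets the plasticity state and runs the fitted model on the
other group's trial sequence without refitting; out-of-sample error is
the mean |p − choice|.

Identifiability, measured on synthetic cohorts: fitted alpha correlates
with truth at about 0.6 on average over 20-subject cohorts spanning
alpha in [0.05, 0.6], with substantial cohort-to-cohort spread
(0.4–0.8; increasing the multi-start count does not change this, so the
limit is identifiability, not optimization).  Beta recovers poorly —
only the magnitude parameter is usefully identified, consistent with
which parameter carries the behavioral correlate.  Within a single subject the likelihood is nearly flat in
alpha when C_0 is arbitrary (profile spread under 1.5 nats across
alpha in [0.05, 0.5]), so fitted models under-express adaptation.  The
consequences are visible in the counterfactual analyses: the paired
out-of-sample-error ordering (plastic < static) and the within-model
effect (narrow-fitted plastic models predict lower common-range
acceptance in the wide context than their own postdiction) are robust,
while the cross-model group difference for the plastic variant lands
near zero instead of clearly negative (the static variant's is strongly
positive, about +45 points, as expected from extrapolation without
adaptation).  With C_0 matched to the generating agent the transplants
track the true agents, which give about −14 points; the gap is a
property of fitting with an arbitrary C_0, not of the rule.

## Noise robustness

Choice consistency under integration-layer output noise: the probability
that sign(b + w·(z + eta)) matches the noiseless choice, per noise sd.
Two conditions of the comparison matter.  The decoder (readout) is
refit to each code — the claim concerns the information the adapted
code retains, and a readout frozen at its pre-adaptation value
mechanically shrinks value margins.  And the benefit requires the
premise of the whole account, initial inputs sampling the saturating
range: with strongly saturated initial networks (c = 6, about half the
initial inputs outside the responsive band) the adapted code is clearly
more noise-robust (consistency 0.88 vs 0.82 at sd 0.1, growing with c);
at the default c = 3 (73% already responsive) adaptation's variance
compression outweighs the desaturation gain and the comparison inverts.
Both regimes are reported by the acceptance script.

## The alternative: efficient coding at the attribute layer

The same infomax principle applied to the attribute units themselves
(our derivation; gradient-ascent steps on thresholds and log-slopes,
with connectivity untouched) yields units that converge toward the
input distribution — the competing account in which adaptation happens
before integration.  As expected, it produces no apparent value range
adaptation in the integration layer (EV-binned curve endpoints vary
across conditions where efficient value synthesis holds them fixed).
One printed signature of the alternative does not reproduce under our
derivation: gain-encoding strength *decreases* with gain range in both
scenarios here, because correlation-based dissimilarity is
self-normalizing — once a layer rank-recodes the spanned range,
per-dollar encoding scales as 1/range regardless of where the
adaptation sits.  An increase with range would require gain-driven
pattern variance growing super-linearly with range at the integration
layer, which no attribute-layer infomax rule we can derive produces.

## Numerical choices and degenerate inputs

Logistic choice fits use IRLS; on separation or single-class data a
Gaussian ridge (sd 10 per coefficient) is applied and flagged.
Sliding-window loss-aversion estimates (non-overlapping 16-trial
windows) are heavy-tailed log-ratios; group summaries clip them to
[−2.5, 2.5].  A programmed per-subject drift of 0.16 in lambda is below
this estimator's noise floor (se of the end-minus-start contrast about
0.3), so per-subject detection saturates near 60%; drifts of the size
the adaptive cohorts produce (about 0.8) are detected decisively at the
group level.  Log-determinants of near-singular covariance products get
a ridge of 1e−8 · trace/dim and a flag.  RDM entries for constant
patterns are NaN and dropped pairwise.  EV-decile bins with heavy ties
are merged and flagged.  All generators and fits are pure functions of
their seeds.
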