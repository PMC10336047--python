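# Methods

`dyadsync` models spontaneous convergence between two people who repeatedly
estimate the same quantity and see each other's answers, and analyzes the
oscillatory synchrony of their EEG around those feedback moments.  This
note documents the models, the synthetic ground-truth generators, the
numerical choices, and what the validation experiments do and do not show.

## The task and its behavioral derivatives

A dyad sees a number line (endpoints within 0–150, 40–50 units apart) with
a dot, and each partner types an integer estimate of the dot's position.
Estimates are revealed simultaneously three times per trial (FB1, FB2,
FB3), giving two revision opportunities per trial; a session is 4 blocks
of 25 trials.  From each opportunity we derive the signed change of each
partner's estimate and the dyad's convergence (absolute gap) before and
after.  Trials are classed high_high / low_low / mixed by comparing both
opportunities' adjustment magnitudes |Δself| against the participant's own
median across all 200 opportunities (ties go low; mixed trials are
excluded from the adjustment contrast).

## Reinforcement-learning layer

Each revision opportunity is a binary choice, converge vs not-converge,
labeled by the convergence criterion: an action is convergent if the
participant kept an estimate already equal to the peer's or moved so the
gap shrank.  Option values follow the Rescorla–Wagner rule
`Q[k] += alpha * (r - Q[k])` with `q0 = (0, 0)`, and choices follow a
softmax `p[k] ∝ exp(tau * Q[k])` with learning rate `alpha ∈ [0, 1]` and
temperature `tau ∈ (0, 2]` (bounded above to keep the alpha–tau
relationship monotone; `tau -> 0` is random choice).  Three reward models
share this machinery and differ only in `r`:

* **M1** — pursuit of convergence: ±1 by the convergence criterion above.
* **M2** — relative adjustment: sign of |Δself| − |Δpeer|; 0 when both
  kept still and, by our convention, for equal nonzero moves.
* **M3** — convergence outcome: +1 if the gap shrank or is held at zero,
  −1 if it grew, 0 if unchanged and nonzero.

Fitting is per participant by maximum likelihood over the 200 choice
events (event probabilities floored at 1e−12), with a coarse
alpha × tau grid seeding an L-BFGS-B polish plus random restarts; models
are compared by `BIC = −2 logLL + 2 log(T)` with `T` = number of modeled
choice events by default (a `t_mode` switch uses trials instead), and by
Tukey-adjusted pairwise contrasts of per-participant log-likelihoods
(repeated-measures error term, studentized-range reference).

Prediction errors `PE_t = r_t − Q_t[k]` are recorded before each update
and aligned to FB2/FB3 for the neural interaction analyses.

### What parameter recovery can and cannot show

Under M1 the observable reward is locked to the choice label, so once Q
saturates (about 15 events at alpha = 0.3, tau = 1.5) the choice
probabilities stop carrying information about alpha.  An exhaustive
grid-search MLE on exactly the study's recovery design (alpha = 0.3,
tau = 1.5, 200 events, 50 sessions) has a median |alpha error| of about
0.145 — recovery is validated against that information floor, on streams
simulated from the model itself.  Recovery through the full dyadic
generator is additionally limited by the observational filter (see below)
and is validated as an ordering property: cohorts generated at clearly
different learning rates yield ordered, near-truth median estimates.

## Synthetic behavior generator

Two softmax/Rescorla–Wagner agents play the task against each other.  Per
trial both read the dot with Gaussian perceptual noise (sd 10 number-line
units, about a fifth of the line span — enough initial disagreement that
convergence remains in progress at both opportunities); a converging agent
moves a per-participant fraction of the current gap toward the peer
(drawn once per participant from U(0.2, 0.45); at least one unit, never
overshooting), a non-converging agent keeps its estimate.  Agents learn on
their intended option with the reward the task actually delivered.

Two deliberate features:

* **Inter-individual step variation** makes the relative-adjustment
  reward (M2) informative — with identical policies both partners move
  identical amounts and M2 degenerates to ties.
* **The observational filter is real**: when the dyad has already
  converged, keeping one's estimate is coded convergent whatever the
  latent intent was, and simultaneous integer moves can cancel.  About
  10% of intents are therefore unrecoverable from the logs, which is why
  round-trip recovery is noisier than correctly-specified recovery.

The generator's manifest records true parameters, per-event choices,
rewards and prediction errors for every participant.

## Synthetic EEG generator

Epochs span −2..2 s around every feedback event at 1024 Hz (25 scalp
channels in a standard 10-20/10-10 montage plus two mastoids).  Each
channel sums narrowband Gaussian oscillators (theta 4–8, alpha 8–13,
beta 13–25 Hz; amplitudes 1.0 / 1.5 / 0.8) and 1/f background noise.
Narrowband noise has a drifting phase, so two independent channels
decorrelate within a trial and single-trial phase clustering sits at a
noise-determined baseline.

Coupling is planted per (pair, band, window, feedback repetition): within
the window the destination's band component is replaced (50 ms
raised-cosine crossfade) by the source's analytic signal with i.i.d.
von Mises(0, kappa) phase offsets, so the planted raw-phase difference is
exactly von Mises and its expected phase clustering is the mean resultant
length I1(k)/I0(k) — recorded in the manifest next to the realized
resultant as an analytic oracle.  Plans may scale kappa per epoch with the
participant's ground-truth prediction error (linear in the min-max
normalized PE) to plant PE-dependent synchrony.  Inter-brain plans use the
same mechanism across the two partners' recordings.

By default the oscillators and couplings are defined at the
current-source-density level and the emitted scalp potentials are their
regularized inverse-spline image (`csd_space=True`).  The pipeline's
surface Laplacian then recovers the planted structure instead of a
spatially smeared version of it: planting directly in channel space puts
coupling into every neighbor of a planted electrode once the Laplacian
mixes channels, which is realistic volume-conduction behavior but makes
"which pairs are coupled" ill-defined as ground truth.  The spatially
uniform mode is invisible to the Laplacian and is dropped by the
pseudo-inverse; it is common to all conditions and cancels in contrasts.

What the generator does **not** emulate: ocular/muscle artifacts (the ICA
cleaning stage of real data has no synthetic counterpart), realistic
forward-model topographies, inter-subject anatomical variation, and
non-stationary band power.  Passing tests therefore validate the
pipeline's statistical behavior under known ground truth, not its
robustness to real-world artifacts.

## Preprocessing

Fixed order: zero-phase Butterworth band-pass 1–42 Hz (order 4) →
spherical-spline surface Laplacian (Perrin-style; m = 4, lambda = 1e−5,
50 Legendre terms, electrode cloud projected onto its least-squares
sphere; mastoids dropped) → per-channel ERP subtraction within feedback
repetition → complex Morlet phase extraction on a 1 Hz grid (theta
4–7, alpha 8–12, beta 13–25; band edges assigned to the band whose
nominal range starts there) with cycles rising linearly 4→8 over
4→25 Hz.  The Laplacian and ERP subtraction are both linear, so their
relative order does not change the result (asserted in a test).  Samples
within half a wavelet of an epoch edge are flagged and refused by the
windowing stage; with −2..2 s epochs the analysis windows are far from
the edges.  The Laplacian implementation is cross-checked against an
established EEG package's current-source-density transform (identical to
1e−13 given identical geometry).

## Connectivity

Single-trial inter-site phase clustering
`ISPC = |mean_t exp(i (phi_i - phi_j)))|` over the window's samples
(0–500 ms and 500–1000 ms after feedback onset, half-open at 1024 Hz),
then an equal-weight mean over the band's frequencies.  Clustering is
over time within the single trial, which is what a trial-level GLM needs.
Intra-brain mode enumerates the 300 unordered scalp pairs of one head;
inter-brain mode the 625 ordered cross-head pairs of a dyad, aligned by
(trial, repetition) and refusing misaligned inputs.

## Two-level statistics

**First level.**  Per connection and per unit (participant for intra,
dyad for inter), single-trial ISPC is compressed off the boundaries
(`y' = (y(n−1)+0.5)/n`) and fit by maximum-likelihood beta regression
(logit mean link, log precision link, constant precision).  Designs:
feedback repetition (3-level categorical, FB1 reference); FB × adjustment
(high_high / low_low only); FB × PE over FB2/FB3 with PE standardized
within unit.  Contrasts are linear combinations on the link scale with
delta-method SEs; positive FB2−FB1 means synchrony increased at FB2.
Units are combined per connection by fixed-effect inverse-variance
weighting, or passed through per unit (`pooling="none"`).

**Second level.**  A hierarchical Gaussian meta-analysis across
connections: `y ~ N(beta0 + u_c, sqrt(sigma^2 + se^2))`,
`u_c ~ N(0, sigma_u)`, priors `beta0 ~ N(0, 10)`,
`sigma ~ half-Student-t(3, 0, 2.5)`, `sigma_u ~ Gamma(1, 10)` (shape–rate),
first-level SEs as known measurement error (switchable).  The u_c are
marginalized analytically, an affine-invariant ensemble sampler with
differential-evolution moves runs over the 2–3 hyperparameters
(32 walkers × 6000 steps, 2000 burn-in, split-R-hat < 1.01 enforced, all
seeds fixed), and per-connection effects beta0 + u_c are drawn from their
exact Gaussian conditionals.  A connection is credible when the ROPE
±0.01·SD(y) (SD of the dependent variable entering the model, on the link
scale) lies wholly outside the 95% highest-density interval (shortest
sorted window) of its effect posterior; the sign is the posterior mean's
sign.  Node degree (credible connections per electrode) summarizes maps.

**Identifiability of the variance split.**  With one pooled estimate per
connection the likelihood constrains only `sigma^2 + sigma_u^2`; the
sampler then works in polar coordinates (total scale sampled, split angle
drawn from its conditional prior — the exact posterior), but
per-connection effects mix over shrinkage levels and credibility
decisions become prior-sensitive.  The pipeline therefore feeds
unit-level estimates to the meta-analysis by default, which identifies
the residual scale from within-connection scatter.  This partial pooling
is the procedure's multiple-comparison mitigation; no frequentist
correction is applied.

## Validation experiments and problem sizes

The canned experiments (`dyadsync.experiments`) run the study's
conditions end to end: parameter recovery (50 sessions, 100 trials),
BIC model identification (50 sessions per generating model), planted
coupling detection (5 alpha-band FB2-window pairs at kappa = 10 among 300
intra pairs, 2 dyads × 100 trials) and global-null specificity (same
sizes, no coupling).  The EEG experiments run at 256 Hz with the
alpha-band grid only — the band sits far below either Nyquist rate, and
this keeps a full two-level analysis around a minute on one CPU; the
generator's recording default remains 1024 Hz.

Known behavior worth stating plainly: with five planted effects that are
huge on the logit scale, the Gaussian varying-effect scale inflates to
accommodate them, which weakens the shrinkage protecting null
connections; the false-alarm rate of the credibility rule then sits near
the nominal 5% rather than far below it (under the global null it is
essentially zero).  A heavier-tailed varying-effect distribution would
restore shrinkage under such spike-like alternatives, but the Gaussian
hierarchy is the model this package implements.

## Known limitations

* The RL likelihood treats forced events (already-converged trials) as
  free choices; their labels are structurally convergent, which caps
  alpha recovery through the dyadic generator.
* Beta-regression SEs come from the observed information under a working
  beta likelihood; heavy-tailed deviations of ISPC from the beta family
  propagate into mildly anti-conservative credibility decisions.
* The EDF ingest path is a thin convenience wrapper and is not exercised
  by the test suite (no EDF writer in the dependency set).
* Epoched synthetic data is generated already cut; filter edge effects at
  epoch boundaries are mitigated by the −2..2 s margins, not by
  continuous-recording filtering.
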