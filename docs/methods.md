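# Methods

## Task model

Two reward boxes run independent variable-interval (VI) schedules. Time is
discretized into bins of width dt = 10 ms; in each bin an unarmed box arms
with probability dt/VI, and an armed box stays armed (latches) until the
next press on it. The probability that a reward is waiting t seconds after
the preceding press on a box is therefore

    P_rew(t) = 1 − (1 − dt/VI)^(t/dt),

which converges first-order in dt to the constant-hazard form
1 − exp(−t/VI). Sessions consist of blocks, each defined by a (VI₁, VI₂)
pair and a reward budget (34 or 66 by default); the schedule changes
silently immediately after the block's budget is delivered. Between presses
the availability state is advanced lazily by sampling the geometric
first-arming bin rather than stepping every 10 ms bin; by memorylessness of
the Bernoulli process this is distributionally identical to per-bin
stepping, and the test suite compares the two directly. On a block change,
pending arming times of still-unarmed boxes are resampled under the new
schedule (again exact by memorylessness).

## Strategy agents

**Threshold agent (win-stay / lose-switch).** Waits are log-normal
(median 6 s, σ = 0.55 — the rule constrains only switching, so the wait
distribution is a free choice set to a plausible inter-press range).
After every reward the loss counter resets; after each unrewarded press it
increments, and the agent switches once the counter reaches a per-visit
threshold drawn from N(loss_mean = 2.5, loss_sd = 1.5). The agent never
consults the schedules or elapsed time. Travel between the boxes (120 cm)
takes 3 s and affects only event times.

**MVT agent (complete information).** The agent knows the current VI pair
and its own press history, hence the exact P_rew of both boxes.

* *When to press:* at the closed-form crossing time of the true
  current-box P_rew through a per-press threshold
  θ = 0.5 + 0.18·(local reward ratio − ½) + N(0, 0.22), clipped to
  [0.05, 0.95]. The jitter produces the wide wait range seen in freely
  timed pressing; the small reward-ratio coupling makes the agent slightly
  more patient at a box with a good recent record.
* *Where to press:* at that decision time the agent switches iff
  P_rew(other) − θ̄ exceeds the switching cost. The base cost (0.5
  probability units) is scaled by (VI_other/VI_current)^0.5 — leaving
  toward a slower box demands a larger margin, the rate-sensitive reading
  of a fixed travel cost — and carries 10 % log-normal private noise.
* *Belief noise:* an AR(1) latent ε(t) (τ = 10 s) models the agent's
  subjective availability estimate. It scales the switch margin by e^ε and
  shifts the press threshold by e^(−0.8·ε), so an "optimistic" agent both
  switches earlier and presses at a lower true availability. The same
  latent drives the synthetic spiking population (below), making it a
  choice-relevant signal that exists in neural activity but not in the
  true task variables.

These defaults place the two agents in the qualitative regimes the analyses
probe: the threshold agent undermatches (generalized matching slope ≈
0.6–0.8 over the unbalanced pairs), the MVT agent overmatches (≈ 1.05–1.15)
with a monkey-like ~7 % switch rate, and on pooled MVT sessions the binned
reward-predictor correlations rank availability probability ≈ waiting time
≫ |reward ratio| ≈ 0. The design constraint worth recording: with a plain
fixed switching cost these two regimes exclude each other, because
overmatching requires the lean box to be over-rewarded per press exactly
where the reward ratio is low, which by itself drives the binned
reward-ratio correlation negative. The VI-scaled cost (which shortens lean
visits without inflating their number) plus the reward-ratio-coupled
patience (which raises reward probability where the ratio is high) is the
package's resolution of that tension.

## Behavioral analyses

The per-press table holds the waiting time (time since the preceding press
on either box; presses with waits > 60 s are excluded, as is the first
press), its natural log, the causally filtered reward ratio, the oracle
availability probability (from the schedule and the same-box gap), the
scheduled rate, the stay/switch label of the *next* press, and the next
waiting time. The reward-ratio filter is a causal half-Gaussian over the
press-indexed binary reward sequence pooled over both boxes (numerator:
rewards of the pressed box; width = s.d. in presses; an empty filtered
history maps to the uninformative value ½). Reward-predictability is
measured by sorting presses along a predictor, binning 50 presses per bin,
and correlating the per-bin mean with the per-bin rewarded fraction; the
binned Pearson r over B bins has null sampling s.d. ≈ B^(−1/2), so this
analysis is run on ~10⁴ pooled presses (16 sessions) where ~200 bins make
the statistic meaningful. Conditional next-wait and switch-probability
analyses group presses by tercile (or the explicit 3–5/5–8/8–60 s preset)
of the wait or reward ratio crossed with the reward outcome; the rewarded
vs unrewarded next-wait discrimination is scored by rank AUC.

## Synthetic neural data

Locomotion is generated at 6 frames/s: the animal dwells at the previously
pressed box with smooth 2 cm jitter and transits the 120 cm with a
smoothstep profile over the 3 s before each switch press; speed is the
frame-to-frame displacement rate. Spiking populations are inhomogeneous
Poisson on a 10 ms grid with rate softplus(b_k + Σ_c w_kc z_c(t) + η_k(t)):
z are z-scored latent channels (waiting-time ramp, current-option reward
ratio, 200–300 ms post-press/reward/choice kernels, locomotion speed, and
the belief latent ε), w_kc are Gaussian with per-channel scales (mixed
selectivity), η_k is private AR(1) drive noise (s.d. 0.3, τ = 5 s), and
baselines are uniform in 2–8 spikes/s. The belief channel rides on each
unit's waiting-time weight (units encode the *subjective* wait), which is
what lets neural readouts of the wait carry choice-relevant variability.
The softplus link (rather than exponential) keeps rates bounded under the
power-5 feature regime.

Two named conditions are used. The *default bundle* (60 units, mixed
20/40–15/25 schedules, 136 rewards) is the parameter-recovery condition.
The *belief-noise bundle* (`belief_noise_bundle_config`) uses long balanced
sessions (VI 20/20 and 30/30 blocks, 200 rewards), halves the wait-ramp
encoding scale (0.45) while raising the belief coupling (1.8) so the
subjective estimate dominates the wait-related population variance, and
uses a high switching cost (0.75) so that arrival presses — which are
almost always rewarded under latching VI — stay rare. Under these
conditions the intended orderings are planted by construction: the true
task variables are a sufficient statistic for reward, while only the
neural side carries the belief latent that drives switching. The
belief-timing gain 0.8 is the value at which the latent's net correlation
with the reward outcome vanishes (its positive switch-frequency channel
cancels against its negative press-timing channel), so the latent informs
*choice* but not *reward*.

## Neural pipeline

Rates are spike counts on a 200 ms grid divided by the bin width and
boxcar-smoothed over 1 s; analysis is restricted to engaged bins (within
5 s of a press). Press-locked tensors use 200 ms bins on [−2, 1] s or
[−3, 1] s, excluding presses less than 2 s after their predecessor; the
scalar pre-press spike count uses [−1.1, −0.1] s. Locomotion is removed per
unit by projecting the engaged-bin rates off span{1, L} where L is the
interpolated speed; including the constant is the package's choice, since
projecting off the raw speed vector alone zeroes the inner product but not
the mean-removed Pearson correlation, and the contract here is exact
decorrelation. The literal rank-1 projector L(LᵀL)⁻¹Lᵀ remains available
(`with_intercept=False`). Bins are half-open [start, start+width), and
press-locked offset 0 is the recorded press time.

The design matrix has exactly 51 columns: 7 pre-press tiles on [−1.4, 0),
7 post-press and 7 post-choice tiles on [0, 1.4), 10 post-reward tiles on
[0, 2.0) (all contiguous 200 ms boxcars; column j is the indicator that
the nearest relevant event sits in tile j, so the tiles partition their
window), and five monomial powers {0.5, 1, 2, 3, 5} of each continuous
trace — waiting time (linear ramp resetting at presses), the current
option's reward ratio (piecewise constant, jumping at presses), and the
two location coordinates — each rescaled to [0, 1] per session before the
powers to keep the power-5 column bounded. Columns are z-scored over
engaged bins before CCA (cross-covariance methods are scale-sensitive).

Sparse CCA standardizes both sides, whitens them with symmetric inverse
square roots (relative eigenvalue floor 1e-12; an optional ridge `reg` for
ill-conditioned inputs), and extracts K = 10 penalized rank-1 pairs from
the whitened cross-covariance by alternating updates with an ℓ1 budget on
the task-side weights (soft-threshold found by bisection), deflating the
rank-1 contribution after each component. Fullness f ∈ (0, 1] maps to the
budget c = 1 + f(√p − 1), the natural range for a unit-ℓ2 vector; f = 1
reduces exactly to classical CCA (verified against the generalized
eigenproblem to 1e-8). Components are ordered by descending training
correlation. Variable assignment uses the whitened (ℓ1-budgeted) weights —
original-coordinate weights are inflated along near-collinear column
groups (the location powers of an essentially two-valued coordinate) by
the whitening inverse — normalizing each variable's absolute weight share
against all six variables; ties break to the lower component index.

Decoding uses leave-one-block-out cross-validation with blocks delimited
by >30 s press gaps; within each fold the (unsparsified) CCA is refit on
the training bins only, so the held-out block never touches any fit,
including the component construction. Binary targets use logistic
regression (weak ridge stabilization) scored by held-out AUC per 200 ms
bin over [−3, 1] s; the next waiting time uses a log-link Gamma GLM (the
target is strictly positive; ridge-on-log fallback for degenerate fits)
scored by held-out Pearson r. The "task components" family lives in the
10-D space of waiting time and the current box's scheduled reward rate,
each through the five powers; peak performance is the mean of the five
best bins in the 2 s before the press, and family comparisons are reported
as averages over several sessions.

## Limitations

The generator plants linear-Gaussian mixed selectivity with softplus-
Poisson noise; passing tests show the pipeline recovers structure of that
form, not that real dlPFC populations satisfy it. Real data add
non-Poisson variability, slow drift, correlated noise, and movement
confounds beyond planar locomotion speed, none of which are modeled. The
agents are normative caricatures: neither reproduces the monkeys'
undermatching together with their strong reward-predictor correlations,
which is why the behavioral analyses are validated in the regime the
informed agent can realize. The binned-correlation analysis is sensitive
to a handful of extreme bins; it is only reported on pooled data. Problem
sizes (sessions of 130–200 rewards, 60 units, 4-session averages, 16-session
pools) were chosen so the full validation runs comfortably on one CPU.
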