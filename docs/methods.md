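# Methods

`tracklag` simulates pseudo-random manual tracking with manipulated visual
feedback and analyzes how a cerebellar Purkinje cell's simple-spike (SS)
firing encodes position error and limb kinematics at lead (predictive) and
lag (feedback) timings.  This note documents the models, the numerical
choices, and what the synthetic data can and cannot establish.

## The task model

**Target trajectories.**  Each target path is a sum of four sinusoids per
axis with frequencies drawn uniformly in [0.05, 0.4] Hz and random phases,
centered on the screen and rescaled to the workspace.  The geometric path
is then re-parameterized in time by the two-thirds power law,
v(t) = K·κ(t)^(−1/3), with the curvature κ floored at 0.05 cm⁻¹ so that
inflection points do not produce unbounded speeds.  K is fixed analytically
by the trial duration, which is drawn uniformly in [3, 10] s (rounded to the
20-ms bin grid); the spatial scale is set so the mean tangential speed is
4 cm/s.  Paths are rejected and regenerated when peak curvature exceeds
2 cm⁻¹ (sharp turns), instantaneous speed leaves [1, 8] cm/s, or the path
leaves a 5.5-cm workspace radius.  A study uses a fixed a-priori library of
100 such trajectories; every trial draws one at random and wraps it in
initial and final hold periods of 0.5–3 s with the target stationary.

**The tracker.**  The simulated animal is a second-order follower with two
pathways:

* a *predictive pursuit* pathway that feeds forward the target's velocity
  and acceleration with no perceptual lag (smooth pursuit of a continuously
  visible target is anticipatory), and, when a hand→cursor delay d is in
  force, aims at the target advanced by d — the trained compensation
  without which the cursor cannot be kept inside the target at all;
* a *corrective* pathway, −kp·E_seen(t − Δ) with kp = 16 s⁻², acting on the
  cursor−target error as actually *seen*: perceived with a sensorimotor
  latency Δ = 150 ms, and, when the cursor is hidden inside the target,
  replaced by a half-weight proprioceptive estimate of the hand−target
  error (prop_gain = 0.5).

Velocity tracking uses gain kv = 8 s⁻¹, making the (kp, kv) pair critically
damped at 4 rad/s.  Because correction runs on the *seen* cursor, both
manipulations mechanically degrade tracking: measured mean |PE| rises from
≈0.47 cm (baseline) to ≈0.51 (hidden), ≈0.55 (delay 100) and ≈0.65 cm
(delay 200) at default noise.  In the noiseless, zero-latency limit the
follower reproduces the target sample-exactly, which pins the integration
scheme.

**Noise.**  Two smooth Gaussian components: a random force (RMS 6 cm/s²,
low-passed at 2 Hz) driving the controller dynamics, and an additive
band-limited positional tremor on the hand path (RMS 0.3 cm, low-passed at
3.5 Hz).  The tremor matters: with loop noise alone the tracking error has
essentially no power above ~1 Hz, its autocorrelation is so broad that an
R²(τ) profile is flat over ±100 ms, and 20-ms peak timing is meaningless.
Real hand movement contains this broadband component.

**Trial admission.**  A trial is emitted only if the cursor never stays
outside the target (radius 1.25 cm by default) for 700 ms or longer;
violating trials are re-simulated with fresh noise (an error names the
noise settings after 20 failures), mirroring the task's abort rule.

## The cell model

The instantaneous SS rate on the 1-kHz spike clock is

    r(t) = r0 + g_lead · PE_pred(t + L_lead)
              + g_lag  · [visible(t − L_lag)] · PE_cursor(t − L_lag)
              + g_pos  · hand(t + L_kin) + g_vel · handvel(t + L_kin),

rectified at zero, with every g a 2-vector acting on the (x, y) pair.
Spikes are drawn by Poisson thinning, which on the 1-kHz clock reduces to a
Bernoulli draw per 1-ms bin with probability r/1000.

* **Lead drive.**  `PE_pred(t) = hand(t) − target(t + d)` is the
  motor-locked prediction of the *displayed* error: the hand position at t
  surfaces as a cursor sample d ms later and is then compared with the
  target at that display time.  In baseline (d = 0) this is simply
  hand − target.  The distinction matters only under a delay, where keeping
  the cursor in the target forces the hand to lead the target by d·v; the
  naive same-time difference hand(t) − target(t) would then be dominated by
  a d·v_target artifact of the display geometry rather than by anything a
  forward model would predict.  Time-locking to the hand is exactly what
  produces the −d shift of the lead peak under the cursor-referenced
  analysis.
* **Lag drive.**  The visible cursor-referenced error, gated sample-wise by
  cursor visibility.  The gate applies to the lag coupling *only*; the lead
  pathway models a motor-command-based prediction and is never gated.  This
  asymmetry is the hypothesis the hidden-cursor study is built to detect.
* **Kinematic drives.**  Hand position and velocity read at a common
  predictive kinematic latency and, with half weight each, at a common
  feedback (lag) latency — real cells show both leading and lagging
  kinematic modulation.  These couplings are hand-referenced and
  visibility-independent, so kinematic encoding should be untouched by
  both manipulations.  Note an intrinsic identifiability limit: hand
  *position* during pseudo-random tracking varies so slowly that its
  autocorrelation is ≈1 across the ±500-ms window; the position R²(τ)
  profile is therefore nearly flat and the τ of a detected position peak
  is noise, even when the encoding itself is strong and stable.  Timing
  comparisons are meaningful for velocity (and position-error) peaks,
  not for position peaks; position encoding contributes to strength
  (R²) comparisons only.  Matching the recordings, where position
  encoding is distinctly rarer than velocity encoding, default position
  couplings are several-fold weaker than velocity couplings.

**Default population** (`sample_cell_truth`): baseline rate U(50, 80)
spikes/s; lead latency on the 20-ms grid in [60, 200] ms, lag latency in
[280, 440] ms, kinematic lead in [60, 160] ms and kinematic lag in
[220, 400] ms (grid draws keep true peaks representable on the analysis
lag grid); PE coupling norms U(15, 30) spikes/s/cm with random
directions; velocity couplings U(1.5, 3) spikes/s per cm/s and position
couplings U(0.4, 1.2) spikes/s/cm.  These yield peak R² values of
roughly 0.02–0.3, at the lower end of what strong recorded cells show.

**Recovery floor** (`sample_strong_pe_truth`): PE norms U(20, 35) with
position ≤ 1.5 and velocity ≤ 0.7.  Strong velocity couplings leak into
the position-error regressions (the tremor's derivative in hand velocity
correlates asymmetrically with nearby position error, and same-time
residualization removes it only at one τ), which can displace the
*absolute* lead-peak location by one to three bins in a multiplexed cell.
The between-condition timing shift Δτ — the quantity of scientific
interest — subtracts this cell-specific displacement and is unbiased in
either regime.  Absolute ground-truth timing recovery to within one bin in
≥90% of cells is guaranteed only above this floor; this is also the regime
in which the hidden-cursor significance-loss construction is clean, since
the same kinematic leak can otherwise sustain spurious positive-τ
significance after the true lag coupling is silenced.  (That surviving
"lag significance" in multiplexed cells is a property of the univariate
significance criterion itself, and is one plausible reason real recordings
show lag-encoding loss in most but not all cells.)

## The analysis chain

1. **Fractional-interval rate.**  Between consecutive spikes the
   instantaneous rate is 1/ISI; outside the first/last spike it is zero
   (no extrapolation).  Each 20-ms bin takes the time-weighted average,
   implemented through the cumulative fractional spike count (piecewise
   linear interpolation of the spike index), which makes the conservation
   property — integral of the rate equals the ISI count — exact to
   rounding.
2. **Filtering.**  Second-order Butterworth, 3-Hz cutoff at the 50-Hz bin
   rate, applied forward–backward (zero phase).  A causal pass would add
   group delay and bias every timing estimate; zero-phase filtering is the
   only choice compatible with interpreting τ at 20-ms resolution.  The
   effective amplitude response is the square of the single-pass design.
3. **Mean subtraction** per trial.
4. **Kinematics.**  Hand velocity by central differences at 200 Hz, then
   decimation by 4 taking the sample at each bin center (10 ms into the
   bin), so that τ shifts are exact index shifts.  Position error is
   cursor − target, never hand − target.  "Inside the target" is strict
   `XE² + YE² < r²`, matching the simulator bit-exactly.
5. **Two-step regression** at each τ ∈ {−500, …, +500} ms (negative =
   firing leads): OLS of F(t+τ) on intercept + the four parameters *not*
   of interest at time t, then OLS of the residuals FR on the parameter
   pair of interest, giving R²(τ), (β₁, β₂)(τ) and the sensitivity
   √(β₁²+β₂²).  Trials are pooled by concatenation; τ-shifted samples that
   would cross a trial boundary are dropped, never wrapped.  Internally
   both steps are solved exactly from one 8×8 Gram matrix per (τ,
   pairing), which makes the shuffle null ~50× cheaper than repeated
   design-matrix solves; the test suite checks the engine against explicit
   normal-equation solves at 1e-8 relative tolerance.
6. **Shuffle null.**  100 repeats; each permutes the assignment of whole
   firing-rate trials to behavior trials (derangement not enforced),
   truncating mismatched pairs to the shorter trial, and recomputes the
   full R² profile.  The significance threshold is the per-τ null mean +
   3 SD — upper side only, since R² is non-negative.
7. **Peaks.**  Strict local maxima of R²(τ) (plateaus resolved toward the
   smaller |τ|, endpoints eligible against their single neighbor); the
   largest significant maximum with τ < 0 is the lead peak, with τ > 0 the
   lag peak; τ = 0 belongs to neither.  Across conditions, peaks are
   matched only when present in both with both coefficients of the same
   sign; matched pairs report Δτ and ΔR².
8. **Inside-target restriction** (hidden-cursor study): behavior samples
   with the cursor outside the target are dropped in *both* conditions;
   the τ-shifted firing sample follows its behavior sample.
9. **Significance loss** (hidden-cursor study): a cell loses its lag
   encoding when the baseline lag peak is significant but no significant
   lag peak with same-sign coefficients exists in the hidden block.  The
   same-sign requirement is the peak-identity rule also used when
   matching peaks across the delay conditions: with tens of thousands of
   pooled samples the 3-SD threshold is low enough that leakage from the
   other couplings occasionally raises a small, sign-inconsistent local
   maximum somewhere on the lag side, and counting that as "retained lag
   encoding" would conflate a different signal with the one identified in
   baseline.

## Study sizes and runtime choices

Population studies use 20 cells with paired 50-trial blocks (the block
structure of the recordings), which puts the standard error of the mean
lead shift near 3–4 ms — comfortably inside the one-bin tolerance.  The
position-error *timing* studies (delay shifts, hidden-cursor collapse,
absolute recovery) run on the PE-dominant population: in multiplexed
cells the kinematic leak occasionally makes a contaminant bump the
largest significant lead-side maximum, and such wrong-peak selections
appear as gross Δτ outliers (the same pathology that plausibly underlies
the ±105–123 ms spreads in the recorded population).  The
kinematic-invariance study instead uses the multiplexed default
population — it needs substantial position/velocity couplings — in its
own 5-cell, 40-trial-block sessions.  The false-positive calibration
uses 100 single-cell runs with 5-trial blocks.  At these sizes every
check is stable and the whole suite runs on a single CPU in roughly
twenty minutes.

## Known limitations

* A stable ≈one-bin (20 ms) skew of the detected lead peak (−L−20 instead
  of −L) appears in all conditions; it stems from the interaction of
  same-time nuisance residualization with error–velocity correlations and
  cancels exactly in between-condition comparisons.
* The mean + 3 SD threshold on a right-skewed R² null is not a calibrated
  familywise test across the 51 τ points; pure-noise cells show a
  per-τ exceedance rate near 1–2% but can still produce an occasional
  significant local maximum somewhere on the grid.
* The tracker has no arm biomechanics, no eye movements, no learning; the
  delay compensation is static within a session, consistent with the
  absence of adaptation in the recordings.
* Synthetic cells are linear in behavior with Poisson variability; real SS
  trains have history dependence and gain modulation the model omits.
  Passing recovery tests therefore demonstrates that the *pipeline*
  recovers the imposed structure under realistic noise — not that real
  Purkinje cells obey the rate model.
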