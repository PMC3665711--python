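# Methods

## The model

A receiver waiting for an object handover must decide *when* to start reaching
and *where* to reach. The model treats this as Bayesian inference over the
handover position with an evidence-triggered decision:

1. **Endpoint estimation.** The observed prefix of the deliverer's planar hand
   path is extrapolated by least-squares fitting a member of the minimum-jerk
   family, `p(t) = p0 + a·s(t/T)` with `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`. For each
   candidate duration `T` on a grid (0.4–2.4 s, step 0.05 s) the amplitude `a`
   is closed-form; the duration is chosen by residual minimization and, for the
   single-fit API, refined by parabolic interpolation. The estimate `x̂` is the
   fitted endpoint; `observed_fraction` is elapsed time over fitted duration.
   When the observed movement is *not* minimum-jerk (the trapezoidal
   joint-space profile of an industrial robot, which sweeps a curved
   end-effector arc), the fit is deliberately misspecified — this is the
   mechanism by which robotic movements mislead early endpoint estimates.

2. **Estimate reliability (lookup table).** No analytic covariance exists for
   this estimator, so `Σ_est` is calibrated by Monte Carlo: for each observed
   fraction, 1000 noisy minimum-jerk deliveries with endpoints uniform over the
   workspace are re-fitted from the corresponding prefix and the empirical
   error covariance is tabulated; averaged variance is forced non-increasing in
   the fraction by isotonic regression, and a 1e-12 m² ridge keeps every matrix
   positive-definite.

3. **Causal inference.** With a Gaussian prior `N(μ_prior, Σ_prior)` over the
   *natural* handover position and a uniform prior `u = 1/area` over the
   workspace rectangle for the *unnatural* case, the posterior probability of a
   natural handover is `A/(A+B)` with `A = P(C=N)·N(x̂; μ_prior, Σ_est+Σ_prior)`
   and `B = (1−P(C=N))·u`. Misclassification costs are equal; a tie at 0.5
   resolves to unnatural (no positive evidence that the prior applies — do not
   fuse). The uniform component's normalization treats the workspace rectangle
   as the full support; estimates outside it keep the same density.

4. **Fusion and decision.** Natural case: the handover-position belief is the
   precision-weighted product of estimate and prior; unnatural case: it reduces
   to the estimate alone. The decision value is the averaged variance (mean
   eigenvalue = trace/2) of that belief's covariance, and the receiver reacts
   at the first sample where it falls below the threshold Γ (plus an optional
   motor latency). Within a trial the prior is constant. If the threshold is
   never reached the reaction time is capped at the movement end and flagged.

5. **Adaptation.** After each handover, with error `e = x_real − μ_prior`:
   `μ ← μ + π_μ·e` and `Σ ← (1−π_Σ)·Σ + π_Σ·(eeᵀ + εI)`, `ε = 1e-6 m²`. A
   small error shifts the prior slightly and shrinks it; a large error shifts
   it strongly and inflates it through the outer product. The exact published
   update is not recoverable from the text available to us (the formula and
   its parameter values live in an unavailable supplement); this delta rule is
   a documented reconstruction that satisfies every stated behavioural
   property and is isolated behind `adaptation.update_prior` so alternates can
   be swapped. The same applies to the Gaussian/uniform mixture normalization
   in step 3, which is the standard causal-inference form.

## Design choices that were genuinely open

**Reliability is keyed by elapsed time, not by the fit's own duration
estimate.** The lookup could be indexed by `observed_fraction =
elapsed/estimated duration`. We key it by elapsed fraction of the delivery
instead (the movement durations of each condition are fixed and assumed
familiar to the receiver). Reason: a noise- or misspecification-driven
*duration collapse* (fitted `T ≈ elapsed`) reports fraction ≈ 1 and would pull
a near-zero covariance out of the table, letting the model manufacture
confidence from an uninformative prefix; in simulation this produced instant
false threshold crossings and made trapezoidal deliveries *faster* than
minimum-jerk ones — inverting the phenomenon the model exists to explain.
Time-driven reliability keeps estimation (which can be wrong) separate from
evidence (which grows with observation), and the wrongness of the trapezoid's
early estimates then acts exactly where it should: in the case posterior.

**Coordinate frame and workspace.** Origin at the table-centre handover point
M; +y from deliverer to receiver, +x to the deliverer's right. Cube pickup row
at y = −0.25 m, placement row at +0.25 m (50 cm between rows); alternative
handover positions R/L at x = ±0.20 m. Uniform support: the 0.75 × 0.50 m
table surface between the rows.

**Default parameters** (all in `src/handover/data/defaults.yaml`):

| parameter | default | why |
|---|---|---|
| `P(C=N)` | 0.8 | receiver's trust that a handover will be natural |
| `Σ_prior` | diag(0.0016) m² (SD 4 cm) | realistic spread of freely chosen handover positions; the original was computed from earlier human data not available here |
| Γ | 1.2e-3 m² | grid value whose simulated baseline mean RT is closest to the reported human baseline (0.23 s) while staying below the once-adapted prior variance `(1−π_Σ)·σ²_prior = 1.28e-3`, so adaptation remains expressible (see `analysis/02_calibrate_threshold.py`) |
| `π_μ`, `π_Σ` | 0.5, 0.2 | fast mean update, slower covariance update |
| observation noise | 0.005 m per axis | perceptual noise on the observed delivery |
| simulation rate | 100 Hz | finer than needed for 1–1.2 s movements |
| exp5 threshold scale | 0.5 | "stricter evidence" stand-in for the industrial robot's unfamiliar appearance |

The simulated baseline mean RT saturates near 0.45 s rather than 0.23 s:
endpoint evidence under this estimator only sharpens past ~45% of the
movement, which floors how early the threshold can be crossed. The model's
claim — and what the tests check — is the *ordering* pattern across
conditions and trials, not the absolute human means, which belong to the
original subjects.

**Robot arm stand-in.** The robot trajectories are generated by a planar
two-link arm (base (−0.50, −0.35) m, links 0.45 m, shoulder-like lateral
offset) moving each joint with a symmetric trapezoidal angular-speed profile
(acceleration fraction 0.15), starting from a midair rest pose (−0.05, −0.45).
A base placed directly behind the handover axis is degenerate — start and
target become collinear with it and the end-effector path is straight, which
would remove the curvature that misleads the estimator — so the offset
placement is essential, not cosmetic. Chord deviation of the default arc is
≈ 5 cm.

## Synthetic recordings

`synthetic.generate_recording` emulates what the two trackers (240 Hz
magnetic, 20 Hz acoustic) would record. The deliverer performs three superposed
minimum-jerk segments — reach to the cube, transport to the handover point,
lowering the hand — yielding exactly three speed peaks; the receiver is
stationary, reaches to the handover point, dwells, and places the object on
the far row. Additive isotropic Gaussian noise (default 3e-6 m per axis)
models tracker jitter.

Two deliberate choices make the *operational* event definitions
well-posed on this data:

- The grasp pause between reach and transport is a 0.10 s velocity-overlap
  blend, not a full stop. A flat zero-speed dwell has no unique speed minimum,
  so the deliverer-onset rule ("first speed minimum below 0.3 m/s after the
  grasp") would land wherever the noise happens to dip. The blend produces a
  V-shaped dip whose per-sample speed change exceeds the derivative noise,
  localizing the rule to ±1 sample. A true dwell (0.15 s) is kept at the
  handover itself.
- Annotations store the event times measured by running the detectors on the
  *clean sampled* traces (and the receiver's movement start is scheduled so
  its 0.01 m/s crossing lands at the nominal reaction time). Extracted and
  annotated quantities are therefore directly comparable, without sub-sample
  or threshold-offset bias.

What the generator does *not* emulate: 3-D lift kinematics, grasp shaping,
velocity-dependent tracker noise, soft-tissue artefacts, or any variability in
movement durations and rest postures across trials. Passing round-trip tests
therefore shows the data-reduction rules are self-consistent at realistic
noise levels — not that they are robust to everything real recordings contain.

## Kinematic data reduction

Positions are filtered by a Gaussian kernel whose −3 dB point equals the
stated cutoff (48 Hz for 240 Hz data, 10 Hz for 20 Hz data); solving
`exp(−2π²σ_t²f_c²) = 1/√2` gives `σ_t = √(ln 2)/(2π f_c)`. Speed is the
magnitude of central-difference velocities. Receiver onset: first sample at
≥ 0.01 m/s. Deliverer onset: first local speed minimum (strict 5-sample
window, ties to the earliest sample) after the grasp with speed < 0.3 m/s;
the grasp time itself must be supplied (synthetic recordings annotate it).
Online correction: ≥ 2 local maxima above 20% of the peak — each with at
least 5% prominence, so single-bell measurement ripple does not count — or a
deceleration phase longer than 65% of the reach. Regression slopes are
ordinary least squares of the six reaction times on trial number.

## Numerical notes

- 2×2 operations in the per-trial inner loop (densities, inverses, fusion) use
  closed-form adjugate algebra, vectorized over all prefixes of a delivery;
  a unit test pins this path to the scalar composition of the public
  operations.
- Endpoint fits over all prefixes of one trajectory share cumulative sums, so
  a full 6-trial subject simulates in ~1 ms; the 500-replicate, 7-condition
  suite runs in about a minute on one core.
- Degenerate inputs: a stationary prefix returns the current position with
  fraction 0 (maximal uncertainty); prefixes shorter than 3 samples cannot
  cross the threshold; singular covariances raise rather than propagate.
- Problem sizes used throughout (500 replicates per condition, 1000 Monte-
  Carlo repetitions per fraction, 100-recording cohorts) were chosen for
  stable means and tight bootstrap intervals.

## Known limitations

- Eq-level fidelity to the original implementation is impossible where the
  supplement is unavailable (adaptation rule, mixture normalization, lookup
  construction, parameter values); all four are reconstructed and flagged
  above.
- The endpoint estimator is a simplification of human movement prediction; no
  gaze, posture, or joint-configuration cues are modeled.
- Online correction *during* an initiated movement is out of scope (the
  estimate is updated only until movement initiation).
- Reaction-time magnitudes are compressed toward the evidence floor (see Γ
  above); only orderings and trial trends are claimed.
- The simulation is planar; real handovers are 3-D.
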