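# Methods

`photoseek` analyzes fiber-photometry recordings taken during operant
drug-seeking sessions: it converts a two-channel fluorescence recording
into ΔF/F, groups nose-pokes into response types by replaying the
reinforcement schedule, cuts and normalizes peri-event epochs, and runs
waveform-level bootstrap and permutation statistics. A synthetic-session
generator with known ground truth backs all validation.

## Preprocessing model

The recording has a calcium-dependent channel (470 nm excitation,
GCaMP) and an isosbestic control channel (405 nm excitation) sampled at
1017.25 Hz. The control channel is calcium-independent but shares
photobleaching and motion artifacts, so the pipeline removes
common-mode disturbance by regression:

1. **Block-mean downsampling** by a factor of 64 (→ 15.89 Hz). Each
   output sample is the mean of a 64-sample block; a trailing partial
   block is dropped. Averaging 64 samples is itself a strong low-pass,
   so no separate anti-alias filter is applied (a decimating
   alternative can be substituted by calling `scipy.signal.decimate`
   upstream; the pipeline takes any factor ≥ 1). The isosbestic fit is
   computed *after* downsampling — equivalent in expectation and much
   cheaper.
2. **Isosbestic fit**: ordinary least squares of the 405 channel onto
   the 470 channel (first-order polynomial). A constant control channel
   makes the fit singular and is rejected.
3. **ΔF/F** = (470 − fitted 405) / fitted 405, elementwise. Fitted
   values with magnitude below a configurable floor (default 1e−9 a.u.)
   raise an error naming the first offending sample.
4. **Detrend**: subtraction of a centered moving average with nominal
   width `round(90 s · fs)` samples. Sample *i*'s window spans
   `[i − (W−1)//2, i + W//2]` and shrinks to the available samples at
   the session edges, so no edge data are discarded. Subtraction (not
   division) is used because ΔF/F is already normalized.
5. **Low-pass**: 2nd-order Butterworth at 3 Hz applied
   forward–backward (`sosfiltfilt`), so the filter is zero-phase and
   event latencies are not lagged. The two-pass magnitude response is
   |H|² — gain 1/2 at the cutoff.

Every step's parameters are recorded in the `DffSignal.provenance`
dict and echoed into all pipeline reports.

Two algebraic properties are worth noting. Scaling both raw channels by
a common positive gain leaves ΔF/F unchanged to ~1e−10 (the fit
coefficients absorb the gain). A constant offset added to the 470
channel is absorbed by the fit intercept, which leaves the regression
residual unchanged but rescales the ΔF/F *denominator* by
≈ F/(F + k); the outputs therefore agree only up to that multiplicative
factor, which is exact (below 1e−6) only when transient and noise
amplitudes are near zero.

## Behavioral model

Sessions are streams of timestamped nose-pokes at an active and an
inactive port. Classification replays the fixed-ratio schedule: active
pokes outside time-out increment a counter; the `fr`-th poke is
reinforced, resets the counter, and opens a time-out (default 20 s)
during which pokes are recorded but have no consequence and do not
advance the counter. The time-out window is open at both ends — a poke
exactly at expiry counts toward the next ratio (a measure-zero choice
under the Poisson generator, fixed for determinism). Recorded outcomes
are authoritative for the rewarded/punished split and are validated
against the replayed schedule; reinforcement recorded at the wrong
ratio count is a hard error. For logs without recorded outcomes the
phase determines the reinforcer (nicotine in self-administration and
punishment, saline in extinction, cue-only in seeking tests); shock
draws cannot be reconstructed from an outcome-free log, so such logs
classify reinforced pokes as unpunished.

Response types: `active_rewarded`, `active_punished` (reinforced +
footshock), `active_nonrewarded` (sub-ratio or time-out), `inactive`.
Every event gets exactly one type; classification is idempotent.

## Epoching

Exclusion rules prevent overlapping epochs from contributing duplicate
traces:

- rule (a): any poke within (0, 20] s after a rewarded (including
  punished-rewarded — both deliver drug; configurable) poke is dropped
  — this removes all time-out responses;
- rule (b): any *unrewarded* active or inactive poke within (0, 5] s of
  a preceding poke at either port is dropped; rewarded pokes are never
  dropped by this rule.

Both rules are evaluated against the raw sequence, so an excluded
predecessor still disqualifies its successors (exclusion is per event,
not iterative thinning), which makes the operation idempotent. Both
interval checks include their upper endpoint.

Epochs run −5…+10 s around the poke. The window holds
`round(15 · fs)` = 238 samples at 15.89 Hz, of which `round(5 · fs)` =
79 precede the event sample; the event is aligned to the nearest sample
of the downsampled grid. Events whose window leaves the recorded signal
are dropped and counted. Each trace is z-scored against the **first
4 s of its baseline** (−5…−1 s, 64 samples): z = (x − m)/s with the
sample SD (ddof = 1). The final pre-poke second is deliberately left
out of the baseline so anticipatory ramps just before the response
remain visible. Traces with baseline SD below 1e−12 carry no noise
estimate and are dropped with a count.

## Inference

**Bootstrap CI vs baseline.** For one response type's n traces, the
mean trace's bootstrap distribution is built from 5000 resamples of n
traces with replacement (realized as multinomial resample counts so a
(5000 × n) weight matrix multiplies the trace matrix — no resampled
copies are materialized). The 95% CI from the 2.5th/97.5th percentiles
is then expanded about the bootstrap-distribution mean by
√(n/(n−1)), correcting the percentile bootstrap's narrowness bias at
finite n; n = 1 is rejected (the factor is undefined). Significance
means the CI excludes 0 strictly.

**Permutation test between types.** The statistic is the difference of
group mean traces. 1000 label shuffles preserving group sizes give a
two-sided pointwise p with the add-one rule,
p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1) ≥ 1/1001. Two-sided was
chosen because both increases and decreases are of interest; group
sizes are preserved because the regrouping permutes labels.
Group-swap symmetry holds exactly for the observed difference and up to
Monte-Carlo resolution for p (the sampled shuffles differ).

**Alpha.** The pointwise alpha is Bonferroni-corrected over the number
of pairwise comparisons: base 0.05 / C(k, 2), e.g. 0.05/6 ≈ 0.008 for
four response types (reported to 3 decimals; the unrounded value is
used internally). For three conditions this formula gives 0.017; an
explicit `alpha` override exists for analyses that fix a different
value (e.g. a more conservative 0.01).

**Consecutive threshold.** Only runs of pointwise significance lasting
at least 0.25 s — ⌈0.25 · fs⌉ = 4 samples at 15.89 Hz — count as
windows. Windows are reported as (start, end) times of the first and
last significant sample.

**Pre/post change.** Per trace, mean ΔF/F over [−2, 0) s and [0, 5) s;
a paired t-test (df = n−1, two-sided) on the differences. A
zero-variance difference vector yields a flagged degenerate result
rather than an exception.

## Synthetic sessions

The generator emulates what the downstream pipeline needs to be tested
against, with known ground truth:

- **Behavior**: independent homogeneous Poisson pokes per port (the
  simplest hazard consistent with free-operant responding; rates are
  config hooks), run through the same FR/time-out replay as the
  classifier; punishment draws use a dedicated seed substream so the
  poke stream is reproducible independently of signal noise.
- **Signal**: per channel, baseline × (1 − bleach) + shared
  Ornstein–Uhlenbeck motion artifact (+ per-channel gain) + white
  noise; the 470 channel additionally carries event-locked transients
  baseline · amp · k(t), where k is a peak-normalized double
  exponential `exp(−t/τ_d) − exp(−t/τ_r)` (peak at
  t* = τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r)) and `amp` is the peak ΔF/F per
  response type. The 405 channel never carries transients — that is
  precisely what makes it a control.

Default parameters (all configurable):

| parameter | default | why |
|---|---|---|
| fs_native | 1017.25 Hz | acquisition rate of the saved signals |
| duration | 3600 s | a 1-h recording session |
| timeout / punish_prob | 20 s / 0.5 | schedule used in punishment sessions |
| rate_active / rate_inactive | 0.02 / 0.008 s⁻¹ | tens of pokes per hour, active-biased |
| τ_rise / τ_decay | 0.2 / 1.5 s | population GCaMP7f transient timescales |
| amp (rew/pun/nonrew/inact) | 0.08 / 0.12 / 0.03 / 0.02 | transients after every poke type, largest for salient outcomes |
| noise_sd | 31 a.u. | calibrated so the mean reinforced trace peaks at z ≈ 3 after preprocessing |
| bleach_frac / bleach_tau | 0.2 / 1200 s | slow exponential photobleaching |
| artifact_sd / artifact_tau | 2 a.u. / 5 s | slow common-mode motion disturbance |
| baseline 470 / 405 | 100 / 80 a.u. | arbitrary fluorescence units |

What the generator does **not** emulate: nicotine pharmacokinetics or
satiety (poke rates are stationary), trial-to-trial amplitude
variability, hemodynamic contamination, wavelength-dependent bleaching
kinetics, or lock-in demodulation artifacts. Passing recovery tests
therefore show that the pipeline recovers what this model injects, not
that real recordings satisfy the model.

## Validation and problem sizes

- Oracle tests: block-mean downsampling, the shrinking-window moving
  average, the least-squares fit, and the paired t each match an
  independent brute-force or closed-form computation (1e−10…1e−12).
- Null familywise error of the permutation test: 200 null comparisons
  (30/30 Gaussian traces, 238 timepoints, 1000 permutations,
  alpha 0.008, 0.25-s filter) — spurious-window rate ≤ 5% (measured 0).
- Bootstrap pointwise coverage: 500 null simulations of 30 zero-mean
  traces — coverage 95% ± 2% (measured ≈ 94%).
- Round-trip recovery through the full synthetic pipeline (FR1,
  0.1 pokes/s, 1-h sessions, ≥ 100 reinforced traces): a significant
  positive window overlapping 0–2 s post-event in ≥ 95 of 100
  transient-bearing sessions (measured 100) and in ≤ 5 of 100
  zero-amplitude sessions (measured 1).

## Known limitations

- **Short spurious CI windows on smoothed noise.** The 3 Hz zero-phase
  low-pass at 15.89 Hz correlates neighboring samples over ~2–3
  samples, so on null data the bootstrap CI excludes zero in runs that
  reach the 4-sample threshold somewhere in a 238-point epoch far more
  often than a white-noise calculation suggests — especially for small
  trace counts (n ≲ 30), where the percentile bootstrap also
  undercovers. Sustained windows anchored to the event are reliable
  (see the recovery numbers above); isolated ~0.25-s windows elsewhere
  in the epoch should be read with caution. The permutation test at
  Bonferroni-corrected alpha does not show this inflation.
- The moving-average edge policy (shrinking window) slightly biases the
  first/last 45 s of a session toward zero mean; epochs there are
  otherwise unaffected.
- Pooled traces are treated as exchangeable units; animal- or
  session-level variance components are out of scope (no mixed-effects
  modeling).
- Cluster-mass or t-max style permutation corrections are not
  implemented; familywise control rests on the Bonferroni alpha and
  the consecutive threshold.
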