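# Methods

## Measurement model

A deuterated-glucose pulse labels the DNA of cells dividing while label is
available in plasma. For each sorted cell sample the GC-MS readout is a
peak-area pair for the unlabeled (M+0) and doubly labeled (M+2) ion of the
derivatized DNA adenosine; plasma glucose availability is measured the same
way on finger-prick samples taken at 35, 185 and 305 minutes after the
first dose.

The correction chain is:

1. **TTR** = area(m+2) / area(m). A zero unlabeled peak is an unusable
   reading, reported as an error, never as TTR = 0.
2. **Calibration.** One OLS standard curve per channel set
   (`measured_ttr = slope · known_enrichment + intercept`), inverted to map
   TTR to enrichment. The abundance matching of standards used in practice
   is not reconstructable from a protocol description; it is represented
   only by the curve's residual SD.
3. **Background.** The subject's own pre-label blood sample of the same
   phase (encoded with `study_day < 0`; there is no separate baseline flag
   in the CSV schema) gives the natural-abundance enrichment, subtracted
   per cell type where a type-specific baseline exists. Negative net
   enrichments are preserved, never clipped — clipping would bias the
   downstream regressions — and flagged `below_detection` when under the
   detection threshold (default 0.0005 enrichment fraction; the threshold
   is a configurable constant, chosen small relative to curve peaks and
   large relative to round-off).
4. **Precursor–product normalization.** `normalized = net / (b · p̄)`, with
   `b = 0.65` the fraction of nucleotides made by de novo synthesis (the
   label-incorporating route) rather than base salvage, and `p̄` the mean
   of the subject's background-corrected during-label plasma glucose
   enrichments of that phase. A simple division by the mean was chosen over
   a time-weighted exposure integral: with half-hourly dosing the plasma
   curve is approximately rectangular, and the division is monotone,
   invertible and exactly testable by round-trip. The normalized value is
   the fraction of cells whose DNA was synthesized during the labeling
   window, which is the scale on which staggered subjects with different
   p̄ can be pooled.

## Conveyor-belt forward model

Granulocytes leave the marrow in production order. The model is an
expected-value cohort convolution — no per-cell sampling — with all cell
quantities relative to a baseline production of 1/day:

- **Label availability** u(t): rectangular pulse of amplitude p̄ over
  [0, 0.42) days, idealizing 12 half-hourly doses plus clearance (~10 h).
  Cohorts born inside the window count as labeled.
- **Postmitotic transit**: shifted exponential (hard minimum δ₀ plus an
  exponential tail of mean θ). Two parameters, a closed-form convolution
  for oracle tests, and the expected transit time δ₀ + θ matches the
  postmitotic-pool transit-time notion; a gamma tail would be a natural
  extension but is not the default.
- **Blood**: exponential residence with half-life t½. Blood enrichment is
  labeled cells / total cells; with constant production the total pool is
  t½/ln 2.
- **Airway**: a fraction φ of cells leaving blood enters a well-mixed
  airway pool with exponential residence mean r, on top of a resident
  unlabeled pool of size P in units of the daily labeled-influx scale
  (φ · production/day). Airway enrichment is labeled content over total
  content, so its steady-state gain relative to blood is r/(r+P) < 1: the
  resident cells dilute the signal for every P > 0, and P → 0 with fast
  residence recovers the blood curve. Sputum curves are therefore lower
  and later than blood, and outlast it.

Default parameters (days), shipped in `data/default_params.yaml`:

| parameter | eosinophil | basophil | rationale |
|---|---|---|---|
| δ₀ (transit shift) | 3.6 | 5.6 | first blood appearance day 4 / day 6 |
| θ (transit tail mean) | 3.0 | 3.5 | width of the up-/downlabeling curve |
| t½ (blood half-life) | 2.5 | 3.5 | reported 2–3 d / 3–4 d ranges |
| φ (airway influx fraction) | 0.1 | – | modest airway homing |
| r (airway residence mean) | 5.0 | – | sputum outlives blood label |
| P (resident airway pool) | 10 | – | ~3-fold sputum dilution |

Under these defaults and daily sampling at the 0.05% threshold the blood
eosinophil curve is detectable on days 4–28 (basophils from day 6), the
airway curve on days 5–33, and the blood peak (~4.7% labeled) falls on
day ~7 — the qualitative landmark set of the study design.

### Numerics

Fixed step dt = 0.1 d (configurable in (0, 0.5]), horizon 60 d. Arrival
masses of the labeled cohort per step are computed in closed form from the
integral of the transit CDF over the labeling window, which keeps the curve
grid-converged (< 0.5% change on halving dt) even at the sharp first
appearance. Unlabeled cohorts use a discretized CDF-difference kernel, so a
grid-multiple change of δ₀ translates the curve exactly (the FIFO
property). Pools update with exponential integrators (`exp(-μ dt)` decay
per step, half-step survival for within-step arrivals); the solve starts
from a burn-in long enough that all pools are at unlabeled steady state at
t = 0, and the bookkeeping (produced = in transit + blood + airway +
exited) balances to float round-off by construction. A "day d" measurement
is the curve value at t = d exactly.

**Degenerate-limit oracle**: for a delta-pulse label (window → dt) with
near-deterministic delay (θ → 0) and steady unlabeled pool, the blood curve
is `pulse_mass · μ · exp(-μ(t-δ₀))` analytically; the simulator matches it
within 1% at every grid point past the shift.

**Fitting** is a bounded Nelder-Mead least-squares over any subset of the
parameters from a supplied initial point, deterministic, requiring at least
4 observed points; non-convergence is reported with the final residual,
and all-zero observations pin production at the zero boundary with a flag.

## Synthetic trial generator

Emulates the two-arm, two-phase design: 10 subjects per arm, labeling at
days 0 and 84, study drug every 28 days starting 4 days after the first
label; per subject 10 blood samples (one pre-label baseline plus four
post-label days per phase, drawn from the day pool
{2,4,5,6,7,8,10,12,14,18,22,27,32,42} with seed-driven staggering,
stratified so each subject covers both regression windows), three sputum
samples taken on blood-draw days (so blood–sputum pairs exist for the
signed-rank tests), and 1 + 3 plasma finger-pricks per phase. Matched
subjects of the two arms share sampling days, mirroring the trial's
largely-similar time points across groups. Baseline counts are lognormal
around the arm medians (eosinophils 0.49 / 0.40 ×10⁶/mL, basophils
0.035 / 0.046) with the 0.25 ×10⁶/mL inclusion floor enforced at
generation.

Treatment scenario (directions from the trial, magnitudes configurable):
eosinophil production relaxes from 1 to a floor of 0.1 with a 1-day time
constant after the first dose; the phase-1 blood half-life is multiplied by
1.8 (slower short-term downlabeling) and the phase-2 multiplier is 1.0
(restored long-term kinetics); airway influx is multiplied by 0.3.
Basophils are unaffected by treatment in counts and kinetics. The second
phase is simulated with zero carry-over label, consistent with the label
being undetectable beyond day 32.

Noise model: multiplicative Gaussian with CV 0.02 per GC-MS peak area;
lognormal counts with CV 0.25 (median-parameterized, so zero CV returns
the truth exactly); lognormal between-subject variability with CV 0.10 on
δ₀, θ and t½ (typical inter-individual kinetic spread — the same subject
keeps its parameters across phases). Measured **counts** follow a
quasi-steady model (baseline × current effective production scale) rather
than the conveyor's delayed count: the reported count collapse within two
days of dosing is margination/clearance-driven and cannot arise from a
production cut that reaches blood only after the ~3.6-day transit. Label
kinetics, by contrast, use the full time-varying conveyor solve.

What the generator does **not** emulate: diurnal variation, within-subject
parameter drift, sputum-induction failures and missingness, correlated
GC-MS drift within a batch, or any mechanistic receptor biology (optional
MFI values are plain arm-specific distribution draws for exercising rank
tests). Passing tests on synthetic data therefore demonstrate the
correctness and power of the analysis chain under the stated model, not
robustness to those real-data features.

## Statistics

Regressions pool the individual normalized-enrichment points of all
subjects in a group (subject identity is kept for diagnostics but not
modeled — the analysis mirrors a simple-regression design, not mixed
effects; pooling was chosen over per-day averaging since the plotted data
are individual points). Windows are closed intervals on phase-local days;
day 7 belongs to the uplabeling window only. The two-line ANCOVA is
computed from closed-form sums of squares: F for slope equality against
the separate-slopes residual (df n−4), then, under a common slope, F for
elevation (df n−3); a zero residual in a noise-free separable case reports
p = 0 with an explicit flag. Rank tests use exact null distributions built
by counting (rank-sum compositions; sign-flip generating function) for
combined n ≤ 16 (Mann-Whitney) and ≤ 15 nonzero pairs (Wilcoxon), with
midrank/tie-corrected, continuity-corrected normal approximations
otherwise; exact enumeration is refused under ties rather than tie-broken.
Dilution ratios divide each post-day-7 value by the day-7 maximum and are
not computable when the reference is missing or below the detection
threshold. No multiplicity correction is applied; p-values are
per-comparison.

## Known limitations

- Absolute life spans are out of reach by design: without progenitor
  kinetics the model identifies relative differences only, and the package
  deliberately does not estimate them.
- The pooled ANCOVA treats points as independent; with between-subject
  kinetic variability the down-window residuals are clustered and curved,
  which makes the slope test conservative on synthetic data (measured
  phase-1 rejection ≈ 0.73–0.76 and phase-2 null rejection ≈ 0.02 at the
  default scenario over hundreds of simulated trials). A mixed-effects or
  per-subject-slope analysis would be better calibrated but is outside the
  analysis being reproduced.
- The rectangular label-availability pulse ignores glucose absorption and
  clearance tails; the normalization division ignores time-weighting of
  the precursor curve.
- The airway pool is a single well-mixed compartment; no return flux from
  tissue to blood is modeled, although the scenario hooks (production
  floor, half-life and influx multipliers) can mimic its observable
  consequences without claiming to identify the mechanism.
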