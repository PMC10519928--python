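# Methods

## Force-partition model

The instrumented limb is modeled as an axial spring network: the
external fixator (stiffness `K_f`, N/mm) in parallel with the load path
through the regenerate, which is the callus column (`K_c`) in series
with the proximal and distal cortical fragments (`K_bp`, `K_bd`). The
fragments combine to the series-equivalent
`K_b = K_bp·K_bd/(K_bp+K_bd)`, always below the smaller fragment
stiffness. Fragment stiffnesses can be derived from CT cross-section
profiles with an axial varying-section rod model,
`K = [Σ_z Δz/(E·A(z))]⁻¹`, using a cortical modulus of E = 21 GPa;
bending is neglected, consistent with the axial network.

During stance the internal force partitions as `F_i = F_f + F_c`
(enforced exactly throughout the pipeline). The apparent callus
stiffness is computed as

    K_c = K_f · F_c·K_b / (F_f·K_b + F_c·K_f).

A caveat worth stating: a textbook parallel-fixator/series-bone
derivation produces a minus sign where this expression has a plus. The
package implements the expression above as its model and uses its exact
algebraic inverse for simulation, so analysis and simulation are
mutually consistent by construction; the load-share fraction

    λ = F_f/F_i = K_f(K_b−K_c) / (K_c·K_b + K_f(K_b−K_c))

is strictly decreasing in `K_c`, equals 1 at `K_c = 0`, and equals 1/2
at `K_c = K_f·K_b/(K_b+K_f)` — the stiffness at which the force
partition overturns. The inverse is exact: round-tripping
partition → stiffness reproduces `K_c` to 1e−9 relative over the full
valid range `0 ≤ K_c < K_b`.

### Internal-force calibration

`F_i` is not observable in vivo. It is estimated as `F_i = r·GRF` with
`r` the mean per-tread ratio `F_f_peak/GRF_peak` over a half-open
early-healing window, default days [7, 14): monitoring starts after a
one-week latency and, before any mature bridge forms, essentially the
whole internal force crosses the fixator (`F_i ≈ F_f`). Both peaks are
taken as maxima over the same stance interval (peak-synchronized
pairing). Window endpoints are configurable.

### Censoring

When `F_f` drops below 2 % of `F_i` (configurable) the fixator is
essentially unloaded and the stiffness estimate leaves the range over
which the load cells were calibrated; the estimate is then reported as
right-censored (`>range`), not as a number. Non-positive `F_i` or `F_c`
yields an invalid (missing) estimate.

## Gait processing

Stance phases are maximal intervals where the baseline-corrected GRF
stays at or above 5 % of body weight, with a 1 % body-weight hysteresis
band on exit and a 0.2 s minimum duration; a stance clipped at the
trace end is kept if it already satisfies the duration rule. Traces are
assumed recorded at amble speed; no speed filtering is applied. Daily
summaries average per-tread peaks; days with fewer than 8 treads are
kept but flagged incomplete (downstream consumers may exclude them).
GRF is normalized to the healthy reference `0.425·BW·g` — the midpoint
of the 42–43 % of body weight a sound limb exerts in this animal model.

## CT morphometry

HU→density calibration is an OLS fit of known insert densities on mean
region HU over the six-insert phantom (defaults 0, 0.1, 0.2, 0.4, 0.6,
0.8 g HA/cm³); noiseless collinear inserts are reproduced to machine
precision. Mineralized tissue is a calibrated-density threshold
(default 0.15 g HA/cm³ — a deliberately low bar that captures early
woven bone; there is no canonical value) restricted to an ROI that
excludes the phantoms and any pin-tract woven bone. Per-slice CSA is
voxel count × in-plane voxel area; TV is the rectangle-rule integral of
CSA over the defect span ± 10 mm margins; per-slice BMD is the mean
mapped density over masked voxels, with empty slices reported missing
(NaN), never zero; the summary BMD is the voxel-weighted mean over the
defect span (mask-only — whether to average over the whole cross
section was an open choice; mask-only matches the segmentation-based
workflow). Contralateral normalization divides treated summaries by the
control limb's means over a matched 15 mm defect-equivalent span; the
control TV denominator is mean CSA × 15 mm. Positions are voxel-center
based (0-based indices, half-open spans in mm). Streak artifacts from
fixator metal are not corrected; affected slices are handled by ROI
exclusion.

## Trend statistics

- **Crossover**: first day with `F_c > F_f`, linearly interpolated
  between the bracketing days (daily sampling is coarse relative to the
  quantity of interest, so whole-day reporting would quantize it).
- **Stabilization**: first day from which the quantity stays inside a
  tolerance band for a hold period; defaults `|F_f| ≤ 5 %` of the mean
  internal force, held 14 days. The band/hold defaults make the
  criterion assertable on simulated data — "settles around zero" is not
  otherwise operational.
- **Trend fits**: three families — exponential saturation
  `A − B·exp(−t/τ)`, a four-parameter logistic, and a monotone spline
  (isotonic regression followed by a shape-preserving cubic). Levenberg–
  Marquardt least squares with data-driven starting values; degenerate
  (constant) data collapse the exponential family to `B ≈ 0` with zero
  residual.
- **GRF–BMD association**: OLS of body-weight-normalized GRF on BMD at
  matched time-points, flagged significant when R² > 0.5 *and* the
  two-sided slope p-value < 0.005. A single pre-specified regression, so
  no multiple-testing adjustment is applied. GRF enters as %BW (a
  config switch allows %-of-healthy instead, which differs only by the
  constant healthy fraction).

## Synthetic cohort

The generator forward-simulates the statistical structure the analysis
assumes, not the biology: per-animal anchor trajectories interpolated
by monotone shape-preserving (PCHIP) splines that pass through every
anchor exactly, never overshoot between monotone anchors, and hold end
values outside the anchor range. A single exponential cannot pass
through the default stiffness anchors, hence the spline family.

Defaults (per animal, 60 kg body weight, `K_f` = 593 N/mm; fragment
stiffnesses from the eight-animal fixture table with `K_b` recomputed
from the series formula):

- `K_c` anchors: (14 d, 60 N/mm), (30 d, `K_f·K_b/(K_b+K_f)` — the
  half-share stiffness, so the designed crossover is day 30), (40 d,
  650), (60 d, 7000), (70 d, 15000). `K_c` is *exactly zero before
  day 14* (bridging onset): physically there is no mineralized bridge
  in the latency fortnight, and it makes the calibration assumption
  `F_i ≈ F_f` hold exactly in the simulator, so noiseless runs are
  identifiable to machine precision.
- GRF recovery: (7 d, 42 %), (120 d, 70.5 %), (180 d, 93 %) of healthy.
- BMD: (0 d, 0.45), (65 d, 0.79), (123 d, 0.81), (365 d, 1.1875)
  g HA/cm³ against a 1.25 g HA/cm³ contralateral cortical reference
  (36 % → 95 %).
- CSA: (0 d, 100 %), (200 d, 229.49 %), (365 d, 156.13 %) of the
  144.79 mm² contralateral reference.
- `r_true` (internal force / GRF) defaults to 1.0; real per-animal
  ratios are unknown, and the pipeline must recover whatever value the
  generator used — which it does exactly in noiseless runs.
- Per-animal anchor jitter defaults to 0: cohort variability comes from
  the per-animal fragment stiffnesses and sensor noise. A `jitter`
  option scales anchor values multiplicatively when heterogeneous
  cohorts are wanted.

Gait traces are half-sine stance pulses (0.5 s stance, 0.4 s gap,
100 Hz, 8 treads/day, days 7–90 by default) with independent 5 %
multiplicative Gaussian noise per tread on each sensor's peak. Stance
onsets sit on the sample grid so designed peaks are attained exactly at
zero noise; the pipeline consumes only peaks, so the pulse shape is
immaterial. The horizon extends to day 90 for every animal so the
stabilization detector's 14-day hold window has tail data.

CT volumes are digital metatarsi at 0.3 mm isotropic spacing (45 mm of
bone axis, the 15 mm defect centered): a cortical annulus of 9 mm outer
radius whose wall area equals the 144.79 mm² control CSA, a solid
callus cylinder over the defect whose radius follows the CSA%
trajectory and whose voxel densities are Gaussian (σ = 0.05 g HA/cm³)
around the day's BMD, and six 2.5 mm-radius phantom rods below the
limb. Densities map to HU through a fixed true line (slope 0.00075
g/cm³ per HU, intercept −0.03 g/cm³, i.e. ~1700 HU for dense cortical
bone) plus additive 2 HU Gaussian noise. The sidecar stores both the
designed (analytic) and the voxelized ground truth, so tests can
distinguish method error from voxelization error (≈ 0.3–0.5 % for the
CSA of these radii at 0.3 mm).

What the generator deliberately does **not** emulate: lobed or
asymmetric callus shapes (overgrowth is a convex radius scaling),
metal streak artifacts (only representable as ROI-excluded outlier
slices), muscle-force variation within a stance, partial platform
contacts, and any tissue-level biology (differentiation, scaffold
resorption). Passing recovery tests therefore demonstrates the
*estimator chain* is correct and unbiased under the assumed noise
structure — not that the model assumptions hold in a real animal.

## Numerical choices and edge cases

- Units: N, mm, N/mm, days, g HA/cm³ internally; kN/mm only at
  reporting boundaries.
- Stiffness-table ingest validates a supplied `K_b` against the series
  formula at 1e−9 relative.
- Degenerate calibrations (fewer than two phantom inserts, identical
  mean HU, non-positive slope) raise rather than return garbage.
- Trend fits on constant data are accepted (zero-residual degenerate
  fits); non-convergence raises with the family and data size attached.
- Crossover with the first sample already crossed returns that day;
  ties (`F_c = F_f` exactly) interpolate to the tie day.
- Problem sizes in the shipped tests and the acceptance script — an
  8-animal cohort at 8 treads/day over days 7–90, and single
  3.15M-voxel volumes — were chosen as the smallest sizes at which the
  cohort means are stable against sensor noise; they run in seconds.

## Known limitations

- The stiffness formula's sign convention is adopted as printed in the
  source model rather than re-derived; both the estimator and the
  simulator use the same convention, so conclusions about *recovery*
  are unaffected, but absolute `K_c` values inherit the convention.
- The stiffness estimate near the censoring boundary is noise-amplified
  (it divides by `F_f`); daily averaging over ≥ 8 treads is the only
  mitigation implemented.
- Contralateral matching is positional along the bone axis from a
  configured landmark; no image registration is performed.
- The cohort-level GRF–BMD regression pairs each CT time-point with the
  nearest gait day within 7 days; sparser gait follow-up silently drops
  pairs.
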