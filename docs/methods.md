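# Methods

This note documents the models implemented in `ppixquant`, the defaults and
their rationale, what the synthetic generator does and does not emulate, and
the numerical conventions.

## Illumination model (`optics`)

Incident blue power density at the field-of-view centre is modelled as

    P(s, D) = gain · s · P_ref · (D_ref / D)^γ

with `s` the lamp setting (fraction of maximum), `D` the working distance
(cm) and `gain` a per-microscope scale factor. Choices:

* **Linear response to the lamp setting.** Measured data show a direct
  positive association between setting and output but no published
  functional form; linear through the origin is the simplest monotone
  choice and is exposed directly through `light_setting` so an alternative
  response curve can be applied upstream.
* **Power-law distance dependence.** The beam is cone-shaped and the
  distance relation is known to be non-linear but not inverse-square at
  these working distances. γ is therefore *calibrated*, as the
  least-squares slope of log power against −log distance. The packaged
  anchor pair (25.2 mW/cm² at 20 cm, 4.7 mW/cm² at 35 cm) gives γ = 3.0008;
  with exactly two anchors the model interpolates both exactly. The 25-cm
  prediction at gain 1 is 12.9 mW/cm², inside the measured 8.9–18.4 mW/cm²
  spread of real instruments (which corresponds to gain ≈ 0.69–1.43).
* **Beam profile.** A two-sided Gaussian: horizontal half-width
  `σ_x·(D/D_ref)` (spot grows linearly with distance, default σ = 20 mm at
  20 cm, i.e. 1 mm per cm of distance), vertical half-width `σ_y` below the
  centre and `σ_y · tilt_skew` above it (default skew 1.15). The skew
  direction reflects the tilted mounting of the scope; the *magnitude* is a
  package choice — only the direction and bell shape are constrained by
  measurement, so the profile is deliberately the simplest skewed bell.
* **Dose arithmetic.** Radiant exposure H (J/cm²) and time relate by
  `t = 1000·H/P` seconds; `dose_to_time` and `time_to_dose` are exact
  inverses. 14.4 J/cm² at 25.2 mW/cm² ↔ 9.5 min.

Units: mW/cm² (power density), J/cm² (dose), cm (distance), mm (FOV
coordinates). No lamp-ageing model is included: measured output shows no
usable correlation with remaining lamp hours.

## Camera model (`camera`)

Linear gains per channel, additive Gaussian read noise before quantization,
round-and-clip to 8 bits. The red channel receives
`red_gain·red + leak·blue_gain·blue`; green carries no signal (red emission
plus blue excitation only). The external camera's long-wave-pass filter is
modelled as `leak ≤ 10⁻³` (≥1000× attenuation); the internal CCD's true
spillover is not published — only the qualitative collapse of its
tumor-to-background ratio is — so its default `leak = 0.05` is a free
parameter chosen to produce a clear, not total, TBR compression. The
ordering "internal TBR < external TBR" is parameter-free: for tumor red
radiance r_t > background r_b and spillover s > 0,
(r_t+s)/(r_b+s) < r_t/r_b.

Shot noise and Bayer demosaicing are omitted: ROI averaging over ~8000
pixels dominates per-pixel noise statistics, and the cameras of interest
were operated at fixed settings.

## Synthetic scenes (`scene`)

Each study renders `n_specimens` image series on the default acquisition
schedule (every 1 min for 10 min, then every 5 min to 30; 15 frames) at
512×512 px, 0.1 mm/px. Four standards sit at the field corners, tumor and
brain discs sit symmetrically about the vertical midline 6 mm either side
of the centre (so both see identical excitation, ~96% of peak), and a
constant dark floor (1.54 a.u.) fills the rest, with a dark-floor reference
disc included in the ROI map.

* **Standards** (sheets of 0.02/0.08 in at 0.5/2.7/8.1 ppt dye):
  `radiance = slope · concentration · thickness · (P_local/P_ref) · (1 + drift(t))`,
  slope 350 a.u./(in·ppt), drift a linear ramp reaching at most +3.5% at
  30 min — the measured photostability envelope. The brightest corner
  pixels of the brightest standard may saturate the 8-bit range, as they do
  on a real camera optimized for the tissue signal; saturation does not
  affect the reference standard used for normalization.
* **Tissue**: `radiance = max(0, I₀ + c·(P_local/P_ref)·ln(t+1))`. The
  initial radiance is independent of the beam (fluorophore load is a tissue
  property); only the *bleaching rate* scales with irradiance, which
  produces the observed centre-faster-than-periphery decay ordering.
  Defaults are solved from two-point constraints on the benchmark
  trajectories: tumor `36.8 − 8.94·ln(t+1)` and brain `8.0 − 1.048·ln(t+1)`
  give TBR 4.6 at t=0 and 2.80 at 10 min, brain 8.0 → 4.40 a.u. over
  30 min, and brain-to-dark-floor 5.19 → 2.86 with the 1.54 a.u. floor.
* **Specimen variability**: one lognormal gain (σ = 0.3) common to tumor
  and brain — inter-animal fluorophore load, cancels in TBR — plus an
  independent tumor-only lognormal jitter (σ = 0.15) that spreads
  per-specimen TBR over roughly 3.2–7.8 while keeping its centre at 4.6.
* **Determinism**: all randomness derives from one `SeedSequence(seed)`;
  identical designs produce bit-identical stacks.

What the generator does **not** emulate: anatomical texture, specular
reflection, motion, autofluorescence spectra, shot noise, and depth or
cavity geometry. Passing tests therefore demonstrate that the *measurement
chain* is correct and well-calibrated under controlled conditions, not that
it is robust to every artefact of real surgical footage.

## Quantification (`quantify`)

ROIs are circles of 51-pixel radius (configurable); a pixel belongs to the
ROI when its centre lies within the radius — the simplest deterministic
inclusion rule, stated because drawing tools differ on boundary handling.
Coordinates are 0-based (row, col) from the top-left. Statistics are the
mean and sample SD (ddof = 1) of red-channel counts. The
tumor-to-background ratio uses the adjacent normal-brain ROI as background;
the dark-floor ROI serves the brain-to-background ratio. No
autofluorescence subtraction is applied. A zero background mean yields NaN
(flagged, not raised) since it arises from valid all-dark frames.

## Ratiometric normalization (`normalize`)

`norm(roi, t) = nominal · mean(roi, t) / mean(ref, t)` — computed **per
time point**, which is what cancels temporal lamp/exposure fluctuation;
normalizing by a series-mean reference would not. The nominal value
defaults to 10 (the reference is declared a constant 10% intensity; the
choice of 10 vs 100 is conventional and exposed as a parameter). Gain
invariance holds to machine precision for any positive per-frame factor,
and the operation is idempotent. Field-of-view inhomogeneity is *not*
corrected: ROIs at different positions keep their excitation ratio. A
flat-field correction map is out of scope.

## Kinetics (`kinetics`)

`fit_log_decay` regresses values on `ln(t + offset)`. The default offset of
1 min makes the t = 0 frame usable (`ln 1 = 0`, so `y₀` is the fitted
initial intensity); with offset 0 any t = 0 samples are dropped with a
warning. Goodness of fit is the Cox–Snell pseudo-R²,
`1 − (L₀/L₁)^{2/n}` with Gaussian likelihoods at their ML variance — which
collapses algebraically to the classical `1 − SSE/SST`; the test suite
asserts the numerical identity. Zero-variance input returns `c = 0, R² = 0`
rather than failing.

A logarithmic decay has no finite half-life from t = 0, so
`half_life_two_point` uses the exponential-through-two-points convention
`t½ = Δt·ln2 / ln(y₁/y₂)` (scale-invariant in y, translation-invariant in
t). Under this convention a quoted half-life of 14 min 25 s corresponds to
a 4.23-fold drop over 30 min; the convention is a parameterized choice, not
a claim about the underlying photochemistry. Group comparisons use the
standard two-sided t-test (scipy); p-values are reported raw, with no
multiple-testing correction.

Percent change is `100·(v(t_b) − v(t_a))/v(t_a)` on whichever series is
supplied. Note that the mean of per-specimen ratios and the ratio of means
are different statistics; both are obtainable from the per-specimen tables
and they can legitimately differ by a few points on skewed data.

## Agreement (`agreement`)

The category space is fixed at k = 5 (scores 0–4) even when categories go
unused: the free-marginal kappa depends on k, not on the observed support.
"Overall agreement" is the pooled fraction of agreeing rater pairs
(Σ agreeing pairs / (items · C(raters,2))) — not the mean of the per-item
modal column, which is a different (and also reported) statistic. The
fixed-marginal chance term is `P_e = Σ_j p_j²` over the pooled category
proportions. All statistics are computed by explicit tallies; the test
suite cross-checks the fixed-marginal kappa against statsmodels on random
tables. Percentages are reported to 1 decimal; raw fractions are retained.

The packaged rating table (9 standards × 4 observers, second grading
attempt) yields pairwise agreement 81.5%, fixed-marginal kappa 75.1% and
free-marginal kappa 76.9%. The packaged *first* attempt is a synthetic
reconstruction (labelled as such): only each observer's agreement count
with the second attempt is known (6, 5, 6, 8 of 9), so a table realising
those counts via single-step score changes is shipped; any such table gives
the identical intrarater summary, 69 ± 14%.

## Problem sizes and tolerances

The replicate-simulation checks use 20 studies × 6 specimens (120
specimen-level ratios per time point), enough to hold the grand-mean
sampling error near 1% given the lognormal variability, and the kinetics
recovery uses 100 replicates at noise SD 0.01 (OLS theory puts the SE of
the mean coefficient near 0.0002). Floating-point identities (gain
invariance, round-trips, Cox–Snell equality) are asserted at 1e-10 to 1e-12
relative; simulation-calibration comparisons at ±15%, dominated by the
deliberate specimen variability, quantization of low-count pixels, and the
~4% excitation shortfall at the tissue discs' off-centre position.
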