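# ppixquant

Quantitative measurement chain for protoporphyrin IX (PpIX) fluorescence
under a neurosurgical operating microscope.

5-aminolevulinic acid (5-ALA) induces fluorescent PpIX accumulation in
malignant glioma; surgeons resect under blue (~405 nm) excitation and judge
the red (~635 nm) emission by eye or from camera frames. Turning that signal
into *numbers* is fragile: the incident blue power density falls steeply
with working distance, the beam profile is bell-shaped and tilted across the
field of view, typical internal colour CCDs leak blue excitation into the
red channel, and PpIX itself photobleaches within minutes. `ppixquant`
implements every stage of a measurement chain that copes with these effects,
plus a ground-truthed synthetic scene generator so the whole chain is
verifiable without microscope hardware:

* **optics** — incident power density `P(D) = P_ref (D_ref/D)^γ` with γ
  calibrated from power-meter anchors (≈3 from the packaged 25.2 mW/cm² @
  20 cm and 4.7 mW/cm² @ 35 cm pair); two-sided-Gaussian beam field with
  vertical skew; radiant-exposure ⇄ time conversion (`t = dose·1000/P`).
* **camera** — linear 8-bit RGB rendering with blue→red crosstalk: an
  internal-CCD model (leak 0.05) and an external long-wave-pass-filtered
  model (leak ≤ 10⁻³, i.e. ≥1000× blue rejection).
* **scene** — synthetic studies: photostable dye-in-polymer standards
  (emission linear in sheet thickness with concentration-dependent slope)
  at the field corners, tumor and normal-brain discs near the centre that
  bleach as `I(t) = max(0, I₀ + c·ln(t+1))` with `c` scaled by local
  irradiance, specimen-to-specimen lognormal variability, and a full
  ground-truth radiance table.
* **quantify** — circular-ROI (51-pixel radius) red-channel mean ± SD time
  series and tumor-to-background ratios (TBR).
* **normalize** — ratiometric normalization: every ROI mean is divided,
  per time point, by a designated photostable standard and scaled to a
  nominal 10%, cancelling any per-frame multiplicative factor exactly.
* **kinetics** — least-squares fits of `y = c·ln(x) + y₀`, Cox–Snell
  pseudo-R² (equal to `1 − SSE/SST` for a Gaussian OLS fit), two-point
  exponential half-life, percent change, and t-tests.
* **agreement** — multi-rater ordinal agreement for the 0–4 visual grading
  scale: per-item modal agreement, overall pairwise agreement `P_o`,
  fixed-marginal (Fleiss-type) kappa `(P_o−P_e)/(1−P_e)` with
  `P_e = Σ p_j²`, and free-marginal kappa `(P_o−1/k)/(1−1/k)`.

## Worked example

```python
import numpy as np
from ppixquant import *
from ppixquant.pipeline import quantify_study, per_specimen_ratios, study_rois
from ppixquant.scene import StudyDesign
from ppixquant.camera import external_camera

design = StudyDesign(n_specimens=6, cameras=(external_camera(),), seed=42)
study = generate_series(design)                       # render 6 specimens x 15 frames
quant = quantify_study(study, camera="external")      # ROI means per frame
tbr = per_specimen_ratios(quant, "tumor", "brain")
print(round(tbr[tbr.time_min == 0]["ratio"].mean(), 2))   # 4.49
print(round(tbr[tbr.time_min == 10]["ratio"].mean(), 2))  # 2.86

ts = extract_timeseries(study.frames["external"][0], study_rois(study),
                        design.times_min)
ns = ratiometric_normalize(ts, "standard-1")          # reference pinned to 10%
tum = ns.normalized_series("tumor")
fit = fit_log_decay(tum.index.to_numpy(), tum.to_numpy())
print(f"c={fit.c:.3f}, R^2={fit.r2:.3f}")             # c=-33.878, R^2=1.000
print(round(half_life_two_point(0, tum.loc[0.0], 30, tum.loc[30.0]), 1))  # 13.3
```

The mean tumor-to-brain ratio starts near 4.5 and falls below 3 within
10 minutes of continuous blue-light exposure — rapid photobleaching that
the photostable standards (pinned at 10% by the normalization) make
comparable across specimens and sessions. The fitted `c` is the normalized
tumor bleaching rate per ln(min); the 13.3 min figure is the half-life of
the exponential through the 0- and 30-minute points.

The same pipeline is scriptable from the shell:

```sh
ppixquant simulate --seed 5 --n-specimens 6 --camera external --out run/
ppixquant quantify run/specimen*.tif --rois run/rois.json \
    --times 0,1,2,3,4,5,6,7,8,9,10,15,20,25,30 --out run/quant.csv
ppixquant normalize run/quant.csv --reference standard-1 --out run/norm.csv
ppixquant fit run/norm.csv --out run/fits.csv
ppixquant agree          # agreement report for the packaged rating table
```

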