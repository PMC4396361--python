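# tectomap

Analysis of the spatial organisation of orientation preference in the mouse
superficial superior colliculus (sSC), for two data modalities:

* **electrode penetrations** — per-trial unit firing rates at several depths
  along a track, analysed with axial circular statistics and a permutation
  test for columnar (depth-wise) clustering of orientation preference;
* **wide-field calcium imaging** — fluorescence stacks acquired during
  retinotopic-patch and drifting-grating stimulation, turned into per-pixel
  retinotopic, orientation, significance and single-condition maps, and
  compared quantitatively against the *concentric* prediction: each pixel
  prefers the grating orientation tangent to the circle around the centre of
  vision through its receptive field.

A synthetic-data generator produces both modalities with known ground truth
(retinotopy, orientation rule, tuning, noise), so every stage of the
pipeline is testable end to end without any recordings.

## The statistics at the core

Orientations φ are axial (period 180°) and analysed on doubled angles.

* Circular mean of a penetration: ½·arg Σₚ exp(2iφₚ); circular variance:
  1 − |Σₚ exp(2iφₚ)|/n (0 = all units aligned, 1 = balanced).
* **Columnar shuffle test**: the observed statistic is the median over
  penetrations of the circular variance; the null distribution redistributes
  the pooled unit preferences at random over all positions on all
  penetrations (10,000×), and p = (1 + #{null ≤ real}) / (1 + N).
* Tuning indices: OI = (R_pref − R_ortho)/(R_pref + R_ortho) on
  orientation-collapsed responses; DSI = |Σ R(φ)e^{iφ}| / Σ R(φ) over
  directions (direction selective if DSI > 0.5); von Mises fits use
  exp(cos 2(φ − φ_pref) − 1).
* Imaging responses: ΔF/F = (R_s − R_0)/R_0 with R_s averaged from 0.3 s
  after stimulus onset to 2 s after offset and R_0 over the preceding 3.3 s,
  optionally divided by (1 + the same response in a non-responsive reference
  region); maps smoothed with a 33 µm Gaussian.
* Per-pixel preferred orientation: ½·arg Σ_φ R(φ,p) e^{2iφ} with R(φ,p) the
  larger of the two opposite drift directions sharing grating orientation φ.
* Retinotopy: per-patch response maps fitted with 2D Gaussians (0.1
  percentage-point pedestal subtracted; ≥ 0.4 % fitted response required),
  patch centres interpolated piecewise-linearly (Delaunay) into dense
  monitor coordinates inside their convex hull, then transformed to azimuth
  = arctan(x/z), elevation = arctan(y/√(x²+z²)) in head-centred coordinates.
* **Concentric prediction**: angle = (90° − atan2(y, x)) mod 180 at each
  pixel's visual-field position (horizontal for the nasal ipsilateral
  field), smoothed axially with a 132 µm Gaussian; agreement with the
  measured map is scored by the Fisher–Lee circular correlation on doubled
  angles and a histogram of axial differences.

## Worked example

Simulate 21 penetrations whose preferred orientations follow the concentric
rule at their receptive fields (within-penetration scatter κ = 8), then run
the columnar and concentric analyses:

```python
import numpy as np
from tectomap import (gen_ephys_dataset, columnar_summary,
                      penetration_concentric_test, PenetrationSummary)

table, truth = gen_ephys_dataset(rule="columnar_concentric", n_penetrations=21,
                                 within_kappa=8.0, seed=42)
pen, shuffle, rayleigh = columnar_summary(table, n_shuffles=10_000, seed=42)
print(f"median circular variance (real): {shuffle.real_median_cv:.3f}")
print(f"shuffle test p = {shuffle.p_value:.2e}")
summaries = [PenetrationSummary(r.penetration_id, r.circ_mean_deg, r.circ_var,
                                int(r.n_units), r.rf_azimuth_deg, r.rf_elevation_deg)
             for r in pen.itertuples() if np.isfinite(r.circ_mean_deg)]
ct, corr = penetration_concentric_test(summaries)
print(f"measured vs concentric across {len(ct)} penetrations: corr = {corr:.2f}")
```

prints

```
median circular variance (real): 0.057
shuffle test p = 1.00e-04
measured vs concentric across 21 penetrations: corr = 0.98
```

The real median circular variance (0.057) sits far below the shuffled
median (≈ 0.47), so the depth-wise alignment of preferences is not chance
(p = 1/10001, the smallest value the permutation scheme can report), and
the penetration means track the concentric angles at their receptive fields.

The same loop exists for imaging from the shell:

```bash
tectomap simulate imaging --rule concentric --size 96 --seed 1 --out sim
tectomap imaging-maps --config sim/config.yaml
tectomap concentric-compare --measured sim/analysis/orientation.tif \
    --predicted sim/analysis/concentric.tif
```

which writes retinotopy/orientation/significance/concentric maps (float
TIFF plus HSV renderings), a patch-fit table, a comparison report and a
manifest under `sim/analysis/`.

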