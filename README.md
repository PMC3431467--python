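# lungqct

Quantitative CT of the lungs: emphysema and air-trapping densitometry,
full-width-at-half-maximum (FWHM) airway morphometry, and
paired-reconstruction agreement analysis — driven by a synthetic thoracic
phantom generator, so the sensitivity of each measure to the
reconstruction algorithm can be studied without patient data.

## The problem

Quantitative CT biomarkers of chronic obstructive pulmonary disease are
computed from the attenuation histogram of the segmented lung and from
airway cross-sections:

* **IN₋₉₅₀** — % of inspiratory lung voxels below −950 HU (density-mask
  emphysema),
* **Perc15** — HU at the 15th percentile of the inspiratory attenuation
  histogram,
* **EXP₋₈₅₆** — % of expiratory lung voxels below −856 HU (air trapping),
* **RVC₋₈₆₀ ₜₒ ₋₉₅₀** — change (expiration − inspiration) of the relative
  lung volume in the −860…−950 HU band,
* **E/I-ratio₍MLD₎** — 100 × expiratory / inspiratory mean lung density,
* **LA, WA, WA%, Pi** — airway lumen area, wall area, wall-area percentage
  `100·WA/(WA+LA)` and internal perimeter, measured by casting rays from a
  lumen seed and placing wall boundaries at half-maximum.

Threshold and percentile indices live in the tails of the attenuation
histogram, so they are sensitive to image noise — and therefore to the
reconstruction algorithm. Iterative reconstruction (IR) denoises relative
to filtered back-projection (FBP); when both reconstructions of the same
acquisition are quantified, the tail-based indices shift systematically
while mean-density ratios and airway geometry are spared. This package
reproduces that experiment end-to-end on synthetic phantoms with known
ground truth: paired inspiratory/expiratory volumes with controllable
emphysema and air-trapping fractions and one embedded airway of known
annular geometry, rendered at a full noise level ("FBP") and at 45 % lower
noise ("IR"), then segmented, measured, and compared per subject with
Lin's concordance correlation coefficient

> pc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)

and the exact Wilcoxon signed-rank test.

## Worked example

```python
from lungqct import PhantomParams, RunConfig, run_study

cfg = RunConfig(n_subjects=5, seed=42,
                base_phantom=PhantomParams(grid_shape=(64, 64, 64)))
res = run_study(cfg)
cols = ["measure", "pc", "agreement_class", "wilcoxon_p", "median_A", "median_B"]
print(res.agreement[cols].round(4).to_string(index=False))
```

```
   measure     pc agreement_class  wilcoxon_p  median_A  median_B
     IN950 0.2300            poor      0.0625   22.1842   14.3177
    Perc15 0.1891            poor      0.0625 -977.4140 -946.7945
    EXP856 0.4262            poor      0.0625   32.4543   23.3764
       RVC 0.1390            poor      0.0625  -15.0492  -31.8885
EIratioMLD 0.9999  almost perfect      0.4375   93.5899   93.6196
        LA 0.9999  almost perfect      0.1250   10.5125   10.5447
        WA 0.9999  almost perfect      0.0625   38.5009   38.4501
     WApct 0.9994  almost perfect      0.0625   77.3837   77.3660
        Pi 0.9999  almost perfect      0.1875   12.0065   12.0369
```

`median_A`/`median_B` are the per-cohort medians under the FBP-level and
IR-level renderings. The tail-based indices (IN₋₉₅₀, Perc15, EXP₋₈₅₆, RVC)
separate sharply between the two noise levels — e.g. the density-mask
emphysema index drops from 22.2 % to 14.3 % when noise is reduced — and
show poor concordance, while E/I-ratio₍MLD₎ and all four airway measures
are nearly identical under both (pc > 0.99): the expected insensitivity of
mean-density ratios and FWHM airway geometry to reconstruction noise.

The same stages are available from the shell:

```bash
lungqct simulate --n 3 --seed 1 --outdir sim/
lungqct segment sim/S001/insp_FBP.nii.gz --out mask.nii.gz
lungqct airway sim/S001/insp_FBP.nii.gz --geometry sim/S001/geometry.json --out airway.json
lungqct run-all --n 30 --seed 1 --outdir study/
lungqct config --show-defaults
```

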