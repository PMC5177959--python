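# aeoscan

Toolkit for **dynamic monitoring of aeolian desertification** from
multispectral satellite time series, and for attributing changes in
desertified area to climatic and anthropogenic drivers.

Aeolian (wind-driven) desertification in arid and semi-arid regions is
conventionally tracked by labour-intensive surveys every few years.
`aeoscan` implements a remote-sensing alternative aimed at analysts who
work with coarse-resolution reflectance composites (MODIS-style 8-day
products, 46 per year) calibrated against occasional fine-resolution
scenes (GF-1-style multispectral + panchromatic pairs):

1. **Pan-sharpening comparison** — PCA component substitution,
   multiplicative and Brovey fusion, scored by per-band mean, standard
   deviation, Shannon entropy and correlation with the raw image, with an
   explicit model-selection rule.
2. **Land cover and scale linkage** — a polynomial-kernel SVM (degree 2)
   labels the fine scene from ~33 field interpretation points; a 1 km
   grid frame with unique cell identities converts the fine map into
   per-cell class proportions, and cells with >70 % desertified (>90 %
   vegetation/others) fraction become **pure pixels**.
3. **NDDI reference-curve matching** — the Normalized Difference
   Desertification Index

   `NDDI = (band1 − band2) / (band1 + band2)`   (red − NIR over red + NIR)

   is computed per pixel for each of the *n* = 46 annual composites.  The
   mean trajectory over pure desertified cells, smoothed with a
   Savitzky–Golay filter, is the class reference curve; each pixel's
   **Mean Absolute Distance**

   `MAD_ij = (1/n) Σ_k |NDDI_ijk − ref_k|`

   measures how desert-like its annual dynamics are.  A **p-tile
   threshold** — the MAD quantile at a prior desertified-area fraction
   taken from survey knowledge — yields the binary desertification map,
   area totals and relative errors against survey figures.
4. **Convergent cross mapping (CCM)** — a dynamical-systems causality
   test for short annual panels (temperature, precipitation, wind speed,
   population vs. desertified area across many sites).  Lagged vectors of
   the effect variable are pooled across sites into a composite library;
   cross-map skill ρ as a function of library length, with bootstrap
   bands, and a convergence p-value `p = Pr[ρ(L_max) ≤ ρ(L_min)]` decide
   whether a driver forces the response.

Synthetic-scene and coupled-panel generators with truth manifests make
the full chain testable without any satellite downloads.

## Worked example

```python
import aeoscan as a
from aeoscan.synthetic import (SceneSpec, CoupledSystemSpec,
                               generate_scene, generate_coupled_panel,
                               generate_training_points)

scene = generate_scene(SceneSpec(n_rows=60, n_cols=60,
                                 desertified_fraction=0.3, seed=42))
train = generate_training_points(scene, n_points=33, seed=43)
svm = a.train_classifier(train, kernel_degree=2)
class_map = svm.classify_map(scene.fine_ms)

frame = a.class_proportions(class_map,
                            a.build_grid_frame(scene.fine_ms.geometry, 1000.0))
pure = a.select_pure_pixels(frame)          # >70% desertified, >90% veg/others

cube = a.build_nddi_cube(scene.coarse_series, scene.coarse_geometry)
mapper = a.DesertificationMapper(prior_fraction=0.3)
binary = mapper.fit_predict(cube, pure)
est = a.area_estimate(binary)
print(f"MAD threshold: {mapper.threshold_:.4f}")
print(f"estimated area: {est:.0f} km2   truth: {scene.truth_area_km2:.0f} km2")

panel, _ = generate_coupled_panel(CoupledSystemSpec(seed=44))
res = a.ccm_curve(panel, cause="wind_speed", effect="desertified_area",
                  n_boot=200, seed=45)
print("rho:", res.rho_mean.round(3).tolist())
print(f"convergence p-value: {res.p_value:.3f}")
```

Output:

```
MAD threshold: 0.1401
estimated area: 1080 km2   truth: 1080 km2
rho: [0.401, 0.47, 0.498, 0.508, 0.508]
convergence p-value: 0.015
```

The p-tile threshold at the true prior (0.3) recovers the desertified
area exactly on this scene, and the cross-map skill for the truly forcing
direction (wind → area in the generator) rises with library length and
converges significantly (p = 0.015).

The same chain runs from the shell:

```bash
aeoscan run --simulate --out runs/demo
aeoscan report runs/demo
```

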