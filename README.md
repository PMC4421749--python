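# filacoord

Quantitative analysis of co-assembling microtubule and actin networks in
dual-channel TIRF time-lapse movies — with a ground-truthed synthetic scene
generator for validating every stage of the pipeline.

## Who this is for

Cytoskeleton labs reconstituting microtubule/actin co-assembly *in vitro*
(tubulin + G-actin + a candidate cross-linker such as tau, or an actin-only
bundler such as fascin) and imaging both polymers live by TIRF microscopy.
The package turns the raw two-channel stacks and the companion biochemistry
(co-sedimentation binding assays, low-speed bundling assays) into the
standard readouts of cross-linking activity:

- **Co-alignment** — the percentage of the microtubule network surface
  co-localizing with F-actin, per frame and as a curve against total
  network surface: `percent = 100 · |MT ∧ actin| / |MT|`. A cross-linker
  drives this toward tens of percent; with independent networks it sits at
  chance level, i.e. near the actin coverage fraction of the field.
- **Filament curvature** — the turning-angle statistic: along a traced
  segment, points are taken 10 px apart, the absolute turning angles at
  each interior point are summed and divided by the traced length
  (degree·µm⁻¹). Straight lines score exactly 0; a circle of radius *R*
  scores `(180/π)/R`. Guided (cross-linked) actin is straightened by the
  stiff microtubule tracks; bundled free actin stays curly.
- **Elongation rates** — from kymographs (distance-along-path × time maps;
  the tip edge slope is the rate, µm/min) for filaments on fixed tracks,
  and from length-vs-time series for motile single filaments.
- **Binding affinity** — `Kd_app` from an iterative hyperbolic
  (single-site saturation) fit `y = Bmax·c/(Kd + c)` to fraction-bound
  data, with `Bmax` free or fixed; plus bundling fractions from
  pellet/supernatant densitometry and the matching nonparametric tests
  (Mann-Whitney, Kruskal-Wallis with Dunn post-hoc comparisons).

Because raw co-assembly data are rarely portable, the package ships a
first-class synthetic generator (`filacoord.synthgen`): 2-D worm-like-chain
filaments growing from their tips, tau-like zippering of actin onto
microtubule tracks, fascin-like actin-actin bundling, PSF blur and
EMCCD-style noise — all with exact per-frame ground truth, so every
measurement stage has an oracle.

## Worked example

```python
import numpy as np
from filacoord import (SceneConfig, simulate_scene, overlap_curve,
                       network_curvature, simulate_binding, fit_binding)

# Tau-like condition: actin zippers onto sparse microtubule tracks
cfg = SceneConfig(field_size_um=40, n_microtubules=3, n_actin=20,
                  zip_probability=1.0, capture_radius_um=1.5,
                  actin_persistence_um=10, duration_s=900,
                  actin_birth_time_s=200, nucleation_margin_um=6, seed=6)
gt = simulate_scene(cfg)
curve = overlap_curve(gt.mt_masks, gt.actin_masks, condition="tau-like")
print(f"co-aligned microtubule surface at scene end: "
      f"{curve.defined_percents()[-1]:.1f}%")

# Saturation-binding replicate at a 241 nM affinity, 5% noise
conc = np.array([0.05, 0.1, 0.2, 0.4, 0.6, 1.0, 1.5, 2.0, 3.0])
(rep,) = simulate_binding(kd_nM=241, bmax_pct=100, concentrations_uM=conc,
                          noise_sd_pct=5, n_replicates=1, seed=0)
fit = fit_binding(rep)
print(f"Kd_app = {fit.kd_app_nM:.0f} nM "
      f"(95% CI {fit.ci95_kd_nM[0]:.0f}-{fit.ci95_kd_nM[1]:.0f} nM)")
```

prints

```
co-aligned microtubule surface at scene end: 56.8%
Kd_app = 241 nM (95% CI 194-299 nM)
```

With zippering enabled, more than half of the microtubule surface ends up
co-aligned with actin; the identical scene with `zip_probability=0` and
`actin_bundle_probability=0.5` (a fascin-like control) ends at 2.6% —
chance level for its actin coverage. The same contrast shows in curvature:
the fascin-like scene's free actin scores a median 4.2 degree·µm⁻¹, while
actin running along microtubule tracks in the tau-like scene scores 0.25.
The binding fit recovers the generating affinity from one noisy replicate.

A thin CLI wraps the library for shell use:

```bash
filacoord simulate --config scene.yaml --out scene_dir --seed 7
filacoord quantify --mt scene_dir/microtubule.tif \
                   --actin scene_dir/actin.tif --out results_dir
filacoord simulate-binding --kd-nm 241 \
                   --concentrations-um 0.05,0.1,0.2,0.4,0.8,1.6,3.2 \
                   --out binding.csv
filacoord fit-binding --data binding.csv
```

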