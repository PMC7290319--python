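# lumenquant

Quantitative shape and contrast-enhancement analysis of dissected aortas on
CT angiography.

In a Stanford type B (DeBakey IIIb) aortic dissection, an intimal tear splits
the descending aorta into a *true lumen* (the original channel, typically
small and weakly enhanced) and a *false lumen* (the new channel, typically
large and strongly enhanced), separated by a dark intimal flap; proximal and
distal to the dissected segment the two channels rejoin into the single
*common duct*. Because the contrast agent concentration tracks blood flow,
the per-channel enhancement pattern carries hemodynamic information that
diameter measurements alone miss. `lumenquant` is for researchers in
vascular image analysis who want those per-cross-section measurements —
diameters, areas, brightness, image-quality ratios, and the agreement and
difference statistics built on them — as reproducible, scriptable code, with
a synthetic dissection phantom for validation.

## What it computes

For every axial slice and every duct present on it (masks come from seeded
region growing with hole filling; ducts are labeled common/true/false):

- **Feret diameter** — the mean of the maximal vertical and horizontal
  extents of the cross-section mask:

  D_F = (D_v + D_h) / 2  [mm]

- **Hydraulic diameter** — the fluid-mechanics effective diameter from the
  flow cross-section area P and wetted perimeter A:

  D_Hy = 4·P / A  [mm]

- **Average brightness** — the mean raw pixel value over the duct mask, a
  surrogate for contrast-agent concentration:

  B_AV = Σ B_i / N_pixels  [pixel]

- **Normalized inter-duct differences** per slice, for brightness and both
  diameters of a duct pair (i, j):

  Dif(x) = |x_i − x_j| / max(x_i, x_j)  ∈ [0, 1]

- **Image quality** — brightness-to-noise BI = B̄/σ_noise and
  contrast-to-noise CNR = (B̄ − B̄_background)/σ_noise, with σ_noise pooled
  from two 100 mm² background regions outside the body and lumen brightness
  from 80 mm² centered regions of interest.

- **Agreement statistics** — Bland–Altman bias and 1.96·SD limits of
  agreement between D_F and D_Hy per duct (plus Spearman rank correlation
  and Mann–Whitney U tests), and cross-patient duct brightness gaps
  |B̄_i − B̄_j| summarized as mean ± SD over patients.

The bundled phantom generates an axial stack in which a bright disk-shaped
common duct splits, over a configurable slice range, into a wall-hugging
true-lumen disk and a crescent-shaped false lumen wrapping it, separated by
a dark flap, with configurable per-region enhancement and additive Gaussian
noise — and returns voxel-exact ground-truth labels alongside.

## Worked example

```python
from lumenquant import PhantomConfig, PipelineConfig, run_pipeline

config = PipelineConfig(phantom=PhantomConfig(seed=17))
bundle = run_pipeline(config)

for duct in ("common", "true", "false"):
    s = bundle.summaries[duct]
    print(f"{duct:6s}  D_F {s['D_F']['mean']:6.2f} mm   "
          f"D_Hy {s['D_Hy']['mean']:6.2f} mm   "
          f"B_AV {s['B_AV']['mean']:6.2f} ± {s['B_AV']['sd']:.2f} px")
for event in bundle.transitions:
    print(f"{event['kind']} at slice {event['slice_index']}: "
          f"before {event['brightness_before']}, after {event['brightness_after']}")
```

prints

```
common  D_F  29.64 mm   D_Hy  29.94 mm   B_AV 179.96 ± 0.30 px
true    D_F  13.65 mm   D_Hy  13.50 mm   B_AV 150.28 ± 0.66 px
false   D_F  28.08 mm   D_Hy  17.64 mm   B_AV 200.11 ± 0.33 px
split at slice 40: before {'common': 180.31...}, after {'true': 150.44..., 'false': 199.53...}
merge at slice 100: before {'true': 150.93..., 'false': 200.24...}, after {'common': 179.45...}
```

Reading the numbers: the default phantom's common duct is a 30 mm disk, so
D_F and D_Hy agree near 30 mm (for a circle the two definitions coincide);
the true lumen is a 13.5 mm disk; the false lumen's crescent shape drives
its hydraulic diameter (17.6 mm) far below its Feret diameter (28.1 mm) —
exactly the shape-sensitivity that makes D_Hy informative for non-circular
channels. At the split the single ~180 px common-duct brightness separates
into a dim true lumen (~150 px) and a bright false lumen (~200 px),
recovering the configured enhancement ordering; at the merge the ordering
runs in reverse.

The same run from a shell:

```sh
lumenquant run --seed 17 --out report/
```

writes `measurements.csv` (one row per slice and duct), per-duct summary
and Bland–Altman JSON, the normalized difference series, split/merge
transition events, BI/CNR quality metrics, the ground-truth comparison
(Dice, relative errors) and a parameter log. `lumenquant phantom`,
`segment`, `measure`, `compare`, `stats` and `quality` expose the
individual stages for file-based workflows.

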