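# lvfractal

Quantifying left-ventricular (LV) trabeculation on cardiovascular MR
short-axis cine stacks by **box-counting fractal analysis**, for
researchers evaluating LV noncompaction (LVNC) diagnostics.

LVNC presents as prominent trabeculation, deep intertrabecular recesses
and a thin compacted myocardial layer. Ratio-based criteria (the
diastolic noncompacted/compacted layer-thickness ratio, or the
trabecular mass fraction) are reader-dependent and struggle with
borderline cases. The fractal dimension (FD) of the trabeculated
endocardial border summarizes its complexity in one unitless index: a
planar curve has 1 < FD < 2, and trabeculation pushes FD upward.

## What the package computes

For each end-diastolic short-axis slice, the trabeculated endocardial
border is delineated by a two-phase region-based (Chan–Vese style)
level set inside a region of interest around the blood pool, and the FD
of the one-pixel border is estimated by box counting:

```
N(s) ~ s^(-FD)   =>   FD = slope of log N(s) vs log(1/s)
```

over a geometric schedule of box sizes `s` (ratio 2^(1/4), from 2 px to
45 % of the border's bounding box), with counts minimized over a 3×3
grid of sub-cell grid phases. Per-stack summaries follow the standard
conventions:

* **global FD** — mean per-slice FD over included slices,
* **maximum FD** — largest single-slice FD,
* **per-third maxima** — maxima within the basal / mid / apical thirds,

with the most apical slice always excluded (partial-volume artefact).
The layer-ratio criterion (LVNC if ≥ 2.3; hyper-trabeculated if
≥ 1.8 and < 2.3) and the mass-fraction criterion (LVNC if > 20 %) are
implemented alongside, plus the full agreement battery: ICC(2,1),
Bland–Altman limits, Fleiss' kappa, ROC/Youden and exact binomial CIs.

No patient data are required: a phantom generator synthesizes SSFP-like
short-axis stacks (bright blood, dark myocardium, 1.8 mm pixels, 8 mm
slices + 2 mm gap) whose endocardial roughness is a controlled,
seeded variable, with per-group presets (`lvnc`, `hypertrabeculated`,
`normal`) that reproduce the group orderings reported for real cohorts.

## Worked example

```python
from lvfractal import profile_for_group, generate_cine_stack
from lvfractal import auto_roi, segment_slice, analyze_stack

stack, truth = generate_cine_stack(profile_for_group("lvnc", seed=3))
segs = [
    segment_slice(img, auto_roi(img, stack.pixel_spacing_mm), stack.pixel_spacing_mm)
    for img in stack.slices
]
result = analyze_stack(segs)
print(f"global FD {result.global_fd:.3f}  max FD {result.max_fd:.3f}")
print({k: round(v, 3) for k, v in result.third_max_fd.items()})
```

prints

```
global FD 1.280  max FD 1.363
{'basal': 1.274, 'mid': 1.347, 'apical': 1.363}
```

— a noncompaction-preset phantom: high global FD, and the per-third
maximum located apically (trabeculation increasing toward the apex),
the pattern that distinguishes LVNC stacks from hyper-trabeculated and
normal ones, whose FD peaks mid-ventricle.

The same pipeline runs from the shell:

```bash
lvfract phantom --group lvnc --seed 3 --out out/
lvfract analyze --input out/lvnc-00003.nii.gz --out out/subject.json
lvfract repro --n 5 --seed 1 --out out/agreement.json
```

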