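# powerseg

Robust two-phase segmentation of noisy grayscale images with a power-mean
data term and fuzzy memberships — plus re-implemented classical baselines
(piecewise-constant CV, fuzzy-energy FEBM), Jaccard/Dice evaluation, and a
seeded synthetic phantom generator for end-to-end validation.

## The problem

Region-based variational segmentation fits each region with a representative
intensity by least squares, and least squares is exactly what breaks on
speckled ultrasound-like images and impulse outliers: squared residuals hand
the outliers the loudest vote.  `powerseg` replaces the least-squares data
term with a concave power of the squared residual.  The model minimizes

```
F(z, c1, c2) = μ ∫ |∇z| + ∫ α (u − c1)² z^m + ∫ β (u − c2)² (1 − z)^m,
α = ((u − c1)²)^(p−1),   β = ((u − c2)²)^(p−1),   0 < p ≤ 1,
```

over a fuzzy membership `z ∈ [0,1]` and intensities `c1, c2`.  Since
`α (u − c1)² = ((u − c1)²)^p`, pixels far from a region's representative are
down-weighted — the segmentation analogue of the *generalized sample mean*
`argmin_a Σ ((u_i − a)²)^p`, a robust location estimate solved by an
iteratively reweighted fixed point.  For `m = 2` the membership has the
closed form `z = d2^p / (d1^p + d2^p)`; `p = 1` recovers the classical fuzzy
energy model exactly.  Intended users: people studying or benchmarking
region-based segmentation of noisy biological/medical images.

## Worked example

```python
from powerseg import ModelParams, dice, jaccard, realize, segment, three_object_spec

image, truth = realize(three_object_spec(seed=0))   # disk+rectangle+ring, speckle 0.2
result = segment(image, ModelParams(), ground_truth=truth)
print(result.iterations, result.converged)
print(round(result.centers.c2, 3))
print(round(jaccard(result.mask, truth), 4), round(dice(result.mask, truth), 4))
```

prints

```
71 True
0.21
0.7514 0.8581
```

i.e. the solver converged in 71 alternating iterations, recovered the
background intensity 0.21 (truth 0.2), and the thresholded membership
overlaps the ground-truth objects with Jaccard 0.75 / Dice 0.86 under
variance-0.2 multiplicative speckle — noise heavy enough that ~25% of
foreground pixels are individually closer to the background intensity (see
`docs/methods.md` for what bounds accuracy in this regime).  On noiseless
or mildly noisy phantoms the same call recovers the objects exactly
(Jaccard 1.0).  The scripts in `examples/` walk through robust location
estimation, segmentation, baseline comparison and initialization
independence.

## Command line

```bash
powerseg simulate --spec spec.yaml --seed 0 --out-image img.png --out-truth truth.png
powerseg segment  --input img.png --model proposed --p 0.5 --mu 0.7 --sigma 3 \
                  --out mask.png --trace-out energy.csv
powerseg evaluate --pred mask.png --truth truth.png --report report.json
```

`segment` also accepts `--model cv|febm`, `--solver time_marching`, the
initialization modes `half_plane|disk|random|constant`, and a YAML config
file (`--config`) that command-line flags override.

## Layout

- `src/powerseg/powermean.py` — power mean, robust objective, MM fixed point
- `src/powerseg/model.py` — energy, closed-form/time-marching solvers, `segment`
- `src/powerseg/baselines.py` — CV and FEBM reference models
- `src/powerseg/metrics.py` — Jaccard and Dice
- `src/powerseg/phantom.py` — seeded phantoms: speckle/Gaussian/salt-pepper noise, bias fields
- `src/powerseg/image_io.py`, `src/powerseg/cli.py` — image/mask IO and the CLI
- `docs/methods.md` — model, discretization, design choices, honest limits
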