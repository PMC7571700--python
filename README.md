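# meioquant

Quantification of cortical membrane furrowing and fluorescence dynamics in
live-imaged oocytes during meiosis I.

During anaphase of oocyte meiosis I, transient furrow-like membrane
ingressions appear around the whole cortex while the contractile ring pinches
off the first polar body. Comparing how much a genotype furrows — and how its
spindle and cortical proteins behave while it does — requires turning
multi-channel time-lapse movies into a handful of numbers per oocyte. This
package implements that quantification chain as a tested, reusable library
for anyone analyzing cortical dynamics in time-lapse microscopy of
near-convex cells:

- **Membrane contour pipeline** — segment the membrane channel at a single
  central z-plane, trace the cell boundary with sub-pixel precision (ridge
  refinement onto the membrane tube), resample it to N points equally spaced
  in arc length with a stable angular index across frames, and estimate the
  signed curvature κ(s, t) per membrane point.
- **Furrow statistic** — for each membrane point, the temporal mean μ_i and
  standard deviation σ_i of curvature over the furrowing window. A furrow is
  at least two consecutive points with μ_i < 0 and σ_i at least two standard
  deviations above the cortex-average SD; qualifying runs separated by a
  single non-qualifying point merge into one furrow, on a circular index.
- **Fluorescence metrics** — total spindle intensity
  (mean_spindle / mean_cyto) × spindle ROI area, spindle-to-cytoplasm ratio
  time courses on the t = 0 = end-of-meiosis-I convention, and Otsu/Li
  stack-histogram threshold area fractions for cortical patch coverage.
- **Statistics** — one-way ANOVA across genotypes, variance F-tests, and
  two-tailed t-tests whose pooled/Welch variant is gated by the F-test.
- **Synthetic oocyte generator** — contour series and rendered two-channel
  movies (membrane tube + chromatin/spindle channel, Poisson + read noise)
  with exact ground truth for furrow count/position, patch area fraction,
  and intensities, used throughout the test suite.

## Worked example

```python
import numpy as np
import meioquant as mq

# a synthetic oocyte with 4 furrows, imaged every 10 s for 360 s
params = mq.SynthParams(n_furrows=4)
series, truth = mq.generate_contour_series(params, seed=11)
result = mq.count_furrows(series, oocyte_id="synthetic-oocyte")

print(f"{result.oocyte_id}: {result.furrow_count} cortical furrows")
for call in result.calls:
    print(f"  furrow at {call.location_deg:6.1f} deg, "
          f"{call.n_points} membrane points, "
          f"min mean curvature {call.min_mu:+.3f} 1/um")
print("ground truth angles:",
      sorted(round(float(np.degrees(t)), 1) for t, _, _ in truth.furrows))

control = mq.GroupData("control", np.array([5., 6, 4, 5, 7, 5, 6, 4]))
mutant = mq.GroupData("mutant", np.array([2., 1, 3, 2, 2, 0, 1, 2]))
report = mq.compare_groups([control, mutant])
pair = report.pairs[0]
print(f"ANOVA F = {report.anova_F:.2f}, p = {report.anova_p:.2g}; "
      f"{pair.variant} t-test p = {pair.t_p:.2g}")
```

prints

```
synthetic-oocyte: 4 cortical furrows
  furrow at   13.9 deg, 4 membrane points, min mean curvature -0.196 1/um
  furrow at   53.5 deg, 5 membrane points, min mean curvature -0.237 1/um
  furrow at  113.5 deg, 6 membrane points, min mean curvature -0.300 1/um
  furrow at  211.2 deg, 5 membrane points, min mean curvature -0.210 1/um
ground truth angles: [13.6, 53.3, 114.0, 210.3]
ANOVA F = 55.02, p = 3.3e-06; pooled t-test p = 3.3e-06
```

The four detected furrows land within ~1° of where the generator put them,
and the two synthetic genotypes differ significantly with the pooled-variance
t-test selected because the F-test found no variance difference.

The same statistic runs on rendered movies through the imaging path:

```python
stack, render_truth = mq.render_movie(series, params, seed=11)   # TIFF-ready
est = mq.extract_contour_series(stack, "membrane")               # segment
mq.count_furrows(est).furrow_count                               # -> 4
```

A thin CLI wraps the same functions: `meioquant simulate | segment |
furrows | compare` (see `meioquant --help`).

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline end to end from a seed:
synthetic two-genotype furrow counting with the full ANOVA/F-test/t-test
report, one rendered movie pushed through segmentation → curvature → furrow
count with spindle-ratio extraction, and Otsu/Li patch area fractions against
generator truth. It writes the target report JSON to `--out` and a
human-readable summary alongside it:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
| --- | --- |
| `meioquant.imaging_io` | TIFF stacks, projections, spindle-plane selection, CSV/JSON output |
| `meioquant.synthetic` | synthetic contour series, movie renderer, patchy cortex |
| `meioquant.contour` | segmentation, sub-pixel contours, arc-length resampling, curvature |
| `meioquant.furrows` | furrow qualification/merging/counting, temporal overlays |
| `meioquant.fluorescence` | mean grey, spindle intensity, ratios, Otsu/Li patch fractions |
| `meioquant.stats` | ANOVA, variance F-tests, F-test-gated t-tests |

See `docs/methods.md` for the model, parameter defaults, and the reasoning
behind the threshold-rule reading and synthetic-world choices.
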