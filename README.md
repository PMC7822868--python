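# chromascene

Information-theoretic analysis of how many surfaces in a scene an
observer can distinguish — and, across an interval of changing
illumination, still identify — by colour alone.

## Background

Surface colour is a powerful cue for telling materials apart, but it is
not fixed: the light falling on an outdoor scene fluctuates from minute
to minute, both in its spatial distribution (moving shadows, clouds —
*geometric* change) and in its spectral composition (the daylight locus
— *spectral* change). A colour signal that identified a surface a
moment ago may later be indistinguishable from the signal of a
different surface.

This package quantifies that limit. Scene surfaces are represented by
the colour coordinates of their reflected radiance — CIECAM02
lightness/red–green/yellow–blue correlates (J, aC, bC) or spatially
filtered S-CIELAB coordinates — and an observer's colour response is
the coordinate vector perturbed by threshold-matched noise. The mutual
information between responses at two instants,

```
I(A; B) = h(A) + h(B) − h(A, B),
```

estimated with a Kozachenko–Leonenko k-nearest-neighbour entropy
estimator, bounds the average number of surfaces separable by colour:

```
N = 2^I.
```

With both instants coincident, N counts *distinguishable* surfaces;
across a time interval containing an illumination change, N counts
*identifiable* surfaces. On scenes with fluctuating illumination N
declines approximately linearly in log N vs log Δt, so a few reference
intervals (2, 10, 60 min) summarise the decay.

The package includes:

- hyperspectral radiance cube I/O (ENVI, HDF5, flat binary + JSON
  sidecar) with validation and pixel sampling (`chromascene.io`);
- cone excitations, von Kries scaling, CIELAB, a full CIECAM02 forward
  transform, S-CIELAB opponent-channel spatial filtering, and CIE
  daylight-series illuminants parameterised by correlated colour
  temperature (`chromascene.colorimetry`);
- k-NN differential entropy and mutual information with
  threshold-matched observer noise (`chromascene.information`);
- a synthetic scene generator — spatially correlated reflectance
  fields, optional discrete palettes with known ground truth, and
  interval-dependent multiplicative gain fields emulating geometric
  illumination change (`chromascene.synthetic`);
- surface-count analyses, log–log time-course regression, strip-wise
  colour-difference profiles, a successive-difference (residual) SD
  estimator for irradiance time series, and BCa bootstrap aggregation
  across scenes (`chromascene.analysis`);
- an orchestration layer and CLI with seeded, manifest-checked runs
  (`chromascene.pipeline`, `chromascene.cli`).

## Worked example

Three synthetic 96×96 scenes under 6500 K daylight, 4000 pixels per
scene, CIECAM02 coordinates, a 0.5 ΔE discrimination threshold, and a
gain field whose amplitude grows with the interval between views:

```python
import numpy as np
from chromascene.pipeline import RunConfig, run_distinguishability, run_identifiability
from chromascene.synthetic import SceneConfig

cfg = RunConfig(
    scene=SceneConfig(width=96, height=96),
    n_scenes=3, n_pixels=4000, seed=1,
    intervals=(1.0, 2.0, 5.0, 15.0, 60.0, 240.0),
)
agg, table = run_distinguishability(cfg)
print(f"distinguishable surfaces: {agg.mean_n:.0f} "
      f"(95% CI {agg.ci_low:.0f}-{agg.ci_high:.0f}, {agg.n_scenes} scenes)")

aggs, fits, _ = run_identifiability(cfg)
slope = np.mean([f.slope for f in fits.values()])
print(f"time-course slope (log2 N vs log2 dt): {slope:.3f}")
for dt in (2.0, 10.0, 60.0):
    print(f"identifiable after {dt:>4.0f} min: {aggs[dt].mean_n:.0f}")
```

Output:

```
distinguishable surfaces: 584 (95% CI 577-588, 3 scenes)
time-course slope (log2 N vs log2 dt): -0.289
identifiable after    2 min: 306
identifiable after   10 min: 192
identifiable after   60 min: 115
```

Around 580 surfaces in these synthetic scenes are distinguishable by
colour at a single instant; after an hour of simulated illumination
change only ~115 remain identifiable, with the count falling roughly
as a power law in the interval.

The same analyses are available from the command line:

```sh
chromascene simulate --seed 3 --width 96 --height 96 --out scene.h5
chromascene cubeinfo scene.h5
chromascene distinguish --seed 1 --outdir out/
chromascene identify --seed 1 --outdir out/
chromascene spectral-control --seed 1 --outdir out/
```

Each run writes tidy TSV tables, a JSON summary, and a `MANIFEST.json`
with SHA-256 checksums and the configuration hash.

## Testing

```sh
python -m pytest -q tests/
```

The suite checks the estimators against closed-form oracles (uniform
and Gaussian entropies, the correlated-Gaussian mutual-information
formula, discrete-palette scenes with known label information), the
CIECAM02 transform against its published worked example, daylight
spectra against the chromaticity locus, and structural identities such
as the exact equality of identifiability at zero interval with
distinguishability.

## Reproduction

The headline quantities are reproduced by the seeded acceptance
script, which writes a JSON report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; repeated runs with the same seed
are bit-identical, and nearby seeds give statistically consistent
values. See `docs/methods.md` for the model, parameter choices, and
numerical details.
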