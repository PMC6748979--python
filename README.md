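# vesselmink

Morphometry of 3D capillary networks from confocal z-stacks, built around the
four 3D **Minkowski functionals**: volume V, surface area S, mean breadth b̄
(the integral of mean curvature / 2π, related to tortuosity and resistance to
flow) and the Euler number χ (components − tunnels + cavities, which counts
vascular loops/collaterals as negative contributions).

The package is for researchers quantifying microvascular architecture — for
example the radial peri-papillary capillary plexus of the retina — who need
measures of *higher-order* structure (loops, tortuosity, calibre scaling)
rather than just vessel density, and who want those measures to be additive
so that averages across samples are well defined.

The analysis runs in two stages:

1. **Tubular-model conversion** — an adaptive structure filter turns a noisy
   fluorescence z-stack into a binary vessel model: multi-scale Hessian
   vesselness (scales bootstrapped from a local-thickness calibre estimate),
   point-wise maximum of the log scores across calibres, Otsu binarisation,
   then outlier elimination in voxel values and cluster sizes.
2. **Dilation analysis** — the vessel set is inflated via its exact Euclidean
   distance transform; the four functionals evaluated at each radius give
   four *signatures* per sample; ten summary features per signature
   (moments and critical points) give a fixed 40-feature vector; cohorts are
   analysed by PCA, age-group ANOVA (Bonferroni) and bootstrapped stepwise
   regression with selection-frequency reporting.

A synthetic-phantom module generates tubular networks with known component
and loop counts, calibres and tortuosity, plus confocal-like rendering
(anisotropic PSF, noise, speckle, autofluorescence background), so every
stage is testable against ground truth. See `docs/methods.md` for the model
details and conventions.

## Worked example

Measure a solid torus (one loop) and a two-component network phantom:

```python
import numpy as np
from vesselmink.phantoms import make_torus, make_network, NetworkSpec
from vesselmink.minkowski import minkowski_3d
from vesselmink.signatures import signature, extract_features

mf = minkowski_3d(make_torus(8, 3, (13, 27, 27)))
print(mf.volume, round(mf.surface_area, 1), round(mf.mean_breadth, 2), mf.euler)
# 1348.0 922.9 24.0 0

vol, truth = make_network(NetworkSpec(n_components=2, n_loops=3, seed=5,
                                      grid_shape=(96, 96, 96)))
sig = signature(vol, np.arange(0, 8, dtype=float))
print(sig.curve("euler3D")[:4])   # [-1. -1. -1. -1.]
fv = extract_features(sig)
print(round(fv["euler3D_mean"], 3), fv["vol_maxScale"])
# -1.0 7.0
```

The torus volume is its voxel count (1348); the Crofton surface estimate is
within ~3% of the analytic 4π²Rr ≈ 947.5 at this coarse digitization, and
the mean breadth (ball-diameter normalization) within ~5% of πR ≈ 25.1;
χ = 0 because one component minus one tunnel. The network's Euler signature
starts at 2 − 3 = −1 (two components, three loops) and stays there across
these dilations because disjoint structures are placed with guaranteed
clearance; `euler3D_mean` averages the curve over the dilation range, and
`vol_maxScale` is the radius at which the volume curve peaks (here the last
radius, since dilation volume is non-decreasing).

From the shell, the same pipeline runs as:

```bash
vesselmink phantom --kind network --out net.tif --seed 5 --render
vesselmink segment --in net_stack.tif --out mask.tif --scales auto
vesselmink thickness --in mask.tif --out thick.tif --stats calibre.csv
vesselmink signature --in mask.tif --rmax 12 --out sig.csv
vesselmink features --in sig.csv --out features.csv
vesselmink run-cohort --manifest manifest.csv --out results/ --seed 1
```

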