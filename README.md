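# fractal3d

Correlation-dimension (D₂) analysis of segmented 3D brain structures.

Structural complexity of a brain structure — how convoluted its surface
and interior are across spatial scales — can be summarized by a fractal
dimension.  `fractal3d` implements the probabilistic box-counting variant
used in volumetric neuroimaging: a binary mask (e.g. a FreeSurfer `aseg`
cerebellar-cortex label) is covered with grids of cubes of edge *r*, each
cube *i* carries probability mass *pᵢ = Nᵢ(r)/N_all*, and the correlation
sum

    C(r) = Σᵢ pᵢ²

scales as *r*^D₂ over the linear portion of the log-log plot.  D₂ is the
slope of ln C(r) vs ln r, fitted over the contiguous box-size range that
maximizes R² (the "breakpoint" fit), with the grid re-counted at 20 random
offsets per box size and the median C(r) kept.  The package is aimed at
researchers comparing structural complexity between groups: it bundles the
estimator with exact validation phantoms (Menger sponge), parametric
rough-shell surrogates, synthetic case/control cohorts, and the
accompanying nonparametric statistics (Mann-Whitney U with Bonferroni
correction, Cohen's U3 with bootstrap CI, partial Spearman correlations
controlling for age).

See `docs/methods.md` for the model, parameter defaults and design
choices.

## Worked example

Estimate the dimension of the classic validation phantom — a 5-iteration
Menger sponge voxelized at 486³ with 2-voxel holes:

```python
import fractal3d as f3

vol = f3.generate_menger(f3.MengerSpec(iterations=5, cell_scale=2))
res = f3.estimate_fd(vol, f3.FDParams(offset_seed=17))
print(f"theoretical FD : {f3.menger_theoretical_fd():.6f}")
print(f"estimated FD   : {res.fd:.4f}")
print(f"fitted range   : r = {res.r_min_used} .. {res.r_max_used} "
      f"({res.n_points_used} box sizes, breakpoint {res.breakpoint})")
print(f"fit quality    : R^2 = {res.r_squared:.5f}, RMSE = {res.rmse:.4f}")
```

prints

```
theoretical FD : 2.726833
estimated FD   : 2.6819
fitted range   : r = 3 .. 29 (27 box sizes, breakpoint 3)
fit quality    : R^2 = 0.99998, RMSE = 0.0082
```

The theoretical value is the sponge's similarity dimension ln 20 / ln 3
(20 of 27 subcubes kept at scale factor 3).  The empirical estimate sits a
few hundredths below it — the expected finite-size behavior of box
counting on an exactly self-similar, strongly lacunar set — with an almost
perfectly linear fit over the selected scaling range.

The same estimator applied to a segmentation is two calls:

```python
from fractal3d import read_labeled, extract_mask, crop_and_center, estimate_fd

aseg = read_labeled("aseg.mgz")
right_cereb = crop_and_center(extract_mask(aseg, {47}))  # right cerebellar cortex
result = estimate_fd(right_cereb)
```

A full group analysis (per-subject FD per hemisphere, Mann-Whitney with
Bonferroni over hemispheres, U3, R²/RMSE and volume checks, PIQ>VIQ
Spearman analysis) runs from a YAML config on the command line:

```sh
fractal3d compare --config analysis.yaml
```

and synthetic inputs for all of the above come from the phantom and cohort
generators (`fractal3d phantom menger|shell`, `fractal3d cohort`).

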