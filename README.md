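# chla3d

Three-dimensional spatial interpolation of chlorophyll-a (Chl-a) for
coastal seas, with cross-validated method comparison and regional
ecological indicators.

## The problem

Ship surveys measure Chl-a (μg/L, the standard proxy for phytoplankton
biomass) at scattered stations and a few depths; assessing a sea area —
total standing amounts per sub-region, bloom-area extent — needs a complete
3D concentration field. `chla3d` reconstructs that field from station
tables and is aimed at marine-ecology and water-quality analysts working
with survey data from shallow shelf seas such as the Bohai Sea.

Two features of such data drive the design:

* Chl-a spans more than two orders of magnitude, so fitting happens on
  log10 concentrations and predictions are back-transformed (always > 0).
* Vertical change rates far exceed horizontal ones. All interpolation is
  done in **work coordinates**: horizontal position is Miller-projected
  with radian-scale (order-1) coordinates, and depth is rescaled as
  z′ = depth/1000, which places the per-axis change rates on a comparable
  footing before any Euclidean distance is computed.

## Methods

**Augmented RBF interpolation.** With stations p_i = (x_i, y_i, z_i′) and
D′_i = log10 C_i, the interpolant is

    D̃′(q) = Σ_i β_i φ(‖q − p_i‖) + λ₁ + λ₂x + λ₃y + λ₄z

where the coefficients solve the symmetric block system

    [ A  P ] [β]   [D′]
    [ Pᵀ 0 ] [λ] = [0 ],   A_ij = φ(d_ij),  P = [1, x, y, z].

The orthogonality rows Pᵀβ = 0 make the interpolant reproduce any field
affine in the work coordinates exactly. Kernels: linear φ(d) = d, gaussian
φ(d) = exp(−d²/2ε²), multiquadric φ(d) = √(1 + d²/ε²); ε = 0.1 (work
units) by default.

**Inverse distance weighting.** D̃(q) = Σ_i C_i d_i^{−α} / Σ_i d_i^{−α}
with α = 3, on raw concentrations; queries within 10⁻¹² work units of a
station snap to its observation.

**Evaluation.** Paired ten-fold cross-validation (records permuted once,
fold k = every 10th record starting at k), scored by MAE and MRE on
back-transformed concentrations and Pearson r between log10 estimates and
log10 observations.

**Indicators.** Per-layer regional totals by two routes — areal
integration of the gridded field (Σ concentration × cell area, μg·L⁻¹·km²)
and mean station concentration × region area — plus bloom area: summed
area of cells strictly above 10 μg/L.

Because real survey data of this kind are typically not public, the
package includes a synthetic generator (`chla3d.synthetic`) producing
truth fields with coastal/estuary enhancement, vertical decay and
lognormal noise, and survey samples with realistic per-layer counts
(368 surface / 99 middle / 13 bottom by default).

## Worked example

```python
from chla3d import scenario_paperlike, cross_validate

stations, truth = scenario_paperlike(seed=1)   # 480-station synthetic survey
report = cross_validate(stations, methods=("rbf-linear", "idw"), seed=1)
print(report.summary())
```

```
Ten-fold cross-validation
==============================================================================
records: 480   seed: 1
method               MAE med  MAE mean   MRE med   r(log)   slope
------------------------------------------------------------------------------
rbf-linear            0.3180    0.3273    0.2380    0.954   0.901
idw                   0.5237    0.5214    0.7564    0.828   0.601
```

The linear-kernel RBF halves the median fold MAE relative to IDW on this
scenario, its log-log correlation with the held-out observations is 0.954,
and its regression slope (0.90) is closer to the ideal 1 than IDW's (0.60)
— IDW's convex weighting pulls estimates toward the local mean, flattening
the slope. Gridding and indicators:

```python
from chla3d import make_grid, interpolate_field
from chla3d.indicators import default_bohai_regions, indicator_table

grid = make_grid(resolution_deg=0.1)               # 117–123°E, 37–41°N box
field = interpolate_field(stations, grid, "rbf-linear")
table = indicator_table(field, default_bohai_regions(grid), stations=stations)
```

The same pipeline is scriptable from the shell:

```sh
chla3d simulate --seed 1 --out-dir run/
chla3d crossval run/stations.csv
chla3d interpolate run/stations.csv --out run/field.nc
chla3d indicators run/field.nc --stations run/stations.csv
```

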