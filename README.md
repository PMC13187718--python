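# vorogrow

Simulation and analysis of geometric ordering in bacterial communities:
radial colony expansion with collision-induced arrest, the Voronoi
tessellations it converges to, and the image-similarity and inference
tooling needed to compare simulated partitions against (pseudo-)
experimental colony masks.

## The model

Bacterial populations inoculated at fixed points on a soft agar surface (or
at an air–liquid interface, or inside a host gut) expand radially at a
roughly constant front speed until their boundary meets another population,
where both fronts arrest and leave a low-cell-density linear interface.
`vorogrow` implements this **radial growth model (RGM)** as competing
first-arrival propagation on a 2D or 3D grid: colony *i*, seeded at *cᵢ*
with rate *vᵢ* (mm/h), claims cells in increasing arrival time

  Tᵢ(x) = (shortest path length from cᵢ through empty or own territory) / vᵢ ,

a claimed cell is never relabelled (contact inhibition), cells beyond the
arena wall are unclaimable, and simultaneous arrivals go to the lowest
label. With equal rates the claimed partition converges to the classical
Voronoi tessellation of the seeds — cell boundaries on the perpendicular
bisectors between neighbouring seeds. With unequal rates the interface near
the seeds follows the multiplicatively weighted (Apollonius) boundary
|x−c₁|/v₁ = |x−c₂|/v₂, and a fast colony engulfs a slow neighbour by
wrapping around it along near-geodesic paths.

The package provides:

- `simulate_rgm`, `snapshot`, `colony_mask` — the growth model on disk /
  rectangle (2D) and sphere / box (3D) arenas, with an optional interface
  band of width `dmin` carved between collided colonies;
- `voronoi_2d`, `voronoi_label_grid`, `weighted_arrival_label_grid`,
  `region_hulls_3d` — reference partitions built independently of the
  simulation (polygon diagrams, nearest-seed grids, Apollonius grids,
  convex hulls of 3D regions);
- `jaccard`, `chamfer_mean`, `pearson_binary`, `agreement_map`,
  `multilabel_report` — binary-mask similarity with area-weighted
  aggregates, as used to score simulations against segmented images;
- `TimelapseGrowthModel(...).fit()` — seeding-centre and growth-rate
  inference from label-field time-lapses, with `resimulate()` and
  `score()` to close the loop (reconstruction workflow);
- `make_arrangement`, `render_pseudo_experiment`, `make_timelapse` —
  seeding presets (triangle/square/cross/hexagon/annulus/disordered/cube)
  and fully seeded synthetic "experiments" with rough boundaries, interface
  gaps and speckle, retaining ground truth;
- PNG/TIFF + JSON-sidecar I/O and a `vorogrow` command line
  (`simulate`, `voronoi`, `compare`, `fit`, `synth`).

## Worked example

Three colonies seeded 40 mm apart in a triangle on a 45 mm dish, grown to
confluence and compared against the nearest-seed partition of the same
seeds:

```python
import vorogrow as vg

arena = vg.Arena(dim=2, shape="disk", extent=45.0, resolution=0.18)
config = vg.make_arrangement("triangle", spacing=40.0)
labels, arrivals = vg.simulate_rgm(
    config, arena, vg.SimParams(t_max=110.0, stencil_order=5)
)

oracle = vg.voronoi_label_grid(
    arena.index_to_world(arena.world_to_index(config.positions)), arena
)
claimed = labels.grid > 0
report = vg.multilabel_report(
    {k: (oracle.grid == k) & claimed for k in config.labels},
    {k: (labels.grid == k) & claimed for k in config.labels},
    resolution=arena.resolution,
)
print(report.to_frame().to_string(index=False))
```

```
   label  jaccard  chamfer_mm  pearson  area_cells
       1 0.998398    0.021194 0.998914       65526
       2 0.999176    0.010318 0.999441       65480
       3 0.999220    0.009655 0.999472       65358
weighted 0.998931    0.013727 0.999276      196364
```

Per-colony Jaccard ≈ 0.999 and mean Chamfer distance ≈ 0.01–0.02 mm: the
grown partition is the Voronoi tessellation to within a tenth of a cell.
Rates and centres can be read back off a noisy time-lapse (boundary
roughness 0.5 mm) of two colonies with a 1.5 : 1 rate contrast:

```python
tl = vg.make_timelapse(
    config=vg.SeedConfig(positions=[[-8.0, 0.0], [8.0, 2.0]], rates=[1.5, 1.0]),
    arena=vg.Arena(2, "disk", 30.0, 0.2),
    times=[1, 2, 3, 4, 5, 6],
    params=vg.SynthParams(boundary_sigma=0.5, rng_seed=1),
)
fit = vg.TimelapseGrowthModel(
    tl.frames, tl.times, resolution=0.2, origin=tl.arena.origin, arena=tl.arena
).fit()
print(fit.summary())
```

```
Radial growth fit
  frames: 6  span: 1-6 h  resolution: 0.2 mm/cell
 label  center_x  center_y  rate_mm_per_h  intercept_mm  rms_residual_mm  n_frames  first_frame
     1    -7.872    0.3497          1.503      -0.06379          0.01605         6            0
     2     8.185     1.423          0.966        0.1408          0.05731         6            0
```

The fitted rates (1.50 and 0.97 mm/h against the configured 1.5 and 1.0)
come from regressing each colony's mean uncollided boundary radius on
time; `fit.resimulate()` re-runs the growth model from the fitted
configuration and `fit.score()` reports its similarity to the observed
final frame.

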