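# culmforce

Multiscale analysis of cereal culm (stem) lodging resistance, implemented as
a tested, fully synthetic-data-driven pipeline:

- **synthetic_data** — parametric hollow culms with two helical
  vascular-bundle rings, rasterized into MRI-like label volumes
  (168 × 168 × 26 voxels over a 4.2 × 4.2 × 13 mm field of view),
  two-parent + F2 trait tables with additive inheritance, and noisy
  linear-mixture IR spectra with ground truth recorded.
- **geometry** — per-slice centroid extraction and nearest-neighbour
  chaining of bundle centerlines from label volumes, bundle counts
  (absolute and per wall area), incline estimation versus the
  cross-sectional plane, and the cylindrical analysis grid
  (1° azimuth × 20 radial increments × 1 mm slices × 15 mm segment =
  108 000 voxels by default).
- **mechanics** — force-redistribution model: windward surface pressure
  loading, magnitude-conserving radial propagation (|Fin| = |Fout| at every
  voxel), out-of-plane deflection at fibre voxels accumulated into a warp
  field, per-fibre axial/bending partitioning (F_N² + F_b² = F_I²), a
  360-angle attack sweep, and optimal-attack identification.
- **spectra** — spectral range truncation, vector / min-max normalization,
  least-squares decomposition against a versioned component reference
  library (baseline polynomial + cellulose, xylan, lignin G/S, pectin,
  protein, lipid), lignin S/G ratio, PCA chemotype scores, and per-component
  effect-size screening.
- **traits** — Welch and Mann–Whitney comparisons (exact enumeration for
  small samples), pooled-sd Cohen's D with threshold classes, moment-based
  normality screening, Pearson correlation, broad-sense heritability
  H² = (V_F2 − √(V_P1·V_P2)) / V_F2, fold changes, and linkage-map density
  summaries.
- **cli** — `culmforce` with subcommands `simulate`, `geometry`,
  `mechanics`, `spectra`, `traits`, `demo` and `compare`; every run writes
  a manifest with seeds and output hashes.

## CLI examples

```sh
# end-to-end demo: volume, centerlines, 108000-voxel grid, sweep, renders
culmforce demo --preset rye_resistant --seed 1 --out demo_out/

# contrast two presets (bundle counts, inclines, sweep amplitudes)
culmforce compare --preset-a rye_resistant --preset-b rye_prone --out cmp/

# mechanics only, custom grid
culmforce mechanics --preset rye_prone --alpha-step 2 --nr 10 \
    --segment 10 --sweep --out mech_out/
```

Label volumes are written as multi-page TIFF and raw NRRD; centerlines,
sweeps, loadings and trait reports as CSV; manifests as JSON.

## Conventions

- Coordinates are right-handed; the stem axis is +z; azimuth is measured
  from +x counter-clockwise in degrees; lengths in mm.
- Fibre incline is the angle between the centerline tangent and the
  cross-sectional plane (90° = parallel to the axis);
  `incline_from_axis_deg` converts to the from-axis tilt.
- Attack angle α means the impacting force travels along azimuth α − 180°;
  signed axial force is positive for fibre stretching.
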