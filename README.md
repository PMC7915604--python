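# specsep

Band-by-band pairwise spectral class-separability analysis for
forest-type discrimination, comparing a hyperspectral and a
multispectral sensor view of the same labeled field.

The pipeline:

1. **Scene I/O** (`specsep.cube_io`) — ENVI-style reflectance cubes
   (flat binary + text header carrying wavelengths, grid and CRS),
   GeoJSON class polygons, VNIR/SWIR overlap-band bookkeeping, and
   nearest-neighbor grid alignment.
2. **Synthetic scenes** (`specsep.synthetic`) — two sensor presets
   ("hyper": 239 bands, 66 VNIR + 173 SWIR with 9 wavelength-coincident
   pairs at 30 m; "multi": the 10 Sentinel-2 land-monitoring bands) and
   a generator drawing per-class Gaussian reflectance with configurable
   mean spectra, standard deviations and wavelength windows of injected
   class contrast. Known generating parameters make every downstream
   stage testable against a ground-truth oracle.
3. **Signatures** (`specsep.signatures`) — per-class pixel extraction by
   center containment within labeled polygons (third- or fourth-level
   nomenclature), per-band mean/sd/covariance and median signatures.
4. **Separability metrics** (`specsep.metrics`) — M-statistic,
   Bhattacharyya distance, Jeffries–Matusita distance and transformed
   divergence, in univariate and multivariate form, each with a [0, 1]
   normalization so metrics on different scales can be averaged.
5. **Pairwise pipeline** (`specsep.pipeline`) — tidy per (class pair,
   band, metric) tables, per-pair maxima with argmax wavelength, and
   best-wavelength selection by the mean of the normalized metrics.
6. **Comparison report** (`specsep.report`, `specsep.cli`) — cross-sensor
   percentage increments per pair and metric, per-area and cross-area
   summaries, and a deterministic CSV/JSON artifact bundle.

## CLI

Simulate a two-sensor scene pair with labeled polygons, then run the
comparison:

```sh
specsep simulate --seed 7 --out scenes/
specsep run --hyper scenes/hyper.img --multi scenes/multi.img \
    --regions scenes/regions.geojson --level fourth \
    --metrics M,B,JM,TD --jm-convention eq3 --out results/
```

Outputs include per-sensor separability tables, best-wavelength
matrices, per-pair increment tables with summary means, signature CSVs,
a QC report of undefined metric cells, and a run log recording every
convention and parameter. Exit code 2 marks input errors, 3 marks
computation errors.

## Conventions

- JM distance defaults to the bound-2 form `2(1 - exp(-B))`; the
  bound-sqrt(2) square-root convention is available via
  `--jm-convention sqrt` and is recorded in the run log.
- Sample statistics use the n-1 denominator; degenerate variances are
  floored by a configurable ridge (default 1e-10).
- Pixel-in-polygon rule: center containment, boundary counts as inside;
  pixels claimed by two classes are excluded and logged.
- Normalizations: JM/2, TD/2, 1-exp(-B), M/(1+M).
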