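# glosscue

A tested pipeline for studying how the spatial structure of a three-point
illumination affects gloss-related image statistics:

- **`mesh_gen`** — blob-shaped test objects (subdivided icospheres displaced
  by seeded 3-D gradient noise) plus sphere/cylinder primitives, with OBJ
  I/O.
- **`renderer`** — a ray-cast renderer with diffuse + GGX microfacet
  specular shading (Schlick Fresnel, Smith height-correlated visibility),
  three white point lights placed on a radius-5 arc by a spread parameter
  `alpha` in [0, 1], a constant ambient term, range-limited falloff,
  optional intensity clipping and side-by-side stereo rendering.
- **`highlight_stats`** — gloss-layer segmentation (luminance > mean + 2 SD
  of the foreground, 8-connected components) and the four global highlight
  statistics (number, mean size, percentage area, strength), three contrast
  measures, and validity flags (empty layer / clipped pixels).
- **`split_analysis`** — an analytic model of superposed specular lobes on a
  circular cross-section, Rayleigh-style dip detection of when a highlight
  group resolves into separate highlights, and the critical spread
  `alpha*(smoothness)`.
- **`gloss_model`** — the experiment design grids, a linear gloss model on
  the four statistics (standardized + raw coefficients, R², Spearman and
  Pearson correlations, factor-subset fits) and a synthetic observer for
  parameter-recovery validation.
- **`cli_io`** — pipeline orchestration, CSV/JSON/OBJ/PGM/PNG formats,
  deterministic fixtures and the command-line interface.

## CLI

```sh
glosscue render --shape blob1 --smoothness 0.4 --alpha 0.32 --intensity 1.5 \
    --stereo --out render_out/
glosscue stats --image render_out/luminance.pgm --mask render_out/mask.pgm \
    --n-views 2 --out stats.csv
glosscue alpha-star --smoothness 0.2:0.6:0.1 --criterion rayleigh --out curves.csv
glosscue fit --records stats.csv --split shape,intensity --out fits.csv
glosscue pipeline --seed 0 --out run/        # full grid; --tiny for a smoke run
glosscue fixtures --seed 0 --out fixtures/
```

`glosscue pipeline` runs meshes → renders → statistics CSV → split-curve CSV
→ synthetic-observer fits CSV and writes a manifest with content hashes; a
run is reproducible from its config JSON plus the seed.

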