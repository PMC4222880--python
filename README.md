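# pelagostat

Geostatistical analysis of small-pelagic-fish acoustic surveys.

Scientific acoustic surveys of shoaling fish (anchovy, sardine, sprat and the
like) record a biomass density for every 1-nm sampling segment (EDSU) along
parallel transects, year after year. `pelagostat` turns such per-EDSU records
into the standard suite of spatial indicators used in fisheries
geostatistics:

- **Aggregation** — presence area, concentration (Lorenz-type) curves, and the
  *space selectivity index* G = 2 ∫₀¹ (Q(p) − p) dp, twice the area between
  the concentration curve Q and the diagonal (the Gini coefficient of the
  biomass distribution);
- **Spatial structure** — bidirectional empirical variograms
  γ(h) = Σ (z(xᵢ) − z(xⱼ))² / 2N(h) of log-biomass Y = ln(B + c), fitted as
  nugget + nested spherical models with direction-specific ranges, the
  multi-year *mean variogram* (pairs pooled within years only), and an
  interannual stability test against a 95% envelope built by turning-bands
  simulation of Gaussian random fields;
- **Mapping** — ordinary kriging on a 1×1 nm grid with an anisotropic moving
  neighbourhood, node-wise average/variability maps, and classification of
  the domain into recurrent, occasional and unfavourable areas by a
  median split of the mean and SD maps;
- **Distribution indicators** — centre of gravity, inertia (weighted mean
  squared distance, nm²) with principal-axis ellipses, greedy recursive
  *patch* identification under anisotropic distance thresholds, empirical
  orthogonal functions (EOF) of the annual maps, and the pointwise temporal
  CV of relative biomass;
- **Interspecific collocation** at three scales — inertia-ellipse
  intersection-over-union (global), patch-ellipse-union IoU (intermediate),
  and co-occurrence, the local index of collocation
  LIC = Σzᵢzⱼ / √(Σzᵢ² Σzⱼ²) and the dominance index (zᵢ−zⱼ)/(zᵢ+zⱼ)
  (local), with seeded bootstrap randomization tests.

Because per-EDSU survey data are rarely deposited, the package ships a
first-class synthetic survey generator (`pelagostat.simulate`) that emulates
a 9-transect, 12-nm-spaced, 1-nm-EDSU design with three species presets whose
latent Gaussian fields, zero inflation, skewness and ten-year biomass
trajectories reproduce the statistical regime such surveys operate in.

## Worked example

```python
import numpy as np
from pelagostat import (default_simulation_spec, simulate_survey,
                        annual_summaries, inertia,
                        cooccurrence_index, local_index_of_collocation)

ds = simulate_survey(default_simulation_spec(seed=1))   # 3 species, 10 years
summ = annual_summaries(ds)
print(summ[summ.year == 2003][["species", "presence_area_pct",
                               "selectivity", "cv_biomass"]]
      .round(3).to_string(index=False))

pts = ds.points(2003)
a, s = ds.values("anchovy_like", 2003), ds.values("sardine_like", 2003)
g = inertia(pts, a)
print("CG = (%.1f, %.1f) nm, inertia = %.0f nm^2, RMS distance = %.1f nm"
      % (g.cg[0], g.cg[1], g.inertia, np.sqrt(g.inertia)))
print("co-occurrence = %.3f, LIC = %.3f"
      % (cooccurrence_index(a, s), local_index_of_collocation(a, s)))
```

prints

```
     species  presence_area_pct  selectivity  cv_biomass
anchovy_like             88.889        0.691       2.147
sardine_like             90.681        0.679       1.626
  sprat_like             35.125        0.774       1.902
CG = (22.6, 11.6) nm, inertia = 887 nm^2, RMS distance = 29.8 nm
co-occurrence = 0.802, LIC = 0.090
```

Reading the output: in 2003 the anchovy- and sardine-like populations occupy
~90% of the sampled EDSUs while the sprat-like one occupies 35%; all three
are strongly concentrated in space (selectivity 0.68–0.77, i.e. far above the
0 of a homogeneous distribution); the anchovy-like population is dispersed
around its centre of gravity with an RMS distance of ~30 nm (most of the
survey domain); and while the two main species co-occur at 80% of the EDSUs
where either is present, their biomass densities barely collocate
(LIC ≈ 0.09) — presence overlaps, hotspots do not.

## Command line

The `pelagostat` console script wraps each stage
(`simulate`, `validate`, `project`, `aggregate`, `variogram`, `indices`,
`krige`, `classify`, `collocate`) plus `run`, which executes the whole
pipeline from one YAML config and writes CSV/JSON products and a manifest
with checksums and seeds:

```sh
pelagostat simulate --seed 1 --out survey.csv
pelagostat run --out-dir results_run --seed 1
```

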