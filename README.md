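# legrange

Crossed-random-effects occupancy GLMMs for global species-introduction
analysis, with a synthetic-world generator, range geoprocessing and
parametric-bootstrap inference.

## The problem

Most legume species depend on symbiosis with nitrogen-fixing rhizobia,
acquired from soil after germination. Does that dependency limit where
legumes establish outside their native range? Answering this at a global
scale means modelling a complete species × region matrix of non-native
presence while controlling for confounders — native latitude, native
range area, life form and history, region size, and above all
human-mediated introduction effort — and while respecting that
observations within a species or within a region are not independent.

`legrange` is for quantitative ecologists who want that full analysis
chain as a tested library: ingesting name-coded occurrence records
against a hierarchical polygon gazetteer (in the style of the WGSRPD/TDWG
scheme), deriving geographic covariates on the sphere, imputing missing
binary traits by taxonomic means, fitting the mixed model, and running
simulate-and-refit bootstrap inference. A first-class synthetic-data
generator with known ground truth makes every stage testable offline.

## The model

For species *i* and region *j*, non-native presence is Bernoulli with

```
logit P_ij = α + β_SS·SS_i + Σ_k β_k·x_ik + β_z·x_jz + β_int·SS_i·u_i
             + SP[i] + RE[j]
```

where `SS` is the binary symbiosis trait, `x_ik` are species covariates
(absolute native latitude, total native area, woody, annual, human-use
count `u_i`), `x_jz` is region area, and `SP ~ N(0, V_species)`,
`RE ~ N(0, V_region)` are crossed random intercepts. Fitting maximises
the Laplace-approximate marginal likelihood; the crossed design's arrow
structure (the species block of the penalised information is diagonal)
reduces every inner solve to a dense system of region-count size, so a
3,530 × 51 fit takes seconds. The fit agrees with `lme4::glmer` to four
decimals on identical data. Confidence intervals come from a parametric
bootstrap (simulate B response matrices from the fit, refit, take
empirical quantiles). See `docs/methods.md` for details and caveats.

## Worked example

Simulate a world from the published non-native-only calibration
(downsized to 400 species × 30 regions), fit, and bootstrap:

```python
from legrange import paper_calibrated_config, generate_world, OccupancyGLMM
from legrange.bootstrap import parametric_bootstrap, ci_table

cfg = paper_calibrated_config("nonnative_only").with_(
    n_species=400, n_regions=30, n_genera=80, n_tribes=20, seed=42)
world = generate_world(cfg)
res = OccupancyGLMM.from_world(world).fit()
print(res.summary())
```

```
Crossed random-intercept binomial occupancy GLMM (Laplace ML)
  n_species=400  n_regions=30  cells=12000
  log-likelihood (Laplace) = -2200.353   converged=True
  variance components: species=0.6404, region=0.98

  coefficient             estimate  approx SE
  intercept                -2.9489     0.2974
  symbiosis                -0.9164     0.2313
  ...
```

The generating symbiosis coefficient is −0.587; the fit returns −0.92
with SE 0.23 on this single draw. Bootstrap CIs and the covariates-at-zero
group means:

```python
draws = parametric_bootstrap(res, B=200, seed=1)
print(ci_table(draws, levels=(0.95,), point_estimates=res.params).round(3))
print(res.effect_summary(B=200, seed=2).round(2))
```

```
                  estimate  lower_95  upper_95 significance
symbiosis           -0.916    -1.312    -0.696            *
n_uses               0.257     0.123     0.353            *
symbiosis_x_uses     0.185     0.080     0.325            *
...

               mean_introduced_regions  lower_95  upper_95
non-symbiotic                     2.70      2.19      3.17
symbiotic                         1.15      1.05      1.25
```

Read: with all covariates at zero, non-symbiotic species are predicted in
~2.7 non-native regions versus ~1.2 for symbiotic ones — symbiosis is
associated with markedly lower introduction success — while the positive
interaction says the gap narrows as human uses accumulate.

The same stages are scriptable from a shell via the `legrange` CLI
(`simulate`, `ingest`, `covariates`, `fit`, `bootstrap`, `all`,
`report`), each reading and writing plain CSV/TSV/GeoJSON/JSON files.

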