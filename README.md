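# geobiodiv

Can a single *geodiversity index* — the spatial variability of the abiotic
environment — stand in for carefully chosen environmental variables when
predicting biodiversity and ecosystem functioning? `geobiodiv` implements
that comparison end-to-end for elevational-gradient study systems: it builds
the compound geodiversity index from classified environmental rasters,
standardizes taxon Shannon diversity to complete sample coverage, fits both
model families as Gaussian additive models, and decomposes the
environmental model's explained deviance into pure and shared fractions of
climate, habitat and soil. Because field data for such comparisons are
rarely depositable, the package includes a first-class synthetic-landscape
generator with known ground truth, so the whole pipeline is testable
offline.

It is aimed at macroecologists and conservation modellers who want to test
geodiversity–biodiversity hypotheses, and at methodologists who need a
transparent, reproducible reference implementation of the pieces.

## The quantities at the core

**Compound geodiversity index.** Each selected environmental raster is
classified into k = 5 classes by Fisher's optimal partitioning (exact
dynamic programming on the within-class sum of squared deviations). Around
each plot the 3 × 3 pixel block (nine pixels) is read like a community —
each class a "species", its pixel frequency its abundance — and its Shannon
entropy H_j = −Σ p_i ln p_i is computed. The index is the sum over the
selected variables:

    G = Σ_j H_j ,   H_j ∈ [0, ln 5],  G ∈ [0, 3 ln 5].

**Coverage-standardized Shannon diversity.** Plot abundance vectors are
extrapolated to complete sample coverage with the singleton/doubleton
coverage estimator Ĉ = 1 − (f₁/n)·(n−1)f₁/((n−1)f₁+2f₂) and the asymptotic
Shannon entropy estimator, reported as the Hill number exp(Ĥ) (effective
number of species).

**Model comparison.** Each response (taxon diversity or an ecosystem
function) is fitted two ways on identical plots: a three-predictor Gaussian
additive model (one cubic regression spline per predictor, edf 1–3,
smoothing by GCV) using one variable from each of climate, habitat and
soil — chosen by univariate AIC subject to a pairwise |r| ≤ 0.6
collinearity rule — and a univariate model on the compound index G built
from the *same three* rasters. Explained deviance (1 − RSS/RSS_null) is the
comparison currency, and the environmental model is decomposed by
inclusion–exclusion over the 7 predictor subsets (smoothing parameters
frozen at the full-model values) into three pure, three pairwise-shared and
one triple-shared fraction; shared fractions may be negative.

See `docs/methods.md` for the full model account, parameter defaults and
limitations.

## Worked example

```python
from geobiodiv import ScenarioConfig, StudyConfig, run_study

# a condition-driven synthetic landscape: true diversity follows the value
# of mean temperature along a 1000-3000 m gradient, 60 plots
cfg = StudyConfig(scenario=ScenarioConfig(seed=7))
results = run_study(cfg)
res = results["diversity:community"]
print(res.selected)
print(res.env_fit.explained_deviance, res.geodiv_fit.explained_deviance)
```

prints (numbers from this exact run):

```
selected predictors : {'climate': 'temp_mean', 'habitat': 'tpi', 'soil': 'organic_layer_depth'}
environmental model : explained deviance = 0.993, edf total = 6.84
geodiversity model  : explained deviance = 0.119
variance partition  : pure = {'climate': 0.427, 'habitat': 0.000, 'soil': 0.001}
diversity-function r = 0.80
```

Read: the pipeline recovered the true driver (mean temperature), the
environmental-variable model explains essentially all of the diversity
signal, while the compound geodiversity index — built from the very same
three rasters — explains little. The variance partition attributes the
explained deviance almost entirely to climate (pure fraction 0.43, the rest
shared), matching how the landscape was generated. In a
`driver_mode="heterogeneity"` scenario, where diversity responds to local
environmental variability instead, the index model becomes competitive.

The same stages are available from the shell:

```bash
geobiodiv generate --config scenario.yaml --out data/ --seed 7
geobiodiv geodiv --rasters data/rasters/temp_mean.tif \
                 --rasters data/rasters/tpi.tif \
                 --rasters data/rasters/ph.tif \
                 --plots data/plots.csv --classes 5 --out geodiv.csv
geobiodiv diversity --counts data/community_community.csv --out diversity.csv
geobiodiv run --config study.yaml --out report/ --seed 7
```

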