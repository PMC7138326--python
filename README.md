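# reefniche

Niche-space modelling for reef corals: which parts of a reef tract are
environmentally suitable for each species, and how fragmented does that
habitat become under disturbance?

`reefniche` re-implements, as a tested and reusable pipeline, the full
analysis chain used to map contemporary coral niche space from
presence/absence surveys: derivation of environmental predictor rasters
(including a wind-fetch wave-energy model), a weighted boosted-regression-tree
occurrence model per species, habitat-suitability mapping with per-subregion
area accounting, hold-out evaluation, and a patch nearest-neighbor
disturbance simulation. Because real reef survey data are rarely released,
the package ships a seeded synthetic reef-scape generator that emulates the
statistical shape of such surveys — a coast-parallel reef band, daily
environmental fields, and virtual species with *known* logistic responses —
so the whole pipeline runs, and is validated, without any external download.

It is intended for quantitative ecologists building species distribution
models on gridded coastal data, and for anyone who wants an auditable,
dependency-light boosted-regression-tree implementation for weighted
Bernoulli data.

## The model

For each species, presence/absence $y_i \in \{0,1\}$ at site $i$ is related
to environmental predictors $x_i$ by a stagewise additive ensemble of small
regression trees on the logit scale:

$$\mathrm{logit}\, p_i \;=\; f(x_i) \;=\; \beta_0 + \nu \sum_{m=1}^{M} T_m(x_i)$$

fit by gradient boosting of the Bernoulli deviance
$D = -2\sum_i w_i\,[\,y_i \log p_i + (1-y_i)\log(1-p_i)\,]$:

* case weights $w_i$ equalize the total weight of presences and absences,
  so $\beta_0 = \mathrm{logit}(\text{weighted prevalence}) = 0$ and a 0.5
  probability threshold is meaningful;
* each tree $T_m$ is fit to the gradient residuals $y_i - p_i$ on a random
  bag of the training sites (bag fraction 0.8, without replacement), with
  exhaustive midpoint split search and one-step Newton terminal values
  $\sum w r / \sum w\,p(1-p)$;
* the shrinkage $\nu$ (learning rate) defaults to 0.0015, and the tree
  count $M$ is selected by 5-fold cross-validated predictive deviance
  inside the training split;
* predictor importance is Friedman's relative influence (per-predictor sum
  of split gains, normalized to 100 %), and response shapes are read from
  partial-dependence curves.

Around the model sit the spatial stages: per-pixel aggregation of daily
SST/chlorophyll/K490 stacks (mean, population variance, range), Euclidean
distance from coast, wave energy
$E = \rho g H^2/16$ with significant wave height from the classical
deep-water growth laws ($H = c_H (gF/U^2)^{e_H}\, U^2/g$ for fetch $F$ below
38 km, $H = k_H U^2/g$ for fully developed seas beyond it), harmonization of
all layers to a 1-km grid clipped to a 1-km reef buffer, a ≥10 %-prevalence
species filter (with an exception list for conservation-priority species),
suitable-area accounting above the 50 % probability threshold, and mean
Euclidean nearest-neighbor distance among habitat patches across a rising
series of thresholds that mimics increasing disturbance.

## Worked example

```bash
reefniche demo --seed 11 --out demo_run
```

runs the full synthetic pipeline (50 x 80 km grid, 90 daily fields, 400
survey sites, three virtual species) in a few seconds and prints:

```
                   species  presence_pct      auc  suitable_pct  total_suitable_km2
        virtual_generalist     63.520408 0.682171     51.983299               249.0
         virtual_deep_step     36.479592 0.650560     31.106472               149.0
virtual_thermal_specialist     14.030612 0.877488     30.688935               147.0
```

Each row is one modelled species: its prevalence across the surveyed sites,
the AUC of the fitted model on the held-out 20 % of sites, and the share and
extent (km²) of the reef buffer predicted suitable (occurrence probability
above 0.5). The generalist occupies most of the tract but is weakly
predictable (AUC 0.68); the thermal specialist — driven by a narrow SST-range
and turbidity optimum — is rarer but much easier to predict (AUC 0.88),
mirroring the prevalence-dependence seen in real survey models.

The run directory also holds, per species, the probability surface
(`probability_*.asc`), relative-influence table, serialized model JSON,
per-subregion area table (`subregion_areas.csv`), and the disturbance sweep
(`patch_sweep_*.csv`), e.g. for the thermal specialist:

```
threshold,n_patches,mean_enn_km,total_area_km2
0.5,6,3.414,147.0
0.6,5,4.827,103.0
0.7,3,11.196,75.0
0.8,0,,0.0
```

— as the simulated disturbance intensifies (higher threshold), surviving
habitat shrinks and the mean distance between patches grows until the
metapopulation collapses (no patches; distance undefined).

Library use mirrors scikit-learn:

```python
from reefniche import BoostedTreesClassifier
est = BoostedTreesClassifier(learning_rate=0.05, max_trees=300, cv_folds=5)
est.fit(X_train, y_train)            # X: DataFrame of predictors
p = est.predict_proba(X_test)[:, 1]  # occurrence probabilities
est.relative_influence_              # % influence per predictor, sums to 100
est.partial_dependence("sst_range")  # marginal response curve
```

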