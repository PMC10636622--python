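# sewersense

Wastewater-based substance-use surveillance analytics: from passive-sampler
measurements at treatment plants to community-level drug loads, regional
rank statistics, a stepwise discriminant classifier of geography, and Ward
clustering of communities with similar use profiles.

## The problem

A Polar Organic Chemical Integrative Sampler (POCIS) deployed at a plant
inlet accumulates dissolved drugs and metabolites on its sorbent over a
multi-day deployment. In the linear-uptake regime, the time-weighted average
water concentration of an analyte is

```
Cw = Cs · Ms / (Rs · t)          [ng/L]
```

where `Cs` is the sorbent-phase concentration (ng/g, mean of triplicates),
`Ms` the sorbent mass (g), `Rs` the analyte-specific sampling rate (L/day,
from published calibration studies) and `t` the exposure time (days). The
community's collective excretion rate and per-capita load follow as

```
CER     = Cw · Q · 10⁻⁹          [g/day]      (Q = plant flow, L/day)
CER/pop = CER · 10⁶ / population [µg/person/day]
```

On a panel of plants (here: 12 plants, 7 west / 5 east of the Mississippi,
11 analytes), the package then computes:

- **Spearman rank correlations** among analyte CERs, with significance from
  `t = ρ√((n−2)/(1−ρ²))` on `n−2` df;
- **Mann-Whitney U** regional comparisons of CER/pop (tie-corrected normal
  approximation with continuity correction; east-first group order, so
  west-elevated analytes carry negative z) and of opioid-to-methadone
  ratios, a treatment-access proxy;
- **stepwise linear discriminant analysis** of region: Wilks
  `Λ = det(W)/det(T)` forward selection / backward elimination with partial
  *F* enter/stay thresholds at p = .15, pooled-covariance LDA with equal
  priors, leave-one-out cross-validation, and precision / sensitivity /
  specificity / F1 / accuracy;
- **Ward minimum-variance clustering** of plants on range-standardized
  per-capita loads, with the semipartial R² of every merge, and JSON /
  Newick dendrogram export.

Because no plant-level data are published for this design, the package ships
a first-class synthetic generator (`sewersense.synthetic`): correlated
multivariate-lognormal water concentrations (Gaussian copula on the log
scale), planted west/east multipliers, optional cluster archetypes,
population-coupled flows and multiplicative triplicate noise — inverted
through the sampler equation so every downstream stage has an exact
parameter-recovery test.

## Worked example

```python
import sewersense as ss

cfg = ss.default_config(seed=7)            # 7 west + 5 east, 11 analytes
plants, measurements, truth = ss.generate_panel(cfg)
loads = ss.compute_loads(plants, measurements)

tests = ss.regional_tests(loads, plants)   # Mann-Whitney per analyte
print(tests[tests.analyte == "meth"])

wide = loads.pivot("cer_per_capita_ug_day")
region = {p.plant_id: p.region for p in plants}
res = ss.StepwiseDiscriminantAnalysis(
    wide, [region[p] for p in wide.index]
).fit()
print(res.summary())
```

prints:

```
  analyte    u         z  p_value
6    meth  5.0 -1.948795  0.05132
Stepwise linear discriminant analysis
==========================================
Enter/stay thresholds: p <= 0.15 / p <= 0.15
Priors: equal; positive class: west

Step  Action  Variable              Wilks lambda   F        p
   1  enter   1,7-dimethylxanthine      0.6739      4.84   0.0524
   2  enter   mdma                      0.3414      8.76   0.0159
   3  enter   cotinine                  0.1916      6.26   0.0369
   4  remove  1,7-dimethylxanthine      0.2440      2.19   0.1772
   5  enter   temazepam                 0.1821      2.72   0.1379

Selected variables: mdma, cotinine, temazepam

Resubstitution (positive = west): tp=7 fp=0 tn=5 fn=0
  precision=1.00 sensitivity=1.00 specificity=1.00 F1=1.00 accuracy=100%

Leave-one-out CV (positive = west): tp=7 fp=0 tn=5 fn=0
  precision=1.00 sensitivity=1.00 specificity=1.00 F1=1.00 accuracy=100%
```

The planted METH effect comes out west-elevated — negative `z` under the
(east, west) group ordering, p ≈ .05 at 12 plants — and the trace shows the
stepwise machinery at work: a variable enters, is later displaced by a
stronger pair, and the final model classifies all 12 plants correctly in
leave-one-out cross-validation. (Which analytes are selected varies from
panel to panel at n = 12; that instability is a property of small-sample
stepwise selection the synthetic experiments quantify.) The `u` statistic is
for the first (east) group. The same analysis writes every table to CSV/JSON
via `ss.run_pipeline(ss.RunConfig(synthetic=cfg))`, and the `sewersense` CLI
exposes each stage (`simulate`, `loads`, `stats`, `discriminate`, `cluster`,
`run`).

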