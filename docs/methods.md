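# Methods

This note documents the models implemented in `sewersense`, the default
parameter choices and why they were made, the numerical conventions, and
what the synthetic experiments do and do not demonstrate.

## Passive-sampler back-calculation

A POCIS sampler in its linear-uptake regime accumulates analyte mass
proportionally to the water concentration; the time-weighted average
concentration over a deployment is `Cw = Cs·Ms/(Rs·t)`. `Cs` is the mean of
the replicate sorbent-phase concentrations (ng/g) — the equation is linear
in `Cs`, so averaging replicates before or after back-calculation is
equivalent, and the package averages first to keep one `Cw` per
plant × analyte. Sampling rates `Rs` (L/day) are literature calibration
constants, shipped as a default table alongside instrument detection limits
(`sewersense.rates`); both are overridable from CSV.

Downstream conversions are pure unit arithmetic: `CER = Cw·Q·10⁻⁹` g/day
(`Q` a single weekly-mean flow per plant, matching the time resolution of a
7-day integrative sample) and `CER/pop = CER·10⁶/population` µg/person/day.
Per-capita loads are reported **per day**; the flow is a daily volume, so
the per-day basis follows directly from the units.

Non-detects: when a reporting limit (on the sorbent scale, ng/g) is
supplied, replicates below it are substituted with limit/2 by default
(configurable to zero or the full limit) — the common convention in
wastewater epidemiology — and every substitution is logged. No limit is
applied by default because sorbent-scale reporting limits depend on the
extraction workflow and must come from the laboratory.

Opioid-to-methadone CER ratios (morphine, hydrocodone, oxycodone against
methadone; a proxy for treatment availability relative to opioid use) are
computed per plant; a plant with zero methadone CER yields a flagged missing
value — never 0 or infinity — and is excluded from downstream rank tests
with a logged warning.

## Rank statistics

Spearman's ρ is the Pearson correlation of mid-ranks; significance uses
`t = ρ√((n−2)/(1−ρ²))` on `n−2` df (two-sided) at every n, which is the
convention that yields df = 10 statistics on a 12-plant panel. |ρ| = 1 is
reported as p = 0 with an `exact_monotone` flag rather than a divergent t.

The Mann-Whitney regional comparison uses the normal approximation on the
first group's rank sum with tie-corrected variance
`σ² = n₁n₂/12·(n+1 − Σ(t³−t)/(n(n−1)))` and a 0.5 continuity correction
that shrinks |z| (on by default, configurable off — it matters at n = 12).
The pipeline fixes the group order as (east, west), so analytes elevated in
the west carry negative z; the sign convention lives in the pipeline layer,
not in the math layer. P-values are two-sided throughout. No
multiple-testing adjustment is applied by default, matching the single-test
reporting style of small surveillance panels; a Benjamini-Hochberg column is
available behind a flag.

By full enumeration of the rank-sum distribution, the continuity-corrected
approximation stays within 0.05 (absolute) of the exact permutation p for
all no-tie configurations with 3–7 observations per group; with only 1–2
observations in a group the approximation itself is off by up to 0.13, so no
guarantee is made there. The same enumeration gives the test's exact
attainable size at a 7/5 split: 0.0303 at nominal α = 0.05 — discrete rank
tests at n = 12 are conservative, which the type-I Monte-Carlo experiment
reproduces.

## Stepwise discriminant analysis

Wilks' Λ of a variable set is `det(W)/det(T)` (within-group over total SSCP
determinants, computed via `slogdet`; a non-positive within determinant is
perfect separation, Λ = 0). Selection follows the classical stepwise
discriminant procedure: the candidate with the largest partial
`F = ((n−m−g)/(g−1))·(1−Λp)/Λp`, `Λp = Λ(model+x)/Λ(model)`, enters when its
F(g−1, n−m−g) p-value is ≤ the enter threshold (default .15); after each
entry the weakest retained variable leaves while its F-to-remove p-value
exceeds the stay threshold (default .15); alternation stops when no move is
possible. Ties on F break by input column order; Λ = 0 maps to a capped F
sentinel (10¹²) with p = 0 so perfect separators enter without overflow. The
procedure cannot enter more variables than `n − g − 1` (the partial-F
denominator df must stay positive).

Classification uses the pooled within-class covariance (denominator `n−g`)
linear discriminant with equal priors by default (proportional or explicit
priors configurable); score ties break to the first class in sorted label
order. A singular pooled covariance raises rather than silently
regularizing; an explicit ridge (`εI`) is available for stress tests.
Leave-one-out cross-validation refits the discriminant on each n−1 subset
with the **selected variable set held fixed** — re-running selection inside
each fold is available behind `loocv_reselect` but off by default, since the
procedure being validated is the classifier built from the chosen variables;
both resubstitution and LOOCV confusion matrices are reported (neither
dominates the other in general). The positive class is west; precision,
sensitivity, specificity, F1 and accuracy come from the LOOCV matrix, with
undefined ratios reported as NaN, never as silent zeros.

Two small-sample facts, established with the synthetic experiments, are
worth knowing. First, with two *independent* equally strong discriminators
at 6+6 plants, "exactly the planted pair selected" plateaus near 85%
regardless of effect size: the first-entered variable is nearly collinear
with the group indicator, which inflates the variance of the second
variable's partial F. A strongly *positively correlated* pair with
*opposite* regional effects — precisely the methadone/temazepam pattern in
the observed correlation structure — acts as a suppressor pair and is
recovered essentially always; the recovery experiment uses that faithful
configuration. Second, any null candidate enters with probability ≈ the
enter threshold (.15), so panels carrying many uninformative analytes will
routinely admit one extra variable; this is a property of stepwise selection
at p = .15, not a defect.

## Ward clustering

Features (per-capita loads of the misuse-relevant analytes: cotinine, MDMA,
methamphetamine, morphine, hydrocodone, methadone, oxycodone, temazepam) are
range standardized (`(v−min)/(max−min)` per analyte; min/max are recorded in
the output for provenance; a constant analyte is an error naming the
column). Agglomeration minimizes the increase in total within-cluster error
sum of squares, maintained with the Lance-Williams recurrence for Ward
seeded with `d(i,j) = ‖xᵢ−xⱼ‖²/2` — algebraically identical to recomputing
the ANOVA between-cluster sum of squares from scratch, which a brute-force
oracle verifies on random panels. Each merge carries its semipartial
R² = ΔESS / total SS; over a full agglomeration these sum to 1. Ward's
criterion is reducible, so merge heights are monotone non-decreasing. Ties
break by the lexicographically smallest pair of smallest member ids — any
stable rule is valid; this one is deterministic. `cut_tree(root, k)` undoes
the k−1 costliest merges and labels clusters by their smallest member id.
Dendrograms export to nested JSON and to Newick with branch lengths from
merge heights (scipy's equivalent Ward heights are `√(2·ΔESS)`; the tests
check that identity).

## The synthetic generator

The generator emulates the surveyed design — 12 plants (7 west, 5 east),
11 analytes, 7-day deployments, 0.2 g of sorbent, triplicate measurements —
and is the forward model of the back-calculation, so a zero-noise panel
round-trips exactly.

- **Latent concentrations** are multivariate lognormal via a Gaussian copula
  on the log scale: positive, right-skewed, with a planted correlation
  structure. Default log-medians are the published per-analyte medians;
  default marginal spreads are `(ln q3 − ln q1)/1.349` from the published
  IQRs (these are across-plant summaries, the only variance information
  available; the within-plant spread is unknowable from the publication).
- **Regional effects** multiply the lognormal median for western plants
  (location shift on the log scale — the simplest effect a rank test
  detects). Defaults plant effects only where the observed analyses support
  them: METH 11.42, temazepam 1.55, methadone 0.44 (west/east ratios of the
  published per-capita medians). For these three the variance the planted
  effect itself contributes across a 7/12-west panel, `p(1−p)·ln²(mult)`, is
  subtracted from the IQR-derived marginal variance so the generated
  marginal spread still matches the published one.
- **Correlation** defaults to two compound-symmetric blocks mirroring the
  observed correlation table: a misuse block (METH, morphine, hydrocodone,
  methadone, oxycodone, temazepam) at ρ = 0.75 and a licit block
  (1,7-dimethylxanthine, acetaminophen, caffeine, cotinine) at ρ = 0.70.
- **Populations** are lognormal (median 50,000, log-sd 1 — small towns to
  metro areas); **flow** couples to population as
  `population × 380 L/person/day × lognormal noise (CV 0.2)`, so per-capita
  loads stay interpretable; **replicate noise** is multiplicative mean-one
  lognormal with CV 0.15 (a typical analytical relative SD), preserving
  positivity and collapsing to exact replicates at CV 0.
- **Cluster archetypes** optionally add per-archetype log-offset profiles on
  top of the regional structure, giving Ward clustering a planted truth.
- One seeded generator (`numpy` PCG64) drives the whole panel; identical
  config and seed reproduce the panel bitwise.

What the generator does *not* emulate: within-week temporal variation
(a 7-day integrative sample is a single time average), in-sewer analyte
degradation, sampler uptake kinetics beyond the linear-`Rs` model, LC-MS/MS
peak-level artifacts, and any spatial structure finer than the east/west
label. Passing recovery tests therefore show the *statistical machinery* is
correct under the stated model, not that real wastewater data satisfy that
model.

## Experiment sizes and numerical conventions

The Monte-Carlo operating characteristics (`sewersense.experiments`) use
500 replicate panels for the METH power estimate (10× west multiplier at
6+6 plants; rejection two-sided p ≤ .05 in the west-elevated direction),
2,000 panels for the null type-I rate (7+5 plants, all multipliers 1), and
200 panels for the stepwise pair-recovery rate — sizes that give Monte-Carlo
standard errors of about 0.005–0.01 on the reported rates. Oracle
comparisons run full enumeration for the Mann-Whitney (group sizes 3–7),
100 random small panels for the Ward/ESS identity and 50 for LOOCV versus a
per-fold refit oracle. Floating-point tolerances: exact identities
(round trip, semipartial-R² sum) are asserted at 10⁻⁹ relative; oracle
identities at 10⁻⁹ relative with 10⁻¹² absolute floors; a 10⁻¹² slack
absorbs float noise in monotonicity assertions.

## Known limitations

- Sorbent mass per disk and laboratory reporting limits are deployment
  specific; the defaults (0.2 g, no limit) must be overridden to match a
  real campaign.
- The stepwise procedure inherits every small-sample pathology of its
  class: selection instability panel to panel, ~15% spurious admission per
  null candidate at the .15 threshold, and the independent-pair plateau
  described above. The package reports the full decision trace so such
  behaviour is visible rather than hidden.
- Spearman significance uses the t approximation at all n; no exact tables.
- No consumption back-estimation to doses is attempted — the analysis stops
  at excretion loads, as the surveillance design does.
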