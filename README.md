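# phytomedia

Design and optimization of plant tissue-culture mineral media, built
around the workflow used to develop an improved micropropagation medium
for kiwiberry (*Actinidia arguta*): a D-optimal design over groups of
Murashige–Skoog (MS) salts, decomposition of every medium into an 18-ion
profile, neurofuzzy IF–THEN rule models that identify which ions drive
shoot growth and quality, and a neural-network + genetic-algorithm search
that proposes a new salt formulation.

It is intended for plant-biotechnology researchers who want to analyse
(or re-analyse) media-optimization experiments with transparent,
scriptable tools instead of closed commercial software.

## What it computes

**Stoichiometry.** A medium is a map salt → mg/L. Each salt contributes
`count × conc / M` mM of every ion it releases (`M` = molar mass of the
hydrate), so a recipe becomes a fixed 18-ion vector — resolving the *ion
confounding* that arises because several salts share ions.

**Neurofuzzy models.** Each response `y` (shoot number SN, shoot length
SL, leaf area LA, shoot quality SQ, basal callus BC, hyperhydricity H) is
an additive sum of tensor-product B-spline submodels over small ion
subsets:

```
y(x) = a0 + Σ_s  B_s(x_{I_s}) β_s ,   |I_s| ≤ 4
```

with triangular (order-2 B-spline) membership functions — 2 or 3 per ion,
apexes uniformly spaced over the ion's empirical range — that double as
fuzzy sets Low/(Mid)/High. Structures are chosen by a structural-risk
criterion `mse · exp(−ln(1−C1)·C2·p/(3n))` (C1 = 0.868, 0.8 for SN;
C2 = 4.8), and each fitted submodel is read out as IF–THEN rules with
membership degrees.

**Optimization.** Per-response multilayer perceptrons (14 salt inputs,
one hidden layer of 2–4 sigmoid nodes, linear output, RPROP training,
80/20 split) act as surrogates for a real-coded genetic algorithm that
maximizes the weighted geometric mean of one-sided desirability ramps
(weights SQ=10, SN=9, SL=8, LA=7; targets SQ>4.0, SN>4.4, SL>1.6 cm,
LA>28 cm²).

**Validation statistics.** One-way ANOVA + Tukey HSD (α=0.001) for
continuous responses, Kruskal–Wallis for ordinal scores, and Welch t
tests computable directly from printed mean ± SD tables.

The published design, ion/response table, and standard media recipes
(MS, B5, St, Ha and the optimized medium) ship as package data, so the
whole analysis runs offline.

## Worked example

```python
>>> from phytomedia import datasets, recipe_to_ion_profile
>>> from phytomedia.pipeline import fit_ion_models
>>> ms = datasets.ms_recipe()
>>> profile = recipe_to_ion_profile(ms)
>>> round(profile["NH4+"], 2), round(profile["NO3-"], 2), round(profile["K+"], 2)
(20.61, 39.41, 20.05)
```

The MS basal medium dissolves to 20.61 mM ammonium, 39.41 mM nitrate and
20.05 mM potassium — matching the published ion table. Fitting the six
response models on the 34-treatment study data:

```python
>>> models = fit_ion_models()
>>> {out: round(m.r2_, 1) for out, m in models.items()}
{'SN': 82.3, 'SL': 93.1, 'LA': 92.9, 'SQ': 93.2, 'BC': 93.3, 'H': 89.3}
```

Every response is explained with training R² between 82% and 93% (the
study reports 75–93% for its own models). The union of ions the six
models select has 11 members, 9 of which are in the study's critical set;
the two extras (Ca²⁺, Mn²⁺) are design-confounded stand-ins for missed
members of their salt groups (PO₄³⁻, I⁻/MoO₂²⁻) — within one factor group
the design cannot tell ions apart. Rules read off a fitted model:

```python
>>> models["SQ"].extract_rules().iloc[5][["antecedent", "consequent", "MD"]]
antecedent    {'K+': 'High', 'Fe2+': 'Low', 'Ca2+': 'High'}
consequent                                             High
MD                                                      1.0
```

i.e. "IF K⁺ High AND Fe²⁺ Low AND Ca²⁺ High THEN shoot quality High" with
full membership — the same reading as the study's rule tables. Running the
optimizer end to end (`phytomedia optimize`, or
`phytomedia.pipeline.optimize_medium`) proposes a medium predicted at
SQ ≈ 4.4, SN ≈ 4.8, SL ≈ 2.3 cm, LA ≈ 34 cm² — meeting all four desired
values (100% agreement) and echoing the published optimized medium's
predictions (4.4, 4.8, 2.6, 39.5).

A command-line layer mirrors the pipeline stages:

```bash
phytomedia ions --out ions.csv          # design -> 18-ion matrix
phytomedia fit-rules --outdir rules/    # rules.csv, ranges.csv, fit_summary.csv
phytomedia fit-ann && phytomedia optimize
phytomedia validate                     # stats on the validation summaries
phytomedia design --n-runs 33 --seed 7  # fresh D-optimal design
phytomedia simulate --output SL         # synthetic experiment, known truth
```

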