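# Methods

This note records the models, numerical choices and known limitations of
the package, in the order of the analysis pipeline.

## Salt–ion stoichiometry

A medium recipe (salt → mg/L) is decomposed over a fixed 18-ion basis
{NH₄⁺, NO₃⁻, K⁺, Ca²⁺, Mg²⁺, PO₄³⁻, SO₄²⁻, Cl⁻, Fe²⁺, BO₃⁻, Mn²⁺, Zn²⁺,
Cu²⁺, MoO₂²⁻, Na⁺, Co²⁺, I⁻, EDTA⁻}. Each registered salt carries a
hydrate molar mass and integer ion yields; a salt at `c` mg/L contributes
`yield × c / M` mM per ion. Three conventions matter:

- The molybdate anion of Na₂MoO₄·2H₂O is booked under the key "MoO₂²⁻"
  (the label used in the source tables), with 2 Na⁺ per formula unit —
  the only reading that reproduces both the Mo and Na columns.
- H₃BO₃ yields one BO₃⁻; Na₂EDTA·2H₂O yields 2 Na⁺ + 1 EDTA⁻. No
  speciation, chelation or pH chemistry is modeled; Fe²⁺ and EDTA⁻ are
  counted independently.
- Comparisons against printed tables use round-half-away-from-zero at
  each column's printed precision. Because the published design levels
  are themselves printed to 2 decimals, recomputed ion values can differ
  from the printed matrix by up to the propagated level error
  (0.005 × the ion's mM-per-unit-level sensitivity) plus print rounding;
  the round-trip test uses exactly that tolerance. The 1× control rows,
  whose levels are exact, reproduce to print rounding alone.

## D-optimal designs

Five factors scale salt groups of the MS medium (NH₄NO₃ 0.2–1×,
KNO₃ 0.1–1×, mesos 0.25–3×, micros 0.1–1.5×, iron 1–5×). Candidates are
a uniform full-factorial grid including the range endpoints; a Fedorov
exchange search maximizes det(XᵀX) of the model matrix (default: full
quadratic, 21 terms) on factors coded to [−1, 1]. Exchange uses
first-improvement scans in candidate-index order, so runs are
deterministic given the seed of the random start; the log-determinant
trace is non-decreasing by construction. Replicate pairs are exact row
copies counted inside the requested run total (as in the study's 33 runs
containing three pairs), and 1× control rows are appended flagged. The
study's exact 33 printed runs come from closed commercial software and
are shipped as a data fixture, not regenerated; the generator's contract
is the property suite (monotone exchange, bound respect, superiority to
random designs of equal size). The printed design contains one
undeclared duplicate pair (runs 9 and 12), kept verbatim as a fixture
anomaly.

## Neurofuzzy models

**Bases.** Each ion used by a model carries a triangular partition:
order-2 B-splines on 2 or 3 uniformly spaced apexes spanning the ion's
empirical min/max over the training runs. These are simultaneously the
fuzzy sets Low/(Mid)/High: the label-crossover points are the midpoints
between adjacent apexes, giving closed-form dominance ranges
(min + range/2 for two sets; min + range/4 and min + 3·range/4 for
three). Using full-precision empirical domains (not the printed, rounded
ion values) is what reproduces the published fuzzification table to its
printed decimals.

**Model.** A response is `intercept + Σ tensor-spline submodels` over ion
subsets of size ≤ 4. All submodels are fitted jointly by ridge regression
(factor 1e−6) on the response min–max scaled to [0, 1]; scaling makes
mean-squared errors comparable across responses and matches the
magnitude of the published per-model MSEs. Because each submodel's basis
rows sum to one, one direction per submodel is redundant with the
intercept; the effective parameter count is
`Σ cells − #submodels + 1`. This convention reproduces all six published
model degrees of freedom from the published structures.

**Structure selection.** Candidate moves are: add a univariate submodel,
add a two-ion tensor directly (interactions with weak marginal effects
are invisible to one-ion additions), expand a submodel with a new ion,
merge two submodels, raise a density 2→3, and (in refinement) drop a
submodel, remove one ion from a tensor, or lower a density. The search
is two-phase: a growth phase forces the best-scoring complexity-
increasing move repeatedly up to an effective-parameter cap of n/2,
recording the path; then the path element with the lowest structural-
risk score is selected and refined with the full move set. The score is

    score = mse · exp(−ln(1−C1) · C2 · p / (3n))

with C1 the per-response confidence constant (0.868; 0.8 for shoot
number — lowering C1 deliberately relaxes the penalty) and C2 = 4.8. The
1/3 constant was calibrated once so that these constants yield model
complexities in the range the study reports (5–16 effective parameters
at n = 34) and then frozen. The exact selection internals of the
commercial neurofuzzy software are not public; fitting its published
structures with this package's bases reproduces its published training
R² almost exactly, so the basis family and fitting are faithful and only
the search differs.

**Error floor.** When replicate standard deviations are available (the
study tables print mean ± SD at 45 explants per treatment), the
selection criterion floors the mse at the replication variance of a
treatment mean, inflated by the one-sided 90% chi-square allowance
chi²₀.₉(n−1)/(n−1). Below this floor, accuracy differences are
statistically indistinguishable from replication noise and only
complexity counts, so the smallest floor-reaching model wins. This is
what makes a constant-truth experiment come back intercept-only and
stops spurious refinement near interpolation.

**Rules.** At every combination of apexes the tensor basis is one-hot,
so each coefficient is the submodel's prediction for one linguistic
cell. Cell predictions are min–max normalized within the submodel to
s ∈ [0, 1]; the rule consequent is High with membership s when s ≥ 0.5,
else Low with membership 1 − s. Constant submodels are emitted with
membership 0.5 and flagged degenerate. How the source software derived
its printed membership degrees is unspecified; this normalization is the
package's declared convention.

**Fit statistics.** Training R² is `(1 − SSE/SST)·100`. The
model-accuracy ANOVA uses f-ratio `(SSR/df1)/(SSE/(df2−df1))` with
df1 = effective parameters and df2 = n−1; this reproduces the study's
printed f-ratios from its printed R² and dfs. Its printed "f-critical
(α = 0.05)" values are numerically the upper 0.1% quantile of
F(df1, df2) with df2 the *total* df — not a textbook convention — so the
critical value is exposed under `convention="study"` alongside the
textbook `convention="residual"` default.

## Neural surrogates and optimization

One MLP per response: 14 salt concentrations in, one hidden layer of 2–4
asymmetric-sigmoid nodes selected by held-out MSE, linear output.
Training is full-batch iRPROP⁻ (η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1,
Δ ∈ [10⁻⁶, 50] — standard constants, not study-specified) on
min–max-scaled data, up to 1000 epochs with a 0.0001 target error, an
80/20 split (27/7 at n = 34), and early stopping on the blended
criterion 0.9·train + 0.1·test MSE after a minimum of 20 epochs; the
returned weights are those of the best blended criterion. Everything is
bit-reproducible given the seed. Out-of-sample R² benchmarks test
predictions against the *training* mean: with only ~7 held-out rows the
within-test mean is too unstable a baseline (a near-constant test split
would make 1 − SSE/SST explode).

The optimizer's genes are the five factor levels (not 14 free salts), so
candidates stay inside the salt groupings the surrogates were trained
on; a free-salt mode exists but is off by default. Fitness is the
weighted geometric mean (Derringer–Suich form; any zero-desirability
response vetoes a candidate) of one-sided linear ramps from each
response's training minimum (the declared lower-anchor policy; the study
states targets and weights but no anchors) to its desired value. The GA
is real-coded: tournament selection (size 3), BLX-0.5 blend crossover at
rate 0.9, per-gene Gaussian mutation (rate 0.1, scale 0.1 × range),
elitism 2, population 100, 200 generations — defaults declared here, as
the study names the method but no settings. Elitism makes the
best-so-far fitness non-decreasing, and the optimum is always compared
against the MS control under the same surrogates.

## Validation statistics

Continuous responses: one-way ANOVA with Tukey HSD pairwise comparisons
at the study's strict α = 0.001 (the studentized-range quantile at that
α, not a 0.05 default), summarized as a compact letter display via
greedy insert–absorb. Ordinal responses: Kruskal–Wallis with tie
correction. For printed mean ± SD tables, a Welch t test with
Satterthwaite df runs directly on the summaries, and
`samples_from_summaries` reconstructs standardized normal samples whose
sample mean and SD hit the printed values exactly, letting the
sample-based procedures re-run from summaries. Vessel nesting is not
modeled (no mixed models), matching the source analysis.

## Synthetic experiments

Ground truths are sparse additive tensor-spline surfaces — the exact
family the neurofuzzy stage assumes — over declared active ion subsets,
scaled so the noise-free response spans a realistic range per response
(SN 1–8, SL 0.7–2.6 cm, LA 3–41 cm², ordinal scores on their scales).
Each submodel is normalized to a comparable span so every declared
subset is detectable in principle. Explant values follow the study's
hierarchy (3 experimental rounds × 5 vessels × 3 explants): latent value
= truth + vessel effect + explant noise, with the vessel SD defaulting
to half the explant SD (the study never separates these components).
Ordinal outputs threshold the latent value at evenly spaced cutpoints,
consistent with treating score means as continuous downstream. The
per-treatment mean ± SD table is column-identical to the bundled study
table, so synthetic data are a drop-in for every stage.

Structure-recovery benchmarks sample ion tables with *independent*
columns. On the study's own five-factor design this would be ill-posed:
all ions of one salt group (e.g. Ca²⁺/Mg²⁺/PO₄³⁻ from mesos, the seven
micros ions) have identical min–max-scaled profiles, so active ions are
identifiable only up to group membership. That confounding is visible in
the real fits too: the six models' selected-ion union overlaps the
study's critical set in 9 of 12 ions, and the discrepancies are
precisely within-group swaps.

## Problem sizes and limitations

Tests and the acceptance script run the full 34-treatment analysis; the
simulation-based checks use 8–25 seeded replicates and the GA checks use
reduced populations (40–60) and generations (25–60), sizes chosen so the
whole suite completes in minutes while keeping Monte-Carlo error small
relative to the asserted margins.

Known limitations, measured on this package's own benchmarks:

- Structure selection at n = 34 with 18 candidate ions is intrinsically
  unstable: per-parameter chance capture (~10–15% mse) overlaps the
  weakest responses' true per-parameter signal. With the chosen penalty,
  exact active-set recovery at 10% explant noise is ~0.5–0.6 (truth
  coverage ~0.8), and plain unreplicated noise is rejected in only ~1/3
  of runs — the replication-noise floor, not the penalty, is what makes
  constant-truth experiments come back empty (~0.9). Stronger penalties
  reject noise reliably but drop the weakest responses below the 70% R²
  the analysis requires.
- Held-out R² of the neural surrogates is dominated by which 7
  treatments land in the test split; minima across all six responses of
  ~50–55% (best of 5 seeds) are typical, well below the study's claimed
  76.66% lower bound, which this package cannot reproduce from the
  printed data.
- The synthetic generator emulates the replicate hierarchy and ordinal
  scoring but not mechanistic plant physiology, treatment-by-vessel
  interactions, or non-Gaussian explant noise; passing recovery tests
  show the pipeline works when its model family is true, not that real
  media effects are spline-additive.
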