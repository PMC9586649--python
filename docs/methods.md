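# Methods

This note documents the statistical model, the conventions the package
commits to where the literature allows more than one, and what the test
suite's simulation-based checks do and do not establish.

## Score model and G study

Balanced designs only. A design names the object of measurement (the test
taker) and the facets of the procedure; facets may be fully crossed or
nested (`p:s x f x st`: persons nested in sites, sites crossed with forms
and stations). Effects are enumerated by closing every subset of facets
under nesting ancestry; subsets whose closures coincide are confounded in
balanced data and collapse to one effect, which keeps the
expected-mean-square (EMS) system non-singular. A fully crossed design
with the object plus *k* facets yields 2^(k+1)−1 effects.

Estimation is the classical ANOVA method:

* sums of squares by the T-term identity
  `T(α) = T(μ) + Σ_{β⊆α} SS(β)`, with `T(α)` the sum over α's cells of
  (cell count)·(cell mean)²;
* `df(α) = Π_primary (n−1) · Π_nesting n`, and `MS = SS/df`;
* `E[MS_α] = Σ_β c_{αβ} σ²_β` with `c_{αβ}` the product of the sizes of
  the facets absent from β when β contains α, zero otherwise. With effects
  ordered by increasing index-set size (ties broken by facet order) the
  coefficient matrix is upper triangular, and the system is solved exactly
  by back-substitution.

Negative raw solutions are truncated to zero **after** the full solve; the
raw values and a truncation flag are retained in every report so
sensitivity analyses are not silently biased. REML was deliberately not
used: for balanced designs the ANOVA estimator is unbiased, closed-form
and coincides with REML expectations, and it keeps the dependency
footprint to numpy/scipy/pandas.

Unbalanced or incomplete tables are rejected with the first offending cell
named, never averaged over: the EMS solution is only exact under balance.
Nested facet sizes are always counts *per parent combination*, and nested
level labels are local to their parent (label 3 in site A and label 3 in
site B are different persons).

## D study

For a plan assigning size `n_f` to every non-object facet:

* **relative error** — components of effects containing the object,
  excluding the object effect itself;
* **absolute error** — those plus every effect not containing the object;
* each component is divided by the product of the plan sizes of the
  effect's facets *other than the object facet*.

The coefficient is `σ²_object / (σ²_object + σ²_error)` (generalizability
coefficient for relative error, dependability for absolute). A 0/0 is an
explicit error, not a silent zero.

**Nested-object convention.** When the object is nested (`p:s`), the object
variance is `σ²_p:s`. The site main effect enters the absolute error only
(divided by `n_s`), and by the divisor rule above the person-within-site
interaction terms are averaged over `n_s` as well (e.g. `σ²_pf:s /
(n_s·n_f)`). This corresponds to treating site membership as part of the
randomness of the measurement procedure — appropriate when candidates are
randomly assigned to sites, as in the multi-site OSCE setting the package
is aimed at. The alternative convention, conditioning on a fixed site of
administration (no `n_s` in person-interaction divisors), is standard when
site is a fixed context; it is not currently exposed. Coefficients are
reported to 4 decimals for display; computations always use full
precision.

Plan sizes are positive integers (they count stations, forms, sites);
fractional sizes are rejected. No optimizer is provided — a grid sweep
over user-supplied plans covers the intended "compare a handful of
candidate configurations" workflow.

## Costs, ICER, CEAC

Plan cost is `Σ_f unit_cost_f · n_f + fixed_cost` — exact sums, no
rounding. The ICER is `ΔC/ΔE` with signs preserved, so a cost-saving,
less-effective intervention yields a positive ratio. ΔE = 0 raises an
explicit dominance error. ICERs can be rescaled to money per 0.01 of
coefficient; currency display rounding is nearest integer, half away from
zero, applied after snapping to 9 decimals so that a mathematically exact
.5 that binary floats represent as .49999…9 still rounds up. Display
rounding never feeds back into computation.

The CEAC draws (ΔC, ΔE) independently: ΔE normal truncated to [−1, 1]
(coefficient differences cannot leave that range), ΔC normal or lognormal
on the magnitude (moment-matched, sign carried), either parameterized by a
standard deviation or a coefficient of variation. For each willingness-to-
pay λ (per rescale unit, converted to per-1.0 internally) the curve is the
fraction of draws with incremental net benefit `λ·ΔE − ΔC` strictly
positive; exact ties count as not cost-effective. Independence of ΔC and
ΔE is an assumption, not a theorem — in this package's setting the cost
difference comes from an accounting model and the effectiveness difference
from a psychometric one, with no shared estimation error, which makes
independence the natural default; a joint distribution is out of scope.

Coefficient uncertainty: the parametric bootstrap resamples each mean
square as `MS·χ²_df/df` (the exact distribution of a mean square under
normal theory), re-solves the EMS system with truncation and recomputes
the plan coefficient; the default is 1000 replicates. A single dataset's
bootstrap SE is itself a noisy statistic (its spread across datasets is on
the order of ±25% at moderate G-study sizes), which is why the validation
compares the *mean* bootstrap SE across datasets with the empirical
sampling SD. The jackknife deletes the i-th person label within every
parent group, preserving balance. The config's `sd: auto` combines the
two plans' bootstrap SEs in quadrature for the ΔE distribution — a
conservative choice since the two plans' coefficients are computed from
the same components and are positively correlated.

Seeds are mandatory for every stochastic step; nothing seeds from the
clock. Pipeline outputs are written only after all four steps succeed, and
re-running an unchanged configuration is byte-identical.

## Synthetic data generator

`simulate_scores` draws one independent zero-mean normal per effect per
level combination with variance equal to the true component and sums them
onto the grand mean — exactly the model the G study assumes. It emulates
balanced, continuous, homoscedastic ratings. It does **not** emulate
bounded or ordinal rating scales, rater severity drift, station content
structure, or missingness; passing recovery tests therefore demonstrate
that the estimation chain is correct under its own model, not that real
OSCE data satisfy that model. Because ANOVA estimators are moment-based,
the unbiasedness checks would survive non-normal effect distributions with
the same variances, but only normal generation is shipped.

The packaged demo (`precog demo`) mimics a six-site OSCE — 4 forms, 18
stations, persons nested in sites, 30 examinees per site (per-site cohort
size is a free parameter of the scenario; 30 keeps the demo table at
12,960 rows). Its true components were chosen once so the plug-in
dependability of the 6×4×18 plan is ≈0.80, with station difficulty the
dominant facet effect, as is typical for OSCEs. The values are
illustrative, not estimates from any real examination; the estimated demo
coefficient varies by a few hundredths across simulation seeds (six sites
give facet-main-effect estimates only 5 degrees of freedom).

## Validation sizes and numerical choices

The test suite checks, at sizes chosen to keep the default run around ten
seconds: EMS coefficients against Monte-Carlo mean-square expectations
(10⁴ replicates per design, four designs up to four facets, 3-SE
tolerance, tensor-algebra oracle independent of the package's ANOVA path);
parameter recovery at (100 persons, 8 tasks, 4 raters) over 200 replicates
with |bias| under 10% of each true component; closed-form agreement of the
two-facet relative coefficient to 1e-12 over 1000 random inputs; and CEAC
limits (degenerate step exactly at the ICER; 0.5 ± 0.01 at λ = ICER for
symmetric normal deltas at 10⁵ draws). Sums of squares are validated
against an effect-mean-definition oracle and the ANOVA identity
`ΣSS = Σ(x−x̄)²` at 1e-8 relative tolerance.

Known limitations: balanced designs only; all facets random (no fixed
facets, no multivariate G theory); no per-component confidence intervals
(only the aggregate coefficient SE); two-plan comparisons (no multi-way
efficiency frontiers or extended dominance); costs taken as given, with no
discounting or inflation adjustment.
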