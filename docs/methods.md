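# Methods

## Inbreeding under serial sib mating

`pedigree.sib_mating_F` iterates the second-order recursion
`F_t = 0.25 (1 + 2 F_{t-1} + F_{t-2})` in double precision with the
boundary convention `F_0 = F_{-1} = 0` (unrelated, non-inbred founders);
this is the convention that yields the textbook `F_1 = 0.25` for the
offspring of a single sib mating.  No rational-arithmetic mode is
provided — values are only ever consumed to a few decimals.  The
complement `1 − F_t` satisfies the linear recurrence
`y_t = 0.5 y_{t-1} + 0.25 y_{t-2}`, whose dominant root `(1 + √5)/4 ≈
0.809` is the asymptotic per-generation hazard ratio; the test suite
checks both identities.

Experiment generations are 1-based over crosses.  The first cross pairs
outbred individuals and the second pairs their (non-inbred) offspring, so
crosses 1 and 2 carry parental F = 0 and cross g ≥ 3 carries
`F_{g-2}`.  `parental_F_for_cross` makes this offset explicit rather than
leaving it to callers.

## The logistic load model

Each cross is Bernoulli with success probability
`R(F) = expit(β0 + β1 F)`; `fit_load_model` fits (β0, β1) by maximum
likelihood (IRLS through `statsmodels` GLM, convergence tolerance 1e-10,
up to 200 iterations) and reports observed-information standard errors
and the two-sided Wald z-test of β1 = 0.  Lines surviving to the stopping
point contribute only their observed crosses; no censoring correction is
applied, matching the per-cross binomial model.  Conversions to load
parameters use overflow-safe identities: `A_R = ln(1 + e^{-β0})` and
`B_R = ln(1 + e^{-(β0+β1)}) − ln(1 + e^{-β0})`; the inverse uses
`β0 = −ln(expm1(A_R))`, which round-trips to ~1e-12 across the usable
coefficient range.

Degenerate designs are errors, not silent regularisations: fewer than two
F levels raises `DesignError`, and an all-same outcome or complete
separation along F raises `FitDegenerateError` naming the condition.  A
Firth-penalised fit (Jeffreys-prior score correction) is available behind
`firth=True` for separated data, off by default because plain ML is the
reference analysis.  Delta-method standard errors for (A_R, B_R)
(`load_standard_errors`) are an optional extension, clearly separate from
the per-coefficient errors.

Stage-wise fits condition exactly as the experiment nests the phenotypes:
copulation on all records, fertility on copulated crosses, development on
fertile crosses.  A degenerate stage returns its exception in the result
mapping without affecting the other stages.

`expected_survival_curve` gives the no-inbreeding-depression null
(`S_g = R(0)^g`, exponential decay at a constant hazard) and the
inbreeding alternative that compounds `R(F_parents(t))` along the actual
F trajectory; the gap between the two curves is the visual signature of
concealed load.

## Lotka–Euler relative fitness

Age x is measured in hours from the initial pairing; the first laying
interval is 0–6 h and subsequent ones 8 h wide, and each interval
contributes its adult-progeny count at the interval midpoint — the
least-biased placement under a piecewise-constant laying rate, since the
source experiments do not state a finer convention.  Only progeny that
reach adulthood are counted; there is no embryo column in the data model.
Survivorship within the laying window is implicitly 1.

`solve_r` finds the unique r > 0 with mean founder `w(r) = 1` by Brent
root-finding on a bracket expanded geometrically from (0, 1]; mean w is
strictly decreasing in r, so the root is unique, and the solution is
polished to `|mean w − 1| < 1e-8`.  Degenerate founder sets (mean total
progeny ≤ 1) only solve under an explicit `allow_nonpositive` flag.
Because x starts at adulthood and laying begins within hours, the solved
r is numerically large (order 1 per hour) — it is a normalising constant,
not an estimate of the intrinsic rate of increase; development time to
maturity is deliberately not added, though a fixed `maturation_offset`
is available for sensitivity analysis.  Zero-progeny females score w = 0
and stay in the analysis; exclusion is reserved for the explicit
censored flag (failed matings, desiccation).  Fitness comparisons are
always founder-vs-descendants within one founder strain, and among-line
heterogeneity uses the tie-corrected Kruskal–Wallis H with its chi-square
p-value (H defined as 0 when every observation is tied).

## Synthetic data

The generator reproduces the statistical structure the estimators assume,
at the canonical design scale: 108 independent lines, up to 20
generations of sib mating.  Stage-level truth is three independent
conditional Bernoullis (matching the conditional analysis exactly); a
single overall (β0, β1) pair may be used instead, in which case records
carry no stage flags.  Maternal-effect lethality is modelled per line per
generation as an event that kills the whole brood regardless of the
development draw — the simplest mechanism producing whole-brood,
non-segregating failure; its rate is a free parameter with default 0, as
no quantitative rate is established.  `analytic_survival` provides the
closed-form survival curve the Monte-Carlo fractions must converge to,
and the acceptance tests check that agreement at 10⁵ lines for
homogeneous, stage-heterogeneous and lethal settings.

Reproductive schedules draw per-interval adult-progeny counts from a
negative binomial (dispersion k, variance μ + μ²/k; k = ∞ gives Poisson)
around a hump-shaped mean profile `w(x) ∝ x e^{-x/12h}` scaled to a
founder total of 250 adult progeny — an overdispersed, early-peaked brood
profile typical of mated *Caenorhabditis* females.  Inbred lines scale
the means by per-line multipliers (default 0.9, 0.4, 0.1: one nearly
fit, one damaged, one severe), may delay laying by whole intervals, or
may be maternal-effect lethal (all counts zero).  Random streams are
split per line via `SeedSequence.spawn`, so enlarging an experiment never
perturbs existing lines.

What the generator does *not* emulate: experimenter/block effects,
among-line random effects in the cross-success hazard, genotype-level
mechanisms (loci, dominance, purging), or within-female laying
autocorrelation.  Passing tests therefore demonstrate correctness of the
estimators under the assumed phenotype-level model, not robustness to
those real-data features.

## Test and calibration scales

Simulation-based checks run at the design scale where the scale itself is
the claim (parameter recovery and Wald coverage: 100 replicates of
108 lines × 20 generations; simulator-vs-oracle: 10⁵ lines) and at
reduced replicate counts for nominal-size checks (300–400 replicates),
with acceptance bands of three binomial or empirical standard errors
throughout.  The tiny likelihood-oracle dataset (8 records) is compared
against a direct Nelder–Mead maximisation of the written-out Bernoulli
log-likelihood to 1e-4.

## Known limitations

* The logistic model pools crosses within strain; no mixed-effects or
  per-line frailty variant is provided.
* Separation handling is binary (error or Firth); there is no profile-
  likelihood confidence interval for near-separated data.
* The Lotka–Euler module models fecundity timing only; survivorship
  schedules l(x) beyond the laying window are out of scope.
* Published per-strain coefficient estimates ship with the package, but
  the raw cross records and reproductive schedules behind them do not;
  quantitative per-line fitness values from the original assays are
  therefore not reproducible here and the fitness module is validated on
  synthetic schedules and closed-form properties instead.
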