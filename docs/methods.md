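# Methods

## Problem and data model

The package links two measurements made on the same mosquito
population: (1) genotype counts at *kdr* loci of the voltage-gated
sodium channel (F1534C, V1016G, S989P; mutant alleles written C, G, P),
and (2) phenotypic resistance, defined as 100 minus the pooled 24 h
mortality percentage of a WHO adult tube bioassay.  The modelling goal
is a function mapping a *predictor* — one mutant allele frequency, or
the sum of two or three of them — to the resistance percentage.

Allele frequencies are simple allele counts: with counts
(n_wild_hom, n_het, n_mut_hom) among n typed individuals, the mutant
frequency is (n_het + 2 n_mut_hom) / (2n).  Frequencies are computed
per locus over the individuals typed at that locus, because typing
success differs between loci within one population.  Arithmetic is kept
at full precision; the reporting layer rounds to 4 decimals with
round-half-to-even.  "Haplotype" tables are unphased multilocus
genotype combinations (labels like CC/VV); no phasing or EM step is
performed, matching how such tables are produced from per-individual
genotype calls.

## WHO classification

Diagnostic-dose bands: mortality ≥ 98 % susceptible, 90–97 % possible
resistance, < 90 % resistant.  The middle band is implemented as the
half-open interval [90, 98) so the three bands tile [0, 100] without an
undefined gap between 97 and 98.  At 5× intensity doses, ≥ 98 %
indicates low-intensity resistance, anything lower moderate-to-high.
Moribund individuals count as dead; the CSV schema carries a single
`dead_24h` column that already includes them.  Abbott's correction
(for control mortality in (5 %, 20 %]; test invalid above 20 %) is
implemented but off by default, since the mortality data this package
mirrors is reported uncorrected.

## Minimax rational fitting

The model class is the classical rational function with monomial bases
and denominator constant term fixed at 1:

    R(x) = sum_i a_i x^{n_i}  /  (1 + sum_j b_j x^{d_j}).

Fixing q(0)'s coefficient removes the p/q scale degeneracy and makes
the error-level constraints linear.  For a level z ≥ 0,

    |y_i q(x_i) − p(x_i)| ≤ z q(x_i),   q(x_i) ≥ δ   for all i

is a linear feasibility system in (a, b), solved with HiGHS via
`scipy.optimize.linprog`.  The set of feasible levels is an interval
[z*, ∞), so z* is located by bisection:

- bracket: lo = 0; hi = (max y − min y)/2 when the numerator contains
  power 0 (the best constant is then feasible with b = 0), otherwise
  max |y|;
- stop when hi − lo ≤ tol (default 1e-9, iteration cap 200);
- the returned model is the solver's witness at the final feasible
  level, so the reported z* overestimates the infimum by at most tol
  and can undershoot it by the LP's feasibility tolerance (~1e-7) —
  uniqueness of the coefficient vector is not promised.

Numerical failures of the LP are treated as infeasible and logged;
this is conservative and keeps the bisection bracket valid.

Safeguards around poles: the denominator floor δ = 1e-6 applies at the
data points during fitting; after fitting, strict positivity of q is
verified on a 1001-point grid over [min x, max x], and a sign change
marks the model invalid.  Evaluation raises a pole error when
|q(x)| < 1e-12 and flags extrapolation outside the fitted domain.

**Degree selection.**  Dense bases (numerator 0..n, denominator 1..m)
are tried descending from (10, 10), decrementing the larger degree
first and both on ties, with (1, 0) and (0, 0) appended so a line and a
constant are always reachable.  The first *suitable* fit wins:
no solver failures, finite coefficients and error, denominator positive
on the domain grid.  If nothing is suitable the best constant is
returned with a warning.

**Conditioning.**  Monomial bases at degree 10 are severely
ill-conditioned; published coefficients of this model family reach
~1e10, and refitting the same data can give wildly different,
numerically equivalent coefficient vectors.  Coefficients are therefore
not a meaningful output surface — predictions and uniform errors are.
Fitting defaults to the raw predictor to mirror the published setup; an
optional affine rescaling of x onto [−1, 1] (`rescale_x`) is stored on
the model and inverted transparently at evaluation.

**Linear comparator.**  `linear_uniform_error` returns the OLS line's
maximum absolute residual.  Published regression "errors" in this model
family do not state whether they are OLS-line max-residuals or best
uniform-line errors; the OLS reading is implemented because the
comparison figures show least-squares regression lines.  The best
uniform line is always available as a minimax fit with basis {0, 1} and
is never worse.

**Published fixtures.**  The seven published models are transcribed
with their decimal coefficient strings.  `evaluate_printed_model`
evaluates them in exact rational arithmetic (`fractions.Fraction`),
rounding only the final ratio: float64 evaluation of these
ill-conditioned coefficient sets can lose up to ~8 significant digits
through cancellation, and float64 *storage* of the coefficients already
perturbs the worst model's predictions at the 1e-8 relative level.  One
transcription quirk is preserved verbatim: Model 5's printed b1 repeats
its a6 value exactly; no silent correction is applied.  Fixture domains
are [0, k] for a k-locus predictor sum.

## Predictor datasets and ranking

`build_predictor` joins allele-frequency records with resistance
percentages by population; the resistance phenotype joined is the same
insecticide phenotype as the genotyped sample (permethrin-resistant
samples pair with permethrin resistance), the only self-consistent
reading of such a design.  Populations missing a required locus are
dropped with a logged count.  `rank_models` orders models by ascending
fitted uniform error, ties broken by model id.

The uniform errors published for this model family are not
recomputable from public material alone — the original fitting dataset
merges 133 in-study samples with 281 samples from an earlier survey,
and the per-population (x, y) pairs are not printed — so the test suite
validates the fitter against independent oracles (exact
reference-subset solutions for polynomial bases, a boxed grid search
plus feasibility cross-checks for rational bases) instead of against
those error values.

## Synthetic studies

`generate_study` emulates the field design: 10 populations (default),
per-locus sample sizes drawn uniformly from [11, 32] (the observed
range of the packaged genotype table), genotypes multinomial under
Hardy–Weinberg with optional inbreeding F (class probabilities
((1−p)² + Fpq, 2pq(1−F), p² + Fpq)), and bioassays of 4 × 25 mosquitoes
with binomial kill counts.  True allele frequencies are drawn uniformly
on [0.05, 0.95] per population and locus.

The planted resistance function is logistic in the predictor, scaled to
[0, 100], with midpoint at the centre of the predictor's range and
steepness 8 — smooth, monotone, spreading resistance over most of its
range across populations, and *not* exactly representable by a
low-degree rational, so recovery tests exercise genuine approximation.
A planted-rational mode exists for exact-recovery tests (zero noise ⇒
fitted uniform error ≤ 1e-6 when the basis contains the planted form).

Noise enters only through binomial sampling of bioassay kills.  The
fitting dataset pairs the *planted* predictor value with the observed
resistance, so the realised noise sup-norm max_i |y_obs − y_true| is
well defined; genotype-count sampling noise exercises the
allele-frequency pipeline separately.  In zero-noise mode genotype
counts are largest-remainder-rounded expectations (integer counts at
n ≤ 32 cannot realise arbitrary frequencies exactly) and the fitting
dataset carries the exact planted values.

What passing synthetic tests do **not** show about real data: real
populations violate Hardy–Weinberg through inbreeding and substructure
(only the F deviation is modelled), bioassay kills are
overdispersed relative to binomial when tube effects exist, resistance
depends on more than the modelled loci (metabolic resistance), and the
true genotype–phenotype relationship need not be monotone or smooth.

## Problem sizes and defaults

Recovery and property tests run at the study's own scale — 10
populations, 4 × 25 bioassays, ≤ 10-point fitting datasets — with
parsimonious dense bases (numerator ≤ 3, denominator ≤ 2) for recovery
checks: with only 10 data points a degree-(10, 10) basis can
interpolate the noise outright, which tests nothing about recovery.
The degree-(10, 10) search remains the default for data analysis,
mirroring the published procedure.

## Known limitations

- The fitter is exact only on the data points; between points a
  high-degree rational may oscillate even with a positive denominator.
  Degree parsimony, the positivity grid and the extrapolation flag
  mitigate but do not eliminate this.
- Bisection cost is one LP per probe (~36 probes at tol 1e-9); very
  large datasets would favour a dedicated quasiconvex solver.
- No uncertainty quantification: coefficients are non-identifiable by
  design, and no confidence band is attached to z* or predictions.
- The WHO band edges are sharp; mortality exactly at a boundary is
  classified by the half-open convention above, which may differ from
  other implementations' rounding.
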