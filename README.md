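# kdrfit

Genotype-to-phenotype analysis of pyrethroid resistance in *Aedes
aegypti*: estimate *kdr* (knockdown-resistance) mutant allele
frequencies from genotype counts, classify WHO adult-bioassay mortality,
and model phenotypic resistance percentage as a best uniform (minimax)
rational function of the allele frequencies.

It is written for vector-surveillance scientists who genotype field
populations at the voltage-gated sodium channel loci F1534C, V1016G and
S989P (mutant alleles *C*, *G*, *P*) and want to predict the phenotypic
resistance a WHO tube bioassay would measure — a genotype assay is far
cheaper than rearing the hundreds of live, age-standardised females a
bioassay consumes.

## The statistics

**Allele frequencies.** For a locus typed in *n* individuals with
counts (wild hom, het, mutant hom), the mutant allele frequency is
(het + 2·mut hom) / 2*n*, computed per locus over the individuals typed
at that locus.

**WHO classification.** Pooled 24 h mortality over treated replicates
(nominally 4 × 25 mosquitoes): ≥ 98 % susceptible, 90–97 % possible
resistance, < 90 % resistant at the diagnostic dose; at a 5× intensity
dose, ≥ 98 % indicates low-intensity resistance. Resistance % =
100 − mortality %.

**Minimax rational models.** Given data (x_i, y_i) — predictor x a
mutant allele frequency (or a sum of them), response y the resistance
percentage — the package fits the classical rational function

    R(x) = (a_0 + a_1 x^{n_1} + ... ) / (1 + b_1 x^{d_1} + ...)

minimising the uniform (Chebyshev) error z = max_i |y_i − R(x_i)|.
For a fixed level z the constraint |y_i − R(x_i)| ≤ z with q(x_i) > 0 is
a pair of linear inequalities in the coefficients, so membership is a
linear feasibility problem and the optimal z* is found by bisection.
Degrees are chosen by trial and error descending from (10, 10).  An
ordinary-least-squares line's maximum absolute residual is reported as
the comparator; the minimax fit can never lose to it in the uniform
norm.

The seven published models (predictors C, G, P, C+G, C+P, G+P, C+G+P)
are packaged as evaluable fixtures with their printed coefficients.

## Worked example

```sh
$ python examples/fit_minimax.py
minimax rational (degree 2/1) uniform error : 6
OLS line uniform error                      : 9.31022
bisection iterations                        : 36
prediction at C = 0.5                       : 52.67 %
```

Seven sigmoid-shaped (C, resistance %) points are fitted with a
degree-(2, 1) rational function.  The uniform error 6 means the worst
data point sits 6 percentage points from the fitted curve — against
9.3 for the best least-squares line, which must average away the bend.
The fitted model predicts 52.7 % phenotypic resistance for a population
with C allele frequency 0.5.

The other example scripts cover allele-frequency estimation
(`allele_frequencies.py`, which reproduces the packaged study table and
its extremes 0.9167 for C and 0.5536 for G), bioassay classification,
the published model fixtures, and a full synthetic study with known
ground truth.

The same stages are available as a CLI:

```sh
kdrfit simulate --seed 7 --outdir study
kdrfit freqs study/genotypes.csv --out allele_freqs.csv
kdrfit bioassay study/bioassay.csv --out mortality.csv
kdrfit fit study/fitdata.csv --start-degree 3
kdrfit report --out report.md
kdrfit evaluate 0.0 --published 3    # -> 0.265
```

## Layout

- `src/kdrfit/genotype_data.py` — genotype counts, allele frequencies,
  multilocus genotype-combination tables
- `src/kdrfit/bioassay.py` — mortality, Abbott correction, WHO bands
- `src/kdrfit/minimax.py` — the bisection / linear-feasibility fitter
- `src/kdrfit/models.py` — the seven predictors, batch fitting, the
  published fixtures
- `src/kdrfit/synthetic.py` — synthetic studies with planted truth
- `src/kdrfit/cli.py` — the `kdrfit` command
- `docs/methods.md` — modelling assumptions and numerical choices
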