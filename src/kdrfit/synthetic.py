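"""Synthetic study generator with known ground truth.

Emulates the field-study design end to end so every pipeline stage is
testable without external data: per-population mutant allele
frequencies at the three vgsc loci, Hardy-Weinberg genotype counts at
realistic per-locus sample sizes (11-32 typed individuals, the observed
range of the genotype table), and WHO bioassays of four replicates of
25 mosquitoes whose kill counts are binomial draws around a planted
smooth resistance-versus-predictor function.

The planted resistance function is logistic by default — smooth,
monotone and *not* exactly representable by a low-degree rational
function, so fits are exercised honestly — with a planted-rational mode
for exact-recovery tests.  Noise enters only through binomial sampling
of bioassay kills, mirroring the measurement process; the fitting
dataset pairs the planted predictor value with the observed resistance
percentage.  Genotype-count sampling noise exercises the
allele-frequency pipeline separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .bioassay import BioassayReplicate, BioassayTest, DoseClass
from .genotype_data import LocusGenotypeCounts, PopulationKey
from .minimax import RationalModel, evaluate

__all__ = [
    "SyntheticScenario",
    "SyntheticTruth",
    "logistic_resistance",
    "sample_genotype_counts",
    "sample_bioassay",
    "generate_study",
]


def logistic_resistance(x, midpoint: float, steepness: float):
    """Logistic resistance %: 100 / (1 + exp(-steepness (x - midpoint)))."""
    x = np.asarray(x, dtype=float)
    out = 100.0 / (1.0 + np.exp(-steepness * (x - midpoint)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one simulated study.

    ``predictor`` names the planted predictor of resistance: ``"C"`` (the
    F1534C mutant frequency alone) or ``"C+G+P"`` (the three-locus sum).
    With the default logistic resistance function the midpoint sits at the
    centre of the predictor's range and the steepness of 8 spreads
    resistance over most of [0, 100] across populations.
    """

    seed: int
    n_populations: int = 10
    n_typed_range: tuple[int, int] = (11, 32)
    replicates: tuple[int, int] = (4, 25)  # (count, size)
    inbreeding_f: float = 0.0
    predictor: Literal["C", "C+G+P"] = "C"
    resistance_function: Literal["logistic", "rational"] = "logistic"
    logistic_midpoint: float | None = None  # default: centre of predictor range
    logistic_steepness: float = 8.0
    planted_model: RationalModel | None = None
    noise: Literal["binomial", "none"] = "binomial"
    freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        lo, hi = self.n_typed_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid n_typed_range")
        if self.replicates[0] < 1 or self.replicates[1] < 1:
            raise ValueError("replicate count and size must be >= 1")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must lie in [0, 1]")
        if self.resistance_function == "rational" and self.planted_model is None:
            raise ValueError("rational resistance function requires planted_model")

    @property
    def predictor_loci(self) -> tuple[str, ...]:
        return ("C",) if self.predictor == "C" else ("C", "G", "P")

    @property
    def predictor_range(self) -> tuple[float, float]:
        return (0.0, float(len(self.predictor_loci)))

    def resistance_at(self, x):
        """Planted true resistance % at predictor value(s) x."""
        if self.resistance_function == "logistic":
            mid = self.logistic_midpoint
            if mid is None:
                mid = 0.5 * sum(self.predictor_range)
            return logistic_resistance(x, mid, self.logistic_steepness)
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        vals = np.array(
            [evaluate(self.planted_model, float(v), warn_extrapolation=False) for v in xs]
        )
        return float(vals[0]) if np.isscalar(x) else vals


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated study (reproducible from the scenario)."""

    scenario: SyntheticScenario
    populations: tuple[PopulationKey, ...]
    true_freqs: tuple[dict[str, float], ...]   # per population: symbol -> freq
    predictor_values: tuple[float, ...]
    true_resistance: tuple[float, ...]
    observed_resistance: tuple[float, ...]

    @property
    def noise_sup_norm(self) -> float:
        """Realised sup-norm of the response noise max_i |y_obs - y_true|."""
        return float(
            np.max(np.abs(np.asarray(self.observed_resistance) - np.asarray(self.true_resistance)))
        )


def _hw_probs(p: float, f: float) -> np.ndarray:
    q = 1.0 - p
    probs = np.array([q * q + f * p * q, 2.0 * p * q * (1.0 - f), p * p + f * p * q])
    if probs.min() < -1e-12 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"invalid genotype probabilities for p={p}, F={f}")
    return np.clip(probs, 0.0, 1.0)


def sample_genotype_counts(
    freq: float,
    n: int,
    f: float,
    rng: np.random.Generator,
    locus: str = "F1534C",
) -> LocusGenotypeCounts:
    """Multinomial Hardy-Weinberg genotype counts, optional inbreeding F.

    Class probabilities are ((1-p)^2 + Fpq, 2pq(1-F), p^2 + Fpq) with
    q = 1 - p, which reduce to Hardy-Weinberg proportions at F = 0 and to
    fixation of homozygotes at F = 1.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = rng.multinomial(n, _hw_probs(freq, f))
    return LocusGenotypeCounts(locus, n, int(counts[0]), int(counts[1]), int(counts[2]))


def _expected_genotype_counts(freq: float, n: int, f: float, locus: str) -> LocusGenotypeCounts:
    """Nearest-integer expected counts (largest-remainder rounding to sum n)."""
    expected = n * _hw_probs(freq, f)
    floors = np.floor(expected).astype(int)
    remainder = expected - floors
    for idx in np.argsort(-remainder)[: n - floors.sum()]:
        floors[idx] += 1
    return LocusGenotypeCounts(locus, n, int(floors[0]), int(floors[1]), int(floors[2]))


def sample_bioassay(
    true_mortality: float,
    rng: np.random.Generator,
    replicates: tuple[int, int] = (4, 25),
    population: PopulationKey | None = None,
    insecticide: str = "permethrin",
    concentration_pct: float = 0.75,
) -> BioassayTest:
    """Binomial kill counts per replicate at a planted true mortality %."""
    if not 0.0 <= true_mortality <= 100.0:
        raise ValueError("true_mortality must lie in [0, 100]")
    count, size = replicates
    dead = rng.binomial(size, true_mortality / 100.0, size=count)
    reps = tuple(BioassayReplicate(size, int(d)) for d in dead)
    return BioassayTest(
        population=population or PopulationKey("synthetic", 0, "synthetic"),
        insecticide=insecticide,
        concentration_pct=concentration_pct,
        dose_class=DoseClass.DIAGNOSTIC,
        replicates=reps,
        control=BioassayReplicate(size, 0, is_control=True),
    )


def generate_study(scenario: SyntheticScenario, outdir: str | Path) -> SyntheticTruth:
    """Generate one full study into ``outdir``.

    Writes ``genotypes.csv`` and ``bioassay.csv`` in the pipeline's input
    schemas, ``fitdata.csv`` pairing the planted predictor with the
    realised resistance %, and ``truth.json`` recording the ground truth.
    Byte-identical across runs for a fixed scenario.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    symbol_to_locus = {"C": "F1534C", "G": "V1016G", "P": "S989P"}
    n_reps, rep_size = scenario.replicates

    populations, freqs_per_pop, xs, y_true, y_obs = [], [], [], [], []
    genotype_rows, bioassay_rows, fit_rows = [], [], []
    for i in range(scenario.n_populations):
        pop = PopulationKey(f"pop{i:02d}", 2020, "synthetic resistant")
        populations.append(pop)
        freqs = {
            sym: float(rng.uniform(*scenario.freq_range)) for sym in ("C", "G", "P")
        }
        freqs_per_pop.append(freqs)
        x = sum(freqs[s] for s in scenario.predictor_loci)
        resistance = float(scenario.resistance_at(x))
        mortality = 100.0 - resistance

        for sym, locus in symbol_to_locus.items():
            n_typed = int(rng.integers(scenario.n_typed_range[0], scenario.n_typed_range[1] + 1))
            if scenario.noise == "binomial":
                counts = sample_genotype_counts(
                    freqs[sym], n_typed, scenario.inbreeding_f, rng, locus
                )
            else:
                counts = _expected_genotype_counts(
                    freqs[sym], n_typed, scenario.inbreeding_f, locus
                )
            genotype_rows.append(
                [pop.site, pop.year, pop.phenotype_label, locus,
                 counts.n_typed, counts.n_wild_hom, counts.n_het, counts.n_mut_hom]
            )

        if scenario.noise == "binomial":
            dead = rng.binomial(rep_size, mortality / 100.0, size=n_reps)
        else:
            exact = n_reps * rep_size * mortality / 100.0
            dead = np.full(n_reps, int(round(exact)) // n_reps)
            dead[: int(round(exact)) % n_reps] += 1
        for rep_id, d in enumerate(dead):
            bioassay_rows.append(
                [pop.site, pop.year, "permethrin", 0.75, "diagnostic",
                 rep_id, rep_size, int(d), 0]
            )
        bioassay_rows.append(
            [pop.site, pop.year, "permethrin", 0.75, "diagnostic",
             n_reps, rep_size, 0, 1]
        )

        if scenario.noise == "binomial":
            observed_mortality = 100.0 * float(np.sum(dead)) / (n_reps * rep_size)
            observed = 100.0 - observed_mortality
        else:
            observed = resistance
        xs.append(x)
        y_true.append(resistance)
        y_obs.append(observed)
        fit_rows.append([scenario.predictor, repr(x), repr(observed)])

    pd.DataFrame(
        genotype_rows,
        columns=["site", "year", "phenotype", "locus",
                 "n_typed", "n_wild_hom", "n_het", "n_mut_hom"],
    ).to_csv(outdir / "genotypes.csv", index=False)
    pd.DataFrame(
        bioassay_rows,
        columns=["site", "year", "insecticide", "concentration_pct", "dose_class",
                 "replicate_id", "exposed", "dead_24h", "is_control"],
    ).to_csv(outdir / "bioassay.csv", index=False)
    pd.DataFrame(fit_rows, columns=["predictor_label", "x", "y"]).to_csv(
        outdir / "fitdata.csv", index=False
    )

    truth = SyntheticTruth(
        scenario=scenario,
        populations=tuple(populations),
        true_freqs=tuple(freqs_per_pop),
        predictor_values=tuple(xs),
        true_resistance=tuple(y_true),
        observed_resistance=tuple(y_obs),
    )
    truth_doc = {
        "seed": scenario.seed,
        "n_populations": scenario.n_populations,
        "predictor": scenario.predictor,
        "resistance_function": scenario.resistance_function,
        "noise": scenario.noise,
        "inbreeding_f": scenario.inbreeding_f,
        "true_freqs": freqs_per_pop,
        "predictor_values": xs,
        "true_resistance": y_true,
        "observed_resistance": y_obs,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=1) + "\n")
    return truth
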