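"""Genotype-count ingestion and kdr allele-frequency estimation.

Populations of *Aedes aegypti* are genotyped at voltage-gated sodium
channel (vgsc) loci carrying knockdown-resistance (kdr) substitutions
(F1534C, V1016G, S989P).  Each locus yields counts of the three diploid
genotype classes — wild homozygote, heterozygote, mutant homozygote —
from which the mutant allele frequency is the allele count divided by
twice the number of typed individuals.  Multilocus genotype combinations
(written CC/VV etc.; unphased, so not gametic haplotypes) are summarised
as simple proportions of individuals typed at every listed locus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LOCI",
    "LocusGenotypeCounts",
    "PopulationKey",
    "AlleleFrequencyRecord",
    "MultilocusGenotypeTable",
    "mutant_allele_frequency",
    "allele_frequency_table",
    "extreme_frequency",
    "genotype_combination_frequencies",
    "combination_labels",
    "read_genotypes_csv",
    "write_allele_freqs_csv",
    "read_multilocus_csv",
    "round4",
]

#: wild / mutant amino-acid letters for each supported vgsc locus
LOCI: dict[str, tuple[str, str]] = {
    "F1534C": ("F", "C"),
    "V1016G": ("V", "G"),
    "S989P": ("S", "P"),
}

GENOTYPES_CSV_COLUMNS = [
    "site", "year", "phenotype", "locus",
    "n_typed", "n_wild_hom", "n_het", "n_mut_hom",
]
MULTILOCUS_CSV_COLUMNS = ["site", "year", "phenotype", "combo_label", "count"]


class EmptyLocusError(ValueError):
    """Raised when a frequency is requested from zero typed individuals."""


@dataclass(frozen=True)
class PopulationKey:
    """A study population: collection site, year and pyrethroid phenotype."""

    site: str
    year: int
    phenotype_label: str

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.site} {self.year} ({self.phenotype_label})"


@dataclass(frozen=True)
class LocusGenotypeCounts:
    """Counts of the three genotype classes at one vgsc locus."""

    locus: str
    n_typed: int
    n_wild_hom: int
    n_het: int
    n_mut_hom: int

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}; expected one of {sorted(LOCI)}")
        for name in ("n_typed", "n_wild_hom", "n_het", "n_mut_hom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_wild_hom + self.n_het + self.n_mut_hom != self.n_typed:
            raise ValueError(
                f"genotype class counts {self.n_wild_hom}+{self.n_het}+{self.n_mut_hom} "
                f"do not sum to n_typed={self.n_typed}"
            )

    @property
    def wild_allele(self) -> str:
        return LOCI[self.locus][0]

    @property
    def mutant_allele(self) -> str:
        return LOCI[self.locus][1]


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    """Mutant allele frequency of one locus in one population."""

    population: PopulationKey
    locus: str
    mutant_freq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutant_freq <= 1.0:
            raise ValueError("mutant_freq must lie in [0, 1]")

    @property
    def wild_freq(self) -> float:
        return 1.0 - self.mutant_freq

    @property
    def mutant_allele(self) -> str:
        return LOCI[self.locus][1]


@dataclass
class MultilocusGenotypeTable:
    """Counts of unphased multilocus genotype combinations (e.g. ``CC/VV``)."""

    population: PopulationKey
    loci: Sequence[str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.loci) not in (2, 3):
            raise ValueError("loci must list 2 or 3 loci")
        valid = set(combination_labels(self.loci))
        for label, count in self.counts.items():
            if label not in valid:
                raise ValueError(f"combination label {label!r} not in the "
                                 f"{len(valid)}-label alphabet for loci {list(self.loci)}")
            if count < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n_complete(self) -> int:
        return sum(self.counts.values())


def combination_labels(loci: Sequence[str]) -> list[str]:
    """All 9 (two-locus) or 27 (three-locus) genotype-combination labels.

    Per-locus genotype order is wild homozygote, heterozygote, mutant
    homozygote (e.g. FF, FC, CC for F1534C).
    """
    per_locus = []
    for locus in loci:
        wild, mut = LOCI[locus]
        per_locus.append([wild + wild, wild + mut, mut + mut])
    return ["/".join(combo) for combo in itertools.product(*per_locus)]


def round4(x: float) -> float:
    """Reporting-layer rounding to 4 decimals, round-half-to-even."""
    return float(Decimal(repr(x)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_EVEN))


def mutant_allele_frequency(counts: LocusGenotypeCounts) -> float:
    """Mutant allele frequency (n_het + 2 n_mut_hom) / (2 n_typed).

    Full precision; use :func:`round4` when formatting for report output.

    Raises
    ------
    EmptyLocusError
        If no individuals were typed at the locus.
    """
    if counts.n_typed < 1:
        raise EmptyLocusError(f"no individuals typed at {counts.locus}")
    return (counts.n_het + 2 * counts.n_mut_hom) / (2 * counts.n_typed)


def allele_frequency_table(
    rows: Iterable[tuple[PopulationKey, LocusGenotypeCounts]],
) -> list[AlleleFrequencyRecord]:
    """One :class:`AlleleFrequencyRecord` per (population, locus) pair.

    Duplicate (population, locus) pairs are rejected: counts for the same
    locus in the same population must be pooled upstream, not listed twice.
    """
    records: list[AlleleFrequencyRecord] = []
    seen: set[tuple[PopulationKey, str]] = set()
    for population, counts in rows:
        key = (population, counts.locus)
        if key in seen:
            raise ValueError(f"duplicate entry for {population} locus {counts.locus}")
        seen.add(key)
        records.append(
            AlleleFrequencyRecord(population, counts.locus, mutant_allele_frequency(counts))
        )
    return records


def extreme_frequency(
    records: Iterable[AlleleFrequencyRecord], locus: str
) -> tuple[list[AlleleFrequencyRecord], float]:
    """Maximum mutant frequency at a locus and every population attaining it.

    Returns ``(argmax_records, max_freq)``; the list has more than one entry
    only on an exact tie.
    """
    at_locus = [r for r in records if r.locus == locus]
    if not at_locus:
        raise ValueError(f"no records for locus {locus!r}")
    best = max(r.mutant_freq for r in at_locus)
    return [r for r in at_locus if r.mutant_freq == best], best


def genotype_combination_frequencies(table: MultilocusGenotypeTable) -> dict[str, float]:
    """Proportion of completely typed individuals per genotype combination.

    Every label of the combination alphabet appears in the output (zero for
    unobserved combinations); proportions sum to 1 within 1e-12.
    """
    total = table.n_complete
    if total < 1:
        raise ValueError("empty table: no individuals typed at all listed loci")
    freqs = {label: 0.0 for label in combination_labels(table.loci)}
    for label, count in table.counts.items():
        freqs[label] = count / total
    return freqs


# ---------------------------------------------------------------------------
# CSV interfaces


def read_genotypes_csv(path: str | Path) -> list[tuple[PopulationKey, LocusGenotypeCounts]]:
    """Read the ``genotypes.csv`` schema.

    Header: ``site,year,phenotype,locus,n_typed,n_wild_hom,n_het,n_mut_hom``.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in GENOTYPES_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    rows = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            population = PopulationKey(str(row["site"]), int(row["year"]), str(row["phenotype"]))
            counts = LocusGenotypeCounts(
                locus=str(row["locus"]),
                n_typed=int(row["n_typed"]),
                n_wild_hom=int(row["n_wild_hom"]),
                n_het=int(row["n_het"]),
                n_mut_hom=int(row["n_mut_hom"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
        rows.append((population, counts))
    return rows


def write_allele_freqs_csv(records: Sequence[AlleleFrequencyRecord], path: str | Path) -> None:
    """Write ``allele_freqs.csv`` with 4-decimal frequency formatting."""
    df = pd.DataFrame(
        {
            "site": [r.population.site for r in records],
            "year": [r.population.year for r in records],
            "phenotype": [r.population.phenotype_label for r in records],
            "locus": [r.locus for r in records],
            "mutant_allele": [r.mutant_allele for r in records],
            "mutant_freq": [f"{round4(r.mutant_freq):.4f}" for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_multilocus_csv(path: str | Path, loci: Sequence[str]) -> list[MultilocusGenotypeTable]:
    """Read ``multilocus.csv`` (site,year,phenotype,combo_label,count)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MULTILOCUS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    tables: dict[PopulationKey, dict[str, int]] = {}
    for _, row in df.iterrows():
        pop = PopulationKey(str(row["site"]), int(row["year"]), str(row["phenotype"]))
        tables.setdefault(pop, {})[str(row["combo_label"])] = int(row["count"])
    return [MultilocusGenotypeTable(pop, loci, counts) for pop, counts in tables.items()]
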