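"""WHO adult-bioassay mortality, resistance percentage and classification.

A WHO tube test exposes replicates of adult female mosquitoes (nominally
4 tubes x 25 mosquitoes, plus one untreated control tube) to an
insecticide-impregnated paper for 1 h; dead plus knocked-down-and-
incapacitated individuals at 24 h count as susceptible.  Pooled mortality
across treated replicates classifies the population:

* diagnostic dose — >=98% mortality: susceptible; [90, 98): possible
  resistance; <90%: resistant;
* 5x intensity dose — >=98%: low-intensity resistance; otherwise
  moderate-to-high intensity.

Resistance percentage is 100 minus mortality percentage and is the
response variable of the genotype-to-phenotype models.

Abbott's correction for control mortality between 5% and 20% is provided
but disabled by default: the source mortality data this package mirrors
is reported uncorrected.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .genotype_data import PopulationKey

__all__ = [
    "DoseClass",
    "DiagnosticClass",
    "IntensityClass",
    "AbbottVerdict",
    "BioassayReplicate",
    "BioassayTest",
    "MortalityResult",
    "mortality_percent",
    "abbott_correction",
    "classify_diagnostic",
    "classify_intensity",
    "read_bioassay_csv",
    "write_mortality_csv",
]

BIOASSAY_CSV_COLUMNS = [
    "site", "year", "insecticide", "concentration_pct", "dose_class",
    "replicate_id", "exposed", "dead_24h", "is_control",
]


class DoseClass(str, enum.Enum):
    DIAGNOSTIC = "diagnostic"
    INTENSITY_5X = "intensity_5x"


class DiagnosticClass(str, enum.Enum):
    SUSCEPTIBLE = "susceptible"
    POSSIBLE_RESISTANCE = "possible_resistance"
    RESISTANT = "resistant"


class IntensityClass(str, enum.Enum):
    LOW_INTENSITY = "low_intensity"
    MODERATE_TO_HIGH = "moderate_to_high"


class AbbottVerdict(str, enum.Enum):
    """Outcome of applying the control-mortality rule."""

    UNCORRECTED = "uncorrected"
    CORRECTED = "corrected"
    TEST_INVALID = "test_invalid"


@dataclass(frozen=True)
class BioassayReplicate:
    """One tube: mosquitoes exposed and dead (incl. moribund) at 24 h."""

    exposed: int
    dead_24h: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.exposed < 1:
            raise ValueError("exposed must be >= 1")
        if not 0 <= self.dead_24h <= self.exposed:
            raise ValueError(
                f"dead_24h={self.dead_24h} outside [0, exposed={self.exposed}]"
            )


@dataclass(frozen=True)
class BioassayTest:
    """One insecticide x concentration assay on one population."""

    population: PopulationKey
    insecticide: str
    concentration_pct: float
    dose_class: DoseClass
    replicates: tuple[BioassayReplicate, ...]
    control: BioassayReplicate | None = None

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("at least one treated replicate is required")
        if any(r.is_control for r in self.replicates):
            raise ValueError("treated replicate list must not contain controls")


@dataclass(frozen=True)
class MortalityResult:
    """Pooled mortality with its WHO classification."""

    mortality_pct: float
    resistance_pct: float
    classification: DiagnosticClass | IntensityClass
    corrected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.mortality_pct <= 100.0:
            raise ValueError("mortality_pct must lie in [0, 100]")


def classify_diagnostic(mortality_pct: float) -> DiagnosticClass:
    """WHO diagnostic-dose band for a mortality percentage.

    The printed "90-97%" band is implemented as the half-open interval
    [90, 98) so the three bands tile [0, 100] without gaps.
    """
    if not 0.0 <= mortality_pct <= 100.0:
        raise ValueError("mortality percentage must lie in [0, 100]")
    if mortality_pct >= 98.0:
        return DiagnosticClass.SUSCEPTIBLE
    if mortality_pct >= 90.0:
        return DiagnosticClass.POSSIBLE_RESISTANCE
    return DiagnosticClass.RESISTANT


def classify_intensity(mortality_pct: float) -> IntensityClass:
    """WHO 5x-intensity band: >=98% mortality is low-intensity resistance."""
    if not 0.0 <= mortality_pct <= 100.0:
        raise ValueError("mortality percentage must lie in [0, 100]")
    if mortality_pct >= 98.0:
        return IntensityClass.LOW_INTENSITY
    return IntensityClass.MODERATE_TO_HIGH


def abbott_correction(
    treated_mortality: float, control_mortality: float
) -> tuple[float | None, AbbottVerdict]:
    """Abbott's control-mortality correction.

    Control <= 5%: treated mortality returned unchanged.  Control in
    (5%, 20%]: returns 100 (T - C) / (100 - C).  Control > 20%: the test is
    invalid and ``(None, TEST_INVALID)`` is returned.  A corrected value
    below 0 (treated mortality under control mortality) is clamped to 0
    with a warning.
    """
    for name, v in (("treated", treated_mortality), ("control", control_mortality)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} mortality must lie in [0, 100]")
    if control_mortality <= 5.0:
        return treated_mortality, AbbottVerdict.UNCORRECTED
    if control_mortality > 20.0:
        return None, AbbottVerdict.TEST_INVALID
    corrected = 100.0 * (treated_mortality - control_mortality) / (100.0 - control_mortality)
    if corrected < 0.0:
        warnings.warn(
            "treated mortality below control mortality; corrected value clamped to 0",
            stacklevel=2,
        )
        corrected = 0.0
    return min(corrected, 100.0), AbbottVerdict.CORRECTED


def mortality_percent(test: BioassayTest, apply_abbott: bool = False) -> MortalityResult:
    """Pooled 24 h mortality over treated replicates, classified by dose class.

    ``apply_abbott=True`` applies :func:`abbott_correction` using the control
    tube (if present); an invalid test raises.
    """
    exposed = sum(r.exposed for r in test.replicates)
    dead = sum(r.dead_24h for r in test.replicates)
    mortality = 100.0 * dead / exposed
    corrected = False
    if apply_abbott and test.control is not None:
        control_mortality = 100.0 * test.control.dead_24h / test.control.exposed
        value, verdict = abbott_correction(mortality, control_mortality)
        if verdict is AbbottVerdict.TEST_INVALID:
            raise ValueError(
                f"control mortality {control_mortality:.1f}% > 20%: test invalid"
            )
        if verdict is AbbottVerdict.CORRECTED:
            mortality = value  # type: ignore[assignment]
            corrected = True
    if test.dose_class is DoseClass.INTENSITY_5X:
        classification: DiagnosticClass | IntensityClass = classify_intensity(mortality)
    else:
        classification = classify_diagnostic(mortality)
    return MortalityResult(
        mortality_pct=mortality,
        resistance_pct=100.0 - mortality,
        classification=classification,
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_bioassay_csv(path: str | Path) -> list[BioassayTest]:
    """Read ``bioassay.csv`` and assemble one test per
    (site, year, insecticide, concentration, dose class)."""
    df = pd.read_csv(path)
    missing = [c for c in BIOASSAY_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    tests = []
    keys = ["site", "year", "insecticide", "concentration_pct", "dose_class"]
    for (site, year, insecticide, conc, dose), grp in df.groupby(keys, sort=True):
        treated, control = [], None
        for _, row in grp.iterrows():
            rep = BioassayReplicate(
                exposed=int(row["exposed"]),
                dead_24h=int(row["dead_24h"]),
                is_control=bool(int(row["is_control"])),
            )
            if rep.is_control:
                control = rep
            else:
                treated.append(BioassayReplicate(rep.exposed, rep.dead_24h))
        tests.append(
            BioassayTest(
                population=PopulationKey(str(site), int(year), str(insecticide)),
                insecticide=str(insecticide),
                concentration_pct=float(conc),
                dose_class=DoseClass(str(dose)),
                replicates=tuple(treated),
                control=control,
            )
        )
    return tests


def write_mortality_csv(
    tests_and_results: Iterable[tuple[BioassayTest, MortalityResult]],
    path: str | Path,
) -> None:
    """Write ``mortality.csv`` (one classified row per assay)."""
    rows = []
    for test, result in tests_and_results:
        rows.append(
            {
                "site": test.population.site,
                "year": test.population.year,
                "insecticide": test.insecticide,
                "concentration_pct": test.concentration_pct,
                "dose_class": test.dose_class.value,
                "mortality_pct": f"{result.mortality_pct:.4f}",
                "resistance_pct": f"{result.resistance_pct:.4f}",
                "classification": result.classification.value,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
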