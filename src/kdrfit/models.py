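"""The seven genotype-to-phenotype resistance models.

Each model relates one predictor — a single mutant kdr allele frequency
(C = F1534C, G = V1016G, P = S989P) or a sum of two or three of them —
to the phenotypic resistance percentage (100 minus bioassay mortality).
This module builds the seven predictor datasets from joined allele
frequencies and mortality results, fits them with the minimax rational
engine, summarises fitted and linear-comparator uniform errors, and
packages the previously published model coefficients as evaluable
fixtures.

The published coefficients reach magnitudes of ~1e10, a signature of
severe ill-conditioning of the monomial basis at degree <= 10; fixture
evaluation therefore reproduces predictions and uniform errors, not the
coefficients themselves, and new fits will generally find different
(equally optimal) coefficient vectors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genotype_data import AlleleFrequencyRecord, PopulationKey
from .minimax import (
    BasisSpec,
    FitDataset,
    FitResult,
    RationalModel,
    degree_search,
    linear_uniform_error,
    model_to_dict,
)

__all__ = [
    "PREDICTOR_SPECS",
    "PredictorSpec",
    "ModelSummary",
    "printed_model",
    "printed_model_terms",
    "evaluate_printed_model",
    "build_predictor",
    "fit_all_models",
    "rank_models",
    "write_summary_csv",
    "write_models_json",
]

logger = logging.getLogger(__name__)

#: allele symbol -> locus name
SYMBOL_TO_LOCUS = {"C": "F1534C", "G": "V1016G", "P": "S989P"}


@dataclass(frozen=True)
class PredictorSpec:
    """Which mutant allele frequencies are summed to form the predictor."""

    model_id: int
    loci_summed: frozenset[str]

    def __post_init__(self) -> None:
        if not self.loci_summed or not self.loci_summed <= {"C", "G", "P"}:
            raise ValueError("loci_summed must be a non-empty subset of {C, G, P}")

    @property
    def label(self) -> str:
        return "+".join(s for s in "CGP" if s in self.loci_summed)

    @property
    def domain(self) -> tuple[float, float]:
        return (0.0, float(len(self.loci_summed)))


PREDICTOR_SPECS: tuple[PredictorSpec, ...] = (
    PredictorSpec(1, frozenset("C")),
    PredictorSpec(2, frozenset("G")),
    PredictorSpec(3, frozenset("P")),
    PredictorSpec(4, frozenset("CG")),
    PredictorSpec(5, frozenset("CP")),
    PredictorSpec(6, frozenset("GP")),
    PredictorSpec(7, frozenset("CGP")),
)


@dataclass(frozen=True)
class ModelSummary:
    """One row of the model-comparison summary."""

    model_id: int
    predictor: str
    uniform_error: float | None
    linear_uniform_error: float | None
    status: str


# ---------------------------------------------------------------------------
# Published model fixtures
#
# Coefficients are stored as the exact decimal strings of the published
# tables so that a high-precision oracle can re-evaluate them without a
# float round trip.  Model 5's b1 duplicates its a6 verbatim in the
# source table (a likely transcription artefact there); it is kept as
# printed, without correction.

_PRINTED: dict[int, dict] = {
    1: {
        "numerator": [
            (0, "-923296331.8627"), (1, "6380109874.0697"), (2, "-13473410689.6903"),
            (4, "-28532687959.5758"), (6, "-85005552114.6877"), (7, "101202429859.4744"),
            (8, "-36864215471.3718"),
        ],
        "denominator": [
            (1, "977656565.50054"), (2, "-5549465100.10692"), (3, "9462195446.17072"),
            (5, "-11956488868.64405"), (7, "16094216688.79076"), (8, "-9133869507.80082"),
        ],
    },
    2: {
        "numerator": [
            (0, "0.265"), (1, "72.623546"), (2, "-1753.282611"),
            (4, "587661.614865"), (5, "-3658541.295479"), (10, "2791813478.236963"),
        ],
        "denominator": [
            (3, "22210.172599"), (5, "317108.798456"), (7, "-73562577.313898"),
            (10, "6460398372.242500"),
        ],
    },
    3: {
        "numerator": [
            (0, "0.265000000"), (1, "21.770418667"), (2, "-689.751733001"),
            (3, "4574.275487255"), (5, "100363.819053150"), (7, "-9832564.821468228"),
        ],
        "denominator": [
            (3, "-20761.7526681"), (4, "351809.4233696"), (6, "-27622486.3631150"),
            (7, "124158795.6834685"),
        ],
    },
    4: {
        "numerator": [
            (0, "347231.89871471"), (2, "-5451048.06473052"), (4, "51173428.72019885"),
            (5, "-85704569.96654052"), (7, "76784470.23534042"), (9, "-68790001.27416702"),
            (10, "31638575.86718503"),
        ],
        "denominator": [
            (1, "7890147.9804573"), (2, "-34553409.8652851"), (4, "210801390.1094063"),
            (5, "-327273010.8525403"), (7, "268191635.6432237"), (9, "-227546166.070013"),
            (10, "102477501.8803313"),
        ],
    },
    5: {
        "numerator": [
            (0, "2268560.18995798"), (1, "-13665908.18768946"), (2, "25073847.09740878"),
            (4, "-39784443.81799661"), (6, "88661124.33358555"), (7, "-91510924.12885486"),
            (8, "28981251.69289512"),
        ],
        "denominator": [
            (1, "28981251.69289512"), (3, "164958.059405934"), (4, "-2274557.572140106"),
            (6, "4000282.615553982"), (8, "-3111181.159339364"),
        ],
    },
    6: {
        "numerator": [
            (0, "0.265000000"), (1, "-7.610292612"), (4, "28033.919141146"),
            (5, "-109436.419251507"), (10, "6933109.075299110"),
        ],
        "denominator": [
            (1, "-30.87308061"), (3, "4346.23483591"), (7, "-1035659.71583039"),
            (10, "19900821.93857696"),
        ],
    },
    7: {
        "numerator": [
            (0, "716166607.22713"), (1, "-2830518552.86041"), (3, "10388466329.42499"),
            (5, "-37716698071.84403"), (6, "40370145440.69236"), (8, "-13600454700.55536"),
            (10, "2678494991.40093"),
        ],
        "denominator": [
            (1, "8017117875.1734"), (2, "-47249603859.7930"), (3, "86218011175.7724"),
            (5, "-171072974438.1670"), (6, "163788016008.2528"), (8, "-48590946801.6674"),
            (10, "8907013521.3133"),
        ],
    },
}

#: published uniform error per model, for ranking/reporting comparisons
PRINTED_UNIFORM_ERRORS: dict[int, float] = {
    1: 4.44788e-4,
    2: 0.06502,
    3: 0.065,
    4: 0.02291,
    5: 0.05706,
    6: 0.065,
    7: 6.85122e-4,
}


def printed_model_terms(model_id: int) -> dict:
    """Raw (power, decimal-string coefficient) terms of a published model."""
    if model_id not in _PRINTED:
        raise KeyError(f"no published fixture for model {model_id}")
    return _PRINTED[model_id]


def printed_model(model_id: int) -> RationalModel:
    """A published model as an evaluable :class:`RationalModel`."""
    terms = printed_model_terms(model_id)
    spec = PREDICTOR_SPECS[model_id - 1]
    return RationalModel(
        basis=BasisSpec(
            tuple(p for p, _ in terms["numerator"]),
            tuple(p for p, _ in terms["denominator"]),
        ),
        numer_coeffs=tuple(float(c) for _, c in terms["numerator"]),
        denom_coeffs=tuple(float(c) for _, c in terms["denominator"]),
        domain=spec.domain,
    )


def evaluate_printed_model(model_id: int, x: float) -> float:
    """Predicted resistance % of a published model at predictor value x.

    Evaluates the transcribed decimal coefficients in exact rational
    arithmetic (the published coefficients reach ~1e10 and largely cancel,
    so float64 evaluation can lose up to ~8 significant digits near the
    worst-conditioned predictor values); only the final ratio is rounded
    to a float.  Raises a pole error when the printed denominator is
    exactly zero at x.
    """
    terms = printed_model_terms(model_id)
    spec = PREDICTOR_SPECS[model_id - 1]
    lo, hi = spec.domain
    if not lo <= x <= hi:
        import warnings

        warnings.warn(
            f"model {model_id} evaluated outside its domain [{lo}, {hi}]: extrapolation",
            stacklevel=2,
        )
    xf = Fraction(x)
    p = sum(Fraction(c) * xf**pw for pw, c in terms["numerator"])
    q = 1 + sum(Fraction(c) * xf**pw for pw, c in terms["denominator"])
    if q == 0:
        raise ZeroDivisionError(f"model {model_id} has a pole at x={x}")
    return float(p / q)


# ---------------------------------------------------------------------------
# Dataset construction and batch fitting


def build_predictor(
    freq_records: Iterable[AlleleFrequencyRecord],
    resistance: Mapping[PopulationKey, float],
    spec: PredictorSpec,
) -> FitDataset:
    """Join allele frequencies with resistance % into one (x, y) dataset.

    x is the sum of mutant allele frequencies over the spec's loci; y is
    the population's resistance percentage.  Populations missing any
    required locus or a resistance value are dropped (logged with a count).
    """
    required = {SYMBOL_TO_LOCUS[s] for s in spec.loci_summed}
    by_pop: dict[PopulationKey, dict[str, float]] = {}
    for rec in freq_records:
        by_pop.setdefault(rec.population, {})[rec.locus] = rec.mutant_freq
    xs, ys, dropped = [], [], 0
    for pop, freqs in by_pop.items():
        if not required <= freqs.keys() or pop not in resistance:
            dropped += 1
            continue
        y = resistance[pop]
        if not 0.0 <= y <= 100.0:
            raise ValueError(f"resistance % for {pop} outside [0, 100]: {y}")
        xs.append(sum(freqs[locus] for locus in sorted(required)))
        ys.append(y)
    if dropped:
        logger.info(
            "model %d (%s): dropped %d population(s) lacking a required locus "
            "or resistance value", spec.model_id, spec.label, dropped,
        )
    if not xs:
        raise ValueError(
            f"model {spec.model_id}: no population has all of {sorted(required)} "
            "plus a resistance percentage"
        )
    return FitDataset(x=tuple(xs), y=tuple(ys), predictor_label=spec.label)


def fit_all_models(
    freq_records: Iterable[AlleleFrequencyRecord],
    resistance: Mapping[PopulationKey, float],
    specs: Sequence[PredictorSpec] = PREDICTOR_SPECS,
    start_degree: tuple[int, int] = (10, 10),
    tol: float = 1e-9,
    rescale_x: bool = False,
) -> tuple[list[ModelSummary], dict[int, FitResult]]:
    """Fit every predictor spec; failures are recorded, not raised.

    Returns the summary rows (one per spec, in spec order) and the
    successful :class:`FitResult` objects keyed by model id.
    """
    freq_records = list(freq_records)
    summaries: list[ModelSummary] = []
    fits: dict[int, FitResult] = {}
    for spec in specs:
        try:
            data = build_predictor(freq_records, resistance, spec)
            if len(data) < 2:
                raise ValueError("fewer than 2 populations after joining")
            _, result = degree_search(
                data, start_degree=start_degree, tol=tol, rescale_x=rescale_x
            )
            try:
                _, _, lin_err = linear_uniform_error(data)
            except ValueError:
                lin_err = None
            fits[spec.model_id] = result
            summaries.append(
                ModelSummary(
                    model_id=spec.model_id,
                    predictor=spec.label,
                    uniform_error=result.uniform_error,
                    linear_uniform_error=lin_err,
                    status=result.status,
                )
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("model %d failed: %s", spec.model_id, exc)
            summaries.append(
                ModelSummary(spec.model_id, spec.label, None, None, f"error: {exc}")
            )
    return summaries, fits


def rank_models(summaries: Iterable[ModelSummary]) -> list[int]:
    """Model ids ordered by ascending fitted uniform error; stable on ties.

    Models without a fitted error (failed fits) sort last, in id order.
    """
    rows = sorted(summaries, key=lambda s: s.model_id)
    if not rows:
        raise ValueError("no summaries to rank")
    return [
        s.model_id
        for s in sorted(
            rows,
            key=lambda s: (s.uniform_error is None,
                           s.uniform_error if s.uniform_error is not None else 0.0),
        )
    ]


def write_summary_csv(summaries: Sequence[ModelSummary], path: str | Path) -> None:
    """Model-comparison summary: id, predictor, fitted and linear errors."""

    def fmt(v: float | None) -> str:
        return "" if v is None else f"{v:.6g}"

    df = pd.DataFrame(
        {
            "model_id": [s.model_id for s in summaries],
            "predictor": [s.predictor for s in summaries],
            "uniform_error": [fmt(s.uniform_error) for s in summaries],
            "linear_uniform_error": [fmt(s.linear_uniform_error) for s in summaries],
            "status": [s.status for s in summaries],
        }
    )
    df.to_csv(path, index=False)


def write_models_json(
    summaries: Sequence[ModelSummary],
    fits: Mapping[int, FitResult],
    path: str | Path,
) -> None:
    """Bundle of fitted model documents plus summary rows."""
    docs = []
    for s in summaries:
        entry: dict = {
            "model_id": s.model_id,
            "predictor": s.predictor,
            "status": s.status,
            "linear_uniform_error": s.linear_uniform_error,
        }
        if s.model_id in fits:
            result = fits[s.model_id]
            entry["model"] = model_to_dict(
                result.model,
                predictor_label=s.predictor,
                uniform_error=result.uniform_error,
                fitted_on=f"{len(result.model.basis.numerator_powers)}-term numerator fit",
            )
        docs.append(entry)
    Path(path).write_text(json.dumps(docs, indent=1) + "\n")
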