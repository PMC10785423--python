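"""Best uniform (minimax, Chebyshev) rational approximation on a point set.

The model class is the classical rational function

    R(x) = p(x) / q(x),    p(x) = sum_i a_i x^{n_i},
                           q(x) = 1 + sum_j b_j x^{d_j},

with monomial bases and the denominator's constant term fixed at 1 (this
removes the p/q scale degeneracy).  Given data (x_i, y_i), the fit
minimises the uniform error

    z* = min_{a,b} max_i | y_i - p(x_i)/q(x_i) |

subject to q(x_i) >= delta > 0.  For a fixed error level z the constraint
|y_i - p/q| <= z with q > 0 is equivalent to the pair of linear
inequalities

    y_i q(x_i) - p(x_i) <= z q(x_i)
    p(x_i) - y_i q(x_i) <= z q(x_i)

so membership of z in the feasible set is a linear feasibility problem in
the coefficients (a, b), solved here by linear programming (HiGHS).  The
feasible set of levels is an interval [z*, inf), hence z* is located by
bisection: each probe either produces witness coefficients (level
feasible, shrink from above) or a certificate of infeasibility (shrink
from below).

This quasiconvex reformulation-plus-bisection approach is standard for
discrete rational Chebyshev approximation; no Remez-type exchange is
performed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "BasisSpec",
    "RationalModel",
    "FitDataset",
    "FitResult",
    "PoleError",
    "evaluate",
    "feasible_at_level",
    "fit_minimax",
    "uniform_error",
    "degree_search",
    "linear_uniform_error",
    "model_to_dict",
    "model_from_dict",
    "save_model_json",
    "load_model_json",
    "read_fitdata_csv",
]

logger = logging.getLogger(__name__)

#: default absolute bisection tolerance on the error level z
DEFAULT_TOL = 1e-9
#: default lower floor on the denominator at the data points
DEFAULT_DELTA = 1e-6
#: default cap on bisection iterations
DEFAULT_MAX_ITER = 200
#: grid size for the post-fit denominator positivity check
POSITIVITY_GRID = 1001
#: default cap on monomial powers
DEGREE_CAP = 10


class PoleError(ZeroDivisionError):
    """Denominator vanishes (|q(x)| < 1e-12) at an evaluation point."""


@dataclass(frozen=True)
class BasisSpec:
    """Monomial powers of the numerator and denominator.

    The denominator's power-0 term is implicit (coefficient fixed at 1) and
    therefore excluded from ``denominator_powers``.
    """

    numerator_powers: tuple[int, ...]
    denominator_powers: tuple[int, ...] = ()
    degree_cap: int = DEGREE_CAP

    def __post_init__(self) -> None:
        num = tuple(self.numerator_powers)
        den = tuple(self.denominator_powers)
        object.__setattr__(self, "numerator_powers", num)
        object.__setattr__(self, "denominator_powers", den)
        if not num:
            raise ValueError("numerator basis must be non-empty")
        if len(set(num)) != len(num) or list(num) != sorted(num):
            raise ValueError("numerator powers must be sorted and distinct")
        if len(set(den)) != len(den) or list(den) != sorted(den):
            raise ValueError("denominator powers must be sorted and distinct")
        if any(p < 0 for p in num) or any(p < 1 for p in den):
            raise ValueError(
                "numerator powers must be >= 0 and denominator powers >= 1 "
                "(the denominator constant term is fixed at 1)"
            )
        if max(num + den) > self.degree_cap:
            raise ValueError(f"powers exceed the degree cap {self.degree_cap}")

    @classmethod
    def dense(cls, num_degree: int, den_degree: int, degree_cap: int = DEGREE_CAP) -> "BasisSpec":
        """Dense basis 0..num_degree over 1..den_degree."""
        return cls(
            tuple(range(num_degree + 1)),
            tuple(range(1, den_degree + 1)),
            degree_cap=max(degree_cap, num_degree, den_degree),
        )

    @property
    def n_free(self) -> int:
        return len(self.numerator_powers) + len(self.denominator_powers)


@dataclass(frozen=True)
class RationalModel:
    """A concrete rational function: basis, coefficients and valid domain.

    ``x_offset``/``x_scale`` hold an optional affine predictor transform
    u = (x - x_offset) / x_scale applied before the polynomials are
    evaluated (identity by default).  Fitting in a rescaled coordinate
    tames the conditioning of high-degree monomial bases; the transform
    travels with the model so callers always evaluate in raw x.
    """

    basis: BasisSpec
    numer_coeffs: tuple[float, ...]
    denom_coeffs: tuple[float, ...]
    domain: tuple[float, float] = (0.0, 1.0)
    x_offset: float = 0.0
    x_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "numer_coeffs", tuple(float(c) for c in self.numer_coeffs))
        object.__setattr__(self, "denom_coeffs", tuple(float(c) for c in self.denom_coeffs))
        if len(self.numer_coeffs) != len(self.basis.numerator_powers):
            raise ValueError("numer_coeffs length does not match basis")
        if len(self.denom_coeffs) != len(self.basis.denominator_powers):
            raise ValueError("denom_coeffs length does not match basis")
        if self.domain[0] > self.domain[1]:
            raise ValueError("empty domain")
        if self.x_scale == 0.0:
            raise ValueError("x_scale must be nonzero")

    def _u(self, x):
        return (np.asarray(x, dtype=float) - self.x_offset) / self.x_scale

    def numerator(self, x):
        u = self._u(x)
        return sum(
            c * u**p for c, p in zip(self.numer_coeffs, self.basis.numerator_powers)
        ) + np.zeros_like(u)

    def denominator(self, x):
        u = self._u(x)
        return 1.0 + sum(
            c * u**p for c, p in zip(self.denom_coeffs, self.basis.denominator_powers)
        ) + np.zeros_like(u)

    def denominator_positive(self, grid_size: int = POSITIVITY_GRID) -> bool:
        """Strict positivity of q on an evenly spaced grid over the domain."""
        lo, hi = self.domain
        grid = np.linspace(lo, hi, grid_size) if hi > lo else np.array([lo])
        return bool(np.all(self.denominator(grid) > 0.0))


def evaluate(model: RationalModel, x, *, warn_extrapolation: bool = True):
    """Evaluate ``p(x)/q(x)``; scalar in, scalar out.

    Outside the model's domain the value is still returned but an
    extrapolation warning is emitted.  A denominator below 1e-12 in
    magnitude raises :class:`PoleError`.
    """
    scalar = np.isscalar(x)
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = model.domain
    if warn_extrapolation and (xv.min() < lo or xv.max() > hi):
        warnings.warn(
            f"evaluating outside the model domain [{lo}, {hi}]: extrapolation",
            stacklevel=2,
        )
    q = model.denominator(xv)
    bad = np.abs(q) < 1e-12
    if np.any(bad):
        raise PoleError(f"denominator vanishes at x={xv[bad][0]!r}")
    out = model.numerator(xv) / q
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class FitDataset:
    """Observed (predictor, response) pairs for fitting."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    predictor_label: str = "x"

    def __post_init__(self) -> None:
        xs = tuple(float(v) for v in self.x)
        ys = tuple(float(v) for v in self.y)
        object.__setattr__(self, "x", xs)
        object.__setattr__(self, "y", ys)
        if len(xs) != len(ys):
            raise ValueError("x and y must have equal length")
        if len(xs) < 1:
            raise ValueError("dataset is empty")
        if not all(np.isfinite(xs)) or not all(np.isfinite(ys)):
            raise ValueError("x and y must be finite")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def domain(self) -> tuple[float, float]:
        return (min(self.x), max(self.x))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a minimax fit: witness model and certified error bracket."""

    model: RationalModel
    uniform_error: float          # z*, the final feasible level
    bracket: tuple[float, float]  # (largest infeasible probe, final feasible level)
    iterations: int
    status: str                   # "ok", "constant_fallback", "invalid_denominator", ...
    solver_failures: int = 0


def _design(data: FitDataset, basis: BasisSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(data.x, dtype=float)
    y = np.asarray(data.y, dtype=float)
    phi = np.column_stack([x**p for p in basis.numerator_powers])
    if basis.denominator_powers:
        psi = np.column_stack([x**p for p in basis.denominator_powers])
    else:
        psi = np.zeros((len(x), 0))
    return phi, psi, y


def feasible_at_level(
    data: FitDataset,
    basis: BasisSpec,
    z: float,
    delta: float = DEFAULT_DELTA,
) -> tuple[bool, np.ndarray | None]:
    """Decide whether uniform error level ``z`` is attainable over ``basis``.

    Solves the linear feasibility system (one coefficient vector for all
    points): for every i,

        |y_i q(x_i) - p(x_i)| <= z q(x_i),    q(x_i) >= delta,

    with q's constant term fixed at 1.  Returns ``(True, coefficients)``
    with a witness ``[a..., b...]`` when feasible.  A numerical solver
    failure is conservatively reported as infeasible (and logged), which
    keeps any enclosing bisection bracket valid.
    """
    if z < 0:
        raise ValueError("error level z must be >= 0")
    if delta <= 0:
        raise ValueError("denominator floor delta must be > 0")
    phi, psi, y = _design(data, basis)
    k, m = phi.shape[1], psi.shape[1]
    # rows: y q - p <= z q ; p - y q <= z q ; -q <= -delta
    a_upper = np.hstack([-phi, (y - z)[:, None] * psi])
    b_upper = -(y - z)
    a_lower = np.hstack([phi, -(y + z)[:, None] * psi])
    b_lower = y + z
    rows = [a_upper, a_lower]
    rhs = [b_upper, b_lower]
    if m:
        rows.append(np.hstack([np.zeros((len(y), k)), -psi]))
        rhs.append(np.full(len(y), 1.0 - delta))
    a_ub = np.vstack(rows)
    b_ub = np.concatenate(rhs)
    try:
        res = linprog(
            c=np.zeros(k + m),
            A_ub=a_ub,
            b_ub=b_ub,
            bounds=[(None, None)] * (k + m),
            method="highs",
        )
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("feasibility solver raised at level z=%g: %s", z, exc)
        return False, None
    if res.status == 0:
        return True, np.asarray(res.x)
    if res.status != 2:  # not a clean infeasibility certificate
        logger.warning(
            "feasibility solver status %d at level z=%g treated as infeasible", res.status, z
        )
    return False, None


def _result_from_witness(
    data: FitDataset,
    basis: BasisSpec,
    witness: np.ndarray,
    z_feasible: float,
    z_infeasible: float,
    iterations: int,
    status: str,
    solver_failures: int,
    x_offset: float = 0.0,
    x_scale: float = 1.0,
) -> FitResult:
    k = len(basis.numerator_powers)
    model = RationalModel(
        basis=basis,
        numer_coeffs=tuple(witness[:k]),
        denom_coeffs=tuple(witness[k:]),
        domain=data.domain,
        x_offset=x_offset,
        x_scale=x_scale,
    )
    return FitResult(
        model=model,
        uniform_error=z_feasible,
        bracket=(z_infeasible, z_feasible),
        iterations=iterations,
        status=status,
        solver_failures=solver_failures,
    )


def fit_minimax(
    data: FitDataset,
    basis: BasisSpec,
    tol: float = DEFAULT_TOL,
    delta: float = DEFAULT_DELTA,
    max_iter: int = DEFAULT_MAX_ITER,
    rescale_x: bool = False,
) -> FitResult:
    """Best uniform rational fit by bisection on the error level.

    The bracket starts at ``lo = 0`` and ``hi`` = the best-constant error
    (max-min)/2 when power 0 belongs to the numerator basis, else
    ``max |y|`` (both levels are feasible by construction with a zero
    denominator part).  Bisection stops when ``hi - lo <= tol``; the
    returned model is the solver witness at the final feasible level, so
    ``uniform_error`` overestimates the true infimum by at most ``tol``.

    ``rescale_x=True`` fits in the affine coordinate u mapping the data
    range onto [-1, 1]; the transform is stored on the returned model and
    inverted transparently on evaluation.
    """
    if len(data) < 2:
        raise ValueError("fitting requires at least 2 points")
    x_offset, x_scale = 0.0, 1.0
    fit_data = data
    if rescale_x:
        lo_x, hi_x = data.domain
        if hi_x > lo_x:
            x_offset = 0.5 * (lo_x + hi_x)
            x_scale = 0.5 * (hi_x - lo_x)
            fit_data = FitDataset(
                tuple((xi - x_offset) / x_scale for xi in data.x),
                data.y,
                data.predictor_label,
            )
    y = np.asarray(data.y)
    if 0 in basis.numerator_powers:
        hi = float(y.max() - y.min()) / 2.0
    else:
        hi = float(np.abs(y).max())
    failures = 0

    feasible, witness = feasible_at_level(fit_data, basis, hi, delta)
    if not feasible:
        # should not occur for the constructive brackets above; only a
        # numerical failure can land here, so widen once before giving up
        failures += 1
        hi = max(2.0 * hi, 1.0)
        feasible, witness = feasible_at_level(fit_data, basis, hi, delta)
        if not feasible:
            raise RuntimeError(
                "initial error bracket infeasible: feasibility solver failed "
                f"at level z={hi!r}"
            )

    lo = 0.0
    iterations = 0
    # z=0 may already be feasible (data exactly representable)
    feasible0, witness0 = feasible_at_level(fit_data, basis, 0.0, delta)
    if feasible0:
        return _result_from_witness(
            data, basis, witness0, 0.0, 0.0, 0, "ok", failures, x_offset, x_scale
        )
    while hi - lo > tol and iterations < max_iter:
        mid = 0.5 * (lo + hi)
        iterations += 1
        ok, cand = feasible_at_level(fit_data, basis, mid, delta)
        if ok:
            hi, witness = mid, cand
        else:
            lo = mid
    return _result_from_witness(
        data, basis, witness, hi, lo, iterations, "ok", failures, x_offset, x_scale
    )


def uniform_error(model: RationalModel, data: FitDataset) -> float:
    """Maximum absolute residual max_i |y_i - R(x_i)| of a model on data."""
    preds = evaluate(model, np.asarray(data.x), warn_extrapolation=False)
    return float(np.max(np.abs(np.asarray(data.y) - preds)))


def _degree_sequence(start: tuple[int, int]) -> list[tuple[int, int]]:
    """Descending (numerator, denominator) degree trials.

    The larger degree is decremented first; ties decrement both.  The
    sequence is completed with (1, 0) and (0, 0) so a plain line and a
    constant are always tried before giving up.
    """
    seq = []
    n, m = start
    while n >= 1 or m >= 1:
        seq.append((n, m))
        if n > m:
            n -= 1
        elif m > n:
            m -= 1
        else:
            n, m = n - 1, m - 1
        if n < 0 or m < 0:
            break
    for tail in [(1, 0), (0, 0)]:
        if tail not in seq:
            seq.append(tail)
    return seq


def _suitable(result: FitResult) -> bool:
    coeffs = result.model.numer_coeffs + result.model.denom_coeffs
    return (
        result.solver_failures == 0
        and np.isfinite(result.uniform_error)
        and all(np.isfinite(c) for c in coeffs)
        and result.model.denominator_positive()
    )


def degree_search(
    data: FitDataset,
    start_degree: tuple[int, int] = (10, 10),
    tol: float = DEFAULT_TOL,
    delta: float = DEFAULT_DELTA,
    rescale_x: bool = False,
) -> tuple[BasisSpec, FitResult]:
    """Trial-and-error degree selection, descending from ``start_degree``.

    Dense bases are fitted in decreasing degree order and the first
    *suitable* fit is returned.  A fit is suitable when the feasibility
    solver reported no numerical failures, all coefficients and the error
    level are finite, and the fitted denominator is strictly positive on a
    1001-point grid over the data range.  If no basis down to a line is
    suitable the best constant is returned with status
    ``"constant_fallback"`` and a warning.
    """
    last_constant: FitResult | None = None
    for n_deg, m_deg in _degree_sequence(start_degree):
        basis = BasisSpec.dense(n_deg, m_deg)
        try:
            result = fit_minimax(data, basis, tol=tol, delta=delta, rescale_x=rescale_x)
        except (RuntimeError, ValueError):
            continue
        if (n_deg, m_deg) == (0, 0):
            last_constant = result
        if _suitable(result):
            return basis, result
    warnings.warn("no suitable rational basis found; falling back to the best constant")
    if last_constant is None:
        basis = BasisSpec((0,))
        last_constant = fit_minimax(data, basis, tol=tol, delta=delta)
    fallback = FitResult(
        model=last_constant.model,
        uniform_error=last_constant.uniform_error,
        bracket=last_constant.bracket,
        iterations=last_constant.iterations,
        status="constant_fallback",
        solver_failures=last_constant.solver_failures,
    )
    return fallback.model.basis, fallback


def linear_uniform_error(data: FitDataset) -> tuple[float, float, float]:
    """Uniform-norm error of the ordinary least-squares line.

    Returns ``(slope, intercept, max |residual|)``.  This is the
    comparator for the minimax fits: an OLS line minimises the sum of
    squares, so its maximum absolute residual is at least the best
    uniform line's error.
    """
    x = np.asarray(data.x)
    y = np.asarray(data.y)
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("the least-squares line needs >= 2 distinct x values")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    max_resid = float(np.max(np.abs(y - (slope * x + intercept))))
    return float(slope), float(intercept), max_resid


# ---------------------------------------------------------------------------
# Serialization


def model_to_dict(
    model: RationalModel,
    predictor_label: str = "x",
    uniform_error: float | None = None,
    fitted_on: str | None = None,
) -> dict:
    """JSON-ready document; floats survive a round trip bit-exactly."""
    return {
        "predictor_label": predictor_label,
        "domain": list(model.domain),
        "numerator": [
            {"power": p, "coeff": c}
            for p, c in zip(model.basis.numerator_powers, model.numer_coeffs)
        ],
        "denominator": [
            {"power": p, "coeff": c}
            for p, c in zip(model.basis.denominator_powers, model.denom_coeffs)
        ],
        "x_offset": model.x_offset,
        "x_scale": model.x_scale,
        "uniform_error": uniform_error,
        "fitted_on": fitted_on,
    }


def model_from_dict(doc: dict) -> RationalModel:
    num = sorted(doc["numerator"], key=lambda t: t["power"])
    den = sorted(doc["denominator"], key=lambda t: t["power"])
    powers = [t["power"] for t in num] + [t["power"] for t in den]
    basis = BasisSpec(
        tuple(t["power"] for t in num),
        tuple(t["power"] for t in den),
        degree_cap=max([DEGREE_CAP] + powers),
    )
    return RationalModel(
        basis=basis,
        numer_coeffs=tuple(t["coeff"] for t in num),
        denom_coeffs=tuple(t["coeff"] for t in den),
        domain=tuple(doc["domain"]),
        x_offset=doc.get("x_offset", 0.0),
        x_scale=doc.get("x_scale", 1.0),
    )


def save_model_json(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model_json(path: str | Path) -> RationalModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def read_fitdata_csv(path: str | Path) -> FitDataset:
    """Read ``fitdata.csv`` (predictor_label,x,y)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("predictor_label", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    labels = df["predictor_label"].unique()
    if len(labels) != 1:
        raise ValueError(f"{path}: expected a single predictor_label, found {list(labels)}")
    return FitDataset(
        x=tuple(df["x"].astype(float)),
        y=tuple(df["y"].astype(float)),
        predictor_label=str(labels[0]),
    )
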