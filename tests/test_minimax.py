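import json

import numpy as np
import pytest

from oracles import best_uniform_line, best_uniform_polynomial, grid_minimax

from kdrfit.minimax import (
    BasisSpec,
    FitDataset,
    PoleError,
    RationalModel,
    degree_search,
    evaluate,
    feasible_at_level,
    fit_minimax,
    linear_uniform_error,
    load_model_json,
    model_from_dict,
    model_to_dict,
    save_model_json,
    uniform_error,
)


def rational(num, den, xs):
    """Sample y = p(x)/q(x) for planted coefficient dicts {power: coeff}."""
    xs = np.asarray(xs, float)
    p = sum(c * xs**k for k, c in num.items())
    q = 1.0 + sum(c * xs**k for k, c in den.items())
    return p / q


class TestBasisSpec:
    def test_dense(self):
        basis = BasisSpec.dense(3, 2)
        assert basis.numerator_powers == (0, 1, 2, 3)
        assert basis.denominator_powers == (1, 2)
        assert basis.n_free == 6

    def test_invalid_bases_rejected(self):
        with pytest.raises(ValueError):
            BasisSpec(())
        with pytest.raises(ValueError):
            BasisSpec((0, 0))
        with pytest.raises(ValueError):
            BasisSpec((0,), (0,))  # denominator constant term is implicit
        with pytest.raises(ValueError):
            BasisSpec((0, 11))  # beyond the degree cap


class TestEvaluate:
    def test_hand_evaluation(self):
        model = RationalModel(BasisSpec((0, 1), (1,)), (1.0, 2.0), (1.0,))
        assert evaluate(model, 1.0) == pytest.approx(1.5)

    def test_constant_model(self):
        model = RationalModel(BasisSpec((0,)), (42.0,), ())
        for x in (0.0, 0.3, 1.0):
            assert evaluate(model, x) == 42.0

    def test_pole_raises(self):
        model = RationalModel(BasisSpec((0,), (1,)), (1.0,), (-1.0,))  # q = 1 - x
        with pytest.raises(PoleError):
            evaluate(model, 1.0)

    def test_extrapolation_warns(self):
        model = RationalModel(BasisSpec((0,)), (1.0,), (), domain=(0.0, 1.0))
        with pytest.warns(UserWarning, match="extrapolation"):
            evaluate(model, 2.0)

    def test_rescaled_model_evaluates_in_raw_x(self):
        # u = (x - 1) / 2; R(u) = u  ->  R(3.0) = 1.0
        model = RationalModel(BasisSpec((1,)), (1.0,), (), domain=(-1.0, 3.0),
                              x_offset=1.0, x_scale=2.0)
        assert evaluate(model, 3.0) == pytest.approx(1.0)


class TestFeasibility:
    def test_representable_data_feasible_at_zero(self):
        xs = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        ys = rational({0: 1.0, 1: 2.0}, {1: 0.5}, xs)
        ok, witness = feasible_at_level(
            FitDataset(tuple(xs), tuple(ys)), BasisSpec((0, 1), (1,)), 0.0
        )
        assert ok and witness is not None

    def test_constant_bound_infeasible_below_half_range(self):
        data = FitDataset((0.0, 1.0, 2.0), (10.0, 30.0, 20.0))
        ok, _ = feasible_at_level(data, BasisSpec((0,)), 9.99)
        assert not ok
        ok, _ = feasible_at_level(data, BasisSpec((0,)), 10.0)
        assert ok

    def test_negative_level_rejected(self):
        data = FitDataset((0.0, 1.0), (0.0, 1.0))
        with pytest.raises(ValueError):
            feasible_at_level(data, BasisSpec((0,)), -1.0)


class TestFitMinimax:
    def test_constant_law(self):
        data = FitDataset((0.0, 1.0, 2.0), (10.0, 20.0, 30.0))
        result = fit_minimax(data, BasisSpec((0,)), tol=1e-9)
        # slack: the LP's feasibility tolerance lets z* undershoot by ~1e-7
        assert result.uniform_error == pytest.approx(10.0, abs=1e-6)
        assert result.model.numer_coeffs[0] == pytest.approx(20.0, abs=1e-6)

    def test_exact_representability(self):
        xs = np.linspace(0.1, 0.9, 6)
        ys = rational({0: 1.0, 1: 2.0}, {1: 0.5}, xs)
        result = fit_minimax(FitDataset(tuple(xs), tuple(ys)), BasisSpec((0, 1), (1,)))
        assert result.uniform_error <= 1e-9

    def test_bracket_certificate(self):
        rng = np.random.default_rng(5)
        data = FitDataset(tuple(np.linspace(0, 1, 7)), tuple(rng.uniform(0, 100, 7)))
        basis = BasisSpec((0, 1), (1,))
        tol = 1e-9
        result = fit_minimax(data, basis, tol=tol)
        z = result.uniform_error
        assert z > tol
        assert feasible_at_level(data, basis, z + tol)[0]
        assert not feasible_at_level(data, basis, z - tol)[0]
        lo, hi = result.bracket
        assert hi - lo <= tol

    def test_residual_bound(self):
        rng = np.random.default_rng(7)
        data = FitDataset(tuple(np.linspace(0, 1, 8)), tuple(rng.uniform(0, 100, 8)))
        result = fit_minimax(data, BasisSpec((0, 1, 2), (1,)))
        assert uniform_error(result.model, data) <= result.uniform_error + 1e-6

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        xs = tuple(np.linspace(0, 1, 6))
        ys = rng.uniform(0, 50, 6)
        basis = BasisSpec((0, 1), (1,))
        z1 = fit_minimax(FitDataset(xs, tuple(ys)), basis).uniform_error
        z3 = fit_minimax(FitDataset(xs, tuple(3.0 * ys)), basis).uniform_error
        assert z3 == pytest.approx(3.0 * z1, rel=1e-6)

    def test_nesting_monotonicity(self):
        rng = np.random.default_rng(13)
        data = FitDataset(tuple(np.linspace(0, 1, 8)), tuple(rng.uniform(0, 100, 8)))
        small = fit_minimax(data, BasisSpec((0, 1))).uniform_error
        larger = fit_minimax(data, BasisSpec((0, 1, 2), (1,))).uniform_error
        assert larger <= small + 1e-8

    def test_minimax_line_beats_ols_line(self):
        rng = np.random.default_rng(17)
        data = FitDataset(tuple(np.linspace(0, 2, 9)), tuple(rng.uniform(0, 100, 9)))
        _, _, ols_err = linear_uniform_error(data)
        z = fit_minimax(data, BasisSpec((0, 1))).uniform_error
        assert z <= ols_err + 1e-9

    def test_matches_exact_line_oracle(self):
        """LP route agrees with the 3-point-subset characterisation of the
        best uniform line."""
        rng = np.random.default_rng(19)
        for _ in range(10):
            xs = np.sort(rng.uniform(0, 1, 6))
            ys = rng.uniform(0, 100, 6)
            z = fit_minimax(FitDataset(tuple(xs), tuple(ys)), BasisSpec((0, 1))).uniform_error
            assert z == pytest.approx(best_uniform_line(xs, ys), abs=1e-6)

    def test_matches_exact_quadratic_oracle(self):
        """LP route agrees with the exact (k+1)-point-reference oracle."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            xs = np.sort(rng.uniform(0.05, 1, 6))
            ys = rng.uniform(0, 100, 6)
            z = fit_minimax(FitDataset(tuple(xs), tuple(ys)), BasisSpec((0, 1, 2))).uniform_error
            assert z == pytest.approx(best_uniform_polynomial(xs, ys, (0, 1, 2)), abs=1e-6)

    def test_consistent_with_grid_search_with_denominator(self):
        """With a free denominator the optimal coefficient set is unbounded
        (near-projective scaling), so a boxed search only upper-bounds z*;
        the LP must never exceed that bound, and must accept the grid's
        level as feasible."""
        rng = np.random.default_rng(23)
        xs = np.sort(rng.uniform(0.0, 1.0, 6))
        ys = rational({0: 10.0, 1: 25.0}, {1: 0.8}, xs) + rng.normal(0, 2.0, 6)
        data = FitDataset(tuple(xs), tuple(ys))
        z_lp = fit_minimax(data, BasisSpec((0, 1), (1,))).uniform_error
        z_grid, _ = grid_minimax(
            xs, ys, (0, 1), (1,),
            box=[(-20.0, 40.0), (-10.0, 60.0), (-0.5, 2.0)],
        )
        assert z_lp <= z_grid + 1e-6
        assert feasible_at_level(data, BasisSpec((0, 1), (1,)), z_grid + 1e-9)[0]

    def test_rescale_x_changes_coordinates_not_fit(self):
        rng = np.random.default_rng(29)
        xs = np.linspace(10.0, 12.0, 8)
        ys = rng.uniform(0, 100, 8)
        data = FitDataset(tuple(xs), tuple(ys))
        plain = fit_minimax(data, BasisSpec((0, 1, 2)))
        scaled = fit_minimax(data, BasisSpec((0, 1, 2)), rescale_x=True)
        assert scaled.uniform_error == pytest.approx(plain.uniform_error, abs=1e-6)
        grid = np.linspace(10.0, 12.0, 11)
        np.testing.assert_allclose(
            evaluate(scaled.model, grid, warn_extrapolation=False),
            evaluate(plain.model, grid, warn_extrapolation=False),
            atol=1e-4,
        )

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_minimax(FitDataset((1.0,), (2.0,)), BasisSpec((0,)))


class TestDegreeSearch:
    def test_line_data(self):
        xs = np.linspace(0, 1, 12)
        data = FitDataset(tuple(xs), tuple(3.0 + 2.0 * xs))
        _, result = degree_search(data)
        assert result.uniform_error <= 1e-7
        assert result.model.denominator_positive()

    def test_constant_data(self):
        data = FitDataset(tuple(np.linspace(0, 1, 5)), (7.0,) * 5)
        _, result = degree_search(data)
        assert result.uniform_error == pytest.approx(0.0, abs=1e-9)

    def test_planted_near_pole_outside_domain(self):
        # q = 1 - 0.9 x has its zero at x = 1.11, outside the data range
        xs = np.linspace(0.0, 0.95, 12)
        ys = rational({0: 5.0, 1: 10.0}, {1: -0.9}, xs)
        basis, result = degree_search(data := FitDataset(tuple(xs), tuple(ys)))
        assert result.uniform_error <= 1e-6
        assert result.model.denominator_positive()
        assert uniform_error(result.model, data) <= result.uniform_error + 1e-6


class TestLinearUniformError:
    def test_collinear(self):
        xs = np.linspace(0, 1, 5)
        slope, intercept, err = linear_uniform_error(
            FitDataset(tuple(xs), tuple(2.0 * xs + 1.0))
        )
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_symmetric_case(self):
        # symmetric data: the OLS line is flat at the mean 10/3
        slope, intercept, err = linear_uniform_error(
            FitDataset((0.0, 1.0, 2.0), (0.0, 10.0, 0.0))
        )
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(10.0 / 3.0)
        assert err == pytest.approx(20.0 / 3.0)

    def test_identical_x_rejected(self):
        with pytest.raises(ValueError):
            linear_uniform_error(FitDataset((1.0, 1.0), (0.0, 5.0)))


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path):
        rng = np.random.default_rng(31)
        data = FitDataset(tuple(np.linspace(0, 1, 7)), tuple(rng.uniform(0, 100, 7)))
        result = fit_minimax(data, BasisSpec((0, 1, 2), (1,)))
        doc = model_to_dict(result.model, "C", result.uniform_error, "test data")
        path = tmp_path / "model.json"
        save_model_json(doc, path)
        restored = load_model_json(path)
        assert restored == result.model  # dataclass equality: bit-exact floats

    def test_dict_round_trip_through_json_text(self):
        model = RationalModel(
            BasisSpec((0, 2), (1,)), (0.1 + 0.2, -1e-17), (3.141592653589793,)
        )
        doc = json.loads(json.dumps(model_to_dict(model)))
        assert model_from_dict(doc) == model
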