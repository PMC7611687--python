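"""Closed-form and iterative equilibrium solvers, and their agreement."""

import numpy as np
import pytest

from normgame import (
    AltruismSpec,
    CommunityParams,
    ExponentialAttitudeModel,
    LinearAttitudeModel,
    check_uniqueness,
    foc_residual,
    reciprocal_system_exists,
    solve_best_response,
    solve_closed_form,
)
from normgame.equilibrium import boundary_residual_norm
from conftest import random_linear_instance


class TestFocResidual:
    def test_zero_at_scenario1_equilibrium(self, scenario1):
        p, model = scenario1
        res = foc_residual(np.full((10, 10), 0.05), p, model)
        assert res == pytest.approx(np.zeros((10, 10)), abs=1e-15)

    def test_upward_pressure_at_zero_effort(self, scenario1):
        """With no effort, each woman's marginal benefit of persuasion is
        s(1-t) n f / c = 0.05 > 0 everywhere."""
        p, model = scenario1
        res = foc_residual(np.zeros((10, 10)), p, model)
        assert res == pytest.approx(np.full((10, 10), 0.05))

    @pytest.mark.parametrize(
        "alt",
        [
            AltruismSpec.none(),
            AltruismSpec.process(0.4),
            AltruismSpec.empathetic(0.6),
            AltruismSpec.reciprocal(0.07),
        ],
    )
    def test_solver_output_satisfies_foc(self, scenario1, alt):
        p, model = scenario1
        state = solve_best_response(p, model, alt)
        assert state.exists and state.converged
        assert state.max_foc_residual < 1e-8


class TestClosedForm:
    def test_scenario1_baseline(self, scenario1):
        p, model = scenario1
        st = solve_closed_form(p, model)
        assert st.efforts == pytest.approx(np.full((10, 10), 0.05))
        assert st.attitudes == pytest.approx(np.full(10, 1.95))
        assert st.violence == pytest.approx(np.full(10, 19.5))
        assert st.welfare == pytest.approx(np.full(10, -19.5125))

    def test_scenario2_baseline(self, scenario2):
        p, model = scenario2
        st = solve_closed_form(p, model)
        assert st.efforts == pytest.approx(np.full((20, 20), 0.9375))
        assert st.attitudes == pytest.approx(np.full(20, 0.125))
        assert st.violence == pytest.approx(np.full(20, 31.25))

    def test_reciprocal_near_boundary(self, scenario1):
        p, model = scenario1
        st = solve_closed_form(p, model, AltruismSpec.reciprocal(0.095))
        assert st.exists
        assert st.efforts == pytest.approx(np.full((10, 10), 1.0))
        assert st.violence == pytest.approx(np.full(10, 10.0))

    def test_reciprocal_nonexistence_at_one_over_n(self, scenario1):
        p, model = scenario1
        st = solve_closed_form(p, model, AltruismSpec.reciprocal(0.1))
        assert not st.exists and not st.converged
        assert np.all(np.isnan(st.violence))

    def test_requires_linear_model(self):
        p = CommunityParams.homogeneous(3)
        model = ExponentialAttitudeModel(intercepts=np.full(3, 2.0), slopes=0.1)
        with pytest.raises(TypeError):
            solve_closed_form(p, model)

    def test_reciprocal_scaling_law(self, scenario1):
        """Symmetric unit-cost communities obey e*(rho) = e*(0) / (1 - n rho),
        increasing without bound as rho approaches 1/n."""
        p, model = scenario1
        e0 = solve_closed_form(p, model).efforts[0, 0]
        prev = 0.0
        for rho in (0.02, 0.05, 0.08, 0.095):
            e = solve_closed_form(p, model, AltruismSpec.reciprocal(rho)).efforts[0, 0]
            assert e == pytest.approx(e0 / (1 - 10 * rho))
            assert e > prev
            prev = e

    def test_zero_slope_entries_give_boundary_efforts(self):
        """Dyads whose persuasion has no effect settle at zero effort with a
        nonpositive first-order condition (complementarity)."""
        p = CommunityParams.homogeneous(4)
        slopes = np.full((4, 4), 0.1)
        slopes[2, :] = 0.0  # nobody can move man 3's attitude
        model = LinearAttitudeModel(intercepts=np.full(4, 2.0), slopes=slopes)
        st = solve_closed_form(p, model)
        assert np.all(st.efforts[2, :] == 0.0)
        res = foc_residual(st.efforts, p, model)
        assert np.all(res[2, :] <= 0.0)

    def test_baseline_effort_monotonic_in_parameters(self):
        """Closed-form effort rises with suffering, norm payoffs and slopes,
        falls with effort cost, violence cost and tolerance."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            p, model = random_linear_instance(rng)
            e = solve_closed_form(p, model).efforts
            up = CommunityParams(n=p.n, s=p.s * 1.5, t=p.t, c=p.c, N=p.N, D=p.D)
            assert np.all(solve_closed_form(up, model).efforts >= e)
            up = CommunityParams(n=p.n, s=p.s, t=p.t, c=p.c, N=p.N * 1.5, D=p.D)
            assert np.all(solve_closed_form(up, model).efforts >= e)
            down = CommunityParams(n=p.n, s=p.s, t=p.t, c=p.c * 2, N=p.N, D=p.D)
            assert np.all(solve_closed_form(down, model).efforts <= e)
            down = CommunityParams(n=p.n, s=p.s, t=p.t, c=p.c, N=p.N, D=p.D * 2)
            assert np.all(solve_closed_form(down, model).efforts <= e)
            down = CommunityParams(
                n=p.n, s=p.s, t=1 - 0.5 * (1 - p.t), c=p.c, N=p.N, D=p.D
            )
            assert np.all(solve_closed_form(down, model).efforts <= e)


class TestExistenceTest:
    def test_symmetric_threshold_is_one_over_n(self, scenario1):
        p, _ = scenario1
        assert reciprocal_system_exists(p, 0.0999)
        assert not reciprocal_system_exists(p, 0.1)
        assert not reciprocal_system_exists(p, 0.25)

    def test_heterogeneous_costs_shift_threshold(self):
        # d == 2 everywhere doubles the symmetric threshold to 2/n
        p = CommunityParams.homogeneous(5, effort_cost=2.0)
        assert reciprocal_system_exists(p, 0.39)
        assert not reciprocal_system_exists(p, 0.4)


class TestBestResponseSolver:
    def test_matches_closed_form_scenario1(self, scenario1):
        p, model = scenario1
        st = solve_best_response(p, model)
        ref = solve_closed_form(p, model)
        assert st.converged
        assert st.efforts == pytest.approx(ref.efforts, abs=1e-9)

    def test_fixed_point_converges_immediately(self, scenario1):
        p, model = scenario1
        ref = solve_closed_form(p, model)
        st = solve_best_response(p, model, init=ref.efforts)
        assert st.converged and st.iterations == 1

    def test_reciprocal_nonexistence_flagged(self, scenario1):
        p, model = scenario1
        st = solve_best_response(
            p, model, AltruismSpec.reciprocal(0.1), init=np.full((10, 10), 0.05)
        )
        assert not st.exists

    def test_oracle_equivalence_on_random_instances(self):
        """Iterative and closed-form solvers agree entrywise on random
        linear communities across all altruism variants."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            p, model = random_linear_instance(rng)
            variant = rng.choice(["none", "process", "empathetic", "reciprocal"])
            if variant == "reciprocal":
                weight = 0.5 * float(p.D.min()) / p.n
            elif variant == "none":
                weight = 0.0
            else:
                weight = float(rng.uniform(0, 1))
            alt = AltruismSpec(variant, weight)
            ref = solve_closed_form(p, model, alt)
            st = solve_best_response(p, model, alt)
            assert st.exists and st.converged
            assert np.abs(st.efforts - ref.efforts).max() < 1e-8

    def test_nonlinear_model_satisfies_foc(self):
        """The generic scalar-root path handles a strictly convex attitude
        model: the returned profile satisfies the first-order conditions."""
        p = CommunityParams.homogeneous(3)
        model = ExponentialAttitudeModel(intercepts=np.full(3, 2.0), slopes=0.3)
        st = solve_best_response(p, model, tol=1e-11)
        assert st.exists and st.converged
        assert boundary_residual_norm(st.efforts, p, model) < 1e-8
        assert np.all(st.attitudes > 0) and np.all(st.attitudes < 2)

    def test_invalid_options_rejected(self, scenario1):
        p, model = scenario1
        with pytest.raises(ValueError):
            solve_best_response(p, model, damping=0.0)
        with pytest.raises(ValueError):
            solve_best_response(p, model, tol=-1e-3)


class TestUniqueness:
    def test_scenario1_unique(self, scenario1):
        p, model = scenario1
        report = check_uniqueness(p, model, n_starts=10, seed=0)
        assert report.verdict == "unique"
        assert report.max_pairwise_distance < 1e-6

    def test_scenario2_unique(self, scenario2):
        p, model = scenario2
        report = check_uniqueness(p, model, n_starts=5, seed=0)
        assert report.verdict == "unique"

    def test_nonexistent_reciprocal_inconclusive(self, scenario1):
        p, model = scenario1
        report = check_uniqueness(
            p, model, AltruismSpec.reciprocal(0.1), n_starts=3, seed=0
        )
        assert report.verdict == "inconclusive"

    def test_requires_two_starts(self, scenario1):
        p, model = scenario1
        with pytest.raises(ValueError):
            check_uniqueness(p, model, n_starts=1)
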