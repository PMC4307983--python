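"""Model-core tests: reductions, vector field, equilibria, scans, timing."""

import numpy as np
import pytest

from galswitch import (
    BISTABLE,
    MONO_OFF,
    MONO_ON,
    ModelParams,
    SpeciesState,
    SugarSchedule,
    basin_fraction_on,
    bifurcation_scan,
    default_params,
    delta_b,
    dominant_eigenvalue,
    find_equilibria,
    quasi_static_regimes,
    reduced_inputs,
    regime_map,
    rhs,
    simulate,
)
from galswitch.model import jacobian

from _oracles import binding_equilibrium_ode, equilibria_1d


# ---------------------------------------------------------------- parameters


class TestDefaultParams:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            default_params("bogus")
        with pytest.raises(ValueError, match="unknown variant"):
            ModelParams(variant="bogus")

    def test_reduced_affinity_matches_published_perturbation(self):
        """K_R scaled by 1.25 gives the published perturbed thresholds."""
        p = default_params("repressor")
        assert p.k_r1 * 1.25 == pytest.approx(80.8, abs=1e-9)
        assert p.k_r4 * 1.25 == pytest.approx(40.6, abs=1e-9)

    def test_default_set_is_bistable_at_150nM_gal(self, params):
        """The shipped defaults produce a bistable band at 150 nM galactose."""
        grid = np.geomspace(2.0, 1000.0, 12)
        rm = regime_map(params, grid, np.array([150.0]))
        assert rm.bistable_area >= 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(d=-0.1)
        with pytest.raises(ValueError):
            ModelParams(n_a=0.5)

    def test_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        params.to_yaml(path)
        assert ModelParams.from_yaml(path) == params


# ---------------------------------------------------------- fast equilibrium


class TestReducedInputs:
    def test_no_galactose_means_no_activated_g1(self, params):
        st = SpeciesState(100.0, 30.0, 20.0, 10.0)
        alg = reduced_inputs(st, params, glu=50.0, gal=0.0)
        assert alg.g1_star == 0.0

    def test_weak_binding_limit_frees_everything(self, params):
        st = SpeciesState(100.0, 30.0, 20.0, 0.0)
        p = params.replace(k_seq80=1e9, k_seq4=1e9)
        alg = reduced_inputs(st, p, glu=0.0, gal=150.0)
        assert alg.g80_free == pytest.approx(30.0, rel=1e-6)
        assert alg.g4_free == pytest.approx(20.0, rel=1e-6)

    @pytest.mark.parametrize(
        "state",
        [
            SpeciesState(120.0, 40.0, 25.0, 0.0),
            SpeciesState(5.0, 35.0, 60.0, 0.0),
            SpeciesState(300.0, 10.0, 3.0, 0.0),
        ],
    )
    def test_matches_mass_action_binding_ode(self, params, state):
        """Algebraic fast equilibrium equals the mass-action ODE limit."""
        gal = 200.0
        alg = reduced_inputs(state, params, glu=0.0, gal=gal)
        g80_free, g4_free = binding_equilibrium_ode(
            alg.g1_star,
            state.g80_total,
            state.g4_total,
            params.k_seq80,
            params.k_seq4,
        )
        assert alg.g80_free == pytest.approx(g80_free, rel=1e-6, abs=1e-9)
        assert alg.g4_free == pytest.approx(g4_free, rel=1e-6, abs=1e-9)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            reduced_inputs(SpeciesState(1, 1, 1, 0), params, glu=-1.0, gal=0.0)

    def test_invariant_ranges(self, params):
        st = SpeciesState(80.0, 25.0, 40.0, 0.0)
        alg = reduced_inputs(st, params, glu=10.0, gal=90.0)
        assert 0.0 <= alg.g1_star <= st.g1_total
        assert 0.0 <= alg.g80_free <= st.g80_total
        assert 0.0 <= alg.g4_free <= st.g4_total


# ----------------------------------------------------------------- vector field


class TestRhs:
    def test_pure_decay_when_production_off(self, params):
        p = params.replace(alpha1=1e-12, alpha80=1e-12, alpha4=1e-12, b1=0, b80=0, b4=0)
        st = SpeciesState(10.0, 20.0, 30.0, 0.0)
        d = rhs(st, p, glu=0.0, gal=0.0)
        assert d.g1_total == pytest.approx(-p.d * 10.0, rel=1e-9)
        assert d.g80_total == pytest.approx(-p.d * 20.0, rel=1e-9)
        assert d.g4_total == pytest.approx(-p.d * 30.0, rel=1e-9)

    def test_repressor_inactive_without_glucose(self, params):
        st = SpeciesState(10.0, 10.0, 10.0, 0.0)
        assert rhs(st, params, glu=0.0, gal=0.0).r_active == 0.0

    def test_vanishes_at_equilibria(self, params):
        for eq in find_equilibria(params, 25.0, 150.0):
            d = rhs(eq.state, params, 25.0, 150.0)
            assert np.linalg.norm(d.as_array()) < 1e-8

    def test_nan_state_rejected(self, params):
        with pytest.raises(ValueError):
            rhs(SpeciesState(float("nan"), 1, 1, 0), params, 0.0, 0.0)

    def test_dilution_variant_scales_decay_with_glucose(self):
        p = default_params("dilution").replace(
            alpha1=1e-12, alpha80=1e-12, alpha4=1e-12, b1=0, b80=0, b4=0
        )
        st = SpeciesState(10.0, 10.0, 10.0)
        lo = rhs(st, p, glu=0.0, gal=0.0)
        hi = rhs(st, p, glu=1e6, gal=0.0)
        assert lo.g1_total == pytest.approx(-p.d * 10.0, rel=1e-9)
        assert hi.g1_total == pytest.approx(-p.d * (1 + p.s1) * 10.0, rel=1e-6)


# ------------------------------------------------------------------ simulation


class TestSimulate:
    def test_exponential_decay_closed_form(self, params):
        p = params.replace(alpha1=1e-12, alpha80=1e-12, alpha4=1e-12, b1=0, b80=0, b4=0)
        x0 = SpeciesState(50.0, 40.0, 30.0, 0.0)
        t = np.linspace(0, 10, 21)
        traj = simulate(p, SugarSchedule.constant(0.0, 0.0), x0, t)
        expected = 50.0 * np.exp(-p.d * t)
        assert np.allclose(traj.g1_total, expected, rtol=1e-6)

    def test_stays_at_stable_equilibrium(self, params):
        eqs = find_equilibria(params, 25.0, 150.0)
        on = max((e for e in eqs if e.stable), key=lambda e: e.g1_total)
        t = np.linspace(0, 100, 41)
        traj = simulate(params, SugarSchedule.constant(25.0, 150.0), on.state, t)
        dev = np.abs(traj.states - on.state.as_array()).max()
        assert dev < 1e-4

    def test_converges_to_on_under_mono_on_inputs(self, params):
        """Under mono-ON inputs every start relaxes to the ON equilibrium."""
        eqs = find_equilibria(params, 5.0, 150.0)
        assert len([e for e in eqs if e.stable]) == 1
        target = eqs[-1].state.as_array()
        rng = np.random.default_rng(0)
        for _ in range(3):
            x0 = SpeciesState(*(rng.uniform(0.1, 1.0, 4) * [500, 50, 40, 100]))
            traj = simulate(
                params, SugarSchedule.constant(5.0, 150.0), x0, np.linspace(0, 150, 31)
            )
            assert np.allclose(traj.states[-1], target, rtol=1e-3, atol=1e-6)

    def test_nonnegative_states(self, params):
        x0 = SpeciesState(2000.0, 90.0, 90.0, 300.0)
        traj = simulate(
            params, SugarSchedule.constant(100.0, 50.0), x0, np.linspace(0, 50, 26)
        )
        assert traj.states.min() > -1e-9

    def test_bad_grid_rejected(self, params):
        with pytest.raises(ValueError):
            simulate(
                params,
                SugarSchedule.constant(0, 0),
                SpeciesState(1, 1, 1, 0),
                np.array([0.0, 0.0, 1.0]),
            )


# ------------------------------------------------------------------ equilibria


class TestFindEquilibria:
    def test_bistable_point_matches_dense_oracle(self, params):
        """Inside the band: two stable states and the saddle between them."""
        eqs = find_equilibria(params, 25.0, 150.0)
        oracle = equilibria_1d(params, 25.0, 150.0)
        assert len(eqs) == len(oracle) == 3
        assert [e.stable for e in eqs] == [True, False, True]
        for e, o in zip(eqs, oracle):
            assert e.g1_total == pytest.approx(o["g1_total"], rel=1e-6)

    def test_no_galactose_gives_single_off_state(self, params):
        eqs = find_equilibria(params, 50.0, 0.0)
        oracle = equilibria_1d(params, 50.0, 0.0)
        assert len(eqs) == len(oracle) == 1
        assert eqs[0].stable
        assert eqs[0].g1_total < params.g1_on_threshold

    @pytest.mark.parametrize("glu", [3.0, 30.0, 120.0, 700.0])
    def test_counts_match_oracle_across_glucose(self, params, glu):
        eqs = find_equilibria(params, glu, 150.0)
        oracle = equilibria_1d(params, glu, 150.0)
        assert len(eqs) == len(oracle)
        for e, o in zip(eqs, oracle):
            assert e.g1_total == pytest.approx(o["g1_total"], rel=1e-5)

    def test_residuals_within_tolerance(self, params):
        for eq in find_equilibria(params, 30.0, 150.0):
            assert eq.residual_norm < 1e-8

    def test_stability_flag_matches_flow(self, params):
        """Stable equilibria attract a 1% perturbation; the saddle does not."""
        eqs = find_equilibria(params, 25.0, 150.0)
        sched = SugarSchedule.constant(25.0, 150.0)
        t = np.linspace(0, 200, 21)
        for eq in eqs:
            y0 = SpeciesState(*(eq.state.as_array() * 1.01))
            end = simulate(params, sched, y0, t).states[-1]
            returned = np.linalg.norm(end - eq.state.as_array()) < 0.05 * (
                np.linalg.norm(eq.state.as_array()) + 1.0
            )
            assert returned == eq.stable


class TestDominantEigenvalue:
    def test_pure_decay_spectrum(self, params):
        """With productions off the Jacobian is -d·I (plus the R* row)."""
        p = params.replace(
            alpha1=1e-12, alpha80=1e-12, alpha4=1e-12, b1=1e-6, b80=1e-6, b4=1e-6,
            g1_on_threshold=0.0,
        )
        lam = dominant_eigenvalue(p, glu=0.0, gal=0.0)
        assert lam == pytest.approx(p.d, rel=1e-5)

    def test_finite_difference_jacobian_on_linear_system(self, params):
        """FD Jacobian reproduces the analytic Jacobian of a linear field."""
        p = params.replace(alpha1=1e-12, alpha80=1e-12, alpha4=1e-12, b1=0, b80=0, b4=0)
        glu = 40.0
        st = SpeciesState(10.0, 5.0, 3.0, 20.0)
        J = jacobian(p, glu, 0.0, st)
        expected = np.diag([-p.d, -p.d, -p.d, -(p.k_r * glu + p.k_rd)])
        assert np.allclose(J, expected, rtol=1e-6, atol=1e-8)

    def test_decreases_with_glucose_on_the_on_branch(self, params, band_150):
        lo, hi = band_150.glu_low_star, band_150.glu_high_star
        grid = np.linspace(lo * 1.05, hi * 0.97, 10)
        lams = [dominant_eigenvalue(params, g, 150.0) for g in grid]
        assert all(a >= b - 1e-9 for a, b in zip(lams, lams[1:]))

    def test_error_when_no_on_state(self, params):
        with pytest.raises(RuntimeError, match="ON"):
            dominant_eigenvalue(params, glu=500.0, gal=150.0)


# ---------------------------------------------------------------------- basins


class TestBasinFraction:
    def test_monostable_shortcuts(self, params):
        assert basin_fraction_on(params, 5.0, 150.0, n_samples=10, seed=0) == 1.0
        assert basin_fraction_on(params, 500.0, 150.0, n_samples=10, seed=0) == 0.0

    def test_deterministic_for_fixed_seed(self, params):
        a = basin_fraction_on(params, 25.0, 150.0, n_samples=150, seed=3)
        b = basin_fraction_on(params, 25.0, 150.0, n_samples=150, seed=3)
        assert a == b

    def test_decreases_toward_the_upper_fold(self, params, band_150):
        lo, hi = band_150.glu_low_star, band_150.glu_high_star
        n = 300
        f_lo = basin_fraction_on(params, lo * 1.1, 150.0, n_samples=n, seed=1)
        f_hi = basin_fraction_on(params, hi * 0.98, 150.0, n_samples=n, seed=1)
        se = 2.0 * np.sqrt(0.25 / n)
        assert f_lo >= f_hi - 2 * se


# ------------------------------------------------------------------ bifurcation


class TestBifurcationScan:
    def test_regime_sequence_and_thresholds(self, params, band_150):
        labels = band_150.regime_per_point
        # contiguous blocks in the order mono_ON -> bistable -> mono_OFF
        order = [lab for i, lab in enumerate(labels) if i == 0 or lab != labels[i - 1]]
        assert order == [MONO_ON, BISTABLE, MONO_OFF]
        assert band_150.glu_low_star < band_150.glu_high_star

    def test_midpoint_of_band_is_bistable(self, params, band_150):
        mid = 0.5 * (band_150.glu_low_star + band_150.glu_high_star)
        eqs = find_equilibria(params, mid, 150.0)
        assert len([e for e in eqs if e.stable]) == 2

    def test_grid_above_band_reports_no_thresholds(self, params, band_150):
        grid = np.linspace(band_150.glu_high_star * 1.5, band_150.glu_high_star * 4, 4)
        diag = bifurcation_scan(params, 150.0, grid)
        assert all(lab == MONO_OFF for lab in diag.regime_per_point)
        assert diag.glu_low_star is None and diag.glu_high_star is None

    def test_single_cell_regime_map_consistent(self, params, band_150):
        mid = 0.5 * (band_150.glu_low_star + band_150.glu_high_star)
        rm = regime_map(
            params, np.array([mid]), np.array([150.0])
        )
        assert rm.labels[0, 0] == BISTABLE


class TestVariants:
    def test_open_loop_expands_bistable_area(self):
        """Removing GAL80 negative feedback enlarges the bistable region."""
        glu = np.geomspace(5.0, 300.0, 10)
        gal = np.array([75.0, 150.0, 300.0])
        wt = regime_map(default_params("repressor"), glu, gal)
        ol = regime_map(default_params("gal80_open_loop"), glu, gal)
        assert ol.bistable_area >= wt.bistable_area

    def test_reduced_affinity_shifts_window_up(self, params, band_150):
        """Weaker promoter repression moves both saddle-nodes to higher
        glucose, so glucose decay reaches the bifurcation point sooner."""
        p_red = params.replace(k_r1=params.k_r1 * 1.25, k_r4=params.k_r4 * 1.25)
        diag = bifurcation_scan(p_red, 150.0, np.geomspace(2.0, 500.0, 20))
        assert diag.glu_low_star > band_150.glu_low_star


# -------------------------------------------------------- quasi-static / delta_b


class TestQuasiStatic:
    def test_constant_mono_on_inputs(self, params):
        t = np.linspace(0, 5, 6)
        res = quasi_static_regimes(
            params, (t, np.full_like(t, 5.0)), (t, np.full_like(t, 150.0))
        )
        assert all(lab == MONO_ON for lab in res.regimes)
        assert res.activation_time == t[0]

    def test_decaying_glucose_predicts_activation_at_threshold(self, params, band_150):
        """Exponential glucose decay crossing glu_low* at 5 h activates there."""
        glu_star = band_150.glu_low_star
        glu0 = 200.0
        k = np.log(glu0 / glu_star) / 5.0
        t = np.arange(0, 8.001, 0.5)
        res = quasi_static_regimes(
            params, (t, glu0 * np.exp(-k * t)), (t, np.full_like(t, 150.0))
        )
        assert res.activation_time == pytest.approx(5.0, abs=0.5 + 1e-9)

    def test_second_glucose_step_prolongs_bimodality(self, params, band_150):
        glu_star = band_150.glu_low_star
        glu0 = 200.0
        k = np.log(glu0 / glu_star) / 5.0
        t = np.arange(0, 14.001, 0.5)
        single = glu0 * np.exp(-k * t)
        second = single + np.where(t >= 5.0, glu0 * np.exp(-k * (t - 5.0)), 0.0)
        gal = (t, np.full_like(t, 150.0))
        res1 = quasi_static_regimes(params, (t, single), gal)
        res2 = quasi_static_regimes(params, (t, second), gal)
        assert res2.predicted_delta_g > res1.predicted_delta_g


class TestDeltaB:
    def test_closed_form_for_exponential_decay(self, params, band_150):
        glu_star = band_150.glu_low_star
        k = 0.5
        glu0 = 300.0
        t = np.linspace(0, 20, 2001)
        traj = (t, glu0 * np.exp(-k * t))
        expected = np.log(glu0 / glu_star) / k
        got = delta_b(params, traj, gal_level=150.0, gal_delay=0.0)
        assert got == pytest.approx(expected, rel=2e-3)

    def test_zero_beyond_crossing_time(self, params, band_150):
        t = np.linspace(0, 20, 201)
        traj = (t, 300.0 * np.exp(-0.5 * t))
        assert (
            delta_b(
                params, traj, 150.0, gal_delay=19.0, glu_low_star=band_150.glu_low_star
            )
            == 0.0
        )

    def test_monotone_in_delay(self, params, band_150):
        t = np.linspace(0, 20, 201)
        traj = (t, 300.0 * np.exp(-0.5 * t))
        vals = [
            delta_b(
                params, traj, 150.0, gal_delay=dly, glu_low_star=band_150.glu_low_star
            )
            for dly in (0.0, 3.1, 4.2, 5.3, 6.3)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_no_crossing_flagged(self, params):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError, match="no bifurcation crossing"):
            delta_b(params, (t, np.full_like(t, 500.0)), 150.0)
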