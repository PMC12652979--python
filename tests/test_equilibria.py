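"""Steady states, stability classes, and balance-curve cross-validation."""

import numpy as np
import pytest

from erswitch.dynamics import TreatmentSchedule, simulate
from erswitch.equilibria import (
    classify_stability,
    find_equilibria,
    nullcline_intersections,
    nullclines,
)
from erswitch.model import ModelState, StressorInput


class TestClassifyStability:
    def test_all_negative_is_stable(self):
        assert classify_stability([-1, -2, -3, -4, -5]) == "stable"

    def test_mixed_signs_is_saddle(self):
        assert classify_stability([+1, -1, -1, -1, -1]) == "saddle"

    def test_all_positive_is_unstable(self):
        assert classify_stability([1, 2, 3, 4, 5]) == "unstable"

    def test_near_zero_is_marginal(self):
        assert classify_stability([-1, -1, -1, -1, 1e-12]) == "marginal"

    def test_requires_five_eigenvalues(self):
        with pytest.raises(ValueError):
            classify_stability([-1, -2])

    def test_canonical_equilibria_hyperbolic(self, params):
        """No marginal classification at the canonical parameter set."""
        for eq in find_equilibria(params, StressorInput()):
            assert eq.stability != "marginal"


class TestFindEquilibria:
    def test_unstressed_bistability(self, params):
        """Two stable states (homeostatic and apoptotic) separated by a
        saddle; the homeostatic one has small but nonzero basal AUT-A."""
        eqs = find_equilibria(params, StressorInput())
        assert len(eqs) == 3
        stable = [e for e in eqs if e.is_stable]
        others = [e for e in eqs if not e.is_stable]
        assert len(stable) == 2 and len(others) == 1
        phys = min(stable, key=lambda e: e.state.apo_a)
        assert phys.state.apo_a < 0.1 * params.apo_t
        assert 0.0 < phys.state.aut_a < 0.5 * params.aut_t

    def test_low_tg_single_apoptotic_state(self, params):
        eqs = find_equilibria(params, StressorInput(stress=5.0, tg=0.25))
        stable = [e for e in eqs if e.is_stable]
        assert len(stable) == 1
        assert stable[0].state.apo_a > 0.5 * params.apo_t
        assert stable[0].state.aut_a < 0.5 * params.aut_t

    def test_sorted_by_apoptosis_inducer(self, params):
        eqs = find_equilibria(params, StressorInput(stress=5.0))
        apo = [e.state.apo_a for e in eqs]
        assert apo == sorted(apo)

    def test_start_saturation(self, params):
        """Doubling the number of starts (and a many-start brute-force run)
        leaves the merged equilibrium set unchanged."""
        base = find_equilibria(params, StressorInput(), n_starts=60)
        more = find_equilibria(params, StressorInput(), n_starts=120, seed=7)
        brute = find_equilibria(params, StressorInput(), n_starts=600,
                                seed=13)
        for other in (more, brute):
            assert len(other) == len(base)
            for a, b in zip(base, other):
                assert np.max(np.abs(a.state.to_array()
                                     - b.state.to_array())) < 1e-6
                assert a.stability == b.stability

    def test_n_starts_floor(self, params):
        with pytest.raises(ValueError, match="27"):
            find_equilibria(params, StressorInput(), n_starts=10)

    def test_residuals_below_tolerance(self, params):
        from erswitch.model import _rhs_raw

        for eq in find_equilibria(params, StressorInput(stress=5.0)):
            r = _rhs_raw(eq.state.to_array(), params, 5.0, 0.0, 0.0, 1.0)
            assert np.max(np.abs(r)) < 1e-10


class TestBasins:
    def test_stable_states_attract_small_perturbations(self, params):
        eqs = find_equilibria(params, StressorInput())
        stable = [e for e in eqs if e.is_stable]
        for eq in stable:
            y0 = np.clip(eq.state.to_array() + 1e-3, 0.0, None)
            traj = simulate(params, TreatmentSchedule(StressorInput(), (),
                                                      200.0),
                            ModelState.from_array(y0))
            back = np.max(np.abs(traj.states[-1] - eq.state.to_array()))
            assert back < 1e-4

    def test_saddle_perturbations_reach_a_stable_state(self, params):
        eqs = find_equilibria(params, StressorInput())
        saddle = next(e for e in eqs if e.stability == "saddle")
        stable = [e.state.to_array() for e in eqs if e.is_stable]
        for sign in (+1.0, -1.0):
            y0 = np.clip(saddle.state.to_array() + sign * 1e-3, 0.0, None)
            traj = simulate(params, TreatmentSchedule(StressorInput(), (),
                                                      400.0),
                            ModelState.from_array(y0))
            dists = [np.max(np.abs(traj.states[-1] - s)) for s in stable]
            assert min(dists) < 1e-4

    def test_no_stable_state_mixes_survival_and_death(self, params,
                                                      stress_inputs):
        """Autophagy and apoptosis are mutually exclusive at every stable
        state across the study's treatment settings."""
        for inp in stress_inputs.values():
            for eq in find_equilibria(params, inp):
                if eq.is_stable:
                    both = (eq.state.aut_a > 0.5 * params.aut_t
                            and eq.state.apo_a > 0.5 * params.apo_t)
                    assert not both


class TestNullclines:
    def test_resolution_floor(self, params):
        with pytest.raises(ValueError, match="resolution"):
            nullclines(params, StressorInput(), resolution=50)

    def test_balance_residuals(self, params):
        """Every returned curve point satisfies its balance condition after
        QSS reduction to residual < 1e-6."""
        from erswitch.equilibria import _qss_rate

        curve_a, curve_q = nullclines(params, StressorInput(stress=5.0),
                                      resolution=100)
        for curve, which in ((curve_a, 2), (curve_q, 4)):
            pts = curve.points[::9]
            assert len(pts) > 5
            for a, q in pts:
                rate, _ = _qss_rate(a, q, params, curve.input, which)
                assert abs(rate) < 1e-6

    def test_unstressed_three_intersections(self, params):
        curve_a, curve_q = nullclines(params, StressorInput(),
                                      resolution=120)
        xs = nullcline_intersections(curve_a, curve_q)
        assert len(xs) == 3

    @pytest.mark.parametrize("stress", [0.0, 5.0, 15.0, 30.0, 50.0])
    def test_intersections_match_equilibria(self, params, stress):
        """Curve crossings and multi-start equilibria are two independent
        computations of the same objects; their planar projections agree."""
        inp = StressorInput(stress=stress)
        curve_a, curve_q = nullclines(params, inp, resolution=120)
        xs = nullcline_intersections(curve_a, curve_q)
        eqs = find_equilibria(params, inp)
        proj = np.array([[e.state.aut_a, e.state.apo_a] for e in eqs])
        assert len(xs) == len(proj)
        for p in proj:
            assert np.min(np.max(np.abs(xs - p), axis=1)) < 1e-3

    def test_tg_shifts_apoptosis_curve_more(self, params):
        """Direct APO-A activation by thapsigargin displaces the APO-A
        balance curve further than the AUT-A curve."""
        base_a, base_q = nullclines(params, StressorInput(stress=5.0),
                                    resolution=100)
        tg_a, tg_q = nullclines(params, StressorInput(stress=5.0, tg=0.25),
                                resolution=100)

        def mean_displacement(c0, c1):
            # symmetrized mean nearest-vertex distance between the curves
            def one_way(p0, p1):
                d = [np.min(np.linalg.norm(p1 - pt, axis=1))
                     for pt in p0[::5]]
                return float(np.mean(d))

            return 0.5 * (one_way(c0.points, c1.points)
                          + one_way(c1.points, c0.points))

        shift_aut = mean_displacement(base_a, tg_a)
        shift_apo = mean_displacement(base_q, tg_q)
        assert shift_apo > shift_aut
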