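"""Scenario registry, rescue-window and washout scans, robustness ensembles."""

import numpy as np
import pytest

from erswitch.dynamics import classify_outcome, simulate
from erswitch.scenarios import (
    ALWAYS_REVERSIBLE,
    EnsembleSpec,
    study_scenarios,
    perturbation_ensemble,
    rescue_window_scan,
    run_scenario,
    washout_scan,
)


@pytest.fixture(scope="module")
def registry():
    return study_scenarios()


class TestRegistry:
    def test_registry_contract(self, registry):
        assert len(registry) >= 13
        for name, spec in registry.items():
            assert spec.name == name
            spec.schedule.validate()

    def test_core_outcome_matrix(self, params, registry):
        """Low tunicamycin rescues by autophagy; high tunicamycin and any
        thapsigargin dose kill."""
        expected = {
            "TM-low": "autophagy",
            "TM-high": "apoptosis",
            "TG-low": "apoptosis",
            "TG-high": "apoptosis",
            "DTT-low": "apoptosis",
        }
        for name, label in expected.items():
            assert run_scenario(params, registry[name]).label == label

    def test_inducer_treatments(self, params, registry):
        """Pre-, co- and (early) delayed inducer treatment rescue high
        tunicamycin stress; under thapsigargin the delayed treatment fails."""
        assert run_scenario(
            params, registry["inducer-pre-TM-high"]).label == "autophagy"
        assert run_scenario(
            params, registry["inducer-co-TM-high"]).label == "autophagy"
        assert run_scenario(
            params, registry["inducer-delayed-TM-high"]).label == "autophagy"
        assert run_scenario(
            params, registry["inducer-delayed-TG-high"]).label == "apoptosis"

    def test_registry_labels_all_verified(self, params, registry):
        for spec in registry.values():
            if spec.expected_label is not None:
                assert run_scenario(params, spec).label == spec.expected_label, \
                    spec.name

    def test_escalation_matches_constant_high_stress(self, params, registry):
        """Stressor doses add up: escalating 5 -> 50 ends like constant 50,
        for several escalation times."""
        high_label = run_scenario(params, registry["TM-high"]).label
        from dataclasses import replace

        base = registry["escalation"]
        for t_esc in [5.0, 20.0, 50.0, 80.0, 120.0]:
            events = tuple(replace(e, time=t_esc) for e in
                           base.schedule.events)
            sched = replace(base.schedule, events=events,
                            t_end=t_esc + 200.0)
            spec = replace(base, schedule=sched)
            assert run_scenario(params, spec).label == high_label


class TestRescueWindow:
    def test_tm_window_exists_and_is_finite(self, params, registry):
        latest = rescue_window_scan(params, registry["TM-high"],
                                    delays=list(np.arange(0.0, 12.0, 1.0)))
        assert latest is not None
        assert 0.0 < latest < 12.0

    def test_tg_has_no_window(self, params, registry):
        latest = rescue_window_scan(params, registry["TG-high"],
                                    delays=[0.0, 1.0, 2.0, 4.0, 8.0])
        assert latest is None

    def test_cotreatment_rescues_and_delays_death(self, params, registry):
        """Delay 0 (co-treatment) succeeds on high tunicamycin; where
        apoptosis still occurs (thapsigargin), inducer treatment postpones
        its onset relative to the unrescued control."""
        latest = rescue_window_scan(params, registry["TM-high"],
                                    delays=[0.0, 1.0, 2.0, 4.0, 8.0, 12.0])
        assert latest is not None and latest >= 0.0

        control = run_scenario(params, registry["TG-high"])
        for name in ("inducer-pre-TG-high", "inducer-co-TG-high"):
            treated = run_scenario(params, registry[name])
            assert treated.label == "apoptosis"
            onset = treated.onset_time_apoptosis
            if name.startswith("inducer-pre"):
                # compare time since stressor addition, not absolute time
                onset -= 20.0
            assert onset > control.onset_time_apoptosis

    def test_beyond_window_inducer_never_reverses(self, params, registry):
        """Past the latest rescue delay the commitment is irreversible."""
        latest = rescue_window_scan(params, registry["TM-high"],
                                    delays=list(np.arange(0.0, 12.0, 1.0)))
        from dataclasses import replace
        from erswitch.dynamics import TreatmentEvent

        for delay in [latest + 1.0, latest + 5.0, latest + 20.0]:
            sched = registry["TM-high"].schedule.with_event(
                TreatmentEvent(delay, "kaua_mult", 10.0))
            sched = replace(sched, t_end=delay + 200.0)
            from erswitch.model import physiological_state

            traj = simulate(params, sched, physiological_state(params))
            assert classify_outcome(traj).label == "apoptosis"


class TestWashout:
    def test_low_stress_always_reversible(self, params):
        thr = washout_scan(params, 5.0,
                           washout_times=[1.0, 5.0, 20.0, 60.0, 120.0])
        assert thr == ALWAYS_REVERSIBLE

    def test_high_stress_finite_threshold(self, params):
        thr = washout_scan(params, 50.0,
                           washout_times=list(np.arange(0.5, 10.5, 0.5)))
        assert np.isfinite(thr)
        assert 0.5 <= thr <= 10.0

    def test_threshold_separates_outcomes(self, params, phys_init):
        """Washing out before the threshold restores homeostasis; after it,
        apoptosis persists even at zero stress."""
        from erswitch.dynamics import TreatmentEvent, TreatmentSchedule
        from erswitch.model import StressorInput

        thr = washout_scan(params, 50.0,
                           washout_times=list(np.arange(0.5, 10.5, 0.5)))
        for w, expected in [(thr - 0.3, "homeostasis"),
                            (thr + 0.3, "apoptosis")]:
            sched = TreatmentSchedule(
                StressorInput(stress=50.0),
                (TreatmentEvent(w, "stress", 0.0),), w + 200.0)
            traj = simulate(params, sched, phys_init)
            assert classify_outcome(traj).label == expected


class TestEnsemble:
    def test_zero_cv_preserves_everything(self, params):
        draws, report = perturbation_ensemble(
            params, EnsembleSpec(seed=5, n=3, cv=0.0))
        assert report["preserved_fraction"] == 1.0
        for d in draws:
            assert d.ks_apo == params.ks_apo
            assert d.kaua_base == params.kaua_base

    def test_seeded_determinism(self, params):
        a_draws, a = perturbation_ensemble(params,
                                           EnsembleSpec(seed=42, n=4, cv=0.1))
        b_draws, b = perturbation_ensemble(params,
                                           EnsembleSpec(seed=42, n=4, cv=0.1))
        assert a == b
        for da, db in zip(a_draws, b_draws):
            assert da.to_dict() == db.to_dict()

    def test_two_streams_agree_within_sampling_error(self, params):
        """Preserved-label fractions from independent RNG streams differ by
        no more than generous binomial sampling error."""
        n = 24
        _, r1 = perturbation_ensemble(params, EnsembleSpec(seed=1, n=n,
                                                           cv=0.1))
        _, r2 = perturbation_ensemble(params, EnsembleSpec(seed=2, n=n,
                                                           cv=0.1))
        p_hat = 0.5 * (r1["preserved_fraction"] + r2["preserved_fraction"])
        se = np.sqrt(max(p_hat * (1 - p_hat), 0.25 / n) * 2.0 / n)
        assert abs(r1["preserved_fraction"]
                   - r2["preserved_fraction"]) <= 4.0 * se + 1.0 / n

    def test_invalid_spec_rejected(self, params):
        with pytest.raises(ValueError):
            perturbation_ensemble(params, EnsembleSpec(seed=0, n=0, cv=0.1))
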