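"""Verify the pinned calibrated_default parameter set against its design
constraints.

The calibration targets are the model's qualitative claims: bistability of
homeostasis and death at zero stress, autophagic survival at stress = 5,
apoptosis with a transient autophagy peak at stress = 50, loss of the
survival state under thapsigargin, a rescue window under the autophagy
inducer for tunicamycin but not thapsigargin, and washout reversibility
thresholds.  This script recomputes every constraint from the pinned YAML
and writes a pass/fail table to results/calibration_report.csv.  It is the
script to re-run (and extend) whenever the parameter file is retuned.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from erswitch.dynamics import (
    TreatmentSchedule,
    classify_outcome,
    detect_transient_peak,
    simulate,
)
from erswitch.equilibria import find_equilibria
from erswitch.model import StressorInput, canonical_parameters, physiological_state
from erswitch.scenarios import (
    ALWAYS_REVERSIBLE,
    study_scenarios,
    rescue_window_scan,
    washout_scan,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    params = canonical_parameters("calibrated_default")
    init = physiological_state(params)
    reg = study_scenarios()
    rows = []

    def record(name, ok, value):
        rows.append({"constraint": name, "ok": bool(ok), "value": value})
        print(f"{'PASS' if ok else 'FAIL'}  {name}: {value}")

    eq0 = find_equilibria(params, StressorInput())
    n_stable = sum(e.is_stable for e in eq0)
    record("stress0_two_stable_one_saddle",
           n_stable == 2 and len(eq0) == 3, f"{n_stable}/{len(eq0)}")
    phys = min((e for e in eq0 if e.is_stable), key=lambda e: e.state.apo_a)
    record("stress0_basal_autophagy_small",
           0.0 < phys.state.aut_a < 0.4, round(phys.state.aut_a, 3))

    eq_tg = find_equilibria(params, StressorInput(stress=5.0, tg=0.25))
    stab_tg = [e for e in eq_tg if e.is_stable]
    record("tg_low_single_apoptotic_state",
           len(stab_tg) == 1 and stab_tg[0].state.apo_a > 0.5,
           len(stab_tg))

    def outcome(**kw):
        traj = simulate(params,
                        TreatmentSchedule(StressorInput(**kw), (), 200.0),
                        init)
        return traj, classify_outcome(traj)

    _, low = outcome(stress=5.0)
    record("tm_low_autophagy", low.label == "autophagy", low.label)
    traj_high, high = outcome(stress=50.0)
    peak = detect_transient_peak(traj_high, "aut_a")
    record("tm_high_apoptosis_with_transient_peak",
           high.label == "apoptosis" and peak is not None,
           f"{high.label}, peak={None if peak is None else round(peak[1], 3)}")
    _, tglow = outcome(stress=5.0, tg=0.25)
    record("tg_low_apoptosis", tglow.label == "apoptosis", tglow.label)
    _, dtt = outcome(stress=5.0, dtt=0.25)
    record("dtt_low_apoptosis", dtt.label == "apoptosis", dtt.label)
    _, resc = outcome(stress=50.0, kaua_mult=10.0)
    record("cotreatment_rescues_high_tm", resc.label == "autophagy",
           resc.label)

    win_tm = rescue_window_scan(params, reg["TM-high"],
                                delays=list(np.arange(0.0, 12.0, 0.5)))
    record("tm_rescue_window_finite",
           win_tm is not None and 0.0 < win_tm < 12.0, win_tm)
    win_tg = rescue_window_scan(params, reg["TG-high"],
                                delays=[0.0, 1.0, 2.0, 4.0])
    record("tg_no_rescue_window", win_tg is None, win_tg)

    thr5 = washout_scan(params, 5.0,
                        washout_times=[1.0, 5.0, 20.0, 60.0, 120.0])
    record("washout_low_always_reversible", thr5 == ALWAYS_REVERSIBLE, thr5)
    thr50 = washout_scan(params, 50.0,
                         washout_times=list(np.arange(0.25, 10.25, 0.25)))
    record("washout_high_finite_threshold",
           np.isfinite(thr50) and thr50 > 0.0, thr50)

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "calibration_report.csv",
                              index=False)
    n_fail = sum(not r["ok"] for r in rows)
    print(f"\n{len(rows) - n_fail}/{len(rows)} constraints satisfied -> "
          f"{RESULTS / 'calibration_report.csv'}")
    return 1 if n_fail else 0


if __name__ == "__main__":
    raise SystemExit(main())
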