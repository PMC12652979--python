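"""Autophagy-inducer rescue-window scan.

For high tunicamycin (stress = 50) and high thapsigargin (stress = 50,
tg = 0.25), adds the 10x autophagy inducer at increasing delays after the
stressor and asks whether apoptosis is still averted.  Tunicamycin admits a
finite window: treatment up to ~3 time units after the stressor still locks
the network into the high-AUT-A survival state; later treatment cannot
reverse commitment.  Thapsigargin admits no window at all, because its
direct APO-A activation removes the survival state even at full inducer
strength.  Per-delay labels and bisection-refined thresholds go to
results/rescue_window.csv / .json.
"""

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from erswitch.dynamics import TreatmentEvent, classify_outcome, simulate
from erswitch.model import canonical_parameters, physiological_state
from erswitch.scenarios import KAUA_TREATED, study_scenarios, rescue_window_scan

RESULTS = Path(__file__).resolve().parents[1] / "results"
DELAYS = list(np.arange(0.0, 12.0, 0.5))


def per_delay_labels(params, base, delays):
    init = physiological_state(params)
    rows = []
    for d in delays:
        if d == 0.0:
            sched = replace(base.schedule,
                            initial_input=replace(base.schedule.initial_input,
                                                  kaua_mult=KAUA_TREATED))
        else:
            sched = base.schedule.with_event(
                TreatmentEvent(d, "kaua_mult", KAUA_TREATED))
            sched = replace(sched, t_end=d + 200.0)
        label = classify_outcome(simulate(params, sched, init)).label
        rows.append({"base": base.name, "delay": d, "label": label})
    return rows


def main() -> None:
    params = canonical_parameters("calibrated_default")
    reg = study_scenarios()
    RESULTS.mkdir(exist_ok=True)

    rows, summary = [], {}
    for name in ("TM-high", "TG-high"):
        rows += per_delay_labels(params, reg[name], DELAYS)
        latest = rescue_window_scan(params, reg[name], delays=DELAYS)
        summary[name] = {"latest_successful_delay": latest,
                         "inducer_kaua": KAUA_TREATED}
        print(f"{name}: latest rescue delay = {latest}")

    pd.DataFrame(rows).to_csv(RESULTS / "rescue_window.csv", index=False)
    (RESULTS / "rescue_window.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(f"-> {RESULTS / 'rescue_window.json'}")


if __name__ == "__main__":
    main()
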