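# erswitch — the ER stress decision between autophagy and apoptosis

`erswitch` is an ODE model and analysis pipeline for the endoplasmic-reticulum
(ER) stress response: how a cell under ER stress chooses between
autophagy-dependent survival and apoptotic death, and how that choice depends
on *which* chemical stressor is applied — tunicamycin (TM), thapsigargin (TG)
or dithiothreitol (DTT) — and on co-treatment with an autophagy inducer.

It is written for systems biologists who want to reproduce, probe or extend
the dynamical analysis: time courses under treatment schedules with step
events (addition, escalation, washout, delayed rescue), phase-plane /
balance-curve analysis, steady-state location with stability classification,
and one-parameter bifurcation diagrams in the stress level.

## The model

Five lumped variables (all activities in arbitrary units, totals normalized
to 1):

| variable | meaning |
|----------|---------|
| `upr`    | UPR sensor activity (the lumped IRE1/PERK/ATF6 program) |
| `bcl2`   | active anti-apoptotic BCL-2 |
| `aut_a`  | active autophagy-inducer group (Beclin-1-like) |
| `aut_i`  | caspase-cleaved, inactive autophagy inducer |
| `apo_a`  | active apoptosis-inducer group (caspase-like) |

Each species follows the generic kinetic template
dX<sub>a</sub>/dt = production·(X<sub>T</sub> − X<sub>a</sub>) −
consumption·X<sub>a</sub>, with Michaelis–Menten saturation on the
switch-forming steps and mass action on cleavage. The wiring is:

- ER stress (TM acts purely here) activates the UPR sensor;
- UPR and active caspases inactivate BCL-2;
- BCL-2 holds both inducers off;
- AUT-A and APO-A antagonize each other — the caspase arm cleaves AUT-A into
  AUT-I (a double-negative feedback loop);
- AUT-I promotes APO-A activation (a positive feedback loop);
- TG adds direct activation of both inducers, DTT of the apoptosis inducer
  only; an autophagy inducer multiplies the AUT-A activation constant
  (`kaua`, treated value 10× baseline).

The feedback structure makes the network a **one-way bistable switch** in
the stress level: survival and apoptotic steady states coexist from zero
stress up to a saddle-node (limit point); beyond it only the apoptotic state
remains, and because the apoptotic state is stable even at zero stress,
commitment is irreversible.

## Worked example

```python
from erswitch import (StressorInput, TreatmentSchedule, canonical_parameters,
                      simulate, classify_outcome, find_equilibria)
from erswitch.model import physiological_state

params = canonical_parameters("calibrated_default")

# how many steady states does the unstressed network have?
for eq in find_equilibria(params, StressorInput()):
    print(eq.stability, round(eq.state.aut_a, 3), round(eq.state.apo_a, 3))

# low vs high tunicamycin
for stress in (5.0, 50.0):
    sched = TreatmentSchedule(StressorInput(stress=stress), (), 200.0)
    traj = simulate(params, sched, physiological_state(params))
    print(stress, classify_outcome(traj).label)
```

prints

```
stable 0.27 0.004
saddle 0.022 0.539
stable 0.011 0.987
5.0 autophagy
50.0 apoptosis
```

i.e. the unstressed cell sits in a homeostatic state with a little basal
autophagy (AUT-A ≈ 0.27) and inactive caspases, separated by a saddle from a
fully apoptotic state; a low TM dose (stress = 5) ends in sustained
autophagy, a high dose (stress = 50) in apoptosis (preceded by a transient
AUT-A peak).

The same analyses are scripted end to end under `analysis/`
(`01_phase_plane.py` … `06_robustness.py`, with `00_calibrate.py`
re-verifying the pinned parameter set); each writes its tables to
`results/`. A CLI mirrors them for one-off runs:

```bash
erswitch --out-dir out simulate --scenario TM-low
erswitch --out-dir out bifurcate --s-max 60
erswitch --out-dir out scan --kind rescue --scenario TG-high
erswitch --out-dir out export-ode       # XPP .ode export of the model
```

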