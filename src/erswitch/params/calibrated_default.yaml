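# Pinned canonical parameter set (variant: calibrated_default).
# Totals normalized to 1 a.u.; rate constants in 1/time (a.u.).
# Calibrated by analysis/00_calibrate.py to satisfy, simultaneously:
#   - 2 stable + 1 saddle equilibria at stress = 0 (homeostasis bistable
#     with the apoptotic state, making commitment irreversible);
#   - autophagy outcome at stress = 5;
#   - apoptosis with a transient AUT-A peak at stress = 50;
#   - a single stable (apoptotic) state at stress = 5 with tg = 0.25;
#   - a finite autophagy-inducer rescue window under high tunicamycin
#     (kaua x 10) and none under high thapsigargin;
#   - washout reversibility at stress = 5, a finite reversibility
#     threshold at stress = 50.
schema_version: 1
metadata:
  variant: calibrated_default
  autophagy_pool: conserved  # activation/inactivation/cleavage only
# UPR sensor (mass action; stress enters only here)
ks_upr: 0.004
kact_upr: 0.02
kin_upr: 0.8
kd_upr: 0.0
# BCL-2 (fast mediator of the stress dose)
kact_bcl2: 6.0
kin_bcl2: 0.6
upr_on_bcl2: 57.0
apo_on_bcl2: 30.0
j_act_bcl2: 0.1
j_in_bcl2: 0.1
# autophagy inducer (Michaelian activation so the inducer multiplier acts
# gradedly; sharp inactivation for the stress-dose switch)
kaua_base: 6.0
kin_aut: 0.88
bcl2_on_aut: 2.1
apo_on_aut: 15.0
cleave_rate: 2.0
kd_auti: 6.0
tg_on_aut: 1.2
j_act_aut: 1.0
j_in_aut: 0.05
# apoptosis inducer (slow, zero-order switch)
ks_apo: 0.1325
kin_apo: 0.00075
bcl2_on_apo: 0.45
aut_on_apo: 0.15
auti_on_apo: 0.04
tg_on_apo: 0.55
dtt_on_apo: 0.55
j_act_apo: 0.01
j_in_apo: 0.01
# total pools
upr_t: 1.0
bcl2_t: 1.0
aut_t: 1.0
apo_t: 1.0
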