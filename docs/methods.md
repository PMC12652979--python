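# Methods

## Model

The ER stress decision network is modeled as five coupled ODEs over lumped
protein activities (arbitrary units, a.u.; every total pool is normalized to
1 a.u., time is in a.u. of inverse rate constants). Writing U = `upr`,
B = `bcl2`, A = `aut_a`, I = `aut_i`, P = `apo_a`, and `pool` = AUT_T − A − I
for the uncleaved inactive autophagy inducer:

    dU/dt = (ks_upr + kact_upr·stress)·(UPR_T − U) − (kin_upr + kd_upr)·U

    dB/dt = kact_bcl2·(BCL2_T − B)/(j_act_bcl2 + BCL2_T − B)
            − (kin_bcl2 + upr_on_bcl2·U)·B/(j_in_bcl2 + B)
            − apo_on_bcl2·P·B

    dA/dt = (kaua_base·kaua_mult + tg_on_aut·tg)·pool/(j_act_aut + pool)
            − (kin_aut + bcl2_on_aut·B + apo_on_aut·P)·A/(j_in_aut + A)
            − cleave_rate·P·A

    dI/dt = cleave_rate·P·A − kd_auti·I

    dP/dt = (ks_apo + auti_on_apo·I + tg_on_apo·tg + dtt_on_apo·dtt)
              ·(APO_T − P)/(j_act_apo + APO_T − P)
            − (kin_apo + bcl2_on_apo·B + aut_on_apo·A)·P/(j_in_apo + P)

Saturating (Michaelis–Menten) forms sit on the switch-forming
activation/inactivation steps, producing zero-order ultrasensitivity where
the Michaelis constants are small; the caspase cleavage reactions (P acting
on A and on B) are mass action. `kd_auti` returns cleaved material to the
uncleaved pool, so A + I + pool = AUT_T exactly along trajectories (recorded
as `autophagy_pool: conserved` in the parameter metadata).

Stressor semantics: tunicamycin has no separate input — a TM dose *is* the
`stress` input, which enters only the UPR activation term. Thapsigargin
adds direct activation to both inducers on top of `stress`; dithiothreitol
adds direct activation to the apoptosis inducer only. An autophagy inducer
(resveratrol-class compound) multiplies the AUT-A activation constant; the
treated condition `kaua = 10` is stored as `kaua_mult = 10` on top of
`kaua_base`, so schedules are portable across parameter variants.

BAX appears in the wiring only as the conduit of BCL-2's inhibition of
caspase activation; it carries no reported dynamics of its own and is folded
into the algebraic `bcl2_on_apo` term rather than being a state variable.

## Calibrated parameter set

No published numeric parameter set is bundled with this repository
(`canonical_parameters("appendixA")` therefore raises), so the pinned
`calibrated_default` set is the canonical one. It was calibrated — by
analysis of the Goldbeter–Koshland balance conditions of each switch,
followed by numerical verification (`analysis/00_calibrate.py` re-checks all
twelve constraints) — to satisfy simultaneously:

1. at stress = 0: two stable states (homeostatic, with small but nonzero
   basal AUT-A, and apoptotic) separated by a saddle;
2. stress = 5: sustained autophagy (final AUT-A > 0.6, APO-A < 0.1);
3. stress = 50: apoptosis after a transient AUT-A peak that later falls
   below 25 % of its height;
4. stress = 5 with tg = 0.25: a single stable state, apoptotic — mild TG is
   lethal where mild TM is not;
5. a finite rescue window for the 10× autophagy inducer under high TM and
   no window under high TG;
6. washout of stress = 5 always reversible; washout of stress = 50
   reversible only before a finite threshold.

The structural choices that make all six attainable at once:

- **Timescale ordering** UPR and BCL-2 fast, AUT-A intermediate, APO-A slow
  (its rates ~20× smaller). The stress dose is therefore relayed almost
  instantaneously to the BCL-2 level, autophagy engages before apoptosis can
  creep up at low stress, and the slow caspase switch produces wide,
  experimentally meaningful rescue and washout windows.
- **Graded inducer response** AUT-A activation is Michaelian
  (`j_act_aut = 1`, of order the pool), so multiplying `kaua` by 10 raises
  the steady AUT-A level substantially instead of saturating — this is what
  lets inducer treatment stabilize a survival state at stress levels where
  it otherwise folds away.
- **Sharp caspase switch** APO-A uses small Michaelis constants (0.01), so
  its on/off states are near the pool boundaries and the decision is
  near-binary.
- **Strong saturating caspase attack on AUT-A** (`apo_on_aut = 15`) pins
  AUT-A low in every apoptotic state — including under the 10× inducer —
  keeping autophagy and apoptosis mutually exclusive; the mass-action
  cleavage flux (`cleave_rate = 2`, `kd_auti = 6`) feeds the AUT-I positive
  loop without letting it erode the rescued state at its low caspase level.

With this set the survival branch folds at stress ≈ 5.97; the bistable
interval is (0, 5.97), so commitment past the fold is irreversible at zero
stress; the stress-50 washout threshold is ≈ 3.6 a.u. and the TM rescue
window ≈ 3.3 a.u. The `results/` tables produced by the `analysis/` drivers
hold the exact values.

## Numerical methods

- **Integration** piecewise LSODA with the analytic Jacobian,
  rtol 1e-8 / atol 1e-10, ≥ 500 output points per segment. Treatment events
  are handled by segment restarts only — the state is continuous across an
  event, inputs jump; no in-step discontinuity handling is ever needed.
- **Outcome classification** apoptosis iff APO-A exceeds half its total on
  the entire final 10 % of the (post-event) horizon; else autophagy iff
  AUT-A does; else homeostasis. The model's attractors are near-fully
  on/off, so any threshold in [0.4, 0.6]×total gives identical labels
  (asserted as a test property). Default horizon: 200 a.u. after the last
  event, ample for settling at these rates. A transient peak is recorded
  when the trace later falls below 25 % of its global maximum — a repo
  convention for "transient".
- **Equilibria** multi-start Newton (scipy `hybr` + Newton polish to
  residual < 1e-10): a regular 3-per-axis grid over (aut_a, apo_a, bcl2)
  with the fast variables preset, seeded random starts, and — because the
  sharp switches give attractors tiny Newton basins — eight corner starts
  relaxed briefly along the flow before solving. Roots are kept only inside
  the physical box, merged at 1e-6 max-norm and classified by Jacobian
  eigenvalues (stable / saddle / unstable; |Re λ| ≤ 1e-9 is *marginal* and
  treated as a failure everywhere, since all claims assume hyperbolicity).
  Saturation is tested against a 600-start brute-force run.
- **Balance curves** the three hidden states are solved to quasi-steady
  state per grid point by root finding (hybr with a guaranteed scalar
  bracketing fallback — the hidden subsystem is triangular and each residual
  monotone); the zero contours of the plane rates are extracted with
  contourpy on a ≥ 100² grid and every vertex is bisection-polished to
  residual < 1e-6. Intersections (candidate equilibria) come from
  segment-pair crossing detection and independently cross-validate
  `find_equilibria` to 1e-3 in the plane.
- **Continuation** pseudo-arclength with secant prediction and a bordered
  Newton corrector; steps adapt in [1e-5, 1] from 0.1; folds are flagged by
  a sign change of the stress progression along arclength and refined by
  step bisection to |Δstress| < 1e-4. Branches are seeded from the
  equilibria at both ends of the stress range and deduplicated by proximity.
  A dense sweep (multi-start roots on a fine stress grid, nearest-neighbour
  linking) is implemented as the independent oracle.
- **Scans** rescue and washout thresholds assume (and verify — a
  non-monotone success pattern raises) a single success/failure boundary,
  refined by bisection to 0.01 time units. Inducer pre-treatment leads the
  stressor by 20 a.u. "Always reversible" is reported as `inf`.
- **Ensembles** each rate constant (not Michaelis constants or totals) is
  multiplied by an independent log-normal factor with median 1 and given cv,
  from a seeded `default_rng`; identical seeds give identical ensembles.

## What the scenario generator emulates — and what it does not

The scenario registry stands in for experimental treatments: step changes in
stressor concentration with instantaneous uptake, no pharmacokinetics, no
cell-to-cell variability, no death before the caspase switch. Time and
activity units are arbitrary, so only *orderings* of onsets and thresholds
are meaningful, never wall-clock hours of any experiment. Passing tests
therefore show that the wiring logic reproduces the qualitative decision
behavior (which outcome, which orderings, which treatments rescue), not that
the model is quantitatively predictive for any cell line.

## Robustness and limitations

Multiplicative perturbation of all 22 rate constants preserves the full
TM-low/TM-high/TG-low outcome triple in ~99 % of draws at cv = 0.02, ~89 %
at cv = 0.05 and ~63 % at cv = 0.1 (`analysis/06_robustness.py`; seeded).
The soft spot is deliberate: the low-TM dose (stress = 5) sits close below
the fold (≈ 5.97), exactly the regime the dose–response analysis is about,
so modest parameter jitter can move the fold across it.

Known limitations: the three UPR branches are one lumped sensor; no
stochasticity, no spatial effects, no explicit BAX dynamics; DTT has no
published simulation figure, so its direct-action coefficient is
model-extrapolated (set equal to TG's) and the DTT scenario is labeled
accordingly; absolute times and doses are not calibrated to any experiment.
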