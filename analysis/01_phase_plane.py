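"""Balance curves and steady states in the (AUT-A, APO-A) plane.

Recomputes the phase-plane pictures of the unstressed network and of the
low/high tunicamycin and thapsigargin treatments: under no stress the AUT-A
and APO-A balance curves intersect three times (homeostasis, saddle,
apoptotic state); low TM leaves the survival intersection in place with
AUT-A high; high TM and any TG dose leave only the apoptotic intersection.
Writes nullcline polylines and classified equilibria to results/.
"""

from pathlib import Path

import pandas as pd

from erswitch.equilibria import find_equilibria, nullclines
from erswitch.model import StressorInput, canonical_parameters

RESULTS = Path(__file__).resolve().parents[1] / "results"

CONDITIONS = {
    "unstressed": StressorInput(),
    "tm_low": StressorInput(stress=5.0),
    "tm_high": StressorInput(stress=50.0),
    "tg_low": StressorInput(stress=5.0, tg=0.25),
    "tg_high": StressorInput(stress=50.0, tg=0.25),
}


def main() -> None:
    params = canonical_parameters("calibrated_default")
    RESULTS.mkdir(exist_ok=True)
    eq_rows, nc_rows = [], []
    for name, inp in CONDITIONS.items():
        eqs = find_equilibria(params, inp)
        curve_a, curve_q = nullclines(params, inp, resolution=120)
        for e in eqs:
            s = e.state
            eq_rows.append({
                "condition": name, "stability": e.stability,
                "upr": s.upr, "bcl2": s.bcl2, "aut_a": s.aut_a,
                "aut_i": s.aut_i, "apo_a": s.apo_a,
            })
        for curve in (curve_a, curve_q):
            for bid, br in enumerate(curve.branches):
                for a, q in br[::2]:
                    nc_rows.append({"condition": name,
                                    "variable": curve.variable,
                                    "branch": bid, "aut_a": a, "apo_a": q})
        n_stable = sum(e.is_stable for e in eqs)
        print(f"{name:12s}: {len(eqs)} equilibria ({n_stable} stable)")

    pd.DataFrame(eq_rows).to_csv(RESULTS / "phase_plane_equilibria.csv",
                                 index=False, float_format="%.8g")
    pd.DataFrame(nc_rows).to_csv(RESULTS / "phase_plane_nullclines.csv",
                                 index=False, float_format="%.8g")
    print(f"-> {RESULTS / 'phase_plane_equilibria.csv'}")
    print(f"-> {RESULTS / 'phase_plane_nullclines.csv'}")


if __name__ == "__main__":
    main()
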