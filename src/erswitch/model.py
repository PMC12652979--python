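"""Core ODE model: state, parameters, stressor inputs, right-hand side, Jacobian.

State variables (all in arbitrary units, a.u.)
----------------------------------------------
upr     activity of the lumped UPR sensor
bcl2    active (uncleaved) BCL-2
aut_a   active autophagy inducer
aut_i   caspase-cleaved, inactive autophagy inducer
apo_a   active apoptosis inducer

Wiring
------
ER stress (and tunicamycin, which acts purely through it) activates the UPR
sensor; the UPR sensor and active caspases (APO-A) inactivate BCL-2; BCL-2
holds both inducers off by promoting their inactivation; AUT-A and APO-A
antagonize each other (the APO-A arm is realized as caspase cleavage of AUT-A
into AUT-I); AUT-I feeds back positively on APO-A activation.  Thapsigargin
adds direct activation terms on both inducers, dithiothreitol on the
apoptosis inducer only, and an autophagy inducer multiplies the AUT-A
activation rate constant.

Each species follows the generic kinetic template

    dXa/dt = production(XT - Xa) - consumption(Xa)

with Michaelis--Menten (zero-order-capable) terms for the switch-forming
activation/inactivation reactions and mass action for the cleavage reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "STATE_NAMES",
    "ModelState",
    "ParameterSet",
    "StressorInput",
    "rhs",
    "jacobian",
    "canonical_parameters",
    "physiological_state",
    "load_parameters",
    "save_parameters",
    "export_ode",
]

STATE_NAMES = ("upr", "bcl2", "aut_a", "aut_i", "apo_a")

PARAMS_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ModelState:
    """Instantaneous activities of the five lumped species (a.u.)."""

    upr: float
    bcl2: float
    aut_a: float
    aut_i: float
    apo_a: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.upr, self.bcl2, self.aut_a, self.aut_i, self.apo_a], dtype=float
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(float(v) for v in np.asarray(y, dtype=float)))

    def validate(self, params: "ParameterSet | None" = None, tol: float = 0.0) -> None:
        """Raise ``ValueError`` naming the offending component if inadmissible."""
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"state component {name!r} is not finite: {v!r}")
            if v < -tol:
                raise ValueError(f"state component {name!r} is negative: {v!r}")
        if params is not None:
            if self.upr > params.upr_t + tol:
                raise ValueError("state component 'upr' exceeds the UPR total pool")
            if self.bcl2 > params.bcl2_t + tol:
                raise ValueError("state component 'bcl2' exceeds the BCL-2 total pool")
            if self.aut_a + self.aut_i > params.aut_t + tol:
                raise ValueError(
                    "state components 'aut_a' + 'aut_i' exceed the autophagy-inducer"
                    " total pool"
                )
            if self.apo_a > params.apo_t + tol:
                raise ValueError(
                    "state component 'apo_a' exceeds the apoptosis-inducer total pool"
                )


@dataclass(frozen=True)
class StressorInput:
    """Time-constant external inputs.

    ``stress`` drives UPR activation (tunicamycin acts exclusively here);
    ``tg`` adds direct activation on both inducers; ``dtt`` adds direct
    activation on the apoptosis inducer only; ``kaua_mult`` multiplies the
    AUT-A activation rate constant (an autophagy inducer such as resveratrol;
    baseline 1).
    """

    stress: float = 0.0
    tg: float = 0.0
    dtt: float = 0.0
    kaua_mult: float = 1.0

    def validate(self) -> None:
        for name in ("stress", "tg", "dtt", "kaua_mult"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"stressor input {name!r} must be finite and >= 0")


FIELD_NAMES_INPUT = ("stress", "tg", "dtt", "kaua_mult")

# rate-constant fields (perturbed in robustness ensembles); Michaelis constants
# and total pools are excluded.
RATE_FIELDS = (
    "ks_upr",
    "kact_upr",
    "kin_upr",
    "kd_upr",
    "kact_bcl2",
    "kin_bcl2",
    "upr_on_bcl2",
    "apo_on_bcl2",
    "kaua_base",
    "kin_aut",
    "bcl2_on_aut",
    "apo_on_aut",
    "cleave_rate",
    "kd_auti",
    "tg_on_aut",
    "ks_apo",
    "kin_apo",
    "bcl2_on_apo",
    "aut_on_apo",
    "auti_on_apo",
    "tg_on_apo",
    "dtt_on_apo",
)

MICHAELIS_FIELDS = (
    "j_act_bcl2",
    "j_in_bcl2",
    "j_act_aut",
    "j_in_aut",
    "j_act_apo",
    "j_in_apo",
)

TOTAL_FIELDS = ("upr_t", "bcl2_t", "aut_t", "apo_t")


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants (1/time), Michaelis constants (dimensionless in a.u.
    of the normalized pools) and total pools (a.u.) of the ODE system.

    ``metadata`` records the variant name, schema version and whether the
    autophagy pool is conserved by the formulation (it is: activation,
    inactivation and cleavage only move material between the three pool
    compartments, so aut_a + aut_i + uncleaved = aut_t exactly).
    """

    # --- UPR sensor (mass action) ---
    ks_upr: float
    kact_upr: float  # per unit stress
    kin_upr: float
    kd_upr: float
    # --- BCL-2 ---
    kact_bcl2: float
    kin_bcl2: float
    upr_on_bcl2: float
    apo_on_bcl2: float  # caspase cleavage of BCL-2, mass action
    j_act_bcl2: float
    j_in_bcl2: float
    # --- autophagy inducer ---
    kaua_base: float
    kin_aut: float
    bcl2_on_aut: float
    apo_on_aut: float
    cleave_rate: float  # APO-A-driven AUT-A -> AUT-I, mass action
    kd_auti: float  # AUT-I return to the uncleaved inactive pool
    tg_on_aut: float
    j_act_aut: float
    j_in_aut: float
    # --- apoptosis inducer ---
    ks_apo: float
    kin_apo: float
    bcl2_on_apo: float
    aut_on_apo: float
    auti_on_apo: float
    tg_on_apo: float
    dtt_on_apo: float
    j_act_apo: float
    j_in_apo: float
    # --- total pools ---
    upr_t: float
    bcl2_t: float
    aut_t: float
    apo_t: float
    metadata: dict = field(default_factory=dict, compare=False)

    def validate(self) -> None:
        for name in RATE_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"rate constant {name!r} must be finite and >= 0")
        for name in MICHAELIS_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(f"Michaelis constant {name!r} must be finite and > 0")
        for name in TOTAL_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(f"total pool {name!r} must be finite and > 0")

    def with_rates(self, **updates: float) -> "ParameterSet":
        return replace(self, **updates)

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "metadata"
        }
        d["metadata"] = dict(self.metadata)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        d.setdefault("metadata", {})
        return cls(**d)


def _rhs_raw(y, p: ParameterSet, stress: float, tg: float, dtt: float,
             kaua_mult: float):
    """Unvalidated RHS on a raw 5-vector; shared by all numerical code paths."""
    u, b, a, i, q = y

    act_u = p.ks_upr + p.kact_upr * stress
    du = act_u * (p.upr_t - u) - (p.kin_upr + p.kd_upr) * u

    in_b = p.kin_bcl2 + p.upr_on_bcl2 * u
    db = (
        p.kact_bcl2 * (p.bcl2_t - b) / (p.j_act_bcl2 + p.bcl2_t - b)
        - in_b * b / (p.j_in_bcl2 + b)
        - p.apo_on_bcl2 * q * b
    )

    pool = p.aut_t - a - i
    act_a = p.kaua_base * kaua_mult + p.tg_on_aut * tg
    in_a = p.kin_aut + p.bcl2_on_aut * b + p.apo_on_aut * q
    da = (
        act_a * pool / (p.j_act_aut + pool)
        - in_a * a / (p.j_in_aut + a)
        - p.cleave_rate * q * a
    )

    di = p.cleave_rate * q * a - p.kd_auti * i

    act_q = p.ks_apo + p.auti_on_apo * i + p.tg_on_apo * tg + p.dtt_on_apo * dtt
    in_q = p.kin_apo + p.bcl2_on_apo * b + p.aut_on_apo * a
    dq = (
        act_q * (p.apo_t - q) / (p.j_act_apo + p.apo_t - q)
        - in_q * q / (p.j_in_apo + q)
    )

    return np.array([du, db, da, di, dq])


def _jac_raw(y, p: ParameterSet, stress: float, tg: float, dtt: float,
             kaua_mult: float):
    """Analytic Jacobian on a raw 5-vector (rows follow STATE_NAMES order)."""
    u, b, a, i, q = y
    J = np.zeros((5, 5))

    act_u = p.ks_upr + p.kact_upr * stress
    J[0, 0] = -act_u - (p.kin_upr + p.kd_upr)

    in_b = p.kin_bcl2 + p.upr_on_bcl2 * u
    J[1, 0] = -p.upr_on_bcl2 * b / (p.j_in_bcl2 + b)
    J[1, 1] = (
        -p.kact_bcl2 * p.j_act_bcl2 / (p.j_act_bcl2 + p.bcl2_t - b) ** 2
        - in_b * p.j_in_bcl2 / (p.j_in_bcl2 + b) ** 2
        - p.apo_on_bcl2 * q
    )
    J[1, 4] = -p.apo_on_bcl2 * b

    pool = p.aut_t - a - i
    act_a = p.kaua_base * kaua_mult + p.tg_on_aut * tg
    in_a = p.kin_aut + p.bcl2_on_aut * b + p.apo_on_aut * q
    dact_dpool = act_a * p.j_act_aut / (p.j_act_aut + pool) ** 2
    J[2, 1] = -p.bcl2_on_aut * a / (p.j_in_aut + a)
    J[2, 2] = (
        -dact_dpool
        - in_a * p.j_in_aut / (p.j_in_aut + a) ** 2
        - p.cleave_rate * q
    )
    J[2, 3] = -dact_dpool
    J[2, 4] = -p.apo_on_aut * a / (p.j_in_aut + a) - p.cleave_rate * a

    J[3, 2] = p.cleave_rate * q
    J[3, 3] = -p.kd_auti
    J[3, 4] = p.cleave_rate * a

    act_q = p.ks_apo + p.auti_on_apo * i + p.tg_on_apo * tg + p.dtt_on_apo * dtt
    in_q = p.kin_apo + p.bcl2_on_apo * b + p.aut_on_apo * a
    J[4, 1] = -p.bcl2_on_apo * q / (p.j_in_apo + q)
    J[4, 2] = -p.aut_on_apo * q / (p.j_in_apo + q)
    J[4, 3] = p.auti_on_apo * (p.apo_t - q) / (p.j_act_apo + p.apo_t - q)
    J[4, 4] = (
        -act_q * p.j_act_apo / (p.j_act_apo + p.apo_t - q) ** 2
        - in_q * p.j_in_apo / (p.j_in_apo + q) ** 2
    )

    return J


def rhs(state: ModelState, params: ParameterSet,
        inp: StressorInput) -> np.ndarray:
    """Time derivatives of the five state variables (a.u. per time unit)."""
    params.validate()
    inp.validate()
    state.validate(params, tol=1e-9)
    return _rhs_raw(state.to_array(), params, inp.stress, inp.tg, inp.dtt,
                    inp.kaua_mult)


def jacobian(state: ModelState, params: ParameterSet,
             inp: StressorInput) -> np.ndarray:
    """5x5 matrix of exact partial derivatives d(rhs_i)/d(state_j)."""
    params.validate()
    inp.validate()
    state.validate(params, tol=1e-9)
    return _jac_raw(state.to_array(), params, inp.stress, inp.tg, inp.dtt,
                    inp.kaua_mult)


# --------------------------------------------------------------------------
# canonical parameters


def _params_resource(name: str):
    return resources.files("erswitch").joinpath("params", f"{name}.yaml")


def load_parameters(source) -> ParameterSet:
    """Load a ParameterSet from a YAML file path or file-like object."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    schema = doc.pop("schema_version", None)
    if schema != PARAMS_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported parameter-file schema_version {schema!r};"
            f" expected {PARAMS_SCHEMA_VERSION}"
        )
    ps = ParameterSet.from_dict(doc)
    ps.validate()
    return ps


def save_parameters(params: ParameterSet, path) -> None:
    doc = params.to_dict()
    doc["schema_version"] = PARAMS_SCHEMA_VERSION
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def canonical_parameters(variant: str = "calibrated_default") -> ParameterSet:
    """Return a version-pinned canonical parameter set.

    ``calibrated_default`` is the repository's pinned set (totals normalized
    to 1 a.u.), calibrated to reproduce the full qualitative outcome matrix
    of the model: bistability at stress = 0, autophagy at stress = 5,
    apoptosis with a transient AUT-A peak at stress = 50, and a single
    apoptotic state under thapsigargin (tg = 0.25) at stress = 5.

    ``appendixA`` is reserved for a transliteration of the original XPP
    implementation; that source is not bundled with this repository, so
    requesting it raises ``LookupError``.
    """
    if variant == "calibrated_default":
        with _params_resource("calibrated_default").open("r") as fh:
            return load_parameters(fh)
    if variant == "appendixA":
        raise LookupError(
            "parameter variant 'appendixA' is not bundled: the original XPP"
            " source is unavailable; use 'calibrated_default'"
        )
    raise ValueError(f"unknown parameter variant {variant!r}")


def physiological_state(params: ParameterSet) -> ModelState:
    """A physiological initial condition: everything off except full BCL-2.

    Starting from this corner of the admissible box, the unstressed system
    relaxes to the homeostatic equilibrium (low AUT-A, inactive APO-A).
    """
    return ModelState(upr=0.0, bcl2=params.bcl2_t, aut_a=0.0, aut_i=0.0,
                      apo_a=0.0)


# --------------------------------------------------------------------------
# XPP export


_ODE_TEMPLATE_LINES = [
    "# ER stress decision network: UPR / BCL-2 / AUT-A / AUT-I / APO-A",
    "# exported by erswitch {version}; parameter variant: {variant}",
    "upr'=(ks_upr+kact_upr*stress)*(upr_t-upr)-(kin_upr+kd_upr)*upr",
    "bcl2'=kact_bcl2*(bcl2_t-bcl2)/(j_act_bcl2+bcl2_t-bcl2)"
    "-(kin_bcl2+upr_on_bcl2*upr)*bcl2/(j_in_bcl2+bcl2)-apo_on_bcl2*apo_a*bcl2",
    "aut_a'=(kaua_base*kaua_mult+tg_on_aut*tg)*(aut_t-aut_a-aut_i)"
    "/(j_act_aut+aut_t-aut_a-aut_i)"
    "-(kin_aut+bcl2_on_aut*bcl2+apo_on_aut*apo_a)*aut_a/(j_in_aut+aut_a)"
    "-cleave_rate*apo_a*aut_a",
    "aut_i'=cleave_rate*apo_a*aut_a-kd_auti*aut_i",
    "apo_a'=(ks_apo+auti_on_apo*aut_i+tg_on_apo*tg+dtt_on_apo*dtt)"
    "*(apo_t-apo_a)/(j_act_apo+apo_t-apo_a)"
    "-(kin_apo+bcl2_on_apo*bcl2+aut_on_apo*aut_a)*apo_a/(j_in_apo+apo_a)",
]


def export_ode(params: ParameterSet, inp: StressorInput | None = None,
               init: ModelState | None = None) -> str:
    """Render the model as XPP .ode text with bit-identical parameter values."""
    from erswitch import __version__

    inp = inp or StressorInput()
    init = init or physiological_state(params)
    lines = [
        line.format(version=__version__,
                    variant=params.metadata.get("variant", "custom"))
        for line in _ODE_TEMPLATE_LINES
    ]
    par_names = list(RATE_FIELDS) + list(MICHAELIS_FIELDS) + list(TOTAL_FIELDS)
    for name in par_names:
        lines.append(f"par {name}={getattr(params, name)!r}")
    for name in FIELD_NAMES_INPUT:
        lines.append(f"par {name}={getattr(inp, name)!r}")
    for name in STATE_NAMES:
        lines.append(f"init {name}={getattr(init, name)!r}")
    lines.append("@ total=200,meth=stiff")
    lines.append("done")
    return "\n".join(lines) + "\n"
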