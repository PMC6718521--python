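"""Model family for blood glucose control after oral glucose ingestion.

The model tracks eight states — glucose in the intestine, absorbed gut
glucose, blood glucose G, insulin I, C-peptide CP, effective insulin X, and
the two incretins GIP and GLP-1 — coupled through thirteen fluxes.  Insulin
(and C-peptide) secretion is driven by

    v10 = k10 * (G + a*GIP + b*G*GIP + c*GLP1 + d*G*GLP1),

where the coefficients a..d encode independent (a, c) and glucose-
cooperative (b, d) incretin actions.  A :class:`ModelStructure` fixes any
subset of a..d to zero and may remove the GLP-1 state entirely, yielding the
candidate family searched during model selection.

Eighteen kinetic parameters and six initial levels are estimated; the
remaining parameters (k9, k11, k12, k13, GIP_B, GLP1_B) are *derived* from
the requirement that the system is at steady state before ingestion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

import numpy as np

from . import _core

__all__ = [
    "ModelStructure",
    "KineticParameters",
    "InitialState",
    "DerivedParameters",
    "IngestionSchedule",
    "Subject",
    "ingestion_flux",
    "close_parameters",
    "flux_vector",
    "rhs",
    "KINETIC_NAMES",
    "INITIAL_NAMES",
    "STATE_NAMES",
    "SPECIES_STATE_INDEX",
]

#: Names of the 18 estimated kinetic parameters, in canonical order.
KINETIC_NAMES = (
    "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k10",
    "L2", "L4", "L6", "L8", "L11", "V",
    "a", "b", "c", "d",
)

#: Names of the 6 estimated initial levels.
INITIAL_NAMES = ("GIP0", "GLP10", "G0", "I0", "CP0", "X0")

#: Full-model state names in integration order.
STATE_NAMES = ("IntestG", "GIP", "GLP1", "AGutG", "G", "I", "CP", "X")

#: Measured species -> column in the padded 8-state vector.
SPECIES_STATE_INDEX = {"G": 4, "I": 5, "CP": 6, "GIP": 1, "GLP1": 2}


class ClosureDomainError(ValueError):
    """Raised when the steady-state closure is evaluated outside its domain."""


@dataclass(frozen=True)
class ModelStructure:
    """Which incretin-coupling coefficients are free and whether GLP-1 exists.

    ``include_glp1=False`` removes the GLP-1 equation structurally: the
    coefficients c and d are forced to zero and the GLP-1 secretion and
    relaxation parameters (k4, k5, L4) and initial level GLP1(0) are no
    longer estimated.
    """

    a_free: bool = True
    b_free: bool = True
    c_free: bool = True
    d_free: bool = True
    include_glp1: bool = True

    def __post_init__(self):
        if not self.include_glp1 and (self.c_free or self.d_free):
            object.__setattr__(self, "c_free", False)
            object.__setattr__(self, "d_free", False)

    @property
    def free_coefficients(self) -> tuple[str, ...]:
        return tuple(
            n for n, f in zip("abcd", (self.a_free, self.b_free, self.c_free, self.d_free)) if f
        )

    @property
    def zeroed_coefficients(self) -> tuple[str, ...]:
        return tuple(n for n in "abcd" if n not in self.free_coefficients)

    @property
    def free_kinetic_names(self) -> tuple[str, ...]:
        """Kinetic parameters estimated under this structure."""
        skip = set(self.zeroed_coefficients)
        if not self.include_glp1:
            skip |= {"k4", "k5", "L4"}
        return tuple(n for n in KINETIC_NAMES if n not in skip)

    @property
    def free_initial_names(self) -> tuple[str, ...]:
        if self.include_glp1:
            return INITIAL_NAMES
        return tuple(n for n in INITIAL_NAMES if n != "GLP10")

    @property
    def n_free(self) -> int:
        """Total count of estimated quantities (kinetic + initial levels)."""
        return len(self.free_kinetic_names) + len(self.free_initial_names)

    @property
    def state_names(self) -> tuple[str, ...]:
        if self.include_glp1:
            return STATE_NAMES
        return tuple(n for n in STATE_NAMES if n != "GLP1")

    @property
    def label(self) -> str:
        parts = []
        if not self.include_glp1:
            parts.append("noGLP1")
        zeroed = self.zeroed_coefficients
        if not self.include_glp1:
            zeroed = tuple(z for z in zeroed if z not in ("c", "d"))
        if zeroed:
            parts.append("=".join(zeroed) + "=0")
        return ",".join(parts) if parts else "full"

    def to_dict(self) -> dict:
        return {
            "a_free": self.a_free, "b_free": self.b_free,
            "c_free": self.c_free, "d_free": self.d_free,
            "include_glp1": self.include_glp1,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelStructure":
        return cls(**{k: bool(d[k]) for k in ("a_free", "b_free", "c_free", "d_free", "include_glp1")})


@dataclass(frozen=True)
class KineticParameters:
    """The 18 estimated kinetic parameters.

    Units: k2, k4 [pM/min]; k3, k5, k7 [1/min]; k6 [g/min]; k8, k10 set the
    hepatic-production and secretion scales; L2, L4, L6 [g]; L8 [units of X];
    L11 [pM]; V converts gut appearance [g/min] to blood glucose [mg/dL/min];
    a..d carry units making each secretion term glucose-equivalent.
    """

    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k10: float
    L2: float
    L4: float
    L6: float
    L8: float
    L11: float
    V: float
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0

    def masked(self, structure: ModelStructure) -> "KineticParameters":
        """Return a copy with structure-fixed coefficients forced to 0."""
        upd = {n: 0.0 for n in structure.zeroed_coefficients}
        if not structure.include_glp1:
            upd.update(k4=0.0, k5=0.0)
        return replace(self, **upd)

    def validate(self, structure: ModelStructure | None = None) -> None:
        for n in ("k2", "k3", "k6", "k7", "k8", "k10", "L2", "L6", "L8", "L11", "V"):
            if getattr(self, n) <= 0:
                raise ValueError(f"kinetic parameter {n} must be strictly positive")
        glp1 = structure.include_glp1 if structure is not None else True
        if glp1:
            for n in ("k4", "k5", "L4"):
                if getattr(self, n) <= 0:
                    raise ValueError(f"kinetic parameter {n} must be strictly positive")
        for n in "abcd":
            if getattr(self, n) < 0:
                raise ValueError(f"coupling coefficient {n} must be nonnegative")

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls) if f.name in d})


@dataclass(frozen=True)
class InitialState:
    """The six estimated pre-ingestion levels; IntestG(0) = AGutG(0) = 0."""

    GIP0: float
    GLP10: float
    G0: float
    I0: float
    CP0: float
    X0: float
    IntestG0: float = field(default=0.0)
    AGutG0: float = field(default=0.0)

    def validate(self, structure: ModelStructure | None = None) -> None:
        if self.IntestG0 != 0.0 or self.AGutG0 != 0.0:
            raise ValueError("IntestG(0) and AGutG(0) must be 0 (pre-ingestion)")
        glp1 = structure.include_glp1 if structure is not None else True
        names = ["GIP0", "G0", "I0", "CP0", "X0"] + (["GLP10"] if glp1 else [])
        for n in names:
            if getattr(self, n) <= 0:
                raise ClosureDomainError(f"initial level {n} must be strictly positive")

    def to_vector(self, structure: ModelStructure) -> np.ndarray:
        """Padded 8-state initial vector (GLP1 column 0 when removed)."""
        glp10 = self.GLP10 if structure.include_glp1 else 0.0
        return np.array(
            [0.0, self.GIP0, glp10, 0.0, self.G0, self.I0, self.CP0, self.X0],
            dtype=float,
        )

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in INITIAL_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "InitialState":
        return cls(**{n: float(d[n]) for n in INITIAL_NAMES if n in d})


@dataclass(frozen=True)
class DerivedParameters:
    """Parameters fixed by the pre-ingestion steady-state requirement."""

    k9: float
    k11: float
    k12: float
    k13: float
    GIP_B: float
    GLP1_B: float

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def close_parameters(
    kp: KineticParameters, init: InitialState, structure: ModelStructure
) -> DerivedParameters:
    """Derive k9, k11, k12, k13 and the basal incretin levels.

    Setting every state derivative to zero at the initial state with no
    ingestion gives::

        k9  = k8 / (G0 * X0 * (X0 + L8))
        k11 = k10 * (L11 + I0)/I0 * S0
        k12 = k10 * S0 / CP0
        k13 = I0 / ((I0 + L11) * X0)
        GIP_B = GIP0,  GLP1_B = GLP10

    with S0 = G0 + a*GIP0 + b*G0*GIP0 + c*GLP10 + d*G0*GLP10 the basal
    secretion drive.  For GLP-1-free structures GLP1 terms vanish (c=d=0,
    GLP1(0) contributes 0).
    """
    init.validate(structure)
    kpm = kp.masked(structure)
    g0, i0, cp0, x0 = init.G0, init.I0, init.CP0, init.X0
    gip0 = init.GIP0
    glp10 = init.GLP10 if structure.include_glp1 else 0.0
    s0 = g0 + kpm.a * gip0 + kpm.b * g0 * gip0 + kpm.c * glp10 + kpm.d * g0 * glp10
    if s0 <= 0:
        raise ClosureDomainError("basal secretion drive must be positive")
    return DerivedParameters(
        k9=kpm.k8 / (g0 * x0 * (x0 + kpm.L8)),
        k11=kpm.k10 * (kpm.L11 + i0) / i0 * s0,
        k12=kpm.k10 * s0 / cp0,
        k13=i0 / ((i0 + kpm.L11) * x0),
        GIP_B=gip0,
        GLP1_B=glp10,
    )


@dataclass(frozen=True)
class IngestionSchedule:
    """Oral glucose input as non-overlapping (start, grams, duration) events.

    Each event delivers grams/duration [g/min] over [start, start+duration).
    Bolus-type ingestion is a single event with the conventional 0.5-min
    duration.
    """

    events: tuple[tuple[float, float, float], ...]

    def __init__(self, events):
        evs = tuple((float(s), float(g), float(d)) for s, g, d in events)
        for s, g, d in evs:
            if g <= 0 or d <= 0:
                raise ValueError("event grams and duration must be positive")
            if s < 0:
                raise ValueError("event start must be nonnegative")
        ordered = sorted(evs)
        for (s1, _, d1), (s2, _, _) in zip(ordered, ordered[1:]):
            if s2 < s1 + d1 - 1e-12:
                raise ValueError("ingestion events may not overlap")
        object.__setattr__(self, "events", tuple(ordered))

    @classmethod
    def bolus(cls, grams: float, start: float = 0.0, duration: float = 0.5) -> "IngestionSchedule":
        return cls([(start, grams, duration)])

    @classmethod
    def continuous(cls, grams: float, duration: float, start: float = 0.0) -> "IngestionSchedule":
        return cls([(start, grams, duration)])

    @classmethod
    def empty(cls) -> "IngestionSchedule":
        sched = object.__new__(cls)
        object.__setattr__(sched, "events", ())
        return sched

    @property
    def total_grams(self) -> float:
        return sum(g for _, g, _ in self.events)

    @property
    def end_time(self) -> float:
        return max((s + d for s, _, d in self.events), default=0.0)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, rates) arrays for the compiled integrator."""
        starts = np.array([s for s, _, _ in self.events], dtype=float)
        ends = np.array([s + d for s, _, d in self.events], dtype=float)
        rates = np.array([g / d for _, g, d in self.events], dtype=float)
        return starts, ends, rates

    def boundaries(self) -> np.ndarray:
        starts, ends, _ = self.arrays()
        return np.unique(np.concatenate([starts, ends]))


def ingestion_flux(schedule: IngestionSchedule, t: float) -> float:
    """Ingestion flux [g/min] at time t: grams/duration inside an event window,
    0 otherwise.  A 50-g bolus over 0.5 min gives 50/0.5 = 100 g/min."""
    if not np.isfinite(t):
        raise ValueError("time must be finite")
    starts, ends, rates = schedule.arrays()
    return float(_core.flux_at(float(t), starts, ends, rates))


@dataclass(frozen=True)
class Subject:
    """A complete per-subject model: structure, kinetics, and initial levels."""

    structure: ModelStructure
    kinetics: KineticParameters
    initial: InitialState
    name: str = "subject"

    def __post_init__(self):
        self.kinetics.validate(self.structure)
        self.initial.validate(self.structure)

    @property
    def derived(self) -> DerivedParameters:
        return close_parameters(self.kinetics, self.initial, self.structure)

    def param_vector(self) -> np.ndarray:
        """Padded 24-entry parameter vector for the compiled kernels."""
        kp = self.kinetics.masked(self.structure)
        der = self.derived
        return np.array(
            [kp.k2, kp.k3, kp.k4, kp.k5, kp.k6, kp.k7, kp.k8, kp.k10,
             kp.L2, kp.L4, kp.L6, kp.L8, kp.L11, kp.V,
             kp.a, kp.b, kp.c, kp.d,
             der.k9, der.k11, der.k12, der.k13, der.GIP_B, der.GLP1_B],
            dtype=float,
        )

    def state_vector(self) -> np.ndarray:
        return self.initial.to_vector(self.structure)

    @property
    def species(self) -> tuple[str, ...]:
        """Measured species this subject's model predicts."""
        sp = ("G", "I", "CP", "GIP")
        return sp + ("GLP1",) if self.structure.include_glp1 else sp

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "structure": self.structure.to_dict(),
            "kinetics": self.kinetics.to_dict(),
            "initial": self.initial.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "Subject":
        return cls(
            structure=ModelStructure.from_dict(d["structure"]),
            kinetics=KineticParameters.from_dict(d["kinetics"]),
            initial=InitialState.from_dict(d["initial"]),
            name=d.get("name", "subject"),
        )

    @classmethod
    def from_json(cls, path) -> "Subject":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def flux_vector(state: np.ndarray, params: np.ndarray, glucose_flux: float) -> np.ndarray:
    """The 13 fluxes v1..v13 at a padded state with a given ingestion flux."""
    out = np.empty(13)
    _core.fluxes(np.asarray(state, dtype=float), np.asarray(params, dtype=float),
                 float(glucose_flux), out)
    return out


def rhs(state: np.ndarray, params: np.ndarray, glucose_flux: float) -> np.ndarray:
    """Right-hand side of the 8 state equations (padded layout)."""
    out = np.empty(_core.N_STATES)
    _core.rhs(np.asarray(state, dtype=float), np.asarray(params, dtype=float),
              float(glucose_flux), out)
    return out
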