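"""Synthetic subjects and datasets emulating the six-condition study design.

A synthetic subject is a ground-truth model (structure + kinetics + initial
levels).  Datasets are produced by simulating each ingestion protocol,
sampling the measured species on a clinical time grid, and adding
independent Gaussian measurement noise whose SD is a fraction of each
series' dynamic range (negative draws are clipped to zero, as concentration
assays report nonnegative values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExperimentDataset
from .model import (
    IngestionSchedule,
    InitialState,
    KineticParameters,
    ModelStructure,
    Subject,
)
from .simulate import SolverSettings, sample_at, simulate

__all__ = [
    "Protocol",
    "standard_protocols",
    "SyntheticSubjectSpec",
    "generate_dataset",
    "random_admissible_subject",
    "DEFAULT_GRID",
    "BOLUS_DURATION",
    "CONTINUOUS_DURATION",
]

#: Sampling grid [min] spanning the ~4-h return-to-baseline window.
DEFAULT_GRID = (0.0, 10.0, 20.0, 30.0, 45.0, 60.0, 75.0, 90.0, 120.0, 150.0, 180.0, 240.0)

BOLUS_DURATION = 0.5     # min; "within a minute" ingestion modeled as 0.5 min
CONTINUOUS_DURATION = 120.0  # min; 2-h continuous ingestion


@dataclass(frozen=True)
class Protocol:
    """One ingestion condition: a dose delivered as bolus or continuously."""

    name: str
    dose_g: float
    mode: str  # "bolus" | "continuous"
    duration: float

    def schedule(self) -> IngestionSchedule:
        return IngestionSchedule([(0.0, self.dose_g, self.duration)])


def standard_protocols() -> tuple[Protocol, ...]:
    """The six dose x duration conditions: {25, 50, 75} g x {bolus, 2-h}."""
    out = []
    for dose in (25, 50, 75):
        out.append(Protocol(f"{dose}B", float(dose), "bolus", BOLUS_DURATION))
        out.append(Protocol(f"{dose}C", float(dose), "continuous", CONTINUOUS_DURATION))
    return tuple(out)


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """Ground truth plus the measurement process for one synthetic subject.

    noise_fraction: Gaussian SD as a fraction of each (condition, species)
    series' noise-free range; either a scalar or a per-species mapping.
    """

    subject: Subject
    grid: tuple[float, ...] = DEFAULT_GRID
    noise_fraction: float | dict = 0.05
    seed: int = 0
    solver: SolverSettings = field(
        default_factory=lambda: SolverSettings(method="rk4", step=0.05, horizon=480.0)
    )

    def noise_for(self, species: str) -> float:
        if isinstance(self.noise_fraction, dict):
            frac = float(self.noise_fraction.get(species, 0.0))
        else:
            frac = float(self.noise_fraction)
        if frac < 0:
            raise ValueError("noise fraction must be nonnegative")
        return frac


def generate_dataset(
    spec: SyntheticSubjectSpec, protocols: tuple[Protocol, ...] | None = None
) -> ExperimentDataset:
    """Simulate every protocol from the ground truth and add measurement noise.

    Deterministic given the spec's seed.  A GLP-1-free subject yields no
    GLP-1 series (the model does not predict one).
    """
    if protocols is None:
        protocols = standard_protocols()
    grid = np.asarray(spec.grid, dtype=float)
    if grid.min() < 0 or grid.max() > spec.solver.horizon:
        raise ValueError("sampling grid must lie within [0, horizon]")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for proto in protocols:
        traj = simulate(spec.subject, proto.schedule(), spec.solver)
        for species in spec.subject.species:
            clean = sample_at(traj, grid, species)
            frac = spec.noise_for(species)
            if frac > 0:
                sd = frac * (clean.max() - clean.min())
                noisy = np.clip(clean + rng.normal(0.0, sd, size=clean.size), 0.0, None)
            else:
                noisy = clean
            for t, v in zip(grid, noisy):
                rows.append(
                    {
                        "subject_id": spec.subject.name,
                        "condition": proto.name,
                        "species": species,
                        "time_min": t,
                        "value": v,
                        "included": True,
                    }
                )
    frame = pd.DataFrame(rows)
    return ExperimentDataset(frame, allowed_conditions={p.name for p in protocols})


def random_admissible_subject(rng: np.random.Generator) -> Subject:
    """A random draw from moderate physiological parameter ranges, with a
    random coupling structure.

    Used by steady-state-closure property checks: every draw must close to
    an exact pre-ingestion steady state.  Ranges are log-uniform and bounded
    well inside the fitting module's default search box.
    """

    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    structure = ModelStructure(
        a_free=bool(rng.integers(2)),
        b_free=bool(rng.integers(2)),
        c_free=bool(rng.integers(2)),
        d_free=bool(rng.integers(2)),
        include_glp1=bool(rng.integers(2)),
    )
    kin = KineticParameters(
        k2=logu(0.5, 20), k3=logu(0.01, 0.5), k4=logu(0.1, 5), k5=logu(0.01, 0.5),
        k6=logu(0.1, 2), k7=logu(0.01, 0.5), k8=logu(0.5, 10), k10=logu(0.001, 0.1),
        L2=logu(1, 30), L4=logu(1, 30), L6=logu(1, 30), L8=logu(0.5, 10),
        L11=logu(100, 5000), V=logu(0.05, 1),
        a=logu(0.05, 3) if structure.a_free else 0.0,
        b=logu(0.005, 0.2) if structure.b_free else 0.0,
        c=logu(0.05, 3) if structure.c_free else 0.0,
        d=logu(0.001, 0.05) if structure.d_free else 0.0,
    )
    init = InitialState(
        GIP0=logu(5, 50), GLP10=logu(2, 20), G0=logu(60, 120),
        I0=logu(20, 100), CP0=logu(200, 800), X0=logu(0.3, 3),
    )
    return Subject(structure=structure, kinetics=kin, initial=init, name="draw")
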