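"""Bundled synthetic ground-truth subjects.

Three subjects whose incretin-coupling structures match the kinds of
structures model selection tends to favor in healthy adults:

- ``subjA``: GLP-1-free with a = 0 — insulin secretion driven by glucose
  plus the glucose-GIP cooperative term only;
- ``subjB``: b = c = 0 — independent GIP action plus glucose-GLP-1
  cooperation;
- ``subjC``: a = c = d = 0 — glucose-GIP cooperation only, with GLP-1
  dynamics present but not acting on secretion.

Parameter values are fixture choices tuned once to give physiological
dynamics (fasting glucose ~85-95 mg/dL, 50-g-bolus peak ~150 mg/dL, insulin
rising several-fold with a strong incretin contribution, all species back
near baseline within ~4 h); they are synthetic stand-ins, not measured
values.
"""

from __future__ import annotations

from .model import InitialState, KineticParameters, ModelStructure, Subject

__all__ = ["fixture_subjects", "fixture_subject"]


def fixture_subjects() -> dict[str, Subject]:
    subjA = Subject(
        name="subjA",
        structure=ModelStructure(a_free=False, b_free=True, c_free=False, d_free=False,
                                 include_glp1=False),
        kinetics=KineticParameters(
            k2=6.0, k3=0.08, k4=1.2, k5=0.12, k6=0.90, k7=0.12, k8=2.5, k10=0.015,
            L2=4.0, L4=6.0, L6=5.0, L8=2.0, L11=800.0, V=0.22,
            a=0.0, b=0.08, c=0.0, d=0.0,
        ),
        initial=InitialState(GIP0=15.0, GLP10=6.0, G0=90.0, I0=40.0, CP0=400.0, X0=1.0),
    )
    subjB = Subject(
        name="subjB",
        structure=ModelStructure(a_free=True, b_free=False, c_free=False, d_free=True,
                                 include_glp1=True),
        kinetics=KineticParameters(
            k2=6.5, k3=0.12, k4=1.2, k5=0.035, k6=0.85, k7=0.11, k8=2.8, k10=0.013,
            L2=4.5, L4=15.0, L6=5.5, L8=2.2, L11=900.0, V=0.24,
            a=1.5, b=0.0, c=0.0, d=0.012,
        ),
        initial=InitialState(GIP0=20.0, GLP10=8.0, G0=95.0, I0=50.0, CP0=450.0, X0=1.1),
    )
    subjC = Subject(
        name="subjC",
        structure=ModelStructure(a_free=False, b_free=True, c_free=False, d_free=False,
                                 include_glp1=True),
        kinetics=KineticParameters(
            k2=5.5, k3=0.075, k4=1.1, k5=0.13, k6=0.95, k7=0.13, k8=2.3, k10=0.017,
            L2=3.8, L4=5.5, L6=4.8, L8=1.8, L11=750.0, V=0.21,
            a=0.0, b=0.09, c=0.0, d=0.0,
        ),
        initial=InitialState(GIP0=13.0, GLP10=5.0, G0=85.0, I0=35.0, CP0=350.0, X0=0.9),
    )
    return {"subjA": subjA, "subjB": subjB, "subjC": subjC}


def fixture_subject(name: str) -> Subject:
    return fixture_subjects()[name]
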