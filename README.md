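# glucopt

Forward modeling and inverse design of oral glucose ingestion patterns.

## The problem

After an oral glucose load, blood glucose, insulin, C-peptide, and the
incretin hormones GIP and GLP-1 rise and return to baseline within hours.
How the *temporal pattern* of ingestion — the same total dose taken as a
bolus, continuously, or intermittently — shapes the glucose excursion is a
question with direct relevance to postprandial hyperglycemia.  `glucopt`
addresses it in two coupled steps:

1. **Forward problem.** An 8-state ODE model of glucose–insulin–incretin
   dynamics is fit per subject to multi-condition time courses (three
   doses × two ingestion durations).  Insulin secretion is driven by
   `v10 = k10 (G + a·GIP + b·G·GIP + c·GLP1 + d·G·GLP1)`; the structure of
   the incretin action (which of a–d are nonzero, whether GLP-1 appears at
   all) is chosen per subject by AIC, `N log(RSS) + 2K`, over the 16–20
   candidate structures.  Parameters are estimated by evolutionary
   programming with simplex refinement on the min-max-normalized RSS; the
   pre-ingestion steady state closes four rate constants and the basal
   incretin levels analytically.

2. **Inverse problem.** Given a fitted subject model, an evolutionary
   program searches the integer ingestion patterns u = [u0, u5, …, u60]
   (5-min grid, Σu = 50 g, u0 ≥ 1 g; ~10^12 feasible compositions) for the
   pattern minimizing the simulated peak of blood glucose (G_Max) or
   insulin (I_Max) over 8 h.  On small instances the optimizer is verified
   against exhaustive enumeration.

The package is aimed at systems-biology practitioners who want a tested,
reusable implementation of this forward/inverse pipeline.  Human data are
replaced by a synthetic-subject generator that emulates the six-condition
design with configurable measurement noise, so every stage — fitting,
structure selection, pattern optimization — is testable end to end.

## Worked example

```python
import glucopt as g
from glucopt.patterns import ObjectiveSpec, OptimizerSettings, optimize

subj = g.fixture_subject("subjA")          # bundled synthetic subject

# forward: simulate a 50-g bolus
traj = g.simulate(subj, g.IngestionSchedule.bolus(50.0),
                  g.SolverSettings(method="rk4", step=0.05))
print(f"bolus peak G = {g.peak_value(traj, 'G'):.1f} mg/dL, "
      f"peak I = {g.peak_value(traj, 'I'):.1f} pM")

# inverse: find the glucose-minimizing 50-g pattern over 0-60 min
res = optimize(subj, ObjectiveSpec(target="glucose_peak"),
               OptimizerSettings(pop_size=60, n_generations=60, trials=1, seed=1))
print("pattern u* =", list(res.best_pattern.grams))
print(f"optimized peak G = {res.best_j:.1f} mg/dL")
```

prints

```
bolus peak G = 153.3 mg/dL, peak I = 237.1 pM
pattern u* = [10, 1, 0, 1, 0, 1, 4, 1, 4, 1, 0, 0, 27]
optimized peak G = 122.5 mg/dL
```

The optimized pattern is *intermittent* — most of the dose at 0 and
60 min with small amounts in between — and cuts the glucose peak by
~20% relative to the bolus (153.3 → 122.5 mg/dL) and below the 1-h
continuous reference as well.  The same machinery with
`target="insulin_peak"` yields the insulin-minimizing pattern.

The full pipeline (synthesize data → fit → select structure → optimize →
peak-comparison report) runs from the shell:

```bash
glucopt pipeline --out-dir runs/demo --subject subjB --seed 7
glucopt synth --subject subjC --noise 0.05 --seed 1 --out subjC.csv
glucopt select --dataset subjC.csv --out-table aic.csv --out-structure sel.json
```

## Layout

| module | contents |
| --- | --- |
| `glucopt.model` | states, fluxes, structures, steady-state closure, schedules |
| `glucopt.simulate` | Euler / RK4 / LSODA integration, sampling, peaks |
| `glucopt.synth` | six-condition protocols, synthetic subjects, noise model |
| `glucopt.fixtures` | three bundled ground-truth subjects |
| `glucopt.fitting` | normalized RSS, EP global search, simplex + least-squares refinement |
| `glucopt.selection` | candidate enumeration, AIC, warm-started selection scan |
| `glucopt.patterns` | ingestion patterns, EP optimizer, exhaustive oracle |
| `glucopt.io` / `glucopt.cli` | dataset CSV I/O, pipeline, `glucopt` command |

See `docs/methods.md` for the model equations, numerical choices, and
design rationale.
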