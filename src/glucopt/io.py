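"""Dataset files, run configuration, and the end-to-end pipeline.

Datasets are long-format CSV (subject_id, condition, species, time_min,
value, included) so conditions with different sampling grids coexist.
Every artifact written by the pipeline embeds the RNG seed and a hash of
the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DatasetError, ExperimentDataset, SPECIES
from .fitting import FitSettings, fit
from .fixtures import fixture_subject
from .model import IngestionSchedule, Subject
from .patterns import ObjectiveSpec, OptimizerSettings, optimize
from .selection import enumerate_candidates, select_model
from .simulate import SolverSettings, peak_value, simulate
from .synth import SyntheticSubjectSpec, generate_dataset, standard_protocols

__all__ = ["RunConfig", "read_dataset", "write_dataset", "run_pipeline"]

log = logging.getLogger("glucopt")


def write_dataset(dataset: ExperimentDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)


def read_dataset(path, allowed_conditions=None) -> ExperimentDataset:
    """Read and validate a long-format dataset CSV.

    Raises DatasetError with a line reference for malformed rows; species
    and condition tokens are checked against the known vocabularies.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise DatasetError(f"cannot parse {path}: {exc}") from exc
    required = ["subject_id", "condition", "species", "time_min", "value", "included"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")
    for col in ("time_min", "value"):
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise DatasetError(f"{path}:{line}: non-numeric {col!r}")
        frame[col] = pd.to_numeric(frame[col])
    badsp = ~frame["species"].isin(SPECIES)
    if badsp.any():
        line = int(badsp.idxmax()) + 2
        raise DatasetError(
            f"{path}:{line}: unknown species {frame['species'][badsp.idxmax()]!r}"
        )
    return ExperimentDataset(frame, allowed_conditions=allowed_conditions)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run.

    Exactly one of ``dataset_path`` (measured data) or ``synth_subject``
    (name of a bundled fixture, or a subject-JSON path) provides the data.
    ``structure_from`` selects how the model structure is chosen:
    "selection" (AIC over the candidate set) or "truth" (the synthetic
    subject's own structure; only for synthetic runs).
    """

    out_dir: str
    dataset_path: str | None = None
    synth_subject: str | None = "subjA"
    noise_fraction: float = 0.05
    structure_from: str = "selection"
    seed: int = 0
    stages: tuple[str, ...] = ("synth", "fit", "optimize", "report")
    fit_settings: FitSettings = field(default_factory=FitSettings)
    optimizer_settings: OptimizerSettings = field(default_factory=OptimizerSettings)
    objective_horizon: float = 480.0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _meta(config: RunConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash()}


def _json_dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=lambda o: float(o) if isinstance(
            o, (np.integer, np.floating)) else str(o))


def run_pipeline(config: RunConfig) -> dict:
    """synth -> fit/select -> optimize -> report, with all artifacts on disk.

    Returns the report dict: per-schedule peak glucose and insulin under
    the 50-g bolus, the 50-g 1-h continuous schedule, and the optimized
    glucose- and insulin-minimization patterns.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _meta(config)
    rng_seeds = np.random.SeedSequence(config.seed).spawn(3)

    # --- data stage ---------------------------------------------------------
    truth_subject = None
    if config.dataset_path is not None:
        dataset = read_dataset(config.dataset_path)
    else:
        name = config.synth_subject or "subjA"
        if name.endswith(".json"):
            truth_subject = Subject.from_json(name)
        else:
            truth_subject = fixture_subject(name)
        spec = SyntheticSubjectSpec(
            subject=truth_subject,
            noise_fraction=config.noise_fraction,
            seed=int(rng_seeds[0].generate_state(1)[0] % (2**31)),
        )
        dataset = generate_dataset(spec)
        write_dataset(dataset, out / "dataset.csv")
        _json_dump({**meta, "subject": truth_subject.to_dict()}, out / "synth_meta.json")
    log.info("dataset: %d points, conditions %s", dataset.n_points(), dataset.conditions)

    # --- fit / select stage -------------------------------------------------
    fit_settings = dataclasses.replace(
        config.fit_settings, seed=int(rng_seeds[1].generate_state(1)[0] % (2**31))
    )
    if config.structure_from == "truth" and truth_subject is not None:
        structure = truth_subject.structure
        fit_res = fit(dataset, structure, fit_settings)
    else:
        cands = enumerate_candidates(include_glp1_free="GLP1" not in dataset.species)
        sel = select_model(dataset, cands, fit_settings)
        sel.table().drop(columns=["error"]).to_csv(out / "aic_table.csv", index=False)
        _json_dump(
            {**meta, "selected": sel.selected.structure.to_dict(),
             "label": sel.selected.label, "tie_break": sel.tie_break,
             "metadata": sel.metadata},
            out / "selection.json",
        )
        structure = sel.selected.structure
        fit_res = sel.selected_fit
    fitted = fit_res.subject(name=dataset.subject_id + "-fitted")
    _json_dump({**meta, **fit_res.to_dict()}, out / "fit.json")

    # fitted-vs-data trajectories
    solver = SolverSettings(method="rk4", step=0.05, horizon=config.objective_horizon)
    rows = []
    for proto in standard_protocols():
        if proto.name not in dataset.included_conditions:
            continue
        traj = simulate(fitted, proto.schedule(), solver)
        for sp in fitted.species:
            try:
                t, v = dataset.series(proto.name, sp)
            except KeyError:
                continue
            sim = np.interp(t, traj.times, traj.column(sp))
            for ti, vi, si in zip(t, v, sim):
                rows.append({"condition": proto.name, "species": sp,
                             "time_min": ti, "measured": vi, "fitted": si})
    pd.DataFrame(rows).to_csv(out / "fitted_vs_data.csv", index=False)

    # --- optimize stage -----------------------------------------------------
    report: dict = {**meta, "subject_id": dataset.subject_id,
                    "structure": structure.label, "fit_rss": fit_res.best_rss}
    if "optimize" in config.stages:
        opt_settings = dataclasses.replace(
            config.optimizer_settings,
            seed=int(rng_seeds[2].generate_state(1)[0] % (2**31)),
        )
        schedules = {
            "bolus_50g": IngestionSchedule.bolus(50.0),
            "continuous_1h_50g": IngestionSchedule.continuous(50.0, 60.0),
        }
        results = {}
        for target in ("glucose_peak", "insulin_peak"):
            obj = ObjectiveSpec(target=target, horizon=config.objective_horizon)
            res = optimize(fitted, obj, opt_settings)
            tag = "glucose_min" if target == "glucose_peak" else "insulin_min"
            results[tag] = res
            res.pattern_frame().to_csv(out / f"pattern_{tag}.tsv", sep="\t", index=False)
            pd.DataFrame({"generation": range(len(res.trace)), "best_J": res.trace}).to_csv(
                out / f"trace_{tag}.csv", index=False
            )
            from .patterns import pattern_to_schedule

            schedules[tag] = pattern_to_schedule(res.best_pattern)

        fine = SolverSettings(method="euler", step=0.001, horizon=config.objective_horizon)
        peaks = {}
        for name, sched in schedules.items():
            traj = simulate(fitted, sched, fine)
            peaks[name] = {"peak_G": peak_value(traj, "G"), "peak_I": peak_value(traj, "I")}
        report["peaks"] = peaks
        report["glucose_min_pattern"] = list(results["glucose_min"].best_pattern.grams)
        report["insulin_min_pattern"] = list(results["insulin_min"].best_pattern.grams)
        pd.DataFrame(peaks).T.rename_axis("schedule").to_csv(out / "peaks.csv")

    _json_dump(report, out / "report.json")
    return report
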