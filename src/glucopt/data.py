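"""Long-format container for multi-condition time-course measurements.

A dataset holds, per (condition, species), a measured time series: blood
glucose G [mg/dL], insulin I [pM], C-peptide CP [pM], intact GIP [pM], and
intact GLP-1 [pM], over ingestion conditions such as the standard six
(25/50/75 g by bolus or 2-h continuous).  Conditions can be flagged as
excluded and then contribute nothing to fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ExperimentDataset", "SPECIES", "STANDARD_CONDITIONS", "DatasetError"]

SPECIES = ("G", "I", "CP", "GIP", "GLP1")
STANDARD_CONDITIONS = ("25B", "25C", "50B", "50C", "75B", "75C")

_COLUMNS = ["subject_id", "condition", "species", "time_min", "value", "included"]


class DatasetError(ValueError):
    pass


class ExperimentDataset:
    """Measured (or synthetic) time courses in long format.

    Wraps a DataFrame with columns subject_id, condition, species, time_min,
    value, included.  Rows with ``included == False`` (whole conditions
    excluded from fitting, mirroring how anomalous experiments are dropped)
    are retained but ignored by every fitting-facing accessor.
    """

    def __init__(self, frame: pd.DataFrame, allowed_conditions=None):
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise DatasetError(f"dataset missing columns: {missing}")
        frame = frame[_COLUMNS].copy()
        frame["time_min"] = frame["time_min"].astype(float)
        frame["value"] = frame["value"].astype(float)
        frame["included"] = frame["included"].astype(bool)
        bad = set(frame["species"]) - set(SPECIES)
        if bad:
            raise DatasetError(f"unknown species token(s): {sorted(bad)}")
        allowed = set(allowed_conditions) if allowed_conditions is not None else set(STANDARD_CONDITIONS)
        badc = set(frame["condition"]) - allowed
        if badc:
            raise DatasetError(f"unknown condition label(s): {sorted(badc)}")
        dup = frame.duplicated(subset=["subject_id", "condition", "species", "time_min"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise DatasetError(
                f"duplicate measurement at condition {row.condition}, species "
                f"{row.species}, t = {row.time_min}"
            )
        self.frame = frame.sort_values(["condition", "species", "time_min"]).reset_index(drop=True)

    # -- accessors -----------------------------------------------------------

    @property
    def subject_id(self) -> str:
        return str(self.frame["subject_id"].iloc[0])

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["condition"].unique()))

    @property
    def included_conditions(self) -> tuple[str, ...]:
        inc = self.frame[self.frame["included"]]
        return tuple(sorted(inc["condition"].unique()))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s in SPECIES if s in set(self.frame["species"]))

    def series(self, condition: str, species: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.frame[
            (self.frame["condition"] == condition) & (self.frame["species"] == species)
        ]
        if sel.empty:
            raise KeyError(f"no series for ({condition}, {species})")
        return sel["time_min"].to_numpy(), sel["value"].to_numpy()

    def keys(self, species_subset=None) -> list[tuple[str, str]]:
        """(condition, species) pairs included in fitting."""
        inc = self.frame[self.frame["included"]]
        out = []
        for cond in sorted(inc["condition"].unique()):
            for sp in SPECIES:
                if species_subset is not None and sp not in species_subset:
                    continue
                if ((inc["condition"] == cond) & (inc["species"] == sp)).any():
                    out.append((cond, sp))
        return out

    def n_points(self, species_subset=None) -> int:
        """Total number of included data points (the N of the AIC formula)."""
        inc = self.frame[self.frame["included"]]
        if species_subset is not None:
            inc = inc[inc["species"].isin(species_subset)]
        return int(len(inc))

    def series_range(self, condition: str, species: str) -> float:
        _, v = self.series(condition, species)
        return float(v.max() - v.min())

    def fasting_value(self, species: str) -> float:
        """Mean measured level at t = 0 across included conditions."""
        inc = self.frame[
            self.frame["included"]
            & (self.frame["species"] == species)
            & (self.frame["time_min"] == 0.0)
        ]
        if inc.empty:
            raise KeyError(f"no t = 0 measurements for species {species}")
        return float(inc["value"].mean())

    def validate_ranges(self) -> None:
        """Every included series must have max > min (the RSS denominator)."""
        for cond, sp in self.keys():
            if self.series_range(cond, sp) <= 0:
                raise DatasetError(f"degenerate series (max = min): ({cond}, {sp})")

    def with_condition_excluded(self, condition: str) -> "ExperimentDataset":
        frame = self.frame.copy()
        frame.loc[frame["condition"] == condition, "included"] = False
        return ExperimentDataset(frame, allowed_conditions=set(frame["condition"]))

    def without_species(self, species: str) -> "ExperimentDataset":
        frame = self.frame[self.frame["species"] != species].copy()
        return ExperimentDataset(frame, allowed_conditions=set(frame["condition"]))

    # -- equality (used by round-trip tests) ---------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExperimentDataset):
            return NotImplemented
        return self.frame.equals(other.frame)
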