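"""AIC selection of the incretin-coupling structure.

Candidate structures are the 2^4 = 16 on/off combinations of the secretion
coefficients {a, b, c, d}, optionally extended by the 4 GLP-1-free variants
(combinations of {a, b} with the GLP-1 state removed).  Each candidate is
fit to the same dataset and scored by

    AIC = N log(RSS) + 2 K          (natural log)

where N is the total number of fitted data points — identical across
candidates by construction — and K counts every estimated quantity: the
free kinetic parameters plus the free initial levels.  The candidate
minimizing AIC is selected; ties break toward smaller K, then label order.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .data import ExperimentDataset
from .fitting import FitSettings, FitResult, RssEvaluator, _refine_chain, fit
from .model import ModelStructure

__all__ = ["CandidateStructure", "SelectionResult", "enumerate_candidates", "aic", "select_model"]


@dataclass(frozen=True)
class CandidateStructure:
    structure: ModelStructure
    label: str

    @property
    def K(self) -> int:
        """Number of estimated quantities (kinetic parameters + initial levels)."""
        return self.structure.n_free


@dataclass(frozen=True)
class SelectionResult:
    records: tuple[dict, ...]       # per candidate: label, rss, N, K, aic, error
    selected: CandidateStructure
    selected_fit: FitResult
    tie_break: str
    metadata: dict = field(default_factory=dict)

    def table(self):
        import pandas as pd

        return pd.DataFrame([{k: r.get(k) for k in ("label", "rss", "N", "K", "aic", "error")}
                             for r in self.records])


def enumerate_candidates(include_glp1_free: bool = False) -> list[CandidateStructure]:
    """All 16 coefficient on/off combinations, plus (optionally) the 4
    structurally GLP-1-free variants over {a, b}."""
    out = []
    for a, b, c, d in itertools.product((True, False), repeat=4):
        s = ModelStructure(a_free=a, b_free=b, c_free=c, d_free=d, include_glp1=True)
        out.append(CandidateStructure(structure=s, label=s.label))
    if include_glp1_free:
        for a, b in itertools.product((True, False), repeat=2):
            s = ModelStructure(a_free=a, b_free=b, c_free=False, d_free=False,
                               include_glp1=False)
            out.append(CandidateStructure(structure=s, label=s.label))
    return out


def aic(rss_value: float, n_data: int, k_params: int) -> float:
    """AIC = N log(RSS) + 2K, natural logarithm.

    RSS = 0 (an exact fit) is reported as -inf with a warning: the
    normal-residual likelihood degenerates and the model trivially wins.
    """
    if n_data < 0 or k_params < 0:
        raise ValueError("n_data and k_params must be nonnegative")
    if rss_value < 0:
        raise ValueError("RSS must be nonnegative")
    if rss_value == 0:
        warnings.warn("AIC of an exact fit (RSS = 0) reported as -inf")
        return -math.inf
    return n_data * math.log(rss_value) + 2 * k_params


def _warm_vector(donor: FitResult, candidate: ModelStructure) -> np.ndarray | None:
    """Project a superset-structure fit onto a nested candidate's free names."""
    names = candidate.free_kinetic_names + candidate.free_initial_names
    by_name = dict(zip(donor.free_names, donor.best_theta))
    try:
        return np.log(np.array([by_name[n] for n in names]))
    except KeyError:
        return None


def select_model(
    dataset: ExperimentDataset,
    candidates: list[CandidateStructure] | None = None,
    fit_settings: FitSettings | None = None,
    warm_start: bool = True,
) -> SelectionResult:
    """Fit every candidate on identical data and select the AIC minimizer.

    All candidates see the same N: if any candidate lacks the GLP-1 state,
    the GLP-1 series is dropped from the comparison (the species must be
    predictable by every model being compared).

    With ``warm_start`` (default), the maximal candidate of each family
    (GLP-1-including / GLP-1-free) is fit with the full configured budget
    and every nested candidate is fit with a reduced EP budget plus a
    refinement started from the family fit projected onto its free
    parameters — the usual way a nested AIC scan is run.  With
    ``warm_start=False`` every candidate gets the full budget
    independently.
    """
    if candidates is None:
        candidates = enumerate_candidates(include_glp1_free="GLP1" not in dataset.species)
    if not candidates:
        raise ValueError("need at least one candidate structure")
    fit_settings = fit_settings or FitSettings()

    species_subset = None
    if any(not c.structure.include_glp1 for c in candidates):
        species_subset = tuple(s for s in dataset.species if s != "GLP1")

    n_data = dataset.n_points(species_subset)

    # fit the maximal candidate of each family at full budget
    families: dict[bool, FitResult] = {}
    if warm_start:
        for glp1 in sorted({c.structure.include_glp1 for c in candidates}, reverse=True):
            fam = [c for c in candidates if c.structure.include_glp1 == glp1]
            maximal = max(fam, key=lambda c: c.K)
            families[glp1] = fit(dataset, maximal.structure, fit_settings, species_subset)

    reduced = dc_replace(
        fit_settings,
        n_trials=1,
        pop_size=max(10, fit_settings.pop_size // 5),
        n_generations=max(10, fit_settings.n_generations // 5),
        simplex_maxiter=max(400, fit_settings.simplex_maxiter // 2),
        polish_max_nfev=max(150, fit_settings.polish_max_nfev // 2),
    )

    records = []
    fits: dict[str, FitResult] = {}
    # decreasing K: every nested candidate can then warm-start from the
    # best already-fitted superset, which keeps all fits near their floors
    order = sorted(range(len(candidates)), key=lambda i: -candidates[i].K)
    for idx in order:
        cand = candidates[idx]
        try:
            if warm_start:
                fam_fit = families[cand.structure.include_glp1]
                if cand.K == len(fam_fit.free_names):
                    res = fam_fit
                else:
                    names = set(cand.structure.free_kinetic_names
                                + cand.structure.free_initial_names)
                    donors = [
                        f for f in fits.values()
                        if f.structure.include_glp1 == cand.structure.include_glp1
                        and names <= set(f.free_names)
                    ]
                    donors.sort(key=lambda f: f.best_rss)
                    starts = []
                    for donor in [fam_fit] + donors[:1]:
                        xw = _warm_vector(donor, cand.structure)
                        if xw is not None and not any(
                            np.allclose(xw, s) for s in starts
                        ):
                            starts.append(xw)
                    if not starts:
                        res = fit(dataset, cand.structure, reduced, species_subset)
                    else:
                        ev = RssEvaluator(dataset, cand.structure, reduced.solver,
                                          species_subset)
                        x_best, f_best = None, math.inf
                        for xw in starts:
                            x_ref, f_ref = _refine_chain(xw, ev, reduced)
                            if f_ref < f_best:
                                x_best, f_best = x_ref, f_ref
                        # one extra polish pass on the winner
                        x_best, f_best = _refine_chain(x_best, ev, reduced)
                        res = FitResult(
                            structure=cand.structure, free_names=ev.free_names,
                            best_theta=np.exp(x_best), best_rss=float(f_best),
                            trial_rss=(float(f_best),), settings=reduced,
                        )
            else:
                res = fit(dataset, cand.structure, fit_settings, species_subset)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score = aic(res.best_rss, n_data, cand.K)
            fits[cand.label] = res
            records.append({"label": cand.label, "rss": res.best_rss, "N": n_data,
                            "K": cand.K, "aic": score, "error": None,
                            "_cand": cand})
        except Exception as exc:  # record and keep selecting over successes
            records.append({"label": cand.label, "rss": math.nan, "N": n_data,
                            "K": cand.K, "aic": math.nan, "error": str(exc),
                            "_cand": cand})

    ok = [(r, r["_cand"]) for r in records if r["error"] is None]
    if not ok:
        raise RuntimeError("every candidate fit failed")
    ok.sort(key=lambda rc: (rc[0]["aic"], rc[0]["K"], rc[0]["label"]))
    best_rec, best_cand = ok[0]
    tie = "unique minimum"
    if len(ok) > 1 and math.isclose(ok[1][0]["aic"], best_rec["aic"], abs_tol=1e-12):
        tie = f"AIC tie with {ok[1][0]['label']}; broke by smaller K, then label order"

    public = tuple({k: v for k, v in r.items() if k != "_cand"} for r in records)
    return SelectionResult(
        records=public,
        selected=best_cand,
        selected_fit=fits[best_cand.label],
        tie_break=tie,
        metadata={
            "n_data": n_data,
            "species": list(species_subset) if species_subset is not None else list(dataset.species),
            "warm_start": warm_start,
            "k_counts_initial_levels": True,
            "glp1_series_dropped": species_subset is not None and "GLP1" in dataset.species,
        },
    )
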