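"""Per-subject parameter estimation by evolutionary programming + simplex.

The objective is the min-max-normalized residual sum of squares

    RSS = sum_i sum_k sum_t [ (sim_{i,k}(t) - exp_{i,k}(t))
                              / (max_t exp_{i,k} - min_t exp_{i,k}) ]^2

over ingestion conditions i, measured species k, and sampling times t;
excluded conditions contribute nothing.  The search runs in log-parameter
space (all estimated quantities are positive scales), globally with classic
self-adaptive Gaussian-mutation EP and locally with Nelder-Mead refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from . import _core
from .data import DatasetError, ExperimentDataset
from .model import (
    INITIAL_NAMES,
    KINETIC_NAMES,
    SPECIES_STATE_INDEX,
    InitialState,
    KineticParameters,
    ModelStructure,
    Subject,
)
from .simulate import SolverSettings

__all__ = ["FitSettings", "FitResult", "RssEvaluator", "rss", "ep_global_search",
           "simplex_refine", "fit"]

_PENALTY_RSS = 1e12  # finite sentinel for failed integrations

# index of each kinetic name in the padded 24-parameter vector
_KIN_INDEX = {n: i for i, n in enumerate(KINETIC_NAMES)}
# index of each initial level in the padded 8-state vector
_INIT_INDEX = {"GIP0": 1, "GLP10": 2, "G0": 4, "I0": 5, "CP0": 6, "X0": 7}

#: Physiologically-motivated default search ranges per kinetic parameter.
#: Chosen once from the parameter units (first-order rates bounded by
#: minutes-scale physiology, Michaelis constants by assay-plausible
#: amounts); initial levels are bounded relative to the fasting data.
DEFAULT_KINETIC_BOUNDS = {
    "k2": (1e-2, 1e3),   # pM/min, incretin secretion capacity
    "k3": (1e-4, 1e2),   # 1/min
    "k4": (1e-2, 1e3),   # pM/min
    "k5": (1e-4, 1e2),   # 1/min
    "k6": (1e-2, 1e1),   # g/min, gut absorption capacity
    "k7": (1e-4, 1e2),   # 1/min
    "k8": (1e-2, 1e3),   # hepatic production scale
    "k10": (1e-5, 1e1),  # secretion scale
    "L2": (1e-1, 1e3),   # g
    "L4": (1e-1, 1e3),   # g
    "L6": (1e-1, 1e3),   # g
    "L8": (1e-2, 1e2),   # units of X
    "L11": (1e0, 1e5),   # pM
    "V": (1e-3, 1e1),    # (g/min) -> (mg/dL/min) conversion
    "a": (1e-4, 1e2),
    "b": (1e-4, 1e2),
    "c": (1e-4, 1e2),
    "d": (1e-4, 1e2),
}


@dataclass(frozen=True)
class FitSettings:
    """Search configuration.

    Desk-scale defaults (3 trials of 200 parents x 200 generations) replace
    the cluster-scale 40 x 5000 x 5000 regime, which remains reachable
    through these fields.  Bounds are per-parameter (lower, upper) on the
    natural scale, searched in log space; unspecified kinetic parameters get
    ``default_bounds`` and initial levels get ``init_level_factor`` times
    the fasting measurement (X0, unmeasured, gets generic bounds).
    """

    n_trials: int = 3
    pop_size: int = 200
    n_generations: int = 200
    bounds: dict = field(default_factory=dict)
    default_bounds: tuple[float, float] = (1e-4, 1e4)
    init_level_factor: tuple[float, float] = (0.1, 10.0)
    x0_bounds: tuple[float, float] = (1e-2, 1e2)
    tournament_q: int = 10
    simplex_maxiter: int = 2000
    simplex_fatol: float = 1e-10
    simplex_xatol: float = 1e-7
    polish: str = "least_squares"  # "none" | "least_squares"
    polish_max_nfev: int = 400
    seed: int = 0
    solver: SolverSettings = field(
        default_factory=lambda: SolverSettings(method="rk4", step=0.25, horizon=480.0)
    )

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("trials must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name} must satisfy 0 < lower < upper")


@dataclass(frozen=True)
class FitResult:
    structure: ModelStructure
    free_names: tuple[str, ...]
    best_theta: np.ndarray          # natural scale, ordered as free_names
    best_rss: float
    trial_rss: tuple[float, ...]
    settings: FitSettings

    @property
    def kinetics(self) -> KineticParameters:
        vals = dict(zip(self.free_names, self.best_theta))
        full = {n: vals.get(n, 0.0) for n in KINETIC_NAMES}
        # structurally removed but positivity-validated parameters get
        # placeholder 1s; they are masked out of the dynamics
        if not self.structure.include_glp1:
            full.update(k4=1.0, k5=1.0, L4=1.0)
        return KineticParameters(**full)

    @property
    def initial(self) -> InitialState:
        vals = dict(zip(self.free_names, self.best_theta))
        if not self.structure.include_glp1:
            vals.setdefault("GLP10", 1.0)
        return InitialState(**{n: vals[n] for n in INITIAL_NAMES})

    def subject(self, name: str = "fitted") -> Subject:
        return Subject(structure=self.structure, kinetics=self.kinetics,
                       initial=self.initial, name=name)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.to_dict(),
            "free_names": list(self.free_names),
            "best_theta": [float(v) for v in self.best_theta],
            "best_rss": float(self.best_rss),
            "trial_rss": [float(v) for v in self.trial_rss],
        }


class RssEvaluator:
    """Precompiled normalized-RSS objective for one dataset + structure.

    Builds, per included condition, the ingestion schedule, the union of
    measurement times (which must lie on the integration grid), and the
    per-series min-max denominators, then evaluates candidate parameter
    vectors with the fixed-step compiled integrator.
    """

    def __init__(
        self,
        dataset: ExperimentDataset,
        structure: ModelStructure,
        solver: SolverSettings | None = None,
        species_subset: tuple[str, ...] | None = None,
        protocols=None,
    ):
        from .synth import standard_protocols

        self.structure = structure
        self.solver = solver or SolverSettings(method="rk4", step=0.25, horizon=480.0)
        model_species = ("G", "I", "CP", "GIP") + (("GLP1",) if structure.include_glp1 else ())
        species = [s for s in dataset.species if s in model_species]
        if species_subset is not None:
            species = [s for s in species if s in species_subset]
        self.species = tuple(species)

        proto_by_name = {p.name: p for p in (protocols or standard_protocols())}
        dt = self.solver.step
        self._conditions = []
        n_pts = 0
        for cond in dataset.included_conditions:
            sched = proto_by_name[cond].schedule()
            starts, ends, rates = sched.arrays()
            entries = []
            all_times = []
            for sp in self.species:
                try:
                    t, v = dataset.series(cond, sp)
                except KeyError:
                    continue
                rng = v.max() - v.min()
                if rng <= 0:
                    raise DatasetError(f"degenerate series (max = min): ({cond}, {sp})")
                entries.append((sp, t, v, rng))
                all_times.append(t)
            if not entries:
                continue
            t_union = np.unique(np.concatenate(all_times))
            steps = np.round(t_union / dt)
            if not np.allclose(steps * dt, t_union, rtol=0, atol=1e-9):
                raise ValueError("measurement times must lie on the solver step grid")
            out_steps = steps.astype(np.int64)
            n_steps = int(round(t_union[-1] / dt))
            pos = {tv: i for i, tv in enumerate(t_union)}
            series = []
            for sp, t, v, rng in entries:
                idx = np.array([pos[tv] for tv in t], dtype=np.int64)
                series.append((SPECIES_STATE_INDEX[sp], idx, v, rng))
                n_pts += len(t)
            self._conditions.append((starts, ends, rates, out_steps, n_steps, series))
        if not self._conditions:
            raise DatasetError("dataset has no included, usable series")
        self.n_points = n_pts

        # free-parameter layout
        self.free_names = structure.free_kinetic_names + structure.free_initial_names
        self._nk = len(structure.free_kinetic_names)
        self._kin_idx = np.array(
            [_KIN_INDEX[n] for n in structure.free_kinetic_names], dtype=np.int64
        )
        self._init_idx = np.array(
            [_INIT_INDEX[n] for n in structure.free_initial_names], dtype=np.int64
        )
        self._method = _core.EULER if self.solver.method == "euler" else _core.RK4
        self._fasting = {}
        for sp in self.species:
            try:
                self._fasting[sp] = dataset.fasting_value(sp)
            except KeyError:
                pass

    # -- parameter plumbing --------------------------------------------------

    def assemble(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
        """Free vector (natural scale) -> (padded params, padded y0); None if
        the steady-state closure is out of domain."""
        p = np.zeros(_core.N_PARAMS)
        y0 = np.zeros(_core.N_STATES)
        p[self._kin_idx] = theta[: self._nk]
        y0[self._init_idx] = theta[self._nk:]
        if not self.structure.include_glp1:
            p[_KIN_INDEX["L4"]] = 1.0  # inert placeholder; k4 = k5 = 0 masks it
        gip0, glp10 = y0[1], y0[2]
        g0, i0, cp0, x0 = y0[4], y0[5], y0[6], y0[7]
        if min(gip0, g0, i0, cp0, x0) <= 0:
            return None
        s0 = g0 + p[14] * gip0 + p[15] * g0 * gip0 + p[16] * glp10 + p[17] * g0 * glp10
        if s0 <= 0:
            return None
        p[18] = p[6] / (g0 * x0 * (x0 + p[11]))            # k9
        p[19] = p[7] * (p[12] + i0) / i0 * s0              # k11
        p[20] = p[7] * s0 / cp0                            # k12
        p[21] = i0 / ((i0 + p[12]) * x0)                   # k13
        p[22] = gip0                                        # GIP_B
        p[23] = glp10                                       # GLP1_B
        return p, y0

    def rss(self, theta: np.ndarray) -> float:
        asm = self.assemble(np.asarray(theta, dtype=float))
        if asm is None:
            return _PENALTY_RSS
        p, y0 = asm
        dt = self.solver.step
        total = 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            for starts, ends, rates, out_steps, n_steps, series in self._conditions:
                out, failt = _core.integrate_fixed(
                    y0, p, starts, ends, rates, dt, out_steps, n_steps, self._method, False
                )
                if failt >= 0:
                    return _PENALTY_RSS
                for col, idx, v, rng in series:
                    r = (out[idx, col] - v) / rng
                    total += float(r @ r)
                if not math.isfinite(total) or total > _PENALTY_RSS:
                    return _PENALTY_RSS
        return total

    __call__ = rss

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Normalized residual vector (length n_points); large finite
        entries stand in for failed integrations so least-squares polishing
        stays well-defined."""
        asm = self.assemble(np.asarray(theta, dtype=float))
        res = np.empty(self.n_points)
        if asm is None:
            res.fill(1e6)
            return res
        p, y0 = asm
        dt = self.solver.step
        pos = 0
        for starts, ends, rates, out_steps, n_steps, series in self._conditions:
            out, failt = _core.integrate_fixed(
                y0, p, starts, ends, rates, dt, out_steps, n_steps, self._method, False
            )
            for col, idx, v, rng in series:
                if failt >= 0:
                    res[pos:pos + len(idx)] = 1e6
                else:
                    res[pos:pos + len(idx)] = (out[idx, col] - v) / rng
                pos += len(idx)
        np.nan_to_num(res, copy=False, nan=1e6, posinf=1e6, neginf=-1e6)
        np.clip(res, -1e6, 1e6, out=res)
        return res

    def rss_log(self, x: np.ndarray) -> float:
        return self.rss(np.exp(x))

    # -- bounds ---------------------------------------------------------------

    def log_bounds(self, settings: FitSettings) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(len(self.free_names))
        hi = np.empty(len(self.free_names))
        for j, name in enumerate(self.free_names):
            if name in settings.bounds:
                b = settings.bounds[name]
            elif name == "X0":
                b = settings.x0_bounds
            elif name in INITIAL_NAMES:
                sp = {"GIP0": "GIP", "GLP10": "GLP1", "G0": "G", "I0": "I", "CP0": "CP"}[name]
                base = self._fasting.get(sp)
                if base is not None and base > 0:
                    f0, f1 = settings.init_level_factor
                    b = (f0 * base, f1 * base)
                else:
                    b = settings.default_bounds
            elif name in DEFAULT_KINETIC_BOUNDS:
                b = DEFAULT_KINETIC_BOUNDS[name]
            else:
                b = settings.default_bounds
            lo[j], hi[j] = math.log(b[0]), math.log(b[1])
        return lo, hi

    def data_informed_start(self, settings: FitSettings) -> np.ndarray:
        """Log-vector seeding initial levels at the fasting measurements and
        kinetic parameters at the geometric center of their bounds."""
        lo, hi = self.log_bounds(settings)
        x = 0.5 * (lo + hi)
        for j, name in enumerate(self.free_names):
            if name in INITIAL_NAMES and name != "X0":
                sp = {"GIP0": "GIP", "GLP10": "GLP1", "G0": "G", "I0": "I", "CP0": "CP"}[name]
                base = self._fasting.get(sp)
                if base is not None and base > 0:
                    x[j] = np.clip(math.log(base), lo[j], hi[j])
            elif name == "X0":
                x[j] = 0.0  # X0 = 1: the dimensionless scale choice
        return x


def rss(
    dataset: ExperimentDataset,
    kinetics: KineticParameters,
    initial: InitialState,
    structure: ModelStructure,
    solver: SolverSettings | None = None,
) -> float:
    """One-shot normalized RSS of a fully specified model against a dataset."""
    ev = RssEvaluator(dataset, structure, solver)
    theta = np.array(
        [getattr(kinetics, n) for n in structure.free_kinetic_names]
        + [getattr(initial, n) for n in structure.free_initial_names]
    )
    return ev.rss(theta)


def ep_global_search(
    evaluator: RssEvaluator,
    settings: FitSettings,
    rng: np.random.Generator | None = None,
    n_best: int = 5,
):
    """Classic self-adaptive EP over log-parameters.

    Each parent spawns one child by Gaussian mutation with per-dimension
    self-adaptive step sizes; survivors among the 2N pool are chosen by a
    q-opponent win-count tournament.  Returns (candidates, trace): the
    n_best distinct best (log-vector, rss) pairs and the non-increasing
    best-so-far RSS trace.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    lo, hi = evaluator.log_bounds(settings)
    n_dim = lo.size
    mu = settings.pop_size
    tau = 1.0 / math.sqrt(2.0 * math.sqrt(n_dim))
    tau_p = 1.0 / math.sqrt(2.0 * n_dim)

    pop = rng.uniform(lo, hi, size=(mu, n_dim))
    pop[0] = evaluator.data_informed_start(settings)
    sig = np.full((mu, n_dim), 0.15) * (hi - lo)
    fit_vals = np.array([evaluator.rss_log(x) for x in pop])

    order = np.argsort(fit_vals)
    best_x = pop[order[0]].copy()
    best_f = float(fit_vals[order[0]])
    trace = [best_f]

    for _ in range(settings.n_generations):
        common = rng.normal(size=(mu, 1))
        child_sig = sig * np.exp(tau_p * common + tau * rng.normal(size=(mu, n_dim)))
        np.clip(child_sig, 1e-8, hi - lo, out=child_sig)
        children = pop + child_sig * rng.normal(size=(mu, n_dim))
        np.clip(children, lo, hi, out=children)
        child_fit = np.array([evaluator.rss_log(x) for x in children])

        i_min = int(np.argmin(child_fit))
        if child_fit[i_min] < best_f:
            best_f = float(child_fit[i_min])
            best_x = children[i_min].copy()
        trace.append(best_f)

        # (mu + mu) tournament: count wins against q random opponents
        all_x = np.vstack([pop, children])
        all_sig = np.vstack([sig, child_sig])
        all_fit = np.concatenate([fit_vals, child_fit])
        n_all = 2 * mu
        opp = rng.integers(0, n_all - 1, size=(n_all, settings.tournament_q))
        opp += opp >= np.arange(n_all)[:, None]  # exclude self
        wins = (all_fit[opp] > all_fit[:, None]).sum(axis=1)
        keep = np.lexsort((all_fit, -wins))[:mu]
        pop, sig, fit_vals = all_x[keep], all_sig[keep], all_fit[keep]

    order = np.argsort(fit_vals)
    cands = [(best_x, best_f)]
    for i in order:
        if len(cands) >= n_best:
            break
        if not any(np.array_equal(pop[i], cx) for cx, _ in cands):
            cands.append((pop[i].copy(), float(fit_vals[i])))
    return cands, np.array(trace)


def simplex_refine(
    x_log: np.ndarray,
    evaluator: RssEvaluator,
    settings: FitSettings,
) -> tuple[np.ndarray, float]:
    """Nelder-Mead refinement in log space; never returns a worse RSS.

    Out-of-bounds proposals are evaluated at the clipped point plus a
    quadratic penalty steering the simplex back inside.
    """
    lo, hi = evaluator.log_bounds(settings)
    f0 = evaluator.rss_log(x_log)
    if not math.isfinite(f0):
        raise RuntimeError("non-finite RSS at the refinement start point")

    def obj(x):
        xc = np.clip(x, lo, hi)
        pen = float(np.sum((x - xc) ** 2))
        return evaluator.rss_log(xc) + 1e3 * pen

    res = minimize(
        obj, x_log, method="Nelder-Mead",
        options={
            "maxiter": settings.simplex_maxiter,
            "maxfev": settings.simplex_maxiter,
            "fatol": settings.simplex_fatol,
            "xatol": settings.simplex_xatol,
            "adaptive": True,
        },
    )
    x_ref = np.clip(res.x, lo, hi)
    f_ref = evaluator.rss_log(x_ref)
    if f_ref <= f0:
        return x_ref, float(f_ref)
    return np.asarray(x_log, dtype=float), float(f0)


def polish_least_squares(
    x_log: np.ndarray,
    evaluator: RssEvaluator,
    settings: FitSettings,
    max_nfev: int | None = None,
) -> tuple[np.ndarray, float]:
    """Bounded trust-region least-squares polish on the residual vector,
    in log-parameter space; never returns a worse RSS."""
    lo, hi = evaluator.log_bounds(settings)
    if max_nfev is None:
        max_nfev = settings.polish_max_nfev
    x0 = np.clip(x_log, lo, hi)
    f0 = evaluator.rss_log(x0)
    try:
        res = least_squares(
            lambda x: evaluator.residuals(np.exp(x)),
            x0, bounds=(lo, hi), method="trf",
            x_scale="jac", max_nfev=max_nfev,
        )
        f1 = evaluator.rss_log(res.x)
        if math.isfinite(f1) and f1 < f0:
            return res.x, float(f1)
    except Exception:
        pass
    return x0, float(f0)


def _refine_chain(x_log, ev, settings):
    """simplex refinement, then the optional least-squares polish."""
    x_ref, f_ref = simplex_refine(x_log, ev, settings)
    if settings.polish == "least_squares":
        x_ref, f_ref = polish_least_squares(x_ref, ev, settings)
    return x_ref, f_ref


def fit(
    dataset: ExperimentDataset,
    structure: ModelStructure,
    settings: FitSettings | None = None,
    species_subset: tuple[str, ...] | None = None,
    x_warm: np.ndarray | None = None,
) -> FitResult:
    """Run the configured number of independent EP trials, refine each by
    Nelder-Mead (plus the configured polish), and return the best.
    ``x_warm`` optionally adds one extra refinement started from a given
    log-parameter vector (used by the model-selection warm-start scan)."""
    settings = settings or FitSettings()
    ev = RssEvaluator(dataset, structure, settings.solver, species_subset)
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_trials)
    trial_rss = []
    best_x, best_f = None, math.inf
    for ss in seeds:
        rng = np.random.default_rng(ss)
        cands, _ = ep_global_search(ev, settings, rng)
        x_trial, f_trial = None, math.inf
        for x_cand, _ in cands[:2]:
            x_ref, f_ref = _refine_chain(x_cand, ev, settings)
            if f_ref < f_trial:
                x_trial, f_trial = x_ref, f_ref
        trial_rss.append(f_trial)
        if f_trial < best_f:
            best_x, best_f = x_trial, f_trial
    if x_warm is not None:
        x_ref, f_ref = _refine_chain(np.asarray(x_warm, dtype=float), ev, settings)
        trial_rss.append(f_ref)
        if f_ref < best_f:
            best_x, best_f = x_ref, f_ref
    return FitResult(
        structure=structure,
        free_names=ev.free_names,
        best_theta=np.exp(best_x),
        best_rss=float(best_f),
        trial_rss=tuple(float(v) for v in trial_rss),
        settings=settings,
    )
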