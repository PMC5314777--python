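"""Rate-parameter estimation from abundance-response data.

The kinetic model's rate constants are fitted to (factor, abundance %,
flux %) observations by minimizing a weighted sum of squared residuals,
alternating a Hooke-Jeeves pattern search with global-best particle-swarm
optimization over a fixed 10-stage schedule, each stage warm-started from
the incumbent best.  All searching happens in log10 parameter space, since
rate constants plausibly span decades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .kinetics import RateParameterSet, TotalsConfig, abundance_scan
from .network import ReactionNetwork

#: objective value charged to parameter points where the steady state fails
NONCONVERGENCE_PENALTY = 1e6


@dataclass(frozen=True)
class FitRecord:
    factor: str
    abundance_pct: float
    flux_pct: float
    weight: float = 1.0


@dataclass
class FitDataset:
    records: list[FitRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 3:
            raise ValueError("a fit dataset needs at least 3 records")
        if any(r.abundance_pct <= 0 for r in self.records):
            raise ValueError("abundances must be positive")

    @property
    def factors(self) -> list[str]:
        return sorted({r.factor for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FitDataset":
        return cls([FitRecord(str(r.factor), float(r.abundance_pct),
                              float(r.flux_pct), float(getattr(r, "weight", 1.0)))
                    for r in df.itertuples()])

    @classmethod
    def from_csv(cls, path: str) -> "FitDataset":
        return cls.from_frame(pd.read_csv(path))


class ScanObjective:
    """Weighted SSE between model and observed flux percentages.

    ``free_params`` names the entries of a template
    :class:`RateParameterSet` being optimized (e.g. ``kon_G[A]`` or
    ``k_init``); a candidate log10 vector is grafted onto the template,
    the model's abundance scans are evaluated at the dataset's abundances,
    and squared flux differences are accumulated.  Points where the steady
    state fails to converge are charged a large finite penalty so the
    search can move through bad regions.
    """

    def __init__(self, network: ReactionNetwork, template: RateParameterSet,
                 totals: TotalsConfig, dataset: FitDataset,
                 free_params: Sequence[str], *, coarse: bool = True):
        self.network = network
        self.template = template
        self.totals = totals
        self.dataset = dataset
        self.free_params = list(free_params)
        self.coarse = coarse
        self.n_evaluations = 0

    def params_from_log10(self, x: np.ndarray) -> RateParameterSet:
        d = self.template.to_dict()
        for ref, xv in zip(self.free_params, x):
            val = 10.0 ** float(xv)
            if "[" in ref:
                name, lig = ref[:-1].split("[")
                d[name][lig] = val
            else:
                d[ref] = val
        return RateParameterSet.from_dict(d)

    def x0_log10(self) -> np.ndarray:
        return np.log10([self.template.value(ref) for ref in self.free_params])

    def __call__(self, x: np.ndarray) -> float:
        self.n_evaluations += 1
        params = self.params_from_log10(np.asarray(x, dtype=float))
        total = 0.0
        for factor in self.dataset.factors:
            recs = [r for r in self.dataset.records if r.factor == factor]
            grid = sorted({r.abundance_pct for r in recs})
            try:
                scan = abundance_scan(self.network, params, self.totals, factor, grid,
                                      coarse=self.coarse)
            except (RuntimeError, ValueError):
                return NONCONVERGENCE_PENALTY
            if not scan.converged.all():
                return NONCONVERGENCE_PENALTY
            model = dict(zip(scan.abundance_pct, scan.flux_pct))
            for r in recs:
                total += r.weight * (model[r.abundance_pct] - r.flux_pct) ** 2
        return total


def objective(params: RateParameterSet, dataset: FitDataset,
              model_builder: Callable[[RateParameterSet, str, Sequence[float]], dict]) -> float:
    """Weighted SSE given an arbitrary scan evaluator.

    ``model_builder(params, factor, abundances)`` returns a mapping
    ``abundance_pct -> flux_pct``; non-convergence may be signalled by
    raising, which is charged :data:`NONCONVERGENCE_PENALTY`.
    """
    total = 0.0
    for factor in dataset.factors:
        recs = [r for r in dataset.records if r.factor == factor]
        try:
            model = model_builder(params, factor, sorted({r.abundance_pct for r in recs}))
        except Exception:
            return NONCONVERGENCE_PENALTY
        for r in recs:
            total += r.weight * (model[r.abundance_pct] - r.flux_pct) ** 2
    return total


def hooke_jeeves(f: Callable[[np.ndarray], float], x0, *, step_init: float = 0.5,
                 step_min: float = 1e-4, budget: int = 2000,
                 bounds=None) -> tuple[np.ndarray, float, int]:
    """Classic pattern search: exploratory moves plus pattern acceleration.

    Coordinates are probed at +/- the current step; a successful exploratory
    sweep triggers a pattern move from the previous base point; failures
    halve the step until ``step_min``.  Never returns a point worse than x0.
    """
    if not step_init > step_min > 0:
        raise ValueError("require step_init > step_min > 0")
    x = np.asarray(x0, dtype=float).copy()
    lo, hi = _unpack_bounds(bounds, x.size)

    def clamp(v):
        return np.clip(v, lo, hi)

    evals = 0

    def feval(v):
        nonlocal evals
        evals += 1
        return f(v)

    if budget <= 0:
        return x, np.inf, 0
    fx = feval(x)
    step = step_init
    base, fbase = x.copy(), fx

    def explore(center, fc):
        nonlocal evals
        pt, fpt = center.copy(), fc
        for i in range(pt.size):
            for delta in (step, -step):
                if evals >= budget:
                    return pt, fpt
                trial = pt.copy()
                trial[i] = np.clip(trial[i] + delta, lo[i], hi[i])
                ft = feval(trial)
                if ft < fpt:
                    pt, fpt = trial, ft
                    break
        return pt, fpt

    while evals < budget and step > step_min:
        new, fnew = explore(base, fbase)
        if fnew < fbase:
            # pattern move: double down along the improvement direction
            while evals < budget:
                pattern = clamp(new + (new - base))
                base, fbase = new, fnew
                fpat = feval(pattern)
                cand, fcand = explore(pattern, fpat)
                if fcand < fbase:
                    new, fnew = cand, fcand
                else:
                    break
        else:
            step /= 2.0
    if fbase < fx:
        x, fx = base, fbase
    return x, fx, evals


def particle_swarm(f: Callable[[np.ndarray], float], bounds, *, n_particles: int = 20,
                   iters: int = 50, seed: int = 0, inertia: float = 0.7,
                   cognitive: float = 1.5, social: float = 1.5,
                   x_init=None) -> tuple[np.ndarray, float, int]:
    """Global-best PSO with inertia; positions are clamped to the bounds.

    ``x_init`` optionally seeds one particle (warm start); runs are
    reproducible given the seed.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    lo, hi = _unpack_bounds(bounds, None)
    dim = lo.size
    rng = np.random.default_rng(seed)
    X = lo + (hi - lo) * rng.random((n_particles, dim))
    if x_init is not None:
        X[0] = np.clip(np.asarray(x_init, dtype=float), lo, hi)
    V = 0.1 * (hi - lo) * (rng.random((n_particles, dim)) - 0.5)

    F = np.array([f(x) for x in X])
    pbest, fpbest = X.copy(), F.copy()
    g = int(np.argmin(F))
    gbest, fgbest = X[g].copy(), float(F[g])
    evals = n_particles

    for _ in range(iters):
        r1 = rng.random((n_particles, dim))
        r2 = rng.random((n_particles, dim))
        V = inertia * V + cognitive * r1 * (pbest - X) + social * r2 * (gbest - X)
        X = np.clip(X + V, lo, hi)
        F = np.array([f(x) for x in X])
        evals += n_particles
        better = F < fpbest
        pbest[better], fpbest[better] = X[better], F[better]
        g = int(np.argmin(fpbest))
        if fpbest[g] < fgbest:
            gbest, fgbest = pbest[g].copy(), float(fpbest[g])
    return gbest, fgbest, evals


def _unpack_bounds(bounds, dim):
    if bounds is None:
        if dim is None:
            raise ValueError("bounds required")
        return np.full(dim, -np.inf), np.full(dim, np.inf)
    lo = np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.asarray([b[1] for b in bounds], dtype=float)
    if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("bounds must be finite ordered intervals")
    return lo, hi


@dataclass
class FitConfig:
    """10-stage alternating schedule over log10-parameter space."""

    bounds: list[tuple[float, float]]  # log10 bounds per free parameter
    schedule: tuple[str, ...] = ("hooke_jeeves", "particle_swarm") * 5
    hj_budget: int = 400
    hj_step_init: float = 0.5
    hj_step_min: float = 1e-4
    pso_particles: int = 12
    pso_iters: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.schedule) != 10:
            raise ValueError("the fitting schedule has exactly 10 stages")
        if any(s not in ("hooke_jeeves", "particle_swarm") for s in self.schedule):
            raise ValueError("unknown stage type")
        _unpack_bounds(self.bounds, None)


@dataclass
class FitResult:
    best_x_log10: np.ndarray
    best_params: RateParameterSet | None
    objective: float
    stage_trace: list[dict] = field(default_factory=list)
    evaluations: int = 0

    def to_json(self, path: str, free_params=None) -> None:
        out = {
            "objective": self.objective,
            "best_log10": list(map(float, self.best_x_log10)),
            "stage_trace": self.stage_trace,
            "evaluations": self.evaluations,
        }
        if free_params is not None:
            out["parameters"] = {ref: 10.0 ** float(x)
                                 for ref, x in zip(free_params, self.best_x_log10)}
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)


def alternating_fit(f: Callable[[np.ndarray], float], x0, config: FitConfig,
                    params_from_x: Callable[[np.ndarray], RateParameterSet] | None = None,
                    ) -> FitResult:
    """Run the 10-stage Hooke-Jeeves / particle-swarm alternation.

    Every stage is warm-started from the incumbent best, so the best
    objective is non-increasing across stages.
    """
    x = np.asarray(x0, dtype=float).copy()
    fx = f(x)
    evals = 1
    trace = []
    for stage_no, stage in enumerate(config.schedule, start=1):
        if stage == "hooke_jeeves":
            cand, fcand, used = hooke_jeeves(
                f, x, step_init=config.hj_step_init, step_min=config.hj_step_min,
                budget=config.hj_budget, bounds=config.bounds)
        else:
            cand, fcand, used = particle_swarm(
                f, config.bounds, n_particles=config.pso_particles,
                iters=config.pso_iters, seed=config.seed + stage_no, x_init=x)
        evals += used
        if fcand < fx:
            x, fx = cand, fcand
        trace.append({"stage": stage_no, "method": stage,
                      "best_objective": float(fx), "evaluations": used})
    best_params = params_from_x(x) if params_from_x is not None else None
    return FitResult(x, best_params, float(fx), trace, evals)


def fit_scan_data(network: ReactionNetwork, template: RateParameterSet,
                  totals: TotalsConfig, dataset: FitDataset,
                  free_params: Sequence[str], config: FitConfig) -> FitResult:
    """Convenience wrapper: build the scan objective and run the schedule."""
    obj = ScanObjective(network, template, totals, dataset, free_params)
    return alternating_fit(obj, obj.x0_log10(), config, obj.params_from_log10)
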