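"""Mass-action kinetics of the assembly network.

The enumerated network is compiled into a deterministic mass-action ODE
system over molecule numbers per cell.  The 43S pre-initiation pool and the
free 40S pool are buffered (boundary) species, so the published-size model
has 215 - 2 = 213 time-dependent states.  Peptide output accumulates
linearly once the assembly/initiation subsystem reaches its quasi-steady
state; the translation flux is J = k_elong * [EL] (equivalently
k_init * [full complex] * [43S] at stationarity).

Units: amounts are molecules per cell; unimolecular rate constants are s^-1
and bimolecular constants (molecules/cell)^-1 s^-1.  No volume conversion is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import sparse
from scipy.integrate import solve_ivp

from .network import DEFAULT_LIGANDS, ReactionNetwork, free_monomer, full_complex_label

LIGAND_PARAM_NAMES = ("kon_G", "koff_G", "kon_R", "koff_R", "kc_G", "kc_R", "koff_bridge")


@dataclass(frozen=True)
class RateParameterSet:
    """Per-ligand binding constants plus the two translation-stage constants.

    For each ligand X: ``kon_G[X]``/``koff_G[X]`` and ``kon_R[X]``/``koff_R[X]``
    for forming/breaking the bond to each scaffold (association constants are
    shared between free-ligand binding and bimolecular bridging, both of which
    form the same bond), ``kc_G[X]``/``kc_R[X]`` for the unimolecular
    intramolecular closures, and ``koff_bridge[X]`` for breaking a bond that
    lies inside a closed ring.  With four ligands and no cooperativity this is
    7 * 4 + 2 = 30 distinct parameters.
    """

    kon_G: dict[str, float]
    koff_G: dict[str, float]
    kon_R: dict[str, float]
    koff_R: dict[str, float]
    kc_G: dict[str, float]
    kc_R: dict[str, float]
    koff_bridge: dict[str, float]
    k_init: float
    k_elong: float

    def __post_init__(self) -> None:
        for name in LIGAND_PARAM_NAMES:
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"negative rate constant in {name}")
        if self.k_init < 0 or self.k_elong < 0:
            raise ValueError("negative stage rate constant")

    @property
    def n_parameters(self) -> int:
        return sum(len(getattr(self, n)) for n in LIGAND_PARAM_NAMES) + 2

    def value(self, ref: str) -> float:
        """Resolve a reaction's parameter reference like ``kon_G[A]``."""
        if ref == "k_init":
            return self.k_init
        if ref == "k_elong":
            return self.k_elong
        name, lig = ref[:-1].split("[")
        return getattr(self, name)[lig]

    def to_dict(self) -> dict:
        out = {n: dict(getattr(self, n)) for n in LIGAND_PARAM_NAMES}
        out["k_init"] = self.k_init
        out["k_elong"] = self.k_elong
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameterSet":
        return cls(**{k: (dict(v) if isinstance(v, dict) else float(v)) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path: str) -> "RateParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def symmetric(cls, ligands=DEFAULT_LIGANDS, *, kon=1e-5, koff=1.0,
                  kc=1.0, koff_bridge=1.0, k_init=1e-5, k_elong=2.0) -> "RateParameterSet":
        """All ligands alike -- convenient for toy models and fitting tests."""
        mk = lambda v: {x: v for x in ligands}  # noqa: E731
        return cls(kon_G=mk(kon), koff_G=mk(koff), kon_R=mk(kon), koff_R=mk(koff),
                   kc_G=mk(kc), kc_R=mk(kc), koff_bridge=mk(koff_bridge),
                   k_init=k_init, k_elong=k_elong)


def default_parameters() -> RateParameterSet:
    """Illustrative (non-published) rate constants.

    The study's fitted constants live in supplementary model files that are
    not part of the printed record, so the package ships a default set chosen
    to reproduce the qualitative behaviour the printed results establish: a
    bell-shaped (prozone) flux response to eIF4G abundance peaking near the
    physiological level, and saturating, plateau-like responses to eIF4E and
    eIF4A overexpression.

    Ligands bind eIF4G with Kd = 10^4 molecules/cell and the mRNA directly
    only weakly (Kd = 10^8): partners reach the mRNA predominantly through
    the scaffold, then lock by intramolecular ring closure (effective
    closed/open weight kc/koff_bridge = 10).  The weak direct mRNA binding
    is what keeps partner overexpression from triggering its own prozone.
    """
    base = RateParameterSet.symmetric(
        kon=1e-4, koff=1.0, kc=10.0, koff_bridge=1.0, k_init=5e-6, k_elong=2.0,
    )
    return RateParameterSet.from_dict(
        {**base.to_dict(), "kon_R": {x: 1e-8 for x in DEFAULT_LIGANDS}}
    )


@dataclass(frozen=True)
class TotalsConfig:
    """Total molecule numbers per cell and the buffered (boundary) pools.

    Defaults follow yeast-scale abundances: ~22,000 eIF4G molecules per cell
    at wild type, partner factors of the same order, and ~60,000 translatable
    mRNA 5' ends.
    """

    totals: dict[str, float] = field(default_factory=lambda: {
        "G": 22_000.0, "R": 60_000.0,
        "A": 25_000.0, "E": 22_000.0, "D": 22_000.0, "P": 25_000.0,
    })
    fixed_amounts: dict[str, float] = field(default_factory=lambda: {
        "S43": 10_000.0, "S40": 0.0,
    })

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.totals.values()):
            raise ValueError("negative total")
        if any(v < 0 for v in self.fixed_amounts.values()):
            raise ValueError("negative fixed pool")

    @property
    def fixed_pools(self) -> tuple[str, ...]:
        return tuple(self.fixed_amounts)

    def scaled(self, kind: str, factor: float) -> "TotalsConfig":
        totals = dict(self.totals)
        totals[kind] = totals[kind] * factor
        return replace(self, totals=totals)

    def initial_amounts(self, network: ReactionNetwork) -> np.ndarray:
        """All material free: monomers at their totals, stage pools buffered."""
        x0 = np.zeros(network.n_species)
        for kind, amt in self.totals.items():
            x0[network.species_index(free_monomer(kind).label)] = amt
        if network.has_translation_stage:
            for name, amt in self.fixed_amounts.items():
                x0[network.species_index(name)] = amt
        return x0


class KineticModel:
    """Compiled mass-action ODE system d x/dt = S v(x), v_j = k_j prod x_i."""

    def __init__(self, network: ReactionNetwork, params: RateParameterSet,
                 totals: TotalsConfig):
        self.network = network
        self.params = params
        self.totals = totals

        n_sp = network.n_species
        n_rx = network.n_irreversible
        self.k = np.array([params.value(r.rate_param) for r in network.reactions])
        self.i1 = np.array([network.species_index(r.reactants[0])
                            for r in network.reactions], dtype=np.intp)
        self.i2 = np.array([network.species_index(r.reactants[1])
                            if len(r.reactants) == 2 else -1
                            for r in network.reactions], dtype=np.intp)
        self.bimolecular = self.i2 >= 0

        rows, cols, vals = [], [], []
        for j, r in enumerate(network.reactions):
            for lab in r.reactants:
                rows.append(network.species_index(lab)); cols.append(j); vals.append(-1.0)
            for lab in r.products:
                rows.append(network.species_index(lab)); cols.append(j); vals.append(1.0)
        S = sparse.coo_matrix((vals, (rows, cols)), shape=(n_sp, n_rx)).tocsr()

        self.fixed = np.zeros(n_sp, dtype=bool)
        if network.has_translation_stage:
            for name in totals.fixed_pools:
                self.fixed[network.species_index(name)] = True
        # boundary species have zero net rate
        S = S.tolil()
        S[np.flatnonzero(self.fixed), :] = 0.0
        self.S = S.tocsr()

        self.x0 = totals.initial_amounts(network)
        self.labels = [s.label for s in network.species]
        # composition matrix for conservation checking: kind -> coefficient vector
        self.kinds = ["G", "R"] + list(network.ligands)
        self.comp = np.zeros((len(self.kinds), n_sp))
        for i, sp in enumerate(network.species):
            for tok, n in sp.composition:
                if tok in self.kinds:
                    self.comp[self.kinds.index(tok), i] = n

    # -- core maps ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return self.network.n_species

    @property
    def n_states(self) -> int:
        """Time-dependent state variables (species minus boundary pools)."""
        return self.n_species - int(self.fixed.sum())

    def rates(self, x: np.ndarray) -> np.ndarray:
        v = self.k * x[self.i1]
        v[self.bimolecular] *= x[self.i2[self.bimolecular]]
        return v

    def rhs(self, x: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(x)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        n_rx = len(self.k)
        rows = np.concatenate([np.arange(n_rx), np.flatnonzero(self.bimolecular)])
        cols = np.concatenate([self.i1, self.i2[self.bimolecular]])
        dv1 = self.k.copy()
        dv1[self.bimolecular] *= x[self.i2[self.bimolecular]]
        dv2 = self.k[self.bimolecular] * x[self.i1[self.bimolecular]]
        dV = sparse.coo_matrix((np.concatenate([dv1, dv2]), (rows, cols)),
                               shape=(n_rx, self.n_species)).tocsr()
        return (self.S @ dV).toarray()

    def conserved_totals(self, x: np.ndarray) -> np.ndarray:
        return self.comp @ x

    def flux(self, x: np.ndarray) -> float:
        """Translation flux J = k_elong * [EL], peptides s^-1 cell^-1."""
        return self.params.k_elong * x[self.network.species_index("EL")]

    def flux_via_initiation(self, x: np.ndarray) -> float:
        i_full = self.network.species_index(full_complex_label(self.network.ligands))
        i_s43 = self.network.species_index("S43")
        return self.params.k_init * x[i_full] * x[i_s43]


def build_model(network: ReactionNetwork, params: RateParameterSet,
                totals: TotalsConfig) -> KineticModel:
    """Compile network + parameters + totals into an ODE model.

    Raises ``KeyError`` for a missing parameter reference and ``ValueError``
    for negative totals (via the config's own validation).
    """
    for r in network.reactions:
        params.value(r.rate_param)  # fail fast on missing references
    return KineticModel(network, params, totals)


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray  # (n_times, n_species)
    success: bool
    message: str = ""


def simulate_timecourse(model: KineticModel, t_end: float, *, x0=None,
                        rtol: float = 1e-8, atol: float = 1e-10,
                        n_out: int = 50) -> Trajectory:
    """Stiff integration of the full system; boundary pools stay constant."""
    x0 = model.x0 if x0 is None else np.asarray(x0, dtype=float)
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if t_end == 0:
        return Trajectory(np.array([0.0]), x0[None, :], True)
    sol = solve_ivp(lambda t, x: model.rhs(x), (0.0, t_end), x0, method="BDF",
                    jac=lambda t, x: model.jacobian(x), rtol=rtol, atol=atol,
                    t_eval=np.linspace(0.0, t_end, n_out))
    if not sol.success:
        raise RuntimeError(f"integrator failure: {sol.message}")
    return Trajectory(sol.t, sol.y.T, sol.success, sol.message)


@dataclass
class SteadyStateResult:
    amounts: np.ndarray
    flux: float
    residual_norm: float
    converged: bool
    labels: list[str] = field(default_factory=list, repr=False)

    def amount(self, label: str) -> float:
        return float(self.amounts[self.labels.index(label)])

    def flux_gap(self, model: KineticModel) -> float:
        """Relative gap between k_elong*[EL] and k_init*[full]*[S43]."""
        j1 = model.flux(self.amounts)
        j2 = model.flux_via_initiation(self.amounts)
        if max(j1, j2) == 0:
            return 0.0
        return abs(j1 - j2) / max(j1, j2)


def steady_state(model: KineticModel, *, t_max: float = 1e8,
                 rel_rate_tol: float = 1e-9, newton_tol: float = 1e-10,
                 x0=None, coarse: bool = False) -> SteadyStateResult:
    """Quasi-steady state of the cycling subsystem: integrate, then refine.

    The trajectory is extended in decades until the relative rate of change
    of every non-peptide species falls below ``rel_rate_tol`` per second;
    a damped Newton step then polishes the root.  Because the dynamic
    subsystem conserves the six molecule totals, six residual rows (the free
    monomers) are replaced by the conservation equations, which removes the
    Jacobian's null space.  PEP grows linearly at rate J and is excluded.

    ``coarse`` trades the tight integration phase for a single loose solve
    (the Newton polish restores full accuracy); useful inside fitting loops.
    """
    pep = model.network.species_index("PEP") if model.network.has_translation_stage else -1
    scale = max(max(model.totals.totals.values()), 1.0)

    x = (model.x0 if x0 is None else np.asarray(x0, dtype=float)).copy()
    converged = False
    if coarse:
        traj = simulate_timecourse(model, 1e4, x0=x, n_out=2, rtol=1e-4, atol=1e-6)
        x = traj.x[-1]
    else:
        t_end = 100.0
        while t_end <= t_max:
            traj = simulate_timecourse(model, t_end, x0=x, n_out=2)
            x = traj.x[-1]
            dx = model.rhs(x)
            if pep >= 0:
                dx = dx.copy(); dx[pep] = 0.0
            if np.max(np.abs(dx)) / scale < rel_rate_tol:
                converged = True
                break
            t_end *= 10.0

    # damped Newton refinement with conservation-law row replacement
    free_idx = np.array([model.network.species_index(free_monomer(k).label)
                         for k in model.kinds])
    targets = np.array([model.totals.totals[k] for k in model.kinds])
    solve_mask = ~model.fixed.copy()
    if pep >= 0:
        solve_mask[pep] = False
    sub = np.flatnonzero(solve_mask)
    pos = {int(i): p for p, i in enumerate(sub)}

    def residual(xv: np.ndarray) -> np.ndarray:
        f = model.rhs(xv)[sub]
        for row, (fi, tgt) in enumerate(zip(free_idx, targets)):
            f[pos[int(fi)]] = model.comp[row] @ xv - tgt
        return f

    def res_jac(xv: np.ndarray) -> np.ndarray:
        J = model.jacobian(xv)[np.ix_(sub, sub)]
        for row, fi in enumerate(free_idx):
            J[pos[int(fi)], :] = model.comp[row, sub]
        return J

    for _ in range(50):
        f = residual(x)
        if np.max(np.abs(f)) / scale < newton_tol:
            break
        try:
            step = np.linalg.solve(res_jac(x), -f)
        except np.linalg.LinAlgError:
            break
        lam, f0 = 1.0, np.linalg.norm(f)
        for _ in range(30):
            x_new = x.copy()
            x_new[sub] = x[sub] + lam * step
            if x_new[sub].min() >= -1e-9 * scale and \
                    np.linalg.norm(residual(x_new)) < f0:
                x = np.clip(x_new, 0.0, None)
                break
            lam *= 0.5
        else:
            break

    f = residual(x)
    res_norm = float(np.max(np.abs(f)) / scale)
    converged = converged or res_norm < newton_tol
    return SteadyStateResult(x, model.flux(x), res_norm, converged, list(model.labels))


@dataclass
class ScanResult:
    """Flux response to varying one factor's total abundance."""

    kind: str
    abundance_pct: np.ndarray
    flux_pct: np.ndarray
    flux_abs: np.ndarray
    amounts: np.ndarray  # (n_points, n_species)
    converged: np.ndarray
    labels: list[str] = field(default_factory=list, repr=False)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"factor": self.kind,
                             "abundance_pct": self.abundance_pct,
                             "flux_pct": self.flux_pct})


def abundance_scan(network: ReactionNetwork, params: RateParameterSet,
                   totals: TotalsConfig, kind: str, grid_pct,
                   **ss_kwargs) -> ScanResult:
    """One steady state per grid point, flux normalized to the 100% point.

    The nominal point is inserted if the grid omits it, so the result always
    contains (100%, 100%) by construction.
    """
    grid = np.asarray(sorted(set(np.round(np.asarray(grid_pct, dtype=float), 10))
                             | {100.0}))
    if np.any(grid <= 0):
        raise ValueError("abundance percentages must be positive")
    flux = np.empty_like(grid)
    conv = np.zeros(grid.shape, dtype=bool)
    amounts = np.empty((len(grid), network.n_species))
    for i, pct in enumerate(grid):
        model = build_model(network, params, totals.scaled(kind, pct / 100.0))
        ss = steady_state(model, **ss_kwargs)
        flux[i] = ss.flux
        conv[i] = ss.converged
        amounts[i] = ss.amounts
    nominal = flux[np.argmin(np.abs(grid - 100.0))]
    if nominal <= 0:
        raise RuntimeError("nominal flux is zero; cannot normalize scan")
    return ScanResult(kind, grid, 100.0 * flux / nominal, flux, amounts, conv,
                      [s.label for s in network.species])


def rate_control_coefficient(scan: ScanResult, at_percent: float) -> float:
    """Normalized flux sensitivity d(J/J0) / d(a/a0) at a grid-interior point.

    Central finite differences on the scan grid, linearly interpolated to the
    requested abundance.
    """
    a = scan.abundance_pct / 100.0
    j = scan.flux_pct / 100.0
    p = at_percent / 100.0
    if not (a[0] < p < a[-1]) and not np.isclose(p, a[0]) and not np.isclose(p, a[-1]):
        raise ValueError("at_percent outside the scanned grid")
    slope = np.gradient(j, a)
    return float(np.interp(p, a, slope))


def g_free_complex_burden(scan: ScanResult, network: ReactionNetwork,
                          pct: float) -> float:
    """Summed amount of G-containing complexes lacking mRNA at a grid point.

    Diagnoses the prozone mechanism: excess eIF4G redistributes ligands into
    incomplete, mRNA-free intermediates.
    """
    i = int(np.argmin(np.abs(scan.abundance_pct - pct)))
    mask = np.array([sp.has_G and not sp.has_R and sp.size > 1
                     for sp in network.species])
    return float(scan.amounts[i, mask].sum())
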