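"""Synthetic-data generators for every pipeline stage.

Cytometry events are built from the standard intrinsic/extrinsic noise
decomposition: each cell draws a shared log-normal scale factor (extrinsic -
size, cell cycle, global expression capacity), every fluorescence channel
multiplies it by its own independent intrinsic deviate, and the scatter
signals report the same shared factor through their own measurement noise.
mRNA counts come from a negative binomial (Poisson at the dispersion floor);
abundance-response datasets are kinetic-model scans with multiplicative
noise; competition assays are Poisson colony counts.

Every generator is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import FitDataset, FitRecord
from .kinetics import RateParameterSet, TotalsConfig, abundance_scan
from .network import ReactionNetwork


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean log-normal draws with the requested CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)


@dataclass(frozen=True)
class FlowSimConfig:
    n_events: int = 50_000
    duration: float = 12.0  # s of acquisition
    extrinsic_cv: float = 0.25
    intrinsic_cv: dict[str, float] = field(default_factory=lambda: {"gfp": 0.12})
    channel_mean: dict[str, float] = field(default_factory=lambda: {"gfp": 1_000.0})
    fsc_mean: float = 70_000.0
    ssc_mean: float = 45_000.0
    scatter_noise_cv: float = 0.03  # measurement noise of FSC/SSC around the size factor
    scatter_size_exponent: float = 2.0 / 3.0  # scatter tracks diameter/area, not volume
    debris_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.debris_fraction < 1:
            raise ValueError("debris fraction in [0, 1)")
        if self.extrinsic_cv < 0 or self.scatter_noise_cv < 0 \
                or any(v < 0 for v in self.intrinsic_cv.values()):
            raise ValueError("CVs must be >= 0")
        if set(self.intrinsic_cv) != set(self.channel_mean):
            raise ValueError("intrinsic_cv and channel_mean must name the same channels")


def simulate_events(config: FlowSimConfig) -> pd.DataFrame:
    """Synthetic cytometry event table with columns time,fsc,ssc,<channels>.

    Per cell: extrinsic factor ``s`` (log-normal, unit mean); channel
    intensity = mean * s * (1 + intrinsic normal deviate), clipped at zero;
    FSC/SSC = mean * s**exponent * (1 + scatter noise), the sublinear
    exponent reflecting that scatter reports cell diameter/cross-section
    while expression capacity scales with volume.  Debris events are drawn
    outside the default scatter windows with low fluorescence.  Timestamps
    are uniform over the acquisition and the table is time-sorted.
    """
    rng = np.random.default_rng(config.seed)
    n_debris = int(round(config.n_events * config.debris_fraction))
    n_cells = config.n_events - n_debris

    s = _lognormal_factor(rng, config.extrinsic_cv, n_cells)
    cols: dict[str, np.ndarray] = {}
    for ch, mean in config.channel_mean.items():
        eps = rng.standard_normal(n_cells) * config.intrinsic_cv[ch]
        cols[ch] = np.clip(mean * s * (1.0 + eps), 0.0, None)
    s_scatter = s ** config.scatter_size_exponent
    fsc = np.clip(config.fsc_mean * s_scatter
                  * (1.0 + rng.standard_normal(n_cells) * config.scatter_noise_cv), 0.0, None)
    ssc = np.clip(config.ssc_mean * s_scatter
                  * (1.0 + rng.standard_normal(n_cells) * config.scatter_noise_cv), 0.0, None)

    if n_debris:
        # rejection-sample scatter positions outside the standard windows
        df, ds = [], []
        while len(df) < n_debris:
            cf = rng.uniform(0, 150_000, n_debris)
            cs = rng.uniform(0, 150_000, n_debris)
            outside = ~((cf >= 40_000) & (cf <= 100_000) & (cs >= 10_000) & (cs <= 90_000))
            df.extend(cf[outside]); ds.extend(cs[outside])
        fsc = np.concatenate([fsc, df[:n_debris]])
        ssc = np.concatenate([ssc, ds[:n_debris]])
        for ch, mean in config.channel_mean.items():
            cols[ch] = np.concatenate([cols[ch],
                                       rng.uniform(0, 0.1 * mean, n_debris)])

    table = pd.DataFrame({"time": rng.uniform(0, config.duration, config.n_events),
                          "fsc": fsc, "ssc": ssc, **cols})
    return table.sort_values("time").reset_index(drop=True)


@dataclass(frozen=True)
class CountSimConfig:
    mean: float
    cv: float
    n: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.cv < 0 or self.n < 2:
            raise ValueError("invalid CV or sample size")


def simulate_mrna_counts(config: CountSimConfig) -> np.ndarray:
    """Overdispersed per-cell mRNA counts with the requested mean and CV.

    Negative binomial in (mean, CV) parameterization; exactly Poisson at the
    dispersion floor CV^2 = 1/mean.  Sub-Poisson targets are infeasible for
    this family and raise.
    """
    rng = np.random.default_rng(config.seed)
    m, c = config.mean, config.cv
    var = (c * m) ** 2
    floor = 1.0 / m
    if c * c < floor * (1 - 1e-9):
        raise ValueError(
            f"infeasible target: CV^2 = {c*c:.4g} below the Poisson floor 1/mean = {floor:.4g}")
    if abs(c * c - floor) <= 1e-9 * floor:
        return rng.poisson(m, config.n)
    r = m * m / (var - m)  # NB size parameter
    p = r / (r + m)
    return rng.negative_binomial(r, p, config.n)


@dataclass(frozen=True)
class ScanSimConfig:
    params: RateParameterSet
    totals: TotalsConfig
    factor: str = "G"
    grid_pct: tuple[float, ...] = (20.0, 50.0, 100.0, 200.0, 500.0)
    noise_cv: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.replicates < 1:
            raise ValueError("invalid noise CV or replicate count")


def simulate_scan_dataset(network: ReactionNetwork, config: ScanSimConfig) -> FitDataset:
    """Model fluxes at the grid abundances, degraded by multiplicative noise."""
    rng = np.random.default_rng(config.seed)
    scan = abundance_scan(network, config.params, config.totals,
                          config.factor, config.grid_pct)
    records = []
    for _ in range(config.replicates):
        noise = _lognormal_factor(rng, config.noise_cv, len(scan.abundance_pct))
        for a, f, z in zip(scan.abundance_pct, scan.flux_pct, noise):
            records.append(FitRecord(config.factor, float(a), float(f * z)))
    return FitDataset(records)


def simulate_competition(true_fitness_ratio: float, n_colonies: int,
                         seed: int = 0):
    """Poisson colony counts for a 1:1 mixed culture grown to a final
    tested:competitor ratio of ``true_fitness_ratio``.

    ``n_colonies`` is the expected count per plate at t0; the t98 plates
    split the same expectation by the final population fractions, so the
    competition-fraction estimator is unbiased within counting error.
    """
    from .stats import CompetitionCounts

    if true_fitness_ratio <= 0:
        raise ValueError("fitness ratio must be positive")
    if n_colonies <= 0:
        raise ValueError("need a positive expected colony count")
    rng = np.random.default_rng(seed)
    frac = true_fitness_ratio / (1.0 + true_fitness_ratio)
    draw = lambda lam: max(1, int(rng.poisson(lam)))  # noqa: E731
    return CompetitionCounts(
        tested_t0=draw(n_colonies / 2),
        tested_t98=draw(n_colonies * frac),
        competitor_t0=draw(n_colonies / 2),
        competitor_t98=draw(n_colonies * (1.0 - frac)),
    )
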