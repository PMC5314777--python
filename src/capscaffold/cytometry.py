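"""Flow-cytometry gene-expression noise pipeline.

Event tables (time, FSC, SSC, one or two fluorescence channels) flow through
time trimming, scatter-window gating, location of the highest-density centre
of the FSC-SSC scatterplot, and radial gating around that centre.  Shrinking
the gate radius removes cell-size/cycle (extrinsic) heterogeneity, so the CV
of the fluorescence channel approaches the intrinsic noise floor; the
dual-reporter statistic Noise^2 = <(G - M)^2> / (2 <G> <M>) estimates the
same uncorrelated component from two-colour data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("time", "fsc", "ssc", "gfp")


def _check_events(events: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks columns: {missing}")


@dataclass(frozen=True)
class GateConfig:
    """Gating thresholds; defaults follow the standard acquisition protocol."""

    head_trim: float = 1.0  # s removed at the start of acquisition
    tail_trim: float = 0.2  # s removed at the end
    fsc_window: tuple[float, float] = (40_000.0, 100_000.0)
    ssc_window: tuple[float, float] = (10_000.0, 90_000.0)
    density_bin_width: float = 2_500.0  # a.u., FSC-SSC histogram bin
    radii: tuple[float, ...] = tuple(np.geomspace(1_000.0, 30_000.0, 15))
    min_gate_events: int = 200
    plateau_n_radii: int = 3
    plateau_stability_tol: float = 0.15  # max relative spread across plateau radii

    def __post_init__(self) -> None:
        if self.head_trim < 0 or self.tail_trim < 0:
            raise ValueError("trims must be >= 0")
        for lo, hi in (self.fsc_window, self.ssc_window):
            if not lo < hi:
                raise ValueError("scatter windows must be ordered")


def trim_time(events: pd.DataFrame, head: float = 1.0, tail: float = 0.2) -> pd.DataFrame:
    """Drop the unstable-flow portions: keep time in (t_min + head, t_max - tail]."""
    _check_events(events)
    t = events["time"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValueError("events must be time-sorted")
    if len(t) == 0:
        raise ValueError("empty event table")
    # half-open at the head so the unstable first seconds are excluded, but
    # zero trims are the identity
    head_ok = (t >= t[0]) if head == 0 else (t > t[0] + head)
    kept = events[head_ok & (t <= t[-1] - tail)]
    if kept.empty:
        raise ValueError("empty after trim")
    return kept.reset_index(drop=True)


def scatter_gate(events: pd.DataFrame, config: GateConfig | None = None) -> pd.DataFrame:
    """Keep events inside the closed FSC and SSC windows."""
    config = config or GateConfig()
    _check_events(events)
    f_lo, f_hi = config.fsc_window
    s_lo, s_hi = config.ssc_window
    kept = events[events["fsc"].between(f_lo, f_hi) & events["ssc"].between(s_lo, s_hi)]
    if kept.empty:
        raise ValueError("empty after scatter gating")
    return kept.reset_index(drop=True)


def density_centre(events: pd.DataFrame, bin_width: float = 2_500.0) -> tuple[float, float]:
    """Centre of the modal bin of the 2-D FSC-SSC histogram.

    Ties are broken by the larger 3x3-smoothed neighbourhood mass, then by
    lowest bin indices, so the result is deterministic.
    """
    _check_events(events)
    if len(events) < 100:
        raise ValueError("need at least 100 events to locate the density centre")
    fsc = events["fsc"].to_numpy()
    ssc = events["ssc"].to_numpy()
    fbins = np.arange(fsc.min(), fsc.max() + bin_width, bin_width)
    sbins = np.arange(ssc.min(), ssc.max() + bin_width, bin_width)
    if len(fbins) < 2:
        fbins = np.array([fsc.min(), fsc.min() + bin_width])
    if len(sbins) < 2:
        sbins = np.array([ssc.min(), ssc.min() + bin_width])
    H, fe, se = np.histogram2d(fsc, ssc, bins=(fbins, sbins))
    peak = H.max()
    candidates = np.argwhere(H == peak)
    if len(candidates) > 1:
        padded = np.pad(H, 1)
        mass = [padded[i:i + 3, j:j + 3].sum() for i, j in candidates]
        order = np.lexsort((candidates[:, 1], candidates[:, 0], -np.asarray(mass)))
        candidates = candidates[order]
    i, j = candidates[0]
    return (float((fe[i] + fe[i + 1]) / 2), float((se[j] + se[j + 1]) / 2))


def radial_gate(events: pd.DataFrame, centre: tuple[float, float],
                radius: float) -> pd.DataFrame:
    """Keep events within Euclidean FSC-SSC distance <= radius of the centre."""
    _check_events(events)
    d = np.hypot(events["fsc"].to_numpy() - centre[0],
                 events["ssc"].to_numpy() - centre[1])
    kept = events[d <= radius]
    if kept.empty:
        raise ValueError("empty after radial gating")
    return kept.reset_index(drop=True)


def cv(values) -> float:
    """Coefficient of variation sigma/mu with the sample (n-1) deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mu = v.mean()
    if mu <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / mu)


def cv_vs_radius(events: pd.DataFrame, centre: tuple[float, float], radii,
                 channel: str = "gfp", min_events: int = 200) -> pd.DataFrame:
    """CV of ``channel`` within each gate radius.

    Radii retaining fewer than ``min_events`` events are inadmissible and get
    NaN.  Raises if no radius is admissible.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must increase")
    d = np.hypot(events["fsc"].to_numpy() - centre[0],
                 events["ssc"].to_numpy() - centre[1])
    x = events[channel].to_numpy()
    rows = []
    for r in radii:
        sel = x[d <= r]
        rows.append({"radius": r, "n": sel.size,
                     "cv": cv(sel) if sel.size >= min_events else np.nan})
    curve = pd.DataFrame(rows)
    if curve["cv"].isna().all():
        raise ValueError("insufficient events at every radius")
    return curve


def plateau_cv(curve: pd.DataFrame, n_radii: int = 3,
               stability_tol: float = 0.15) -> tuple[float, bool]:
    """Estimate of the minimum ("intrinsic") CV from the gate-radius curve.

    Mean CV over the ``n_radii`` smallest admissible radii; the boolean flags
    whether their relative spread stays within ``stability_tol`` (an unstable
    plateau signals under-sampled small gates).
    """
    ok = curve.dropna(subset=["cv"]).sort_values("radius").head(n_radii)
    if ok.empty:
        raise ValueError("no admissible radii")
    values = ok["cv"].to_numpy()
    centre = values.mean()
    stable = bool(np.all(np.abs(values - centre) <= stability_tol * centre))
    return float(centre), stable


def dual_reporter_noise(gfp, mcherry, normalize: bool = True) -> float:
    """Intrinsic-noise statistic Noise^2 = <(G - M)^2> / (2 <G> <M>).

    With ``normalize`` on (the default) the two channels are first scaled to
    a common mean, appropriate when the reporters have different absolute
    brightness; the statistic is then invariant to common rescaling and
    symmetric in its arguments.  The square root is the CV-like value used
    for reporting.
    """
    g = np.asarray(gfp, dtype=float)
    m = np.asarray(mcherry, dtype=float)
    if g.shape != m.shape or g.size < 2:
        raise ValueError("channels must be paired, length >= 2")
    if g.mean() <= 0 or m.mean() <= 0:
        raise ValueError("channel means must be positive")
    if normalize:
        g = g / g.mean()
        m = m / m.mean()
    return float(np.mean((g - m) ** 2) / (2.0 * g.mean() * m.mean()))


@dataclass
class NoiseSummary:
    """Per-stage event counts plus the CV decomposition of one sample."""

    n_events: dict[str, int]
    channel_mean: float
    channel_sd: float
    total_cv: float
    cv_curve: pd.DataFrame
    plateau_cv: float
    plateau_stable: bool
    centre: tuple[float, float]
    dual_reporter_noise2: float | None = None

    @property
    def dual_reporter_cv(self) -> float | None:
        if self.dual_reporter_noise2 is None:
            return None
        return float(np.sqrt(self.dual_reporter_noise2))

    def to_dict(self) -> dict:
        out = {
            "n_events": self.n_events,
            "channel_mean": self.channel_mean,
            "channel_sd": self.channel_sd,
            "total_cv": self.total_cv,
            "plateau_cv": self.plateau_cv,
            "plateau_stable": self.plateau_stable,
            "centre": list(self.centre),
            "cv_curve": self.cv_curve.to_dict(orient="list"),
        }
        if self.dual_reporter_noise2 is not None:
            out["dual_reporter_noise2"] = self.dual_reporter_noise2
            out["dual_reporter_cv"] = self.dual_reporter_cv
        return out


def noise_pipeline(events: pd.DataFrame, config: GateConfig | None = None,
                   channel: str = "gfp") -> NoiseSummary:
    """Full pipeline: trim -> scatter gate -> density centre -> radial CV curve.

    A pure function of (events, config): identical inputs give identical
    outputs.
    """
    config = config or GateConfig()
    counts = {"raw": len(events)}
    events = trim_time(events, config.head_trim, config.tail_trim)
    counts["after_trim"] = len(events)
    events = scatter_gate(events, config)
    counts["after_scatter_gate"] = len(events)
    centre = density_centre(events, config.density_bin_width)
    total = cv(events[channel])
    curve = cv_vs_radius(events, centre, config.radii, channel=channel,
                         min_events=config.min_gate_events)
    plateau, stable = plateau_cv(curve, config.plateau_n_radii,
                                 config.plateau_stability_tol)
    noise2 = None
    if "mcherry" in events.columns:
        noise2 = dual_reporter_noise(events[channel], events["mcherry"])
    return NoiseSummary(counts, float(events[channel].mean()),
                        float(events[channel].std(ddof=1)), total, curve,
                        plateau, stable, centre, noise2)
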