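"""The tri-phase fit: thermal rate, RGRa, phase bins, breakpoints.

Leaf elongation in grasses under progressive soil drying shows three
phases.  While water is plentiful the hourly elongation rate (LER) is set
by meristem temperature alone, LER = a*T, with *a* the genotype's thermal
growth rate.  As the soil matric potential Psi (log10 hPa) rises past a
genotype-specific point the thermally corrected rate RGRa = LER/(a*T)
declines linearly with Psi, and past a second point growth arrests
(RGRa ~ 0).  The fit proceeds in five stages:

1. *a* from the first 24 h (through-origin least squares of LER on T),
   assuming water is non-limiting there;
2. RGRa = LER/(a*T) for every hour;
3. mean RGRa per quarter-log10-hPa bin of Psi, each bin labelled
   normal (> 0.9), arrest (< 0.2) or slow (between, inclusive), with a
   one-step rebound rule: a bin dipping to <= 0.9 whose next non-empty bin
   recovers above 0.9 stays normal;
4. ordinary least squares RGRa = i + c*Psi on the hours in slow bins plus
   the highest-Psi normal bin (retained to anchor the upper breakpoint);
5. the breakpoints: growth slows where the line crosses RGRa = 1
   (sigma_upper = (1 - i)/c) and arrests where it crosses 0
   (sigma_lower = -i/c).

Hours after re-watering never enter any stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
    InsufficientSpreadError,
    NonDecreasingResponseError,
)

__all__ = [
    "FitConfig",
    "ThermalFit",
    "PsiBin",
    "SlowPhaseFit",
    "TriPhaseResult",
    "fit_thermal_rate",
    "relative_growth",
    "classify_bins",
    "select_slow_subset",
    "fit_slow_phase",
    "breakpoints",
    "fit_triphase",
    "results_to_csv",
]

BIN_WIDTH = 0.25


@dataclass(frozen=True)
class FitConfig:
    """Tunable constants of the procedure (defaults follow the method as
    published: 24 h thermal window, 0.9/0.2 thresholds, quarter bins)."""

    thermal_window_h: float = 24.0
    normal_threshold: float = 0.9
    arrest_threshold: float = 0.2
    bin_width: float = BIN_WIDTH
    retain_last_normal_bin: bool = True
    response_variable: str = "rgra"  # or "ler" for the raw-rate variant

    def __post_init__(self) -> None:
        if not 0 < self.arrest_threshold < self.normal_threshold < 1:
            raise DomainError(
                "thresholds must satisfy 0 < arrest < normal < 1, got "
                f"{self.arrest_threshold}, {self.normal_threshold}"
            )
        if self.bin_width <= 0:
            raise DomainError("bin width must be positive")


@dataclass(frozen=True)
class ThermalFit:
    """Through-origin slope of LER on meristem temperature."""

    a: float                # mm h-1 degC-1
    window_h: float
    r_squared: float
    n_points: int

    @property
    def a_um(self) -> float:
        """The slope in um per degC per hour, the conventional reporting unit."""
        return self.a * 1000.0


@dataclass(frozen=True)
class PsiBin:
    """One quarter-interval of log10 Psi with its mean RGRa and phase label."""

    lo: float
    hi: float
    mean_rgra: float        # NaN when empty
    n_points: int
    phase: str              # normal | slow | arrest | empty


@dataclass(frozen=True)
class SlowPhaseFit:
    """The slow-phase line RGRa = i + c*Psi."""

    i: float
    c: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class TriPhaseResult:
    """Everything the fit produced for one tiller, intermediates included.

    ``slow`` is None (and the sigmas NaN) for a tiller that never left the
    normal phase — a well-watered control; ``phase_summary`` then says
    "normal throughout".
    """

    tiller_id: str
    thermal: ThermalFit
    slow: SlowPhaseFit | None
    sigma_upper: float      # log10 hPa, growth-slow point
    sigma_lower: float      # log10 hPa, growth-arrest point
    bins: list[PsiBin] = field(default_factory=list)
    n_hours: int = 0
    phase_summary: str = ""
    extrapolated: bool = False  # sigma estimates outside the observed Psi range

    @property
    def responded(self) -> bool:
        return self.slow is not None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=float)

    def to_row(self) -> dict:
        """Flat record for the per-tiller results CSV."""
        return {
            "tiller_id": self.tiller_id,
            "a_um": self.thermal.a_um,
            "i": self.slow.i if self.slow else np.nan,
            "c": self.slow.c if self.slow else np.nan,
            "sigma_upper": self.sigma_upper,
            "sigma_lower": self.sigma_lower,
            "r2_thermal": self.thermal.r_squared,
            "r2_slow": self.slow.r_squared if self.slow else np.nan,
            "n_hours": self.n_hours,
        }


def results_to_csv(results: list[TriPhaseResult], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame([r.to_row() for r in results])
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# stage 1: thermal rate


def fit_thermal_rate(series: pd.DataFrame, window_h: float = 24.0) -> ThermalFit:
    """Least squares of LER on T through the origin over the first
    ``window_h`` hours: a = sum(T*LER)/sum(T^2).

    The through-origin form encodes the biological boundary condition that
    elongation stops at 0 degC.  Water is assumed non-limiting inside the
    window, so the window must not extend past the onset of stress.
    """
    win = series[(series["hour"] < window_h) & ~series["after_rewatering"]]
    win = win.dropna(subset=["ler_mm_h", "temp_c"])
    t = win["temp_c"].to_numpy(dtype=float)
    y = win["ler_mm_h"].to_numpy(dtype=float)
    mask = t > 0
    t, y = t[mask], y[mask]
    if len(t) < 3:
        raise InsufficientDataError(
            f"thermal fit needs >= 3 hours with T > 0 in the first {window_h} h, got {len(t)}"
        )
    denom = float(np.sum(t * t))
    if denom == 0.0:
        raise DegenerateFitError("all temperatures are zero; slope undefined")
    a = float(np.sum(t * y)) / denom
    resid = y - a * t
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum(y**2))  # uncentred: the model has no intercept
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ThermalFit(a=a, window_h=window_h, r_squared=max(r2, 0.0), n_points=len(t))


# ---------------------------------------------------------------------------
# stage 2: relative growth


def relative_growth(series: pd.DataFrame, fit: ThermalFit) -> pd.DataFrame:
    """Attach rgra = LER/(a*T) to every hour (NaN where T <= 0)."""
    if fit.a <= 0:
        raise DomainError(f"thermal rate must be positive, got {fit.a}")
    out = series.copy()
    t = out["temp_c"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rgra = out["ler_mm_h"].to_numpy(dtype=float) / (fit.a * t)
    rgra[t <= 0] = np.nan
    out["rgra"] = rgra
    return out


# ---------------------------------------------------------------------------
# stage 3: quarter-bin classification


def classify_bins(series: pd.DataFrame, config: FitConfig = FitConfig()) -> list[PsiBin]:
    """Mean RGRa per quarter-log10-hPa bin of Psi, labelled by phase.

    Bins sit on absolute quarter boundaries (…, 2.00–2.25, 2.25–2.50, …)
    spanning the observed pre-rewatering Psi range.  Labels: normal if the
    bin mean exceeds ``normal_threshold``, arrest if below
    ``arrest_threshold``, slow otherwise (boundary values are slow).  The
    rebound rule then rescues single dips: a non-normal, non-arrest bin
    whose next non-empty bin is normal is relabelled normal.
    """
    df = series[~series["after_rewatering"]].dropna(subset=["rgra", "psi_log10"])
    if df.empty:
        raise InsufficientDataError("no usable hours with rgra and psi")
    w = config.bin_width
    psi = df["psi_log10"].to_numpy(dtype=float)
    rgra = df["rgra"].to_numpy(dtype=float)
    lo0 = np.floor(psi.min() / w) * w
    hi0 = np.floor(psi.max() / w) * w
    edges_lo = np.round(np.arange(lo0, hi0 + w / 2, w), 10)
    bins: list[PsiBin] = []
    for lo in edges_lo:
        hi = round(lo + w, 10)
        sel = (psi >= lo) & (psi < hi)
        n = int(sel.sum())
        if n == 0:
            bins.append(PsiBin(lo=lo, hi=hi, mean_rgra=float("nan"), n_points=0, phase="empty"))
            continue
        m = float(rgra[sel].mean())
        if m > config.normal_threshold:
            phase = "normal"
        elif m < config.arrest_threshold:
            phase = "arrest"
        else:
            phase = "slow"
        bins.append(PsiBin(lo=lo, hi=hi, mean_rgra=m, n_points=n, phase=phase))
    # rebound rule: a slow dip followed (next non-empty bin) by normal stays normal
    occupied = [k for k, b in enumerate(bins) if b.phase != "empty"]
    for pos, k in enumerate(occupied[:-1]):
        nxt = occupied[pos + 1]
        if bins[k].phase == "slow" and bins[nxt].phase == "normal":
            bins[k] = dataclasses.replace(bins[k], phase="normal")
    return bins


# ---------------------------------------------------------------------------
# stage 4: slow-phase subset and regression


def select_slow_subset(
    series: pd.DataFrame,
    bins: list[PsiBin],
    config: FitConfig = FitConfig(),
) -> pd.DataFrame | None:
    """Hourly points for the slow-phase regression, or None when the tiller
    never slowed (a control: phase normal throughout).

    Selected: every hour in a slow bin, plus (by default) every hour of the
    highest-Psi normal bin, which anchors the upper end of the line and
    stabilises the growth-slow estimate.  Arrest is terminal: hours in the
    first arrest bin and everything drier are excluded even if a later bin
    mean drifts back above the arrest threshold.
    """
    slow_bins = [b for b in bins if b.phase == "slow"]
    if not slow_bins:
        return None
    df = series[~series["after_rewatering"]].dropna(subset=["rgra", "psi_log10"])
    psi = df["psi_log10"].to_numpy(dtype=float)
    keep = np.zeros(len(df), dtype=bool)
    arrest_lo = min((b.lo for b in bins if b.phase == "arrest"), default=np.inf)
    for b in bins:
        if b.lo >= arrest_lo:
            continue
        if b.phase == "slow":
            keep |= (psi >= b.lo) & (psi < b.hi)
    if config.retain_last_normal_bin:
        normal = [b for b in bins if b.phase == "normal" and b.lo < arrest_lo]
        if normal:
            top = max(normal, key=lambda b: b.lo)
            keep |= (psi >= top.lo) & (psi < top.hi)
    return df.loc[keep]


def fit_slow_phase(points: pd.DataFrame, config: FitConfig = FitConfig()) -> SlowPhaseFit:
    """Ordinary least squares of the response on Psi with free intercept.

    The response is RGRa (the thermally corrected rate) by default; setting
    ``response_variable='ler'`` reproduces the raw-rate variant for
    comparison.  The slope must come out negative — growth declining with
    drying — or the tri-phase model does not apply.
    """
    ycol = "rgra" if config.response_variable == "rgra" else "ler_mm_h"
    x = points["psi_log10"].to_numpy(dtype=float)
    y = points[ycol].to_numpy(dtype=float)
    if len(x) < 3:
        raise InsufficientDataError(f"slow-phase fit needs >= 3 points, got {len(x)}")
    if x.max() - x.min() < BIN_WIDTH:
        raise InsufficientSpreadError(
            f"slow-phase points span only {x.max() - x.min():.3f} log10 hPa "
            f"(need >= {BIN_WIDTH})"
        )
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    c = float(np.sum((x - xm) * (y - ym))) / sxx
    i = ym - c * xm
    if c >= 0:
        raise NonDecreasingResponseError(
            f"slow-phase slope is {c:.4g} >= 0; growth does not decline with drying"
        )
    resid = y - (i + c * x)
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return SlowPhaseFit(i=i, c=c, r_squared=r2, n_points=len(x))


# ---------------------------------------------------------------------------
# stage 5: breakpoints


def breakpoints(fit: SlowPhaseFit) -> tuple[float, float]:
    """(sigma_upper, sigma_lower): where the slow-phase line crosses
    RGRa = 1 and RGRa = 0.

    sigma_upper = (1 - i)/c, sigma_lower = -i/c; since c < 0 the identity
    sigma_lower - sigma_upper = -1/c > 0 guarantees the ordering.
    """
    if fit.c >= 0:
        raise DomainError(f"breakpoints need a negative slope, got c = {fit.c}")
    sigma_upper = (1.0 - fit.i) / fit.c
    sigma_lower = -fit.i / fit.c
    return sigma_upper, sigma_lower


# ---------------------------------------------------------------------------
# the composed fit


def fit_triphase(
    series: pd.DataFrame,
    config: FitConfig = FitConfig(),
    *,
    tiller_id: str | None = None,
) -> TriPhaseResult:
    """Run the five stages on one tiller's hourly series.

    Hours flagged ``after_rewatering`` are excluded from every stage.  A
    series that never leaves the normal phase (a well-watered control)
    yields a ThermalFit with ``phase_summary='normal throughout'`` and NaN
    breakpoints — a result, not an error.
    """
    tid = tiller_id or series.attrs.get("tiller_id", "tiller")
    pre = series[~series["after_rewatering"]]
    thermal = fit_thermal_rate(series, window_h=config.thermal_window_h)
    with_rgra = relative_growth(series, thermal)
    bins = classify_bins(with_rgra, config)
    subset = select_slow_subset(with_rgra, bins, config)
    n_hours = int(pre["ler_mm_h"].notna().sum())
    if subset is None:
        return TriPhaseResult(
            tiller_id=tid,
            thermal=thermal,
            slow=None,
            sigma_upper=float("nan"),
            sigma_lower=float("nan"),
            bins=bins,
            n_hours=n_hours,
            phase_summary="normal throughout",
        )
    slow = fit_slow_phase(subset, config)
    s_up, s_lo = breakpoints(slow)
    psi_obs = pre["psi_log10"].dropna()
    extrapolated = bool(
        s_up < psi_obs.min() or s_lo > psi_obs.max()
    ) if len(psi_obs) else True
    phases = [b.phase for b in bins if b.phase != "empty"]
    return TriPhaseResult(
        tiller_id=tid,
        thermal=thermal,
        slow=slow,
        sigma_upper=s_up,
        sigma_lower=s_lo,
        bins=bins,
        n_hours=n_hours,
        phase_summary="/".join(dict.fromkeys(phases)),
        extrapolated=extrapolated,
    )
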