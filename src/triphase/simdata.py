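"""Synthetic leaf-growth phenotyping experiments with known ground truth.

The generator emulates a growth-cabinet water-deprivation experiment on
clonal grass tillers: a square-wave day/night temperature regime (16/8 h,
25/15 °C), soil that dries toward a matric-potential plateau near
4.3 log10 hPa, and leaf elongation that follows the tri-phase response

    LER(t) = a * T(t) * g(psi(t)),

where g is 1 below the growth-slow point (sigma_upper), falls linearly to 0
at the growth-arrest point (sigma_lower), and stays 0 beyond.  Because the
generative model is exactly the model the fitter assumes, fitting simulated
data is a parameter-recovery experiment: the recovered a, sigma_upper and
sigma_lower can be compared against the configured truth.

All randomness is driven by ``SimConfig.seed``; identical configurations
produce bit-identical traces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidConfigError

__all__ = [
    "SimConfig",
    "GrowthTrace",
    "MeristemTempTrace",
    "SoilMoistureTrace",
    "simulate_temperature",
    "simulate_soil_drying",
    "simulate_growth",
    "simulate_experiment",
    "write_experiment",
    "noise_sd_for_fraction",
]

TEMP_PHYSICAL_RANGE = (0.0, 45.0)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters and sampling layout of a synthetic experiment.

    Defaults reproduce the reference water-deprivation setup: 16/8 h
    photoperiod at 25/15 °C day/night, drying from ~63 hPa (1.8 log10) to a
    plateau of ~4.3 log10 hPa, 130 h of water deprivation followed by
    re-watering and 35 h of continued tracking, and seven clonal replicates.
    The truth values default to the reference experiment's cohort means:
    a = 52.9 um per degree-hour, growth slows at 2.70 and arrests at
    3.83 log10 hPa.
    """

    a_true: float = 0.0529          # mm h-1 degC-1
    sigma_upper_true: float = 2.70  # log10 hPa, growth starts slowing
    sigma_lower_true: float = 3.83  # log10 hPa, growth arrests
    psi_start: float = 1.8          # log10 hPa at experiment start
    psi_plateau: float = 4.3        # log10 hPa asymptote of drying
    psi_timescale: float = 60.0     # h, characteristic time of log10 psi rise
    psi_shape_k: float = 3.0        # Weibull shape; 1 = pure exponential rise
    duration: float = 165.0         # h total tracked
    rewater_time: float | None = 130.0  # h, None = never re-watered
    photoperiod_day: float = 16.0   # h of light per 24 h cycle
    temp_day: float = 25.0          # degC
    temp_night: float = 15.0        # degC
    temp_lag: float = 0.0           # h, first-order meristem thermal lag
    noise_sd_ler: float = 0.3       # mm h-1 sd on the instantaneous rate
    no_shrink: bool = False         # truncate noise so length never decreases
    growth_cadence: float = 2.0     # min between leaf-length registrations
    temp_cadence: float = 10.0      # min between temperature readings
    soil_cadence: float = 4.0       # h between soil-moisture readings
    n_replicates: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma_upper_true < self.sigma_lower_true:
            raise InvalidConfigError(
                "growth must slow before it arrests: "
                f"sigma_upper {self.sigma_upper_true} >= sigma_lower {self.sigma_lower_true}"
            )
        if not self.psi_start < self.psi_plateau:
            raise InvalidConfigError(
                f"psi_start {self.psi_start} must be below psi_plateau {self.psi_plateau}"
            )
        for name in ("psi_timescale", "duration", "photoperiod_day",
                     "growth_cadence", "temp_cadence", "soil_cadence"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.psi_shape_k <= 0:
            raise InvalidConfigError("psi_shape_k must be positive")
        if self.temp_lag < 0:
            raise InvalidConfigError("temp_lag must be non-negative")
        if self.noise_sd_ler < 0:
            raise InvalidConfigError("noise_sd_ler must be non-negative")
        if self.n_replicates < 1:
            raise InvalidConfigError("n_replicates must be at least 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GrowthTrace:
    """Cumulative leaf length (mm) of one tiller at the tracker cadence."""

    tiller_id: str
    timestamps: np.ndarray  # minutes since experiment start
    leaf_length: np.ndarray  # cumulative mm

    def __post_init__(self) -> None:
        _check_times(self.timestamps, "growth")
        if not np.all(np.isfinite(self.leaf_length)):
            raise InvalidConfigError("leaf lengths must be finite")


@dataclass(frozen=True)
class MeristemTempTrace:
    """Meristem temperature (degC) readings."""

    timestamps: np.ndarray  # minutes
    temperature: np.ndarray  # degC

    def __post_init__(self) -> None:
        _check_times(self.timestamps, "temperature")
        lo, hi = TEMP_PHYSICAL_RANGE
        if np.any(self.temperature < lo) or np.any(self.temperature > hi):
            raise InvalidConfigError(
                f"temperature outside physical range {TEMP_PHYSICAL_RANGE}"
            )


@dataclass(frozen=True)
class SoilMoistureTrace:
    """Raw soil matric potential magnitude (hPa, > 0) readings."""

    timestamps: np.ndarray  # minutes
    psi_raw: np.ndarray  # hPa

    def __post_init__(self) -> None:
        _check_times(self.timestamps, "soil")
        if np.any(self.psi_raw <= 0):
            raise InvalidConfigError("psi_raw must be strictly positive (log10 domain)")


def _check_times(t: np.ndarray, what: str) -> None:
    if len(t) == 0:
        raise InvalidConfigError(f"empty {what} trace")
    if np.any(np.diff(t) <= 0):
        raise InvalidConfigError(f"{what} timestamps must be strictly increasing")


# ---------------------------------------------------------------------------
# environment


def _air_temperature(t_h: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Square-wave cabinet temperature; day starts at hour 0 of each cycle."""
    phase = np.mod(t_h, 24.0)
    return np.where(phase < cfg.photoperiod_day, cfg.temp_day, cfg.temp_night)


def _meristem_temperature(t_h: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Air square wave through a first-order lag with time constant temp_lag.

    The lag ODE  dT/dt = (T_air - T)/tau  is integrated exactly over each
    constant-temperature segment, so the result is analytic, not a numerical
    approximation.  With tau = 0 the output is the square wave itself.
    """
    air = _air_temperature(t_h, cfg)
    if cfg.temp_lag == 0.0 or cfg.temp_day == cfg.temp_night:
        return air.astype(float)
    tau = cfg.temp_lag
    # breakpoints of the square wave inside [0, max(t)]
    half = [0.0]
    t_end = float(t_h[-1])
    k = 0.0
    while k < t_end:
        if k + cfg.photoperiod_day <= t_end:
            half.append(k + cfg.photoperiod_day)
        k += 24.0
        if k <= t_end:
            half.append(k)
    half = np.asarray(sorted(set(half)))
    # steady initial condition: assume the cabinet ran overnight, so the
    # meristem starts at the night temperature relaxed toward day onset
    temp0 = cfg.temp_night
    seg_starts = half
    seg_temps = np.empty(len(seg_starts))
    state = temp0
    seg_state = [state]
    for i in range(len(seg_starts) - 1):
        target = cfg.temp_day if np.mod(seg_starts[i], 24.0) < cfg.photoperiod_day else cfg.temp_night
        dt = seg_starts[i + 1] - seg_starts[i]
        state = target + (state - target) * np.exp(-dt / tau)
        seg_state.append(state)
    seg_temps[:] = seg_state
    idx = np.searchsorted(seg_starts, t_h, side="right") - 1
    target = np.where(
        np.mod(seg_starts[idx], 24.0) < cfg.photoperiod_day, cfg.temp_day, cfg.temp_night
    )
    out = target + (seg_temps[idx] - target) * np.exp(-(t_h - seg_starts[idx]) / tau)
    return out


def simulate_temperature(cfg: SimConfig) -> MeristemTempTrace:
    """Meristem temperature sampled every ``temp_cadence`` minutes.

    A 25/15 °C (by default) square wave on the photoperiod, smoothed by a
    first-order lag; values always lie within [temp_night, temp_day].
    """
    t_min = _grid_with_endpoint(cfg.duration * 60.0, cfg.temp_cadence)
    temp = _meristem_temperature(t_min / 60.0, cfg)
    return MeristemTempTrace(timestamps=t_min, temperature=temp)


def _grid_with_endpoint(end: float, step: float) -> np.ndarray:
    """Regular grid from 0 that always contains the endpoint, so sensor
    traces cover the full experiment even when the duration is not a
    multiple of the cadence."""
    t = np.arange(0.0, end, step)
    if t[-1] < end:
        t = np.append(t, end)
    return t


def psi_log10_curve(t_h: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Ground-truth log10 matric potential at hours ``t_h``.

    A saturating Weibull rise,

        psi(t) = plateau - (plateau - start) * exp(-(t / timescale)^k),

    strictly increasing toward the plateau; with k = 1 this is the plain
    exponential-saturating form.  The default k = 3 starts nearly flat —
    the wet end of the soil retention curve, where suction barely responds
    to water loss — which keeps the thermal-fit window unstressed and
    matches the reference drying trajectory (mean below 2 log10 hPa over
    the first 24 h, below 3 over the next 24 h, plateau ~4.3 by 96 h).
    Re-watering is an instantaneous reset to ``psi_start``.
    """
    t_h = np.asarray(t_h, dtype=float)
    u = (np.clip(t_h, 0.0, None) / cfg.psi_timescale) ** cfg.psi_shape_k
    psi = cfg.psi_plateau - (cfg.psi_plateau - cfg.psi_start) * np.exp(-u)
    if cfg.rewater_time is not None:
        psi = np.where(t_h >= cfg.rewater_time, cfg.psi_start, psi)
    return psi


def simulate_soil_drying(cfg: SimConfig) -> SoilMoistureTrace:
    """Raw matric potential (hPa) sampled every ``soil_cadence`` hours."""
    t_h = _grid_with_endpoint(cfg.duration * 60.0, cfg.soil_cadence * 60.0) / 60.0
    psi = psi_log10_curve(t_h, cfg)
    return SoilMoistureTrace(timestamps=t_h * 60.0, psi_raw=10.0 ** psi)


# ---------------------------------------------------------------------------
# growth


def tri_phase_g(psi_log10: np.ndarray, sigma_upper: float, sigma_lower: float) -> np.ndarray:
    """The tri-phase growth multiplier g(psi): 1 below sigma_upper, linear
    decline to 0 at sigma_lower, 0 beyond (all in log10 hPa)."""
    psi_log10 = np.asarray(psi_log10, dtype=float)
    g = (sigma_lower - psi_log10) / (sigma_lower - sigma_upper)
    return np.clip(g, 0.0, 1.0)


def _hold_interp(t_query: np.ndarray, t_known: np.ndarray, v_known: np.ndarray) -> np.ndarray:
    """Zero-order hold: the value of the most recent reading at or before t."""
    idx = np.searchsorted(t_known, t_query, side="right") - 1
    if np.any(idx < 0):
        raise AlignmentError("trace does not cover the start of the growth window")
    return v_known[idx]


def simulate_growth(
    cfg: SimConfig,
    temp: MeristemTempTrace,
    soil: SoilMoistureTrace,
    *,
    tiller_id: str = "tiller_1",
    rng: np.random.Generator | None = None,
) -> GrowthTrace:
    """Cumulative leaf length from the tri-phase rate model.

    The instantaneous rate a_true * T(t) * g(psi(t)) is evaluated on the
    tracker grid (``growth_cadence`` minutes) with the sensor values held
    from their most recent reading, Gaussian rate noise (sd
    ``noise_sd_ler``) is added, and the rate is integrated to cumulative
    length.  With zero noise the trace is deterministic and non-decreasing.
    """
    dt_min = cfg.growth_cadence
    t_min = np.arange(0.0, cfg.duration * 60.0 + 0.5 * dt_min, dt_min)
    if temp.timestamps[-1] < t_min[-2] or soil.timestamps[-1] < t_min[-2]:
        raise AlignmentError(
            "temperature/soil traces do not cover the configured duration"
        )
    # rate on each interval [t_k, t_k+1): temperature is held from the most
    # recent reading (a cabinet regime switches stepwise), while psi is
    # interpolated linearly in log10 between readings (drying is continuous;
    # the sensor merely samples it every few hours)
    t_mid = t_min[:-1]
    temp_at = _hold_interp(t_mid, temp.timestamps, temp.temperature)
    if t_mid[0] < soil.timestamps[0]:
        raise AlignmentError("soil trace starts after the growth window")
    psi_at = np.interp(t_mid, soil.timestamps, np.log10(soil.psi_raw))
    g = tri_phase_g(psi_at, cfg.sigma_upper_true, cfg.sigma_lower_true)
    rate = cfg.a_true * temp_at * g  # mm h-1
    if cfg.noise_sd_ler > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(0.0, cfg.noise_sd_ler, size=rate.shape)
        rate = rate + noise
        if cfg.no_shrink:
            rate = np.clip(rate, 0.0, None)
    dt_h = dt_min / 60.0
    length = np.concatenate([[0.0], np.cumsum(rate * dt_h)])
    return GrowthTrace(tiller_id=tiller_id, timestamps=t_min, leaf_length=length)


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[list[GrowthTrace], MeristemTempTrace, SoilMoistureTrace]:
    """Full experiment: shared environment, ``n_replicates`` growth traces.

    Replicates share the temperature and soil traces (one cabinet, one pot
    regime) and differ only in their noise stream, each drawn from an
    independent child of ``cfg.seed``.
    """
    temp = simulate_temperature(cfg)
    soil = simulate_soil_drying(cfg)
    root = np.random.default_rng(cfg.seed)
    streams = root.spawn(cfg.n_replicates)
    growths = [
        simulate_growth(cfg, temp, soil, tiller_id=f"tiller_{i + 1}", rng=streams[i])
        for i in range(cfg.n_replicates)
    ]
    return growths, temp, soil


def noise_sd_for_fraction(cfg: SimConfig, fraction: float) -> float:
    """Per-sample rate-noise sd that makes the *hourly* LER noise equal to
    ``fraction`` of the mean unstressed rate.

    The mean unstressed rate is a_true times the photoperiod-weighted mean
    temperature — the typical LER before drying bites.  Per-sample noise
    averages down by the square root of the number of registrations per
    hour when the rate is integrated, so the per-sample sd is scaled up by
    that factor: "10 % rate noise" then means hourly LER values scatter
    with a 10 % sd.
    """
    t_mean = (
        cfg.photoperiod_day * cfg.temp_day
        + (24.0 - cfg.photoperiod_day) * cfg.temp_night
    ) / 24.0
    samples_per_hour = 60.0 / cfg.growth_cadence
    return fraction * cfg.a_true * t_mean * np.sqrt(samples_per_hour)


# ---------------------------------------------------------------------------
# disk round trip


def write_experiment(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the tidy trace CSVs plus a ground-truth sidecar JSON.

    Files: ``growth.csv`` (tiller_id, time_min, length_mm), ``temperature.csv``
    (time_min, temp_c), ``soil.csv`` (time_min, psi_hpa), ``truth.json``
    (every SimConfig field, including the seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    growths, temp, soil = simulate_experiment(cfg)
    growth_df = pd.concat(
        [
            pd.DataFrame(
                {
                    "tiller_id": g.tiller_id,
                    "time_min": g.timestamps,
                    "length_mm": g.leaf_length,
                }
            )
            for g in growths
        ],
        ignore_index=True,
    )
    paths = {
        "growth": out / "growth.csv",
        "temperature": out / "temperature.csv",
        "soil": out / "soil.csv",
        "truth": out / "truth.json",
    }
    growth_df.to_csv(paths["growth"], index=False, float_format="%.17g")
    pd.DataFrame({"time_min": temp.timestamps, "temp_c": temp.temperature}).to_csv(
        paths["temperature"], index=False, float_format="%.17g"
    )
    pd.DataFrame({"time_min": soil.timestamps, "psi_hpa": soil.psi_raw}).to_csv(
        paths["soil"], index=False, float_format="%.17g"
    )
    paths["truth"].write_text(json.dumps(cfg.to_dict(), indent=2))
    return paths
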