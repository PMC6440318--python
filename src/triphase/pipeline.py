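"""End-to-end drivers: traces in, per-tiller tri-phase results out."""

from __future__ import annotations

from pathlib import Path

from .simdata import (
    GrowthTrace,
    MeristemTempTrace,
    SimConfig,
    SoilMoistureTrace,
    simulate_experiment,
)
from .timeseries_io import (
    build_hourly_series,
    read_growth_csv,
    read_soil_csv,
    read_temperature_csv,
)
from .triphase_core import FitConfig, TriPhaseResult, fit_triphase

__all__ = ["fit_experiment", "fit_experiment_dir", "fit_simulated"]


def fit_experiment(
    growths: list[GrowthTrace],
    temp: MeristemTempTrace,
    soil: SoilMoistureTrace,
    *,
    fit_config: FitConfig = FitConfig(),
    rewater_time: float | None = None,
    span: float = 0.75,
    degree: int = 2,
) -> list[TriPhaseResult]:
    """Fit every tiller of one experiment against the shared sensor traces."""
    results = []
    for g in growths:
        series = build_hourly_series(
            g, temp, soil, rewater_time=rewater_time, span=span, degree=degree
        )
        results.append(fit_triphase(series, fit_config))
    return results


def fit_experiment_dir(
    path: str | Path,
    *,
    fit_config: FitConfig = FitConfig(),
    rewater_time: float | None = None,
    span: float = 0.75,
    degree: int = 2,
) -> list[TriPhaseResult]:
    """Fit an experiment directory holding growth.csv, temperature.csv, soil.csv."""
    path = Path(path)
    growths = read_growth_csv(path / "growth.csv")
    temp = read_temperature_csv(path / "temperature.csv")
    soil = read_soil_csv(path / "soil.csv")
    return fit_experiment(
        growths, temp, soil,
        fit_config=fit_config, rewater_time=rewater_time, span=span, degree=degree,
    )


def fit_simulated(
    cfg: SimConfig, *, fit_config: FitConfig = FitConfig()
) -> list[TriPhaseResult]:
    """Simulate an experiment and fit it, the parameter-recovery loop.

    The re-watering time is taken from the simulation configuration, as a
    real analyst would know it from the lab protocol.
    """
    growths, temp, soil = simulate_experiment(cfg)
    return fit_experiment(
        growths, temp, soil, fit_config=fit_config, rewater_time=cfg.rewater_time
    )
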