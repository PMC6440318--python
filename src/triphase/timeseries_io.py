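"""Trace file I/O and summarization to the hourly analysis grid.

Three tidy CSV dialects come in (leaf length per tiller at tracker cadence,
meristem temperature, raw soil matric potential); one hourly table comes
out, the substrate of the tri-phase fit:

=================  =========================================================
column             meaning
=================  =========================================================
hour               integer hours since experiment start (window [h, h+1))
ler_mm_h           hourly leaf elongation rate, (L1 - L0)/(t1 - t0) * 60,
                   where L1/L0 are the max/min length inside the hour and t
                   is in minutes
temp_c             hourly mean meristem temperature
psi_log10          soil matric potential on the log10 hPa scale, imputed to
                   the hour midpoint by loess; only observations taken
                   before re-watering enter the fit
after_rewatering   True for hours at or after the re-watering event
ler_reversed       True where the in-hour maximum precedes the minimum
                   (noise artefact; the rate is reported signed)
rgra               thermally corrected relative growth rate LER/(a*T);
                   absent until a thermal fit exists
=================  =========================================================

Hours missing from any stream are dropped from the joined table (an inner
join), never zero-filled.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, FormatError
from .simdata import GrowthTrace, MeristemTempTrace, SoilMoistureTrace
from .smoothing import loess_fit

__all__ = [
    "read_growth_csv",
    "read_temperature_csv",
    "read_soil_csv",
    "write_hourly_csv",
    "compute_hourly_ler",
    "summarize_temperature",
    "impute_psi_hourly",
    "detect_rewatering",
    "align_hourly",
    "build_hourly_series",
]

log = logging.getLogger(__name__)

GROWTH_COLUMNS = ["tiller_id", "time_min", "length_mm"]
TEMP_COLUMNS = ["time_min", "temp_c"]
SOIL_COLUMNS = ["time_min", "psi_hpa"]


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    # round_trip: exact float parsing, so write->read reproduces bit-identical
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_growth_csv(path: str | Path) -> list[GrowthTrace]:
    """Read a growth CSV (tiller_id, time_min, length_mm) into traces."""
    df = _read_csv(path, GROWTH_COLUMNS)
    traces = []
    for tid, grp in df.groupby("tiller_id", sort=True):
        t = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{path}: non-monotone timestamps for tiller {tid}")
        traces.append(
            GrowthTrace(
                tiller_id=str(tid),
                timestamps=t,
                leaf_length=grp["length_mm"].to_numpy(dtype=float),
            )
        )
    if not traces:
        raise FormatError(f"{path}: no tillers found")
    return traces


def read_temperature_csv(path: str | Path) -> MeristemTempTrace:
    df = _read_csv(path, TEMP_COLUMNS)
    if df.empty:
        raise FormatError(f"{path}: empty temperature trace")
    return MeristemTempTrace(
        timestamps=df["time_min"].to_numpy(dtype=float),
        temperature=df["temp_c"].to_numpy(dtype=float),
    )


def read_soil_csv(path: str | Path) -> SoilMoistureTrace:
    df = _read_csv(path, SOIL_COLUMNS)
    if df.empty:
        raise FormatError(f"{path}: empty soil trace")
    psi = df["psi_hpa"].to_numpy(dtype=float)
    if np.any(psi <= 0):
        raise DomainError(f"{path}: matric potential must be > 0 hPa for log10")
    return SoilMoistureTrace(
        timestamps=df["time_min"].to_numpy(dtype=float), psi_raw=psi
    )


def write_hourly_csv(series: pd.DataFrame, path: str | Path) -> None:
    """Write the hourly table (hour, ler_mm_h, temp_c, psi_log10, after_rewatering)."""
    cols = ["hour", "ler_mm_h", "temp_c", "psi_log10", "after_rewatering"]
    series.loc[:, cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# hourly summaries


def _hour_of(t_min: np.ndarray) -> np.ndarray:
    # half-open windows [h, h+1) in hours since start
    return np.floor(t_min / 60.0).astype(int)


def compute_hourly_ler(trace: GrowthTrace) -> pd.DataFrame:
    """Hourly LER from a cumulative-length trace.

    For each hour window [h, h+1) with at least two registrations, the rate
    is (length at time of in-hour maximum minus length at time of in-hour
    minimum) divided by the time between them (minutes), times 60 — i.e.
    mm h-1.  Hours with fewer than two registrations are omitted.  For a
    clean, non-decreasing trace the maximum sits at the window end and the
    minimum at its start; noise can reverse that order, in which case the
    signed rate is negative and the hour is flagged ``ler_reversed``.
    """
    t = np.asarray(trace.timestamps, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"tiller {trace.tiller_id}: non-monotone timestamps")
    length = np.asarray(trace.leaf_length, dtype=float)
    hours = _hour_of(t)
    rows = []
    for h in np.unique(hours):
        sel = hours == h
        if sel.sum() < 2:
            continue
        lh, th = length[sel], t[sel]
        i_max, i_min = int(np.argmax(lh)), int(np.argmin(lh))
        dt = th[i_max] - th[i_min]
        if dt == 0.0:
            # constant length: zero rate over the window
            rows.append((int(h), 0.0, False))
            continue
        rate = (lh[i_max] - lh[i_min]) / dt * 60.0
        rows.append((int(h), float(rate), bool(dt < 0)))
    if not rows:
        raise FormatError(f"tiller {trace.tiller_id}: no hour has >= 2 samples")
    return pd.DataFrame(rows, columns=["hour", "ler_mm_h", "ler_reversed"])


def summarize_temperature(trace: MeristemTempTrace) -> pd.DataFrame:
    """Hourly arithmetic mean of meristem temperature."""
    if len(trace.timestamps) == 0:
        raise FormatError("empty temperature trace")
    df = pd.DataFrame(
        {"hour": _hour_of(np.asarray(trace.timestamps, dtype=float)),
         "temp_c": trace.temperature}
    )
    out = df.groupby("hour", as_index=False)["temp_c"].mean()
    return out


def detect_rewatering(trace: SoilMoistureTrace, *, drop_threshold: float = 0.5) -> float | None:
    """Detect a re-watering event as a drop of at least ``drop_threshold``
    log10 hPa between consecutive soil observations.

    Returns the event time in hours, or None if no such drop occurs.
    """
    psi = np.log10(np.asarray(trace.psi_raw, dtype=float))
    drops = np.diff(psi) <= -drop_threshold
    if not drops.any():
        return None
    i = int(np.argmax(drops)) + 1
    return float(trace.timestamps[i]) / 60.0


def impute_psi_hourly(
    trace: SoilMoistureTrace,
    rewater_time: float | None = None,
    *,
    span: float = 0.75,
    degree: int = 2,
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Impute log10 soil matric potential onto hour midpoints by loess.

    The raw readings are log10-transformed first; only observations strictly
    before ``rewater_time`` (hours) enter the fit — including post-watering
    readings would drag the smooth down and badly underestimate the final
    soil moisture.  By default no value is produced outside the time range
    of the observations used (``extrapolate=False``), nor for hours at or
    after re-watering.

    Returns a frame with columns hour, psi_log10; hours outside the
    imputation domain are present with NaN so that downstream joins keep
    the hour (flagged, not silently vanished).
    """
    t_h = np.asarray(trace.timestamps, dtype=float) / 60.0
    psi = np.asarray(trace.psi_raw, dtype=float)
    if np.any(psi <= 0):
        raise DomainError("matric potential must be > 0 hPa for the log10 transform")
    psi_log = np.log10(psi)
    if rewater_time is not None:
        keep = t_h < rewater_time
    else:
        keep = np.ones_like(t_h, dtype=bool)
    t_fit, y_fit = t_h[keep], psi_log[keep]
    last_hour = int(np.floor(t_h[-1]))
    mids = np.arange(last_hour + 1) + 0.5
    valid = np.ones_like(mids, dtype=bool)
    if rewater_time is not None:
        valid &= mids < rewater_time
    if not extrapolate and len(t_fit) > 0:
        valid &= (mids >= t_fit[0]) & (mids <= t_fit[-1])
    values = np.full(mids.shape, np.nan)
    values[valid] = loess_fit(t_fit, y_fit, mids[valid], span=span, degree=degree)
    return pd.DataFrame({"hour": np.arange(last_hour + 1), "psi_log10": values})


def align_hourly(
    ler: pd.DataFrame,
    temp: pd.DataFrame,
    psi: pd.DataFrame,
    *,
    rewater_time: float | None = None,
) -> pd.DataFrame:
    """Inner-join the three hourly streams into one analysis table.

    Hours missing from any stream are dropped (and counted in a log
    message).  Hours at or after ``rewater_time`` are flagged, not dropped:
    the fitters exclude them, but they remain visible for plotting the
    post-watering rebound.
    """
    merged = ler.merge(temp, on="hour").merge(psi, on="hour")
    if merged.empty:
        raise AlignmentError("hourly LER, temperature and psi do not overlap")
    n_union = len(set(ler["hour"]) | set(temp["hour"]) | set(psi["hour"]))
    n_dropped = n_union - len(merged)
    if n_dropped:
        log.info("align_hourly: dropped %d hours missing from some stream", n_dropped)
    merged = merged.sort_values("hour", ignore_index=True)
    if rewater_time is None:
        merged["after_rewatering"] = False
    else:
        merged["after_rewatering"] = merged["hour"] >= rewater_time
    return merged


def build_hourly_series(
    growth: GrowthTrace,
    temp: MeristemTempTrace,
    soil: SoilMoistureTrace,
    *,
    rewater_time: float | None = None,
    auto_detect_rewatering: bool = True,
    span: float = 0.75,
    degree: int = 2,
) -> pd.DataFrame:
    """Convenience composition: hourly LER + mean T + imputed psi for one tiller.

    If ``rewater_time`` is not given and ``auto_detect_rewatering`` is on,
    a drop of >= 0.5 log10 hPa between consecutive soil readings marks the
    event.  Post-watering hours carry LER and temperature but NaN psi and
    an ``after_rewatering`` flag; the fitters exclude them.
    """
    if rewater_time is None and auto_detect_rewatering:
        rewater_time = detect_rewatering(soil)
    ler = compute_hourly_ler(growth)
    tmp = summarize_temperature(temp)
    psi = impute_psi_hourly(soil, rewater_time, span=span, degree=degree)
    out = align_hourly(ler, tmp, psi, rewater_time=rewater_time)
    out.attrs["tiller_id"] = growth.tiller_id
    out.attrs["rewater_time"] = rewater_time
    return out
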