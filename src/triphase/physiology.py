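"""Relative water content (RWC) of leaf samples.

RWC = 100 * (FW - DW) / (TW - DW), from the fresh weight at sampling, the
turgid weight after full rehydration, and the oven-dry weight.  It indexes
leaf hydration independently of the growth data and is used to confirm
that a drying treatment actually stressed the plants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DomainError

__all__ = ["RWCSample", "compute_rwc", "rwc_table", "process_rwc_csv"]


@dataclass(frozen=True)
class RWCSample:
    """One leaf sample's weights (g) and its relative water content (%).

    ``valid`` is False when the weights are not physically ordered
    (DW <= FW <= TW); the RWC value is still reported, flagged rather than
    clamped, so data-entry errors stay visible.
    """

    fresh_weight: float
    turgid_weight: float
    dry_weight: float
    rwc: float
    valid: bool


def compute_rwc(fresh_weight: float, turgid_weight: float, dry_weight: float) -> RWCSample:
    """RWC (%) of a single sample.

    Raises DomainError when TW <= DW (no water-holding capacity: the
    denominator is meaningless).  Values outside [0, 100] are returned
    with ``valid=False``.
    """
    if turgid_weight <= dry_weight:
        raise DomainError(
            f"degenerate sample: turgid weight {turgid_weight} g <= dry weight {dry_weight} g"
        )
    rwc = 100.0 * (fresh_weight - dry_weight) / (turgid_weight - dry_weight)
    valid = dry_weight <= fresh_weight <= turgid_weight
    return RWCSample(
        fresh_weight=fresh_weight,
        turgid_weight=turgid_weight,
        dry_weight=dry_weight,
        rwc=rwc,
        valid=valid,
    )


def rwc_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Append ``rwc_pct`` and ``valid`` to a samples frame with columns
    plant_id, sample_id, fw_g, tw_g, dw_g."""
    out = samples.copy()
    computed = [
        compute_rwc(r.fw_g, r.tw_g, r.dw_g) for r in out.itertuples(index=False)
    ]
    out["rwc_pct"] = [s.rwc for s in computed]
    out["valid"] = [s.valid for s in computed]
    return out


def process_rwc_csv(path: str | Path, out_path: str | Path | None = None) -> pd.DataFrame:
    """Read a sample CSV, compute per-sample RWC, and (optionally) write it
    back with per-plant means appended as ``plant_mean_pct``.

    A plant's RWC is the mean over its samples (at least two mature leaves
    per plant is the usual sampling design); per-sample values are retained.
    """
    df = rwc_table(pd.read_csv(path))
    df["plant_mean_pct"] = df.groupby("plant_id")["rwc_pct"].transform("mean")
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
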