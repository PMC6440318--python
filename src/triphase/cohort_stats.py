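"""Cohort aggregation and one-way ANOVA over per-tiller fit results.

Groups are experiments (reproducibility check: the same genotype fitted in
repeated runs should give indistinguishable parameter distributions) or
genotypes (the interesting case: real differences in thermal growth rate
and in the drying points).  The classical one-way F test is used for each
parameter separately, as per-panel raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "PARAMETERS",
    "attach_groups",
    "summarize_groups",
    "one_way_anova",
    "anova_table",
]

# per-tiller CSV columns that are cohort parameters of interest
PARAMETERS = ["a_um", "sigma_upper", "sigma_lower"]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean and sd of each tri-phase parameter."""

    group_id: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]  # empty when n == 1


@dataclass(frozen=True)
class AnovaResult:
    parameter: str
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def attach_groups(results: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Join the per-tiller results with a (tiller_id, group_id) mapping.

    Every tiller must be mapped; unmapped ids raise with the full list.
    """
    merged = results.merge(mapping, on="tiller_id", how="left")
    missing = merged.loc[merged["group_id"].isna(), "tiller_id"].tolist()
    if missing:
        raise DomainError(f"tillers without a group mapping: {missing}")
    return merged


def summarize_groups(
    results: pd.DataFrame, parameters: list[str] | None = None
) -> list[GroupSummary]:
    """Deterministic per-group means/sds, ordered by group label."""
    parameters = parameters or PARAMETERS
    out = []
    for gid, grp in results.groupby("group_id", sort=True):
        n = len(grp)
        means = {p: float(grp[p].mean()) for p in parameters}
        sds = {p: float(grp[p].std(ddof=1)) for p in parameters} if n > 1 else {}
        out.append(GroupSummary(group_id=str(gid), n=n, means=means, sds=sds))
    return out


def one_way_anova(values_by_group: dict[str, np.ndarray], parameter: str) -> AnovaResult:
    """Classical one-way fixed-effects F test across the groups.

    All-identical values give F = 0, p = 1 (no evidence of differences,
    not an error).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs at least two groups")
    n_total = sum(len(g) for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if df_within < 2:
        raise InsufficientDataError(
            f"ANOVA needs >= 2 within-group degrees of freedom, got {df_within}"
        )
    values = np.concatenate(groups)
    if np.allclose(values, values[0]):
        return AnovaResult(parameter, 0.0, df_between, df_within, 1.0)
    f_stat, p = stats.f_oneway(*groups)
    return AnovaResult(parameter, float(f_stat), df_between, df_within, float(p))


def anova_table(
    results: pd.DataFrame, parameters: list[str] | None = None
) -> pd.DataFrame:
    """One ANOVA row per parameter from a grouped per-tiller results frame."""
    parameters = parameters or PARAMETERS
    rows = []
    for p in parameters:
        by_group = {
            str(g): grp[p].dropna().to_numpy()
            for g, grp in results.groupby("group_id", sort=True)
        }
        r = one_way_anova(by_group, p)
        rows.append(
            {
                "parameter": r.parameter,
                "f_stat": r.f_stat,
                "df_between": r.df_between,
                "df_within": r.df_within,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)
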