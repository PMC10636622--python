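"""Nonparametric statistics: Spearman rank correlation and Mann-Whitney U.

Spearman's rho is the Pearson correlation of mid-ranks, with significance
from t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom (two-sided).
The Mann-Whitney test uses the normal approximation on the first group's rank
sum W1, with tie-corrected variance and an optional 0.5 continuity correction
that shrinks |z|:

    z = (W1 - E[W1] -/+ 0.5) / sigma,
    sigma^2 = n1*n2/12 * (n + 1 - sum(t^3 - t) / (n*(n-1)))

In pipeline use the group order is fixed as (east, west), so analytes elevated
in the west yield negative z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError
from .pocis import AnalyteLoadTable, PlantRecord


@dataclass(frozen=True)
class CorrelationResult:
    analyte_a: str
    analyte_b: str
    rho: float
    t_stat: float
    df: int
    p_value: float
    exact_monotone: bool = False


@dataclass(frozen=True)
class RankTestResult:
    variable: str
    group_order: tuple[str, str]
    u_statistic: float
    z: float
    p_value: float


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Spearman rank correlation with t-based two-sided significance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 observations, got {n}")
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    df = n - 2
    if abs(rho) >= 1.0 - 1e-12:
        # exact monotone relation: t diverges, report p = 0 with a flag
        sign = 1.0 if rho > 0 else -1.0
        return CorrelationResult(names[0], names[1], sign, sign * math.inf, df, 0.0, True)
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(names[0], names[1], rho, t, df, min(p, 1.0))


def mann_whitney(
    first_group: Sequence[float],
    second_group: Sequence[float],
    variable: str = "",
    group_order: tuple[str, str] = ("first", "second"),
    continuity: bool = True,
) -> RankTestResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    ``u_statistic`` is U for the first group; ``z`` is signed so a first group
    with systematically smaller values gives negative z.
    """
    a = np.asarray(first_group, dtype=float)
    b = np.asarray(second_group, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("both groups must be non-empty")
    n = n1 + n2
    if n < 4:
        raise InsufficientDataError("need total n >= 4 for the normal approximation")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical across both groups")
    ranks = stats.rankdata(pooled)
    w1 = float(ranks[:n1].sum())
    u1 = w1 - n1 * (n1 + 1) / 2.0
    e_w1 = n1 * (n + 1) / 2.0

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise DegenerateDataError("zero variance in rank sum")
    sigma = math.sqrt(var)

    diff = w1 - e_w1
    if continuity:
        # shrink |z| by half a rank unit; an exact-null rank sum stays z = 0
        diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff) if diff != 0 else 0.0
    z = diff / sigma
    p = min(2.0 * stats.norm.sf(abs(z)), 1.0)
    return RankTestResult(variable, group_order, u1, z, p)


def correlation_matrix(
    loads: AnalyteLoadTable, value: str = "cer_g_day"
) -> pd.DataFrame:
    """Long-format symmetric table of all pairwise Spearman correlations.

    Columns: analyte_a, analyte_b, rho, t, df, p_value (one row per unordered
    pair, a < b in panel order).
    """
    wide = loads.pivot(value)
    cols = list(wide.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = spearman(wide[a].to_numpy(), wide[b].to_numpy(), names=(a, b))
            rows.append(
                {
                    "analyte_a": a,
                    "analyte_b": b,
                    "rho": r.rho,
                    "t": r.t_stat,
                    "df": r.df,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows)


def regional_tests(
    loads: AnalyteLoadTable,
    plants: Sequence[PlantRecord],
    value: str = "cer_per_capita_ug_day",
    group_order: tuple[str, str] = ("east", "west"),
    continuity: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-analyte Mann-Whitney comparison of regions on the chosen quantity.

    The (east, west) group order reproduces the convention that west-elevated
    analytes carry negative z.  ``fdr=True`` appends Benjamini-Hochberg
    adjusted p-values (off by default; the primary analysis is unadjusted).
    """
    region = {p.plant_id: p.region for p in plants}
    wide = loads.pivot(value)
    grp = pd.Series([region[pid] for pid in wide.index], index=wide.index)
    rows = []
    for analyte in wide.columns:
        col = wide[analyte]
        res = mann_whitney(
            col[grp == group_order[0]].to_numpy(),
            col[grp == group_order[1]].to_numpy(),
            variable=analyte,
            group_order=group_order,
            continuity=continuity,
        )
        rows.append(
            {"analyte": analyte, "u": res.u_statistic, "z": res.z, "p_value": res.p_value}
        )
    out = pd.DataFrame(rows)
    if fdr:
        out["p_bh"] = stats.false_discovery_control(out["p_value"].to_numpy())
    return out


def ratio_regional_tests(
    ratios: dict[str, pd.Series],
    plants: Sequence[PlantRecord],
    group_order: tuple[str, str] = ("east", "west"),
    continuity: bool = True,
) -> pd.DataFrame:
    """Mann-Whitney regional comparison of opioid-to-methadone ratios.

    ``ratios`` maps a name (e.g. ``"oxycodone_to_methadone"``) to a per-plant
    Series; NaN entries (flagged missing, zero-methadone plants) are dropped.
    """
    region = {p.plant_id: p.region for p in plants}
    rows = []
    for name, series in ratios.items():
        s = series.dropna()
        grp = pd.Series([region[pid] for pid in s.index], index=s.index)
        res = mann_whitney(
            s[grp == group_order[0]].to_numpy(),
            s[grp == group_order[1]].to_numpy(),
            variable=name,
            group_order=group_order,
            continuity=continuity,
        )
        rows.append(
            {"ratio": name, "u": res.u_statistic, "z": res.z, "p_value": res.p_value}
        )
    return pd.DataFrame(rows)
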