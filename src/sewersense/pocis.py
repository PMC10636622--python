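"""Passive-sampler back-calculation of water concentrations and community loads.

A POCIS device deployed at a plant inlet accumulates dissolved analytes on its
sorbent for the deployment period.  In the linear-uptake regime the
time-weighted average water concentration is

    Cw = Cs * Ms / (Rs * t)        [ng/L]

where ``Cs`` is the sorbent-phase concentration (ng/g), ``Ms`` the sorbent
mass (g), ``Rs`` the analyte-specific sampling rate (L/day) and ``t`` the
exposure time (days).  The collective excretion rate of the community is then

    CER = Cw * Q * 1e-9            [g/day]

with ``Q`` the plant flow (L/day), and the per-capita load is
``CER * 1e6 / population`` in ug/person/day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, MissingAnalyteError
from .rates import DEFAULT_SAMPLING_RATES, INSTRUMENT_DETECTION_LIMIT_PG, OPIOID_WHITELIST

logger = logging.getLogger(__name__)

REGIONS = ("east", "west")

#: Non-detect substitution policies: value used for a replicate below the
#: reporting limit.
ND_POLICIES = ("zero", "half_limit", "limit")


@dataclass(frozen=True)
class PlantRecord:
    """One wastewater treatment plant.

    Parameters
    ----------
    plant_id : opaque identifier (never geocoded).
    region : ``"east"`` or ``"west"`` (of the Mississippi River).
    population : persons served, > 0.
    flow_rate : weekly-mean plant flow in L/day, > 0.
    """

    plant_id: str
    region: str
    population: float
    flow_rate: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise DomainError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not self.population > 0:
            raise DomainError(f"population must be > 0, got {self.population}")
        if not self.flow_rate > 0:
            raise DomainError(f"flow_rate must be > 0, got {self.flow_rate}")


@dataclass(frozen=True)
class SorbentMeasurement:
    """Sorbent-phase measurements for one plant x analyte.

    ``replicate_cs`` holds the (typically 3) replicate sorbent-phase
    concentrations in ng/g; ``sorbent_mass`` is Ms in g and ``exposure_days``
    the deployment time t in days.
    """

    plant_id: str
    analyte: str
    replicate_cs: tuple[float, ...]
    sorbent_mass: float
    exposure_days: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicate_cs", tuple(float(v) for v in self.replicate_cs))
        if len(self.replicate_cs) < 1:
            raise DomainError("at least one replicate is required")
        if any(v < 0 for v in self.replicate_cs):
            raise DomainError("replicate sorbent concentrations must be >= 0")
        if not self.sorbent_mass > 0:
            raise DomainError(f"sorbent_mass must be > 0, got {self.sorbent_mass}")
        if not self.exposure_days > 0:
            raise DomainError(f"exposure_days must be > 0, got {self.exposure_days}")


class SamplingRateTable:
    """Analyte -> POCIS sampling rate Rs (L/day), with optional detection limits."""

    def __init__(
        self,
        rates: Mapping[str, float],
        detection_limit_pg: Mapping[str, float] | None = None,
    ) -> None:
        for analyte, rs in rates.items():
            if not rs > 0:
                raise DomainError(f"sampling rate for {analyte!r} must be > 0, got {rs}")
        self._rates = dict(rates)
        self.detection_limit_pg = dict(detection_limit_pg or {})

    @classmethod
    def default(cls) -> "SamplingRateTable":
        """Literature sampling rates for the 11-analyte panel."""
        return cls(DEFAULT_SAMPLING_RATES, INSTRUMENT_DETECTION_LIMIT_PG)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SamplingRateTable":
        df = pd.read_csv(path)
        limits = None
        if "detection_limit_pg" in df.columns:
            limits = dict(zip(df["analyte"], df["detection_limit_pg"].astype(float)))
        return cls(dict(zip(df["analyte"], df["rs_L_day"].astype(float))), limits)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"analyte": list(self._rates), "rs_L_day": list(self._rates.values())}
        )
        if self.detection_limit_pg:
            df["detection_limit_pg"] = [
                self.detection_limit_pg.get(a, math.nan) for a in self._rates
            ]
        df.to_csv(path, index=False)

    def __contains__(self, analyte: str) -> bool:
        return analyte in self._rates

    def __iter__(self):
        return iter(self._rates)

    def rs(self, analyte: str) -> float:
        try:
            return self._rates[analyte]
        except KeyError:
            raise MissingAnalyteError(
                f"no sampling rate for analyte {analyte!r}"
            ) from None


def substitute_nondetects(
    values: Sequence[float], reporting_limit: float, policy: str = "half_limit"
) -> tuple[float, ...]:
    """Replace replicate values below ``reporting_limit`` per the chosen policy.

    The reporting limit is expressed on the sorbent-concentration scale (ng/g).
    """
    if policy not in ND_POLICIES:
        raise DomainError(f"nd policy must be one of {ND_POLICIES}, got {policy!r}")
    if reporting_limit < 0:
        raise DomainError("reporting limit must be >= 0")
    sub = {"zero": 0.0, "half_limit": reporting_limit / 2.0, "limit": reporting_limit}[policy]
    out = tuple(sub if v < reporting_limit else float(v) for v in values)
    if out != tuple(float(v) for v in values):
        logger.info(
            "substituted %d non-detect replicate(s) below %g ng/g with %g (%s)",
            sum(v < reporting_limit for v in values), reporting_limit, sub, policy,
        )
    return out


def back_calculate_cw(
    m: SorbentMeasurement,
    rates: SamplingRateTable,
    reporting_limit: float | None = None,
    nd_policy: str = "half_limit",
) -> float:
    """Time-weighted average water concentration Cw (ng/L) from sorbent data.

    Replicates are averaged (arithmetic mean of Cs) before substitution into
    Cw = Cs * Ms / (Rs * t); the uptake model is linear in Cs so the order is
    immaterial.  ``reporting_limit`` (ng/g), if given, triggers non-detect
    substitution on each replicate first.
    """
    rs = rates.rs(m.analyte)
    reps = m.replicate_cs
    if reporting_limit is not None:
        reps = substitute_nondetects(reps, reporting_limit, nd_policy)
    cs_mean = float(np.mean(reps))
    return cs_mean * m.sorbent_mass / (rs * m.exposure_days)


def collective_excretion_rate(cw: float, plant: PlantRecord) -> float:
    """Collective excretion rate CER = Cw * Q * 1e-9, in g/day."""
    if cw < 0:
        raise DomainError(f"cw must be >= 0, got {cw}")
    return cw * plant.flow_rate * 1e-9


def per_capita(cer: float, plant: PlantRecord) -> float:
    """Per-capita load CER/pop in ug/person/day (g -> ug conversion)."""
    if cer < 0:
        raise DomainError(f"cer must be >= 0, got {cer}")
    return cer * 1e6 / plant.population


LOAD_COLUMNS = ("plant_id", "analyte", "cw_ng_L", "cer_g_day", "cer_per_capita_ug_day")


@dataclass
class AnalyteLoadTable:
    """Long-format table of derived loads: one row per plant x analyte."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(LOAD_COLUMNS) - set(self.frame.columns)
        if missing:
            raise DomainError(f"load table missing columns: {sorted(missing)}")
        for col in ("cw_ng_L", "cer_g_day", "cer_per_capita_ug_day"):
            if (self.frame[col] < 0).any():
                raise DomainError(f"negative values in {col}")

    def pivot(self, value: str = "cer_per_capita_ug_day") -> pd.DataFrame:
        """Wide plants x analytes matrix of the chosen quantity."""
        return self.frame.pivot(index="plant_id", columns="analyte", values=value)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnalyteLoadTable":
        return cls(pd.read_csv(path))


def compute_loads(
    plants: Iterable[PlantRecord],
    measurements: Iterable[SorbentMeasurement],
    rates: SamplingRateTable | None = None,
    reporting_limit: float | None = None,
    nd_policy: str = "half_limit",
) -> AnalyteLoadTable:
    """Back-calculate Cw, CER and CER per capita for every plant x analyte."""
    rates = rates if rates is not None else SamplingRateTable.default()
    by_id = {p.plant_id: p for p in plants}
    rows = []
    for m in measurements:
        if m.plant_id not in by_id:
            raise MissingAnalyteError(f"measurement for unknown plant {m.plant_id!r}")
        plant = by_id[m.plant_id]
        cw = back_calculate_cw(m, rates, reporting_limit, nd_policy)
        cer = collective_excretion_rate(cw, plant)
        rows.append(
            {
                "plant_id": m.plant_id,
                "analyte": m.analyte,
                "cw_ng_L": cw,
                "cer_g_day": cer,
                "cer_per_capita_ug_day": per_capita(cer, plant),
            }
        )
    frame = pd.DataFrame(rows, columns=list(LOAD_COLUMNS))
    return AnalyteLoadTable(frame)


def opioid_methadone_ratio(
    loads: AnalyteLoadTable,
    opioid: str,
    whitelist: Sequence[str] = OPIOID_WHITELIST,
) -> pd.Series:
    """Per-plant CER(opioid) / CER(methadone) ratio.

    Plants with zero methadone CER yield NaN (flagged missing, logged) rather
    than zero or infinity, and are dropped from downstream rank tests.
    """
    if opioid not in whitelist:
        raise DomainError(
            f"opioid must be one of {tuple(whitelist)}, got {opioid!r}"
        )
    cer = loads.pivot("cer_g_day")
    for name in (opioid, "methadone"):
        if name not in cer.columns:
            raise MissingAnalyteError(f"analyte {name!r} absent from load table")
    num, den = cer[opioid], cer["methadone"]
    ratio = num.where(den > 0) / den.where(den > 0)
    n_missing = int(ratio.isna().sum())
    if n_missing:
        logger.warning(
            "%d plant(s) have zero methadone CER; %s/methadone ratio flagged missing",
            n_missing, opioid,
        )
    ratio.name = f"{opioid}_to_methadone"
    return ratio


# ---------------------------------------------------------------------------
# CSV I/O for the plant / sorbent tables (UTF-8, '.' decimal, headered)

def write_plants(plants: Iterable[PlantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "plant_id": p.plant_id,
                "region": p.region,
                "population": p.population,
                "flow_rate_L_day": p.flow_rate,
            }
            for p in plants
        ]
    ).to_csv(path, index=False)


def read_plants(path: str | Path) -> list[PlantRecord]:
    df = pd.read_csv(path)
    return [
        PlantRecord(str(r.plant_id), str(r.region), float(r.population), float(r.flow_rate_L_day))
        for r in df.itertuples()
    ]


def write_sorbent(measurements: Iterable[SorbentMeasurement], path: str | Path) -> None:
    rows = []
    for m in measurements:
        for i, cs in enumerate(m.replicate_cs, start=1):
            rows.append(
                {
                    "plant_id": m.plant_id,
                    "analyte": m.analyte,
                    "replicate": i,
                    "cs_ng_g": cs,
                    "sorbent_mass_g": m.sorbent_mass,
                    "exposure_days": m.exposure_days,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sorbent(path: str | Path) -> list[SorbentMeasurement]:
    df = pd.read_csv(path)
    out = []
    for (plant_id, analyte), grp in df.groupby(["plant_id", "analyte"], sort=False):
        grp = grp.sort_values("replicate")
        out.append(
            SorbentMeasurement(
                str(plant_id),
                str(analyte),
                tuple(grp["cs_ng_g"].astype(float)),
                float(grp["sorbent_mass_g"].iloc[0]),
                float(grp["exposure_days"].iloc[0]),
            )
        )
    return out
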