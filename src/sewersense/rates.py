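"""Literature sampling rates and study-level constants.

POCIS sampling rates ``Rs`` (L/day) are analyte-specific calibration constants
taken from published uptake studies; they convert the mass of an analyte
accumulated on the sorbent into a time-weighted average water concentration.
The per-analyte medians and interquartile ranges of the observed water
concentrations (ng/L, across the 12 surveyed plants) are kept alongside
because the synthetic-data generator uses them to place its lognormal
marginals.
"""

from __future__ import annotations

#: Canonical analyte names, in panel column order.
ANALYTES: tuple[str, ...] = (
    "1,7-dimethylxanthine",
    "acetaminophen",
    "caffeine",
    "cotinine",
    "mdma",
    "meth",
    "morphine",
    "hydrocodone",
    "methadone",
    "oxycodone",
    "temazepam",
)

#: POCIS sampling rate Rs in L/day per analyte (literature values).
DEFAULT_SAMPLING_RATES: dict[str, float] = {
    "1,7-dimethylxanthine": 0.046,
    "acetaminophen": 0.048,
    "caffeine": 0.044,
    "cotinine": 0.034,
    "mdma": 0.222,
    "meth": 0.231,
    "morphine": 0.261,
    "hydrocodone": 0.050,
    "methadone": 0.408,
    "oxycodone": 0.152,
    "temazepam": 0.421,
}

#: Instrument detection limit per analyte, picograms on-column (LC-MS/MS).
INSTRUMENT_DETECTION_LIMIT_PG: dict[str, float] = {
    "1,7-dimethylxanthine": 1.74,
    "acetaminophen": 2.51,
    "caffeine": 4.24,
    "cotinine": 4.01,
    "mdma": 1.88,
    "meth": 2.37,
    "morphine": 8.13,
    "hydrocodone": 4.23,
    "methadone": 1.66,
    "oxycodone": 3.79,
    "temazepam": 1.67,
}

#: Observed time-weighted average water concentration per analyte across the
#: surveyed plants: (median, q1, q3) in ng/L.
CW_MEDIAN_IQR: dict[str, tuple[float, float, float]] = {
    "1,7-dimethylxanthine": (848.41, 572.09, 2148.04),
    "acetaminophen": (2449.80, 1363.87, 7337.70),
    "caffeine": (19078.02, 9424.05, 29977.54),
    "cotinine": (259.51, 128.79, 563.98),
    "mdma": (2.41, 0.24, 4.14),
    "meth": (63.03, 25.27, 181.71),
    "morphine": (11.36, 7.65, 40.80),
    "hydrocodone": (43.09, 19.66, 74.61),
    "methadone": (5.27, 1.49, 12.49),
    "oxycodone": (13.25, 6.36, 19.02),
    "temazepam": (8.14, 3.95, 17.97),
}

#: Default clustering feature set: the misuse-relevant analytes, excluding the
#: purely licit markers (caffeine, its metabolite, acetaminophen).
CLUSTER_FEATURES: tuple[str, ...] = (
    "cotinine",
    "mdma",
    "meth",
    "morphine",
    "hydrocodone",
    "methadone",
    "oxycodone",
    "temazepam",
)

#: Opioid analytes whose ratio to methadone is a treatment-access proxy.
OPIOID_WHITELIST: tuple[str, ...] = ("morphine", "hydrocodone", "oxycodone")
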