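"""Monte-Carlo experiments over the synthetic study conditions.

These drive the package end to end on replicate synthetic panels and report
operating characteristics: power of the regional Mann-Whitney comparison
under a planted methamphetamine effect, its type-I error under the null, and
the stepwise discriminant's recovery of a planted pair of regional
discriminators.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .discriminant import stepwise_select
from .pocis import compute_loads
from .rank_stats import regional_tests
from .rates import CW_MEDIAN_IQR
from .synthetic import SyntheticConfig, default_config, generate_panel, null_config

_MOD = 2**31 - 1


def _seed(base: int, i: int) -> int:
    return (base + i) % _MOD


def meth_power(
    n_panels: int = 500,
    n_west: int = 6,
    n_east: int = 6,
    multiplier: float = 10.0,
    alpha: float = 0.05,
    seed_base: int = 0,
) -> float:
    """Fraction of panels where the regional Mann-Whitney on METH CER/pop
    rejects at ``alpha`` in the west-elevated direction (negative z)."""
    base = default_config(0)
    base = replace(
        base,
        n_plants_west=n_west,
        n_plants_east=n_east,
        region_multiplier={**base.region_multiplier, "meth": multiplier},
    )
    hits = 0
    for i in range(n_panels):
        cfg = replace(base, seed=_seed(seed_base, i))
        plants, measurements, _ = generate_panel(cfg)
        loads = compute_loads(plants, measurements)
        tests = regional_tests(loads, plants)
        row = tests[tests["analyte"] == "meth"].iloc[0]
        hits += row["p_value"] <= alpha and row["z"] < 0
    return hits / n_panels


def null_type1(
    n_panels: int = 2000,
    analyte: str = "meth",
    alpha: float = 0.05,
    seed_base: int = 0,
) -> float:
    """Rejection rate of the regional Mann-Whitney at ``alpha`` when every
    regional multiplier is 1 (pure null, 7 west + 5 east)."""
    base = null_config(0)
    hits = 0
    for i in range(n_panels):
        cfg = replace(base, seed=_seed(seed_base, i))
        plants, measurements, _ = generate_panel(cfg)
        loads = compute_loads(plants, measurements)
        tests = regional_tests(loads, plants)
        hits += tests[tests["analyte"] == analyte].iloc[0]["p_value"] <= alpha
    return hits / n_panels


def stepwise_pair_recovery(
    n_seeds: int = 200,
    effect_sd: float = 3.0,
    rho: float = 0.75,
    log_sd: float = 0.5,
    seed_base: int = 0,
) -> float:
    """Fraction of panels where stepwise selection returns exactly the two
    planted discriminators.

    The panel carries exactly two analytes, methadone and temazepam, with
    opposite regional effects of ``effect_sd`` within-group log-SD and
    within-group log correlation ``rho`` — the configuration the surveyed
    data exhibit (a strongly correlated pair with opposite regional shifts).
    """
    corr = np.array([[1.0, rho], [rho, 1.0]])
    planted = {"methadone", "temazepam"}
    hits = 0
    for i in range(n_seeds):
        cfg = SyntheticConfig(
            n_plants_west=6,
            n_plants_east=6,
            analytes=("methadone", "temazepam"),
            log_mean={
                "methadone": math.log(CW_MEDIAN_IQR["methadone"][0]),
                "temazepam": math.log(CW_MEDIAN_IQR["temazepam"][0]),
            },
            log_sd={"methadone": log_sd, "temazepam": log_sd},
            region_multiplier={
                "methadone": math.exp(-effect_sd * log_sd),
                "temazepam": math.exp(effect_sd * log_sd),
            },
            correlation=corr,
            seed=_seed(seed_base, i),
        )
        plants, measurements, _ = generate_panel(cfg)
        loads = compute_loads(plants, measurements)
        wide = loads.pivot("cer_per_capita_ug_day")
        region = {p.plant_id: p.region for p in plants}
        labels = [region[pid] for pid in wide.index]
        selected, _ = stepwise_select(wide, labels)
        hits += set(selected) == planted
    return hits / n_seeds
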