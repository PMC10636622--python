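"""End-to-end pipeline: loads -> rank statistics -> discriminant -> clustering.

A single :class:`RunConfig` (YAML/JSON-loadable) drives the whole analysis on
either a synthetic panel or on-disk CSV tables.  Every convention-level choice
(non-detect policy, priors, continuity correction, tie-breaks) is echoed into
the report header so a run is self-describing, and identical config + seed
produce a bitwise-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import clustering as clus
from . import rank_stats as rs
from .discriminant import StepwiseDiscriminantAnalysis
from .errors import ConfigError
from .pocis import (
    AnalyteLoadTable,
    SamplingRateTable,
    compute_loads,
    opioid_methadone_ratio,
    read_plants,
    read_sorbent,
)
from .rates import CLUSTER_FEATURES, OPIOID_WHITELIST
from .synthetic import SyntheticConfig, default_config, generate_panel, write_panel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full surveillance-analysis run."""

    # inputs: either a synthetic config, or the three CSV paths
    synthetic: SyntheticConfig | None = None
    plants_csv: str | None = None
    sorbent_csv: str | None = None
    rates_csv: str | None = None
    # load stage
    nd_policy: str = "half_limit"
    reporting_limit: float | None = None
    # statistics stage
    continuity: bool = True
    group_order: tuple[str, str] = ("east", "west")
    fdr: bool = False
    opioids: tuple[str, ...] = OPIOID_WHITELIST
    # discriminant stage
    threshold_enter: float = 0.15
    threshold_stay: float = 0.15
    priors: str = "equal"
    loocv_reselect: bool = False
    discriminant_candidates: tuple[str, ...] | None = None
    # clustering stage
    cluster_features: tuple[str, ...] = CLUSTER_FEATURES
    # run plumbing
    output_dir: str = "sewersense_run"
    seed: int = 0

    def validate(self) -> None:
        for thr in (self.threshold_enter, self.threshold_stay):
            if not 0.0 < thr < 1.0:
                raise ConfigError(f"thresholds must be in (0, 1), got {thr}")
        if not self.cluster_features:
            raise ConfigError("cluster feature list must be non-empty")
        if self.synthetic is None:
            if not (self.plants_csv and self.sorbent_csv):
                raise ConfigError(
                    "either a synthetic config or plants_csv + sorbent_csv is required"
                )
            for p in (self.plants_csv, self.sorbent_csv, self.rates_csv):
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"input file does not exist: {p}")
        else:
            self.synthetic.validate()

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = d["synthetic"]
            d["synthetic"] = (
                default_config(int(d.get("seed", 0)))
                if syn == "default"
                else SyntheticConfig.from_dict(syn)
            )
        for key in ("group_order", "opioids", "cluster_features", "discriminant_candidates"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the (JSON-serialisable) run report.

    Writes loads.csv, corr.csv, tests.csv, ratios.csv, lda_report.json,
    tree.json, tree.nwk, report.json and summary.txt into the output
    directory.  Any stage failure aborts with the stage named in the log.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        rates = (
            SamplingRateTable.from_csv(config.rates_csv)
            if config.rates_csv
            else SamplingRateTable.default()
        )
        if config.synthetic is not None:
            plants, measurements, truth = generate_panel(config.synthetic, rates)
            write_panel(plants, measurements, truth, outdir)
        else:
            plants = read_plants(config.plants_csv)
            measurements = read_sorbent(config.sorbent_csv)

        stage = "loads"
        loads = compute_loads(
            plants, measurements, rates, config.reporting_limit, config.nd_policy
        )
        loads.to_csv(outdir / "loads.csv")

        stage = "rank statistics"
        corr = rs.correlation_matrix(loads)
        corr.to_csv(outdir / "corr.csv", index=False)
        tests = rs.regional_tests(
            loads,
            plants,
            group_order=config.group_order,
            continuity=config.continuity,
            fdr=config.fdr,
        )
        tests.to_csv(outdir / "tests.csv", index=False)

        stage = "opioid/methadone ratios"
        ratios = {
            f"{op}_to_methadone": opioid_methadone_ratio(loads, op, config.opioids)
            for op in config.opioids
        }
        ratio_tests = rs.ratio_regional_tests(
            ratios, plants, config.group_order, config.continuity
        )
        ratio_tests.to_csv(outdir / "ratios.csv", index=False)

        stage = "discriminant analysis"
        wide = loads.pivot("cer_per_capita_ug_day")
        region = {p.plant_id: p.region for p in plants}
        labels = [region[pid] for pid in wide.index]
        sda = StepwiseDiscriminantAnalysis(
            wide,
            labels,
            threshold_enter=config.threshold_enter,
            threshold_stay=config.threshold_stay,
            priors=config.priors,
            candidates=list(config.discriminant_candidates)
            if config.discriminant_candidates is not None
            else None,
        )
        disc = sda.fit(loocv_reselect=config.loocv_reselect)
        (outdir / "lda_report.json").write_text(
            json.dumps(disc.to_dict(), indent=2, sort_keys=True)
        )

        stage = "clustering"
        features = [f for f in config.cluster_features if f in wide.columns]
        missing = set(config.cluster_features) - set(features)
        if missing:
            logger.warning("cluster features absent from panel, skipped: %s",
                           sorted(missing))
        ward = clus.WardClustering(wide[features]).fit()
        ward.to_json(outdir / "tree.json")
        ward.to_newick(outdir / "tree.nwk")
    except Exception:
        logger.exception("pipeline aborted in stage: %s", stage)
        raise

    report = {
        "header": {
            "seed": config.seed,
            "nd_policy": config.nd_policy,
            "reporting_limit": config.reporting_limit,
            "continuity_correction": config.continuity,
            "group_order": list(config.group_order),
            "fdr": config.fdr,
            "threshold_enter": config.threshold_enter,
            "threshold_stay": config.threshold_stay,
            "priors": config.priors,
            "loocv_reselect": config.loocv_reselect,
            "cluster_features": list(features),
            "tie_breaks": "stepwise: input column order; ward: smallest member id",
            "synthetic": None
            if config.synthetic is None
            else config.synthetic.to_dict(),
        },
        "n_plants": len(plants),
        "loads_rows": len(loads.frame),
        "correlations": corr.to_dict(orient="records"),
        "regional_tests": tests.to_dict(orient="records"),
        "ratio_tests": ratio_tests.to_dict(orient="records"),
        "discriminant": disc.to_dict(),
        "clustering": ward.to_dict(),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    summary = [
        f"sewersense run ({len(plants)} plants)",
        "",
        disc.summary(),
        "",
        ward.summary(),
    ]
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    return report
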