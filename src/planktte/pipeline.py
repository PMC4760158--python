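"""End-to-end orchestration: particle CSVs in, analysis tables out.

A :class:`PipelineConfig` (read from YAML or JSON) names the input files and
carries every estimation setting — biomass conversion factors, size-diversity
options, the model formulas and bootstrap settings — plus a single seed that
drives all stochastic stages through independently derived streams.  Each
output file embeds the SHA-256 hash of the canonical configuration as a
comment header so results can be traced to the exact settings that produced
them; a ``run_manifest.json`` records hash, seed and output names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry, transfer_metrics
from .env_covariates import env_table, read_env_csv
from .errors import ConfigurationError
from .inference import dredge_all_subsets, rank_univariate
from .morphometry import BiomassConversionTable, GroupConversion, read_particles_csv
from .size_diversity import SizeDiversityOptions, size_diversity_table
from .transfer_metrics import bootstrap_proxy_uncertainty, pppr_table, read_cohorts_csv

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, estimation settings and the master seed for one analysis run."""

    particles_csv: str
    env_csv: str | None = None
    cohorts_csv: str | None = None
    conversion: BiomassConversionTable = field(default_factory=BiomassConversionTable)
    diversity: SizeDiversityOptions = field(default_factory=SizeDiversityOptions)
    response: str = "log10_ppbr"
    grouping: str = "station_id"
    rank_terms: tuple[str, ...] = ("prey_mu", "predator_mu")
    dredge_terms: tuple[str, ...] = ("prey_mu", "predator_mu", "prey_mu:predator_mu")
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        conv_raw = raw.pop("conversion", None)
        if conv_raw is not None:
            def _gc(d):
                if d is None:
                    raise ConfigurationError(
                        "conversion must configure both 'prey' and 'predator' factors"
                    )
                return GroupConversion(**d)
            raw["conversion"] = BiomassConversionTable(
                prey=_gc(conv_raw.get("prey")),
                predator=_gc(conv_raw.get("predator")),
                shrinkage_factor=conv_raw.get("shrinkage_factor", 1.0),
            )
        div_raw = raw.pop("diversity", None)
        if div_raw is not None:
            raw["diversity"] = SizeDiversityOptions(**div_raw)
        for key in ("rank_terms", "dredge_terms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"configuration file {path} is not a mapping")
        return cls.from_dict(raw)

    def canonical_json(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            return obj

        return json.dumps(encode(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _validate(config: PipelineConfig) -> None:
    if not Path(config.particles_csv).exists():
        raise ConfigurationError(f"particle CSV not found: {config.particles_csv}")
    for label, p in (("env_csv", config.env_csv), ("cohorts_csv", config.cohorts_csv)):
        if p is not None and not Path(p).exists():
            raise ConfigurationError(f"{label} not found: {p}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis; returns a manifest of the written artifacts.

    Stages: read + validate -> carnivore filter/shrinkage/biomass ->
    per-sample size diversity -> sample summary table -> univariate
    ranking -> all-subsets AICc dredge -> (optional) production-ratio
    bootstrap.  Deterministic given the configuration seed.
    """
    _validate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    particles = read_particles_csv(config.particles_csv)
    communities = morphometry.frame_to_communities(particles)
    processed = [morphometry.process_sample(c, config.conversion) for c in communities]
    flat = morphometry.communities_to_frame(processed)

    diversity = size_diversity_table(flat, config.diversity)

    env = None
    if config.env_csv is not None:
        env = env_table(read_env_csv(config.env_csv))

    summary = transfer_metrics.build_sample_summaries(processed, diversity, env)
    _write_csv(summary, outdir / "sample_summary.csv", chash, config.seed)

    rank_table, _ = rank_univariate(
        config.response, list(config.rank_terms), config.grouping, summary
    )
    _write_csv(rank_table, outdir / "univariate_ranking.csv", chash, config.seed)

    dredge_table, best, _ = dredge_all_subsets(
        config.response, list(config.dredge_terms), config.grouping, summary
    )
    _write_csv(dredge_table, outdir / "dredge_ranking.csv", chash, config.seed)
    _write_csv(best.params, outdir / "best_model.csv", chash, config.seed)

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "n_samples": int(len(summary)),
        "n_stations": int(summary["station_id"].nunique()),
        "best_model": best.spec.formula,
        "best_aicc": best.aicc,
        "outputs": ["sample_summary.csv", "univariate_ranking.csv",
                    "dredge_ranking.csv", "best_model.csv"],
    }

    if config.cohorts_csv is not None:
        pppr = pppr_table(read_cohorts_csv(config.cohorts_csv))
        paired = summary.merge(pppr, on="sample_id", how="inner")
        if len(paired) >= 3:
            rng = np.random.default_rng([config.seed, 0xB007])
            boot = bootstrap_proxy_uncertainty(
                paired[["log10_ppbr", "log10_pppr"]].to_numpy(),
                n_boot=config.n_boot, seed=rng,
            )
            report = {
                "config_hash": chash,
                "seed": config.seed,
                "n_pairs": boot.n,
                "r": boot.r,
                "ci95": [boot.ci_low, boot.ci_high],
                "n_boot": boot.n_boot,
            }
            with open(outdir / "bootstrap_report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            manifest["outputs"].append("bootstrap_report.json")
        else:
            logger.warning("fewer than 3 proxy/production pairs; bootstrap skipped")

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
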