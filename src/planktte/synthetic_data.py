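"""Synthetic station-structured plankton surveys with known ground truth.

No field data ship with this package, so every downstream stage is tested
against generated communities whose size distributions, regression structure
and random-effect variance are known by construction.

Two generators are provided:

* :func:`simulate_individuals` emulates an imaging survey: per sample and
  trophic group it draws individual log-biovolumes from a configurable
  mixture of normals (mixtures allow the bimodality that stresses the KDE),
  then back-computes major/minor ellipse axes consistent with the
  prolate-spheroid volume and a group-specific aspect-ratio model
  (mesozooplankton elongated, nano-microplankton near-spherical).  Defaults
  mirror a shelf-sea survey: 40 stations, ~3 samples each, 3500 prey and
  2000 predator individuals measured per sample.

* :func:`simulate_lmm_dataset` generates the regression test surface: a
  table of observations grouped into stations with known fixed slopes,
  random-intercept standard deviation and residual noise (defaults: 106
  observations over 40 stations, the survey's layout).

Both are bit-reproducible given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .env_covariates import EnvProfile
from .errors import ConfigurationError
from .morphometry import (
    PARTICLE_COLUMNS,
    PREDATOR,
    PREY,
    SampleCommunity,
    communities_to_frame,
)

#: (weight, mean, sd) mixture components on the natural-log biovolume scale
#: (log um^3).  Prey span the nano-micro range; predators the mesozooplankton
#: range; both bimodal to exercise the density estimator.
DEFAULT_PREY_MIXTURE = ((0.6, 5.5, 1.2), (0.4, 8.5, 1.5))
DEFAULT_PREDATOR_MIXTURE = ((0.7, 16.0, 1.3), (0.3, 19.0, 1.0))


@dataclass(frozen=True)
class EnvSimModel:
    """Gaussian model for per-sample surface conditions and nutrient profiles.

    Surface values are drawn multivariate-normal (station mean + sample
    noise); nutrient concentrations increase linearly with depth down the
    profile and are clipped at zero.  Order of variables: sst, sss, no3,
    po4, sio3.
    """

    means: tuple[float, ...] = (26.0, 33.5, 2.0, 0.15, 5.0)
    sds: tuple[float, ...] = (2.0, 0.8, 1.0, 0.06, 2.0)
    correlation: tuple[tuple[float, ...], ...] | None = None
    mld_mean_m: float = 25.0
    mld_sd_m: float = 8.0
    depth_step_m: float = 10.0
    nutrient_depth_slope: float = 0.03  # relative increase per metre

    def cov(self) -> np.ndarray:
        sds = np.asarray(self.sds, float)
        corr = (
            np.asarray(self.correlation, float)
            if self.correlation is not None
            else np.eye(len(sds))
        )
        return corr * np.outer(sds, sds)


@dataclass(frozen=True)
class CommunitySimConfig:
    """Survey-shaped community generator settings."""

    n_stations: int = 40
    samples_per_station: int = 3
    n_prey_individuals: int = 3500
    n_predator_individuals: int = 2000
    prey_logvol_mixture: tuple[tuple[float, float, float], ...] = DEFAULT_PREY_MIXTURE
    predator_logvol_mixture: tuple[tuple[float, float, float], ...] = DEFAULT_PREDATOR_MIXTURE
    prey_aspect_range: tuple[float, float] = (1.0, 1.5)
    predator_aspect_range: tuple[float, float] = (2.0, 6.0)
    carnivore_fraction: float = 0.1
    weight_log_mean: float = 0.7   # lognormal abundance weights, ind. m^-3
    weight_log_sd: float = 0.7
    env_model: EnvSimModel = field(default_factory=EnvSimModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_stations", "samples_per_station",
                     "n_prey_individuals", "n_predator_individuals"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        for label, mix in (("prey", self.prey_logvol_mixture),
                           ("predator", self.predator_logvol_mixture)):
            weights = [w for w, _, _ in mix]
            if not np.isclose(sum(weights), 1.0):
                raise ConfigurationError(f"{label} mixture weights must sum to 1")
            if any(w < 0 for w in weights) or any(sd <= 0 for _, _, sd in mix):
                raise ConfigurationError(f"{label} mixture needs weights >= 0 and sds > 0")
        for label, (lo, hi) in (("prey", self.prey_aspect_range),
                                ("predator", self.predator_aspect_range)):
            if not (1.0 <= lo <= hi):
                raise ConfigurationError(f"{label} aspect range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.carnivore_fraction <= 1.0:
            raise ConfigurationError("carnivore_fraction must lie in [0, 1]")


def _draw_mixture(rng: np.random.Generator, mixture, n: int) -> np.ndarray:
    weights = np.array([w for w, _, _ in mixture])
    means = np.array([m for _, m, _ in mixture])
    sds = np.array([s for _, _, s in mixture])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    return rng.normal(means[comp], sds[comp])


def _axes_from_logvol(rng: np.random.Generator, logvol: np.ndarray,
                      aspect_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Invert EllipVol = (pi/6) M m^2 given a log-uniform aspect ratio r = M/m."""
    lo, hi = aspect_range
    ratio = np.exp(rng.uniform(np.log(lo), np.log(hi), size=logvol.size))
    vol = np.exp(logvol)
    minor = (6.0 * vol / (np.pi * ratio)) ** (1.0 / 3.0)
    return ratio * minor, minor


def _simulate_env(rng: np.random.Generator, model: EnvSimModel,
                  station_shift: np.ndarray) -> EnvProfile:
    surface = rng.multivariate_normal(np.asarray(model.means) + station_shift,
                                      model.cov())
    sst, sss = surface[0], surface[1]
    nutrients = np.clip(surface[2:], 0.0, None)
    mld = max(float(rng.normal(model.mld_mean_m, model.mld_sd_m)), 2 * model.depth_step_m)
    depths = np.arange(0.0, mld + model.depth_step_m, model.depth_step_m)
    shape = 1.0 + model.nutrient_depth_slope * depths
    return EnvProfile(
        depths=depths,
        no3=np.clip(nutrients[0] * shape, 0.0, None),
        po4=np.clip(nutrients[1] * shape, 0.0, None),
        sio3=np.clip(nutrients[2] * shape, 0.0, None),
        sst=float(sst),
        sss=float(sss),
        mld=mld,
    )


def simulate_individuals(config: CommunitySimConfig) -> list[SampleCommunity]:
    """Generate per-individual particle tables for every station/sample pair.

    Within each sample and group, log-biovolumes are drawn from the
    configured mixture and converted to major/minor axes that reproduce the
    drawn volumes exactly under the prolate-spheroid formula.  A
    ``carnivore_fraction`` of predators is flagged carnivorous; abundance
    weights are lognormal.  Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    communities: list[SampleCommunity] = []
    env_cov_sds = np.asarray(config.env_model.sds, float)
    for s in range(config.n_stations):
        station_id = f"ST{s + 1:03d}"
        station_shift = rng.normal(0.0, 0.5 * env_cov_sds)
        for j in range(config.samples_per_station):
            sample_id = f"{station_id}-{j + 1:02d}"
            cruise_id = f"CR{j + 1:02d}"
            frames = []
            for group, n, mixture, aspect in (
                (PREY, config.n_prey_individuals,
                 config.prey_logvol_mixture, config.prey_aspect_range),
                (PREDATOR, config.n_predator_individuals,
                 config.predator_logvol_mixture, config.predator_aspect_range),
            ):
                logvol = _draw_mixture(rng, mixture, n)
                major, minor = _axes_from_logvol(rng, logvol, aspect)
                carnivore = (
                    rng.random(n) < config.carnivore_fraction
                    if group == PREDATOR
                    else np.zeros(n, dtype=bool)
                )
                weights = rng.lognormal(config.weight_log_mean, config.weight_log_sd, n)
                frames.append(
                    pd.DataFrame(
                        dict(
                            sample_id=sample_id,
                            station_id=station_id,
                            cruise_id=cruise_id,
                            group=group,
                            is_carnivore=carnivore,
                            major_um=major,
                            minor_um=minor,
                            weight_per_m3=weights,
                        )
                    )
                )
            env = _simulate_env(rng, config.env_model, station_shift)
            communities.append(
                SampleCommunity(sample_id, station_id, cruise_id,
                                pd.concat(frames, ignore_index=True), env)
            )
    return communities


@dataclass(frozen=True)
class CovariateModel:
    """Multivariate-normal covariate generator (shared correlation rho)."""

    means: Mapping[str, float]
    sds: Mapping[str, float]
    rho: float = 0.0


@dataclass(frozen=True)
class LmmSimConfig:
    """Ground-truth regression structure for mixed-model recovery tests."""

    n_obs: int = 106
    n_groups: int = 40
    fixed_effects: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    random_intercept_sd: float = 0.3
    residual_sd: float = 0.4
    covariates: CovariateModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obs < self.n_groups:
            raise ConfigurationError("n_obs must be >= n_groups")
        if self.n_groups < 1:
            raise ConfigurationError("need at least one group")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")


def simulate_lmm_dataset(config: LmmSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate an analysis table with known mixed-model parameters.

    Returns ``(data, truth)``: data has one row per observation with all
    covariates, a ``station`` label and the response ``y``; truth records
    the generating intercept, slopes and variance components.  Interaction
    terms may be named 'A:B' (or 'A×B') in ``fixed_effects``; the product
    column is formed from the named covariates.
    """
    rng = np.random.default_rng(config.seed)
    slopes = {k.replace("×", ":"): v for k, v in config.fixed_effects.items()}
    main_names = sorted({p for t in slopes for p in (t.split(":") if ":" in t else [t])})

    cov_model = config.covariates
    if cov_model is None:
        cov_model = CovariateModel(
            means={n: 0.0 for n in main_names}, sds={n: 1.0 for n in main_names}
        )
    names = list(cov_model.means)
    for n in main_names:
        if n not in names:
            raise ConfigurationError(f"no covariate distribution for term {n!r}")
    d = len(names)
    corr = np.full((d, d), cov_model.rho)
    np.fill_diagonal(corr, 1.0)
    sds = np.array([cov_model.sds[n] for n in names])
    X = rng.multivariate_normal(
        np.array([cov_model.means[n] for n in names]), corr * np.outer(sds, sds),
        size=config.n_obs,
    )
    data = pd.DataFrame(X, columns=names)

    # near-even assignment of observations to stations
    base = np.repeat(np.arange(config.n_groups), config.n_obs // config.n_groups)
    extra = np.arange(config.n_obs - base.size)
    group_idx = np.sort(np.concatenate([base, extra]))
    data["station"] = np.array([f"ST{g + 1:03d}" for g in group_idx])

    station_effects = rng.normal(0.0, config.random_intercept_sd, config.n_groups)
    y = np.full(config.n_obs, config.intercept, dtype=float)
    for term, slope in slopes.items():
        parents = term.split(":") if ":" in term else [term]
        col = np.prod([data[p].to_numpy() for p in parents], axis=0)
        y += slope * col
    y += station_effects[group_idx]
    y += rng.normal(0.0, config.residual_sd, config.n_obs)
    data["y"] = y

    truth = dict(
        intercept=config.intercept,
        slopes=slopes,
        random_intercept_sd=config.random_intercept_sd,
        residual_sd=config.residual_sd,
        n_obs=config.n_obs,
        n_groups=config.n_groups,
        seed=config.seed,
    )
    return data, truth


def write_particles_csv(communities: Sequence[SampleCommunity], path,
                        header_comment: str | None = None) -> None:
    """Write all communities to one particle CSV (schema PARTICLE_COLUMNS)."""
    df = communities_to_frame(communities)[PARTICLE_COLUMNS]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def truth_to_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
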