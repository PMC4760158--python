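"""Individual morphometrics: ellipsoidal biovolume, shrinkage correction,
carbon biomass conversion, carnivore filtering and per-sample biomass totals.

Each measured plankton particle is described by the major (``M``) and minor
(``m``) axes, in micrometres, of the ellipse enclosing its imaged area.
Because only two axes are available, the third body axis is assumed equal to
the minor one, giving the prolate-spheroid biovolume

    EllipVol = (pi / 6) * M * m**2    [um^3]

This ellipsoidal volume is preferred over the equivalent spherical diameter
because mesozooplankton are typically elongated; a sphere model would
systematically inflate their volume.

Carbon biomass is obtained from biovolume through configurable power laws
``biomass = factor * EllipVol**exponent`` (literature conversion factors
differ between nano-microplankton and mesozooplankton, and may be refined per
taxon class).  Preserved nano-microplankton cells shrink, so their volumes are
multiplied by a shrinkage factor before conversion.  The processing order is
fixed: carnivore filter -> shrinkage -> biomass conversion -> aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

PREY = "prey"
PREDATOR = "predator"
GROUPS = (PREY, PREDATOR)

#: Column schema of a particle table (one row per measured individual).
PARTICLE_COLUMNS = [
    "sample_id",
    "station_id",
    "cruise_id",
    "group",
    "is_carnivore",
    "major_um",
    "minor_um",
    "weight_per_m3",
]


@dataclass(frozen=True)
class GroupConversion:
    """Power-law biovolume (um^3) to carbon biomass (mg C) conversion."""

    factor: float
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ConfigurationError(f"conversion factor must be > 0, got {self.factor}")


@dataclass(frozen=True)
class BiomassConversionTable:
    """Per-group conversion factors plus the prey shrinkage correction.

    ``shrinkage_factor`` multiplies prey (nano-microplankton) biovolumes to
    undo preservation shrinkage; predators are exempt.  The default of 1.0 is
    a deliberate placeholder — supply a literature value for real data.
    ``class_overrides`` optionally refines the conversion per taxon class.
    """

    prey: GroupConversion = field(default_factory=lambda: GroupConversion(1.0, 1.0))
    predator: GroupConversion = field(default_factory=lambda: GroupConversion(1.0, 1.0))
    shrinkage_factor: float = 1.0
    class_overrides: Mapping[str, GroupConversion] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shrinkage_factor <= 0:
            raise ConfigurationError(
                f"shrinkage_factor must be > 0, got {self.shrinkage_factor}"
            )
        if self.shrinkage_factor == 1.0:
            logger.warning(
                "shrinkage_factor is 1.0 (no preservation-shrinkage correction); "
                "this default is a placeholder, not a literature value"
            )

    def for_group(self, group: str, taxon_class: str | None = None) -> GroupConversion:
        if taxon_class is not None:
            if taxon_class not in self.class_overrides:
                raise ConfigurationError(f"no conversion configured for class {taxon_class!r}")
            return self.class_overrides[taxon_class]
        if group == PREY:
            return self.prey
        if group == PREDATOR:
            return self.predator
        raise ConfigurationError(f"unknown trophic group {group!r}")


@dataclass
class SampleCommunity:
    """All particles measured in one station/date sample pair.

    ``particles`` is a DataFrame following :data:`PARTICLE_COLUMNS` (plus any
    derived columns); every row must share this community's ``sample_id``.
    """

    sample_id: str
    station_id: str
    cruise_id: str
    particles: pd.DataFrame
    env: "object | None" = None  # EnvProfile, kept loose to avoid a cycle

    def __post_init__(self) -> None:
        if len(self.particles) and not (self.particles["sample_id"] == self.sample_id).all():
            raise ValidationError(
                f"particles of community {self.sample_id!r} carry foreign sample_ids"
            )

    @property
    def prey(self) -> pd.DataFrame:
        return self.particles[self.particles["group"] == PREY]

    @property
    def predators(self) -> pd.DataFrame:
        return self.particles[self.particles["group"] == PREDATOR]


def ellipsoid_volume(major_um, minor_um):
    """Prolate-spheroid biovolume (pi/6)*M*m^2 in um^3.

    Accepts scalars or arrays; requires M >= m > 0 elementwise.  Reduces to
    the sphere volume (pi/6)*d^3 when M == m.
    """
    M = np.asarray(major_um, dtype=float)
    m = np.asarray(minor_um, dtype=float)
    if np.any(m <= 0) or np.any(M <= 0):
        raise ValidationError("axes must be strictly positive")
    if np.any(M < m):
        raise ValidationError("major axis must be >= minor axis")
    out = (np.pi / 6.0) * M * m**2
    return float(out) if out.ndim == 0 else out


def apply_shrinkage(volume_um3, group, table: BiomassConversionTable):
    """Multiply prey volumes by the shrinkage factor; predators pass through."""
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v <= 0):
        raise ValidationError("biovolume must be > 0")
    g = np.asarray(group)
    unknown = ~np.isin(g, GROUPS)
    if np.any(unknown):
        raise ConfigurationError(f"unknown trophic group(s): {np.unique(g[unknown])!r}")
    out = np.where(g == PREY, v * table.shrinkage_factor, v)
    return float(out) if out.ndim == 0 else out


def biomass_from_volume(volume_um3, group, table: BiomassConversionTable,
                        taxon_class=None):
    """Carbon biomass (mg C) = factor * biovolume**exponent, per group/class."""
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v <= 0):
        raise ValidationError("biovolume must be > 0")
    g = np.asarray(group)
    out = np.empty_like(v, dtype=float)
    if g.ndim == 0:
        conv = table.for_group(str(g), taxon_class)
        return float(conv.factor * v**conv.exponent)
    for grp in np.unique(g):
        conv = table.for_group(str(grp), taxon_class)
        mask = g == grp
        out[mask] = conv.factor * v[mask] ** conv.exponent
    return out


def remove_carnivores(sample: SampleCommunity) -> SampleCommunity:
    """Drop carnivorous predators (prey rows untouched); logs the count."""
    flagged = (sample.particles["group"] == PREDATOR) & sample.particles["is_carnivore"]
    n = int(flagged.sum())
    if n:
        logger.info("sample %s: removed %d carnivorous predators", sample.sample_id, n)
    return SampleCommunity(
        sample.sample_id,
        sample.station_id,
        sample.cruise_id,
        sample.particles[~flagged].reset_index(drop=True),
        sample.env,
    )


def derive_biomass(particles: pd.DataFrame, table: BiomassConversionTable) -> pd.DataFrame:
    """Add ``biovolume_um3`` (shrinkage-corrected) and ``biomass_mgc`` columns.

    Shrinkage is applied before the biomass power law, so the two commute only
    for exponent 1.
    """
    df = particles.copy()
    raw = ellipsoid_volume(df["major_um"].to_numpy(), df["minor_um"].to_numpy())
    vol = apply_shrinkage(raw, df["group"].to_numpy(), table)
    df["biovolume_um3"] = vol
    df["biomass_mgc"] = biomass_from_volume(vol, df["group"].to_numpy(), table)
    return df


def process_sample(sample: SampleCommunity, table: BiomassConversionTable) -> SampleCommunity:
    """Carnivore filter, then shrinkage + biomass derivation, in that order."""
    filtered = remove_carnivores(sample)
    return SampleCommunity(
        filtered.sample_id,
        filtered.station_id,
        filtered.cruise_id,
        derive_biomass(filtered.particles, table),
        filtered.env,
    )


def total_biomass(particles: pd.DataFrame, group: str) -> float:
    """Total standing stock of one trophic group, mg C m^-3.

    Sum over the group of abundance_weight * individual biomass; raises on an
    empty group because the predator:prey ratio would be undefined downstream.
    """
    sub = particles[particles["group"] == group]
    if not len(sub):
        raise ValidationError(f"no individuals in group {group!r}: biomass undefined")
    if "biomass_mgc" not in sub:
        raise ValidationError("biomass not derived; call derive_biomass first")
    w = sub["weight_per_m3"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValidationError("abundance weights must be > 0")
    return float(np.sum(w * sub["biomass_mgc"].to_numpy(dtype=float)))


def communities_to_frame(communities: Iterable[SampleCommunity]) -> pd.DataFrame:
    """Concatenate the particle tables of several communities."""
    frames = [c.particles for c in communities]
    if not frames:
        return pd.DataFrame(columns=PARTICLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def frame_to_communities(particles: pd.DataFrame) -> list[SampleCommunity]:
    """Split a flat particle table into per-sample communities."""
    out = []
    for sid, sub in particles.groupby("sample_id", sort=True):
        sub = sub.reset_index(drop=True)
        out.append(
            SampleCommunity(
                sample_id=str(sid),
                station_id=str(sub["station_id"].iloc[0]),
                cruise_id=str(sub["cruise_id"].iloc[0]),
                particles=sub,
            )
        )
    return out


def read_particles_csv(path) -> pd.DataFrame:
    """Read a particle table (schema :data:`PARTICLE_COLUMNS`); '#' lines are comments."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"particle CSV missing columns: {missing}")
    df["is_carnivore"] = df["is_carnivore"].astype(bool)
    return df
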