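"""Environmental predictors: depth-integrated nutrients above the mixed
layer, log-transformed nutrient concentrations, and surface hydrography.

"Depth-integrated" is implemented as the depth-weighted *mean* concentration
(uM) between the shallowest measurement and the mixed layer depth (MLD),
i.e. the trapezoid integral divided by the integration span, so that the
result stays on the concentration scale used by the regressions rather than
becoming an areal stock (mmol m^-2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

NUTRIENTS = ("no3", "po4", "sio3")


@dataclass(frozen=True)
class EnvProfile:
    """One sample's hydrographic context.

    depths (m, strictly increasing, shallowest <= mld) index the nutrient
    arrays; sst in deg C, sss in practical salinity units, mld in m.
    """

    depths: np.ndarray
    no3: np.ndarray
    po4: np.ndarray
    sio3: np.ndarray
    sst: float
    sss: float
    mld: float

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", d)
        for name in NUTRIENTS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != d.shape:
                raise ValidationError(f"{name} must align with depths")
            if np.any(arr < 0):
                raise ValidationError(f"{name} concentrations must be >= 0")
            object.__setattr__(self, name, arr)
        if d.size == 0 or np.any(np.diff(d) <= 0):
            raise ValidationError("depths must be non-empty and strictly increasing")
        if self.mld <= 0:
            raise ValidationError("mld must be > 0")
        if d[0] > self.mld:
            raise ValidationError("shallowest measurement must lie at or above the MLD")


def depth_integrated_nutrient(profile: EnvProfile, nutrient: str) -> float:
    """Depth-weighted mean concentration (uM) from the shallowest bottle to the MLD.

    Uses the trapezoid rule on the measured depths; if the MLD falls between
    two bottles the concentration there is linearly interpolated (constant
    extension below the deepest bottle).  A single bottle above the MLD is
    returned as-is with a warning; none is an error.
    """
    if nutrient not in NUTRIENTS:
        raise ValidationError(f"unknown nutrient {nutrient!r}")
    depths = profile.depths
    conc = getattr(profile, nutrient)
    above = depths <= profile.mld
    if not np.any(above):
        raise ValidationError("no nutrient measurements above the mixed layer depth")
    d = depths[above]
    c = conc[above]
    if d.size == 1:
        logger.warning(
            "single %s measurement above MLD; returning it without integration",
            nutrient,
        )
        return float(c[0])
    if d[-1] < profile.mld:
        c_mld = float(np.interp(profile.mld, depths, conc))
        d = np.append(d, profile.mld)
        c = np.append(c, c_mld)
    span = d[-1] - d[0]
    return float(np.trapezoid(c, d) / span)


def log_transform_nutrients(values):
    """Natural log of (value + offset); offset is 0 when all values are positive.

    When zeros are present (below detection limit) the smallest positive
    observed value is used as the offset, logged loudly.  Negative
    concentrations are rejected.  Returns ``(transformed, offset)``.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValidationError("nutrient concentrations must be >= 0")
    if np.all(v > 0):
        offset = 0.0
    else:
        positive = v[v > 0]
        if positive.size == 0:
            raise ValidationError("all nutrient values are zero; log transform undefined")
        offset = float(positive.min())
        logger.warning(
            "zero nutrient concentrations present; log offset %g (smallest "
            "positive observation) applied", offset,
        )
    out = np.log(v + offset)
    return (float(out) if out.ndim == 0 else out), offset


def env_table(profiles: dict[str, EnvProfile]) -> pd.DataFrame:
    """One row per sample: sst, sss and log depth-integrated nutrients.

    Nutrient columns are named log_no3, log_po4, log_sio3 (each nutrient's
    offset rule applies across the whole table, not per sample).
    """
    rows = []
    for sid, prof in sorted(profiles.items()):
        row = {"sample_id": sid, "sst": prof.sst, "sss": prof.sss}
        for nut in NUTRIENTS:
            row[nut] = depth_integrated_nutrient(prof, nut)
        rows.append(row)
    df = pd.DataFrame(rows)
    for nut in NUTRIENTS:
        df[f"log_{nut}"], _ = log_transform_nutrients(df[nut].to_numpy())
    return df.drop(columns=list(NUTRIENTS))


def read_env_csv(path) -> dict[str, EnvProfile]:
    """Read long-format environmental CSV into per-sample profiles.

    Expected columns: sample_id, depth_m, no3, po4, sio3, sst, sss, mld
    (sst/sss/mld repeated on every depth row of a sample).
    """
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "depth_m", "no3", "po4", "sio3", "sst", "sss", "mld"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"environment CSV missing columns: {sorted(missing)}")
    out: dict[str, EnvProfile] = {}
    for sid, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values("depth_m")
        out[str(sid)] = EnvProfile(
            depths=sub["depth_m"].to_numpy(),
            no3=sub["no3"].to_numpy(),
            po4=sub["po4"].to_numpy(),
            sio3=sub["sio3"].to_numpy(),
            sst=float(sub["sst"].iloc[0]),
            sss=float(sub["sss"].iloc[0]),
            mld=float(sub["mld"].iloc[0]),
        )
    return out


def write_env_csv(profiles: dict[str, EnvProfile], path) -> None:
    rows = []
    for sid, p in sorted(profiles.items()):
        for i, d in enumerate(p.depths):
            rows.append(
                dict(sample_id=sid, depth_m=float(d), no3=p.no3[i], po4=p.po4[i],
                     sio3=p.sio3[i], sst=p.sst, sss=p.sss, mld=p.mld)
            )
    pd.DataFrame(rows).to_csv(path, index=False)
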