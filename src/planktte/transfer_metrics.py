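"""Trophic-transfer metrics and their uncertainty.

The working proxy for trophic transfer efficiency (TTE) from
nano-microplankton (prey) to mesozooplankton (predators) is the
log-scale predator-to-prey biomass ratio

    log10(PPBR) = log10(B_predator / B_prey).

Its validation target is the corresponding *production-rate* ratio
log10(PPPR), with production P = g * B and the specific growth rate g
estimated by the artificial-cohort method, g = ln(Wt / W0) / dt, from the
mean-mass change of an incubated size-fractioned cohort.

Also provided: the predator-prey mass ratio (PPMR, log10 of the ratio of
abundance-weighted geometric-mean individual biomasses), the ratio of
predator to prey size diversities, and a case-resampling bootstrap of the
Pearson correlation between proxy and target, with an optional model-refit
hook that reports sign stability of regression coefficients across
resamples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .morphometry import (
    PREDATOR,
    PREY,
    SampleCommunity,
    total_biomass,
)

logger = logging.getLogger(__name__)

#: Columns of the per-sample analysis table.
SUMMARY_COLUMNS = [
    "sample_id",
    "station_id",
    "prey_biomass",
    "predator_biomass",
    "log10_ppbr",
    "prey_mu",
    "predator_mu",
    "ppmr_log10",
    "diversity_ratio",
]


def log10_ppbr(predator_biomass: float, prey_biomass: float,
               sample_id: str | None = None) -> float:
    """log10 of the predator:prey biomass ratio; antisymmetric in its arguments."""
    if predator_biomass <= 0 or prey_biomass <= 0:
        where = f" in sample {sample_id!r}" if sample_id else ""
        raise ValidationError(
            f"non-positive biomass{where}: predator={predator_biomass}, prey={prey_biomass}"
        )
    return math.log10(predator_biomass / prey_biomass)


@dataclass(frozen=True)
class CohortPair:
    """Artificial-cohort incubation: initial/final mean mass (ug C), duration
    (days) and the standing biomass (mg C m^-3) the rate applies to."""

    w0_ugc: float
    wt_ugc: float
    dt_days: float
    biomass_mgc_m3: float

    def __post_init__(self) -> None:
        if self.w0_ugc <= 0 or self.wt_ugc <= 0 or self.dt_days <= 0:
            raise ValidationError("cohort masses and duration must be > 0")
        if self.biomass_mgc_m3 <= 0:
            raise ValidationError("cohort biomass must be > 0")


def cohort_growth_rate(pair: CohortPair) -> float:
    """Specific growth rate g = ln(Wt/W0)/dt in d^-1.

    Negative rates (mass loss during incubation) are kept, with a warning,
    rather than truncated at zero.
    """
    g = math.log(pair.wt_ugc / pair.w0_ugc) / pair.dt_days
    if g < 0:
        logger.warning("negative cohort growth rate %.4g d^-1 (mass loss) retained", g)
    return g


def production(pair: CohortPair) -> float:
    """Production rate P = g * B in mg C m^-3 d^-1."""
    return cohort_growth_rate(pair) * pair.biomass_mgc_m3


def log10_pppr(predator_production: float, prey_production: float,
               sample_id: str | None = None) -> float:
    """log10 of the predator:prey production ratio (the direct TTE estimate)."""
    if predator_production <= 0 or prey_production <= 0:
        where = f" in sample {sample_id!r}" if sample_id else ""
        raise ValidationError(f"non-positive production{where}")
    return math.log10(predator_production / prey_production)


def _weighted_geomean_mass(sub: pd.DataFrame) -> float:
    b = sub["biomass_mgc"].to_numpy(dtype=float)
    w = sub["weight_per_m3"].to_numpy(dtype=float)
    if np.any(b <= 0):
        raise ValidationError("individual biomass must be > 0 for geometric mean")
    return float(np.exp(np.sum(w * np.log(b)) / np.sum(w)))


def ppmr_log10(sample: SampleCommunity) -> float:
    """Predator-prey mass ratio: log10 of the ratio of abundance-weighted
    geometric-mean individual biomasses (predator over prey)."""
    pred, prey = sample.predators, sample.prey
    if not len(pred) or not len(prey):
        raise ValidationError(f"sample {sample.sample_id!r} has an empty trophic group")
    return math.log10(_weighted_geomean_mass(pred) / _weighted_geomean_mass(prey))


def diversity_ratio(predator_mu: float, prey_mu: float) -> float:
    """Ratio of predator to prey size diversity."""
    if prey_mu == 0:
        raise ValidationError("prey size diversity is zero; ratio undefined")
    return predator_mu / prey_mu


def _pearson_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for equally shaped 2-D resample matrices."""
    xm = xs - xs.mean(axis=1, keepdims=True)
    ym = ys - ys.mean(axis=1, keepdims=True)
    num = np.sum(xm * ym, axis=1)
    den = np.sqrt(np.sum(xm**2, axis=1) * np.sum(ym**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


@dataclass(frozen=True)
class BootstrapResult:
    """Case-resampling bootstrap of a Pearson correlation."""

    r: float
    ci_low: float
    ci_high: float
    n_boot: int
    n: int
    boot_r: np.ndarray
    sign_stability: dict[str, float] | None = None


def bootstrap_proxy_uncertainty(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
    refit_hook: Callable[[np.ndarray], dict[str, float]] | None = None,
) -> BootstrapResult:
    """Bootstrap the Pearson correlation between paired proxy/target values.

    Cases (samples, not individuals) are resampled with replacement ``n_boot``
    times; the percentile interval at ``ci_level`` is reported.  If
    ``refit_hook`` is given it is called with the integer resample indices of
    each replicate and must return a name->coefficient mapping; the fraction
    of replicates in which each coefficient keeps the sign of the full-data
    fit is reported as ``sign_stability``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array of (proxy, target) values")
    n = arr.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 pairs to bootstrap a correlation")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    x, y = arr[:, 0], arr[:, 1]
    r_full = _pearson_rows(x[None, :], y[None, :])[0]

    idx = rng.integers(0, n, size=(n_boot, n))
    boot_r = _pearson_rows(x[idx], y[idx])
    boot_r = boot_r[np.isfinite(boot_r)]  # drop degenerate resamples (all-equal draws)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot_r, [alpha, 1.0 - alpha])

    sign_stability = None
    if refit_hook is not None:
        full = refit_hook(np.arange(n))
        counts = {k: 0 for k in full}
        for b in range(n_boot):
            coefs = refit_hook(idx[b])
            for k, v in coefs.items():
                if np.sign(v) == np.sign(full[k]):
                    counts[k] += 1
        sign_stability = {k: c / n_boot for k, c in counts.items()}

    return BootstrapResult(
        r=float(r_full), ci_low=float(lo), ci_high=float(hi),
        n_boot=int(n_boot), n=int(n), boot_r=boot_r,
        sign_stability=sign_stability,
    )


def build_sample_summaries(
    processed: Sequence[SampleCommunity],
    diversity: pd.DataFrame,
    env: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the one-row-per-sample analysis table.

    ``processed`` are communities with derived biomass (see
    morphometry.process_sample); ``diversity`` is the output of
    size_diversity_table; ``env`` optionally merges sst/sss/log-nutrient
    columns on sample_id.
    """
    mu = diversity.pivot(index="sample_id", columns="group", values="mu")
    rows = []
    for com in processed:
        prey_b = total_biomass(com.particles, PREY)
        pred_b = total_biomass(com.particles, PREDATOR)
        prey_mu = float(mu.loc[com.sample_id, PREY])
        pred_mu = float(mu.loc[com.sample_id, PREDATOR])
        rows.append(
            dict(
                sample_id=com.sample_id,
                station_id=com.station_id,
                prey_biomass=prey_b,
                predator_biomass=pred_b,
                log10_ppbr=log10_ppbr(pred_b, prey_b, com.sample_id),
                prey_mu=prey_mu,
                predator_mu=pred_mu,
                ppmr_log10=ppmr_log10(com),
                diversity_ratio=diversity_ratio(pred_mu, prey_mu),
            )
        )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if env is not None:
        df = df.merge(env, on="sample_id", how="left")
    return df


def read_cohorts_csv(path) -> pd.DataFrame:
    """Cohort CSV: sample_id, group, w0_ugc, wt_ugc, dt_days, biomass_mgc_m3."""
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "group", "w0_ugc", "wt_ugc", "dt_days", "biomass_mgc_m3"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def pppr_table(cohorts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample log10(PPPR) from paired prey/predator cohort incubations."""
    rows = []
    for sid, sub in cohorts.groupby("sample_id", sort=True):
        prods = {}
        for _, rec in sub.iterrows():
            pair = CohortPair(rec["w0_ugc"], rec["wt_ugc"], rec["dt_days"],
                              rec["biomass_mgc_m3"])
            prods[rec["group"]] = production(pair)
        if PREY in prods and PREDATOR in prods:
            rows.append(dict(sample_id=sid,
                             log10_pppr=log10_pppr(prods[PREDATOR], prods[PREY], sid)))
    return pd.DataFrame(rows, columns=["sample_id", "log10_pppr"])
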