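"""Random-intercept linear mixed models, univariate ranking, and exhaustive
all-subsets selection by AICc.

Each observation is one station/date sample; pseudo-replication of repeated
visits to the same station is absorbed by a station-level random intercept.
Models compared by AICc are fitted by maximum likelihood (REML likelihoods
are not comparable across fixed-effect structures).

Conventions, fixed across the package and documented in docs/methods.md:

* Denominator degrees of freedom for fixed-effect t tests follow the
  containment rule ``df = n_obs - n_groups - n_fixed_slopes`` (so 106
  observations over 40 stations with one slope give 65, and a single
  ungrouped block with no slopes gives 105).
* Reported standard errors are rescaled from the ML profile scale to the
  containment-df denominator; with one group and zero random-effect variance
  the t statistics then coincide with ordinary least squares.
* AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1) with k counting fixed effects
  (intercept included) plus the two variance components.
* An interaction may enter a model only together with both main effects
  (marginality); AICc ties break toward fewer parameters, then input order.
* p-values are reported for description but never drive selection.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

MAX_DREDGE_TERMS = 20


def _normalize_term(term: str) -> str:
    """Accept 'A×B', 'A*B' or 'A:B' for the interaction of A and B."""
    t = term.strip().replace("×", ":").replace("*", ":")
    return ":".join(p.strip() for p in t.split(":"))


def _interaction_parents(term: str) -> tuple[str, ...]:
    return tuple(term.split(":")) if ":" in term else ()


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification: response ~ fixed terms | grouping."""

    response: str
    fixed_terms: tuple[str, ...]
    grouping: str
    estimation: Literal["ML", "REML"] = "ML"

    def __post_init__(self) -> None:
        terms = tuple(_normalize_term(t) for t in self.fixed_terms)
        object.__setattr__(self, "fixed_terms", terms)
        present = set(terms)
        for t in terms:
            for parent in _interaction_parents(t):
                if parent not in present:
                    raise ConfigurationError(
                        f"interaction {t!r} requires main effect {parent!r} (marginality)"
                    )

    @classmethod
    def from_formula(cls, formula: str, estimation: str = "ML") -> "ModelSpec":
        """Parse 'response ~ A + B + A:B | station' (interactions also as A×B)."""
        if "|" not in formula or "~" not in formula:
            raise ConfigurationError(
                f"formula {formula!r} must look like 'y ~ x1 + x2 | group'"
            )
        lhs_rhs, grouping = formula.rsplit("|", 1)
        response, rhs = lhs_rhs.split("~", 1)
        terms = [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]
        return cls(response.strip(), tuple(terms), grouping.strip(), estimation)

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"{self.response} ~ {rhs}"


@dataclass(frozen=True)
class ModelFit:
    """A fitted random-intercept model with Table-style per-term statistics."""

    spec: ModelSpec
    params: pd.DataFrame  # term, estimate, se, t, p, df
    loglik: float
    n_obs: int
    n_groups: int
    k: int
    aicc: float
    random_intercept_var: float
    residual_var: float
    converged: bool

    @property
    def slopes(self) -> pd.DataFrame:
        return self.params[self.params["term"] != "Intercept"]


def within_group_df(n_obs: int, n_groups: int, n_fixed_slopes: int) -> int:
    """Containment denominator df: n_obs - n_groups - n_fixed_slopes."""
    df = n_obs - n_groups - n_fixed_slopes
    if df <= 0:
        raise ValidationError(
            f"non-positive denominator df ({n_obs} - {n_groups} - {n_fixed_slopes})"
        )
    return df


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2*loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValidationError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _check_design(spec: ModelSpec, data: pd.DataFrame) -> None:
    cols = {spec.response, spec.grouping}
    for t in spec.fixed_terms:
        cols.update(_interaction_parents(t) or (t,))
    missing = sorted(c for c in cols if c not in data.columns)
    if missing:
        raise ValidationError(f"data is missing columns: {missing}")
    # rank check on the fixed design (intercept + mains + products)
    mats = [np.ones(len(data))]
    for t in spec.fixed_terms:
        parents = _interaction_parents(t)
        col = (
            np.prod([data[p].to_numpy(float) for p in parents], axis=0)
            if parents
            else data[t].to_numpy(float)
        )
        mats.append(col)
    X = np.column_stack(mats)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            f"rank-deficient fixed design for terms {list(spec.fixed_terms)}; "
            "some terms are collinear"
        )


def _fixed_effect_se(X: np.ndarray, group_labels: np.ndarray,
                     sigma2: float, tau2: float) -> np.ndarray:
    """sqrt(diag((X' V^-1 X)^-1)) for V = sigma2*I + tau2*ZZ' (random intercept).

    Uses the per-group Woodbury identity
    V_g^-1 = (1/sigma2) * (I - tau2/(sigma2 + n_g*tau2) * J).
    A degenerate noise-free fit (sigma2 = 0) returns zero standard errors.
    """
    p = X.shape[1]
    if sigma2 <= 0:
        return np.zeros(p)
    info = np.zeros((p, p))
    for g in np.unique(group_labels):
        Xg = X[group_labels == g]
        s = Xg.sum(axis=0)
        shrink = tau2 / (sigma2 * (sigma2 + len(Xg) * tau2))
        info += Xg.T @ Xg / sigma2 - shrink * np.outer(s, s)
    return np.sqrt(np.diag(np.linalg.inv(info)))


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit ``response ~ fixed terms`` with a random intercept per group.

    Maximum likelihood by default (so AICc comparisons are valid).  A
    random-intercept variance estimated at (or numerically near) zero is
    permitted with a warning, as is the degenerate noise-free optimum.
    """
    _check_design(spec, data)
    groups = data[spec.grouping]
    n_groups = int(groups.nunique())
    if n_groups < 1:
        raise ValidationError("need at least one group")
    n = int(len(data))

    model = smf.mixedlm(spec.formula, data=data, groups=groups)
    reml = spec.estimation == "REML"
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                result = model.fit(reml=reml, method=method, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result.converged or result.scale == 0:
                break
    if result is None:
        raise ValidationError(f"mixed model {spec.formula!r} could not be fitted")
    if not result.converged:
        logger.warning("fit of %r did not formally converge (degenerate optimum?)",
                       spec.formula)

    fe = result.fe_params
    n_slopes = len(fe) - 1
    df = within_group_df(n, n_groups, n_slopes)

    cov_re = np.asarray(result.cov_re)
    re_var = float(cov_re[0, 0]) if cov_re.size else 0.0
    if re_var <= 1e-8 * max(result.scale, 1e-300):
        logger.warning("random-intercept variance ~0 (singular fit) for %r", spec.formula)

    # Fixed-effect covariance (X' V^-1 X)^-1 from the estimated variance
    # components (robust at the singular boundary where statsmodels' own
    # covariance can lose positive-definiteness), then rescaled from the
    # profile-likelihood denominator to the containment df.
    profile_denom = n - len(fe) if reml else n
    X = np.asarray(model.exog, dtype=float)
    se = _fixed_effect_se(X, np.asarray(groups), float(result.scale), re_var)
    se = se * np.sqrt(profile_denom / df)
    est = np.asarray(fe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)

    params = pd.DataFrame(
        dict(term=list(fe.index), estimate=est, se=se, t=t, p=p, df=df)
    )
    k = len(fe) + 2
    return ModelFit(
        spec=spec,
        params=params,
        loglik=float(result.llf),
        n_obs=n,
        n_groups=n_groups,
        k=k,
        aicc=aicc(float(result.llf), k, n),
        random_intercept_var=re_var,
        residual_var=float(result.scale),
        converged=bool(result.converged),
    )


def _fits_to_table(fits: Sequence[ModelFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            dict(
                model=f.spec.formula,
                n_terms=len(f.spec.fixed_terms),
                k=f.k,
                loglik=f.loglik,
                aicc=f.aicc,
            )
        )
    df = pd.DataFrame(rows)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    return df


def rank_univariate(
    response: str,
    candidate_terms: Sequence[str],
    grouping: str,
    data: pd.DataFrame,
    estimation: str = "ML",
) -> tuple[pd.DataFrame, list[ModelFit]]:
    """Fit one single-predictor model per candidate and rank by AICc.

    Returns a table with one row per candidate (term, AICc, estimate, s.e.,
    t, p, df) sorted by ascending AICc — ties keep input order — plus the
    fits in ranked order.
    """
    if not candidate_terms:
        raise ValidationError("need at least one candidate term")
    fits = [
        fit_lmm(ModelSpec(response, (term,), grouping, estimation), data)
        for term in candidate_terms
    ]
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aicc, i))
    rows = []
    for i in order:
        f = fits[i]
        slope = f.slopes.iloc[0]
        rows.append(
            dict(
                term=slope["term"],
                aicc=f.aicc,
                estimate=slope["estimate"],
                se=slope["se"],
                t=slope["t"],
                p=slope["p"],
                df=slope["df"],
            )
        )
    return pd.DataFrame(rows), [fits[i] for i in order]


def enumerate_admissible_subsets(terms: Sequence[str]) -> list[tuple[str, ...]]:
    """All fixed-term subsets (incl. empty) respecting interaction marginality.

    Subsets are returned in enumeration order: by size, then by term input
    order; duplicates (after normalisation) appear once.
    """
    norm = [_normalize_term(t) for t in terms]
    seen: set[frozenset[str]] = set()
    out: list[tuple[str, ...]] = []
    for r in range(len(norm) + 1):
        for combo in itertools.combinations(range(len(norm)), r):
            subset = tuple(norm[i] for i in combo)
            key = frozenset(subset)
            if key in seen:
                continue
            ok = all(
                all(p in subset for p in _interaction_parents(t)) for t in subset
            )
            if ok:
                seen.add(key)
                out.append(subset)
    return out


def dredge_all_subsets(
    response: str,
    full_terms: Sequence[str],
    grouping: str,
    data: pd.DataFrame,
    estimation: str = "ML",
) -> tuple[pd.DataFrame, ModelFit, list[ModelFit]]:
    """Exhaustive all-subsets selection: fit every admissible fixed-term
    subset by ML and rank by AICc.

    Returns (ranked table, best fit, all fits in ranked order).  Ties break
    toward fewer parameters, then enumeration order.  Refuses more than
    20 terms.
    """
    if len(full_terms) > MAX_DREDGE_TERMS:
        raise ConfigurationError(
            f"{len(full_terms)} terms exceed the combinatorial guard "
            f"({MAX_DREDGE_TERMS}); reduce the candidate set"
        )
    subsets = enumerate_admissible_subsets(full_terms)
    fits = [
        fit_lmm(ModelSpec(response, subset, grouping, estimation), data)
        for subset in subsets
    ]
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aicc, fits[i].k, i))
    ranked = [fits[i] for i in order]
    return _fits_to_table(ranked), ranked[0], ranked


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson r with the two-sided t-based p-value; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and equally long")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(n)


__all__ = [
    "ModelSpec",
    "ModelFit",
    "within_group_df",
    "aicc",
    "fit_lmm",
    "rank_univariate",
    "enumerate_admissible_subsets",
    "dredge_all_subsets",
    "pearson_with_p",
]
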