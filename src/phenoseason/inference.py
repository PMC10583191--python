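"""Multimodel inference of trait and niche effects on phenology.

All predictor subsets (dredge semantics, exhaustive enumeration) are fitted
by OLS on z-scored variables and ranked by the small-sample Akaike
criterion

    AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1),

with k counting every estimated parameter (slopes, intercept, residual
variance).  Akaike weights w_m = exp(-delta_m/2) / sum exp(-delta/2) give
each model's evidence; effects are then conditionally averaged over the
models within a delta < 3 window of the best model, with a predictor's
relative importance defined as the summed (renormalized) weight of the
window models containing it.

Also here: PCA on the correlation matrix with passive projection of a
supplementary variable, and standardized major axis (SMA) regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, InsufficientDataError

__all__ = [
    "all_subsets",
    "average_effects",
    "ModelSet",
    "AveragedEffect",
    "pca_with_supplementary",
    "sma_regression",
    "prepare_covariates",
    "aicc",
]

TRAIT_PREDICTORS = ["log_height", "log_lateral_spread", "sla", "ldmc"]
NICHE_PREDICTORS = [
    "moisture",
    "light",
    "reaction",
    "nutrients",
    "temperature",
    "dist_frequency",
    "dist_severity",
]

#: conventional lateral spread (cm/yr) imputed for non-clonal species
NONCLONAL_SPREAD = 0.5


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion; requires n > k + 1."""
    if n - k - 1 <= 0:
        raise InsufficientDataError(
            f"AICc undefined: n = {n} too small for k = {k}"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class CandidateModel:
    predictors: tuple
    coef: Dict[str, float]
    ci: Dict[str, tuple]
    loglik: float
    k: int
    aicc: float
    delta: float = math.nan
    weight: float = math.nan


class ModelSet:
    """All-subsets OLS fits of one response, ranked by AICc."""

    def __init__(self, response: str, predictors, models, n: int):
        self.response = response
        self.predictors = list(predictors)
        self.models = models  # sorted by AICc
        self.n = n

    def best_window(self, delta_window: float = 3.0) -> List[CandidateModel]:
        """Models within ``delta_window`` Akaike units of the best."""
        return [m for m in self.models if m.delta < delta_window]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictors": ["+".join(m.predictors) or "1" for m in self.models],
                "k": [m.k for m in self.models],
                "loglik": [m.loglik for m in self.models],
                "aicc": [m.aicc for m in self.models],
                "delta": [m.delta for m in self.models],
                "weight": [m.weight for m in self.models],
            }
        )

    def summary(self) -> str:
        head = self.table.head(10).to_string(index=False)
        return (
            f"All-subsets OLS for {self.response!r}: "
            f"{len(self.models)} models, n = {self.n}\n{head}"
        )


def all_subsets(
    response: str,
    predictors: Sequence[str],
    data: pd.DataFrame,
) -> ModelSet:
    """Fit every predictor subset (including intercept-only) by OLS.

    Variables are z-scored first, so coefficients are standardized.
    Requires complete cases and n large enough for the AICc denominator of
    the fullest model.
    """
    predictors = list(predictors)
    cols = [response] + predictors
    data = data[cols].dropna()
    n = len(data)
    max_k = len(predictors) + 2
    if n <= max_k + 2:
        raise InsufficientDataError(
            f"n = {n} too small for {len(predictors)} predictors"
        )
    sd = data.std(ddof=1)
    if (sd == 0).any():
        dead = sd.index[sd == 0].tolist()
        raise DomainError(f"constant variables cannot be z-scored: {dead}")
    z = (data - data.mean()) / sd
    y = z[response].to_numpy()
    models: List[CandidateModel] = []
    for size in range(len(predictors) + 1):
        for subset in combinations(predictors, size):
            X = sm.add_constant(
                z[list(subset)].to_numpy(), has_constant="add"
            )
            fit = sm.OLS(y, X).fit()
            k = len(subset) + 2  # slopes + intercept + residual variance
            ci = fit.conf_int(alpha=0.05)
            models.append(
                CandidateModel(
                    predictors=subset,
                    coef={p: float(fit.params[j + 1]) for j, p in enumerate(subset)},
                    ci={
                        p: (float(ci[j + 1, 0]), float(ci[j + 1, 1]))
                        for j, p in enumerate(subset)
                    },
                    loglik=float(fit.llf),
                    k=k,
                    aicc=aicc(float(fit.llf), k, n),
                )
            )
    best = min(m.aicc for m in models)
    for m in models:
        m.delta = m.aicc - best
    raw = np.array([math.exp(-m.delta / 2.0) for m in models])
    weights = raw / raw.sum()
    for m, w in zip(models, weights):
        m.weight = float(w)
    models.sort(key=lambda m: m.aicc)
    return ModelSet(response, predictors, models, n)


class AveragedEffect(NamedTuple):
    predictor: str
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    importance: float


def average_effects(
    model_set: ModelSet, delta_window: float = 3.0
) -> pd.DataFrame:
    """Conditionally averaged effects over the delta < window model set.

    Weights are renormalized within the window.  A predictor's importance
    is the summed weight of window models containing it; its estimate (and
    CI endpoints) are the weighted means over exactly those models.
    Predictors absent from every window model get importance 0 and missing
    estimates.
    """
    window = model_set.best_window(delta_window)
    if not window:
        raise DomainError("empty best-model window")
    total = sum(m.weight for m in window)
    rows = []
    for p in model_set.predictors:
        holders = [m for m in window if p in m.predictors]
        mass = sum(m.weight for m in holders) / total
        if holders:
            hw = sum(m.weight for m in holders)
            est = sum(m.weight * m.coef[p] for m in holders) / hw
            lo = sum(m.weight * m.ci[p][0] for m in holders) / hw
            hi = sum(m.weight * m.ci[p][1] for m in holders) / hw
        else:
            est = lo = hi = None
        rows.append(
            AveragedEffect(
                predictor=p,
                estimate=est,
                ci_low=lo,
                ci_high=hi,
                importance=float(mass),
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["ci_method"] = "Akaike-weighted per-model 95 % CI endpoints"
    out.attrs["averaging"] = "conditional (models containing the term)"
    out.attrs["delta_window"] = delta_window
    return out


# ---------------------------------------------------------------------------
# PCA with a passively projected supplementary variable
# ---------------------------------------------------------------------------


class PCAResult(NamedTuple):
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    supplementary: Optional[pd.DataFrame]


def pca_with_supplementary(
    variables: pd.DataFrame,
    supplementary: Optional[pd.DataFrame] = None,
) -> PCAResult:
    """PCA of centred, standardized variables with passive projection.

    Eigen-decomposition of the correlation matrix; the supplementary
    variables are projected as their correlations with the axis scores and
    do not influence the decomposition.
    """
    variables = variables.dropna()
    if len(variables) < 3:
        raise InsufficientDataError("PCA needs >= 3 complete rows")
    sd = variables.std(ddof=1)
    if (sd == 0).any():
        dead = sd.index[sd == 0].tolist()
        raise DomainError(f"constant (degenerate) variables: {dead}")
    z = (variables - variables.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[pivot, j] < 0:
            eigvec[:, j] *= -1
    axes = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    scores = pd.DataFrame(
        z.to_numpy() @ eigvec, index=variables.index, columns=axes
    )
    loadings = pd.DataFrame(eigvec, index=variables.columns, columns=axes)
    explained = eigval / eigval.sum()
    supp = None
    if supplementary is not None:
        supplementary = supplementary.loc[variables.index]
        rows = {}
        for name in supplementary.columns:
            v = supplementary[name].to_numpy(dtype=float)
            ok = np.isfinite(v)
            rows[name] = [
                float(np.corrcoef(v[ok], scores[a].to_numpy()[ok])[0, 1])
                for a in axes
            ]
        supp = pd.DataFrame.from_dict(rows, orient="index", columns=axes)
    return PCAResult(scores, loadings, explained, supp)


# ---------------------------------------------------------------------------
# standardized major axis regression
# ---------------------------------------------------------------------------


class SMAResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def sma_regression(x, y) -> SMAResult:
    """Standardized major axis fit: slope = sign(r) * sd(y)/sd(x).

    The p-value is the two-sided correlation test of x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InsufficientDataError("SMA needs n >= 3")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise DomainError("zero variance in SMA input")
    r, p = stats.pearsonr(x, y)
    slope = math.copysign(sy / sx, r) if r != 0 else sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return SMAResult(float(slope), intercept, float(r * r), float(p), int(x.size))


# ---------------------------------------------------------------------------
# covariate loading conventions
# ---------------------------------------------------------------------------


def prepare_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Apply the covariate conventions used by all analyses.

    Non-clonal species (missing lateral spread) get the conventional
    0.5 cm/yr imputed; height and lateral spread are natural-log
    transformed.  Returns species_id + niche columns + the transformed
    trait columns of :data:`TRAIT_PREDICTORS`.
    """
    out = covariates.copy()
    if "lateral_spread_cm_yr" in out:
        spread = out["lateral_spread_cm_yr"].fillna(NONCLONAL_SPREAD)
        out["log_lateral_spread"] = np.log(spread)
    if "height_cm" in out:
        if (out["height_cm"] <= 0).any():
            raise DomainError("non-positive height cannot be log-transformed")
        out["log_height"] = np.log(out["height_cm"])
    keep = ["species_id"] + [
        c for c in NICHE_PREDICTORS + TRAIT_PREDICTORS if c in out.columns
    ]
    return out[keep]
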