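"""Synthetic shoot-size trajectories with known phenological ground truth.

The generator emulates a garden measurement campaign: for every species,
seven shoots measured biweekly (three dimensions each: upper width, lower
width, vegetative length) from early January through the season.  Each
species carries

* a *niche* vector of ordinal-like indicator scores (moisture, light, soil
  reaction, nutrients, temperature, disturbance frequency and severity),
* a *trait* vector (log height, log lateral spread, SLA, LDMC) generated as
  a linear map of niche plus Gaussian noise, and
* *growth* and *senescence* curve parameters generated as linear maps of
  (niche, traits) plus noise, clamped to admissible ranges.

The true size trajectory is piecewise: a logistic growth phase

    g(t) = K_i / (1 + exp(-b (t - a)))

joined at the intersection day ``t_join`` to a generalized-sigmoid
(Richards-type) decline

    K_i * F(t),   F(t) = (1 + exp(s (t - m)))**(-theta),

so that the fraction-crossing days of the decline have the closed form

    t_q = m + (1/s) * log(q**(-1/theta) - 1).

Because the two phases are joined piecewise at their intersection (rather
than multiplied), each phase's crossing times remain exactly those of its
own sigmoid, which makes every downstream recovery test analytic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError

NICHE_VARS = [
    "moisture",
    "light",
    "reaction",
    "nutrients",
    "temperature",
    "dist_frequency",
    "dist_severity",
]
TRAIT_VARS = ["log_height", "log_lateral_spread", "sla", "ldmc"]
PHENO_PARAMS = ["a_true", "b_true", "K_true", "m_true", "s_true", "theta_true"]

#: Baseline (all-noise-off) trait values: ln(40 cm) height, ln(2 cm/yr)
#: lateral spread, 20 mm^2/mg SLA, 200 mg/g LDMC.
DEFAULT_TRAIT_BASELINE = {
    "log_height": math.log(40.0),
    "log_lateral_spread": math.log(2.0),
    "sla": 20.0,
    "ldmc": 200.0,
}

#: Baseline curve parameters of a temperate-season herb: growth inflection
#: day 120, growth rate 0.12 /d, final size 20 cm, senescence midpoint day
#: 260, steepness 0.08 /d, symmetric decline (theta = 1).
DEFAULT_PHENO_BASELINE = {
    "a_true": 120.0,
    "b_true": 0.12,
    "K_true": 20.0,
    "m_true": 260.0,
    "s_true": 0.08,
    "theta_true": 1.0,
}

DEFAULT_TRAIT_NOISE_SD = {
    "log_height": 0.35,
    "log_lateral_spread": 0.5,
    "sla": 4.0,
    "ldmc": 30.0,
}

DEFAULT_PHENO_NOISE_SD = {
    "a_true": 4.0,
    "b_true": 0.015,
    "K_true": 3.0,
    "m_true": 8.0,
    "s_true": 0.01,
    "theta_true": 0.45,
}

#: Admissible ranges the generated parameters are clamped to.
PHENO_CLAMP = {
    "a_true": (30.0, 200.0),
    "b_true": (0.02, 0.5),
    "K_true": (2.0, 200.0),
    "m_true": (150.0, 345.0),
    "s_true": (0.02, 0.3),
    "theta_true": (0.3, 3.0),
}

#: Minimum separation (days) enforced between growth inflection and
#: senescence midpoint so the two phases always intersect cleanly.
MIN_PHASE_GAP = 40.0


@dataclass
class PathMatrices:
    """Linear-map coefficients of the generating cascade.

    ``trait_from_niche[trait][niche_var]`` maps *centred* niche scores to
    traits; ``pheno_from[param][var]`` maps centred niche scores and
    baseline-centred traits to curve parameters.  Unlisted coefficients
    are zero.
    """

    trait_from_niche: Dict[str, Dict[str, float]] = field(default_factory=dict)
    pheno_from: Dict[str, Dict[str, float]] = field(default_factory=dict)

    @classmethod
    def zero(cls) -> "PathMatrices":
        return cls()

    @classmethod
    def default(cls) -> "PathMatrices":
        """Moderate, sign-definite cascade used as the study condition."""
        return cls(
            trait_from_niche={
                "log_height": {"moisture": 0.15, "nutrients": 0.10},
                "log_lateral_spread": {"moisture": 0.12},
                "sla": {"light": -1.5},
                "ldmc": {"light": 8.0, "moisture": -6.0},
            },
            pheno_from={
                "a_true": {"light": 2.0, "moisture": 1.5, "log_height": 6.0},
                "b_true": {"dist_frequency": -0.008, "sla": 0.001},
                "K_true": {"log_height": 6.0},
                "m_true": {
                    "light": 6.0,
                    "dist_frequency": -5.0,
                    "log_lateral_spread": 4.0,
                },
                "s_true": {"ldmc": 0.0002},
                "theta_true": {"ldmc": -0.002},
            },
        )

    def validate(self) -> None:
        for trait, row in self.trait_from_niche.items():
            if trait not in TRAIT_VARS:
                raise ConfigurationError(f"unknown trait {trait!r}")
            for var in row:
                if var not in NICHE_VARS:
                    raise ConfigurationError(
                        f"trait map uses non-niche source {var!r}"
                    )
        for param, row in self.pheno_from.items():
            if param not in PHENO_PARAMS:
                raise ConfigurationError(f"unknown phenology parameter {param!r}")
            for var in row:
                if var not in NICHE_VARS + TRAIT_VARS:
                    raise ConfigurationError(
                        f"phenology map uses unknown source {var!r}"
                    )


@dataclass
class GenerationConfig:
    """Study conditions of a synthetic campaign.

    Defaults mirror the emulated protocol: 7 shoots per species measured
    every 14 days starting day 7, one 365-day season, 5 % multiplicative
    lognormal measurement noise per dimension, and shoot-level final sizes
    K_i lognormal around K_true with CV 0.2.
    """

    n_species: int = 20
    shoots_per_species: int = 7
    cadence_days: int = 14
    first_day: int = 7
    season_days: int = 365
    noise_cv: float = 0.05
    shoot_k_cv: float = 0.2
    #: allometry: vegetative length = length_per_size * size; widths follow
    #: from the frustum volume identity (see :func:`width_per_size`).
    length_per_size: float = 3.0
    niche_mean: float = 5.0
    niche_sd: float = 1.5
    trait_baseline: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_BASELINE)
    )
    pheno_baseline: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENO_BASELINE)
    )
    trait_noise_sd: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_NOISE_SD)
    )
    pheno_noise_sd: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENO_NOISE_SD)
    )
    path_matrices: PathMatrices = field(default_factory=PathMatrices.default)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigurationError("n_species must be positive")
        if self.shoots_per_species < 1:
            raise ConfigurationError("shoots_per_species must be positive")
        if self.cadence_days < 1:
            raise ConfigurationError("cadence_days must be >= 1")
        if self.noise_cv < 0 or self.shoot_k_cv < 0:
            raise ConfigurationError("coefficients of variation must be >= 0")
        if self.niche_sd < 0:
            raise ConfigurationError("niche_sd must be >= 0")
        for name, sd in {**self.trait_noise_sd, **self.pheno_noise_sd}.items():
            if sd < 0:
                raise ConfigurationError(f"negative noise sd for {name!r}")
        self.path_matrices.validate()

    def sample_days(self) -> np.ndarray:
        return np.arange(self.first_day, self.season_days + 1, self.cadence_days)

    def noiseless(self) -> "GenerationConfig":
        """Copy with all measurement and shoot-level noise switched off."""
        return replace(self, noise_cv=0.0, shoot_k_cv=0.0)


@dataclass
class SpeciesTruth:
    """Generating parameters of one species."""

    species_id: str
    niche: Dict[str, float]
    traits: Dict[str, float]
    a_true: float
    b_true: float
    K_true: float
    m_true: float
    s_true: float
    theta_true: float

    def __post_init__(self) -> None:
        if not (self.b_true > 0 and self.s_true > 0 and self.theta_true > 0):
            raise ConfigurationError("rate/shape parameters must be positive")
        if self.K_true <= 0:
            raise ConfigurationError("K_true must be positive")
        if not self.a_true < self.m_true:
            raise ConfigurationError("growth peak must precede senescence midpoint")


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def width_per_size(length_per_size: float) -> float:
    """Width/size ratio making the frustum volume equal size**3.

    With both widths equal (w) and length L = c_L * size, the frustum
    volume pi*L/12 * 3 w^2 equals size^3 iff w = size * sqrt(4/(pi c_L)).
    """
    return math.sqrt(4.0 / (math.pi * length_per_size))


# ---------------------------------------------------------------------------
# species generation
# ---------------------------------------------------------------------------


def generate_species(config: GenerationConfig) -> List[SpeciesTruth]:
    """Draw the generating parameters of ``config.n_species`` species.

    Niche scores are independent normal(niche_mean, niche_sd) clamped to
    [1, 9]; traits and curve parameters follow the configured linear maps
    plus Gaussian noise, clamped to :data:`PHENO_CLAMP`.  Fully
    deterministic given ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    pm = config.path_matrices
    species: List[SpeciesTruth] = []
    width = len(str(max(config.n_species, 1)))
    for i in range(config.n_species):
        niche = {
            v: float(
                np.clip(rng.normal(config.niche_mean, config.niche_sd), 1.0, 9.0)
            )
            for v in NICHE_VARS
        }
        centred = {v: niche[v] - config.niche_mean for v in NICHE_VARS}
        traits = {}
        for trait in TRAIT_VARS:
            value = config.trait_baseline[trait]
            for var, coef in pm.trait_from_niche.get(trait, {}).items():
                value += coef * centred[var]
            value += rng.normal(0.0, config.trait_noise_sd[trait])
            traits[trait] = float(value)
        trait_centred = {
            t: traits[t] - config.trait_baseline[t] for t in TRAIT_VARS
        }
        sources = {**centred, **trait_centred}
        pheno = {}
        for param in PHENO_PARAMS:
            value = config.pheno_baseline[param]
            for var, coef in pm.pheno_from.get(param, {}).items():
                value += coef * sources[var]
            value += rng.normal(0.0, config.pheno_noise_sd[param])
            lo, hi = PHENO_CLAMP[param]
            pheno[param] = float(np.clip(value, lo, hi))
        # keep growth and senescence phases separated
        pheno["m_true"] = float(
            min(
                max(pheno["m_true"], pheno["a_true"] + MIN_PHASE_GAP),
                PHENO_CLAMP["m_true"][1],
            )
        )
        species.append(
            SpeciesTruth(
                species_id=f"sp{i + 1:0{width}d}",
                niche=niche,
                traits=traits,
                **pheno,
            )
        )
    return species


# ---------------------------------------------------------------------------
# the true trajectory
# ---------------------------------------------------------------------------


def growth_phase(t, K: float, a: float, b: float):
    """Logistic growth phase g(t) = K / (1 + exp(-b (t - a)))."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + np.exp(-b * (t - a)))


def decline_fraction(t, m: float, s: float, theta: float):
    """Generalized-sigmoid decline F(t) = (1 + exp(s (t - m)))**(-theta)."""
    t = np.asarray(t, dtype=float)
    return (1.0 + np.exp(s * (t - m))) ** (-theta)


def decline_crossing_day(truth: SpeciesTruth, q: float) -> float:
    """Closed-form day at which the decline sigmoid F equals fraction q.

    t_q = m + (1/s) * log(q**(-1/theta) - 1); q in (0, 1).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return truth.m_true + math.log(q ** (-1.0 / truth.theta_true) - 1.0) / truth.s_true


def join_day(truth: SpeciesTruth) -> float:
    """Day where the growth and decline sigmoids intersect nearest the peak.

    Solves g(t)/K = F(t) between the growth inflection and the senescence
    midpoint; the intersection is independent of the shoot-level K_i since
    both phases scale with it.
    """

    def h(t: float) -> float:
        return float(
            growth_phase(t, 1.0, truth.a_true, truth.b_true)
            - decline_fraction(t, truth.m_true, truth.s_true, truth.theta_true)
        )

    lo, hi = truth.a_true, truth.m_true
    if h(lo) < 0.0 < h(hi):
        return float(brentq(h, lo, hi, xtol=1e-10))
    # degenerate overlap: scan outward for a bracket
    grid = np.linspace(lo - 120.0, hi + 120.0, 961)
    values = np.array([h(t) for t in grid])
    sign_change = np.nonzero(np.diff(np.sign(values)) != 0)[0]
    if sign_change.size:
        k = sign_change[np.argmin(np.abs(grid[sign_change] - 0.5 * (lo + hi)))]
        return float(brentq(h, grid[k], grid[k + 1], xtol=1e-10))
    return 0.5 * (lo + hi)


def true_size(truth: SpeciesTruth, K_i: float, t, t_join: float | None = None):
    """True scalar size of a shoot with final size ``K_i`` at day(s) ``t``.

    Growth sigmoid up to the intersection day, Richards decline after it;
    continuous at the join by construction.  Total on t in [1, 365+].
    """
    if t_join is None:
        t_join = join_day(truth)
    t = np.asarray(t, dtype=float)
    g = growth_phase(t, K_i, truth.a_true, truth.b_true)
    d = K_i * decline_fraction(t, truth.m_true, truth.s_true, truth.theta_true)
    out = np.where(t <= t_join, g, d)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# measurement rendering
# ---------------------------------------------------------------------------


def render_measurements(
    truths: Sequence[SpeciesTruth],
    config: GenerationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Render the long-format measurement table for ``truths``.

    Per shoot: K_i ~ lognormal around K_true (CV ``shoot_k_cv``); the true
    size at each sampling day is inverted to the (upper width, lower width,
    length) triplet consistent with the frustum volume formula; each
    dimension is then multiplied by lognormal noise with CV ``noise_cv``.
    """
    config.validate()
    days = config.sample_days()
    c_len = config.length_per_size
    c_wid = width_per_size(c_len)
    sigma_dim = _lognormal_sigma(config.noise_cv)
    sigma_k = _lognormal_sigma(config.shoot_k_cv)
    rows = []
    for truth in truths:
        tj = join_day(truth)
        for shoot in range(1, config.shoots_per_species + 1):
            K_i = truth.K_true * (
                math.exp(rng.normal(0.0, sigma_k)) if sigma_k > 0 else 1.0
            )
            sizes = true_size(truth, K_i, days, t_join=tj)
            if sigma_dim > 0:
                noise = np.exp(rng.normal(0.0, sigma_dim, size=(days.size, 3)))
            else:
                noise = np.ones((days.size, 3))
            for j, day in enumerate(days):
                rows.append(
                    {
                        "species_id": truth.species_id,
                        "shoot_id": f"{truth.species_id}-s{shoot}",
                        "day_of_year": int(day),
                        "upper_width_cm": c_wid * sizes[j] * noise[j, 0],
                        "lower_width_cm": c_wid * sizes[j] * noise[j, 1],
                        "length_cm": c_len * sizes[j] * noise[j, 2],
                    }
                )
    return pd.DataFrame(rows)


def make_covariates(truths: Sequence[SpeciesTruth]) -> pd.DataFrame:
    """Species covariate table (niche scores + raw-scale traits).

    Species whose generated lateral spread is below 1 cm/yr are treated as
    non-clonal: their lateral spread is reported missing (the database
    convention) and ``clonal`` is False; downstream loading imputes the
    conventional 0.5 cm/yr for them.
    """
    rows = []
    for truth in truths:
        spread = math.exp(truth.traits["log_lateral_spread"])
        clonal = spread >= 1.0
        row = {"species_id": truth.species_id}
        row.update({v: truth.niche[v] for v in NICHE_VARS})
        row["height_cm"] = math.exp(truth.traits["log_height"])
        row["lateral_spread_cm_yr"] = spread if clonal else np.nan
        row["clonal"] = clonal
        row["sla"] = truth.traits["sla"]
        row["ldmc"] = truth.traits["ldmc"]
        rows.append(row)
    return pd.DataFrame(rows)


def truth_frame(truths: Sequence[SpeciesTruth]) -> pd.DataFrame:
    """All SpeciesTruth fields as one flat table."""
    rows = []
    for truth in truths:
        row = {"species_id": truth.species_id}
        row.update({v: truth.niche[v] for v in NICHE_VARS})
        row.update({t: truth.traits[t] for t in TRAIT_VARS})
        for p in PHENO_PARAMS:
            row[p] = getattr(truth, p)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_dataset(config: GenerationConfig):
    """Generate (measurements, covariates, truth) tables from one seed."""
    truths = generate_species(config)
    # dedicated stream so measurement noise does not perturb species draws
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    measurements = render_measurements(truths, config, rng)
    return measurements, make_covariates(truths), truth_frame(truths)


def write_dataset(config: GenerationConfig, outdir) -> dict:
    """Write measurements.csv, covariates.csv and truth.csv to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    measurements, covariates, truth = simulate_dataset(config)
    paths = {
        "measurements": outdir / "measurements.csv",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "truth.csv",
    }
    measurements.to_csv(paths["measurements"], index=False)
    covariates.to_csv(paths["covariates"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
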