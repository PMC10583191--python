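"""Species-level logistic growth curves by nonlinear mixed-effects fits.

One species' growth-phase measurements (all shoots pooled) are modelled as

    x_ij = A + (K + u_Ki - A) / (1 + exp(-b (t_ij - a))) + eps_ij

with shoot-level random effects u ~ N(0, tau^2) on the final size K
(always) and optionally on one further parameter (A, a or b), Gaussian
residuals, and the marginal likelihood evaluated by a Laplace
approximation (exact whenever the random effects enter linearly, i.e. for
A and K).  The candidate set crosses {A estimated, A = 0} with the
random-effect structures {K}, {K, A}, {K, a}, {K, b}; the structure with
the lowest AIC wins.

From the selected fit come the spring phenology parameters: the date of
peak growth ``a`` (the inflection), the log of the standardized growth
rate ``b`` (at A = 0 the identity b = 4 d / K holds, with d the growth
rate at the inflection), and the season start, the day the curve reaches
25 % of final size, which for the logistic is the closed form
``a - ln(3)/b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .errors import DomainError, FitFailureError, InsufficientDataError
from .trajectory import ShootSeries

__all__ = [
    "logistic",
    "LogisticGrowthModel",
    "LogisticGrowthResults",
    "GrowthParams",
    "fit_species_growth",
    "extract_growth_params",
    "select_by_aic",
    "DEFAULT_CANDIDATES",
]

#: (A mode, random-effect structure) candidates, simplest first.
DEFAULT_CANDIDATES: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("zero", ("K",)),
    ("zero", ("K", "a")),
    ("zero", ("K", "b")),
    ("free", ("K",)),
    ("free", ("K", "A")),
    ("free", ("K", "a")),
    ("free", ("K", "b")),
)

#: reduced candidate set (K-random only) for quick orchestration runs
BASIC_CANDIDATES: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("zero", ("K",)),
    ("free", ("K",)),
)

_LN3 = math.log(3.0)


def logistic(t, A: float, K: float, a: float, b: float):
    """Simplified general logistic x(t) = A + (K - A)/(1 + exp(-b(t - a))).

    The inflection sits at t = a with derivative b (K - A) / 4, so for
    A = 0 the standardized-growth-rate identity b = 4 d / K holds.
    """
    if b <= 0:
        raise DomainError("growth rate b must be positive")
    if K <= A:
        raise DomainError("final size K must exceed initial size A")
    t = np.asarray(t, dtype=float)
    out = A + (K - A) * expit(b * (t - a))
    return out if out.ndim else float(out)


def _curve_and_jac(t, A, K, a, b, wanted: Sequence[str]):
    """Logistic values and the Jacobian columns for ``wanted`` parameters."""
    L = expit(b * (t - a))
    f = A + (K - A) * L
    cols = {}
    for name in wanted:
        if name == "A":
            cols[name] = 1.0 - L
        elif name == "K":
            cols[name] = L
        elif name == "a":
            cols[name] = -(K - A) * b * L * (1.0 - L)
        elif name == "b":
            cols[name] = (K - A) * (t - a) * L * (1.0 - L)
    return f, cols


@dataclass
class GrowthParams:
    """Spring phenology of one species."""

    species_id: str
    peak_day: float
    log_b: float
    season_start: float


@dataclass
class _Candidate:
    a_mode: str
    random: Tuple[str, ...]
    params: Dict[str, float] = field(default_factory=dict)
    sigma: float = float("nan")
    tau: Dict[str, float] = field(default_factory=dict)
    loglik: float = -math.inf
    n_params: int = 0
    aic: float = math.inf
    converged: bool = False
    n_restarts: int = 0
    message: str = ""
    ranef: Dict[str, Dict[str, float]] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"A={self.a_mode},random={{{','.join(self.random)}}}"


def select_by_aic(candidates: Sequence) -> object:
    """Converged candidate with the lowest AIC (earlier wins exact ties)."""
    converged = [c for c in candidates if getattr(c, "converged", False)]
    if not converged:
        raise FitFailureError("no candidate converged", diagnostics=candidates)
    best = converged[0]
    for c in converged[1:]:
        if c.aic < best.aic:
            best = c
    return best


class LogisticGrowthModel:
    """Mixed-effects logistic growth model for one species.

    Parameters
    ----------
    days, sizes : arrays of pooled growth-phase observations
    shoots : per-observation shoot labels
    species_id : label carried through to the results
    """

    def __init__(self, days, sizes, shoots, species_id: str = ""):
        self.t = np.asarray(days, dtype=float)
        self.y = np.asarray(sizes, dtype=float)
        shoots = np.asarray(shoots)
        if not (self.t.shape == self.y.shape == shoots.shape):
            raise DomainError("days, sizes and shoots must align")
        self.species_id = species_id
        self.shoot_ids = sorted({str(s) for s in shoots})
        self._groups = [
            np.nonzero(shoots.astype(str) == sid)[0] for sid in self.shoot_ids
        ]
        big = [g for g in self._groups if g.size >= 4]
        if len(big) < 2:
            raise InsufficientDataError(
                "need >= 2 shoots with >= 4 growth-phase points each"
            )
        self._scale = float(np.max(self.y))
        if self._scale <= 0:
            raise DomainError("all sizes are zero")

    @classmethod
    def from_series(
        cls, series: Sequence[ShootSeries], species_id: Optional[str] = None
    ) -> "LogisticGrowthModel":
        """Build from split shoot series, using their growth partitions."""
        days, sizes, shoots = [], [], []
        for s in series:
            days.append(s.growth_days)
            sizes.append(s.growth_sizes)
            shoots.extend([s.shoot_id] * s.growth_points.size)
        sid = species_id if species_id is not None else series[0].species_id
        return cls(
            np.concatenate(days), np.concatenate(sizes), np.array(shoots), sid
        )

    # -- marginal log-likelihood ------------------------------------------

    def _shoot_loglik(self, idx, phi, sigma, tau, random, u0):
        """Laplace marginal log-likelihood of one shoot; returns (ll, u_hat).

        Exact when the random set is within {A, K} (linear); otherwise a
        damped Gauss-Newton finds the posterior mode first.
        """
        t, y = self.t[idx], self.y[idx]
        n, q = t.size, len(random)
        d_inv = 1.0 / tau**2
        s2 = sigma**2

        def assemble(u):
            p = dict(phi)
            for r, ur in zip(random, u):
                p[r] = p[r] + ur
            return p

        if set(random) <= {"A", "K"}:
            f0, cols = _curve_and_jac(
                t, phi["A"], phi["K"], phi["a"], phi["b"], random
            )
            J = np.column_stack([cols[r] for r in random])
            r0 = y - f0
            H = J.T @ J / s2 + np.diag(d_inv)
            u = np.linalg.solve(H, J.T @ r0 / s2)
            resid = r0 - J @ u
            Q = resid @ resid / s2 + np.sum(u * u * d_inv)
        else:
            u = u0.copy() if u0 is not None else np.zeros(q)

            def objective(u):
                p = assemble(u)
                f, _ = _curve_and_jac(t, p["A"], p["K"], p["a"], p["b"], ())
                r = y - f
                return r @ r / s2 + np.sum(u * u * d_inv)

            Q = objective(u)
            for _ in range(60):
                p = assemble(u)
                f, cols = _curve_and_jac(t, p["A"], p["K"], p["a"], p["b"], random)
                J = np.column_stack([cols[r] for r in random])
                r = y - f
                H = J.T @ J / s2 + np.diag(d_inv)
                g = J.T @ r / s2 - u * d_inv
                try:
                    step = np.linalg.solve(H, g)
                except np.linalg.LinAlgError:
                    break
                alpha, improved = 1.0, False
                for _ in range(20):
                    u_new = u + alpha * step
                    Q_new = objective(u_new)
                    if Q_new < Q - 1e-12:
                        u, Q, improved = u_new, Q_new, True
                        break
                    alpha *= 0.5
                if not improved or np.max(np.abs(alpha * step)) < 1e-9:
                    break
            p = assemble(u)
            _, cols = _curve_and_jac(t, p["A"], p["K"], p["a"], p["b"], random)
            J = np.column_stack([cols[r] for r in random])
            H = J.T @ J / s2 + np.diag(d_inv)

        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            return -math.inf, u
        ll = (
            -0.5 * n * math.log(2.0 * math.pi * s2)
            - float(np.sum(np.log(tau)))
            - 0.5 * Q
            - 0.5 * logdet_h
        )
        return ll, u

    def _neg_loglik(self, theta, names, random, cache):
        phi = {"A": 0.0}
        for i, name in enumerate(names):
            phi[name] = theta[i]
        sigma = math.exp(theta[len(names)])
        tau = np.exp(theta[len(names) + 1 :])
        if phi["K"] <= phi["A"]:
            return 1e12
        total = 0.0
        for k, idx in enumerate(self._groups):
            ll, u = self._shoot_loglik(idx, phi, sigma, tau, random, cache.get(k))
            cache[k] = u
            if not np.isfinite(ll):
                return 1e12
            total += ll
        return -total

    # -- initial values ----------------------------------------------------

    def _initial(self, a_mode: str) -> Dict[str, float]:
        t, y = self.t, self.y
        K0 = float(np.max(y))
        A0 = float(max(np.min(y), 0.0)) if a_mode == "free" else 0.0
        # coarse (a, b) grid by pooled fixed-effects RSS
        a_grid = np.quantile(t, [0.15, 0.3, 0.45, 0.6, 0.75, 0.9])
        b_grid = np.array([0.02, 0.05, 0.1, 0.2, 0.5])
        best = (math.inf, float(np.median(t)), 0.1)
        for a0 in a_grid:
            for b0 in b_grid:
                f = A0 + (K0 - A0) * expit(b0 * (t - a0))
                rss = float(np.sum((y - f) ** 2))
                if rss < best[0]:
                    best = (rss, float(a0), float(b0))
        rss, a0, b0 = best
        sigma0 = max(math.sqrt(rss / t.size), 2e-3 * self._scale)
        return {"A": A0, "K": K0, "a": a0, "b": b0, "sigma": sigma0}

    def _bounds(self, names, random):
        t_lo, t_hi = float(np.min(self.t)), float(np.max(self.t))
        s = self._scale
        fixed = {
            "A": (-0.5 * s, 0.75 * s),
            "K": (1e-6 * s, 10.0 * s),
            "a": (t_lo - 60.0, t_hi + 60.0),
            "b": (1e-4, 5.0),
        }
        bounds = [fixed[n] for n in names]
        bounds.append((math.log(1e-3 * s), math.log(2.0 * s)))  # log sigma
        tau_bounds = {
            "K": (math.log(1e-4 * s), math.log(5.0 * s)),
            "A": (math.log(1e-4 * s), math.log(5.0 * s)),
            "a": (math.log(1e-3), math.log(120.0)),
            "b": (math.log(1e-6), math.log(2.0)),
        }
        bounds.extend(tau_bounds[r] for r in random)
        return bounds

    def _theta0(self, init, names, random, rng=None):
        s = self._scale
        tau0 = {"K": 0.2 * init["K"], "A": 0.1 * s, "a": 5.0, "b": 0.3 * init["b"]}
        theta = [init[n] for n in names]
        theta.append(math.log(init["sigma"]))
        theta.extend(math.log(tau0[r]) for r in random)
        theta = np.array(theta, dtype=float)
        if rng is not None:  # restart jitter: +-50 %
            for i, name in enumerate(names):
                if name == "a":
                    theta[i] += rng.uniform(-30.0, 30.0)
                elif name == "A":
                    theta[i] += rng.uniform(-0.1, 0.1) * s
                else:
                    theta[i] *= rng.uniform(0.5, 1.5)
            theta[len(names) :] += np.log(
                rng.uniform(0.5, 1.5, theta.size - len(names))
            )
        return theta

    # -- fitting -----------------------------------------------------------

    def _fit_candidate(self, a_mode, random, max_restarts, rng) -> _Candidate:
        names = (["A"] if a_mode == "free" else []) + ["K", "a", "b"]
        cand = _Candidate(a_mode=a_mode, random=tuple(random))
        init = self._initial(a_mode)
        bounds = self._bounds(names, random)
        cache: Dict[int, np.ndarray] = {}
        res = None
        for attempt in range(max_restarts + 1):
            theta0 = self._theta0(init, names, random, rng if attempt else None)
            theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
            cache.clear()
            res = minimize(
                self._neg_loglik,
                theta0,
                args=(names, random, cache),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 400},
            )
            cand.n_restarts = attempt
            if res.success and self._meaningful(res.x, names, bounds):
                cand.converged = True
                break
            cand.message = str(res.message)
        if not cand.converged:
            return cand
        phi = {"A": 0.0}
        for i, n in enumerate(names):
            phi[n] = float(res.x[i])
        sigma = math.exp(res.x[len(names)])
        tau = np.exp(res.x[len(names) + 1 :])
        cand.params = {k: phi[k] for k in ("A", "K", "a", "b")}
        cand.sigma = sigma
        cand.tau = {r: float(tv) for r, tv in zip(random, tau)}
        cand.loglik = -float(res.fun)
        cand.n_params = len(names) + 1 + len(random)
        cand.aic = -2.0 * cand.loglik + 2.0 * cand.n_params
        for k, idx in enumerate(self._groups):
            _, u = self._shoot_loglik(idx, phi, sigma, tau, random, cache.get(k))
            cand.ranef[self.shoot_ids[k]] = {
                r: float(ur) for r, ur in zip(random, u)
            }
        return cand

    @staticmethod
    def _meaningful(theta, names, bounds) -> bool:
        # fixed effects must not be pinned to the box (variance components
        # may legitimately sit at their lower bound)
        for i in range(len(names)):
            lo, hi = bounds[i]
            margin = 1e-6 * max(1.0, abs(hi - lo))
            if not (lo + margin < theta[i] < hi - margin):
                return False
        return bool(np.all(np.isfinite(theta)))

    def fit(
        self,
        candidates: Optional[Sequence[Tuple[str, Tuple[str, ...]]]] = None,
        max_restarts: int = 5,
        seed: int = 0,
    ) -> "LogisticGrowthResults":
        """Fit all candidate structures and return the lowest-AIC one.

        ``candidates`` is a sequence of (A mode, random set) pairs; the
        default crosses A in {zero, free} with K-only and K-plus-one
        random structures.  ``seed`` drives the restart jitter only.
        """
        if candidates is None:
            candidates = DEFAULT_CANDIDATES
        rng = np.random.default_rng(seed)
        fits = [
            self._fit_candidate(a_mode, random, max_restarts, rng)
            for a_mode, random in candidates
        ]
        best = select_by_aic(fits)
        return LogisticGrowthResults(self, best, fits)


class LogisticGrowthResults:
    """Selected mixed-effects logistic fit plus the full candidate table."""

    def __init__(self, model: LogisticGrowthModel, best: _Candidate, fits):
        self.model = model
        self.species_id = model.species_id
        self._best = best
        self._fits = list(fits)
        self.params = dict(best.params)
        self.sigma = best.sigma
        self.tau = dict(best.tau)
        self.random_structure = best.random
        self.a_mode = best.a_mode
        self.loglik = best.loglik
        self.n_params = best.n_params
        self.aic = best.aic
        self.converged = best.converged
        self.n_restarts = best.n_restarts
        self.ranef_modes = dict(best.ranef)

    @property
    def aic_table(self) -> pd.DataFrame:
        rows = [
            {
                "candidate": c.label,
                "a_mode": c.a_mode,
                "random": "+".join(c.random),
                "loglik": c.loglik,
                "n_params": c.n_params,
                "aic": c.aic,
                "converged": c.converged,
                "n_restarts": c.n_restarts,
                "selected": c is self._best,
            }
            for c in self._fits
        ]
        return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)

    def shoot_params(self, shoot_id: str) -> Dict[str, float]:
        """Fixed effects plus this shoot's random-effect modes."""
        p = dict(self.params)
        for r, u in self.ranef_modes.get(shoot_id, {}).items():
            p[r] = p[r] + u
        return p

    def k_by_shoot(self) -> pd.Series:
        """Predicted final size K_i per shoot (fixed effect + mode)."""
        return pd.Series(
            {sid: self.shoot_params(sid)["K"] for sid in self.model.shoot_ids},
            name="K_i",
        )

    def predict(self, t, shoot_id: Optional[str] = None):
        """Population curve, or a shoot-specific curve for ``shoot_id``."""
        p = self.shoot_params(shoot_id) if shoot_id else self.params
        return logistic(t, p["A"], p["K"], p["a"], p["b"])

    def mean_params(self) -> Dict[str, float]:
        """Fixed effects averaged over shoot modes for random parameters."""
        out = dict(self.params)
        for r in self.random_structure:
            modes = [m.get(r, 0.0) for m in self.ranef_modes.values()]
            if modes:
                out[r] = out[r] + float(np.mean(modes))
        return out

    def growth_params(self) -> GrowthParams:
        return extract_growth_params(self)

    def summary(self) -> str:
        lines = [
            f"Logistic growth fit: species {self.species_id}",
            f"  A mode: {self.a_mode}   random effects: "
            f"{'+'.join(self.random_structure)}",
            f"  loglik {self.loglik:.3f}   n_params {self.n_params}   "
            f"AIC {self.aic:.2f}",
            "  parameter  estimate",
        ]
        for k in ("A", "K", "a", "b"):
            lines.append(f"  {k:>9}  {self.params[k]:.5g}")
        lines.append(f"      sigma  {self.sigma:.5g}")
        for r, tv in self.tau.items():
            lines.append(f"     tau_{r:<2} {tv:.5g}")
        gp = self.growth_params()
        lines.append(
            f"  peak day {gp.peak_day:.2f}   log b {gp.log_b:.4f}   "
            f"season start {gp.season_start:.2f}"
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed sizes and the fitted population curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        for sid, idx in zip(m.shoot_ids, m._groups):
            ax.plot(m.t[idx], m.y[idx], "o", ms=3, alpha=0.5)
        grid = np.linspace(m.t.min(), m.t.max(), 200)
        ax.plot(grid, self.predict(grid), "k-", lw=2, label="population")
        ax.set_xlabel("day of year")
        ax.set_ylabel("size (cm)")
        ax.set_title(f"{self.species_id}: logistic growth fit")
        ax.legend()
        return ax


def extract_growth_params(fit: LogisticGrowthResults) -> GrowthParams:
    """Spring phenology from a converged fit.

    peak_day is ``a`` (mean over shoot modes if a is random), log_b the
    natural log of ``b`` (same convention), and season_start solves
    x(t) = A + 0.25 (K - A), which for the logistic is the closed form
    a - ln(3)/b regardless of A.
    """
    if not fit.converged:
        raise FitFailureError("cannot extract parameters from unconverged fit")
    p = fit.mean_params()
    return GrowthParams(
        species_id=fit.species_id,
        peak_day=p["a"],
        log_b=math.log(p["b"]),
        season_start=p["a"] - _LN3 / p["b"],
    )


def fit_species_growth(
    series: Sequence[ShootSeries],
    candidates: Optional[Sequence[Tuple[str, Tuple[str, ...]]]] = None,
    max_restarts: int = 5,
    seed: int = 0,
) -> LogisticGrowthResults:
    """Fit one species' growth partitions; convenience front door."""
    return LogisticGrowthModel.from_series(series).fit(
        candidates=candidates, max_restarts=max_restarts, seed=seed
    )


def growth_table(
    all_series: Sequence[ShootSeries],
    candidates=None,
    max_restarts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-species growth parameter table from split shoot series."""
    by_species: Dict[str, List[ShootSeries]] = {}
    for s in all_series:
        by_species.setdefault(s.species_id, []).append(s)
    rows = []
    for species_id in sorted(by_species):
        fit = fit_species_growth(
            by_species[species_id],
            candidates=candidates,
            max_restarts=max_restarts,
            seed=seed,
        )
        gp = fit.growth_params()
        rows.append(
            {
                "species_id": species_id,
                "peak_day": gp.peak_day,
                "log_b": gp.log_b,
                "season_start": gp.season_start,
                "a_mode": fit.a_mode,
                "random_structure": "+".join(fit.random_structure),
                "aic": fit.aic,
                "K": fit.params["K"],
            }
        )
    return pd.DataFrame(rows)
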