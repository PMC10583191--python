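"""Piecewise structural equation models fitted by local estimation.

The causal hypothesis is a layered DAG — niche variables drive functional
traits, traits drive the phenological variables, and phenology determines
season length.  Each endogenous variable is regressed (OLS, z-scored) on
its graph parents; the standardized partial slopes are the path
coefficients.  Global fit is assessed by tests of directed separation:
every non-adjacent ordered pair not linked by a correlated error yields an
independence claim, tested by adding the upstream variable to the
downstream variable's parent regression.  The claim p-values combine into
Fisher's C = -2 sum(ln p), chi-square with 2k degrees of freedom under the
hypothesised structure.

``refine`` iterates the standard model-building loop: significant claims
add a directed edge (cross-layer pair) or a correlated error (same-layer
pair), edges whose removal lowers the summed component AIC are pruned, and
the loop stops once no claim is significant and the global p exceeds the
stopping threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, InsufficientDataError, SpecificationError

__all__ = [
    "SEMSpec",
    "PiecewiseSEM",
    "SEMResults",
    "Claim",
    "basis_set",
    "fit_local",
    "fishers_c",
    "refine",
    "default_spec",
]

DEFAULT_LAYER_ORDER = ("niche", "trait", "phenology", "outcome")


class Claim(NamedTuple):
    """Independence claim: upstream _||_ downstream | conditioning."""

    upstream: str
    downstream: str
    conditioning: Tuple[str, ...]


@dataclass
class SEMSpec:
    """Layered DAG specification: nodes, directed edges, correlated errors."""

    nodes: Dict[str, str]  # node -> layer tag
    directed_edges: List[Tuple[str, str]] = field(default_factory=list)
    correlated_errors: List[Tuple[str, str]] = field(default_factory=list)
    layer_order: Tuple[str, ...] = DEFAULT_LAYER_ORDER

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for node, layer in self.nodes.items():
            if layer not in self.layer_order:
                raise SpecificationError(
                    f"node {node!r} has unknown layer {layer!r}"
                )
        rank = {layer: i for i, layer in enumerate(self.layer_order)}
        for u, v in self.directed_edges:
            if u not in self.nodes or v not in self.nodes:
                raise SpecificationError(f"edge ({u}, {v}) uses unknown node")
            if rank[self.nodes[u]] > rank[self.nodes[v]]:
                raise SpecificationError(
                    f"edge ({u}, {v}) points from a later to an earlier layer"
                )
        g = nx.DiGraph(self.directed_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise SpecificationError("edge graph contains a cycle")
        edge_pairs = {frozenset(e) for e in self.directed_edges}
        for u, v in self.correlated_errors:
            if u not in self.nodes or v not in self.nodes:
                raise SpecificationError(
                    f"correlated error ({u}, {v}) uses unknown node"
                )
            if self.nodes[u] != self.nodes[v]:
                raise SpecificationError(
                    f"correlated error ({u}, {v}) must link same-layer nodes"
                )
            if frozenset((u, v)) in edge_pairs:
                raise SpecificationError(
                    f"pair ({u}, {v}) is both an edge and a correlated error"
                )
        if len({frozenset(e) for e in self.correlated_errors}) != len(
            self.correlated_errors
        ):
            raise SpecificationError("duplicate correlated-error pairs")
        if len(edge_pairs) != len(self.directed_edges):
            raise SpecificationError("duplicate or bidirectional edges")

    # -- graph helpers -----------------------------------------------------

    def causal_order(self) -> List[str]:
        """Nodes by (layer, name); the deterministic causal order."""
        rank = {layer: i for i, layer in enumerate(self.layer_order)}
        return sorted(self.nodes, key=lambda n: (rank[self.nodes[n]], n))

    def parents(self, node: str) -> List[str]:
        return sorted(u for u, v in self.directed_edges if v == node)

    def endogenous(self) -> List[str]:
        """Nodes beyond the first populated layer (fitted as responses)."""
        rank = {layer: i for i, layer in enumerate(self.layer_order)}
        first = min(rank[self.nodes[n]] for n in self.nodes)
        return [n for n in self.causal_order() if rank[self.nodes[n]] > first]

    def with_edge(self, u: str, v: str) -> "SEMSpec":
        return replace(self, directed_edges=self.directed_edges + [(u, v)])

    def without_edge(self, u: str, v: str) -> "SEMSpec":
        edges = [e for e in self.directed_edges if e != (u, v)]
        return replace(self, directed_edges=edges)

    def with_correlated_error(self, u: str, v: str) -> "SEMSpec":
        return replace(
            self, correlated_errors=self.correlated_errors + [(u, v)]
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        layers: Dict[str, List[str]] = {}
        for node, layer in self.nodes.items():
            layers.setdefault(layer, []).append(node)
        return {
            "layer_order": list(self.layer_order),
            "layers": {k: sorted(v) for k, v in layers.items()},
            "edges": [list(e) for e in self.directed_edges],
            "correlated_errors": [list(e) for e in self.correlated_errors],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SEMSpec":
        nodes = {
            node: layer
            for layer, members in payload.get("layers", {}).items()
            for node in members
        }
        return cls(
            nodes=nodes,
            directed_edges=[tuple(e) for e in payload.get("edges", [])],
            correlated_errors=[
                tuple(e) for e in payload.get("correlated_errors", [])
            ],
            layer_order=tuple(
                payload.get("layer_order", DEFAULT_LAYER_ORDER)
            ),
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SEMSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_spec() -> SEMSpec:
    """Layered starting model: niche -> traits -> phenology -> season length.

    Complete bipartite edges between consecutive layers; no correlated
    errors.
    """
    nodes = {}
    niche = ["moisture", "light", "reaction", "dist_frequency"]
    traits = ["log_height", "log_lateral_spread", "sla", "ldmc"]
    pheno = ["peak_day", "log_b", "sen_date", "sen_pace", "sen_shape"]
    for n in niche:
        nodes[n] = "niche"
    for n in traits:
        nodes[n] = "trait"
    for n in pheno:
        nodes[n] = "phenology"
    nodes["season_length"] = "outcome"
    edges = (
        [(u, v) for u in niche for v in traits]
        + [(u, v) for u in traits for v in pheno]
        + [(u, "season_length") for u in pheno]
    )
    return SEMSpec(nodes=nodes, directed_edges=edges)


# ---------------------------------------------------------------------------
# d-separation machinery
# ---------------------------------------------------------------------------


def basis_set(spec: SEMSpec) -> List[Claim]:
    """Independence claims of the DAG.

    All ordered non-adjacent pairs (respecting the causal order) that are
    not linked by a correlated error, each conditioned on the parents of
    the downstream (later-ordered) variable.  The ordering of the returned
    list is deterministic.
    """
    order = spec.causal_order()
    position = {n: i for i, n in enumerate(order)}
    adjacent = {frozenset(e) for e in spec.directed_edges}
    excluded = {frozenset(e) for e in spec.correlated_errors}
    claims: List[Claim] = []
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            pair = frozenset((u, v))
            if pair in adjacent or pair in excluded:
                continue
            conditioning = tuple(p for p in spec.parents(v) if p != u)
            claims.append(Claim(u, v, conditioning))
    # re-order deterministically by downstream position then upstream
    claims.sort(key=lambda c: (position[c.downstream], position[c.upstream]))
    return claims


def fishers_c(p_values: Sequence[float]) -> Tuple[float, int, float]:
    """Combine claim p-values: C = -2 sum(ln p), df = 2k, upper chi2 tail."""
    p_values = list(p_values)
    k = len(p_values)
    if k == 0:
        return 0.0, 0, 1.0
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise DomainError(
                f"claim p-value {p} outside (0, 1]: Fisher's C undefined"
            )
    c = -2.0 * sum(math.log(p) for p in p_values)
    df = 2 * k
    return float(c), df, float(stats.chi2.sf(c, df))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class SEMResults:
    """Fitted piecewise SEM: paths, d-sep claims, Fisher's C, AIC variants."""

    def __init__(
        self,
        spec: SEMSpec,
        path_coefficients: pd.DataFrame,
        claim_tests: pd.DataFrame,
        fisher_c: float,
        df: int,
        p_global: float,
        aic_sum: float,
        aic_c: float,
        error_correlations: pd.DataFrame,
        n: int,
    ):
        self.spec = spec
        self.path_coefficients = path_coefficients
        self.claim_tests = claim_tests
        self.fisher_c = fisher_c
        self.df = df
        self.p_global = p_global
        self.aic_sum = aic_sum
        self.aic_c = aic_c
        self.error_correlations = error_correlations
        self.n = n

    def path(self, u: str, v: str) -> float:
        hit = self.path_coefficients[
            (self.path_coefficients["source"] == u)
            & (self.path_coefficients["target"] == v)
        ]
        if hit.empty:
            raise KeyError(f"no path {u} -> {v}")
        return float(hit["estimate"].iloc[0])

    def summary(self) -> str:
        lines = [
            f"Piecewise SEM: n = {self.n}, "
            f"{len(self.path_coefficients)} paths, "
            f"{len(self.claim_tests)} independence claims",
            f"Fisher's C = {self.fisher_c:.1f}, df = {self.df}, "
            f"P = {self.p_global:.3f}",
            f"sum-of-components AIC = {self.aic_sum:.1f}   "
            f"(C-statistic variant: {self.aic_c:.1f})",
            "",
            "Standardized path coefficients:",
            self.path_coefficients.to_string(
                index=False, float_format=lambda v: f"{v: .3f}"
            ),
        ]
        if len(self.error_correlations):
            lines += [
                "",
                "Correlated errors (residual correlations):",
                self.error_correlations.to_string(
                    index=False, float_format=lambda v: f"{v: .3f}"
                ),
            ]
        return "\n".join(lines)


class PiecewiseSEM:
    """Model object binding an :class:`SEMSpec` to a species data table."""

    def __init__(self, spec: SEMSpec, data: pd.DataFrame):
        spec.validate()
        missing = [n for n in spec.nodes if n not in data.columns]
        if missing:
            raise SpecificationError(f"data lacks node columns {missing}")
        complete = data[list(spec.nodes)].dropna()
        if len(complete) < len(spec.nodes) + 2:
            raise InsufficientDataError(
                f"only {len(complete)} complete cases for {len(spec.nodes)} nodes"
            )
        sd = complete.std(ddof=1)
        if (sd == 0).any():
            raise DomainError(
                f"constant node columns: {sd.index[sd == 0].tolist()}"
            )
        self.spec = spec
        self.data = complete
        self._z = (complete - complete.mean()) / sd

    def _regression(self, response: str, terms: Sequence[str]):
        X = sm.add_constant(
            self._z[list(terms)].to_numpy(), has_constant="add"
        )
        return sm.OLS(self._z[response].to_numpy(), X).fit()

    def fit(self) -> SEMResults:
        spec = self.spec
        n = len(self._z)
        path_rows = []
        aic_sum = 0.0
        n_parameters = 0
        for node in spec.endogenous():
            parents = spec.parents(node)
            fit = self._regression(node, parents)
            k = len(parents) + 2  # slopes + intercept + residual variance
            aic_sum += -2.0 * fit.llf + 2.0 * k
            n_parameters += k
            for j, p in enumerate(parents):
                path_rows.append(
                    {
                        "source": p,
                        "target": node,
                        "estimate": float(fit.params[j + 1]),
                        "se": float(fit.bse[j + 1]),
                        "p_value": float(fit.pvalues[j + 1]),
                    }
                )
        claims = basis_set(spec)
        claim_rows = []
        for claim in claims:
            terms = list(claim.conditioning) + [claim.upstream]
            fit = self._regression(claim.downstream, terms)
            claim_rows.append(
                {
                    "upstream": claim.upstream,
                    "downstream": claim.downstream,
                    "conditioning": "+".join(claim.conditioning),
                    "p_value": float(fit.pvalues[len(terms)]),
                }
            )
        claim_df = pd.DataFrame(
            claim_rows,
            columns=["upstream", "downstream", "conditioning", "p_value"],
        )
        c_stat, df, p_global = fishers_c(claim_df["p_value"].tolist())
        err_rows = []
        resid = {}

        def residual(node):
            if node not in resid:
                parents = spec.parents(node)
                if parents:
                    fit = self._regression(node, parents)
                    resid[node] = fit.resid
                else:
                    resid[node] = self._z[node].to_numpy()
            return resid[node]

        for u, v in spec.correlated_errors:
            r = float(np.corrcoef(residual(u), residual(v))[0, 1])
            err_rows.append({"node_a": u, "node_b": v, "r": r})
        return SEMResults(
            spec=spec,
            path_coefficients=pd.DataFrame(
                path_rows,
                columns=["source", "target", "estimate", "se", "p_value"],
            ),
            claim_tests=claim_df,
            fisher_c=c_stat,
            df=df,
            p_global=p_global,
            aic_sum=aic_sum,
            aic_c=c_stat + 2.0 * n_parameters,
            error_correlations=pd.DataFrame(
                err_rows, columns=["node_a", "node_b", "r"]
            ),
            n=n,
        )

    def refine(
        self,
        alpha_add: float = 0.05,
        stop_p: float = 0.2,
        max_iter: int = 20,
        prune: bool = True,
    ):
        """Iterative structure refinement; see :func:`refine`."""
        return refine(
            self.spec,
            self.data,
            alpha_add=alpha_add,
            stop_p=stop_p,
            max_iter=max_iter,
            prune=prune,
        )


def fit_local(spec: SEMSpec, data: pd.DataFrame) -> SEMResults:
    """Fit the piecewise SEM by local estimation (one OLS per response)."""
    return PiecewiseSEM(spec, data).fit()


def refine(
    spec: SEMSpec,
    data: pd.DataFrame,
    alpha_add: float = 0.05,
    stop_p: float = 0.2,
    max_iter: int = 20,
    prune: bool = True,
):
    """Iteratively refine the structure until it is consistent with the data.

    Each iteration fits the model and tests the d-sep basis set.  Among
    claims with p < ``alpha_add`` the smallest-p pair is resolved: a
    cross-layer pair gains a directed edge (earlier layer -> later), a
    same-layer pair a correlated error.  Edges whose removal lowers the
    summed component AIC are pruned (edges added by the loop itself are
    protected).  The loop stops when no claim is significant and the
    global p exceeds ``stop_p``, or at ``max_iter`` (returned flagged).

    Returns (final spec, SEMResults, audit trail) where the audit trail is
    a list of dict events; the last event reports convergence.
    """
    rank = {layer: i for i, layer in enumerate(spec.layer_order)}
    audit: List[dict] = []
    protected: set = set()
    current = spec
    converged = False
    fit = None
    for iteration in range(max_iter + 1):
        fit = PiecewiseSEM(current, data).fit()
        sig = fit.claim_tests[fit.claim_tests["p_value"] < alpha_add]
        if sig.empty and fit.p_global > stop_p:
            converged = True
            break
        if sig.empty:
            break  # nothing to add yet globally inconsistent: stop flagged
        row = sig.sort_values("p_value").iloc[0]
        u, v = str(row["upstream"]), str(row["downstream"])
        if rank[current.nodes[u]] == rank[current.nodes[v]]:
            current = current.with_correlated_error(u, v)
            audit.append(
                {
                    "iteration": iteration,
                    "action": "add_correlated_error",
                    "pair": (u, v),
                    "p_value": float(row["p_value"]),
                }
            )
        else:
            current = current.with_edge(u, v)
            protected.add((u, v))
            audit.append(
                {
                    "iteration": iteration,
                    "action": "add_edge",
                    "pair": (u, v),
                    "p_value": float(row["p_value"]),
                }
            )
        if prune:
            current = _prune_edges(current, data, protected, audit, iteration)
    audit.append(
        {
            "iteration": len(audit),
            "action": "finish",
            "converged": converged,
        }
    )
    return current, fit, audit


def _component_aic(z: pd.DataFrame, spec: SEMSpec) -> float:
    """Summed AIC of the component regressions on pre-standardized data."""
    total = 0.0
    for node in spec.endogenous():
        parents = spec.parents(node)
        X = sm.add_constant(z[parents].to_numpy(), has_constant="add")
        fit = sm.OLS(z[node].to_numpy(), X).fit()
        total += -2.0 * fit.llf + 2.0 * (len(parents) + 2)
    return total


def _prune_edges(spec, data, protected, audit, iteration):
    """Remove edges whose deletion lowers the summed component AIC."""
    current = spec
    z = PiecewiseSEM(current, data)._z
    while True:
        base = _component_aic(z, current)
        best_edge, best_aic = None, base
        for edge in current.directed_edges:
            if tuple(edge) in protected:
                continue
            trial = current.without_edge(*edge)
            aic = _component_aic(z, trial)
            if aic < best_aic - 1e-9:
                best_edge, best_aic = edge, aic
        if best_edge is None:
            return current
        current = current.without_edge(*best_edge)
        audit.append(
            {
                "iteration": iteration,
                "action": "prune_edge",
                "pair": tuple(best_edge),
                "aic_drop": float(base - best_aic),
            }
        )
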