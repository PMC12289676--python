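"""Piecewise structural equation modeling (pSEM).

A mediation hypothesis is encoded as a DAG over herb-dose terms
(exogenous), mediators (liver markers, genus abundances, metabolite
peaks) and outcomes.  Each non-exogenous node is fitted by its own OLS
regression on its parents; overall adequacy is judged by the d-separation
test of directed separation: every non-adjacent pair of variables, given
the union of both variables' parents, should be conditionally
independent.  The k independence-claim p-values combine into Fisher's

    C = -2 sum_i ln p_i  ~  chi^2 with 2k df,

so a *large* p_C means the data are consistent with the hypothesized
paths.  Model parsimony is compared with AIC = C + 2K, K counting all
estimated likelihood parameters (slopes, intercepts and residual
variances of the component models).  Non-significant paths can be pruned
one at a time (largest p first) until all retained paths are significant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PathDag",
    "IndependenceClaim",
    "PsemFit",
    "build_initial_dag",
    "basis_set",
    "test_claim",
    "fishers_c",
    "fit_psem",
    "prune_paths",
    "GraphError",
]

log = logging.getLogger(__name__)

P_CLAMP = 1e-300


class GraphError(ValueError):
    """Invalid path diagram (cycle, name collision, ...)."""


@dataclass(frozen=True)
class PathDag:
    """Directed acyclic mediation graph with node roles.

    Roles: 'term' (exogenous herb-dose term), 'mediator', 'outcome'.
    """

    edges: tuple[tuple[str, str], ...]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise GraphError(f"mediation graph contains a cycle: {cycle}")
        for v, role in self.roles.items():
            if role == "term" and g.in_degree(v) > 0:
                raise GraphError(f"exogenous term {v!r} has parents")

    @property
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.roles)
        g.add_edges_from(self.edges)
        return g

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def parents(self, v: str) -> list[str]:
        return sorted(self.graph.predecessors(v))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "from": [a for a, _ in self.edges],
                "to": [b for _, b in self.edges],
                "from_role": [self.roles.get(a, "") for a, _ in self.edges],
                "to_role": [self.roles.get(b, "") for _, b in self.edges],
            }
        )

    def to_dot(self) -> str:
        shapes = {"term": "circle", "mediator": "box", "outcome": "diamond"}
        lines = ["digraph psem {"]
        for v in self.nodes:
            shape = shapes.get(self.roles.get(v, ""), "ellipse")
            lines.append(f'  "{v}" [shape={shape}];')
        for a, b in self.edges:
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)


def build_initial_dag(effect_models, vip_selected: dict[str, list[str]]) -> PathDag:
    """Initial mediation DAG from SPRA terms and VIP-screened mediators.

    For each effect model: its selected terms point at the outcome and at
    every mediator screened for that outcome; every screened mediator
    points at the outcome.
    """
    edges: list[tuple[str, str]] = []
    roles: dict[str, str] = {}
    for model in effect_models:
        outcome = model.response
        roles[outcome] = "outcome"
        mediators = vip_selected.get(outcome, [])
        for t in model.terms:
            if t in mediators:
                raise GraphError(f"name collision between term and mediator: {t!r}")
            roles[t] = "term"
            edges.append((t, outcome))
            for mv in mediators:
                edges.append((t, mv))
        for mv in mediators:
            if roles.get(mv) == "term":
                raise GraphError(f"name collision between term and mediator: {mv!r}")
            roles[mv] = "mediator"
            edges.append((mv, outcome))
    return PathDag(edges=tuple(dict.fromkeys(edges)), roles=roles)


@dataclass(frozen=True)
class IndependenceClaim:
    """Directed-separation claim: x independent of y given the conditioning set.

    ``y`` is the topologically later variable (the regression response).
    """

    x: str
    y: str
    conditioning: tuple[str, ...]


def basis_set(dag: PathDag) -> list[IndependenceClaim]:
    """Shipley d-separation basis set of a mediation DAG.

    One claim per non-adjacent pair, ordered by topological position, the
    later variable as response, conditioning on the union of both
    variables' parents.
    """
    g = dag.graph
    topo = list(nx.lexicographical_topological_sort(g))
    claims = []
    for j, y in enumerate(topo):
        for x in topo[:j]:
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            cond = set(g.predecessors(x)) | set(g.predecessors(y))
            cond -= {x, y}
            claims.append(IndependenceClaim(x=x, y=y, conditioning=tuple(sorted(cond))))
    return claims


def test_claim(claim: IndependenceClaim, data: pd.DataFrame) -> float:
    """p-value of a d-separation claim via the component-model family.

    Two-sided t-test of x's coefficient in the OLS regression of y on
    {x} union conditioning set.
    """
    cond = [c for c in dict.fromkeys(claim.conditioning) if c not in (claim.x, claim.y)]
    cols = [claim.x] + cond
    n = len(data)
    if n <= len(cols) + 2:
        raise ValueError(
            f"claim {claim.x} _||_ {claim.y} needs n > {len(cols) + 2}, got {n}"
        )
    X = sm.add_constant(data[cols].to_numpy(float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise GraphError(f"singular design for claim variables {cols}")
    fit = sm.OLS(data[claim.y].to_numpy(float), X).fit()
    return float(fit.pvalues[1])


def fishers_c(pvalues) -> tuple[float, int, float]:
    """Fisher's C over independence-claim p-values: (C, df, p_C).

    C = -2 sum ln p_i, df = 2k, p_C the upper chi-square tail.  An empty
    claim list (saturated model) returns (0, 0, 1).  p-values of 0 are
    clamped at 1e-300 with a warning.
    """
    ps = [float(p) for p in pvalues]
    if not ps:
        return 0.0, 0, 1.0
    clamped = []
    for p in ps:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value out of range: {p}")
        if p < P_CLAMP:
            log.warning("claim p-value %g clamped to %g", p, P_CLAMP)
            p = P_CLAMP
        clamped.append(p)
    c = -2.0 * float(np.sum(np.log(clamped)))
    df = 2 * len(clamped)
    return c, df, float(stats.chi2.sf(c, df))


@dataclass(frozen=True)
class ComponentModel:
    """One local OLS: response regressed on its DAG parents."""

    response: str
    parents: tuple[str, ...]
    coefficients: dict[str, float]
    std_coefficients: dict[str, float]
    pvalues: dict[str, float]
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class PsemFit:
    """Fitted piecewise SEM: component models, claims, Fisher's C, AIC."""

    dag: PathDag
    components: tuple[ComponentModel, ...]
    claims: tuple[IndependenceClaim, ...]
    claim_pvalues: tuple[float, ...]
    c_statistic: float
    df: int
    p_value: float
    n_params: int  # K: slopes + intercepts + residual variances
    aic: float
    n_obs: int
    empty: bool = False

    @property
    def paths(self) -> pd.DataFrame:
        rows = []
        for comp in self.components:
            for par in comp.parents:
                rows.append(
                    {
                        "from": par,
                        "to": comp.response,
                        "coefficient": comp.coefficients[par],
                        "std_coefficient": comp.std_coefficients[par],
                        "p_value": comp.pvalues[par],
                    }
                )
        return pd.DataFrame(rows, columns=["from", "to", "coefficient",
                                           "std_coefficient", "p_value"])

    def to_dict(self) -> dict:
        return {
            "paths": self.paths.to_dict(orient="records"),
            "claims": [
                {"x": c.x, "y": c.y, "conditioning": list(c.conditioning), "p": p}
                for c, p in zip(self.claims, self.claim_pvalues)
            ],
            "fisher_c": self.c_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "n_params": self.n_params,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "empty": self.empty,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def fit_psem(dag: PathDag, data: pd.DataFrame) -> PsemFit:
    """Fit every component regression, test the basis set, compute C and AIC."""
    g = dag.graph
    components = []
    n = len(data)
    n_params = 0
    for v in nx.lexicographical_topological_sort(g):
        parents = dag.parents(v)
        if not parents:
            continue
        if n < len(parents) + 2:
            raise ValueError(f"too few observations to fit {v} on {parents}")
        y = data[v].to_numpy(float)
        X = sm.add_constant(data[parents].to_numpy(float))
        fit = sm.OLS(y, X).fit()
        sd_y = y.std(ddof=1)
        coefs = dict(zip(parents, fit.params[1:]))
        std_coefs = {
            p: coefs[p] * data[p].std(ddof=1) / sd_y if sd_y > 0 else 0.0
            for p in parents
        }
        components.append(
            ComponentModel(
                response=v, parents=tuple(parents), coefficients=coefs,
                std_coefficients=std_coefs,
                pvalues=dict(zip(parents, fit.pvalues[1:])),
                intercept=float(fit.params[0]), r_squared=float(fit.rsquared),
            )
        )
        n_params += len(parents) + 2  # slopes + intercept + residual variance
    claims = basis_set(dag)
    pvals = tuple(test_claim(c, data) for c in claims)
    c_stat, df, p_c = fishers_c(pvals)
    return PsemFit(
        dag=dag, components=tuple(components), claims=tuple(claims),
        claim_pvalues=pvals, c_statistic=c_stat, df=df, p_value=p_c,
        n_params=n_params, aic=c_stat + 2 * n_params, n_obs=n,
        empty=not dag.edges,
    )


def prune_paths(
    fit: PsemFit, data: pd.DataFrame, alpha: float = 0.05
) -> tuple[PsemFit, list[dict]]:
    """Iteratively drop the least significant path until all paths pass alpha.

    One path at a time (largest p >= alpha), refitting after each removal;
    nodes left without any edge are dropped.  Returns the final fit and a
    removal log.  A model pruned down to no edges is returned flagged
    ``empty``, not raised.
    """
    removal_log: list[dict] = []
    current = fit
    while True:
        paths = current.paths
        if paths.empty:
            break
        worst = paths.sort_values("p_value", ascending=False).iloc[0]
        if worst["p_value"] < alpha:
            break
        edge = (worst["from"], worst["to"])
        removal_log.append(
            {"from": edge[0], "to": edge[1], "p_value": float(worst["p_value"])}
        )
        edges = tuple(e for e in current.dag.edges if e != edge)
        keep = {v for e in edges for v in e}
        roles = {v: r for v, r in current.dag.roles.items() if v in keep}
        new_dag = PathDag(edges=edges, roles=roles)
        if not edges:
            current = PsemFit(
                dag=new_dag, components=(), claims=(), claim_pvalues=(),
                c_statistic=0.0, df=0, p_value=1.0, n_params=0, aic=0.0,
                n_obs=current.n_obs, empty=True,
            )
            break
        current = fit_psem(new_dag, data)
    return current, removal_log
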