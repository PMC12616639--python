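"""Piecewise structural-equation engine.

A causal DAG over the experiment's variables is estimated piecewise: each
endogenous node gets its own linear mixed model (response on its graph
parents plus exogenous controls, with crossed subject- and pair-level
random intercepts, REML by default).  Global fit is judged by tests of
directed separation: every independence claim the DAG implies (Shipley's
basis set) is tested by adding the claimed-independent variable to the
downstream node's model and reading off its Wald p-value; the claim
p-values combine into Fisher's C = -2 * sum(log p_i), chi-square with 2k
degrees of freedom under the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .dataio import Dataset
from .lmm import LMMResult, fit_crossed_intercepts

__all__ = [
    "CausalGraph",
    "NodeFit",
    "IndependenceClaim",
    "GoodnessOfFit",
    "default_graph",
    "graph_from_dict",
    "graph_from_yaml",
    "fit_node",
    "fit_all",
    "basis_set",
    "dsep_test",
    "dsep_tests",
    "fishers_c",
]


@dataclass(frozen=True)
class CausalGraph:
    """DAG of the structural model plus per-node controls and grouping.

    ``nodes`` fixes the canonical variable order used everywhere (path
    enumeration, basis-set sorting).  ``controls`` lists exogenous
    covariates entering a node's equation without being structural nodes;
    ``grouping`` names the random-intercept factors of each node's model.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    controls: dict[str, tuple[str, ...]] = field(default_factory=dict)
    grouping: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) has an endpoint outside nodes")
        for node, ctrl in self.controls.items():
            for c in ctrl:
                if c in self.nodes:
                    raise ValueError(f"control {c!r} of {node!r} is also a structural node")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return tuple(sorted((u for u, v in self.edges if v == node), key=order.get))

    def endogenous(self) -> tuple[str, ...]:
        """Nodes with at least one parent, in canonical order."""
        resp = {v for _, v in self.edges}
        return tuple(n for n in self.nodes if n in resp)

    def exogenous(self) -> tuple[str, ...]:
        resp = {v for _, v in self.edges}
        return tuple(n for n in self.nodes if n not in resp)

    def topological_order(self) -> tuple[str, ...]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return tuple(nx.lexicographical_topological_sort(self.to_networkx(), key=order.get))

    def extended(self) -> nx.DiGraph:
        """DAG including controls as exogenous parents of their equations."""
        g = self.to_networkx()
        for node, ctrl in self.controls.items():
            for c in ctrl:
                g.add_edge(c, node)
        return g


def default_graph() -> CausalGraph:
    """The five-equation mediation model of the experiment.

    label -> {sweetness, familiarity, healthiness, tastiness, bid};
    sweetness -> {familiarity, healthiness, tastiness, bid};
    familiarity -> {healthiness, tastiness, bid};
    healthiness -> {tastiness, bid}; tastiness -> bid.  Gender and age
    control every equation; the trial index controls the bid only; all
    five equations carry crossed subject and pair random intercepts.
    """
    nodes = ("label", "sweetness", "familiarity", "healthiness", "tastiness", "bid")
    order = ("sweetness", "familiarity", "healthiness", "tastiness", "bid")
    edges = [("label", n) for n in order]
    for i, u in enumerate(order[:-1]):
        for v in order[i + 1:]:
            edges.append((u, v))
    controls = {n: ("gender", "age") for n in order}
    controls["bid"] = ("gender", "age", "trial_index")
    grouping = {n: ("subject_id", "pair_id") for n in order}
    return CausalGraph(nodes=nodes, edges=tuple(edges), controls=controls, grouping=grouping)


def graph_from_dict(data: dict) -> CausalGraph:
    """Build a graph from a declarative mapping (the graph-file format)."""
    nodes = tuple(data["nodes"])
    edges = tuple((str(u), str(v)) for u, v in data["edges"])
    controls = {k: tuple(v) for k, v in data.get("controls", {}).items()}
    grouping = {k: tuple(v) for k, v in data.get("grouping", {}).items()}
    return CausalGraph(nodes=nodes, edges=edges, controls=controls, grouping=grouping)


def graph_from_yaml(path) -> CausalGraph:
    with open(path, "r", encoding="utf-8") as fh:
        return graph_from_dict(yaml.safe_load(fh))


@dataclass
class NodeFit:
    """Mixed-model fit of one node: coefficient table and fit statistics."""

    response: str
    predictors: tuple[str, ...]
    params: pd.DataFrame  # index: const + predictors; columns: estimate, se, z, p
    variance_components: dict[str, float]
    loglik: float
    aic: float
    bic: float
    n_obs: int
    method: str
    converged: bool
    warnings: tuple[str, ...] = ()

    def coefficient(self, predictor: str) -> float:
        return float(self.params.at[predictor, "estimate"])

    def p_value(self, predictor: str) -> float:
        return float(self.params.at[predictor, "p"])


@dataclass(frozen=True)
class IndependenceClaim:
    """An implied conditional independence: x _||_ y | conditioning_set.

    ``y`` is the regression response of the d-separation test; ``x`` the
    added predictor whose Wald p-value judges the claim.
    """

    x: str
    y: str
    conditioning_set: tuple[str, ...]
    p_value: float | None = None


@dataclass(frozen=True)
class GoodnessOfFit:
    C: float
    df: int
    p_value: float
    claims: tuple[IndependenceClaim, ...] = ()


def _design_matrix(dataset: Dataset, predictors: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(dataset.n_records)})
    for p in predictors:
        X[p] = dataset.records[p].to_numpy(dtype=float)
    return X


def fit_node(
    dataset: Dataset,
    graph: CausalGraph,
    node: str,
    method: str = "reml",
    extra_predictors: tuple[str, ...] = (),
    start: tuple[float, float] | None = None,
) -> NodeFit:
    """Fit one node's linear mixed model (parents + controls, crossed REs).

    ``extra_predictors`` supports the d-separation tests, which augment the
    node's model with the claimed-independent variable.
    """
    if node not in graph.endogenous():
        raise ValueError(f"{node!r} is not an endogenous node of the graph")
    predictors = list(graph.parents(node)) + list(graph.controls.get(node, ()))
    for extra in extra_predictors:
        if extra not in predictors:
            predictors.append(extra)
    grouping = graph.grouping.get(node, ("subject_id", "pair_id"))
    if tuple(grouping) != ("subject_id", "pair_id"):
        raise NotImplementedError(
            "only crossed (subject_id, pair_id) random intercepts are supported"
        )
    X = _design_matrix(dataset, tuple(predictors))
    res: LMMResult = fit_crossed_intercepts(
        dataset.records[node].to_numpy(dtype=float),
        X,
        dataset.records["subject_id"].to_numpy(),
        dataset.records["pair_id"].to_numpy(),
        method=method,
        start=start,
    )
    params = pd.DataFrame(
        {"estimate": res.params, "se": res.bse, "z": res.zvalues, "p": res.pvalues}
    )
    return NodeFit(
        response=node,
        predictors=tuple(predictors),
        params=params,
        variance_components={
            "subject_sd": res.subject_sd,
            "pair_sd": res.pair_sd,
            "residual_sd": res.resid_sd,
        },
        loglik=res.loglik,
        aic=res.aic,
        bic=res.bic,
        n_obs=res.n,
        method=method,
        converged=res.converged,
        warnings=tuple(res.warnings),
    )


def fit_all(dataset: Dataset, graph: CausalGraph, method: str = "reml") -> list[NodeFit]:
    """One NodeFit per endogenous node, in topological order."""
    topo = [n for n in graph.topological_order() if n in graph.endogenous()]
    return [fit_node(dataset, graph, node, method=method) for node in topo]


def basis_set(graph: CausalGraph) -> list[IndependenceClaim]:
    """Shipley's basis set of independence claims implied by the DAG.

    Variables are the structural nodes plus the controls (controls act as
    exogenous parents of the equations they enter).  One claim is produced
    for each non-adjacent pair, conditioned on the union of both members'
    parents; pairs of two exogenous variables are excluded (their
    association is unconstrained by the model).  The regression response is
    the member that is not an ancestor of the other (the endogenous member
    when neither is an ancestor).
    """
    ext = graph.extended()
    ctrl_order = []
    for node in graph.nodes:
        for c in graph.controls.get(node, ()):
            if c not in ctrl_order:
                ctrl_order.append(c)
    variables = list(graph.nodes) + ctrl_order
    order = {v: i for i, v in enumerate(variables)}
    exo = {v for v in variables if ext.in_degree(v) == 0}
    ancestors = {v: nx.ancestors(ext, v) for v in variables}
    endogenous = set(graph.endogenous())

    claims = []
    for i, u in enumerate(variables):
        for v in variables[i + 1:]:
            if ext.has_edge(u, v) or ext.has_edge(v, u):
                continue
            if u in exo and v in exo:
                continue
            # response: the non-ancestor (ties: the endogenous member,
            # then the later one in canonical order)
            if u in ancestors[v]:
                x, y = u, v
            elif v in ancestors[u]:
                x, y = v, u
            elif (v in endogenous) and (u not in endogenous):
                x, y = u, v
            elif (u in endogenous) and (v not in endogenous):
                x, y = v, u
            else:
                x, y = (u, v) if order[u] < order[v] else (v, u)
            cond = (set(ext.predecessors(y)) | set(ext.predecessors(x))) - {x, y}
            claims.append(
                IndependenceClaim(
                    x=x, y=y, conditioning_set=tuple(sorted(cond, key=order.get))
                )
            )
    claims.sort(key=lambda c: (order[c.y], order[c.x]))
    return claims


def dsep_test(
    dataset: Dataset, graph: CausalGraph, claim: IndependenceClaim, method: str = "reml"
) -> IndependenceClaim:
    """Test one independence claim with the downstream node's mixed model.

    The model of ``claim.y`` is refitted with ``claim.x`` (and any parents
    of x not already present) added; the returned claim carries the Wald
    p-value of x's coefficient.
    """
    if claim.y not in graph.endogenous():
        raise ValueError(
            f"claim response {claim.y!r} is not an endogenous node; cannot test"
        )
    already = set(graph.parents(claim.y)) | set(graph.controls.get(claim.y, ()))
    extras = [claim.x] + [c for c in claim.conditioning_set if c not in already]
    fit = fit_node(dataset, graph, claim.y, method=method, extra_predictors=tuple(extras))
    return replace(claim, p_value=fit.p_value(claim.x))


def dsep_tests(dataset: Dataset, graph: CausalGraph, method: str = "reml") -> list[IndependenceClaim]:
    return [dsep_test(dataset, graph, c, method=method) for c in basis_set(graph)]


def fishers_c(claims: list[IndependenceClaim]) -> GoodnessOfFit:
    """Fisher's C over the basis-set p-values; chi-square with 2k df.

    An empty claim list yields C = 0, df = 0, p = 1 by convention (a model
    with no testable independence claims is saturated).
    """
    if not claims:
        return GoodnessOfFit(C=0.0, df=0, p_value=1.0, claims=())
    ps = []
    for c in claims:
        p = c.p_value
        if p is None or not 0.0 < p <= 1.0:
            raise ValueError(
                f"claim ({c.x}, {c.y}) has p-value {p!r}; all p-values must lie "
                "in (0, 1] (p = 0 suggests a degenerate test)"
            )
        ps.append(p)
    C = -2.0 * float(np.sum(np.log(ps)))
    df = 2 * len(ps)
    return GoodnessOfFit(
        C=C, df=df, p_value=float(stats.chi2.sf(C, df)), claims=tuple(claims)
    )
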