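"""Path-based effect decomposition on the fitted DAG, with cluster bootstrap.

On a linear recursive system the effect of a source on a target decomposes
over directed paths: each path contributes the product of its edge
coefficients, the *direct* effect is the source's coefficient in the
target's own equation, the *indirect* effect is the sum of all multi-edge
path contributions, and total = direct + indirect (exactly, by
construction).  Per-mediator effects sum the contributions of every path
whose interior passes through that mediator; because paths may pass through
several mediators, per-mediator sums can overlap and need not add up to the
indirect effect.

Confidence intervals come from a nonparametric cluster bootstrap:
subjects (the experiment's sampling unit) are resampled with replacement
with their full trial blocks, all node models are refitted, and percentile
bounds are taken at 2.5% / 97.5%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import Dataset
from .lmm import fit_crossed_intercepts
from .psem import CausalGraph, NodeFit, fit_node

logger = logging.getLogger("sugarsem")

__all__ = [
    "PathEffect",
    "EffectTable",
    "BootstrapResult",
    "EffectError",
    "enumerate_paths",
    "decompose",
    "bootstrap_effects",
    "effects_report",
]


class EffectError(ValueError):
    """A required fitted edge coefficient is unavailable."""


@dataclass(frozen=True)
class PathEffect:
    """One directed path and the product of its fitted edge coefficients."""

    path: tuple[str, ...]
    contribution: float | None = None


@dataclass
class EffectTable:
    """Direct / indirect / total / per-mediator effects of source on target."""

    source: str
    target: str
    direct: float
    indirect: float
    total: float
    per_mediator: dict[str, float]
    paths: tuple[PathEffect, ...]
    se: dict[str, float] | None = None
    ci: dict[str, tuple[float, float]] | None = None
    significant: dict[str, bool] | None = None

    def entries(self) -> dict[str, float]:
        out = {"direct": self.direct, "indirect": self.indirect, "total": self.total}
        out.update({f"mediator:{m}": v for m, v in self.per_mediator.items()})
        return out


@dataclass
class BootstrapResult:
    """Raw replicate-level effect estimates from the cluster bootstrap."""

    n_boot: int
    seed: int
    resample_unit: str
    replicate_effects: pd.DataFrame  # one row per successful replicate
    n_failed: int = 0


def enumerate_paths(graph: CausalGraph, source: str, target: str) -> list[PathEffect]:
    """All directed simple paths source -> target, in canonical order.

    Canonical = lexicographic in the graph's node order, so the output is
    independent of edge-insertion order.
    """
    if source == target:
        raise ValueError("source and target must differ")
    for node in (source, target):
        if node not in graph.nodes:
            raise ValueError(f"{node!r} is not a node of the graph")
    order = {n: i for i, n in enumerate(graph.nodes)}
    paths = [tuple(p) for p in nx.all_simple_paths(graph.to_networkx(), source, target)]
    paths.sort(key=lambda p: tuple(order[n] for n in p))
    return [PathEffect(path=p) for p in paths]


def _coef_lookup(fits) -> dict[str, dict[str, float]]:
    """Accept a list of NodeFit or a plain {response: {predictor: coef}} map."""
    if isinstance(fits, dict):
        return fits
    table: dict[str, dict[str, float]] = {}
    for fit in fits:
        if not isinstance(fit, NodeFit):
            raise TypeError("fits must be NodeFit instances or a coefficient mapping")
        table[fit.response] = {
            pred: float(fit.params.at[pred, "estimate"]) for pred in fit.predictors
        }
    return table


def decompose(
    graph: CausalGraph,
    fits,
    source: str,
    target: str,
    standardize: bool = False,
    data: Dataset | None = None,
) -> EffectTable:
    """Path-algebra effect decomposition of source on target.

    ``fits`` is the list of fitted node models (or a bare coefficient
    mapping).  With ``standardize=True`` each edge coefficient is scaled by
    sd(predictor)/sd(response) using the observed standard deviations of
    ``data`` before the path products are formed.
    """
    coefs = _coef_lookup(fits)
    if standardize:
        if data is None:
            raise ValueError("standardize=True requires the observed dataset")
        sds = data.records[list(graph.nodes)].std(ddof=1)

    def edge_coef(u: str, v: str) -> float:
        try:
            beta = coefs[v][u]
        except KeyError:
            raise EffectError(f"no fitted coefficient for edge {u} -> {v}") from None
        if standardize:
            beta *= sds[u] / sds[v]
        return float(beta)

    paths = []
    for pe in enumerate_paths(graph, source, target):
        contrib = 1.0
        for u, v in zip(pe.path[:-1], pe.path[1:]):
            contrib *= edge_coef(u, v)
        paths.append(PathEffect(path=pe.path, contribution=contrib))

    direct = 0.0
    indirect = 0.0
    mediators = [n for n in graph.nodes if n not in (source, target)]
    per_mediator = {m: 0.0 for m in mediators}
    seen_mediators = set()
    for pe in paths:
        if len(pe.path) == 2:
            direct += pe.contribution
        else:
            indirect += pe.contribution
            for m in pe.path[1:-1]:
                per_mediator[m] += pe.contribution
                seen_mediators.add(m)
    per_mediator = {m: v for m, v in per_mediator.items() if m in seen_mediators}
    return EffectTable(
        source=source,
        target=target,
        direct=direct,
        indirect=indirect,
        total=direct + indirect,
        per_mediator=per_mediator,
        paths=tuple(paths),
    )


def _nodes_to_refit(graph: CausalGraph, source: str, target: str) -> list[str]:
    """Responses whose coefficients enter some source -> target path."""
    needed = set()
    for pe in enumerate_paths(graph, source, target):
        needed.update(pe.path[1:])
    topo = [n for n in graph.topological_order() if n in needed]
    return topo


def bootstrap_effects(
    dataset: Dataset,
    graph: CausalGraph,
    source: str,
    target: str,
    n_boot: int = 1000,
    seed: int = 0,
    resample_unit: str = "subject",
    standardize: bool = False,
    method: str = "reml",
) -> tuple[EffectTable, BootstrapResult]:
    """Cluster-bootstrap percentile CIs for the effect decomposition.

    Clusters (subjects by default, product pairs with
    ``resample_unit="pair"``) are drawn with replacement; each resampled
    cluster keeps its full record block and duplicates receive fresh
    identifiers so the random-intercept structure treats them as distinct
    levels.  Replicates whose refit fails are dropped with a warning; more
    than 5% failures aborts.

    Returns the point-estimate table (fitted on the original data) with
    ``se``, ``ci`` and ``significant`` filled in, plus the replicate-level
    results.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if resample_unit not in ("subject", "pair"):
        raise ValueError("resample_unit must be 'subject' or 'pair'")
    unit_col = "subject_id" if resample_unit == "subject" else "pair_id"

    refit_nodes = _nodes_to_refit(graph, source, target)
    point_fits = {
        node: fit_node(dataset, graph, node, method=method) for node in refit_nodes
    }
    table = decompose(
        graph, list(point_fits.values()), source, target,
        standardize=standardize, data=dataset,
    )
    starts = {
        node: (
            (f.variance_components["subject_sd"] / f.variance_components["residual_sd"]) ** 2
            if f.variance_components["residual_sd"] > 0 else 0.1,
            (f.variance_components["pair_sd"] / f.variance_components["residual_sd"]) ** 2
            if f.variance_components["residual_sd"] > 0 else 0.1,
        )
        for node, f in point_fits.items()
    }

    rec = dataset.records
    units = sorted(rec[unit_col].unique())
    unit_rows = [np.flatnonzero((rec[unit_col] == u).to_numpy()) for u in units]
    sizes = np.array([len(r) for r in unit_rows])
    other_col = "pair_id" if unit_col == "subject_id" else "subject_id"
    other_codes = pd.factorize(rec[other_col])[0]
    rng = np.random.default_rng(seed)

    # design templates, resampled by row indexing (no per-replicate pandas)
    templates = {}
    for node in refit_nodes:
        preds = point_fits[node].predictors
        X = np.column_stack(
            [np.ones(len(rec))]
            + [rec[p].to_numpy(dtype=float) for p in preds]
        )
        templates[node] = (
            rec[node].to_numpy(dtype=float),
            X,
            ["const", *preds],
        )
    node_values = rec[list(graph.nodes)].to_numpy(dtype=float) if standardize else None

    rows = []
    n_failed = 0
    for _ in range(n_boot):
        draw = rng.integers(0, len(units), len(units))
        idx = np.concatenate([unit_rows[k] for k in draw])
        # fresh code per resampled cluster so duplicates are distinct
        # random-effect levels
        new_unit = np.repeat(np.arange(len(units)), sizes[draw])
        other = other_codes[idx]
        subj, pair = (new_unit, other) if unit_col == "subject_id" else (other, new_unit)
        try:
            coefs = {}
            for node in refit_nodes:
                y, X, names = templates[node]
                res = fit_crossed_intercepts(
                    y[idx], X[idx], subj, pair,
                    method=method, start=starts[node], names=names, polish=False,
                )
                coefs[node] = dict(zip(names, res.params.to_numpy()))
            if standardize:
                sds = pd.Series(
                    node_values[idx].std(axis=0, ddof=1), index=list(graph.nodes)
                )
                for node in coefs:
                    coefs[node] = {
                        p: (b * sds[p] / sds[node] if p in sds.index else b)
                        for p, b in coefs[node].items()
                    }
                t = decompose(graph, coefs, source, target)
            else:
                t = decompose(graph, coefs, source, target)
        except (np.linalg.LinAlgError, ValueError) as exc:
            n_failed += 1
            logger.warning("bootstrap replicate dropped: %s", exc)
            continue
        rows.append(t.entries())

    if n_failed > 0.05 * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap replicates failed (> 5%); "
            "the model is too unstable for these data"
        )
    reps = pd.DataFrame(rows)
    table.se = {k: float(reps[k].std(ddof=1)) for k in reps.columns}
    table.ci = {
        k: (
            float(np.percentile(reps[k], 2.5)),
            float(np.percentile(reps[k], 97.5)),
        )
        for k in reps.columns
    }
    table.significant = {k: not (lo <= 0.0 <= hi) for k, (lo, hi) in table.ci.items()}
    boot_result = BootstrapResult(
        n_boot=n_boot,
        seed=seed,
        resample_unit=resample_unit,
        replicate_effects=reps,
        n_failed=n_failed,
    )
    return table, boot_result


def effects_report(tables: list[EffectTable]) -> pd.DataFrame:
    """Flatten effect tables into the Direct/Indirect/Total + mediator layout.

    One row per entry: three summary rows, then one per mediator; columns
    carry the estimate, bootstrap SE and percentile CI bounds when present.
    """
    rows = []
    for t in tables:
        for key, value in t.entries().items():
            if key.startswith("mediator:"):
                effect_type, variable = "Mediator", key.split(":", 1)[1]
            else:
                effect_type, variable = key.capitalize(), t.source
            row = {
                "source": t.source,
                "target": t.target,
                "effect_type": effect_type,
                "variable": variable,
                "estimate": value,
                "se": t.se.get(key) if t.se else np.nan,
                "lower_ci": t.ci[key][0] if t.ci else np.nan,
                "upper_ci": t.ci[key][1] if t.ci else np.nan,
                "significant": t.significant.get(key) if t.significant else np.nan,
            }
            rows.append(row)
    return pd.DataFrame(rows)
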