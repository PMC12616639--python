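"""Replicate simulation studies: parameter recovery, calibration, coverage.

These drive the package's own validation: datasets are generated from the
known generating model and pushed through the estimation machinery, so
bias, test size and interval coverage can be measured against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import bootstrap_effects
from .psem import CausalGraph, basis_set, default_graph, dsep_test, fishers_c, fit_node
from .synthetic import GeneratorConfig, simulate_experiment

__all__ = [
    "RecoveryResult",
    "label_recovery_study",
    "dsep_calibration_study",
    "coverage_study",
    "sweetness_subgraph",
]

#: (node, predictor) pairs of the headline recovery targets.
RECOVERY_TARGETS = (
    ("sweetness", "label"),
    ("familiarity", "label"),
    ("healthiness", "label"),
    ("bid", "tastiness"),
)


@dataclass
class RecoveryResult:
    """Replicate-level estimates for one (response, predictor) target."""

    response: str
    predictor: str
    truth: float
    estimates: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.estimates.mean())

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the replicate mean."""
        return float(self.estimates.std(ddof=1) / np.sqrt(len(self.estimates)))


def label_recovery_study(
    seeds,
    targets=RECOVERY_TARGETS,
    config: GeneratorConfig | None = None,
    graph: CausalGraph | None = None,
) -> dict[tuple[str, str], RecoveryResult]:
    """Simulate one dataset per seed and refit the targeted node models.

    Each target's generating coefficient is read from the config, so the
    study is a closed loop: generate from known truth, estimate, compare.
    """
    base = config if config is not None else GeneratorConfig()
    graph = graph if graph is not None else default_graph()
    nodes = sorted({resp for resp, _ in targets})
    estimates: dict[tuple[str, str], list[float]] = {t: [] for t in targets}
    for seed in seeds:
        ds = simulate_experiment(base.replace(seed=int(seed)))
        fits = {node: fit_node(ds, graph, node) for node in nodes}
        for resp, pred in targets:
            estimates[(resp, pred)].append(fits[resp].coefficient(pred))
    return {
        (resp, pred): RecoveryResult(
            response=resp,
            predictor=pred,
            truth=float(base.coefficients[resp][pred]),
            estimates=np.asarray(vals),
        )
        for (resp, pred), vals in estimates.items()
    }


def dsep_calibration_study(
    config: GeneratorConfig, n_replicates: int, seed: int = 0
) -> pd.DataFrame:
    """Null distribution of the d-separation p-values and Fisher's C.

    The generating model matches the analysis DAG, so every basis-set claim
    holds and its p-value should be uniform; one row per replicate with the
    claim p-values and the combined Fisher's C p-value.
    """
    graph = default_graph()
    claims = basis_set(graph)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        ds = simulate_experiment(config.replace(seed=rep_seed))
        tested = [dsep_test(ds, graph, c) for c in claims]
        row = {f"p_{c.y}": c.p_value for c in tested}
        row["fisher_p"] = fishers_c(tested).p_value
        row["seed"] = rep_seed
        rows.append(row)
    return pd.DataFrame(rows)


def sweetness_subgraph() -> CausalGraph:
    """Two-node label -> sweetness model (the sweetness equation alone)."""
    return CausalGraph(
        nodes=("label", "sweetness"),
        edges=(("label", "sweetness"),),
        controls={"sweetness": ("gender", "age")},
        grouping={"sweetness": ("subject_id", "pair_id")},
    )


def coverage_study(
    config: GeneratorConfig,
    n_replicates: int,
    n_boot: int,
    seed: int = 0,
    graph: CausalGraph | None = None,
    source: str = "label",
    target: str = "sweetness",
) -> pd.DataFrame:
    """Does the 95% percentile bootstrap CI cover the generating total effect?

    One row per outer replicate: the point estimate, the CI and whether it
    covers the generating coefficient (the total label -> sweetness effect
    equals the single direct edge).
    """
    graph = graph if graph is not None else sweetness_subgraph()
    truth = float(config.coefficients[target][source])
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        data_seed = int(rng.integers(0, 2**31 - 1))
        boot_seed = int(rng.integers(0, 2**31 - 1))
        ds = simulate_experiment(config.replace(seed=data_seed))
        table, _ = bootstrap_effects(
            ds, graph, source, target, n_boot=n_boot, seed=boot_seed,
        )
        lo, hi = table.ci["total"]
        rows.append(
            {
                "estimate": table.total,
                "lower": lo,
                "upper": hi,
                "covered": lo <= truth <= hi,
                "data_seed": data_seed,
                "boot_seed": boot_seed,
            }
        )
    return pd.DataFrame(rows)
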