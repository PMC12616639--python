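"""End-to-end orchestration: simulate -> fit -> effects -> describe -> report.

A single global seed deterministically spawns per-stage substreams
(generation, per-target bootstraps) via :class:`numpy.random.SeedSequence`,
so the whole bundle is byte-reproducible and individual stages can be rerun
independently with identical results.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataio import Dataset, read_trials, write_trials
from .descriptives import alpha_by_characteristic, condition_summary
from .effects import bootstrap_effects, effects_report
from .psem import CausalGraph, NodeFit, default_graph, dsep_tests, fishers_c, fit_all
from .synthetic import GeneratorConfig, simulate_experiment

logger = logging.getLogger("sugarsem")

__all__ = ["PipelineConfig", "run_pipeline", "load_real_data", "coefficients_table"]

EFFECT_TARGETS = ("bid", "tastiness")


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    graph: CausalGraph | None = None  # None -> default five-equation model
    n_boot: int = 1000
    seed: int = 0
    output_dir: str = "sugarsem_run"
    standardize: bool = False
    resample_unit: str = "subject"
    method: str = "reml"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = copy.deepcopy(data)
        gen = data.pop("generator", {})
        cfg = cls(generator=GeneratorConfig.from_dict(gen))
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown pipeline config field {key!r}")
            setattr(cfg, key, val)
        return cfg


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent substream seeds (< 2**31) from the global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def coefficients_table(fits: list[NodeFit]) -> pd.DataFrame:
    """Long coefficient table mirroring the study's estimation-results layout."""
    rows = []
    for fit in fits:
        for pred, row in fit.params.iterrows():
            rows.append(
                {
                    "response": fit.response,
                    "predictor": pred,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "z": row["z"],
                    "p": row["p"],
                }
            )
    return pd.DataFrame(rows)


def _model_stats(fits: list[NodeFit]) -> pd.DataFrame:
    rows = []
    for fit in fits:
        rows.append(
            {
                "response": fit.response,
                "n_obs": fit.n_obs,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "bic": fit.bic,
                "subject_sd": fit.variance_components["subject_sd"],
                "pair_sd": fit.variance_components["pair_sd"],
                "residual_sd": fit.variance_components["residual_sd"],
                "method": fit.method,
                "warnings": "; ".join(fit.warnings),
            }
        )
    df = pd.DataFrame(rows)
    total = {
        "response": "TOTAL",
        "n_obs": int(df["n_obs"].iloc[0]) if len(df) else 0,
        "loglik": df["loglik"].sum(),
        "aic": df["aic"].sum(),
        "bic": df["bic"].sum(),
        "subject_sd": np.nan,
        "pair_sd": np.nan,
        "residual_sd": np.nan,
        "method": df["method"].iloc[0] if len(df) else "",
        "warnings": "",
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``output_dir``.

    Bundle: trials.csv, coefficients.csv + model_stats.csv, gof.json,
    effects_bid.csv, effects_tastiness.csv, descriptives.csv, tests.json,
    manifest.json.  Returns the in-memory results keyed by stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = config.graph if config.graph is not None else default_graph()
    gen_seed, boot_seed_bid, boot_seed_tast, session_seed = _stage_seeds(config.seed, 4)

    gen_cfg = config.generator.replace(seed=gen_seed)
    dataset = simulate_experiment(gen_cfg)
    write_trials(dataset, out / "trials.csv")
    logger.info("simulated %d records (seed %d)", dataset.n_records, gen_seed)

    fits = fit_all(dataset, graph, method=config.method)
    coefficients_table(fits).to_csv(out / "coefficients.csv", index=False)
    _model_stats(fits).to_csv(out / "model_stats.csv", index=False)

    claims = dsep_tests(dataset, graph, method=config.method)
    gof = fishers_c(claims)
    gof_payload = {
        "C": gof.C,
        "df": gof.df,
        "p_value": gof.p_value,
        "claims": [
            {
                "x": c.x,
                "y": c.y,
                "conditioning_set": list(c.conditioning_set),
                "p_value": c.p_value,
            }
            for c in gof.claims
        ],
    }
    (out / "gof.json").write_text(json.dumps(gof_payload, indent=2))

    tables = {}
    for target, boot_seed in zip(EFFECT_TARGETS, (boot_seed_bid, boot_seed_tast)):
        table, _ = bootstrap_effects(
            dataset,
            graph,
            "label",
            target,
            n_boot=config.n_boot,
            seed=boot_seed,
            resample_unit=config.resample_unit,
            standardize=config.standardize,
            method=config.method,
        )
        tables[target] = table
        effects_report([table]).to_csv(out / f"effects_{target}.csv", index=False)

    summary = condition_summary(dataset)
    summary.table.to_csv(out / "descriptives.csv")
    tests_payload = {
        "condition_tests": summary.tests,
        "cronbach_alpha": alpha_by_characteristic(dataset),
    }
    (out / "tests.json").write_text(json.dumps(tests_payload, indent=2))

    manifest = {
        "sugarsem_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stage_seeds": {
            "generator": gen_seed,
            "bootstrap_bid": boot_seed_bid,
            "bootstrap_tastiness": boot_seed_tast,
            "session": session_seed,
        },
        "n_boot": config.n_boot,
        "standardize": config.standardize,
        "resample_unit": config.resample_unit,
        "method": config.method,
        "generator": {
            "n_subjects": gen_cfg.n_subjects,
            "n_pairs": gen_cfg.n_pairs,
            "discretize": gen_cfg.discretize,
            "coefficients": gen_cfg.coefficients,
            "residual_sd": gen_cfg.residual_sd,
            "subject_re_sd": gen_cfg.subject_re_sd,
            "pair_re_sd": gen_cfg.pair_re_sd,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "dataset": dataset,
        "fits": fits,
        "gof": gof,
        "effects": tables,
        "descriptives": summary,
        "output_dir": str(out),
    }


def load_real_data(path, schema: dict[str, str] | None = None) -> Dataset:
    """Load a user-supplied trials file into the same analysis path.

    The deposited experimental data (or any file in the canonical or mapped
    schema) flow through fit/effects/describe exactly as synthetic data.  An
    incomplete subject x product design is reported as a warning and the
    analysis proceeds with the unbalanced fit.
    """
    dataset = read_trials(path, schema=schema)
    for v in dataset.validate():
        if v.severity == "warning":
            logger.warning("%s", v)
    return dataset
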