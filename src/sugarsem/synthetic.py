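"""Synthetic data generator for the sugar-free-label bidding experiment.

Emulates the study design: 50 subjects bid on 60 confectionery products (30
matched sugar-containing / sugar-free pairs, the sugar-free member carrying
the label) and rate each product on four 1-5 Likert scales.  Responses are
generated from the recursive linear system the mediation analysis assumes,

    sweetness    = f(label)                                   + controls
    familiarity  = f(label, sweetness)                        + controls
    healthiness  = f(label, familiarity, sweetness)           + controls
    tastiness    = f(label, familiarity, sweetness, health.)  + controls
    bid          = f(label, all four ratings, trial index)    + controls

each equation adding its intercept, gender/age control terms, a
subject-level and a pair-level random intercept, and Gaussian residual
noise.  Edge coefficients default to the point estimates the study reports,
so downstream fitting can be checked against a known ground truth.

Latent (continuous) responses are the default; ``discretize=True`` rounds
ratings to integers clipped to [1, 5] and bids to integers clipped to
[0, 150], reproducing the observable scales at the cost of a small
attenuation bias in linear-model recovery.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import bdm
from .dataio import ConfigError, Dataset

__all__ = [
    "EQUATIONS",
    "GENERATION_ORDER",
    "GeneratorConfig",
    "LatentDraws",
    "default_coefficients",
    "generate_subjects",
    "generate_products",
    "simulate_experiment",
    "simulate_bidding_session",
]

#: Response nodes in generative (topological) order.
GENERATION_ORDER = ["sweetness", "familiarity", "healthiness", "tastiness", "bid"]
EQUATIONS = GENERATION_ORDER


def default_coefficients() -> dict[str, dict[str, float]]:
    """Per-equation intercept ("const") and edge/control coefficients.

    Defaults are the study's fitted point estimates, so that simulate ->
    refit recovers them.
    """
    return {
        "sweetness": {
            "const": 3.678,
            "label": -0.518,
            "gender": 0.077,
            "age": 0.006,
        },
        "familiarity": {
            "const": 3.161,
            "label": -0.877,
            "sweetness": 0.275,
            "gender": 0.191,
            "age": -0.003,
        },
        "healthiness": {
            "const": 3.081,
            "label": 0.353,
            "familiarity": 0.025,
            "sweetness": -0.230,
            "gender": 0.099,
            "age": -0.018,
        },
        "tastiness": {
            "const": 1.184,
            "label": -0.074,
            "familiarity": 0.292,
            "sweetness": 0.110,
            "healthiness": 0.280,
            "gender": 0.087,
            "age": 0.009,
        },
        "bid": {
            "const": 1.445,
            "label": 2.484,
            "familiarity": 1.274,
            "sweetness": 1.935,
            "healthiness": 4.352,
            "tastiness": 5.498,
            "trial_index": -0.049,
            "gender": 7.063,
            "age": -0.094,
        },
    }


def _default_sds(rating: float, bid_: float) -> dict[str, float]:
    return {eq: (bid_ if eq == "bid" else rating) for eq in EQUATIONS}


@dataclass
class GeneratorConfig:
    """Full parameterization of the data-generating process.

    Residual and random-intercept SDs are not reported by the study; the
    defaults give rating dispersion comparable to the observed rating SDs
    (about 1.0-1.3 Likert points) and a plausible bid spread.
    """

    n_subjects: int = 50
    n_pairs: int = 30
    coefficients: dict[str, dict[str, float]] = field(default_factory=default_coefficients)
    residual_sd: dict[str, float] = field(default_factory=lambda: _default_sds(1.0, 25.0))
    subject_re_sd: dict[str, float] = field(default_factory=lambda: _default_sds(0.4, 12.0))
    pair_re_sd: dict[str, float] = field(default_factory=lambda: _default_sds(0.25, 6.0))
    age_mean: float = 26.2
    age_sd: float = 6.9
    age_range: tuple[int, int] = (18, 51)
    n_female: int = 29
    n_male: int = 21
    center_age: bool = False
    discretize: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_pairs < 1:
            raise ConfigError("n_subjects and n_pairs must be >= 1")
        if self.n_male + self.n_female != self.n_subjects:
            raise ConfigError(
                f"n_male + n_female = {self.n_male + self.n_female} "
                f"must equal n_subjects = {self.n_subjects}"
            )
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError("age_range must be ordered (low, high)")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be > 0")
        for name, table in (
            ("residual_sd", self.residual_sd),
            ("subject_re_sd", self.subject_re_sd),
            ("pair_re_sd", self.pair_re_sd),
        ):
            for eq in EQUATIONS:
                if eq not in table:
                    raise ConfigError(f"{name} missing equation {eq!r}")
                if table[eq] < 0:
                    raise ConfigError(f"{name}[{eq!r}] must be >= 0")
        for eq in EQUATIONS:
            if eq not in self.coefficients:
                raise ConfigError(f"coefficients missing equation {eq!r}")
            if "const" not in self.coefficients[eq]:
                raise ConfigError(f"coefficients[{eq!r}] missing intercept 'const'")

    def replace(self, **kwargs) -> "GeneratorConfig":
        """Deep copy with selected fields overridden."""
        cfg = copy.deepcopy(self)
        for key, val in kwargs.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown GeneratorConfig field {key!r}")
            setattr(cfg, key, val)
        return cfg

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown GeneratorConfig field {key!r}")
            if key in ("coefficients", "residual_sd", "subject_re_sd", "pair_re_sd"):
                base = getattr(cfg, key)
                for eq, sub in val.items():
                    if key == "coefficients":
                        base.setdefault(eq, {}).update(sub)
                    else:
                        base[eq] = float(sub)
            elif key == "age_range":
                cfg.age_range = (int(val[0]), int(val[1]))
            else:
                setattr(cfg, key, val)
        return cfg


@dataclass
class LatentDraws:
    """The random-effect and residual draws behind one simulated dataset."""

    subject_effects: pd.DataFrame  # n_subjects x equations
    pair_effects: pd.DataFrame  # n_pairs x equations
    residuals: pd.DataFrame  # n_records x equations


def generate_subjects(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Subject table: ids, exact gender counts, truncated-normal integer ages."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_subjects)))
    ids = [f"S{i + 1:0{width}d}" for i in range(config.n_subjects)]
    gender = np.array([0] * config.n_male + [1] * config.n_female)
    rng.shuffle(gender)
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd,
        size=config.n_subjects, random_state=rng,
    )
    ages = np.clip(np.rint(ages), lo, hi).astype(int)
    return pd.DataFrame({"subject_id": ids, "gender": gender, "age": ages})


def generate_products(config: GeneratorConfig) -> pd.DataFrame:
    """Product table: 2 x n_pairs products, one labeled member per pair."""
    config.validate()
    width = max(2, len(str(config.n_pairs)))
    rows = []
    for i in range(config.n_pairs):
        pair = f"P{i + 1:0{width}d}"
        rows.append({"product_id": f"{pair}_sc", "pair_id": pair, "label": 0})
        rows.append({"product_id": f"{pair}_sf", "pair_id": pair, "label": 1})
    return pd.DataFrame(rows)


def simulate_experiment(
    config: GeneratorConfig, return_draws: bool = False
) -> Dataset | tuple[Dataset, LatentDraws]:
    """Simulate the full experiment: one record per subject x product.

    Reproducible: identical config (including seed) yields an identical
    dataset.  The bidding sequence (``trial_index``) is an independent
    uniform permutation of 1..2*n_pairs per subject.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = generate_subjects(config, rng)
    products = generate_products(config)
    n_products = len(products)
    n = config.n_subjects * n_products

    rec = subjects.merge(products, how="cross")
    rec["trial_index"] = np.concatenate(
        [rng.permutation(n_products) + 1 for _ in range(config.n_subjects)]
    )

    subject_codes = np.repeat(np.arange(config.n_subjects), n_products)
    pair_codes = np.tile(np.repeat(np.arange(config.n_pairs), 2), config.n_subjects)

    sub_eff = pd.DataFrame(
        {eq: rng.normal(0.0, config.subject_re_sd[eq], config.n_subjects) for eq in EQUATIONS},
        index=subjects["subject_id"],
    )
    pair_eff = pd.DataFrame(
        {eq: rng.normal(0.0, config.pair_re_sd[eq], config.n_pairs) for eq in EQUATIONS},
        index=products["pair_id"].unique(),
    )
    resid = pd.DataFrame(
        {eq: rng.normal(0.0, config.residual_sd[eq], n) for eq in EQUATIONS}
    )

    age_values = rec["age"].to_numpy(dtype=float)
    if config.center_age:
        age_values = age_values - age_values.mean()
    covariates: dict[str, np.ndarray] = {
        "label": rec["label"].to_numpy(dtype=float),
        "gender": rec["gender"].to_numpy(dtype=float),
        "age": age_values,
        "trial_index": rec["trial_index"].to_numpy(dtype=float),
    }

    for eq in GENERATION_ORDER:
        coefs = config.coefficients[eq]
        lin = np.full(n, float(coefs["const"]))
        for pred, beta in coefs.items():
            if pred == "const":
                continue
            if pred not in covariates:
                raise ConfigError(
                    f"coefficients[{eq!r}] refers to {pred!r}, which is not "
                    "generated before this equation"
                )
            lin = lin + beta * covariates[pred]
        lin = lin + sub_eff[eq].to_numpy()[subject_codes]
        lin = lin + pair_eff[eq].to_numpy()[pair_codes]
        lin = lin + resid[eq].to_numpy()
        covariates[eq] = lin
        rec[eq] = lin

    if config.discretize:
        for eq in GENERATION_ORDER:
            lo, hi = (0, 150) if eq == "bid" else (1, 5)
            rec[eq] = np.clip(np.rint(rec[eq]), lo, hi).astype(int)

    dataset = Dataset(
        rec,
        provenance=f"synthetic:seed={config.seed}",
        discretized=config.discretize,
    )
    if return_draws:
        return dataset, LatentDraws(sub_eff, pair_eff, resid)
    return dataset


def simulate_bidding_session(dataset: Dataset, seed: int) -> pd.DataFrame:
    """Realize the end-of-session lottery once per subject.

    For each subject one product is drawn uniformly from their records and
    one capsule uniformly from 1..150; the auction outcome follows the BDM
    rule.  Latent-mode bids are rounded and clipped to the admissible
    integer scale before the auction (the mechanism is defined on 0..150).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for subj, block in dataset.records.groupby("subject_id", sort=True):
        if block.empty:  # pragma: no cover - groupby never yields empty
            raise ValueError(f"subject {subj} has no records")
        pick = block.iloc[rng.integers(0, len(block))]
        capsule = int(rng.integers(bdm.CAPSULE_MIN, bdm.CAPSULE_MAX + 1))
        bid = int(np.clip(np.rint(pick["bid"]), 0, bdm.ENDOWMENT))
        outcome = bdm.bdm_outcome(bid, capsule)
        rows.append(
            {
                "subject_id": subj,
                "product_id": pick["product_id"],
                "bid": outcome.bid,
                "capsule_price": outcome.capsule_price,
                "purchased": outcome.purchased,
                "payment": outcome.payment,
                "final_balance": outcome.final_balance,
            }
        )
    if not rows:
        raise ValueError("dataset contains no subjects")
    return pd.DataFrame(rows)
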