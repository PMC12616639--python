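"""Long-format trial data: schema, validation, CSV round-tripping, config I/O.

One row is one subject x product observation from the bidding experiment:
a willingness-to-pay bid (0-150 monetary units) plus four 1-5 Likert
ratings (familiarity, sweetness, healthiness, tastiness), the sugar-free
label flag of the product, the position of the product in the subject's
bidding sequence, and subject covariates (gender, age).

Two value modes exist.  In *discretized* ("realism") mode bids are integers
in [0, 150] and ratings integers in [1, 5], as in the real experiment.  In
*latent* mode responses are the continuous values of the generating linear
model and range checks do not apply; this is the mode used for parameter
recovery, where rounding and clipping would bias the linear fits.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_COLUMNS",
    "RATING_COLUMNS",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "Violation",
    "read_trials",
    "write_trials",
    "validate",
    "load_config",
    "configure_logging",
]

CANONICAL_COLUMNS = [
    "subject_id",
    "product_id",
    "pair_id",
    "label",
    "bid",
    "familiarity",
    "sweetness",
    "healthiness",
    "tastiness",
    "trial_index",
    "gender",
    "age",
]
RATING_COLUMNS = ["familiarity", "sweetness", "healthiness", "tastiness"]

logger = logging.getLogger("sugarsem")


class SchemaError(ValueError):
    """A required column is missing or cannot be mapped."""


class ValidationError(ValueError):
    """The data violate a hard invariant of the trial-record schema."""


class ConfigError(ValueError):
    """A configuration value is out of its admissible range."""


@dataclass(frozen=True)
class Violation:
    """One invariant violation; ``row`` is the 0-based record index or None."""

    row: int | None
    field: str
    message: str
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"row {self.row}" if self.row is not None else "dataset"
        return f"[{self.severity}] {where} / {self.field}: {self.message}"


class Dataset:
    """Validated long-format trial table with derived subject/product tables.

    Parameters
    ----------
    records : DataFrame with the canonical columns (order is preserved).
    provenance : free-text origin tag (synthetic seed or source path).
    discretized : whether integer/range invariants apply; inferred from the
        data (all responses integral) when not given.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        provenance: str = "",
        discretized: bool | None = None,
    ):
        missing = [c for c in CANONICAL_COLUMNS if c not in records.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        self.records = records.loc[:, CANONICAL_COLUMNS].reset_index(drop=True)
        self.provenance = provenance
        if discretized is None:
            vals = self.records[["bid", *RATING_COLUMNS]].to_numpy(dtype=float)
            discretized = bool(np.all(np.isfinite(vals)) and np.all(vals == np.round(vals)))
        self.discretized = discretized
        self.subject_table = (
            self.records.groupby("subject_id", sort=True)[["gender", "age"]]
            .first()
            .reset_index()
        )
        self.product_table = (
            self.records.groupby("product_id", sort=True)[["pair_id", "label"]]
            .first()
            .reset_index()
        )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_table)

    @property
    def n_products(self) -> int:
        return len(self.product_table)

    @property
    def n_pairs(self) -> int:
        return self.records["pair_id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Dataset(n_records={self.n_records}, n_subjects={self.n_subjects}, "
            f"n_products={self.n_products}, provenance={self.provenance!r})"
        )

    def validate(self) -> list[Violation]:
        return validate(self)


def validate(dataset: Dataset) -> list[Violation]:
    """Check every record/dataset invariant; violations are data, not errors.

    Severity "error" marks breaches of hard invariants (ranges, duplicate
    cells, broken pair structure, inconsistent covariates); an incomplete
    subject x product design is only a "warning" (the mixed models handle
    unbalanced data).
    """
    rec = dataset.records
    out: list[Violation] = []

    for col in CANONICAL_COLUMNS:
        na = rec.index[rec[col].isna()]
        for i in na:
            out.append(Violation(int(i), col, "missing value"))
    if out:
        return out  # downstream checks assume complete cases

    if dataset.discretized:
        bad = rec.index[(rec["bid"] < 0) | (rec["bid"] > 150)]
        for i in bad:
            out.append(Violation(int(i), "bid", f"bid {rec.at[i, 'bid']} outside [0, 150]"))
        for col in RATING_COLUMNS:
            bad = rec.index[(rec[col] < 1) | (rec[col] > 5)]
            for i in bad:
                out.append(Violation(int(i), col, f"rating {rec.at[i, col]} outside [1, 5]"))

    bad = rec.index[rec["trial_index"] < 1]
    for i in bad:
        out.append(Violation(int(i), "trial_index", "trial_index must be >= 1"))
    bad = rec.index[~rec["gender"].isin([0, 1])]
    for i in bad:
        out.append(Violation(int(i), "gender", "gender code must be 0 or 1"))
    bad = rec.index[rec["age"] < 18]
    for i in bad:
        out.append(Violation(int(i), "age", "age must be >= 18"))
    bad = rec.index[~rec["label"].isin([0, 1])]
    for i in bad:
        out.append(Violation(int(i), "label", "label must be 0 or 1"))

    dup = rec.duplicated(subset=["subject_id", "product_id"], keep=False)
    for i in rec.index[dup]:
        out.append(
            Violation(int(i), "subject_id/product_id", "duplicated subject x product cell")
        )

    # product -> (pair, label) must be a function
    pm = rec.groupby("product_id")[["pair_id", "label"]].nunique()
    for prod, row in pm.iterrows():
        if row["pair_id"] > 1:
            out.append(Violation(None, "pair_id", f"product {prod} maps to multiple pairs"))
        if row["label"] > 1:
            out.append(Violation(None, "label", f"product {prod} maps to multiple labels"))

    # each pair: exactly two products, one labeled and one not
    pairs = rec.drop_duplicates("product_id").groupby("pair_id")["label"]
    for pair, labels in pairs:
        if len(labels) != 2 or set(labels) != {0, 1}:
            out.append(
                Violation(
                    None,
                    "pair_id",
                    f"pair {pair} must contain exactly one labeled and one "
                    f"unlabeled product (got labels {sorted(labels)})",
                )
            )

    # subject covariates constant within subject
    sm = rec.groupby("subject_id")[["gender", "age"]].nunique()
    for subj, row in sm.iterrows():
        for col in ("gender", "age"):
            if row[col] > 1:
                out.append(
                    Violation(None, col, f"subject {subj} has inconsistent {col} values")
                )

    expected = dataset.n_subjects * dataset.n_products
    if dataset.n_records != expected:
        out.append(
            Violation(
                None,
                "records",
                f"incomplete design: {dataset.n_records} records, expected "
                f"{expected} (= {dataset.n_subjects} subjects x "
                f"{dataset.n_products} products)",
                severity="warning",
            )
        )
    return out


def read_trials(
    path,
    schema: dict[str, str] | None = None,
    provenance: str | None = None,
) -> Dataset:
    """Read a long-format trials CSV into a validated :class:`Dataset`.

    ``schema`` maps canonical column names to the file's column names, e.g.
    ``{"subject_id": "participant", "bid": "wtp"}``; unmapped canonical
    names are looked up verbatim.  Row order is preserved.
    """
    df = pd.read_csv(path)
    if schema:
        rename = {}
        for canonical, actual in schema.items():
            if canonical not in CANONICAL_COLUMNS:
                raise SchemaError(f"unknown canonical column in schema mapping: {canonical}")
            if actual not in df.columns:
                raise SchemaError(
                    f"column {actual!r} (mapped to {canonical!r}) not found in {path}"
                )
            rename[actual] = canonical
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) in {path}: {', '.join(missing)}; "
            "use the schema mapping argument to adapt non-canonical headers"
        )
    ds = Dataset(df, provenance=provenance if provenance is not None else str(path))
    problems = [v for v in ds.validate() if v.severity == "error"]
    if problems:
        head = "; ".join(str(v) for v in problems[:5])
        raise ValidationError(f"{len(problems)} validation error(s) in {path}: {head}")
    return ds


def write_trials(dataset: Dataset, path) -> str:
    """Write the canonical CSV dialect: UTF-8, comma separated, header row.

    Floats are written at full (shortest round-trip) precision so latent-mode
    data survive a write/read cycle bit-exactly.
    """
    dataset.records.to_csv(path, index=False, encoding="utf-8")
    return str(path)


def load_config(path) -> dict:
    """Load a nested key-value configuration file (YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    return cfg


def configure_logging(level: str = "INFO") -> None:
    """Route package logs to standard error with the given level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
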