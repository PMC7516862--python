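"""Dataset readers/writers, schemas, checkpoints and config files.

Datasets travel as comma-separated text with a mandatory header row;
metadata (master seed, config hash, artifact version) is embedded as
``#``-prefixed header comments plus JSON sidecars. Checkpoints are
schema-versioned JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError
from .model import ModelParams
from .simulate import ObservationalDataset, SyntheticTruth

try:
    ARTIFACT_VERSION = version("ibtreat")
except PackageNotFoundError:  # pragma: no cover
    ARTIFACT_VERSION = "unknown"


@dataclass
class DatasetSchema:
    """Column roles of a delimited dataset file."""

    covariates: list[str]
    treatment: str
    outcome: str
    x1: list[str]
    attributes: list[str] = field(default_factory=list)
    outcome_family: str = "gaussian"

    def __post_init__(self):
        roles = list(self.covariates) + [self.treatment, self.outcome] \
            + list(self.attributes)
        dupes = {c for c in roles if roles.count(c) > 1}
        if dupes:
            raise SchemaError(f"columns named in more than one role: {sorted(dupes)}")
        extra = set(self.x1) - set(self.covariates)
        if extra:
            raise SchemaError(f"x1 columns not among covariates: {sorted(extra)}")

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates), "treatment": self.treatment,
            "outcome": self.outcome, "x1": list(self.x1),
            "attributes": list(self.attributes),
            "outcome_family": self.outcome_family,
        }

    @classmethod
    def from_file(cls, path) -> "DatasetSchema":
        with open(path) as fh:
            return cls(**json.load(fh))


def schema_for(dataset: ObservationalDataset) -> DatasetSchema:
    return DatasetSchema(
        covariates=list(dataset.column_names),
        treatment="treatment", outcome="outcome",
        x1=[dataset.column_names[i] for i in dataset.x1_columns],
        attributes=sorted(dataset.attributes),
        outcome_family=dataset.outcome_family,
    )


def load_dataset(path, schema: DatasetSchema) -> ObservationalDataset:
    """Read a delimited dataset against its schema.

    Missing columns raise SchemaError naming them; non-binary treatment
    values and rows with missing always-observed covariates or outcomes
    raise ParseError with the offending row numbers (1-based data rows).
    """
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    needed = list(schema.covariates) + [schema.treatment, schema.outcome] \
        + list(schema.attributes)
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")

    t_raw = frame[schema.treatment]
    bad_t = ~t_raw.isin([0, 1])
    if bad_t.any():
        rows = (np.flatnonzero(bad_t) + 1).tolist()
        raise ParseError(f"non-binary treatment value at row(s) {rows}")

    x2_names = [c for c in schema.covariates if c not in schema.x1]
    check = frame[x2_names + [schema.outcome]]
    bad_rows = np.flatnonzero(check.isna().any(axis=1))
    if bad_rows.size:
        raise ParseError(
            f"missing x2/outcome value at row(s) {(bad_rows + 1).tolist()}"
        )

    x = frame[schema.covariates].to_numpy(dtype=np.float64)
    name_to_idx = {c: i for i, c in enumerate(schema.covariates)}
    x1_idx = tuple(name_to_idx[c] for c in schema.x1)
    x2_idx = tuple(i for i in range(len(schema.covariates)) if i not in x1_idx)
    return ObservationalDataset(
        x=x, t=t_raw.to_numpy(), y=frame[schema.outcome].to_numpy(dtype=np.float64),
        column_names=list(schema.covariates),
        x1_columns=x1_idx, x2_columns=x2_idx,
        outcome_family=schema.outcome_family,
        attributes={c: frame[c].to_numpy() for c in schema.attributes},
    )


def _meta_header(seed, config: dict | None) -> str:
    digest = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True).encode()
    ).hexdigest()[:16]
    return (f"# ibtreat version={ARTIFACT_VERSION} seed={seed} "
            f"config_sha256={digest}\n")


def save_dataset(dataset: ObservationalDataset, path, seed=0,
                 config: dict | None = None) -> None:
    frame = pd.DataFrame(dataset.x, columns=dataset.column_names)
    frame["treatment"] = dataset.t
    frame["outcome"] = dataset.y
    for name, values in dataset.attributes.items():
        frame[name] = values
    with open(path, "w") as fh:
        fh.write(_meta_header(seed, config))
        frame.to_csv(fh, index=False, float_format="%.17g")


def save_truth(truth: SyntheticTruth, path, seed=0) -> None:
    with open(path, "w") as fh:
        json.dump({
            "artifact_version": ARTIFACT_VERSION, "seed": seed,
            "true_ace": truth.true_ace, "regime": truth.regime,
            "y0": truth.y0.tolist(), "y1": truth.y1.tolist(),
            "confounder": np.asarray(truth.confounder).tolist(),
        }, fh)


def load_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticTruth(
        y0=np.array(d["y0"]), y1=np.array(d["y1"]), true_ace=d["true_ace"],
        confounder=np.array(d["confounder"]), regime=d["regime"],
    )


def save_checkpoint(params: ModelParams, path, seed=0,
                    config: dict | None = None) -> None:
    payload = params.to_dict()
    payload["meta"] = {
        "artifact_version": ARTIFACT_VERSION, "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> ModelParams:
    with open(path) as fh:
        payload = json.load(fh)
    payload.pop("meta", None)
    return ModelParams.from_dict(payload)


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text) or {}
    return json.loads(text)
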