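"""Configuration, tabular IO, seeding and run manifests.

All randomness in the package flows through numpy Generators seeded from
a single integer; :func:`stage_rng` fans the global seed out into
independent per-stage streams so that changing one stage's stream leaves
every other stage's output unchanged.
"""

from __future__ import annotations

import datetime
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .learners import BaseLearnerSpec

logger = logging.getLogger("qboost")

_LEARNER_KINDS = {"linear", "pspline", "subject_intercept", "subject_slope"}


class ModelConfig(BaseModel):
    """Validated model/run configuration (YAML or JSON on disk)."""

    model_config = ConfigDict(extra="forbid")

    response: str
    covariates: dict[str, str]          # column -> base-learner kind
    tau: list[float] = [0.025, 0.975]
    step_length: float = 0.1
    m_max: int = 5000
    stopping: str = "bootstrap"         # or validation_set / kfold_cv /
                                        # subject_bootstrap
    reps: int = 25
    folds: int = 10
    subject_col: Optional[str] = None
    slope_covariate: Optional[str] = None
    seed: int = 0

    @field_validator("tau")
    @classmethod
    def _tau_open_interval(cls, v):
        for t in v:
            if not (0.0 < t < 1.0):
                raise ValueError(
                    f"tau={t} violates the constraint 0 < tau < 1")
        return v

    @field_validator("step_length")
    @classmethod
    def _step(cls, v):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"step_length={v} must lie in (0, 1]")
        return v

    @field_validator("covariates")
    @classmethod
    def _kinds(cls, v):
        for col, kind in v.items():
            if kind not in _LEARNER_KINDS:
                raise ValueError(
                    f"covariate {col!r}: unknown base-learner kind "
                    f"{kind!r}; expected one of {sorted(_LEARNER_KINDS)}")
        return v

    @field_validator("m_max")
    @classmethod
    def _mmax(cls, v):
        if v < 1:
            raise ValueError(f"m_max={v} must be a positive integer")
        return v

    def specs(self) -> list[BaseLearnerSpec]:
        out = []
        for col, kind in self.covariates.items():
            if kind == "subject_slope":
                out.append(BaseLearnerSpec(covariate=col, kind=kind,
                                           slope_covariate=col))
            elif kind == "subject_intercept":
                out.append(BaseLearnerSpec(covariate=None, kind=kind))
            else:
                out.append(BaseLearnerSpec(covariate=col, kind=kind))
        return out


def load_config(path) -> ModelConfig:
    """Read and validate a YAML/JSON model configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else \
        yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    return ModelConfig(**data)


def save_config(config: ModelConfig, path) -> None:
    path = Path(path)
    payload = config.model_dump()
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload))


@dataclass
class Dataset:
    """Typed tabular input: response, covariate table, optional subjects."""

    y: np.ndarray
    X: pd.DataFrame
    subject: Optional[np.ndarray] = None
    column_names: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.y) != len(self.X):
            raise ValueError("response and covariate table length differ")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("response contains missing values")
        if self.subject is not None and len(self.subject) != len(self.y):
            raise ValueError("subject labels must match the sample size")
        if not self.column_names:
            self.column_names = list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.y)


def read_table(path, config: ModelConfig) -> Dataset:
    """Read a CSV (comma, dot-decimal, UTF-8, header required) per config.

    Declared numeric covariates are coerced and validated (offending row
    index reported); undeclared columns are ignored with a log note.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValueError(f"input file {path} is empty") from None
    if len(frame) == 0:
        raise ValueError(f"input file {path} has a header but no rows")
    needed = [config.response] + [
        c for c, kind in config.covariates.items()
        if kind != "subject_intercept"]
    if config.subject_col:
        needed.append(config.subject_col)
    missing = sorted(set(needed) - set(frame.columns))
    if missing:
        raise ValueError(f"declared columns missing from {path}: {missing}")
    extra = sorted(set(frame.columns) - set(needed))
    if extra:
        logger.info("ignoring undeclared columns: %s", extra)
    y = pd.to_numeric(frame[config.response], errors="coerce").to_numpy()
    if np.any(~np.isfinite(y)):
        rows = np.flatnonzero(~np.isfinite(y)).tolist()
        raise ValueError(f"non-numeric or missing response values at rows "
                         f"{rows[:10]}")
    cov_cols = [c for c in config.covariates if c in frame.columns]
    X = frame[cov_cols].copy()
    for col, kind in config.covariates.items():
        if kind in ("pspline", "subject_slope") or (
                kind == "linear" and pd.api.types.is_numeric_dtype(X[col])):
            coerced = pd.to_numeric(X[col], errors="coerce")
            bad = np.flatnonzero(~np.isfinite(coerced.to_numpy()))
            if len(bad):
                raise ValueError(
                    f"non-numeric values in numeric column {col!r} at rows "
                    f"{bad.tolist()[:10]}")
            X[col] = coerced
    subject = (frame[config.subject_col].to_numpy().astype(str)
               if config.subject_col else None)
    return Dataset(y=y, X=X, subject=subject)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic, stage-independent child generator of a global seed."""
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def stage_seed(seed: int, stage: str) -> int:
    """A plain integer child seed (< 2**31) for the given stage."""
    return int(stage_rng(seed, stage).integers(2 ** 31))


@dataclass
class RunManifest:
    """Record of one run: config snapshot, seeds and emitted artifacts."""

    config: dict
    seed: int
    artifact_version: str = "0.1.0"
    started: str = ""
    finished: str = ""
    outputs: list = field(default_factory=list)

    def start(self):
        self.started = datetime.datetime.now().isoformat(timespec="seconds")
        return self

    def add_output(self, stage: str, path) -> None:
        self.outputs.append({"stage": stage, "path": str(path)})

    def save(self, path) -> None:
        self.finished = datetime.datetime.now().isoformat(timespec="seconds")
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "artifact_version": self.artifact_version,
             "started": self.started, "finished": self.finished,
             "outputs": self.outputs}, indent=2))
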