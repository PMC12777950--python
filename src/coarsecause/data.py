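"""Unit-level data model, table I/O, and run configuration.

A :class:`Dataset` holds one outcome vector ``y`` (numeric; binary
outcomes coded 0/1), one binary treatment vector ``t``, and an ``n x p``
covariate table ``x`` whose columns are typed continuous or categorical.
Row order defines unit identity when no ``unit_id`` is supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    FinitenessError,
    MissingDataError,
    RoleError,
    TreatmentCodingError,
)

logger = logging.getLogger("coarsecause")

__all__ = ["Dataset", "RunConfig", "load_table", "write_report", "read_report"]


@dataclass
class Dataset:
    """Validated unit-level (Y, T, X) sample.

    Parameters
    ----------
    y : outcome per unit, real-valued (binary outcomes coded 0/1).
    t : treatment indicator per unit, values in {0, 1}; both arms must occur.
    x : covariate table with ``n`` rows; non-numeric columns are treated as
        categorical.
    unit_id : optional stable identifiers; defaults to the row index.
    true_ate, true_att : known truths, attached by the synthetic generator
        so simulation studies can score estimates; ``None`` for real data.
    """

    y: np.ndarray
    t: np.ndarray
    x: pd.DataFrame
    unit_id: np.ndarray | None = None
    true_ate: float | None = None
    true_att: float | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        t = np.asarray(self.t).ravel()
        x = pd.DataFrame(self.x).reset_index(drop=True)
        n = len(self.y)
        if n < 2:
            raise ConfigError(f"need at least 2 units, got {n}")
        if len(t) != n or len(x) != n:
            raise RoleError(
                f"length mismatch: y has {n} rows, t has {len(t)}, x has {len(x)}"
            )
        if x.shape[1] < 1:
            raise RoleError("need at least one covariate column")
        if np.isnan(self.y).any():
            raise MissingDataError("outcome column contains missing values")
        if pd.isna(pd.Series(t)).any():
            raise MissingDataError("treatment column contains missing values")
        if x.isna().any().any():
            bad = list(x.columns[x.isna().any()])
            raise MissingDataError(f"covariate columns with missing cells: {bad}")
        t_num = pd.to_numeric(pd.Series(t), errors="coerce")
        if t_num.isna().any() or not set(np.unique(t_num)).issubset({0.0, 1.0}):
            raise TreatmentCodingError(
                f"treatment must be coded 0/1, found values {sorted(pd.unique(t))!r}"
            )
        self.t = t_num.to_numpy(dtype=int)
        if self.t.sum() == 0 or self.t.sum() == len(self.t):
            raise TreatmentCodingError("both treatment arms must be present")
        self.x = x
        if self.unit_id is None:
            self.unit_id = np.arange(n)
        else:
            self.unit_id = np.asarray(self.unit_id).ravel()
            if len(self.unit_id) != n:
                raise RoleError("unit_id length does not match data")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def categorical_columns(self) -> list[str]:
        return [c for c in self.x.columns if not _is_numeric(self.x[c])]

    @property
    def continuous_columns(self) -> list[str]:
        return [c for c in self.x.columns if _is_numeric(self.x[c])]


def _is_numeric(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    )


@dataclass
class RunConfig:
    """Analysis configuration shared by the CLI and library entry points.

    ``k_or_bins`` is the method-specific size parameter: target cluster
    count for k-means / random-forest strata, per-covariate bin count for
    CEM (``None`` lets CEM pick Sturges' count).
    """

    method: str = "kmeans"
    estimand: str = "ate"
    k_or_bins: int | None = None
    seed: int = 0
    alpha: float = 0.05
    min_per_arm: int = 1
    standardize: bool = True
    rf_trees: int = 500

    def __post_init__(self) -> None:
        if self.method not in {"cem", "kmeans", "rf"}:
            raise ConfigError(f"unknown method {self.method!r}")
        if self.estimand not in {"ate", "att"}:
            raise ConfigError(f"unknown estimand {self.estimand!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.k_or_bins is not None and self.k_or_bins < 1:
            raise ConfigError("k_or_bins must be >= 1")
        if self.min_per_arm < 1:
            raise ConfigError("min_per_arm must be >= 1")
        if self.seed < 0:
            raise ConfigError("seed must be nonnegative")
        if self.rf_trees < 1:
            raise ConfigError("rf_trees must be >= 1")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimand": self.estimand,
            "k_or_bins": self.k_or_bins,
            "seed": self.seed,
            "alpha": self.alpha,
            "min_per_arm": self.min_per_arm,
            "standardize": self.standardize,
            "rf_trees": self.rf_trees,
        }


def load_table(
    path: str | Path,
    roles: Mapping[str, object],
) -> Dataset:
    """Read a CSV/TSV with a header row into a validated :class:`Dataset`.

    ``roles`` maps ``outcome`` and ``treatment`` to column names and
    ``covariates`` to a list of names (or ``None`` / ``"all"`` for every
    remaining column). An optional ``categorical`` entry lists covariate
    columns to force categorical even if their content is numeric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)

    outcome = roles.get("outcome")
    treatment = roles.get("treatment")
    if not outcome or not treatment:
        raise RoleError("roles must name one outcome and one treatment column")
    covariates = roles.get("covariates")
    if covariates in (None, "all"):
        covariates = [c for c in frame.columns if c not in (outcome, treatment)]
    covariates = list(covariates)
    named = [outcome, treatment, *covariates]
    if len(set(named)) != len(named):
        raise RoleError(f"duplicate column roles in {named}")
    missing = [c for c in named if c not in frame.columns]
    if missing:
        raise RoleError(f"role columns absent from table: {missing}")
    if not covariates:
        raise RoleError("at least one covariate column is required")

    x = frame[covariates].copy()
    for col in roles.get("categorical", []) or []:
        if col not in x.columns:
            raise RoleError(f"categorical role {col!r} is not a covariate")
        x[col] = x[col].astype(str)

    y_raw = pd.to_numeric(frame[outcome], errors="coerce")
    if y_raw.isna().any() and not frame[outcome].isna().any():
        raise MissingDataError(f"outcome column {outcome!r} is not numeric")

    unit_id = frame[roles["unit_id"]].to_numpy() if roles.get("unit_id") else None
    return Dataset(
        y=y_raw.to_numpy(), t=frame[treatment].to_numpy(), x=x, unit_id=unit_id
    )


def write_report(estimate, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a JSON analysis report that round-trips through :func:`read_report`.

    Accepts an ``EffectEstimate`` or a ``BiasCorrectionResult`` (anything
    with a ``to_dict``). Refuses non-finite point estimates.
    """
    payload = estimate.to_dict()
    point = payload.get("tau_hat", payload.get("tau_corrected"))
    if point is None or not np.isfinite(point):
        raise FinitenessError(f"refusing to write a non-finite estimate: {point!r}")
    report = {"kind": type(estimate).__name__, "result": payload}
    if config is not None:
        report["config"] = config.to_dict()
        report["seed"] = config.seed
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", path)


def read_report(path: str | Path) -> dict:
    """Read back a report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
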