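"""File formats, configuration and model persistence.

The interchange format for features is a plain numeric CSV with one row per
lesion and (by default) 1152 columns in the canonical schema order of
:mod:`dermdecide.features` — the same layout as the study's supplementary
``excision`` / ``noexcision`` tables.  The reader is permissive (optional
header row, arbitrary float formatting); the writer is canonical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .errors import CorruptBundleError, FormatError, InvalidInputError

logger = logging.getLogger("dermdecide")

BUNDLE_SCHEMA_VERSION = 1

__all__ = [
    "FeatureTable",
    "PipelineConfig",
    "read_feature_csv",
    "write_feature_csv",
    "load_table",
    "save_bundle",
    "load_bundle",
    "load_config_file",
]


@dataclass
class FeatureTable:
    """A labelled feature matrix: rows are lesions, columns are features.

    ``y`` uses the clinical encoding: 1 = excise, 0 = do not excise.
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise InvalidInputError("X must be a 2-D matrix")
        if self.y.shape != (self.X.shape[0],):
            raise InvalidInputError(
                f"y has shape {self.y.shape}, expected ({self.X.shape[0]},)"
            )
        if not np.all(np.isfinite(self.X)):
            raise InvalidInputError("feature matrix contains non-finite values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise InvalidInputError("labels must be binary (0 = no excision, 1 = excise)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise InvalidInputError("both classes must be present")


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with defaults at the
    operating point: Shannon wavelet, 6 levels, ReliefF top 125, 22 principal
    components, RBF-SVM with C=30 and gamma=0.007, probability cutoff 0.5.
    """

    wavelet: str = "shannon"
    levels: int = 6
    literal_normalisation: bool = False
    relieff_k: int = 10
    top_n: int = 125
    n_components: int = 22
    algorithm: str = "svm"          # svm | rf | lr
    C: float = 30.0
    gamma: float = 0.007
    n_trees: int = 200
    min_leaf_size: int = 1
    lr_penalty: str = "L2"
    lr_reg_param: float = 0.1
    folds: int = 10
    repeats: int = 50
    seed: int = 0
    probability_threshold: float = 0.5
    stratify: bool = True
    global_selection: bool = False  # True = rank/extract once on all data (leaky)

    def __post_init__(self) -> None:
        if self.algorithm not in ("svm", "rf", "lr"):
            raise InvalidInputError(f"unknown algorithm {self.algorithm!r}")
        if not 0 < self.probability_threshold < 1:
            raise InvalidInputError("probability_threshold must lie in (0,1)")
        for name in ("levels", "relieff_k", "top_n", "n_components", "folds",
                     "repeats", "n_trees", "min_leaf_size"):
            if int(getattr(self, name)) < 1:
                raise InvalidInputError(f"{name} must be a positive integer")
        if self.C <= 0 or self.gamma <= 0 or self.lr_reg_param <= 0:
            raise InvalidInputError("C, gamma and lr_reg_param must be positive")
        if self.lr_penalty.upper() not in ("L1", "L2"):
            raise InvalidInputError("lr_penalty must be 'L1' or 'L2'")


def _looks_like_header(line: str) -> bool:
    for token in line.strip().split(","):
        token = token.strip()
        if token == "":
            continue
        try:
            float(token)
        except ValueError:
            return True
    return False


def read_feature_csv(path: str | Path, expected_q: int | None = 1152) -> np.ndarray:
    """Read a feature table: one lesion per row, numeric columns only.

    Auto-detects an optional header row.  Raises :class:`FormatError`
    naming the offending row/column on ragged or non-numeric input, and on
    a column-count mismatch with *expected_q* (pass ``None`` to accept any
    width).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"feature CSV not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    if first == "":
        raise FormatError(f"{path}: file is empty")
    header = 0 if _looks_like_header(first) else None
    try:
        df = pd.read_csv(path, header=header, sep=",")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise FormatError(f"{path}: non-numeric or missing value at row {r}, column {c}")
    if expected_q is not None and values.shape[1] != expected_q:
        raise FormatError(
            f"{path}: expected {expected_q} feature columns, found {values.shape[1]}"
        )
    return values


def write_feature_csv(X: np.ndarray, path: str | Path,
                      header: Sequence[str] | None = None) -> None:
    """Write a feature matrix in the canonical CSV dialect (comma separator,
    '.' decimal, optional single header row)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    df = pd.DataFrame(X, columns=list(header) if header is not None else None)
    df.to_csv(path, index=False, header=header is not None, float_format="%.12g")


def load_table(excision_csv: str | Path, noexcision_csv: str | Path,
               expected_q: int | None = 1152) -> FeatureTable:
    """Assemble a labelled :class:`FeatureTable` from the two per-class CSVs
    (excision file -> label 1, no-excision file -> label 0)."""
    pos = read_feature_csv(excision_csv, expected_q)
    neg = read_feature_csv(noexcision_csv, expected_q)
    if pos.shape[1] != neg.shape[1]:
        raise FormatError(
            f"column counts differ: {pos.shape[1]} (excision) vs {neg.shape[1]} (no excision)"
        )
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return FeatureTable(X, y)


def save_bundle(model, config: PipelineConfig, path: str | Path) -> None:
    """Persist a trained model plus its full pipeline configuration as a
    single versioned file, so ``predict`` needs no other flags."""
    payload = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "model": model,
    }
    joblib.dump(payload, path)


def load_bundle(path: str | Path):
    """Inverse of :func:`save_bundle`; returns ``(model, config)``."""
    path = Path(path)
    if not path.exists():
        raise CorruptBundleError(f"bundle not found: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated/corrupt pickles raise many types
        raise CorruptBundleError(f"could not read bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise CorruptBundleError(f"{path} is not a dermdecide model bundle")
    if payload["schema_version"] != BUNDLE_SCHEMA_VERSION:
        raise CorruptBundleError(
            f"unsupported bundle schema version {payload['schema_version']}"
        )
    config = PipelineConfig(**payload["config"])
    return payload["model"], config


def load_config_file(path: str | Path) -> dict:
    """Parse a flat ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored.  Values are coerced to
    bool/int/float where possible; precedence (CLI > file > defaults) is the
    caller's responsibility.
    """
    out: dict = {}
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in valid:
            raise FormatError(f"{path}:{lineno}: unknown option {key!r}")
        if value.lower() in ("true", "false"):
            out[key] = value.lower() == "true"
            continue
        for caster in (int, float):
            try:
                out[key] = caster(value)
                break
            except ValueError:
                continue
        else:
            out[key] = value
    return out
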