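"""Cohort preprocessing: weight stratification, imputation, encoding, scaling.

The pipeline turns a raw tabular cohort (mixed numeric / binary / categorical
features, possibly with missing cells, plus a birth-weight outcome column in
grams) into a fully numeric feature matrix suitable for one-class anomaly
detectors:

1. stratify rows into nested outcome categories by strict weight thresholds
   (< 2500 g low, < 1500 g very low, < 1000 g extreme birth weight);
2. impute missing values (column mean for numeric, column mode for
   binary/categorical, ties broken lexicographically);
3. encode binary features to a single 0/1 column and categorical features to
   a full one-hot block (no dropped level, deterministic level order);
4. min-max scale every encoded column to [0, 1], clipping out-of-range
   values seen at transform time.

Two fitting modes are supported by construction: the paper-faithful *global*
mode fits the transform once on the whole cohort, while the leak-free
*fold-safe* mode refits a :class:`Preprocessor` on the normal rows of each
training fold (see :mod:`lbwdetect.evaluate`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEIGHT_COLUMN = "weight"

#: Nested birth-weight categories and their strict gram thresholds.
WEIGHT_THRESHOLDS: dict[str, float] = {"lbw": 2500.0, "vlbw": 1500.0, "elbw": 1000.0}

KINDS = ("numeric", "binary", "categorical")

# Accepted spellings for binary features; everything is compared lowercase.
_BINARY_MAP = {
    "yes": 1, "no": 0,
    "y": 1, "n": 0,
    "true": 1, "false": 0,
    "1": 1, "0": 0,
    "1.0": 1, "0.0": 0,
}


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one source feature."""

    name: str
    kind: str
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and self.categories is not None:
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"duplicate categories for feature {self.name!r}")


class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` with unique names.

    The outcome column (``weight``) is never part of the schema.
    """

    def __init__(self, features: Iterable[FeatureSpec]):
        feats = tuple(features)
        names = [f.name for f in feats]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if WEIGHT_COLUMN in names:
            raise ValueError(f"{WEIGHT_COLUMN!r} is the outcome, not a feature")
        if not feats:
            raise ValueError("schema must declare at least one feature")
        self.features = feats

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def __iter__(self) -> Iterator[FeatureSpec]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def to_dict(self) -> list[dict]:
        return [
            {"name": f.name, "kind": f.kind,
             "categories": list(f.categories) if f.categories else None}
            for f in self.features
        ]

    @classmethod
    def from_dict(cls, items: Sequence[Mapping]) -> "FeatureSchema":
        return cls(
            FeatureSpec(
                name=d["name"], kind=d["kind"],
                categories=tuple(d["categories"]) if d.get("categories") else None,
            )
            for d in items
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def infer_schema(df: pd.DataFrame, weight_col: str = WEIGHT_COLUMN) -> FeatureSchema:
    """Guess a :class:`FeatureSchema` from a cohort frame.

    Numeric dtypes become ``numeric`` unless their observed values are a
    subset of {0, 1}; object columns whose observed values all map to a
    recognised yes/no spelling become ``binary``; everything else is
    ``categorical`` with lexicographically ordered levels.
    """
    specs: list[FeatureSpec] = []
    for col in df.columns:
        if col == weight_col:
            continue
        observed = df[col].dropna()
        vals = set(observed.unique().tolist())
        if pd.api.types.is_numeric_dtype(observed):
            if vals <= {0, 1, 0.0, 1.0}:
                specs.append(FeatureSpec(col, "binary"))
            else:
                specs.append(FeatureSpec(col, "numeric"))
        elif all(str(v).strip().lower() in _BINARY_MAP for v in vals) and len(vals) <= 2:
            specs.append(FeatureSpec(col, "binary"))
        else:
            cats = tuple(sorted(str(v) for v in vals))
            specs.append(FeatureSpec(col, "categorical", cats))
    return FeatureSchema(specs)


# ---------------------------------------------------------------------------
# stratification

def stratify_by_weight(weights, threshold: float) -> np.ndarray:
    """Binary label vector: 1 iff weight is strictly below ``threshold`` grams."""
    arr = np.asarray(weights, dtype=float)
    if arr.ndim != 1:
        raise ValueError("weights must be one-dimensional")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("weights must be finite and positive; drop invalid rows first")
    return (arr < threshold).astype(np.int8)


def drop_invalid_weight(df: pd.DataFrame, weight_col: str = WEIGHT_COLUMN) -> tuple[pd.DataFrame, int]:
    """Drop rows whose outcome weight is missing, non-finite or non-positive."""
    w = pd.to_numeric(df[weight_col], errors="coerce")
    keep = np.isfinite(w.to_numpy(dtype=float)) & (w.to_numpy(dtype=float) > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d rows with missing/invalid %s", n_dropped, weight_col)
    return df.loc[keep].reset_index(drop=True), n_dropped


def category_labels(weights) -> dict[str, np.ndarray]:
    """The three nested label vectors (lbw, vlbw, elbw) for a weight vector."""
    return {cat: stratify_by_weight(weights, thr) for cat, thr in WEIGHT_THRESHOLDS.items()}


def prevalence(labels) -> float:
    """Positive fraction of a binary label vector (the category's default ratio)."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty label vector")
    return float(arr.sum() / arr.size)


# ---------------------------------------------------------------------------
# imputation / encoding / scaling primitives

def impute_value(values: pd.Series, kind: str):
    """The fill value for a column: observed mean (numeric) or mode.

    Mode ties are broken by the lexicographically smallest level, so the
    transform is deterministic.
    """
    observed = values.dropna()
    if observed.empty:
        raise ValueError(f"column {values.name!r} is entirely missing; cannot impute")
    if kind == "numeric":
        return float(pd.to_numeric(observed).mean())
    counts = observed.value_counts()
    top = counts[counts == counts.max()].index
    return sorted(top, key=str)[0]


def impute_column(values: pd.Series, kind: str, fill=None) -> pd.Series:
    """Fill missing entries, leaving observed values untouched."""
    if fill is None:
        fill = impute_value(values, kind)
    out = values.copy()
    if kind == "numeric":
        out = pd.to_numeric(out, errors="coerce")
    return out.fillna(fill)


def encode_binary(values: pd.Series, name: str) -> np.ndarray:
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        key = str(v).strip().lower()
        if key not in _BINARY_MAP:
            raise ValueError(f"unrecognised binary value {v!r} in feature {name!r}")
        out[i] = _BINARY_MAP[key]
    return out


def encode_categorical(values: pd.Series, categories: Sequence[str], name: str,
                       allow_unseen: bool = False) -> np.ndarray:
    """Full one-hot block (k indicator columns in the declared level order)."""
    index = {c: j for j, c in enumerate(categories)}
    out = np.zeros((len(values), len(categories)), dtype=float)
    for i, v in enumerate(values):
        key = str(v)
        if key not in index:
            if allow_unseen:
                logger.warning("unseen level %r in feature %r encoded as all-zeros", v, name)
                continue
            raise ValueError(f"unseen category {v!r} in feature {name!r}")
        out[i, index[key]] = 1.0
    return out


@dataclass
class MinMaxParams:
    """Fitted per-column minima/maxima for [0, 1] rescaling."""

    min_: np.ndarray
    max_: np.ndarray


def minmax_fit(X: np.ndarray) -> MinMaxParams:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("min-max fit requires a finite matrix")
    return MinMaxParams(min_=X.min(axis=0), max_=X.max(axis=0))


def minmax_apply(params: MinMaxParams, X: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min) per column, clipped into [0, 1].

    Constant columns map to 0; values outside the fitted range are clipped so
    the [0, 1] invariant also holds under fold-safe refitting.
    """
    X = np.asarray(X, dtype=float)
    span = params.max_ - params.min_
    safe = np.where(span > 0, span, 1.0)
    out = (X - params.min_) / safe
    out[:, span <= 0] = 0.0
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# fitted pipeline

@dataclass
class FeatureMatrix:
    """Numeric, imputed, encoded, scaled matrix with column provenance."""

    X: np.ndarray
    columns: tuple[str, ...]
    sources: tuple[str, ...]  # source feature of each encoded column

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.columns) or len(self.columns) != len(self.sources):
            raise ValueError("column metadata does not match matrix width")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def feature_groups(self) -> dict[str, np.ndarray]:
        """Map each source feature to the indices of its encoded columns."""
        groups: dict[str, list[int]] = {}
        for j, src in enumerate(self.sources):
            groups.setdefault(src, []).append(j)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.columns))


class Preprocessor:
    """Fit/transform implementation of the preprocessing pipeline.

    ``fit`` learns the per-column imputation values, categorical level orders
    and min/max scaling parameters; ``transform`` replays them exactly, so a
    transform fitted on training-fold normal rows leaks nothing from the test
    fold.
    """

    def __init__(self, schema: FeatureSchema):
        self.schema = schema
        self._fill: dict[str, object] | None = None
        self._minmax: MinMaxParams | None = None
        self._columns: tuple[str, ...] | None = None
        self._sources: tuple[str, ...] | None = None
        self._categories: dict[str, tuple[str, ...]] = {}

    @property
    def is_fitted(self) -> bool:
        return self._minmax is not None

    def fit(self, df: pd.DataFrame) -> "Preprocessor":
        self._fill = {}
        self._categories = {}
        for spec in self.schema:
            col = df[spec.name]
            self._fill[spec.name] = impute_value(col, spec.kind)
            if spec.kind == "categorical":
                if spec.categories is not None:
                    cats = spec.categories
                else:
                    cats = tuple(sorted(str(v) for v in col.dropna().unique()))
                self._categories[spec.name] = cats
        X, columns, sources = self._encode(df)
        self._columns, self._sources = columns, sources
        self._minmax = minmax_fit(X)
        return self

    def _encode(self, df: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
        assert self._fill is not None
        blocks: list[np.ndarray] = []
        columns: list[str] = []
        sources: list[str] = []
        for spec in self.schema:
            filled = impute_column(df[spec.name], spec.kind, fill=self._fill[spec.name])
            if spec.kind == "numeric":
                blocks.append(filled.to_numpy(dtype=float)[:, None])
                columns.append(spec.name)
                sources.append(spec.name)
            elif spec.kind == "binary":
                blocks.append(encode_binary(filled, spec.name)[:, None])
                columns.append(spec.name)
                sources.append(spec.name)
            else:
                cats = self._categories[spec.name]
                blocks.append(encode_categorical(filled, cats, spec.name))
                columns.extend(f"{spec.name}={c}" for c in cats)
                sources.extend(spec.name for _ in cats)
        return np.hstack(blocks), tuple(columns), tuple(sources)

    def transform(self, df: pd.DataFrame) -> FeatureMatrix:
        if not self.is_fitted:
            raise RuntimeError("Preprocessor must be fitted before transform")
        X, columns, sources = self._encode(df)
        assert columns == self._columns
        return FeatureMatrix(minmax_apply(self._minmax, X), columns, sources)

    def fit_transform(self, df: pd.DataFrame) -> FeatureMatrix:
        return self.fit(df).transform(df)

    # -- exact-replay serialization -------------------------------------
    def to_dict(self) -> dict:
        if not self.is_fitted:
            raise RuntimeError("cannot serialize an unfitted Preprocessor")
        return {
            "schema": self.schema.to_dict(),
            "fill": {k: v for k, v in self._fill.items()},
            "categories": {k: list(v) for k, v in self._categories.items()},
            "min": self._minmax.min_.tolist(),
            "max": self._minmax.max_.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Preprocessor":
        pp = cls(FeatureSchema.from_dict(d["schema"]))
        pp._fill = dict(d["fill"])
        pp._categories = {k: tuple(v) for k, v in d["categories"].items()}
        pp._minmax = MinMaxParams(np.asarray(d["min"], float), np.asarray(d["max"], float))
        cols: list[str] = []
        srcs: list[str] = []
        for spec in pp.schema:
            if spec.kind == "categorical":
                cats = pp._categories[spec.name]
                cols.extend(f"{spec.name}={c}" for c in cats)
                srcs.extend(spec.name for _ in cats)
            else:
                cols.append(spec.name)
                srcs.append(spec.name)
        pp._columns, pp._sources = tuple(cols), tuple(srcs)
        return pp

    @classmethod
    def from_json(cls, path) -> "Preprocessor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# normal-only split

def normal_only_split(labels, fold_assignment, held_fold: int) -> tuple[np.ndarray, np.ndarray]:
    """Row indices for one-class training and mixed-class testing.

    Train = rows of every *other* fold whose label is 0 (normal); test = all
    rows of the held-out fold, both classes.
    """
    labels = np.asarray(labels)
    fold_assignment = np.asarray(fold_assignment)
    if labels.shape != fold_assignment.shape:
        raise ValueError("labels and fold assignment must align")
    test = np.flatnonzero(fold_assignment == held_fold)
    train = np.flatnonzero((fold_assignment != held_fold) & (labels == 0))
    return train, test
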