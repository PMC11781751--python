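"""Synthetic first-trimester maternal cohort generator.

Real low-birth-weight cohorts are private, so every downstream stage of the
framework is exercised on synthetic cohorts that reproduce the *statistical
shape* of such data: one row per pregnancy, a birth-weight outcome in grams,
22 mixed-type first-trimester features by default, missing cells, and the
three nested minority fractions of the screening problem (low < 2500 g,
very low < 1500 g, extreme < 1000 g).

Generating mechanism
--------------------
Each row draws a latent risk ``z ~ N(0, 1)``. Birth weight is a piecewise-
linear, strictly decreasing function of the risk percentile with anchor
points placed exactly at the configured prevalence quantiles, so
thresholding weight at 2500/1500/1000 g recovers the configured prevalences
in expectation and the three labels are nested by construction. A chosen
subset of *informative* features is then shifted in anomalous rows —
numeric features by ``severity`` standard deviations, binary and categorical
features toward an anomaly-specific distribution — with a larger multiplier
for the deeper (rarer, more extreme) tiers. All remaining features are pure
nuisance, which keeps feature-attribution recovery non-trivial.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import (
    WEIGHT_COLUMN,
    WEIGHT_THRESHOLDS,
    FeatureSchema,
    FeatureSpec,
    category_labels,
)

#: Tier multipliers: informative-feature shifts grow for the deeper tiers.
TIER_SCALE = {"lbw": 1.0, "vlbw": 1.5, "elbw": 2.0}

#: Weight (grams) anchors of the risk-percentile -> weight map.
_WEIGHT_TOP, _WEIGHT_FLOOR = 4500.0, 500.0

DEFAULT_PREVALENCE = (0.116, 0.0128, 0.0054)
DEFAULT_INFORMATIVE = ("num_01", "num_02", "num_03", "bin_01", "bin_02", "cat_01")


def _cat_levels(k: int) -> tuple[str, ...]:
    return tuple(f"lvl{i + 1}" for i in range(k))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_samples : cohort size (default 3509 rows).
    n_numeric, n_binary, n_categorical : feature counts per kind
        (defaults 12 + 6 + 4 = 22 source features).
    categorical_levels : level counts, recycled across categorical features.
    prevalence : target positive fractions (lbw, vlbw, elbw); must be nested.
    severity : mean shift of informative numeric features in anomalous rows,
        in units of the feature's standard deviation (delta >= 0).
    informative_features : features carrying the anomaly signal.
    missing_rate : MCAR missingness fraction over feature cells.
    seed : master seed; all randomness derives from it.
    """

    n_samples: int = 3509
    n_numeric: int = 12
    n_binary: int = 6
    n_categorical: int = 4
    categorical_levels: tuple[int, ...] = (3, 4, 5, 3)
    prevalence: tuple[float, float, float] = DEFAULT_PREVALENCE
    severity: float = 1.5
    informative_features: tuple[str, ...] = DEFAULT_INFORMATIVE
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.n_numeric + self.n_binary + self.n_categorical < 1:
            raise ValueError("at least one feature is required")
        if self.severity < 0:
            raise ValueError("severity must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        p_lbw, p_vlbw, p_elbw = self.prevalence
        if not (0 < p_elbw <= p_vlbw <= p_lbw < 1):
            raise ValueError(
                "prevalences must be nested: 0 < elbw <= vlbw <= lbw < 1, "
                f"got {self.prevalence}"
            )
        unknown = set(self.informative_features) - set(self.feature_names)
        if unknown:
            raise ValueError(f"informative features not in schema: {sorted(unknown)}")
        if self.n_samples * p_elbw < 1:
            warnings.warn(
                "expected fewer than one extreme-LBW positive; only the "
                "expectation is honored", stacklevel=2,
            )

    @property
    def numeric_names(self) -> tuple[str, ...]:
        return tuple(f"num_{j + 1:02d}" for j in range(self.n_numeric))

    @property
    def binary_names(self) -> tuple[str, ...]:
        return tuple(f"bin_{j + 1:02d}" for j in range(self.n_binary))

    @property
    def categorical_names(self) -> tuple[str, ...]:
        return tuple(f"cat_{j + 1:02d}" for j in range(self.n_categorical))

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.numeric_names + self.binary_names + self.categorical_names

    def levels_of(self, j: int) -> int:
        return self.categorical_levels[j % len(self.categorical_levels)]

    def schema(self) -> FeatureSchema:
        specs = [FeatureSpec(n, "numeric") for n in self.numeric_names]
        specs += [FeatureSpec(n, "binary") for n in self.binary_names]
        specs += [
            FeatureSpec(n, "categorical", _cat_levels(self.levels_of(j)))
            for j, n in enumerate(self.categorical_names)
        ]
        return FeatureSchema(specs)


@dataclass
class GroundTruth:
    """Generating truth echoed alongside a synthetic cohort."""

    labels: dict[str, np.ndarray]
    informative_features: tuple[str, ...]
    config: SyntheticConfig

    def to_dict(self) -> dict:
        return {
            "labels": {k: np.asarray(v).astype(int).tolist() for k, v in self.labels.items()},
            "informative_features": list(self.informative_features),
            "config": dataclasses.asdict(self.config),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def _risk_to_weight(r: np.ndarray, prevalence: tuple[float, float, float]) -> np.ndarray:
    """Strictly decreasing map of risk percentile -> grams.

    Anchors put exactly ``prevalence`` mass strictly below each of the
    2500/1500/1000 g thresholds (in population), so labels are nested and
    sampled prevalences are binomial around the targets.
    """
    p_lbw, p_vlbw, p_elbw = prevalence
    xp = np.array([0.0, 1 - p_lbw, 1 - p_vlbw, 1 - p_elbw, 1.0])
    fp = np.array([
        _WEIGHT_TOP,
        WEIGHT_THRESHOLDS["lbw"],
        WEIGHT_THRESHOLDS["vlbw"],
        WEIGHT_THRESHOLDS["elbw"],
        _WEIGHT_FLOOR,
    ])
    return np.interp(r, xp, fp)


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one cohort; deterministic under ``config.seed``.

    Returns the cohort frame (``weight`` column in grams plus feature
    columns, missing cells as NaN) and the generating :class:`GroundTruth`.
    """
    n = config.n_samples
    ss = np.random.SeedSequence(config.seed)
    r_risk, r_num, r_bin, r_cat, r_mix, r_miss = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    z = r_risk.standard_normal(n)
    r = norm.cdf(z)
    weight = _risk_to_weight(r, config.prevalence)
    labels = category_labels(weight)

    # per-row shift multiplier: 0 for normal rows, growing with tier depth
    tier = np.zeros(n)
    for cat in ("lbw", "vlbw", "elbw"):
        tier = np.where(labels[cat] == 1, TIER_SCALE[cat], tier)
    bump = config.severity * tier  # total shift in SD units per row

    informative = set(config.informative_features)
    data: dict[str, np.ndarray] = {WEIGHT_COLUMN: weight}

    for j, name in enumerate(config.numeric_names):
        mu, sd = 10.0 * (j + 1), 1.0 + 0.5 * j
        vals = mu + sd * r_num.standard_normal(n)
        if name in informative:
            direction = 1.0 if j % 2 == 0 else -1.0
            vals = vals + direction * bump * sd
        data[name] = vals

    for j, name in enumerate(config.binary_names):
        p = 0.15 + 0.05 * j
        p_row = np.full(n, p)
        if name in informative:
            p_row = np.clip(p + 0.5 * bump * np.sqrt(p * (1 - p)), 0.01, 0.99)
        draws = r_bin.random(n) < p_row
        data[name] = np.where(draws, "Yes", "No")

    for j, name in enumerate(config.categorical_names):
        k = config.levels_of(j)
        levels = np.array(_cat_levels(k))
        base_w = 1.0 / np.arange(1, k + 1)
        base_w /= base_w.sum()
        idx = r_cat.choice(k, size=n, p=base_w)
        if name in informative:
            # anomalous rows drift toward the rarest level
            q = np.clip(0.25 * bump, 0.0, 0.95)
            idx = np.where(r_mix.random(n) < q, k - 1, idx)
        data[name] = levels[idx]

    df = pd.DataFrame(data)
    if config.missing_rate > 0:
        df = inject_missingness(df, config.missing_rate, r_miss)

    truth = GroundTruth(
        labels=labels,
        informative_features=tuple(config.informative_features),
        config=config,
    )
    return df, truth


def inject_missingness(cohort: pd.DataFrame, rate: float, seed) -> pd.DataFrame:
    """Mask feature cells missing-completely-at-random.

    The outcome ``weight`` column is never masked. ``seed`` may be an int,
    a ``SeedSequence`` or a ``Generator``; the result is deterministic.
    """
    if not 0 <= rate < 1:
        raise ValueError("missing rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = cohort.copy()
    feature_cols = [c for c in out.columns if c != WEIGHT_COLUMN]
    if rate == 0 or not feature_cols:
        return out
    mask = rng.random((len(out), len(feature_cols))) < rate
    for j, col in enumerate(feature_cols):
        if mask[:, j].any():
            hit = out[col].to_numpy(dtype=object, copy=True)
            hit[mask[:, j]] = np.nan
            out[col] = hit
            if pd.api.types.is_numeric_dtype(cohort[col]):
                out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def write_cohort(df: pd.DataFrame, path) -> None:
    """CSV with a header row; missing cells are written empty."""
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
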