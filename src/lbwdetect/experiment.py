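"""End-to-end experiment runner: cohort -> preprocessing -> CV -> attribution.

One :class:`ExperimentConfig` (YAML-serializable) drives the whole flow and
a single top-level seed deterministically derives every stage's randomness,
so a rerun with the same config produces byte-identical metric tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detectors import ScorerSpec, make_scorer
from .evaluate import EvalReport, compare_detectors, cross_validate, make_folds
from .interpret import (
    average_feature_ranks,
    compute_baseline,
    local_diffi,
    perturb_attribution,
    select_outlier_points,
)
from .preprocess import (
    WEIGHT_COLUMN,
    FeatureSchema,
    Preprocessor,
    category_labels,
    drop_invalid_weight,
    infer_schema,
)
from .synth import SyntheticConfig, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)

CATEGORIES = ("lbw", "vlbw", "elbw")
DEFAULT_DETECTORS = ("iforest", "hbos", "ecod", "knn", "gmm", "pca")


def derive_seed(base: int, *tokens: int) -> int:
    """Stable stage seed below 2**31 derived from the top-level seed."""
    ss = np.random.SeedSequence([int(base), *[int(t) for t in tokens]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class InterpretSettings:
    detector: str = "iforest"
    methods: tuple[str, ...] = ("perturb", "diffi")
    baseline: str = "training-normal-means"
    outlier_mode: str = "label"
    top_k: int | None = None


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    seed: int = 0
    outdir: str = "runs/experiment"
    synth: SyntheticConfig | None = None
    cohort_csv: str | None = None
    schema_path: str | None = None
    categories: tuple[str, ...] = CATEGORIES
    detectors: tuple[ScorerSpec, ...] = field(
        default_factory=lambda: tuple(ScorerSpec(n) for n in DEFAULT_DETECTORS)
    )
    repeats: int = 2
    folds: int = 5
    mode: str = "global"  # or "fold-safe"
    interpret: InterpretSettings = field(default_factory=InterpretSettings)

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("at least one category is required")
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if not self.detectors:
            raise ValueError("at least one detector is required")
        if self.synth is None and self.cohort_csv is None:
            raise ValueError("either a synth config or a cohort CSV is required")

    # -- YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "outdir": self.outdir,
            "categories": list(self.categories),
            "detectors": [
                {"name": s.name, "params": dict(s.params), "seed": s.seed}
                for s in self.detectors
            ],
            "repeats": self.repeats,
            "folds": self.folds,
            "mode": self.mode,
            "interpret": {
                "detector": self.interpret.detector,
                "methods": list(self.interpret.methods),
                "baseline": self.interpret.baseline,
                "outlier_mode": self.interpret.outlier_mode,
                "top_k": self.interpret.top_k,
            },
        }
        if self.synth is not None:
            d["synth"] = dataclasses.asdict(self.synth)
        if self.cohort_csv is not None:
            d["cohort_csv"] = self.cohort_csv
            d["schema_path"] = self.schema_path
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        synth = None
        if d.get("synth") is not None:
            s = dict(d["synth"])
            for key in ("categorical_levels", "prevalence", "informative_features"):
                if key in s and s[key] is not None:
                    s[key] = tuple(s[key])
            synth = SyntheticConfig(**s)
        detectors = tuple(
            ScorerSpec(name=x["name"], params=dict(x.get("params") or {}),
                       seed=int(x.get("seed", 0)))
            for x in d.get("detectors", [{"name": n} for n in DEFAULT_DETECTORS])
        )
        interp = d.get("interpret", {})
        return cls(
            seed=int(d.get("seed", 0)),
            outdir=d.get("outdir", "runs/experiment"),
            synth=synth,
            cohort_csv=d.get("cohort_csv"),
            schema_path=d.get("schema_path"),
            categories=tuple(d.get("categories", CATEGORIES)),
            detectors=detectors,
            repeats=int(d.get("repeats", 2)),
            folds=int(d.get("folds", 5)),
            mode=d.get("mode", "global"),
            interpret=InterpretSettings(
                detector=interp.get("detector", "iforest"),
                methods=tuple(interp.get("methods", ("perturb", "diffi"))),
                baseline=interp.get("baseline", "training-normal-means"),
                outlier_mode=interp.get("outlier_mode", "label"),
                top_k=interp.get("top_k"),
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_inputs(config: ExperimentConfig, outdir: Path):
    if config.synth is not None:
        synth_cfg = dataclasses.replace(config.synth, seed=derive_seed(config.seed, 0))
        cohort, truth = generate_cohort(synth_cfg)
        schema = synth_cfg.schema()
        write_cohort(cohort, outdir / "cohort.csv")
        truth.to_json(outdir / "cohort.groundtruth.json")
    else:
        cohort = read_cohort(config.cohort_csv)
        schema = (FeatureSchema.from_json(config.schema_path)
                  if config.schema_path else infer_schema(cohort))
    return cohort, schema


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full flow; returns paths and in-memory results."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort, schema = _load_inputs(config, outdir)
    cohort, n_dropped = drop_invalid_weight(cohort)
    labels = category_labels(cohort[WEIGHT_COLUMN].to_numpy(dtype=float))

    preprocessor = Preprocessor(schema)
    fm = preprocessor.fit_transform(cohort)
    preprocessor.to_json(outdir / "transform_params.json")
    logger.info("preprocessed %d rows x %d encoded columns (%d dropped)",
                fm.n_rows, fm.X.shape[1], n_dropped)

    reports: list[EvalReport] = []
    ftests: dict[str, dict] = {}
    for ci, cat in enumerate(config.categories):
        plan = make_folds(labels[cat], repeats=config.repeats, folds=config.folds,
                          seed=derive_seed(config.seed, 1, ci), category=cat)
        cat_reports = []
        for di, spec in enumerate(config.detectors):
            spec_seeded = dataclasses.replace(spec, seed=derive_seed(config.seed, 2, ci, di))
            rep = cross_validate(
                fm, labels[cat], spec_seeded, plan,
                cohort=cohort, preprocessor=Preprocessor(schema),
                mode=config.mode, category=cat,
            )
            cat_reports.append(rep)
        cat_report = EvalReport.concat(cat_reports)
        reports.append(cat_report)
        if len(config.detectors) >= 2:
            ftests[cat] = compare_detectors(cat_report, cat).to_dict()

    report = EvalReport.concat(reports)
    report.to_long().to_csv(outdir / "metrics.csv", index=False)
    summary = {
        "means": report.summary().to_dict(orient="records"),
        "f_tests": ftests,
        "n_rows": int(fm.n_rows),
        "n_dropped_invalid_weight": int(n_dropped),
        "prevalence": {c: float(np.mean(labels[c])) for c in config.categories},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    mean_ranks = _run_interpretation(config, cohort, fm, labels, preprocessor, outdir)

    config.to_yaml(outdir / "resolved_config.yaml")
    logger.info("experiment finished in %.1f s", time.perf_counter() - t0)
    return {
        "outdir": outdir,
        "report": report,
        "summary": summary,
        "mean_ranks": mean_ranks,
    }


def _run_interpretation(config, cohort, fm, labels, preprocessor, outdir: Path):
    """Fit the chosen detector per category and aggregate attributions."""
    settings = config.interpret
    groups = fm.feature_groups()
    results: dict[tuple[str, str], pd.Series] = {}
    for ci, cat in enumerate(config.categories):
        normal = np.flatnonzero(labels[cat] == 0)
        spec = next(
            (s for s in config.detectors if s.name == settings.detector),
            ScorerSpec(settings.detector),
        )
        spec = dataclasses.replace(spec, seed=derive_seed(config.seed, 3, ci))
        model = make_scorer(spec).fit(fm.X[normal])
        if settings.baseline == "training-normal-means":
            baseline = compute_baseline(fm, rows=normal)
        else:
            baseline = compute_baseline(fm, provenance="test-set-means")
        scores = model.score(fm.X)
        ids = select_outlier_points(labels=labels[cat], scores=scores,
                                    mode=settings.outlier_mode, k=settings.top_k)
        for method in settings.methods:
            attr_fn = perturb_attribution if method == "perturb" else local_diffi
            attrs = [attr_fn(model, fm.X[i], baseline, groups, instance_id=int(i))
                     for i in ids]
            pd.concat([a.to_frame() for a in attrs], ignore_index=True).to_csv(
                outdir / f"attributions_{cat}_{method}.csv", index=False)
            ranks = average_feature_ranks(attrs)
            ranks.rename_axis("feature").reset_index().to_csv(
                outdir / f"mean_ranks_{cat}_{method}.csv", index=False)
            results[(cat, method)] = ranks
        with open(outdir / f"bundle_{cat}_{settings.detector}.pkl", "wb") as fh:
            pickle.dump({
                "preprocessor": preprocessor.to_dict(),
                "model": model,
                "baseline": baseline,
                "feature_groups": {k: v.tolist() for k, v in groups.items()},
                "category": cat,
                "detector": settings.detector,
            }, fh)
    return results
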