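"""Config-driven experiment runner: the full simulation grid.

For each outcome the runner draws one held-out test split, builds nested
training splits, and — for each text variant and budget — preprocesses the
corpus, fits the configured classifier and evaluates it on the shared test
set, overall and per demographic subgroup.  The oversampling arm retrains
at a base budget with positive cases added until each target fraction is
reached (trained on the language-replacement text, evaluated on the same
test set).  All randomness flows from one root seed; the manifest records
every derived seed and split so a run is exactly replayable.

Variants:

* ``base`` — cleaned LE + CME text combined;
* ``language_replacement`` — combined text with abbreviation expansion;
* ``le_only`` — cleaned LE text only.

Training split ids are shared across variants; only the text differs, so
variant comparisons are not confounded by sampling noise.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluation, preprocess, splits, synthetic
from .classifiers import ClassifierConfig, predict, train_classifier
from .evaluation import MetricRow
from .preprocess import PreprocessConfig
from .synthetic import GeneratorConfig, NarrativeRecord

__all__ = ["ExperimentConfig", "OversampleSpec", "run_experiment", "report"]

logger = logging.getLogger(__name__)

VARIANTS = ("base", "language_replacement", "le_only")


@dataclass
class OversampleSpec:
    base_budget: int = 1000
    target_fractions: tuple[float, ...] = splits.DEFAULT_OVERSAMPLE_FRACTIONS


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    outcomes: tuple[str, ...] = synthetic.OUTCOMES
    variants: tuple[str, ...] = VARIANTS
    budgets: tuple[int, ...] = splits.DEFAULT_BUDGETS
    oversample: OversampleSpec | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    test_fraction: float = 0.30
    subgroup_keys: tuple[str, ...] = ("race_ethnicity", "sex")
    min_group_n: int = evaluation.DEFAULT_MIN_GROUP_N
    max_tokens: int = 512
    output_dir: str = "results"
    root_seed: int = 0

    def validate(self) -> None:
        if self.generator is None and self.cohort_path is None:
            raise ValueError("either a generator config or a cohort path is required")
        if not self.variants:
            raise ValueError("variants must be non-empty")
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant: {v!r}")
        if not self.budgets or any(
            b2 <= b1 for b1, b2 in zip(self.budgets, self.budgets[1:])
        ):
            raise ValueError("budgets must be non-empty and strictly increasing")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0,1)")
        if self.oversample is not None and self.oversample.base_budget not in self.budgets:
            raise ValueError("oversample base_budget must be one of the budgets")

    @classmethod
    def from_yaml(cls, path, *, root_seed: int | None = None) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        generator = None
        if "generator" in doc:
            generator = synthetic.load_config(yaml.safe_dump(doc["generator"]))
        oversample = None
        if "oversample" in doc:
            oversample = OversampleSpec(
                base_budget=int(doc["oversample"].get("base_budget", 1000)),
                target_fractions=tuple(
                    float(f)
                    for f in doc["oversample"].get(
                        "target_fractions", splits.DEFAULT_OVERSAMPLE_FRACTIONS
                    )
                ),
            )
        classifier = ClassifierConfig(**doc.get("classifier", {}))
        cfg = cls(
            generator=generator,
            cohort_path=doc.get("cohort_path"),
            outcomes=tuple(doc.get("outcomes", synthetic.OUTCOMES)),
            variants=tuple(doc.get("variants", VARIANTS)),
            budgets=tuple(int(b) for b in doc.get("budgets", splits.DEFAULT_BUDGETS)),
            oversample=oversample,
            classifier=classifier,
            test_fraction=float(doc.get("test_fraction", 0.30)),
            subgroup_keys=tuple(doc.get("subgroup_keys", ("race_ethnicity", "sex"))),
            min_group_n=int(doc.get("min_group_n", evaluation.DEFAULT_MIN_GROUP_N)),
            max_tokens=int(doc.get("max_tokens", 512)),
            output_dir=doc.get("output_dir", "results"),
            root_seed=int(doc.get("root_seed", 0)),
        )
        if root_seed is not None:
            cfg.root_seed = root_seed
        cfg.validate()
        return cfg


def _variant_preprocess(variant: str, max_tokens: int) -> PreprocessConfig:
    if variant == "base":
        return PreprocessConfig(source_mode="combined", replace_abbreviations=False,
                                max_tokens=max_tokens)
    if variant == "language_replacement":
        return PreprocessConfig(source_mode="combined", replace_abbreviations=True,
                                max_tokens=max_tokens)
    if variant == "le_only":
        return PreprocessConfig(source_mode="le_only", replace_abbreviations=False,
                                max_tokens=max_tokens)
    raise ValueError(f"unknown variant: {variant!r}")


def _load_cohort(config: ExperimentConfig) -> list[NarrativeRecord]:
    if config.cohort_path is not None:
        path = str(config.cohort_path)
        if path.endswith(".jsonl"):
            return synthetic.read_cohort_jsonl(path)
        return synthetic.read_cohort_csv(path)
    return synthetic.generate_cohort(config.generator)


def _evaluate_cell(
    model,
    test_records: Sequence[NarrativeRecord],
    test_texts: Sequence[str],
    outcome: str,
    variant: str,
    budget: int,
    config: ExperimentConfig,
) -> list[MetricRow]:
    y_true = [r.outcomes[outcome] for r in test_records]
    y_pred = predict(model, test_texts)
    rows = [
        evaluation.make_metric_row(
            y_true, y_pred, outcome=outcome, variant=variant, budget=budget,
            seed=config.root_seed,
        )
    ]
    for key in config.subgroup_keys:
        groups = [getattr(r, key) for r in test_records]
        rows.extend(
            evaluation.stratified_metrics(
                y_true, y_pred, groups, config.min_group_n,
                outcome=outcome, variant=variant, budget=budget,
                seed=config.root_seed, include_overall=False,
            )
        )
    return rows


def run_experiment(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Execute the grid; write results.csv, split plans and a manifest.

    Returns the tidy results DataFrame and the manifest dict.  Re-running
    with the same config reproduces linear-backend results bit-exactly.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = splits.restrict_cohort(_load_cohort(config))
    manifest: dict = {
        "root_seed": config.root_seed,
        "n_records": len(cohort),
        "cohort_digest": synthetic.cohort_digest(cohort),
        "outcomes": {},
        "skipped_cells": [],
    }

    seed_rng = np.random.default_rng(config.root_seed)
    all_rows: list[MetricRow] = []
    for outcome in config.outcomes:
        seeds = {
            purpose: int(seed_rng.integers(0, 2**31 - 1))
            for purpose in ("test", "train", "oversample", "classifier")
        }
        test_ids = splits.make_test_split(
            cohort, outcome, config.test_fraction, seeds["test"]
        )
        pool = [r for r in cohort if r.record_id not in test_ids]
        train_by_budget = splits.make_nested_train_splits(
            pool, outcome, config.budgets, seeds["train"]
        )
        plan = splits.SplitPlan(
            outcome=outcome,
            test_ids=test_ids,
            train_budgets=tuple(config.budgets),
            train_ids_by_budget=train_by_budget,
            seed=seeds["train"],
        )
        plan.validate()
        plan_path = out_dir / f"split_{outcome}.json"
        plan.to_json(plan_path)
        manifest["outcomes"][outcome] = {
            "seeds": seeds,
            "split_plan": plan_path.name,
            "n_test": len(test_ids),
        }

        test_records = sorted(
            (r for r in cohort if r.record_id in test_ids), key=lambda r: r.record_id
        )
        by_id = {r.record_id: r for r in cohort}
        clf_config = replace(config.classifier, seed=seeds["classifier"],
                             max_tokens=config.max_tokens)

        texts_by_variant: dict[str, dict[str, str]] = {}
        needed = set(config.variants) | (
            {"language_replacement"} if config.oversample else set()
        )
        for variant in needed:
            pp = _variant_preprocess(variant, config.max_tokens)
            texts_by_variant[variant] = dict(preprocess.preprocess_corpus(cohort, pp))

        for variant in config.variants:
            texts = texts_by_variant[variant]
            test_texts = [texts[r.record_id] for r in test_records]
            for budget in config.budgets:
                t0 = time.perf_counter()
                train_ids = sorted(train_by_budget[budget])
                train_texts = [texts[i] for i in train_ids]
                train_labels = [by_id[i].outcomes[outcome] for i in train_ids]
                n_pos = sum(train_labels)
                try:
                    model = train_classifier(train_texts, train_labels, clf_config)
                except ValueError as err:
                    logger.warning(
                        "skipping %s/%s/%d: %s", outcome, variant, budget, err
                    )
                    manifest["skipped_cells"].append(
                        {"outcome": outcome, "variant": variant, "budget": budget,
                         "reason": str(err)}
                    )
                    continue
                all_rows.extend(
                    _evaluate_cell(model, test_records, test_texts, outcome,
                                   variant, budget, config)
                )
                logger.info(
                    "%s/%s/%d: %d pos / %d neg, %.2fs",
                    outcome, variant, budget, n_pos, budget - n_pos,
                    time.perf_counter() - t0,
                )

        if config.oversample is not None:
            base_ids = train_by_budget[config.oversample.base_budget]
            os_plan = splits.make_oversampled_splits(
                cohort, outcome, base_ids, test_ids,
                config.oversample.target_fractions, seeds["oversample"],
            )
            os_path = out_dir / f"oversample_{outcome}.json"
            os_plan.to_json(os_path)
            manifest["outcomes"][outcome]["oversample_plan"] = os_path.name
            texts = texts_by_variant["language_replacement"]
            test_texts = [texts[r.record_id] for r in test_records]
            for frac in config.oversample.target_fractions:
                added = os_plan.added_pos_ids_by_fraction[frac]
                if not added:
                    manifest["skipped_cells"].append(
                        {"outcome": outcome, "variant": f"oversample@{frac:g}",
                         "budget": config.oversample.base_budget,
                         "reason": "base composition already meets target fraction"}
                    )
                    continue
                train_ids = sorted(base_ids | added)
                train_texts = [texts[i] for i in train_ids]
                train_labels = [by_id[i].outcomes[outcome] for i in train_ids]
                model = train_classifier(train_texts, train_labels, clf_config)
                all_rows.extend(
                    _evaluate_cell(
                        model, test_records, test_texts, outcome,
                        f"oversample@{frac:g}", len(train_ids), config,
                    )
                )

    df = evaluation.rows_to_dataframe(all_rows)
    df.to_csv(out_dir / "results.csv", index=False)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return df, manifest


def report(results: pd.DataFrame | str, out_dir: str | None = None) -> dict[str, pd.DataFrame]:
    """Summary tables from a tidy results CSV/DataFrame.

    Emits, per outcome: a wide F1 table (budget x variant) with the
    best-F1 variant flagged per budget; a subgroup F1 table; and per-cell
    F1 disparities (max - min across subgroups, separately for race and
    sex groupings).
    """
    if isinstance(results, (str, Path)):
        df = evaluation.read_results_csv(results)
    else:
        df = results.copy()
        missing = set(evaluation.RESULTS_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"malformed results, missing columns: {sorted(missing)}")

    overall = df[df["subgroup"] == "overall"]
    wide = overall.pivot_table(
        index=["outcome", "budget"], columns="variant", values="f1"
    ).reset_index()
    variant_cols = [c for c in wide.columns if c not in ("outcome", "budget")]
    if len(variant_cols) > 1:
        wide["best_variant"] = wide[variant_cols].idxmax(axis=1)

    sub = df[df["subgroup"] != "overall"]
    subgroup_table = sub.pivot_table(
        index=["outcome", "variant", "budget"], columns="subgroup", values="f1"
    ).reset_index()

    race_groups = set(synthetic.RACE_ETHNICITY)
    sex_groups = set(synthetic.SEX)
    disparity_rows = []
    for (outcome, variant, budget), cell in sub.groupby(["outcome", "variant", "budget"]):
        for key, names in (("race_ethnicity", race_groups), ("sex", sex_groups)):
            f1s = cell[cell["subgroup"].isin(names)]["f1"]
            if len(f1s) >= 2:
                disparity_rows.append(
                    {"outcome": outcome, "variant": variant, "budget": budget,
                     "subgroup_key": key,
                     "f1_disparity": float(f1s.max() - f1s.min())}
                )
    disparity_table = pd.DataFrame(disparity_rows)

    tables = {
        "f1_wide": wide,
        "subgroup_f1": subgroup_table,
        "disparity": disparity_table,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"report_{name}.csv", index=False)
    return tables
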