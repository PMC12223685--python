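#!/usr/bin/env python
"""Learning curves across text variants: the core simulation grid.

Trains the class-weighted linear baseline at budgets 100-2000 for all four
outcomes under three text configurations (combined narratives, combined
with abbreviation replacement, LE-only) and reports F1/precision/recall/FNR
on a shared 30% held-out test set per outcome.  Writes the tidy results and
the wide summary tables to results/learning_curves/.
"""

from pathlib import Path

from narrsim.classifiers import ClassifierConfig
from narrsim.experiment import ExperimentConfig, report, run_experiment
from narrsim.synthetic import default_config

OUT = Path("results/learning_curves")


def main() -> None:
    config = ExperimentConfig(
        generator=default_config(n_records=8000, seed=11),
        budgets=(100, 200, 500, 1000, 1500, 2000),
        classifier=ClassifierConfig(seed=0),
        output_dir=str(OUT),
        root_seed=11,
    )
    df, manifest = run_experiment(config)
    tables = report(df, out_dir=str(OUT))

    wide = tables["f1_wide"]
    print("F1 by outcome, budget and text variant:")
    print(wide.to_string(index=False))

    top = wide[wide["budget"] == 2000]
    print("\nAt budget 2000, best variant per outcome:")
    print(top[["outcome", "best_variant"]].to_string(index=False))
    le_drop = (wide["base"] - wide["le_only"]).mean()
    print(f"\nDropping the CME narrative costs {le_drop:.3f} F1 on average —")
    print("records whose police narrative is uninformative lose their signal.")
    if manifest["skipped_cells"]:
        print(f"skipped cells: {manifest['skipped_cells']}")


if __name__ == "__main__":
    main()
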