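"""Multi-start GP symbolic regression on the Margalef index.

A scaled-down search (20 restarts x 100 generations; the full protocol is
100 restarts x 500 generations) on the winter-excluded, standardized data.
Prints the best equation, its fit, and the variable-presence tally across
restarts; writes results/gp_margalef.json.

Run: python analysis/04_gp_search.py [--seed N] [--runs N] [--generations N]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from riverbio import gp, io as rio, pipeline, stats_prep
from riverbio.diversity import INDEX_COLUMNS
from riverbio.pipeline import ENV_PREDICTORS

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 3, runs: int = 20, generations: int = 100) -> None:
    env = rio.read_env_csv(RESULTS / "data" / "environment.csv")
    indices = pd.read_csv(RESULTS / "indices.csv")
    merged = env.merge(indices, on=["station", "month"]).set_index(["station", "month"])
    numeric = merged[ENV_PREDICTORS + list(INDEX_COLUMNS)]

    std_all = stats_prep.minmax_standardize(numeric)
    assignment = stats_prep.kmeans_cluster(std_all, 2, seed=seed)
    months = merged.index.get_level_values("month").to_series(index=merged.index)
    retained = stats_prep.exclude_winter_cluster(assignment, months)
    corr = stats_prep.pearson_correlation_matrix(numeric)
    predictors = stats_prep.drop_collinear(
        corr.loc[ENV_PREDICTORS, ENV_PREDICTORS], 0.95, ["ec", "tds"]
    )

    std = stats_prep.minmax_standardize(merged.loc[retained, predictors + ["margalef"]])
    train, valid = stats_prep.train_validation_split(list(retained), 0.8, seed)
    results = pipeline.run_multistart_gp(
        gp.GpConfig(generations=generations, seed=seed),
        runs,
        std.values.loc[train, predictors].to_numpy(),
        std.values.loc[train, "margalef"].to_numpy(),
        std.values.loc[valid, predictors].to_numpy(),
        std.values.loc[valid, "margalef"].to_numpy(),
    )
    best = pipeline.select_best_equation(results)
    tally = pipeline.tally_variable_presence(results, predictors)

    print(f"{runs} GP restarts ({generations} generations each) on {len(train)} training samples")
    print(f"best-of-restarts equation (training r = {best.train.pearson_r:.3f}, "
          f"validation r = {best.validation.pearson_r:.3f}):")
    print(" ", gp.tree_to_infix(best.tree, predictors))
    print("\nvariable presence across restart best equations (%):")
    for name, pct in sorted(tally.items(), key=lambda kv: -kv[1]):
        print(f"  {name:12s} {pct:5.1f}")

    payload = {
        "equation": gp.tree_to_string(best.tree),
        "infix": gp.tree_to_infix(best.tree, predictors),
        "train_r": best.train.pearson_r,
        "validation_r": best.validation.pearson_r,
        "presence_tally": tally,
    }
    (RESULTS / "gp_margalef.json").write_text(json.dumps(payload, indent=2))
    print(f"\nwrote {RESULTS / 'gp_margalef.json'}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=3)
    parser.add_argument("--runs", type=int, default=20)
    parser.add_argument("--generations", type=int, default=100)
    args = parser.parse_args()
    main(args.seed, args.runs, args.generations)
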