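"""Screening: correlation matrix, seasonal 2-means clustering, collinearity
pruning, and varimax-rotated PCA of the water-quality predictors.

Reads results/data/* and results/indices.csv; writes the correlation matrix,
cluster labels, and rotated loadings under results/screening/.

Run: python analysis/03_screen.py [--seed N]
"""

import argparse
from pathlib import Path

import pandas as pd

from riverbio import io as rio
from riverbio import stats_prep
from riverbio.diversity import INDEX_COLUMNS
from riverbio.pipeline import ENV_PREDICTORS

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 3) -> None:
    out = RESULTS / "screening"
    out.mkdir(parents=True, exist_ok=True)
    env = rio.read_env_csv(RESULTS / "data" / "environment.csv")
    indices = pd.read_csv(RESULTS / "indices.csv")
    merged = env.merge(indices, on=["station", "month"]).set_index(["station", "month"])
    numeric = merged[ENV_PREDICTORS + list(INDEX_COLUMNS)]

    corr = stats_prep.pearson_correlation_matrix(numeric)
    corr.to_csv(out / "correlation_matrix.csv", float_format="%.3f")
    print("correlation matrix (indices vs environment):")
    print(corr.loc[list(INDEX_COLUMNS), ENV_PREDICTORS].round(3))

    std = stats_prep.minmax_standardize(numeric)
    assignment = stats_prep.kmeans_cluster(std, 2, seed=seed)
    months = merged.index.get_level_values("month").to_series(index=merged.index)
    retained = stats_prep.exclude_winter_cluster(assignment, months)
    assignment.labels.rename("cluster").to_csv(out / "clusters.csv")
    winter = months.isin(stats_prep.WINTER_MONTHS)
    frac = (
        assignment.labels[winter].value_counts(normalize=True).max() * 100
    )
    print(f"\n2-means: {frac:.0f}% of Dec-Feb samples share one cluster;")
    print(f"winter cluster excluded -> {len(retained)} samples retained for regression")

    kept = stats_prep.drop_collinear(
        corr.loc[ENV_PREDICTORS, ENV_PREDICTORS], 0.95, ["ec", "tds"]
    )
    dropped = [v for v in ENV_PREDICTORS if v not in kept]
    print(f"collinearity pruning (|r| >= 0.95): dropped {dropped}, kept {kept}")

    pca = stats_prep.pca_varimax(std.values[kept], 4)
    pca.rotated_loadings.to_csv(out / "pca_rotated_loadings.csv", float_format="%.3f")
    cum4 = pca.cumulative_explained[-1] * 100
    print(f"\nrotated PCA: first 4 components explain {cum4:.1f}% of variance")
    print(pca.rotated_loadings.round(3))


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=3)
    main(parser.parse_args().seed)
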