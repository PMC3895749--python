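"""End-to-end analysis: indices -> screening -> multi-start GP -> reporting.

The orchestration follows the screening-then-regression recipe for linking a
biodiversity index to water physicochemistry:

1. compute Shannon / Simpson / Margalef per station-month sample;
2. Pearson correlation matrix of indices and environmental variables;
3. two-cluster K-means on the standardized data; drop the winter cluster;
4. prune perfectly collinear predictors (TDS goes, EC stays);
5. min-max standardize predictors and targets, split 80/20;
6. for each index, run many independent GP searches, tally which predictors
   appear in each best-of-run equation (a crude variable-importance measure),
   and keep the run with the highest training correlation;
7. varimax-rotated PCA of the predictors as an independent importance check;
8. pick the index whose best equation correlates most strongly, and report
   observed-vs-calculated summary statistics on the original index scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import gp, stats_prep
from .diversity import INDEX_COLUMNS, compute_indices_table
from .errors import (
    InsufficientDataError,
    PipelineStageError,
    RiverbioError,
    UndefinedEquationError,
)
from .gp import FitnessReport, GpConfig, GpRunResult

__all__ = [
    "AnalysisConfig",
    "FitSummary",
    "evaluate_margalef_equation",
    "run_multistart_gp",
    "tally_variable_presence",
    "select_best_equation",
    "estimation_error_percent",
    "summarize_fit",
    "full_pipeline",
]

ENV_PREDICTORS = ["temperature", "discharge_q", "ph", "do_mgl", "ec", "bod5", "tds"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the full screening + GP analysis."""

    gp: GpConfig = field(default_factory=GpConfig)
    n_runs: int = 100
    split_fraction: float = 0.8
    k_clusters: int = 2
    collinearity_threshold: float = 0.95
    keep_priority: tuple[str, ...] = ("ec", "tds")
    n_components: int = 4
    winter_months: tuple[int, ...] = stats_prep.WINTER_MONTHS
    correlations_on_all_months: bool = True
    seed: int = 0


def evaluate_margalef_equation(
    do_mgl: float, temperature: float, ec: float, bod5: float
) -> float:
    """Closed-form Margalef estimate MI = DO/T + 2*DO/(T + EC + BOD5).

    Accepts scalars or aligned arrays; the caller declares the input scale
    (raw units or [0,1]-standardized values).
    """
    do_mgl = np.asarray(do_mgl, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    denom2 = np.asarray(temperature + ec + bod5, dtype=float)
    if np.any(temperature == 0.0) or np.any(denom2 == 0.0):
        raise UndefinedEquationError("zero denominator in Margalef equation")
    out = do_mgl / temperature + 2.0 * do_mgl / denom2
    return float(out) if out.ndim == 0 else out


def run_multistart_gp(
    config: GpConfig,
    n_runs: int,
    train_predictors: np.ndarray,
    train_targets: np.ndarray,
    validation_predictors: np.ndarray | None = None,
    validation_targets: np.ndarray | None = None,
) -> list[GpRunResult]:
    """``n_runs`` independent GP searches with seeds spawned from config.seed."""
    if n_runs < 1:
        raise RiverbioError("n_runs must be >= 1")
    master = np.random.default_rng(config.seed)
    run_seeds = master.integers(0, 2**31 - 1, size=n_runs)
    results = []
    for idx, run_seed in enumerate(run_seeds):
        try:
            result = gp.evolve(
                replace(config, seed=int(run_seed)), train_predictors, train_targets
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RiverbioError(f"GP run {idx} failed: {exc}") from exc
        result.run_index = idx
        if validation_predictors is not None and validation_targets is not None:
            result.validation = gp.fitness(
                gp.evaluate_tree(result.tree, validation_predictors),
                validation_targets,
            )
        results.append(result)
    return results


def tally_variable_presence(
    results: Sequence[GpRunResult], variable_names: Sequence[str]
) -> dict[str, float]:
    """Percentage of runs whose best tree contains each predictor."""
    if not results:
        raise RiverbioError("presence tally needs at least one run result")
    counts = {name: 0 for name in variable_names}
    for res in results:
        for idx in gp.tree_variables(res.tree):
            counts[variable_names[idx]] += 1
    return {name: 100.0 * c / len(results) for name, c in counts.items()}


def select_best_equation(results: Sequence[GpRunResult]) -> GpRunResult:
    """Highest training Pearson r; ties -> lower rmse, then lower run index."""
    if not results:
        raise RiverbioError("cannot select from an empty result list")
    return min(
        results, key=lambda r: (-r.train.pearson_r, r.train.rmse, r.run_index)
    )


def estimation_error_percent(observed_stat: float, calculated_stat: float) -> float:
    """100 * |observed - calculated| / |observed|."""
    if observed_stat == 0.0:
        raise RiverbioError("estimation error undefined for a zero observed statistic")
    return 100.0 * abs(observed_stat - calculated_stat) / abs(observed_stat)


@dataclass(frozen=True)
class FitSummary:
    """Observed-vs-calculated summary statistics for one train/validation split."""

    observed_mean: float
    calculated_mean: float
    mean_error_percent: float
    observed_std: float
    calculated_std: float
    std_error_percent: float
    r_squared: float
    mse: float
    rmse: float

    @classmethod
    def from_series(cls, observed: np.ndarray, calculated: np.ndarray) -> "FitSummary":
        obs = np.asarray(observed, dtype=float)
        calc = np.asarray(calculated, dtype=float)
        if obs.size < 2 or obs.shape != calc.shape:
            raise InsufficientDataError("fit summary needs >= 2 aligned observations")
        report = gp.fitness(calc, obs)
        obs_std = float(obs.std(ddof=1))
        calc_std = float(calc.std(ddof=1))
        return cls(
            observed_mean=float(obs.mean()),
            calculated_mean=float(calc.mean()),
            mean_error_percent=estimation_error_percent(obs.mean(), calc.mean()),
            observed_std=obs_std,
            calculated_std=calc_std,
            std_error_percent=estimation_error_percent(obs_std, calc_std),
            r_squared=report.pearson_r**2,
            mse=report.rmse**2,
            rmse=report.rmse,
        )


def summarize_fit(
    train_observed: np.ndarray,
    train_calculated: np.ndarray,
    validation_observed: np.ndarray,
    validation_calculated: np.ndarray,
) -> dict[str, FitSummary]:
    """Table of fit statistics for both splits, on the caller's scale."""
    return {
        "train": FitSummary.from_series(train_observed, train_calculated),
        "validation": FitSummary.from_series(validation_observed, validation_calculated),
    }


# ---------------------------------------------------------------------------

def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def full_pipeline(
    counts: pd.DataFrame, env: pd.DataFrame, config: AnalysisConfig
) -> dict:
    """Run the complete analysis and return a JSON-serialisable report."""
    with _stage("indices"):
        indices = compute_indices_table(counts)
        merged = env.merge(indices, on=["station", "month"], validate="one_to_one")
        merged = merged.set_index(["station", "month"])

    with _stage("correlations"):
        numeric = merged[ENV_PREDICTORS + list(INDEX_COLUMNS)]
        corr = stats_prep.pearson_correlation_matrix(numeric)

    with _stage("clustering"):
        cluster_features = stats_prep.minmax_standardize(numeric)
        assignment = stats_prep.kmeans_cluster(
            cluster_features, config.k_clusters, seed=config.seed
        )
        months = merged.index.get_level_values("month").to_series(index=merged.index)
        retained = stats_prep.exclude_winter_cluster(
            assignment, months, config.winter_months
        )

    with _stage("collinearity"):
        env_corr = corr.loc[ENV_PREDICTORS, ENV_PREDICTORS]
        kept_predictors = stats_prep.drop_collinear(
            env_corr, config.collinearity_threshold, list(config.keep_priority)
        )
        dropped = [v for v in ENV_PREDICTORS if v not in kept_predictors]

    with _stage("standardize"):
        retained_data = merged.loc[retained]
        std = stats_prep.minmax_standardize(
            retained_data[kept_predictors + list(INDEX_COLUMNS)]
        )

    with _stage("split"):
        train_keys, valid_keys = stats_prep.train_validation_split(
            list(retained), config.split_fraction, seed=config.seed
        )
        X_train = std.values.loc[train_keys, kept_predictors].to_numpy()
        X_valid = std.values.loc[valid_keys, kept_predictors].to_numpy()

    with _stage("pca"):
        pca = stats_prep.pca_varimax(
            std.values[kept_predictors], config.n_components
        )

    with _stage("gp_search"):
        per_index: dict[str, dict] = {}
        index_rng = np.random.default_rng([int(config.seed), 7])
        for index_name in INDEX_COLUMNS:
            y_train = std.values.loc[train_keys, index_name].to_numpy()
            y_valid = std.values.loc[valid_keys, index_name].to_numpy()
            gp_config = replace(config.gp, seed=int(index_rng.integers(2**31 - 1)))
            results = run_multistart_gp(
                gp_config, config.n_runs, X_train, y_train, X_valid, y_valid
            )
            best = select_best_equation(results)
            per_index[index_name] = {
                "results": results,
                "best": best,
                "presence": tally_variable_presence(results, kept_predictors),
            }

    with _stage("index_selection"):
        selected_index = max(
            INDEX_COLUMNS, key=lambda name: per_index[name]["best"].train.pearson_r
        )
        best = per_index[selected_index]["best"]

    with _stage("fit_summary"):
        pred_train = gp.evaluate_tree(best.tree, X_train)
        pred_valid = gp.evaluate_tree(best.tree, X_valid)
        obs_train = std.inverse_column(
            std.values.loc[train_keys, selected_index].to_numpy(), selected_index
        )
        obs_valid = std.inverse_column(
            std.values.loc[valid_keys, selected_index].to_numpy(), selected_index
        )
        calc_train = std.inverse_column(pred_train, selected_index)
        calc_valid = std.inverse_column(pred_valid, selected_index)
        fit = summarize_fit(obs_train, calc_train, obs_valid, calc_valid)

    with _stage("series"):
        series_rows = []
        for split, keys, obs, calc in (
            ("train", train_keys, obs_train, calc_train),
            ("validation", valid_keys, obs_valid, calc_valid),
        ):
            for (station, month), o, c in zip(keys, obs, calc):
                series_rows.append(
                    {
                        "station": station,
                        "month": int(month),
                        "split": split,
                        "observed": float(o),
                        "calculated": float(c),
                    }
                )
        series = pd.DataFrame(series_rows).sort_values(["station", "month"])

    report = {
        "config": {
            "n_runs": config.n_runs,
            "split_fraction": config.split_fraction,
            "k_clusters": config.k_clusters,
            "collinearity_threshold": config.collinearity_threshold,
            "n_components": config.n_components,
            "winter_months": list(config.winter_months),
            "seed": config.seed,
            "gp": asdict(config.gp),
        },
        "correlation_matrix": _frame_to_dict(corr),
        "clusters": {
            "labels": {f"{s}:{m}": int(l) for (s, m), l in assignment.labels.items()},
            "retained_samples": [f"{s}:{m}" for s, m in retained],
            "n_retained": int(len(retained)),
        },
        "dropped_variables": dropped,
        "kept_predictors": kept_predictors,
        "presence_tally": {
            name: per_index[name]["presence"] for name in INDEX_COLUMNS
        },
        "pca": {
            "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
            "cumulative_explained": pca.cumulative_explained.tolist(),
            "rotated_loadings": _frame_to_dict(pca.rotated_loadings),
        },
        "cross_run_correlation": {
            name: per_index[name]["best"].train.pearson_r for name in INDEX_COLUMNS
        },
        "selected_index": selected_index,
        "best_equation": {
            "prefix": gp.tree_to_string(best.tree),
            "infix": gp.tree_to_infix(best.tree, kept_predictors),
            "train_rmse_standardized": best.train.rmse,
            "train_r": best.train.pearson_r,
            "validation_r": best.validation.pearson_r if best.validation else None,
            "run_index": best.run_index,
            "seed": best.seed,
        },
        "fit_summary": {split: asdict(s) for split, s in fit.items()},
        "series": series.to_dict(orient="records"),
    }
    return report


def _frame_to_dict(frame: pd.DataFrame) -> dict:
    return {
        "index": [str(i) for i in frame.index],
        "columns": [str(c) for c in frame.columns],
        "values": [[float(v) for v in row] for row in frame.to_numpy()],
    }


def report_to_json(report: dict) -> str:
    """Serialise a pipeline report deterministically."""
    return json.dumps(report, indent=2, sort_keys=True)
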