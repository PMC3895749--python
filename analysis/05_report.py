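"""Full pipeline end-to-end: screening, GP per index, index selection, and
the observed-vs-calculated fit report.

Scaled-down search (20 restarts x 100 generations per index). Writes
results/report.json and results/observed_vs_calculated.csv and prints the
fit-statistics table.

Run: python analysis/05_report.py [--seed N]
"""

import argparse
from pathlib import Path

import pandas as pd

from riverbio import gp, io as rio, pipeline
from riverbio.cli import _counts_to_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 3, runs: int = 20, generations: int = 100) -> None:
    counts = _counts_to_frame(rio.read_counts_csv(RESULTS / "data" / "counts.csv"))
    env = rio.read_env_csv(RESULTS / "data" / "environment.csv")
    config = pipeline.AnalysisConfig(
        gp=gp.GpConfig(generations=generations), n_runs=runs, seed=seed
    )
    report = pipeline.full_pipeline(counts, env, config)

    (RESULTS / "report.json").write_text(pipeline.report_to_json(report))
    series = pd.DataFrame(report["series"])
    series.to_csv(RESULTS / "observed_vs_calculated.csv", index=False, float_format="%.4f")

    print("cross-run best training correlation per index:")
    for name, r in report["cross_run_correlation"].items():
        marker = " <- selected" if name == report["selected_index"] else ""
        print(f"  {name:9s} r = {r:.3f}{marker}")
    print(f"\nbest equation ({report['selected_index']}):")
    print(" ", report["best_equation"]["infix"])
    print("\nfit statistics (original index scale):")
    rows = []
    for split in ("train", "validation"):
        s = report["fit_summary"][split]
        rows.append(
            {
                "split": split,
                "obs mean": round(s["observed_mean"], 2),
                "calc mean": round(s["calculated_mean"], 2),
                "mean err %": round(s["mean_error_percent"], 1),
                "obs std": round(s["observed_std"], 2),
                "calc std": round(s["calculated_std"], 2),
                "std err %": round(s["std_error_percent"], 1),
                "R2": round(s["r_squared"], 3),
                "MSE": round(s["mse"], 3),
            }
        )
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"\nwrote {RESULTS / 'report.json'} and {RESULTS / 'observed_vs_calculated.csv'}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=3)
    parser.add_argument("--runs", type=int, default=20)
    parser.add_argument("--generations", type=int, default=100)
    args = parser.parse_args()
    main(args.seed, args.runs, args.generations)
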