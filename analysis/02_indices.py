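"""Compute Shannon, Simpson, and Margalef indices per station-month sample.

Reads results/data/counts.csv (from 01_simulate.py), writes
results/indices.csv, and prints the per-index summary.

Run: python analysis/02_indices.py
"""

from pathlib import Path

from riverbio import io as rio
from riverbio.diversity import compute_indices_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    vectors = rio.read_counts_csv(RESULTS / "data" / "counts.csv")
    table = compute_indices_table(vectors)
    rio.write_indices_csv(table, RESULTS / "indices.csv")
    print(f"wrote {len(table)} records to {RESULTS / 'indices.csv'}")
    print(table[["shannon", "simpson", "margalef"]].describe().loc[["mean", "std", "min", "max"]].round(3))


if __name__ == "__main__":
    main()
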