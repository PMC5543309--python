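#!/usr/bin/env python
"""Cross-method confidence grid over traits and focal nodes.

Combines the parsimony, ML and rjMCMC answers from the reconstruction
table into 0-3 star scores per trait-node cell and writes the grid
(traits as columns, focal nodes as rows).
"""

import argparse
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from mkanc.confidence import ConfidenceCell, summarize  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=str, default="results/synthetic")
    ap.add_argument("--series", type=str, default="synthetic")
    args = ap.parse_args()
    d = pathlib.Path(args.data_dir)

    table = pd.read_csv(d / "reconstructions.csv")
    cells = []
    for _, row in table.iterrows():
        mp_set = frozenset(int(s) for s in str(row["mp_states"]).split("|"))
        cells.append(ConfidenceCell(
            trait=row["character"], node=row["node"], mp_set=mp_set,
            ml_best=(int(row["ml_state"]),), rj_modal=int(row["rj_state"]),
            rj_mean=float(row["rj_mean"]),
            rj_ci_lower=float(row["rj_ci_lower"]), series=args.series))
    grids = summarize(cells)
    grid = grids[args.series]
    grid.to_csv(d / "confidence_grid.csv")
    counts = grid.stack().value_counts().sort_index()
    dist = ", ".join(f"{int(v)} cells at {int(s)}*" for s, v in counts.items())
    print(f"confidence grid {grid.shape[0]} nodes x {grid.shape[1]} traits: "
          f"{dist} -> {d/'confidence_grid.csv'}")


if __name__ == "__main__":
    main()
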