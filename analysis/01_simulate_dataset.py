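#!/usr/bin/env python
"""Generate the desk-scale synthetic study dataset.

Builds a Yule chronogram, a mixed-arity character matrix (binary, 3-state
unordered, ordered count-derived 4-state) with ~27% missing/inapplicable
cells, and a pseudo-posterior sample of trees with jittered node times and
a few NNI rearrangements — a structural replica of a large floral-trait
study (792 species x 27 characters) at a size every later step can carry
in seconds.  Outputs go to results/synthetic/.
"""

import argparse
import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from mkanc.simulate import study_shaped_dataset  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-species", type=int, default=120)
    ap.add_argument("--n-chars", type=int, default=12)
    ap.add_argument("--n-trees", type=int, default=50)
    ap.add_argument("--out-dir", type=str, default="results/synthetic")
    args = ap.parse_args()

    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rec = study_shaped_dataset(n_species=args.n_species, n_chars=args.n_chars,
                               missing_rate=0.27, inapplicable_share=0.3,
                               n_trees=args.n_trees, seed=args.seed)
    base = rec.trees[0]
    (out / "tree.nwk").write_text(base.newick() + "\n")
    (out / "trees.nwk").write_text(
        "".join(t.newick() + "\n" for t in rec.trees))
    rec.matrix.to_csv(out / "traits.csv")
    (out / "simulation.json").write_text(rec.sidecar())
    (out / "ordered_characters.json").write_text(json.dumps(
        sorted(rec.matrix.ordered)))
    # true node states at the root of the base tree, for later comparison
    root = base.index().root
    truth = {ch: int(states[root]) for ch, states in rec.node_states.items()}
    (out / "true_root_states.json").write_text(json.dumps(truth, indent=1))

    # focal clades: the two children of the root plus the root itself
    idx = base.index()
    kids = idx.children_flat[idx.children_ptr[idx.root]:idx.children_ptr[idx.root + 1]]
    tipsets = {}
    counts = idx._tip_counts()
    for n, c in enumerate(kids):
        members = [lb for lb, tid in idx.tip_id.items()
                   if _in_subtree(idx, tid, int(c))]
        if len(members) >= 2:
            tipsets[f"clade{n + 1}"] = sorted(members)
    (out / "focal_clades.json").write_text(json.dumps(tipsets, indent=1))

    frac = rec.matrix.missing_fraction()
    print(f"wrote {args.n_species} species x {args.n_chars} characters "
          f"({frac:.1%} missing incl. inapplicable), "
          f"{args.n_trees} pseudo-posterior trees, "
          f"{len(tipsets)} focal clades -> {out}/")


def _in_subtree(idx, tip, node):
    v = tip
    while v >= 0:
        if v == node:
            return True
        v = idx.parent[v]
    return False


if __name__ == "__main__":
    main()
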