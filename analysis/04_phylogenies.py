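#!/usr/bin/env python
"""Camin-Sokal clone phylogenies and parallel-origin accounting.

Builds, per vessel, the binary character matrix of the 96 sampled clones and
its irreversible-parsimony tree rooted on the all-zero ancestor; exports
annotated Newick files and tabulates homoplasy: alleles gained on more than
one branch (within-vessel parallel origins) and alleles appearing in clone
trees of different vessels (between-vessel parallelism).
"""

from pathlib import Path

import pandas as pd

from chemoevo.catalog import load_clone_table
from chemoevo.phylo import (
    build_character_matrix,
    camin_sokal_tree,
    count_independent_origins,
    cross_vessel_allele_sharing,
    export_newick,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    clones = load_clone_table(BASE / "inputs" / "clones.tsv")
    out = BASE / "trees"
    out.mkdir(parents=True, exist_ok=True)
    trees, rows = [], []
    for vessel in sorted({c.vessel for c in clones}):
        sub = [c for c in clones if c.vessel == vessel]
        matrix = build_character_matrix(sub)
        tree = camin_sokal_tree(matrix)
        trees.append(tree)
        (out / f"clones_v{vessel}.nwk").write_text(export_newick(tree, annotate=True) + "\n")
        homoplasy = {
            m: count_independent_origins(tree, m)
            for m in matrix.characters
        }
        multi = {m: k for m, k in homoplasy.items() if k >= 2}
        rows += [
            {"vessel": vessel, "mutation": m.token(), "origins": k}
            for m, k in sorted(multi.items())
        ]
        print(
            f"vessel {vessel}: {len(sub)} clones, {len(matrix.characters)} characters, "
            f"tree length {tree.length} "
            f"({tree.length - len(matrix.characters)} extra gains from homoplasy); "
            f"{len(multi)} alleles arose more than once within the vessel"
        )
    pd.DataFrame(rows).to_csv(out / "within_vessel_parallel_origins.tsv", sep="\t", index=False)
    sharing = cross_vessel_allele_sharing(trees)
    shared = {m: v for m, v in sharing.items() if len(v) >= 2}
    print(f"{len(shared)} alleles appear in clone trees of more than one vessel")
    pd.DataFrame(
        [{"mutation": m.token(), "vessels": ",".join(v)} for m, v in sorted(shared.items())]
    ).to_csv(out / "between_vessel_shared_alleles.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
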