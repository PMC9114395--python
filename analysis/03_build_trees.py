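"""Build the crypt phylogeny and place every somatic mutation on it.

Codes genotypes from VAFs (1 / 0 / ?), searches for the maximum-
parsimony tree with bootstrap supports, then assigns substitutions to
branches by maximum likelihood and indels against the same (SBS-built)
tree.  Writes the annotated Newick tree and per-variant placements,
and reports topology and placement recovery against the truth.
"""

from pathlib import Path

import pandas as pd

from cryptphylo import phylo
from cryptphylo.matrix import CountMatrix
from cryptphylo.trees import rf_distance
from cryptphylo.simdata import SimConfig, simulate_cohort

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix = CountMatrix.read(SIM, prefix="normal")
    status = pd.read_csv(OUT / "filter_status.tsv", sep="\t")
    somatic = (status.status == "somatic").to_numpy()
    is_sbs = (matrix.variants.kind == "SBS").to_numpy()

    sbs = matrix.subset_variants(somatic & is_sbs)
    genotypes = phylo.code_genotypes(sbs)
    tree, score, n_co = phylo.search_mp_tree(genotypes, mode="heuristic",
                                             seed=7)
    support = phylo.bootstrap_support(genotypes, tree, n=1000, seed=7)
    print(f"MP tree: parsimony score {score}, {n_co} co-optimal, "
          f"min bootstrap support {min(support.values()):.0f}%")

    a_sbs = phylo.assign_variants_ml(tree, sbs)
    indels = matrix.subset_variants(somatic & ~is_sbs)
    a_id = phylo.assign_indels_to_sbs_tree(tree, indels)
    tree.length[:] = 0
    for b, n in a_sbs.groupby("branch").size().items():
        if b >= 0:
            tree.length[b] = n            # branch length = SBS count

    (OUT / "tree.nwk").write_text(tree.newick(supports=True))
    a_sbs.to_csv(OUT / "assignments_sbs.tsv", sep="\t", index=False)
    a_id.to_csv(OUT / "assignments_indel.tsv", sep="\t", index=False)

    # recovery against the generator's truth
    _, variants, truth = simulate_cohort(SimConfig(seed=1))
    print("Robinson-Foulds distance to the true tree:",
          rf_distance(tree, truth.tree))


if __name__ == "__main__":
    main()
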