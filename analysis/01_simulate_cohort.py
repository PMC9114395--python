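"""Simulate the study cohorts and write them to disk.

Generates (a) the default normal-epithelium patient (8 clonal crypts at
~30X with germline SNPs and shared low-VAF artifacts) and (b) a
tumour-bearing patient (4 normal crypts plus a 6-crypt tumour clade on
a ~50,000-SBS trunk), and writes variant tables, count matrices, the
true trees (Newick) and the full ground truth (JSON) under
results/sim/.  Every downstream analysis step re-derives what it needs
from these seeds through the library, so the whole analysis is
reproducible from this script's constants.
"""

from pathlib import Path

from cryptphylo import simdata

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED_NORMAL = 1
SEED_TUMOUR = 22

normal_config = simdata.SimConfig(seed=SEED_NORMAL)
tumour_config = simdata.SimConfig(
    seed=SEED_TUMOUR, n_crypts=4, patient="PT02",
    tumour_clade=simdata.TumourCladeConfig(n_crypts=6,
                                           trunk_mutations=50_000))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for label, cfg in (("normal", normal_config), ("tumour", tumour_config)):
        matrix, variants, truth = simdata.simulate_cohort(cfg)
        matrix.write(OUT, prefix=label)
        variants.to_csv(OUT / f"{label}.truth_variants.tsv", sep="\t",
                        index=False)
        (OUT / f"{label}.tree.nwk").write_text(truth.tree.newick())
        truth.to_json(OUT / f"{label}.truth.json")
        n_som = (variants.vclass == "somatic").sum()
        print(f"{label}: {matrix.n_variants} sites x {matrix.n_samples} crypts "
              f"({n_som} somatic, {(variants.vclass == 'germline').sum()} "
              f"germline, {(variants.vclass == 'artifact').sum()} artifact)")


if __name__ == "__main__":
    main()
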