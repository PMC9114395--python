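"""Mutation burdens, rates, cohort comparison, tumour fold, drivers.

Derives per-crypt burdens from the branch placements, compares the
simulated carrier cohort against a matched wild-type cohort with the
mixed-model likelihood-ratio test, measures the tumour/normal burden
fold on the tumour-bearing patient, and summarises driver calls for a
cohort annotated at the printed-count scale.
"""

import warnings
from pathlib import Path

import pandas as pd

from cryptphylo import burden, phylo, simdata
from cryptphylo.matrix import CountMatrix
from cryptphylo.simdata import SimConfig, simulate_cohort

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    warnings.filterwarnings("ignore")
    # per-crypt burdens of the normal patient
    _, variants, truth = simulate_cohort(SimConfig(seed=1))
    matrix = CountMatrix.read(SIM, prefix="normal")
    a_sbs = pd.read_csv(OUT / "assignments_sbs.tsv", sep="\t")
    a_id = pd.read_csv(OUT / "assignments_indel.tsv", sep="\t")
    tab = burden.burden_table(a_sbs, a_id, truth.tree, matrix.samples)
    tab.to_csv(OUT / "burden_table.tsv", sep="\t", index=False)
    med = burden.tissue_median_rates(tab)
    print("median SBS rate per tissue (survey crypts):",
          med.round(2).to_dict())

    # mixed-model cohort comparison (carrier vs wild type, equal rates)
    cohort = simdata.simulate_burden_cohort(seed=1)
    stat, p, _ = burden.lmm_lrt(cohort)
    print(f"LRT for a cohort effect on SBS burden: stat={stat:.3f}, p={p:.3f}")

    # tumour vs normal burden fold
    mat_t, var_t, truth_t = simulate_cohort(
        SimConfig(seed=22, n_crypts=4, patient="PT02",
                  tumour_clade=simdata.TumourCladeConfig(
                      n_crypts=6, trunk_mutations=50_000)))
    som = (var_t.vclass == "somatic").to_numpy()
    is_sbs = (var_t.kind == "SBS").to_numpy()
    at = phylo.assign_variants_ml(truth_t.tree,
                                  mat_t.subset_variants(som & is_sbs))
    tab_t = burden.burden_table(at, None, truth_t.tree, mat_t.samples)
    fold = burden.fold_difference(tab_t)
    print(f"tumour/normal SBS burden fold: {fold['fold']:.1f} "
          f"(medians {fold['median_a']:.0f} vs {fold['median_b']:.0f})")

    # driver summary at the printed cohort scale: 23 crypts with one
    # truncating-TSG frameshift, 5 crypts with two known missense drivers
    rows, tsg, known = [], set(), set()
    for i in range(23):
        tsg.add(f"G{i}")
        rows.append({"id": f"a{i}", "sample": f"crypt{i:03d}", "gene": f"G{i}",
                     "change": "X1fs", "consequence": "frameshift",
                     "ref": "T", "alt": "-", "lflank": "A" * 40,
                     "rflank": "T" * 40})
    for i in range(5):
        for j in range(2):
            known.add((f"H{i}_{j}", "R10H"))
            rows.append({"id": f"b{i}{j}", "sample": f"crypt{100 + i:03d}",
                         "gene": f"H{i}_{j}", "change": "R10H",
                         "consequence": "missense", "ref": "C", "alt": "T",
                         "lflank": "A" * 40, "rflank": "G" * 40})
    calls = burden.flag_drivers(pd.DataFrame(rows), known, tsg, set())
    summary = burden.driver_summary(calls, 132)
    print(f"drivers: {summary['crypts_with_driver']}/{summary['n_crypts']} "
          f"crypts ({summary['pct_with_driver']}%); one driver "
          f"{summary['pct_with_one']}%, two {summary['pct_with_two']}%")
    pd.Series(summary).to_json(OUT / "driver_summary.json")


if __name__ == "__main__":
    main()
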