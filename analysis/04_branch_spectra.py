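"""Per-branch SBS96 mutation spectra with inclusion and cap rules.

Treating each tree branch as a sample, builds the branch x channel
count matrix used for signature extraction: branches with fewer than
100 assigned mutations are excluded and branches are capped at 2,500
mutations by seeded subsampling.
"""

from pathlib import Path

import pandas as pd

from cryptphylo import spectra

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    variants = pd.read_csv(SIM / "normal.truth_variants.tsv", sep="\t")
    assignments = pd.read_csv(OUT / "assignments_sbs.tsv", sep="\t")
    assignments = assignments[assignments.branch >= 0]

    patient_of_branch = {b: "PT01" for b in assignments.branch.unique()}
    mat = spectra.branch_spectra(assignments, variants, kind="SBS",
                                 min_mutations=100, cap=2500, seed=11,
                                 patient_of_branch=patient_of_branch)
    mat.to_csv(OUT / "branch_spectra_sbs.tsv", sep="\t")
    counts = mat.drop(columns="patient").sum(axis=1)
    print(f"{len(mat)} branches retained (>= 100 mutations); "
          f"branch sizes {counts.min():.0f}-{counts.max():.0f} after the "
          f"2,500-mutation cap")


if __name__ == "__main__":
    main()
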