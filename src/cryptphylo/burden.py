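"""Per-crypt mutation burdens, rates, cohort comparisons, and drivers.

A crypt's burden is the number of somatic mutations assigned to the
branches on its root-to-leaf path; dividing by age at sampling gives a
per-year rate.  Cohort comparisons use a linear mixed-effect model
(burden ~ age with a per-patient random intercept, ML fit) and a
likelihood-ratio test for a cohort fixed effect.  Driver flagging is a
rule engine over pre-computed consequence annotations.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import chi2

from .trees import Tree

__all__ = [
    "burden_table", "tissue_median_rates", "lmm_lrt", "fold_difference",
    "flag_drivers", "driver_summary", "round_pct",
]

TRUNCATING = {"nonsense", "frameshift", "splice"}


def burden_table(sbs_assignments: pd.DataFrame,
                 id_assignments: pd.DataFrame | None,
                 tree: Tree, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-crypt burdens: sum of assigned variants over the crypt's
    root-to-leaf path, with per-year rates (burden / age)."""
    if "age" not in samples.columns or samples["age"].isna().any():
        raise ValueError("sample table must carry an age per crypt")

    def path_nodes(leaf: int) -> list[int]:
        out = []
        node = leaf
        while tree.parent[node] >= 0:
            out.append(node)
            node = tree.parent[node]
        return out

    def counts_per_branch(assign: pd.DataFrame) -> dict[int, int]:
        placed = assign[assign["branch"] >= 0]
        return placed.groupby("branch").size().to_dict()

    sbs_counts = counts_per_branch(sbs_assignments)
    id_counts = counts_per_branch(id_assignments) if id_assignments is not None else {}
    rows = []
    for leaf, name in enumerate(tree.leaf_names):
        meta = samples[samples["id"] == name].iloc[0]
        path = path_nodes(leaf)
        sbs = sum(sbs_counts.get(b, 0) for b in path)
        idb = sum(id_counts.get(b, 0) for b in path)
        rows.append({
            "sample": name, "patient": meta["patient"],
            "tissue": meta["tissue"], "crypt_type": meta["crypt_type"],
            "cohort": meta.get("cohort", "LS"), "age": float(meta["age"]),
            "sbs_burden": sbs, "id_burden": idb,
            "sbs_rate": sbs / float(meta["age"]),
            "id_rate": idb / float(meta["age"]),
        })
    return pd.DataFrame(rows)


def tissue_median_rates(table: pd.DataFrame, group_by: str = "tissue",
                        crypt_types: tuple = ("survey",),
                        rate: str = "sbs_rate") -> pd.Series:
    """Median per-crypt rate per group, survey-type crypts by default."""
    sub = table[table["crypt_type"].isin(crypt_types)]
    med = sub.groupby(group_by)[rate].median()
    return med


def lmm_lrt(table: pd.DataFrame, response: str = "sbs_burden"
            ) -> tuple[float, float, pd.Series]:
    """Does cohort membership improve a mixed model of burden on age?

    Null: response ~ age with a per-patient random intercept.
    Alternative: adds a cohort fixed effect.  Both fit by maximum
    likelihood; the statistic is 2(l1 - l0) against chi-square(1).
    """
    cohorts = table["cohort"].unique()
    if len(cohorts) != 2:
        raise ValueError("need exactly two cohorts")
    data = table.copy()
    data["y"] = data[response].astype(float)
    null = smf.mixedlm("y ~ age", data, groups=data["patient"]).fit(reml=False)
    alt = smf.mixedlm("y ~ age + C(cohort)", data,
                      groups=data["patient"]).fit(reml=False)
    stat = max(0.0, 2.0 * (alt.llf - null.llf))
    p = float(chi2.sf(stat, df=1))
    return stat, p, alt.params


def fold_difference(table: pd.DataFrame,
                    group_a: str = "tumour", group_b: str = "survey",
                    burden: str = "sbs_burden") -> dict:
    """Ratio of median burdens between two crypt types (tumour over
    normal in the paired-tissue comparison)."""
    a = table.loc[table["crypt_type"] == group_a, burden]
    b = table.loc[table["crypt_type"] == group_b, burden]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    med_b = float(b.median())
    if med_b == 0:
        raise ZeroDivisionError("undefined fold: zero median in the baseline group")
    return {"fold": float(a.median()) / med_b,
            "median_a": float(a.median()), "median_b": med_b,
            "n_a": int(len(a)), "n_b": int(len(b))}


def flag_drivers(variants: pd.DataFrame, driver_list: set[str] | list,
                 tsg_list: set[str] | list, hotspot_list: set | list
                 ) -> pd.DataFrame:
    """Rule engine over annotated variants.

    Requires columns: id, sample, gene, consequence, change; and for
    frameshift microsatellite flagging either a boolean
    ``microsatellite`` column or ref/alt/lflank/rflank sequences.
    Rules fire in priority order: known driver mutation; truncating
    variant in a tumour suppressor; missense at a listed hotspot.
    Synonymous and other consequences never flag.
    """
    required = {"id", "sample", "gene", "consequence", "change"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"missing annotation columns: {sorted(missing)}")
    driver_list = set(driver_list)
    tsg_list = set(tsg_list)
    hotspot_list = set(hotspot_list)
    rows = []
    for r in variants.itertuples():
        if r.consequence in ("synonymous", "other"):
            continue
        rule = None
        if (r.gene, r.change) in driver_list or f"{r.gene}:{r.change}" in driver_list:
            rule = "known"
        elif r.consequence in TRUNCATING and r.gene in tsg_list:
            rule = "truncating-TSG"
        elif r.consequence == "missense" and (
                (r.gene, r.change) in hotspot_list
                or f"{r.gene}:{r.change}" in hotspot_list):
            rule = "hotspot-missense"
        if rule is None:
            continue
        ms_flag = False
        if r.consequence == "frameshift":
            if hasattr(r, "microsatellite") and not pd.isna(r.microsatellite):
                ms_flag = bool(r.microsatellite)
            elif hasattr(r, "lflank"):
                from .spectra import microsatellite_frameshift_flag
                ms_flag = microsatellite_frameshift_flag(
                    r.ref, r.alt, r.lflank, r.rflank)
        rows.append({"id": r.id, "sample": r.sample, "gene": r.gene,
                     "change": r.change, "consequence": r.consequence,
                     "rule_fired": rule, "microsatellite_flag": ms_flag})
    return pd.DataFrame(rows, columns=["id", "sample", "gene", "change",
                                       "consequence", "rule_fired",
                                       "microsatellite_flag"])


def round_pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (printed style)."""
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def driver_summary(calls: pd.DataFrame, n_crypts_total: int) -> dict:
    """Cohort driver-burden summary: crypts with at least one, exactly
    one, exactly two driver mutations (counts and percentages of the
    whole cohort), unique events, unique genes."""
    if n_crypts_total <= 0:
        raise ValueError("n_crypts_total must be positive")
    if len(calls) == 0:
        per_crypt = pd.Series(dtype=int)
    else:
        per_crypt = calls.groupby("sample").size()
    n_any = int((per_crypt >= 1).sum())
    n_one = int((per_crypt == 1).sum())
    n_two = int((per_crypt == 2).sum())
    uniq_events = 0 if len(calls) == 0 else len(
        calls.drop_duplicates(subset=["gene", "change"]))
    uniq_genes = 0 if len(calls) == 0 else calls["gene"].nunique()
    return {
        "n_crypts": n_crypts_total,
        "crypts_with_driver": n_any,
        "crypts_with_one": n_one,
        "crypts_with_two": n_two,
        "pct_with_driver": round_pct(n_any, n_crypts_total),
        "pct_with_one": round_pct(n_one, n_crypts_total),
        "pct_with_two": round_pct(n_two, n_crypts_total),
        "unique_events": int(uniq_events),
        "unique_genes": int(uniq_genes),
    }
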