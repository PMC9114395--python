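"""Burdens, rates, mixed-model comparison, drivers."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cryptphylo import burden, simdata
from cryptphylo.trees import Tree
from channel_cases import L, R


def _tree4():
    # ((s0,s1),(s2,s3)); node4 = cherry(s0,s1)
    return Tree(np.asarray([4, 4, 5, 5, 6, 6, -1]), ["s0", "s1", "s2", "s3"])


def _samples(names, age=50.0):
    return pd.DataFrame({"id": names, "patient": "P", "tissue": "colon",
                         "crypt_type": "survey", "age": age})


def _assign(branch_counts):
    rows = []
    i = 0
    for b, n in branch_counts.items():
        for _ in range(n):
            rows.append({"variant": f"v{i}", "branch": b})
            i += 1
    return pd.DataFrame(rows, columns=["variant", "branch"])


def test_burden_is_a_path_sum_and_rate_a_division():
    tree = _tree4()
    sbs = _assign({4: 10, 0: 5, 2: 7})   # trunk of (s0,s1): 10; private s0: 5
    tab = burden.burden_table(sbs, None, tree, _samples(tree.leaf_names, age=10.0))
    t = tab.set_index("sample")
    assert t.loc["s0", "sbs_burden"] == 15
    assert t.loc["s1", "sbs_burden"] == 10
    assert t.loc["s2", "sbs_burden"] == 7
    assert t.loc["s3", "sbs_burden"] == 0
    assert t.loc["s0", "sbs_rate"] == pytest.approx(1.5)
    # the worked division: burden 550 over 10 years is 55 per year
    tab2 = burden.burden_table(_assign({0: 550}), None, tree,
                               _samples(tree.leaf_names, age=10.0))
    assert tab2.set_index("sample").loc["s0", "sbs_rate"] == pytest.approx(55.0)


def test_burden_requires_age():
    tree = _tree4()
    samples = _samples(tree.leaf_names).drop(columns=["age"])
    with pytest.raises(ValueError):
        burden.burden_table(_assign({0: 1}), None, tree, samples)


def test_tissue_medians_and_invariances():
    tab = pd.DataFrame({
        "sample": list("abc"), "tissue": ["colon"] * 3,
        "crypt_type": ["survey"] * 3, "sbs_rate": [50.0, 55.0, 60.0]})
    med = burden.tissue_median_rates(tab)
    assert med["colon"] == 55.0
    # ordering invariance
    med2 = burden.tissue_median_rates(tab.iloc[::-1])
    assert med2["colon"] == 55.0
    single = burden.tissue_median_rates(tab.iloc[:1])
    assert single["colon"] == 50.0
    # non-survey crypts excluded by default
    tab.loc[2, "crypt_type"] = "tumour"
    assert burden.tissue_median_rates(tab)["colon"] == 52.5


def test_rate_is_age_equivariant():
    rng = np.random.default_rng(0)
    burdens = rng.poisson(2000, 6)
    for age in (20.0, 40.0):
        rates = burdens / age
        assert np.allclose(rates * age, burdens)
    assert np.allclose(burdens / 40.0, (burdens / 20.0) / 2)


def test_lmm_lrt_null_case_and_bounds():
    warnings.filterwarnings("ignore")
    tab = simdata.simulate_burden_cohort(n_patients_a=8, n_patients_b=8, seed=3)
    stat, p, params = burden.lmm_lrt(tab)
    assert stat >= 0.0
    assert 0.0 <= p <= 1.0
    # relabeled halves of one cohort: no real effect, p not extreme
    assert p > 0.001


def test_lmm_lrt_detects_planted_difference():
    warnings.filterwarnings("ignore")
    tab = simdata.simulate_burden_cohort(sbs_rate_a=165.0, sbs_rate_b=55.0,
                                         seed=4)
    stat, p, params = burden.lmm_lrt(tab)
    assert p < 0.01


def test_lmm_requires_two_cohorts():
    tab = simdata.simulate_burden_cohort(seed=0)
    with pytest.raises(ValueError):
        burden.lmm_lrt(tab[tab.cohort == "LS"])


def test_fold_difference_examples():
    tab = pd.DataFrame({
        "crypt_type": ["tumour"] * 3 + ["survey"] * 3,
        "sbs_burden": [50_000, 50_000, 50_000, 500, 500, 500]})
    out = burden.fold_difference(tab)
    assert out["fold"] == pytest.approx(100.0)
    same = pd.DataFrame({"crypt_type": ["tumour", "survey"],
                         "sbs_burden": [500, 500]})
    assert burden.fold_difference(same)["fold"] == pytest.approx(1.0)
    zero = pd.DataFrame({"crypt_type": ["tumour", "survey"],
                         "sbs_burden": [500, 0]})
    with pytest.raises(ZeroDivisionError):
        burden.fold_difference(zero)


def _annot(rows):
    base = {"id": "v", "sample": "c1", "gene": "GENE", "change": "X1Y",
            "consequence": "missense", "ref": "-", "alt": "-",
            "lflank": L(), "rflank": R()}
    return pd.DataFrame([{**base, **r, "id": f"v{i}"} for i, r in enumerate(rows)])


def test_driver_rules_priority_and_complement():
    tsg = {"APC", "NF2"}
    hotspots = {("KRAS", "G12V")}
    known = {("TP53", "R175H")}
    calls = burden.flag_drivers(_annot([
        {"gene": "TP53", "change": "R175H", "consequence": "missense"},
        {"gene": "APC", "change": "Q8X", "consequence": "nonsense"},
        {"gene": "KRAS", "change": "G12V", "consequence": "missense"},
        {"gene": "BRAF", "change": "V600E", "consequence": "missense"},
        {"gene": "APC", "change": "S100S", "consequence": "synonymous"},
    ]), known, tsg, hotspots)
    assert list(calls["rule_fired"]) == ["known", "truncating-TSG",
                                         "hotspot-missense"]
    assert "BRAF" not in set(calls["gene"])


def test_frameshift_in_long_repeat_gets_microsatellite_flag():
    tsg = {"NF2"}
    calls = burden.flag_drivers(_annot([
        {"gene": "NF2", "change": "R172fs", "consequence": "frameshift",
         "ref": "T", "alt": "-", "rflank": R("TTTTT")},
        {"gene": "NF2", "change": "K79fs", "consequence": "frameshift",
         "ref": "T", "alt": "-", "rflank": R("TT")},
    ]), set(), tsg, set())
    assert list(calls["microsatellite_flag"]) == [True, False]


def test_driver_rules_need_annotations():
    with pytest.raises(ValueError):
        burden.flag_drivers(pd.DataFrame({"id": ["v0"]}), set(), set(), set())


def test_driver_summary_matches_printed_cohort_percentages():
    """132 crypts, 28 with drivers (23 one, 5 two) -> 21.2/17.4/3.8%."""
    rows = []
    for i in range(23):
        rows.append({"id": f"a{i}", "sample": f"c{i}", "gene": f"G{i}",
                     "change": "X", "consequence": "missense",
                     "rule_fired": "known", "microsatellite_flag": False})
    for i in range(5):
        for j in range(2):
            rows.append({"id": f"b{i}{j}", "sample": f"d{i}",
                         "gene": f"H{i}{j}", "change": "Y",
                         "consequence": "nonsense",
                         "rule_fired": "truncating-TSG",
                         "microsatellite_flag": False})
    calls = pd.DataFrame(rows)
    out = burden.driver_summary(calls, 132)
    assert out["pct_with_driver"] == 21.2
    assert out["pct_with_one"] == 17.4
    assert out["pct_with_two"] == 3.8
    assert out["crypts_with_driver"] == out["crypts_with_one"] + out["crypts_with_two"]


def test_driver_summary_empty_and_invalid():
    empty = burden.driver_summary(pd.DataFrame(
        columns=["id", "sample", "gene", "change"]), 10)
    assert empty["pct_with_driver"] == 0.0
    with pytest.raises(ValueError):
        burden.driver_summary(pd.DataFrame(columns=["sample"]), 0)


def test_round_pct_half_up():
    assert burden.round_pct(1, 16) == 6.3     # 6.25 rounds up
    assert burden.round_pct(28, 132) == 21.2
    assert burden.round_pct(23, 132) == 17.4
    assert burden.round_pct(5, 132) == 3.8
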