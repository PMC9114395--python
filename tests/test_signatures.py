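"""EM deconvolution, residual signatures, NMF and HDP extraction."""

import numpy as np
import pandas as pd
import pytest

from cryptphylo import signatures, simdata
from cryptphylo.catalogues import SignatureCatalogue
from cryptphylo.signatures import cosine


def _disjoint_catalogue(k=4, block=24):
    """Signatures with fully disjoint channel supports (identifiable)."""
    table = {}
    for i in range(k):
        v = np.zeros(96)
        v[i * block:(i + 1) * block] = 1.0 / block
        table[f"S{i + 1}"] = v
    return SignatureCatalogue(pd.DataFrame(table, index=[f"ch{i}" for i in range(96)]))


def test_cosine_closed_forms():
    assert cosine([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert cosine([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)
    assert cosine([1, 1, 0], [1, 0, 0]) == pytest.approx(1 / np.sqrt(2))
    with pytest.raises(ValueError):
        cosine([0, 0], [1, 0])


def test_em_recovers_vertex_and_exact_mixture():
    cat = _disjoint_catalogue()
    w = signatures.em_deconvolute(cat.vector("S2"), cat)
    assert w[1] == pytest.approx(1.0, abs=1e-6)
    target = 0.6 * cat.vector("S1") + 0.4 * cat.vector("S2")
    w = signatures.em_deconvolute(target, cat)
    assert np.allclose(w, [0.6, 0.4, 0, 0], atol=1e-6)


def test_em_objective_is_monotone():
    rng = np.random.default_rng(0)
    cat = _disjoint_catalogue()
    x = rng.dirichlet(np.ones(96))
    R = cat.matrix
    prev = -np.inf
    for iters in range(1, 40):
        w = signatures.em_deconvolute(x, cat, tol=0.0, max_iter=iters)
        obj = float(x @ np.log(np.maximum(R @ w, 1e-300)))
        assert obj >= prev - 1e-12
        prev = obj


def test_em_rejects_channel_mismatch():
    cat = _disjoint_catalogue()
    with pytest.raises(ValueError):
        signatures.em_deconvolute(np.ones(83) / 83, cat)


def test_reconstitute_exact_mixture_and_strict_threshold():
    cat = _disjoint_catalogue()
    comp = 0.6 * cat.vector("S1") + 0.4 * cat.vector("S2")
    w = signatures.em_deconvolute(comp, cat)
    cos, accepted, selected = signatures.reconstitute(w, cat, comp)
    assert cos == pytest.approx(1.0, abs=1e-9) and accepted
    assert set(selected) == {"S1", "S2"}
    # a contribution exactly at the threshold is excluded (strict >)
    w_manual = np.array([0.15, 0.85, 0.0, 0.0])
    _, _, selected = signatures.reconstitute(w_manual, cat, comp,
                                             contribution_threshold=0.15)
    assert selected == ["S2"]
    _, accepted, selected = signatures.reconstitute(
        np.array([0.1, 0.1, 0.1, 0.1]), cat, comp, contribution_threshold=0.15)
    assert not accepted and selected == []


def test_residual_recovers_planted_novel_signature():
    cat = _disjoint_catalogue()
    # a one-hot channel outside the catalogue subset's support
    novel = np.zeros(96)
    novel[90] = 1.0
    cat3 = cat.subset(["S1", "S2", "S3"])
    comp = 0.5 * cat3.vector("S1") + 0.5 * novel
    w = signatures.em_deconvolute(comp, cat3)
    cos, accepted, selected = signatures.reconstitute(w, cat3, comp)
    assert not accepted
    res = signatures.residual_signature(comp, cat3, selected, w)
    assert res.sum() == pytest.approx(1.0)
    assert (res >= 0).all()
    assert cosine(res, novel) >= 0.99


def test_residual_degenerate_when_component_in_span():
    cat = _disjoint_catalogue()
    comp = cat.vector("S1")
    with pytest.raises(ValueError):
        signatures.residual_signature(comp, cat, ["S1"], np.array([1.0, 0, 0, 0]))


def test_deconvolution_is_idempotent_on_reconstitution():
    cat = _disjoint_catalogue()
    comp = 0.55 * cat.vector("S1") + 0.45 * cat.vector("S3")
    w = signatures.em_deconvolute(comp, cat)
    _, _, selected = signatures.reconstitute(w, cat, comp)
    keep = np.isin(cat.names, selected)
    recon = cat.matrix[:, keep] @ (w[keep] / w[keep].sum())
    w2 = signatures.em_deconvolute(recon, cat)
    _, _, selected2 = signatures.reconstitute(w2, cat, recon)
    assert selected2 == selected


def test_refit_exposures_recovery_and_conservation():
    rng = np.random.default_rng(1)
    cat = _disjoint_catalogue(k=3, block=32)
    V = cat.matrix.T
    mixes = rng.dirichlet(np.ones(3), size=10)
    counts = np.array([rng.multinomial(1000, m @ V) for m in mixes])
    spec = pd.DataFrame(counts, index=[f"b{i}" for i in range(10)],
                        columns=cat.channels)
    frac, abs_counts = signatures.refit_exposures(spec, cat)
    assert np.allclose(frac.sum(axis=1), 1.0)
    assert np.allclose(abs_counts.sum(axis=1), spec.sum(axis=1))
    assert np.abs(frac.to_numpy() - mixes).mean() < 0.05

    pure = pd.DataFrame([rng.multinomial(1000, V[0])], index=["b"],
                        columns=cat.channels)
    frac, _ = signatures.refit_exposures(pure, cat.subset(["S1", "S2"]))
    assert frac.iloc[0, 0] == pytest.approx(1.0, abs=0.02)


def test_nmf_rank_one_data_chooses_k1():
    profile = np.random.default_rng(2).dirichlet(np.ones(96))
    X = np.outer([200, 500, 900, 1400], profile)
    spec = pd.DataFrame(X, index=list("abcd"),
                        columns=[f"ch{i}" for i in range(96)])
    cs = signatures.nmf_extract(spec, k_range=range(1, 4), restarts=5, seed=0)
    assert cs.diagnostics["chosen_k"] == 1
    assert cosine(cs.components[0], profile) > 0.999


def test_nmf_recovers_three_planted_signatures(sbs_catalogue):
    spec, _, V = simdata.simulate_branch_spectra(
        sbs_catalogue, ["SIG_CLOCK", "SIG_MMR", "SIG_APOBEC"], seed=5)
    cs = signatures.nmf_extract(spec, k_range=range(1, 6), restarts=8, seed=2)
    assert cs.diagnostics["chosen_k"] == 3
    for v in V:
        assert max(cosine(c, v) for c in cs.components) >= 0.95
    assert np.allclose(cs.exposures.sum(axis=1), 1.0)


def test_hdp_single_signature_collapses_to_one_component(sbs_catalogue):
    spec, _, V = simdata.simulate_branch_spectra(
        sbs_catalogue, ["SIG_CLOCK"], n_patients=2, branches_per_patient=5,
        count_range=(1000, 1000), seed=3)
    cs = signatures.hdp_extract(spec, mcmc={"burnin": 1000, "n_samples": 25,
                                            "spacing": 10}, seed=3)
    assert len(cs.components) == 1
    assert cosine(cs.components[0], V[0]) >= 0.99
    assert cs.provenance == "hierarchical-sampler"


def test_hdp_merges_identical_signatures_across_patients(sbs_catalogue):
    # the same process active in two patients must come out as one
    # component under the cosine-merge rule, not one per patient
    spec, _, V = simdata.simulate_branch_spectra(
        sbs_catalogue, ["SIG_MMR"], n_patients=2, branches_per_patient=4,
        count_range=(800, 800), seed=9)
    cs = signatures.hdp_extract(spec, mcmc={"burnin": 800, "n_samples": 20,
                                            "spacing": 10}, seed=4)
    assert len(cs.components) == 1


def test_hdp_deterministic_under_seed(sbs_catalogue):
    spec, _, _ = simdata.simulate_branch_spectra(
        sbs_catalogue, ["SIG_CLOCK", "SIG_APOBEC"], n_patients=2,
        branches_per_patient=3, count_range=(300, 600), seed=6)
    kw = dict(mcmc={"burnin": 300, "n_samples": 10, "spacing": 5}, seed=11)
    a = signatures.hdp_extract(spec, **kw)
    b = signatures.hdp_extract(spec, **kw)
    assert np.array_equal(a.components, b.components)
    pd.testing.assert_frame_equal(a.exposures, b.exposures)


def test_hdp_rejects_empty_spectra():
    spec = pd.DataFrame(np.zeros((2, 96)), columns=[f"ch{i}" for i in range(96)])
    with pytest.raises(ValueError):
        signatures.hdp_extract(spec)


def test_component_vectors_normalized_everywhere(sbs_catalogue):
    spec, _, _ = simdata.simulate_branch_spectra(
        sbs_catalogue, ["SIG_CLOCK", "SIG_MMR"], n_patients=2,
        branches_per_patient=3, count_range=(200, 500), seed=8)
    cs = signatures.nmf_extract(spec, k_range=range(1, 4), restarts=4, seed=1)
    assert np.allclose(cs.components.sum(axis=1), 1.0)
    assert (cs.components >= 0).all()
    assert np.allclose(cs.exposures.sum(axis=1), 1.0)
    assert (cs.exposures.to_numpy() >= 0).all()
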