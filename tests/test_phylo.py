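"""Genotype coding, Fitch parsimony, tree search, ML placement."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cryptphylo import phylo, simdata
from cryptphylo.matrix import CountMatrix
from cryptphylo.phylo import GenotypeMatrix
from cryptphylo.trees import Tree, rf_distance


def _matrix(alt, depth, sample_names=None):
    alt = np.asarray(alt)
    nv, ns = alt.shape
    variants = pd.DataFrame({
        "id": [f"v{i}" for i in range(nv)], "chrom": "1",
        "pos": np.arange(nv) + 1, "ref": "C", "alt_allele": "T",
        "kind": "SBS"})
    names = sample_names or [f"s{i}" for i in range(ns)]
    samples = pd.DataFrame({"id": names, "patient": "P", "tissue": "colon",
                            "crypt_type": "survey", "age": 50.0})
    return CountMatrix(variants, samples, alt, np.asarray(depth))


@pytest.mark.parametrize("alt,depth,code", [
    (12, 30, 1),    # VAF 0.4
    (2, 30, 0),     # VAF 0.067
    (6, 30, -1),    # VAF 0.2 -> ambiguous
    (9, 30, -1),    # VAF 0.3 is not > 0.3
    (3, 30, -1),    # VAF 0.1 is not < 0.1
    (0, 0, -1),     # no depth
])
def test_genotype_coding_thresholds(alt, depth, code):
    m = _matrix([[alt]], [[depth]])
    assert phylo.code_genotypes(m).codes[0, 0] == code


def _tree(parent, names):
    return Tree(np.asarray(parent), names)


# ((s0,s1),(s2,s3)) with root 6
BALANCED4 = ([4, 4, 5, 5, 6, 6, -1], ["s0", "s1", "s2", "s3"])


def _geno(rows, names):
    return GenotypeMatrix(np.asarray(rows), [f"v{i}" for i in range(len(rows))],
                          names)


def test_fitch_single_origin_and_homoplasy():
    tree = _tree(*BALANCED4)
    g_cherry = _geno([[1, 1, 0, 0]], tree.leaf_names)
    assert phylo.fitch_score(tree, g_cherry) == 1
    g_split = _geno([[1, 0, 1, 0]], tree.leaf_names)
    assert phylo.fitch_score(tree, g_split) == 2
    g_missing = _geno([[-1, -1, -1, -1]], tree.leaf_names)
    assert phylo.fitch_score(tree, g_missing) == 0


def test_fitch_root_constrained_to_zero():
    tree = _tree(*BALANCED4)
    g_all_present = _geno([[1, 1, 1, 1]], tree.leaf_names)
    # a uniformly present variant still needs one change from the zygote
    assert phylo.fitch_score(tree, g_all_present) == 1


def _bruteforce_score(tree: Tree, codes: np.ndarray) -> int:
    """Oracle: enumerate every ancestral-state completion and count
    changed edges plus a stem change when the sampled root is not 0
    (the zygote carries no somatic variant), minimised per character."""
    internal = [n for n in range(tree.n_nodes) if n >= tree.n_leaves]
    total = 0
    for char in codes:
        best = None
        for states in itertools.product([0, 1], repeat=len(internal)):
            assign = dict(zip(internal, states))
            leaf_opts = [[c] if c in (0, 1) else [0, 1] for c in char]
            for leaf_states in itertools.product(*leaf_opts):
                full = {**assign, **dict(enumerate(leaf_states))}
                changes = int(full[tree.root] != 0)
                changes += sum(full[n] != full[tree.parent[n]]
                               for n in range(tree.n_nodes)
                               if tree.parent[n] >= 0)
                best = changes if best is None else min(best, changes)
        total += best
    return total


def test_fitch_equals_bruteforce_enumeration():
    rng = np.random.default_rng(7)
    names = [f"s{i}" for i in range(6)]
    codes = rng.choice([0, 1, -1], size=(50, 6), p=[0.5, 0.4, 0.1]).astype(np.int8)
    g = _geno(codes, names)
    trees = itertools.islice(phylo.enumerate_rooted_trees(6, names), 25)
    for tree in trees:
        assert phylo.fitch_score(tree, g) == _bruteforce_score(tree, codes)


def _clade_characters(tree: Tree, copies: int = 1) -> np.ndarray:
    """Conflict-free binary characters marking every branch's clade."""
    masks = tree.leafsets()
    bits = np.uint64(1) << np.arange(tree.n_leaves, dtype=np.uint64)
    rows = []
    for b in tree.branches():
        rows += [((masks[b] & bits) > 0).astype(np.int8)] * copies
    return np.asarray(rows)


def test_exhaustive_search_recovers_true_tree_from_perfect_characters():
    true = simdata.simulate_tree(5, seed=3)
    codes = _clade_characters(true)
    g = _geno(codes, true.leaf_names)
    tree, score, n_co = phylo.search_mp_tree(g, mode="exhaustive")
    assert rf_distance(tree, true) == 0
    # every distinct pattern (one per branch) costs exactly one change
    assert score == len(np.unique(codes, axis=0))
    assert n_co == 1


def test_heuristic_matches_exhaustive_score():
    rng = np.random.default_rng(5)
    for n, seed in [(5, 0), (6, 1), (7, 2)]:
        codes = rng.choice([0, 1, -1], size=(30, n), p=[0.5, 0.4, 0.1]).astype(np.int8)
        g = _geno(codes, [f"s{i}" for i in range(n)])
        _, s_ex, _ = phylo.search_mp_tree(g, mode="exhaustive")
        _, s_h, _ = phylo.search_mp_tree(g, mode="heuristic", seed=seed,
                                         restarts=4)
        assert s_h == s_ex


def test_single_character_produces_ties_with_stable_winner():
    g = _geno([[1, 1, 0, 0]], ["s0", "s1", "s2", "s3"])
    t1, s1, n1 = phylo.search_mp_tree(g, mode="exhaustive")
    assert s1 == 1 and n1 > 1
    t2, _, _ = phylo.search_mp_tree(g, mode="exhaustive")
    assert t1.canonical_newick() == t2.canonical_newick()


def test_score_invariant_to_variant_and_sample_permutation():
    rng = np.random.default_rng(9)
    codes = rng.choice([0, 1, -1], size=(40, 6)).astype(np.int8)
    names = [f"s{i}" for i in range(6)]
    g = _geno(codes, names)
    tree, score, _ = phylo.search_mp_tree(g, mode="exhaustive")
    g_vperm = _geno(codes[rng.permutation(40)], names)
    assert phylo.fitch_score(tree, g_vperm) == phylo.fitch_score(tree, g)
    perm = rng.permutation(6)
    g_sperm = GenotypeMatrix(codes[:, perm], g.variant_ids,
                             [names[i] for i in perm])
    assert phylo.fitch_score(tree, g_sperm) == phylo.fitch_score(tree, g)


def test_search_requires_three_samples():
    with pytest.raises(ValueError):
        phylo.search_mp_tree(_geno([[1, 0]], ["a", "b"]))


def test_bootstrap_perfect_characters_give_full_support():
    true = simdata.simulate_tree(6, seed=4)
    codes = _clade_characters(true, copies=100)
    g = _geno(codes, true.leaf_names)
    tree, _, _ = phylo.search_mp_tree(g, mode="heuristic", seed=0)
    support = phylo.bootstrap_support(g, tree, n=100, seed=1)
    assert support and all(v == 100.0 for v in support.values())


def test_bootstrap_bounds_and_zero_replicates():
    true = simdata.simulate_tree(5, seed=8)
    rng = np.random.default_rng(2)
    codes = rng.choice([0, 1], size=(30, 5)).astype(np.int8)
    g = _geno(codes, true.leaf_names)
    tree, _, _ = phylo.search_mp_tree(g, mode="heuristic", seed=0)
    support = phylo.bootstrap_support(g, tree, n=25, seed=3)
    assert all(0.0 <= v <= 100.0 for v in support.values())
    assert phylo.bootstrap_support(g, tree, n=0, seed=3) == {}


def test_private_variant_assigned_to_terminal_branch():
    tree = _tree(*BALANCED4)
    alt = np.array([[15, 0, 0, 0]])
    depth = np.full((1, 4), 30)
    m = _matrix(alt, depth, sample_names=tree.leaf_names)
    out = phylo.assign_variants_ml(tree, m)
    assert out.branch[0] == 0            # s0's terminal branch
    assert out.posterior[0] > 0.99


def test_ubiquitous_variant_assigned_root_adjacent():
    tree = _tree(*BALANCED4)
    m = _matrix(np.full((1, 4), 15), np.full((1, 4), 30),
                sample_names=tree.leaf_names)
    out = phylo.assign_variants_ml(tree, m)
    assert tree.parent[out.branch[0]] == tree.root


def test_zero_depth_variant_reported_unassigned():
    tree = _tree(*BALANCED4)
    m = _matrix(np.zeros((1, 4), int), np.zeros((1, 4), int),
                sample_names=tree.leaf_names)
    out = phylo.assign_variants_ml(tree, m)
    assert out.branch[0] == -1 and np.isnan(out.posterior[0])


def test_indel_assignment_uses_fixed_tree():
    tree = _tree(*BALANCED4)
    empty = _matrix(np.zeros((0, 4), int), np.zeros((0, 4), int),
                    sample_names=tree.leaf_names)
    assert len(phylo.assign_indels_to_sbs_tree(tree, empty)) == 0
    private = _matrix([[0, 0, 14, 0]], np.full((1, 4), 28),
                      sample_names=tree.leaf_names)
    out = phylo.assign_indels_to_sbs_tree(tree, private)
    assert out.branch[0] == 2


def test_branch_lengths_conserve_assigned_counts(default_cohort):
    _, matrix, variants, truth = default_cohort
    som = (variants.vclass == "somatic").to_numpy()
    sub = matrix.subset_variants(som)
    out = phylo.assign_variants_ml(truth.tree, sub)
    placed = out[out.branch >= 0]
    per_branch = placed.groupby("branch").size()
    assert per_branch.sum() == len(placed)
    # leaf burden equals the sum over its root path (conservation)
    leaf = 0
    path, node = [], leaf
    while truth.tree.parent[node] >= 0:
        path.append(node)
        node = truth.tree.parent[node]
    assert sum(per_branch.get(b, 0) for b in path) \
        == placed["branch"].isin(path).sum()


def test_rf_distance_matches_dendropy():
    dendropy = pytest.importorskip("dendropy")
    for seed in range(6):
        a = simdata.simulate_tree(7, seed=seed)
        b = simdata.simulate_tree(7, seed=seed + 100)
        tns = dendropy.TaxonNamespace()
        da = dendropy.Tree.get(data=a.newick(), schema="newick",
                               taxon_namespace=tns)
        db = dendropy.Tree.get(data=b.newick(), schema="newick",
                               taxon_namespace=tns)
        da.is_rooted = db.is_rooted = True
        da.encode_bipartitions()
        db.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
        assert rf_distance(a, b) == expected
    assert rf_distance(a, a) == 0


def test_conflict_free_cohort_recovers_true_topology(default_cohort):
    _, matrix, variants, truth = default_cohort
    som = ((variants.vclass == "somatic") & (variants.kind == "SBS")).to_numpy()
    g = phylo.code_genotypes(matrix.subset_variants(som))
    tree, _, _ = phylo.search_mp_tree(g, mode="heuristic", seed=0, restarts=3)
    assert rf_distance(tree, truth.tree) == 0
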