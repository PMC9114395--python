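"""Maximum-parsimony crypt phylogenies and ML branch placement.

Genotypes are coded from VAFs (1 present / 0 absent / ? ambiguous or no
depth), trees are rooted at an implicit all-zero zygote outgroup, and
the parsimony score is the Fitch small-parsimony count with "?" treated
as {0,1} and the root constrained to state 0.  Tree search is either
exhaustive enumeration of rooted resolved topologies (small patient
cohorts) or seeded stepwise addition with nearest-neighbour-interchange
and subtree-prune-regraft hill climbing.  Somatic variants are then assigned to branches by
maximising a binomial read-count likelihood: carriers at the clonal VAF
below the branch, the sequencing error rate elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .matrix import CountMatrix
from .trees import Tree, rf_distance

__all__ = [
    "GenotypeMatrix", "code_genotypes", "fitch_score",
    "enumerate_rooted_trees", "search_mp_tree", "bootstrap_support",
    "assign_variants_ml", "assign_indels_to_sbs_tree", "branch_label",
    "rf_distance",
]

MISSING = -1  # "?" code


@dataclass
class GenotypeMatrix:
    """variants x samples codes: 1 present, 0 absent, -1 ambiguous."""
    codes: np.ndarray
    variant_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D")
        if not np.isin(self.codes, [-1, 0, 1]).all():
            raise ValueError("codes must be in {0, 1, -1}")

    @property
    def n_variants(self) -> int:
        return self.codes.shape[0]


def code_genotypes(matrix: CountMatrix, present: float = 0.3,
                   absent: float = 0.1) -> GenotypeMatrix:
    """VAF > ``present`` -> 1; VAF < ``absent`` -> 0; otherwise (or when
    depth is zero) ``?``.  Both inequalities are strict."""
    vaf = matrix.vaf()
    codes = np.full(vaf.shape, MISSING, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        codes[vaf > present] = 1
        codes[vaf < absent] = 0
    codes[matrix.depth == 0] = MISSING
    return GenotypeMatrix(codes, list(matrix.variants["id"]),
                          matrix.sample_ids)


# ---------------------------------------------------------------------------
# Fitch scoring


def _leaf_state_sets(codes: np.ndarray) -> np.ndarray:
    """Bit sets per (sample, variant): 1 = {0}, 2 = {1}, 3 = {0,1}."""
    sets = np.full(codes.T.shape, 3, dtype=np.uint8)
    sets[codes.T == 0] = 1
    sets[codes.T == 1] = 2
    return sets


def _fitch(parent: np.ndarray, order: list[int], leaf_sets: np.ndarray,
           weights: np.ndarray) -> int:
    """Weighted Fitch changes over characters; root forced to state 0."""
    n_nodes = len(parent)
    n_leaves = leaf_sets.shape[0]
    n_chars = leaf_sets.shape[1]
    sets = np.zeros((n_nodes, n_chars), dtype=np.uint8)
    sets[:n_leaves] = leaf_sets
    changes = np.zeros(n_chars, dtype=np.int64)
    for node in order:
        p = parent[node]
        if p < 0:
            continue
        cur = sets[p]
        if not cur.any():
            sets[p] = sets[node]
        else:
            inter = cur & sets[node]
            union = cur | sets[node]
            changes += inter == 0
            sets[p] = np.where(inter == 0, union, inter)
    root = order[-1]
    changes += (sets[root] & 1) == 0
    return int((changes * weights).sum())


def _postorder(parent: np.ndarray) -> list[int]:
    children: list[list[int]] = [[] for _ in parent]
    root = -1
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
        else:
            root = i
    out: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(children[node])
    out.reverse()
    return out


def fitch_score(tree: Tree, genotypes: GenotypeMatrix,
                weights: np.ndarray | None = None) -> int:
    """Parsimony score of a tree: minimum total state changes over all
    variants, with "?" free and the zygote root at state 0."""
    if list(tree.leaf_names) != list(genotypes.sample_ids):
        if set(tree.leaf_names) != set(genotypes.sample_ids):
            raise ValueError("tree leaves do not match sample ids")
        perm = [genotypes.sample_ids.index(n) for n in tree.leaf_names]
        codes = genotypes.codes[:, perm]
    else:
        codes = genotypes.codes
    if weights is None:
        weights = np.ones(genotypes.n_variants, dtype=np.int64)
    return _fitch(tree.parent, tree.postorder(), _leaf_state_sets(codes),
                  np.asarray(weights))


def _collapse_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique character patterns and their multiplicities."""
    uniq, counts = np.unique(codes, axis=0, return_counts=True)
    return uniq, counts


# ---------------------------------------------------------------------------
# tree search


def enumerate_rooted_trees(n_leaves: int, leaf_names: list[str]):
    """Yield every rooted resolved topology on the labelled leaves
    ((2n-3)!! of them), each exactly once."""

    def grow(shape, k):
        if k == n_leaves:
            yield shape
            return
        for new in _insertions(shape, k):
            yield from grow(new, k + 1)

    def _insertions(shape, k):
        yield (shape, k)  # new root above everything
        if isinstance(shape, tuple):
            a, b = shape
            for sub in _insertions(a, k):
                yield (sub, b)
            for sub in _insertions(b, k):
                yield (a, sub)

    for shape in grow((0, 1), 2):
        yield _shape_to_tree(shape, leaf_names)


def _shape_to_tree(shape, leaf_names: list[str]) -> Tree:
    n = len(leaf_names)
    parent = [-1] * (2 * n - 1)
    nxt = [n]

    def build(s) -> int:
        if isinstance(s, int):
            return s
        me = nxt[0]
        nxt[0] += 1
        for child in s:
            parent[build(child)] = me
        return me

    build(shape)
    return Tree(np.asarray(parent), list(leaf_names))


def search_mp_tree(genotypes: GenotypeMatrix, mode: str = "heuristic",
                   seed: int = 0, restarts: int = 20
                   ) -> tuple[Tree, int, int]:
    """Find a maximum-parsimony tree.

    Exhaustive mode enumerates all rooted resolved topologies (allowed
    up to 9 leaves); heuristic mode runs seeded random-order stepwise
    addition followed by alternating NNI and SPR hill climbing, per
    restart.  Ties are broken by the lexicographically smallest
    canonical Newick string.
    Returns (tree, score, number of co-optimal topologies found).
    """
    n = len(genotypes.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples")
    patterns, weights = _collapse_patterns(genotypes.codes)
    leaf_sets = _leaf_state_sets(patterns)
    names = list(genotypes.sample_ids)

    def score_parent(parent) -> int:
        return _fitch(parent, _postorder(parent), leaf_sets, weights)

    if mode == "exhaustive":
        if n > 9:
            raise ValueError("exhaustive search limited to 9 leaves")
        best_score = None
        best_trees: list[Tree] = []
        for tree in enumerate_rooted_trees(n, names):
            s = score_parent(tree.parent)
            if best_score is None or s < best_score:
                best_score, best_trees = s, [tree]
            elif s == best_score:
                best_trees.append(tree)
        winner = min(best_trees, key=lambda t: t.canonical_newick())
        return winner, int(best_score), len(best_trees)
    if mode != "heuristic":
        raise ValueError("mode must be 'exhaustive' or 'heuristic'")

    rng = np.random.default_rng(seed)
    best_score = None
    co_optimal: set[str] = set()
    best_tree = None
    for _ in range(max(1, restarts)):
        parent = _stepwise_addition(leaf_sets, weights, n, rng)
        # alternate NNI and SPR hill climbing to a joint local optimum
        s = None
        while True:
            parent, s_nni = _nni_hillclimb(parent, leaf_sets, weights)
            parent, s_spr = _spr_hillclimb(parent, leaf_sets, weights)
            if s is not None and s_spr >= s:
                s = s_spr
                break
            s = s_spr
        tree = Tree(np.asarray(parent), names)
        key = tree.canonical_newick()
        if best_score is None or s < best_score:
            best_score, best_tree, co_optimal = s, tree, {key}
        elif s == best_score:
            co_optimal.add(key)
            if key < best_tree.canonical_newick():
                best_tree = tree
    return best_tree, int(best_score), len(co_optimal)


def _stepwise_addition(leaf_sets, weights, n_leaves, rng) -> list[int]:
    order = [int(x) for x in rng.permutation(n_leaves)]
    shape = (order[0], order[1])

    def insertions(s, k):
        yield (s, k)
        if isinstance(s, tuple):
            a, b = s
            for sub in insertions(a, k):
                yield (sub, b)
            for sub in insertions(b, k):
                yield (a, sub)

    for k in order[2:]:
        best = None
        best_s = None
        for cand in insertions(shape, k):
            parent = _shape_parent(cand, n_leaves)
            s = _fitch(parent, _postorder(parent), _pad_leafsets(leaf_sets, parent, n_leaves), weights)
            if best_s is None or s < best_s:
                best, best_s = cand, s
        shape = best
    return _shape_parent(shape, n_leaves)


def _shape_parent(shape, n_leaves) -> np.ndarray:
    # count leaves present in the partial shape
    leaves: list[int] = []

    def collect(s):
        if isinstance(s, int):
            leaves.append(s)
        else:
            collect(s[0])
            collect(s[1])

    collect(shape)
    k = len(leaves)
    parent = np.full(n_leaves + k - 1, -2, dtype=np.int64)
    nxt = [n_leaves]

    def build(s) -> int:
        if isinstance(s, int):
            return s
        me = nxt[0]
        nxt[0] += 1
        parent[me] = -1
        for child in s:
            parent[build(child)] = me
        return me

    root = build(shape)
    parent[root] = -1
    return parent


def _pad_leafsets(leaf_sets, parent, n_leaves):
    # leaves absent from a partial tree never appear in the postorder, so
    # their state sets are simply unused; shapes already align
    return leaf_sets


def _nni_hillclimb(parent, leaf_sets, weights) -> tuple[np.ndarray, int]:
    parent = np.asarray(parent).copy()
    n_nodes = len(parent)

    def unused(i):  # partial trees mark unused slots with -2
        return parent[i] == -2

    def score(p):
        order = [x for x in _postorder_safe(p)]
        return _fitch(p, order, leaf_sets, weights)

    def _postorder_safe(p):
        children = [[] for _ in p]
        root = -1
        for i, q in enumerate(p):
            if q >= 0:
                children[q].append(i)
            elif q == -1:
                root = i
        out = []
        stack = [root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(children[node])
        out.reverse()
        return out

    cur = score(parent)
    improved = True
    while improved:
        improved = False
        children = [[] for _ in parent]
        for i, q in enumerate(parent):
            if q >= 0:
                children[q].append(i)
        for v in range(n_nodes):
            if unused(v) or parent[v] < 0 or not children[v]:
                continue  # v must be an internal non-root node
            p = parent[v]
            sibs = [c for c in children[p] if c != v]
            if not sibs:
                continue
            s = sibs[0]
            a, b = children[v]
            for x in (a, b):
                trial = parent.copy()
                trial[x], trial[s] = p, v
                ts = score(trial)
                if ts < cur:
                    parent, cur = trial, ts
                    improved = True
                    break
            if improved:
                break
        if improved:
            continue
    return parent, cur


def _spr_hillclimb(parent, leaf_sets, weights) -> tuple[np.ndarray, int]:
    """Subtree prune-regraft hill climbing: escape the NNI local optima
    a greedy stepwise start can leave behind."""
    parent = np.asarray(parent).copy()
    n_nodes = len(parent)

    def score(p):
        children = [[] for _ in p]
        root = -1
        for i, q in enumerate(p):
            if q >= 0:
                children[q].append(i)
            elif q == -1:
                root = i
        out = []
        stack = [root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(children[node])
        out.reverse()
        return _fitch(p, out, leaf_sets, weights)

    def subtree_nodes(p, s):
        children = [[] for _ in p]
        for i, q in enumerate(p):
            if q >= 0:
                children[q].append(i)
        out, stack = set(), [s]
        while stack:
            node = stack.pop()
            out.add(node)
            stack.extend(children[node])
        return out

    cur = score(parent)
    improved = True
    while improved:
        improved = False
        for s in range(n_nodes):
            p = parent[s]
            if p < 0:
                continue                      # cannot prune at the root
            sibs = [c for c in range(n_nodes) if parent[c] == p and c != s]
            if len(sibs) != 1:
                continue
            sib = sibs[0]
            forbidden = subtree_nodes(parent, s) | {p}
            # prune: contract p out of the tree; the freed node p is
            # reused as the attachment point on regraft
            base = parent.copy()
            base[sib] = base[p]
            base[p] = -2
            base[s] = -2
            for v in range(n_nodes):
                if v in forbidden or base[v] == -2:
                    continue
                # regraft s on the branch above v (v may be the root,
                # in which case p becomes the new root)
                trial = base.copy()
                trial[p] = trial[v]
                trial[v] = p
                trial[s] = p
                ts = score(trial)
                if ts < cur:
                    parent, cur = trial, ts
                    improved = True
                    break
            if improved:
                break
    return parent, cur


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(genotypes: GenotypeMatrix, tree: Tree, n: int = 1000,
                      seed: int = 0, restarts: int = 1) -> dict[int, float]:
    """Column-resampling bootstrap: support per internal non-root node
    of ``tree`` = percentage of replicate MP trees containing its clade.
    Writes supports onto ``tree.support`` and returns the mapping."""
    if n <= 0:
        tree.support = {}
        return {}
    rng = np.random.default_rng(seed)
    patterns, weights = _collapse_patterns(genotypes.codes)
    leaf_sets = _leaf_state_sets(patterns)
    n_leaves = len(genotypes.sample_ids)
    total = int(weights.sum())
    probs = weights / total

    clades = {}
    masks = tree.leafsets()
    for node in range(tree.n_nodes):
        if node >= tree.n_leaves and node != tree.root:
            clades[node] = frozenset(
                tree.leaf_names[i] for i in range(tree.n_leaves)
                if masks[node] >> np.uint64(i) & np.uint64(1))
    hits = {node: 0 for node in clades}
    for _ in range(n):
        w = rng.multinomial(total, probs)
        keep = w > 0
        parent = _stepwise_addition(leaf_sets[:, keep], w[keep], n_leaves, rng)
        parent, _ = _nni_hillclimb(parent, leaf_sets[:, keep], w[keep])
        rep = Tree(np.asarray(parent), list(genotypes.sample_ids))
        rep_clades = rep.clades()
        for node, clade in clades.items():
            if clade in rep_clades:
                hits[node] += 1
    support = {node: 100.0 * hits[node] / n for node in clades}
    tree.support = support
    return support


# ---------------------------------------------------------------------------
# maximum-likelihood branch assignment


def branch_label(tree: Tree, node: int) -> str:
    if node < 0:
        return "unassigned"
    if node < tree.n_leaves:
        return tree.leaf_names[node]
    return f"node{node}"


def assign_variants_ml(tree: Tree, matrix: CountMatrix,
                       clonal_vaf: float = 0.5, err: float = 0.001,
                       include_unassigned: bool = True) -> pd.DataFrame:
    """Place each variant on the branch maximising the binomial read
    likelihood (clonal VAF below the branch, error rate elsewhere).

    Returns variant, branch node id (-1 for the off-tree category),
    branch label, best log-likelihood, and the posterior under a uniform
    prior over candidate branches.  Variants with zero depth everywhere
    are reported unassigned with NaN posterior.
    """
    order = [matrix.sample_ids.index(n) for n in tree.leaf_names]
    alt = matrix.alt[:, order]
    depth = matrix.depth[:, order]
    lc = binom.logpmf(alt, depth, clonal_vaf)
    le = binom.logpmf(alt, depth, err)
    branches = tree.branches()
    masks = tree.leafsets()
    leaf_bits = np.uint64(1) << np.arange(tree.n_leaves, dtype=np.uint64)
    ind = np.array([(masks[b] & leaf_bits) > 0 for b in branches], dtype=float)
    scores = le.sum(axis=1, keepdims=True) + (lc - le) @ ind.T
    cand_nodes = list(branches)
    if include_unassigned:
        scores = np.hstack([scores, le.sum(axis=1, keepdims=True)])
        cand_nodes = cand_nodes + [-1]
    best = np.argmax(scores, axis=1)
    m = scores.max(axis=1, keepdims=True)
    post = np.exp(scores - m)
    post /= post.sum(axis=1, keepdims=True)
    best_post = post[np.arange(len(best)), best]
    best_ll = scores[np.arange(len(best)), best]
    nodes = np.array([cand_nodes[i] for i in best])
    no_reads = depth.sum(axis=1) == 0
    nodes[no_reads] = -1
    best_post = np.where(no_reads, np.nan, best_post)
    return pd.DataFrame({
        "variant": matrix.variants["id"],
        "branch": nodes,
        "branch_label": [branch_label(tree, int(b)) for b in nodes],
        "loglik": best_ll,
        "posterior": best_post,
    })


def assign_indels_to_sbs_tree(sbs_tree: Tree, indel_matrix: CountMatrix,
                              clonal_vaf: float = 0.5, err: float = 0.001
                              ) -> pd.DataFrame:
    """Assign indels to the fixed tree built from substitutions (indel
    counts are too sparse in normal crypts to build their own tree)."""
    return assign_variants_ml(sbs_tree, indel_matrix, clonal_vaf, err)
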