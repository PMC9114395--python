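"""Synthetic crypt-cohort generator with full ground truth.

The generator emulates the statistical structure of whole-genome data
from laser-capture-microdissected clonal crypts:

* a rooted binary lineage tree per patient whose internal (ancestral)
  structure is confined to an early developmental window, so mutations
  shared between crypts are few while each crypt's private terminal
  branch spans most of life;
* somatic mutations drawn per branch at signature-specific rates, with
  channels sampled from signature probability vectors and sequence
  contexts constructed so the spectra classifiers re-derive the channel;
* germline SNPs at VAF ~ 0.5 in every crypt;
* shared low-VAF artifact sites with low beta-binomial overdispersion
  (the class the rho filter exists to remove);
* ~30X read counts per cell, binomial around the clonal VAF in carrier
  crypts and around the sequencing error rate elsewhere;
* optional MMR-deficient crypt (rate multiplier, signature-mix override)
  and tumour clade grafted onto a normal lineage via a hypermutated
  trunk.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogues import (SignatureCatalogue, synthetic_id_catalogue,
                         synthetic_sbs_catalogue)
from .matrix import CountMatrix
from .spectra import ID83_LABELS, SBS96_LABELS, revcomp
from .trees import Tree

__all__ = [
    "SimConfig", "SimTruth", "MMRDConfig", "TumourCladeConfig",
    "simulate_tree", "draw_mutations", "sample_reads", "simulate_cohort",
    "default_catalogue", "simulate_burden_cohort",
]


@dataclass
class MMRDConfig:
    """A single morphologically normal but hypermutated crypt."""
    rate_multiplier: float = 4.0
    activities: dict[str, float] | None = None  # overrides terminal mix


@dataclass
class TumourCladeConfig:
    """A clonal tumour: crypts joined by a heavily mutated trunk."""
    n_crypts: int = 6
    trunk_mutations: int = 50_000
    trunk_activities: dict[str, float] | None = None   # channel mix only
    branch_activities: dict[str, float] | None = None
    graft_depth: float = 0.7
    mrca_depth: float = 0.98


@dataclass
class SimConfig:
    n_crypts: int = 8
    patient_age: float = 50.0
    depth_mean: float = 30.0
    clonal_vaf: float = 0.5
    seq_error: float = 0.001
    n_germline: int = 2000
    n_artifact: int = 500
    artifact_vaf_mean: float = 0.1
    artifact_rho: float = 0.02
    # mutations per year attributed to each signature on ordinary branches;
    # desk-scale defaults (SBS:ID ratio ~ 20:1 as in normal colon)
    signature_activities: dict[str, float] = field(
        default_factory=lambda: {"SIG_CLOCK": 6.0, "SIG_FLAT": 4.0,
                                 "ID_SLIP_INS": 0.25, "ID_SLIP_DEL": 0.25})
    embryonic_mutation_count: float = 10.0   # mean extra per early branch
    embryonic_window: float = 0.02           # time-fraction of development
    mmrd_crypt: MMRDConfig | None = None
    tumour_clade: TumourCladeConfig | None = None
    patient: str = "PT01"
    tissue: str = "colon"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.clonal_vaf <= 1:
            raise ValueError("clonal_vaf must be in (0, 1]")
        if not 0 < self.artifact_rho < 1:
            raise ValueError("artifact_rho must be in (0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if any(v < 0 for v in self.signature_activities.values()):
            raise ValueError("activities must be non-negative")


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""
    tree: Tree
    branch_variants: dict[int, list[str]]
    variant_class: dict[str, str]          # somatic | germline | artifact
    variant_signature: dict[str, str]      # somatic only
    seed: int

    def branch_of(self) -> dict[str, int]:
        return {v: b for b, ids in self.branch_variants.items() for v in ids}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "newick": self.tree.newick(),
            "branch_variants": {str(k): v for k, v in self.branch_variants.items()},
            "variant_class": self.variant_class,
            "variant_signature": self.variant_signature,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))


def default_catalogue() -> SignatureCatalogue:
    """Combined synthetic SBS + ID catalogue used by the default config."""
    sbs = synthetic_sbs_catalogue().table
    idc = synthetic_id_catalogue().table
    table = pd.concat(
        [sbs.reindex(sbs.index.union(idc.index, sort=False), fill_value=0.0),
         idc.reindex(sbs.index.union(idc.index, sort=False), fill_value=0.0)],
        axis=1)
    # columns keep their own channel support; validation is per-column
    return SignatureCatalogue(table)


# ---------------------------------------------------------------------------
# tree simulation


def simulate_tree(n_crypts: int, seed: int, embryonic_window: float = 0.02) -> Tree:
    """Random resolved rooted tree with branch time-fractions.

    Leaves sit at depth 1 (time of sampling, as a fraction of age); all
    internal nodes fall inside the early developmental window, so
    root-to-leaf fractions sum to 1 for every leaf.
    """
    if n_crypts < 2:
        raise ValueError("need at least 2 crypts")
    rng = np.random.default_rng(seed)
    parent = _join_topology(n_crypts, rng)
    names = [f"crypt{i + 1:02d}" for i in range(n_crypts)]
    tree = Tree(np.asarray(parent), names)
    _assign_depths(tree, rng, window=embryonic_window)
    return tree


def _join_topology(n_leaves: int, rng: np.random.Generator) -> list[int]:
    """Random coalescent-style joins; returns a parent array with leaves
    numbered 0..n-1 and internal nodes following."""
    lineages = list(range(n_leaves))
    parent = {i: -1 for i in lineages}
    nxt = n_leaves
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        parent[a] = nxt
        parent[b] = nxt
        parent[nxt] = -1
        lineages = [x for x in lineages if x not in (a, b)] + [nxt]
        nxt += 1
    return [parent[k] for k in sorted(parent)]


def _assign_depths(tree: Tree, rng: np.random.Generator, window: float) -> None:
    """Internal depths inside [0, window], leaves at 1; lengths follow."""
    depth = np.ones(tree.n_nodes)
    for node in tree.postorder()[::-1]:  # parents before children
        p = tree.parent[node]
        if node == tree.root:
            depth[node] = 0.0
        elif node >= tree.n_leaves:
            lo = depth[p]
            depth[node] = lo + rng.uniform(0.3, 0.9) * (window - lo)
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        tree.length[node] = depth[node] - depth[p] if p >= 0 else 0.0


def _graft_tumour(tree: Tree, tc: TumourCladeConfig,
                  rng: np.random.Generator) -> tuple[Tree, dict]:
    """Attach a tumour clade to a random normal terminal branch.

    Returns the extended tree plus node-role metadata: the graft node,
    the trunk branch (tumour MRCA) and the tumour node set.
    """
    n_norm = tree.n_leaves
    n_tum = tc.n_crypts
    depths_old = tree.depths()
    host = int(rng.integers(n_norm))

    # old node id -> new id: normal leaves keep 0..n_norm-1, tumour leaves
    # take n_norm..n_norm+n_tum-1, then old internals, then new internals.
    shift = lambda i: i if i < n_norm else i + n_tum
    n_total_leaves = n_norm + n_tum
    parent = [-1] * (2 * n_total_leaves - 1)
    depth = np.ones(2 * n_total_leaves - 1)
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        parent[shift(i)] = shift(p) if p >= 0 else -1
        depth[shift(i)] = depths_old[i]

    nxt = tree.n_nodes + n_tum
    graft = nxt
    nxt += 1
    parent[graft] = parent[host]
    depth[graft] = tc.graft_depth
    parent[host] = graft

    # tumour subtree topology over its leaves
    lineages = list(range(n_norm, n_norm + n_tum))
    sub_parent: dict[int, int] = {}
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        sub_parent[a] = nxt
        sub_parent[b] = nxt
        lineages = [x for x in lineages if x not in (a, b)] + [nxt]
        nxt += 1
    mrca = lineages[0]
    parent[mrca] = graft
    for k, v in sub_parent.items():
        parent[k] = v
    names = tree.leaf_names + [f"tumour{i + 1:02d}" for i in range(n_tum)]
    new = Tree(np.asarray(parent), names, np.zeros(len(parent)))
    # depths: tumour internals between mrca_depth and just below the leaves
    order = new.postorder()[::-1]
    for node in order:
        if node == mrca:
            depth[node] = tc.mrca_depth
        elif node >= n_total_leaves and depth[node] == 1.0 and node != graft:
            lo = depth[new.parent[node]]
            depth[node] = lo + rng.uniform(0.3, 0.9) * (0.995 - lo)
    for node in range(new.n_nodes):
        p = new.parent[node]
        new.length[node] = depth[node] - depth[p] if p >= 0 else 0.0
    tumour_nodes = {n for n in range(new.n_nodes)
                    if n >= n_norm and n < n_total_leaves} | set(sub_parent.values()) | {mrca}
    meta = {"graft": graft, "trunk": mrca, "tumour_nodes": tumour_nodes,
            "host": host}
    return new, meta


# ---------------------------------------------------------------------------
# channel -> variant construction


def _rand_base(rng, exclude: str = "") -> str:
    pool = [b for b in "ACGT" if b not in exclude]
    return pool[int(rng.integers(len(pool)))]


def _rand_seq(rng, n: int, not_start: str = "", not_end: str = "") -> str:
    s = [_rand_base(rng) for _ in range(n)]
    if n and not_start:
        s[0] = _rand_base(rng, not_start)
    if n and not_end:
        s[-1] = _rand_base(rng, not_end)
    return "".join(s)


def _sbs_from_channel(label: str, rng) -> dict:
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    context = five + ref + three
    if rng.random() < 0.5:  # report on the purine strand
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return {"kind": "SBS", "ref": ref, "alt": alt, "context": context,
            "lflank": "", "rflank": ""}


_FLANK = 32


def _id_from_channel(label: str, rng) -> dict:
    size_s, op, cls, n_s = label.split(":")
    size, n = int(size_s), int(n_s)
    if size == 1:
        base = cls
        if op == "Del":
            run = n + 1 if n < 5 else 6 + int(rng.poisson(1.0))
            copies = run - 1
            ref, alt = base, "-"
        else:
            copies = n if n < 5 else 5 + int(rng.poisson(1.0))
            ref, alt = "-", base
        lflank = _rand_seq(rng, _FLANK, not_end=base)
        tail = _rand_seq(rng, _FLANK - copies, not_start=base)
        rflank = base * copies + tail
        if rng.random() < 0.5:  # purine-strand representation
            ref = revcomp(ref) if ref != "-" else "-"
            alt = revcomp(alt) if alt != "-" else "-"
            lflank, rflank = revcomp(rflank), revcomp(lflank)
        return {"kind": "DEL" if op == "Del" else "INS", "ref": ref,
                "alt": alt, "context": "", "lflank": lflank, "rflank": rflank}

    length = size if not (cls == "M" and n >= size) else n + 1
    motif = _rand_seq(rng, length)
    flank_len = max(_FLANK, 6 * length + 4)
    if cls == "M":
        mh = n
        tail = _rand_seq(rng, flank_len - mh, not_start=motif[mh])
        rflank = motif[:mh] + tail
    else:
        if op == "Del":
            units = n + 1 if n < 5 else 6 + int(rng.poisson(1.0))
            copies = units - 1
        else:
            units = n if n < 5 else 5 + int(rng.poisson(1.0))
            copies = units
        tail = _rand_seq(rng, flank_len + 6 * length - copies * length,
                         not_start=motif[0])
        rflank = motif * copies + tail
        if copies == 0 and op == "Del":
            # avoid accidental microhomology with the deleted motif
            tail0 = _rand_base(rng, motif[0])
            rflank = tail0 + rflank[1:]
    lflank = _rand_seq(rng, flank_len, not_end=motif[-1])
    if op == "Del":
        ref, alt = motif, "-"
        kind = "DEL"
    else:
        ref, alt = "-", motif
        kind = "INS"
    return {"kind": kind, "ref": ref, "alt": alt, "context": "",
            "lflank": lflank, "rflank": rflank}


def variant_from_channel(kind: str, label: str, rng) -> dict:
    """Inverse of the spectra classifiers: build a variant whose channel
    re-derives to ``label``."""
    return _sbs_from_channel(label, rng) if kind == "SBS" else _id_from_channel(label, rng)


# ---------------------------------------------------------------------------
# mutation drawing


def draw_mutations(tree: Tree, config: SimConfig,
                   catalogue: SignatureCatalogue | None = None,
                   seed: int | None = None,
                   clade_meta: dict | None = None) -> tuple[pd.DataFrame, SimTruth]:
    """Draw somatic, germline, and artifact variants on a lineage tree.

    Per branch the somatic count is Poisson with mean = branch
    time-fraction x age x total activity; each mutation's channel comes
    from its generating signature's probability vector.  Early internal
    branches additionally carry embryonic mutations.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    for name in config.signature_activities:
        if name not in catalogue.names:
            raise KeyError(f"signature {name!r} not in catalogue")

    sig_vectors: dict[str, tuple[str, np.ndarray, list[str]]] = {}
    all_names = set(config.signature_activities)
    for extra in (config.mmrd_crypt, config.tumour_clade):
        if extra is not None:
            for m in ("activities", "trunk_activities", "branch_activities"):
                d = getattr(extra, m, None)
                if d:
                    all_names |= set(d)
    for name in sorted(all_names):
        vec = catalogue.vector(name)
        # kind by channel support: columns live on either the SBS96 or the
        # ID83 block of the combined catalogue
        labels = catalogue.channels
        support = [labels[i] for i in np.flatnonzero(vec > 0)]
        is_sbs = all(l in SBS96_LABELS for l in support)
        order = SBS96_LABELS if is_sbs else ID83_LABELS
        idx = [labels.index(l) for l in order]
        sig_vectors[name] = ("SBS" if is_sbs else "ID", vec[idx] / vec[idx].sum(), order)

    leafsets = tree.leafsets()
    n_leaves = tree.n_leaves
    clade_meta = clade_meta or {}
    trunk = clade_meta.get("trunk")
    tumour_nodes = clade_meta.get("tumour_nodes", set())
    mmrd_leaf = clade_meta.get("mmrd_leaf")
    depths = tree.depths()

    records: list[dict] = []
    branch_variants: dict[int, list[str]] = {}
    variant_class: dict[str, str] = {}
    variant_signature: dict[str, str] = {}
    counter = 0

    def emit(branch: int, sig: str, n: int) -> None:
        nonlocal counter
        if n <= 0:
            return
        kind, probs, order = sig_vectors[sig]
        channels = rng.choice(len(probs), size=n, p=probs)
        for ch in channels:
            vid = f"v{counter:06d}"
            counter += 1
            rec = variant_from_channel(kind, order[int(ch)], rng)
            rec.update(id=vid, chrom="1", pos=1000 * counter,
                       channel=order[int(ch)],
                       vclass="somatic", branch=branch, signature=sig,
                       ASMD=140.0 + round(float(rng.gamma(4, 3)), 1),
                       CLPM=0.0, Qual=300.0 + round(float(rng.gamma(5, 40)), 1),
                       site_depth=float(max(15, rng.poisson(config.depth_mean))))
            records.append(rec)
            branch_variants.setdefault(branch, []).append(vid)
            variant_class[vid] = "somatic"
            variant_signature[vid] = sig

    age = config.patient_age
    for branch in tree.branches():
        frac = float(tree.length[branch])
        if branch == trunk and config.tumour_clade is not None:
            mix = (config.tumour_clade.trunk_activities
                   or config.signature_activities)
            total = sum(mix.values())
            n_trunk = rng.poisson(config.tumour_clade.trunk_mutations)
            for sig, act in mix.items():
                emit(branch, sig, int(round(n_trunk * act / total)))
            continue
        if branch in tumour_nodes and branch != trunk:
            acts = (config.tumour_clade.branch_activities
                    or config.signature_activities)
        elif mmrd_leaf is not None and branch == mmrd_leaf:
            mc = config.mmrd_crypt
            acts = {k: v * mc.rate_multiplier
                    for k, v in (mc.activities or config.signature_activities).items()}
        else:
            acts = config.signature_activities
        for sig, act in acts.items():
            emit(branch, sig, int(rng.poisson(frac * age * act)))
        is_early_internal = (branch >= n_leaves
                             and depths[branch] <= config.embryonic_window)
        if is_early_internal and config.embryonic_mutation_count > 0:
            mix = config.signature_activities
            total = sum(mix.values()) or 1.0
            n_emb = int(rng.poisson(config.embryonic_mutation_count))
            for sig, act in mix.items():
                emit(branch, sig, int(round(n_emb * act / total)))

    # germline SNPs and shared artifacts: SBS sites with flat channel usage
    for vclass, count in (("germline", config.n_germline),
                          ("artifact", config.n_artifact)):
        for _ in range(count):
            vid = f"v{counter:06d}"
            counter += 1
            label = SBS96_LABELS[int(rng.integers(96))]
            rec = _sbs_from_channel(label, rng)
            rec.update(id=vid, chrom="1", pos=1000 * counter, channel=label,
                       vclass=vclass,
                       branch=tree.root if vclass == "germline" else -1,
                       signature="",
                       ASMD=140.0 + round(float(rng.gamma(4, 3)), 1),
                       CLPM=0.0, Qual=300.0 + round(float(rng.gamma(5, 40)), 1),
                       site_depth=float(max(15, rng.poisson(config.depth_mean))))
            records.append(rec)
            variant_class[vid] = vclass

    cols = ["id", "chrom", "pos", "ref", "alt", "kind", "context", "lflank",
            "rflank", "channel", "vclass", "branch", "signature", "ASMD",
            "CLPM", "Qual", "site_depth"]
    variants = pd.DataFrame.from_records(records)[cols] if records else \
        pd.DataFrame(columns=cols)
    truth = SimTruth(tree, branch_variants, variant_class,
                     variant_signature, seed)
    return variants, truth


# ---------------------------------------------------------------------------
# read sampling


def sample_reads(truth: SimTruth, variants: pd.DataFrame, config: SimConfig,
                 seed: int | None = None) -> CountMatrix:
    """Draw per-cell depths and alt counts for every variant x crypt."""
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(seed)
    tree = truth.tree
    nv, ns = len(variants), tree.n_leaves
    depth = rng.poisson(config.depth_mean, size=(nv, ns))
    p = np.full((nv, ns), config.seq_error)

    leafsets = tree.leafsets()
    branch_col = variants["branch"].to_numpy()
    vclass = variants["vclass"].to_numpy()
    leaf_bits = np.uint64(1) << np.arange(ns, dtype=np.uint64)
    for i in range(nv):
        if vclass[i] == "somatic":
            mask = leafsets[int(branch_col[i])]
            carriers = (mask & leaf_bits) > 0
            p[i, carriers] = config.clonal_vaf
        elif vclass[i] == "germline":
            p[i, :] = config.clonal_vaf
    art = vclass == "artifact"
    if art.any():
        rho = config.artifact_rho
        mu = config.artifact_vaf_mean
        a = mu * (1 - rho) / rho
        b = (1 - mu) * (1 - rho) / rho
        p[art, :] = rng.beta(a, b, size=(int(art.sum()), ns))
    alt = rng.binomial(depth, p)

    samples = pd.DataFrame({
        "id": tree.leaf_names,
        "patient": config.patient,
        "tissue": config.tissue,
        "crypt_type": ["tumour" if n.startswith("tumour") else "survey"
                       for n in tree.leaf_names],
        "age": config.patient_age,
        "cnv": False,
    })
    meta_cols = ["id", "chrom", "pos", "ref", "alt", "kind", "context",
                 "lflank", "rflank", "ASMD", "CLPM", "Qual", "site_depth"]
    vmeta = variants[meta_cols].rename(columns={"alt": "alt_allele"})
    return CountMatrix(vmeta.reset_index(drop=True), samples, alt, depth)


def simulate_cohort(config: SimConfig,
                    catalogue: SignatureCatalogue | None = None
                    ) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Full per-patient cohort: tree, variants, truth, read counts."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_crypts, config.seed,
                         embryonic_window=config.embryonic_window)
    clade_meta: dict = {}
    if config.tumour_clade is not None:
        tree, clade_meta = _graft_tumour(tree, config.tumour_clade, rng)
    if config.mmrd_crypt is not None:
        normal_leaves = [i for i, n in enumerate(tree.leaf_names)
                         if not n.startswith("tumour")
                         and i != clade_meta.get("host", -1)]
        clade_meta["mmrd_leaf"] = int(rng.choice(normal_leaves))
    variants, truth = draw_mutations(tree, config, catalogue,
                                     seed=config.seed + 7,
                                     clade_meta=clade_meta)
    matrix = sample_reads(truth, variants, config, seed=config.seed + 11)
    if "mmrd_leaf" in clade_meta:
        matrix.samples.loc[clade_meta["mmrd_leaf"], "crypt_type"] = "mmrd"
    return matrix, variants, truth


# ---------------------------------------------------------------------------
# lightweight burden cohorts (for the mixed-model analyses)


def simulate_burden_cohort(n_patients_a: int = 10, n_patients_b: int = 10,
                           crypts_per_patient: int = 8,
                           sbs_rate_a: float = 55.0, sbs_rate_b: float = 55.0,
                           id_rate: float = 2.5,
                           patient_cv: float = 0.15,
                           age_range: tuple[float, float] = (23.0, 78.0),
                           seed: int = 0) -> pd.DataFrame:
    """Two-cohort per-crypt burden table drawn directly from the burden
    model (Poisson counts around patient-specific per-year rates with
    log-normal between-patient variation); used for mixed-model power
    and calibration studies without running the full pipeline."""
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, n_pat, rate in (("LS", n_patients_a, sbs_rate_a),
                                ("wildtype", n_patients_b, sbs_rate_b)):
        for p in range(n_pat):
            age = rng.uniform(*age_range)
            prate = rate * rng.lognormal(0.0, patient_cv)
            for c in range(crypts_per_patient):
                rows.append({
                    "sample": f"{cohort}_p{p:02d}_c{c:02d}",
                    "patient": f"{cohort}_p{p:02d}",
                    "cohort": cohort,
                    "tissue": "colon",
                    "crypt_type": "survey",
                    "age": age,
                    "sbs_burden": int(rng.poisson(prate * age)),
                    "id_burden": int(rng.poisson(id_rate * age)),
                })
    table = pd.DataFrame(rows)
    table["sbs_rate"] = table["sbs_burden"] / table["age"]
    table["id_rate"] = table["id_burden"] / table["age"]
    return table


def simulate_branch_spectra(catalogue, signature_names: list[str],
                            n_patients: int = 4, branches_per_patient: int = 3,
                            count_range: tuple[int, int] = (100, 2500),
                            mixing: float = 0.0, seed: int = 0):
    """Planted per-branch channel-count spectra for extraction studies.

    Exposures are block-structured: each branch is generated from one
    signature (plus an optional ``mixing`` fraction spread uniformly
    over the others).  Returns (spectra DataFrame with a ``patient``
    column, true exposure matrix, signature matrix).
    """
    rng = np.random.default_rng(seed)
    V = np.array([catalogue.vector(n) for n in signature_names])
    k = len(signature_names)
    rows, pats, expos, index = [], [], [], []
    for p in range(n_patients):
        for b in range(branches_per_patient):
            mix = np.full(k, mixing / max(k - 1, 1))
            mix[b % k] = 1.0 - mixing
            n = int(rng.integers(count_range[0], count_range[1] + 1))
            rows.append(rng.multinomial(n, mix @ V))
            pats.append(f"P{p + 1}")
            expos.append(mix)
            index.append(f"P{p + 1}_b{b + 1}")
    spec = pd.DataFrame(rows, index=index, columns=catalogue.channels)
    spec.insert(0, "patient", pats)
    spec.index.name = "branch"
    return spec, np.array(expos), V
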