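"""Mutational signature extraction, deconvolution, and refitting.

Two de novo extraction backends operate on per-branch spectra with a
patient -> branch hierarchy:

* :func:`hdp_extract` — a hierarchical Dirichlet process mixture over
  channel-categorical mutations (top node -> patients -> branches),
  sampled by a Chinese-restaurant-franchise Gibbs scheme with vague
  gamma hyperpriors on the three concentration parameters.  Posterior
  cluster spectra are matched across retained samples by cosine
  similarity and averaged; components with pairwise cosine >= 0.9 are
  merged and components supported by fewer than two samples dropped.
* :func:`nmf_extract` — multiplicative-update NMF under generalized
  Kullback-Leibler divergence with seeded restarts; the rank is chosen
  by the stability (cosine silhouette) of restart components.

Extracted components are then deconvoluted into a reference catalogue
by expectation-maximization, reconstituted from references above a
contribution threshold (0.15 for substitution signatures, 0.2 for
indels), and — when the reconstitution cosine fails 0.9 — the selected
references are subtracted to leave a residual "unknown" signature.
Final per-branch exposures come from an EM refit against the selected
references plus accepted residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

from .catalogues import SignatureCatalogue

__all__ = [
    "ComponentSet", "DeconvolutionResult", "cosine",
    "hdp_extract", "nmf_extract", "em_deconvolute", "reconstitute",
    "residual_signature", "refit_exposures", "deconvolute_components",
]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity between non-negative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for zero vectors")
    return float(u @ v / (nu * nv))


@dataclass
class ComponentSet:
    """De novo components (rows sum to 1) with per-branch exposures."""
    components: np.ndarray               # n_components x n_channels
    exposures: pd.DataFrame              # branches x component names
    provenance: str                      # 'hierarchical-sampler' | 'nmf'
    diagnostics: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.exposures.columns)


@dataclass
class DeconvolutionResult:
    weights: pd.Series                   # reference -> EM weight
    selected: list[str]                  # references above the threshold
    reconstitution_cosine: float
    accepted: bool
    residual: np.ndarray | None = None


# ---------------------------------------------------------------------------
# EM deconvolution of a component into reference signatures


def em_deconvolute(component: np.ndarray, catalogue: SignatureCatalogue,
                   tol: float = 1e-8, max_iter: int = 10_000) -> np.ndarray:
    """Mixture weights maximising sum_c x_c log(sum_k w_k R_ck).

    Standard multinomial-mixture EM; the objective is non-decreasing at
    every iteration and the weights stay on the simplex.
    """
    x = np.asarray(component, dtype=float)
    R = catalogue.matrix  # channels x K
    if len(x) != R.shape[0]:
        raise ValueError("component length does not match catalogue channels")
    K = R.shape[1]
    w = np.full(K, 1.0 / K)
    xs = x.sum()
    if xs <= 0:
        raise ValueError("component must have positive mass")
    for _ in range(max_iter):
        mix = R @ w                      # per-channel mixture density
        mix = np.where(mix > 0, mix, 1e-300)
        resp = (R * w[None, :]) / mix[:, None]   # z_ck
        w_new = resp.T @ x
        w_new /= w_new.sum()
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    return w


def reconstitute(weights: np.ndarray, catalogue: SignatureCatalogue,
                 component: np.ndarray, contribution_threshold: float = 0.15,
                 cosine_threshold: float = 0.9
                 ) -> tuple[float, bool, list[str]]:
    """Rebuild a component from references contributing more than the
    threshold (strictly) and compare with the original by cosine.

    Returns (cosine, accepted, selected reference names); with no
    reference above the threshold the component is not reconstitutable.
    """
    w = np.asarray(weights, dtype=float)
    keep = w > contribution_threshold
    names = [n for n, k in zip(catalogue.names, keep) if k]
    if not names:
        return 0.0, False, []
    wk = w[keep] / w[keep].sum()
    recon = catalogue.matrix[:, keep] @ wk
    cos = cosine(recon, component)
    return cos, cos > cosine_threshold, names


def residual_signature(component: np.ndarray, catalogue: SignatureCatalogue,
                       selected: list[str], weights: np.ndarray) -> np.ndarray:
    """Subtract the selected references (at their EM weights) from a
    component; the clipped, renormalized residue is the unknown
    signature.  Raises when the component is fully explained."""
    x = np.asarray(component, dtype=float)
    x = x / x.sum()
    wmap = dict(zip(catalogue.names, np.asarray(weights, dtype=float)))
    explained = np.zeros_like(x)
    for name in selected:
        explained += wmap[name] * catalogue.vector(name)
    residue = np.clip(x - explained, 0.0, None)
    if residue.sum() <= 1e-12:
        raise ValueError("degenerate residual: component lies in the "
                         "span of the selected references")
    return residue / residue.sum()


def refit_exposures(spectra: pd.DataFrame, signatures: SignatureCatalogue,
                    tol: float = 1e-8, max_iter: int = 10_000
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-branch EM fit of a fixed signature set.

    Returns (exposure fractions, absolute mutation counts); fraction
    rows sum to 1 and counts rows sum to the branch totals.
    """
    if signatures.matrix.shape[1] == 0:
        raise ValueError("empty signature set")
    mat = spectra.drop(columns=["patient"], errors="ignore")
    if mat.shape[1] != signatures.n_channels:
        raise ValueError("spectra channels do not match signature channels")
    rows = []
    for _, x in mat.iterrows():
        rows.append(em_deconvolute(x.to_numpy(dtype=float), signatures,
                                   tol=tol, max_iter=max_iter))
    frac = pd.DataFrame(rows, index=mat.index, columns=signatures.names)
    counts = frac.mul(mat.sum(axis=1), axis=0)
    return frac, counts


def deconvolute_components(components: np.ndarray,
                           catalogue: SignatureCatalogue,
                           contribution_threshold: float = 0.15,
                           cosine_threshold: float = 0.9,
                           residual_prefix: str = "N"
                           ) -> dict[int, DeconvolutionResult]:
    """The full per-component workflow: EM deconvolution, thresholded
    reconstitution, and residual construction for components that fail
    to reconstitute."""
    out: dict[int, DeconvolutionResult] = {}
    for i, comp in enumerate(np.atleast_2d(components)):
        w = em_deconvolute(comp, catalogue)
        cos, accepted, selected = reconstitute(
            w, catalogue, comp, contribution_threshold, cosine_threshold)
        residual = None
        if not accepted and selected:
            try:
                residual = residual_signature(comp, catalogue, selected, w)
            except ValueError:
                residual = None
        out[i] = DeconvolutionResult(
            weights=pd.Series(w, index=catalogue.names),
            selected=selected, reconstitution_cosine=cos,
            accepted=accepted, residual=residual)
    return out


# ---------------------------------------------------------------------------
# NMF backend


def nmf_extract(spectra: pd.DataFrame, k_range=range(1, 6),
                restarts: int = 10, seed: int = 0,
                silhouette_threshold: float = 0.8,
                max_iter: int = 2000) -> ComponentSet:
    """Multiplicative-update KL-NMF with stability-based rank selection.

    For each candidate rank the factorization is restarted from seeded
    random inits; restart components are pooled, matched to the
    best-objective solution by greedy cosine assignment, and scored by
    a cosine silhouette.  The chosen rank is the largest one whose mean
    silhouette exceeds the threshold.
    """
    mat = spectra.drop(columns=["patient"], errors="ignore")
    X = mat.to_numpy(dtype=float)
    if X.size == 0:
        raise ValueError("empty spectra")
    results = {}
    for k in k_range:
        if k < 1 or k > X.shape[0]:
            continue
        comps_by_restart = []
        best = None
        for r in range(restarts):
            model = NMF(n_components=k, init="random", solver="mu",
                        beta_loss="kullback-leibler", max_iter=max_iter,
                        random_state=seed * 1000 + 17 * k + r, tol=1e-6)
            W = model.fit_transform(X)
            H = model.components_
            norm = H.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            comps_by_restart.append(H / norm)
            if best is None or model.reconstruction_err_ < best[0]:
                best = (model.reconstruction_err_, W, H / norm)
        stability = _restart_stability(comps_by_restart, best[2])
        results[k] = (stability, best)
    chosen = None
    for k in sorted(results):
        if results[k][0] >= silhouette_threshold:
            chosen = k
    if chosen is None:  # fall back to the most stable rank
        chosen = max(results, key=lambda k: results[k][0])
    stability, (err, W, H) = results[chosen]
    expos = W / np.maximum(W.sum(axis=1, keepdims=True), 1e-300)
    names = [f"N{i + 1}" for i in range(chosen)]
    exposures = pd.DataFrame(expos, index=mat.index, columns=names)
    return ComponentSet(H, exposures, "nmf",
                        {"rank_stability": {k: v[0] for k, v in results.items()},
                         "chosen_k": chosen, "kl_error": float(err)})


def _restart_stability(comps_by_restart: list[np.ndarray],
                       reference: np.ndarray) -> float:
    k = reference.shape[0]
    if k == 1:
        sims = [cosine(c[0], reference[0]) for c in comps_by_restart]
        return float(np.mean(sims))
    pooled, labels = [], []
    for comps in comps_by_restart:
        assign = _greedy_match(comps, reference)
        for i, lab in enumerate(assign):
            pooled.append(comps[i])
            labels.append(lab)
    if len(set(labels)) < 2:
        return 0.0
    return float(silhouette_score(np.asarray(pooled), np.asarray(labels),
                                  metric="cosine"))


def _greedy_match(comps: np.ndarray, reference: np.ndarray) -> list[int]:
    """Greedy 1-1 assignment of rows of ``comps`` to reference rows by
    descending cosine."""
    k = reference.shape[0]
    sims = np.array([[cosine(c, r) for r in reference] for c in comps])
    assign = [-1] * len(comps)
    used = set()
    order = np.dstack(np.unravel_index(np.argsort(-sims, axis=None),
                                       sims.shape))[0]
    for i, j in order:
        if assign[i] == -1 and j not in used:
            assign[i] = int(j)
            used.add(int(j))
        if len(used) == k:
            break
    for i in range(len(assign)):
        if assign[i] == -1:
            assign[i] = int(np.argmax(sims[i]))
    return assign


# ---------------------------------------------------------------------------
# hierarchical Dirichlet process backend


def _crt(n: int, theta: float, rng: np.random.Generator) -> int:
    """Chinese-restaurant table count for n customers, concentration theta."""
    if n <= 0:
        return 0
    i = np.arange(n)
    return int((rng.random(n) < theta / (theta + i)).sum())


def _resample_concentration(counts: np.ndarray, tables: int, conc: float,
                            rng: np.random.Generator,
                            a: float = 1.0, b: float = 1.0) -> float:
    """Escobar-West style auxiliary update shared across groups."""
    counts = counts[counts > 0]
    if len(counts) == 0 or tables == 0:
        return float(rng.gamma(a, 1.0 / b))
    logw = np.log(rng.beta(conc + 1.0, counts))
    s = (rng.random(len(counts)) < counts / (counts + conc)).sum()
    return float(rng.gamma(a + tables - s, 1.0 / (b - logw.sum())))


def hdp_extract(spectra: pd.DataFrame, hierarchy: dict | None = None,
                mcmc: dict | None = None, cos_merge: float = 0.9,
                min_sample: int = 2, seed: int = 0,
                base_conc: float = 1.0, kmax: int = 40) -> ComponentSet:
    """De novo signature extraction with a 3-level HDP mixture.

    ``spectra`` is a branch x channel count matrix (optionally with a
    ``patient`` column, else ``hierarchy`` maps branch -> patient).
    ``mcmc`` keys: ``burnin``, ``n_samples``, ``spacing`` (desk-scale
    defaults 2000/50/10; the study-scale settings 80000/2500/250 are
    accepted the same way).  Deterministic under a fixed seed.
    """
    from ._hdp import gibbs_sweep, seed_kernel

    mcmc = {"burnin": 2000, "n_samples": 50, "spacing": 10, **(mcmc or {})}
    if mcmc["burnin"] <= 0 or mcmc["n_samples"] <= 0 or mcmc["spacing"] <= 0:
        raise ValueError("mcmc settings must be positive")
    mat = spectra.drop(columns=["patient"], errors="ignore")
    if mat.size == 0 or mat.to_numpy().sum() == 0:
        raise ValueError("empty spectra")
    if "patient" in spectra.columns:
        patients = spectra["patient"].astype(str).tolist()
    elif hierarchy is not None:
        patients = [str(hierarchy[b]) for b in mat.index]
    else:
        patients = ["all"] * len(mat)
    pat_names = sorted(set(patients))
    pat_idx = np.array([pat_names.index(p) for p in patients], dtype=np.int64)

    X = mat.to_numpy(dtype=np.int64)
    J, C = X.shape
    P = len(pat_names)
    # unroll counts into per-mutation items
    items_c = np.repeat(np.tile(np.arange(C), J), X.ravel())
    items_j = np.repeat(np.arange(J), X.sum(axis=1))
    N = len(items_c)

    rng = np.random.default_rng(seed)
    seed_kernel(int(rng.integers(2**31 - 1)))
    K0 = min(8, kmax - 2)
    z = rng.integers(K0, size=N).astype(np.int64)
    n_jk = np.zeros((J, kmax), dtype=np.int64)
    M_kc = np.zeros((kmax, C), dtype=np.int64)
    M_k = np.zeros(kmax, dtype=np.int64)
    for i in range(N):
        n_jk[items_j[i], z[i]] += 1
        M_kc[z[i], items_c[i]] += 1
        M_k[z[i]] += 1
    K = K0
    beta = np.zeros(kmax + 1)
    beta[:K + 1] = 1.0 / (K + 1)
    psi = np.zeros((P, kmax + 1))
    psi[:, :K + 1] = 1.0 / (K + 1)
    gamma_c, alpha0, alpha1 = 1.0, 1.0, 1.0

    comps_samples: list[np.ndarray] = []
    expos_samples: list[np.ndarray] = []
    total_sweeps = mcmc["burnin"] + mcmc["n_samples"] * mcmc["spacing"]
    for sweep in range(total_sweeps):
        K = gibbs_sweep(z, items_c, items_j, pat_idx, n_jk, M_kc, M_k, psi,
                        beta, K, alpha0, alpha1, gamma_c, base_conc, kmax)
        # drop empty clusters and relabel compactly; freed stick mass
        # returns to the remainder
        occupied = np.flatnonzero(M_k[:K] > 0)
        if len(occupied) < K:
            nk = len(occupied)
            remap = -np.ones(K, dtype=np.int64)
            remap[occupied] = np.arange(nk)
            z = remap[z]
            n_jk[:, :nk] = n_jk[:, occupied]
            n_jk[:, nk:K] = 0
            M_kc[:nk] = M_kc[occupied]
            M_kc[nk:K] = 0
            M_k[:nk] = M_k[occupied]
            M_k[nk:K] = 0
            kept_beta = beta[occupied]
            beta[:nk] = kept_beta
            beta[nk] = max(1.0 - kept_beta.sum(), 1e-12)
            beta[nk + 1:] = 0.0
            kept_psi = psi[:, occupied]
            psi[:, :nk] = kept_psi
            psi[:, nk] = np.maximum(1.0 - kept_psi.sum(axis=1), 1e-12)
            psi[:, nk + 1:] = 0.0
            K = nk

        # auxiliary table counts and stick resampling
        t_jk = np.zeros((J, K), dtype=np.int64)
        for j in range(J):
            p = pat_idx[j]
            for k in range(K):
                t_jk[j, k] = _crt(int(n_jk[j, k]),
                                  alpha1 * max(psi[p, k], 1e-12), rng)
        npk = np.zeros((P, K), dtype=np.int64)
        for j in range(J):
            npk[pat_idx[j]] += t_jk[j]
        T_pk = np.zeros((P, K), dtype=np.int64)
        for p in range(P):
            for k in range(K):
                T_pk[p, k] = _crt(int(npk[p, k]),
                                  alpha0 * max(beta[k], 1e-12), rng)
        m_k = T_pk.sum(axis=0)
        draw = rng.gamma(np.concatenate([m_k + 1e-8, [gamma_c]]))
        beta[:K + 1] = draw / draw.sum()
        for p in range(P):
            draw = rng.gamma(np.concatenate([npk[p] + alpha0 * beta[:K] + 1e-8,
                                             [alpha0 * beta[K] + 1e-8]]))
            psi[p, :K + 1] = draw / draw.sum()
        gamma_c = _resample_concentration(np.array([m_k.sum()]), K, gamma_c, rng)
        alpha0 = _resample_concentration(npk.sum(axis=1), int(T_pk.sum()),
                                         alpha0, rng)
        alpha1 = _resample_concentration(n_jk[:, :K].sum(axis=1),
                                         int(t_jk.sum()), alpha1, rng)

        if (sweep >= mcmc["burnin"]
                and (sweep - mcmc["burnin"]) % mcmc["spacing"] == 0):
            comp = (M_kc[:K] + base_conc) / (M_k[:K, None] + C * base_conc)
            comp = comp / comp.sum(axis=1, keepdims=True)
            expo = n_jk[:, :K] / np.maximum(X.sum(axis=1), 1)[:, None]
            comps_samples.append(comp.copy())
            expos_samples.append(expo.copy())

    components, exposures, diag = _summarize_posterior(
        comps_samples, expos_samples, cos_merge, min_sample)
    # final exposures: EM refit of each branch onto the merged components
    cat = SignatureCatalogue(pd.DataFrame(
        components.T, index=mat.columns,
        columns=[f"N{i + 1}" for i in range(len(components))]))
    frac, _ = refit_exposures(mat, cat)
    diag.update(n_posterior_samples=len(comps_samples))
    return ComponentSet(components, frac, "hierarchical-sampler", diag)


def _summarize_posterior(comps_samples, expos_samples, cos_merge,
                         min_sample):
    """Match clusters across posterior samples by cosine, average them,
    then apply the merge and minimum-support rules."""
    centroids: list[np.ndarray] = []   # running mean spectra
    cent_expo: list[np.ndarray] = []   # running mean exposure per branch
    cent_mass: list[float] = []
    n_raw = 0
    for comp, expo in zip(comps_samples, expos_samples):
        for k in range(comp.shape[0]):
            n_raw += 1
            vec = comp[k]
            mass = float(expo[:, k].sum())
            if mass <= 0:
                continue
            best, best_cos = -1, 0.0
            for ci, cvec in enumerate(centroids):
                cs = cosine(vec, cvec)
                if cs > best_cos:
                    best, best_cos = ci, cs
            if best >= 0 and best_cos >= cos_merge:
                w_old = cent_mass[best]
                w = w_old + mass
                centroids[best] = (centroids[best] * w_old + vec * mass) / w
                cent_expo[best] = (cent_expo[best] * w_old + expo[:, k] * mass) / w
                cent_mass[best] = w
            else:
                centroids.append(vec.copy())
                cent_expo.append(expo[:, k].copy())
                cent_mass.append(mass)

    # merge centroid pairs that remain closer than the threshold
    merged = True
    n_merges = 0
    while merged and len(centroids) > 1:
        merged = False
        for i in range(len(centroids)):
            for j in range(i + 1, len(centroids)):
                if cosine(centroids[i], centroids[j]) >= cos_merge:
                    wi, wj = cent_mass[i], cent_mass[j]
                    centroids[i] = (centroids[i] * wi + centroids[j] * wj) / (wi + wj)
                    cent_expo[i] = (cent_expo[i] * wi + cent_expo[j] * wj) / (wi + wj)
                    cent_mass[i] = wi + wj
                    del centroids[j], cent_expo[j], cent_mass[j]
                    merged = True
                    n_merges += 1
                    break
            if merged:
                break

    # minimum-support rule: non-trivial exposure in >= min_sample branches
    keep = [i for i in range(len(centroids))
            if (cent_expo[i] > 0.01).sum() >= min_sample]
    dropped = len(centroids) - len(keep)
    if not keep:  # degenerate; keep the heaviest component
        keep = [int(np.argmax(cent_mass))]
    order = sorted(keep, key=lambda i: -cent_mass[i])
    components = np.array([centroids[i] / centroids[i].sum() for i in order])
    exposures = np.array([cent_expo[i] for i in order]).T
    diag = {"n_raw_clusters": n_raw, "n_centroids": len(centroids) + dropped,
            "n_merges": n_merges, "n_dropped_min_sample": dropped}
    return components, exposures, diag
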