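"""Germline, artifact, and quality filtering of per-crypt read counts.

The filtering cascade turns a raw :class:`~cryptphylo.matrix.CountMatrix`
into a per-patient somatic variant set:

1. caller-annotation quality predicates (ASMD/CLPM for substitutions,
   Qual/site depth for indels);
2. a one-sided exact binomial test on counts aggregated over CNV-free
   crypts — a site whose pooled allele fraction is *not* significantly
   below the heterozygous expectation of 0.5 is germline;
3. a beta-binomial overdispersion (rho) filter — shared artifacts show
   a consistent low allele fraction in every crypt (low rho), whereas
   true somatic variants are present in some crypts and absent in
   others (high rho).  Sites with rho below 0.1 (substitutions) or 0.2
   (indels) are dropped as artifacts.

The beta-binomial here is parameterized by mean mu and overdispersion
rho: alpha = mu (1-rho)/rho, beta = (1-mu)(1-rho)/rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix

__all__ = [
    "DEFAULT_SBS_RULES", "DEFAULT_INDEL_RULES",
    "quality_filter", "binomial_germline_test", "classify_germline",
    "estimate_rho", "estimate_rho_many", "overdispersion_filter",
    "run_filters", "clonality_summary", "ClonalitySummary",
]

RHO_LO = 1e-6
RHO_HI = 1 - 1e-6

# (annotation key, comparison, threshold); comparisons: ">=", "=="
DEFAULT_SBS_RULES = [("ASMD", ">=", 140.0), ("CLPM", "==", 0.0)]
DEFAULT_INDEL_RULES = [("Qual", ">=", 300.0), ("site_depth", ">=", 15.0)]


def quality_filter(variants: pd.DataFrame,
                   sbs_rules=None, indel_rules=None,
                   on_missing: str = "fail") -> np.ndarray:
    """Apply annotation predicates per variant kind.

    A variant passes iff all rules applicable to its kind hold.  A rule
    naming an absent annotation fails the variant (``on_missing='fail'``,
    the default) or is ignored (``'skip'``).
    """
    if on_missing not in ("fail", "skip"):
        raise ValueError("on_missing must be 'fail' or 'skip'")
    sbs_rules = DEFAULT_SBS_RULES if sbs_rules is None else sbs_rules
    indel_rules = DEFAULT_INDEL_RULES if indel_rules is None else indel_rules
    out = np.ones(len(variants), dtype=bool)
    kinds = variants["kind"].to_numpy()
    for i in range(len(variants)):
        rules = sbs_rules if kinds[i] == "SBS" else indel_rules
        for key, op, thr in rules:
            if key not in variants.columns or pd.isna(variants[key].iloc[i]):
                if on_missing == "fail":
                    out[i] = False
                continue
            val = float(variants[key].iloc[i])
            ok = val >= thr if op == ">=" else val == thr
            if not ok:
                out[i] = False
    return out


def binomial_germline_test(alt_sum: int, depth_sum: int, p0: float = 0.5) -> float:
    """One-sided exact binomial p-value: probability of an aggregate alt
    count this low or lower if the site were germline heterozygous."""
    if depth_sum <= 0:
        raise ValueError("depth_sum must be positive")
    if not 0 <= alt_sum <= depth_sum:
        raise ValueError("alt_sum must lie in [0, depth_sum]")
    return float(binom.cdf(alt_sum, depth_sum, p0))


def classify_germline(matrix: CountMatrix, alpha: float = 1e-5,
                      p0: float = 0.5) -> pd.DataFrame:
    """Per-variant germline flags via the aggregated exact binomial test.

    Counts are pooled over samples without copy-number variants (boolean
    ``cnv`` column on the sample table; all samples if absent), p-values
    Benjamini-Hochberg adjusted, and a variant is flagged germline when
    its adjusted p is >= ``alpha`` — i.e. only sites whose pooled VAF is
    significantly below ``p0`` survive as candidate somatic.
    """
    use = np.ones(matrix.n_samples, dtype=bool)
    if "cnv" in matrix.samples.columns:
        use = ~matrix.samples["cnv"].to_numpy(dtype=bool)
    alt_sum = matrix.alt[:, use].sum(axis=1)
    depth_sum = matrix.depth[:, use].sum(axis=1)
    p = np.where(depth_sum > 0, binom.cdf(alt_sum, np.maximum(depth_sum, 1), p0), 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "id": matrix.variants["id"],
        "germline_p": p,
        "germline_q": q,
        "germline": q >= alpha,
    })


def _betabin_logpmf(alt, depth, a, b):
    return (gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
            + gammaln(alt + a) + gammaln(depth - alt + b)
            - gammaln(depth + a + b) + gammaln(a + b)
            - gammaln(a) - gammaln(b))


def _rho_loglik(rho, alt, depth, mu):
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return _betabin_logpmf(alt, depth, a, b).sum(axis=-1)


def estimate_rho(alt, depth, grid_size: int = 200) -> float:
    """Maximum-likelihood beta-binomial overdispersion for one site.

    The mean is the pooled alt fraction (plug-in); rho is found by a
    coarse log-spaced grid scan followed by bounded one-dimensional
    refinement, which tracks the global optimum even on flat profiles.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if len(alt) != len(depth) or len(alt) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    if (depth > 0).sum() < 2:
        raise ValueError("need positive depth in at least 2 samples")
    keep = depth > 0
    alt, depth = alt[keep], depth[keep]
    mu = float(np.clip(alt.sum() / depth.sum(), 1e-6, 1 - 1e-6))

    grid = np.exp(np.linspace(np.log(RHO_LO), np.log(RHO_HI), grid_size))
    ll = _rho_loglik(grid[:, None], alt[None, :], depth[None, :], mu)
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    if lo == hi:
        return float(grid[best])
    res = minimize_scalar(lambda r: -float(_rho_loglik(r, alt, depth, mu)),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    return float(np.clip(res.x, RHO_LO, RHO_HI))


def estimate_rho_many(alt: np.ndarray, depth: np.ndarray,
                      grid_size: int = 200) -> np.ndarray:
    """Vectorized :func:`estimate_rho` over the rows of count matrices."""
    out = np.full(alt.shape[0], np.nan)
    for i in range(alt.shape[0]):
        d = depth[i]
        if (d > 0).sum() < 2:
            continue
        out[i] = estimate_rho(alt[i], d, grid_size=grid_size)
    return out


def overdispersion_filter(rho: float, kind: str = "SBS",
                          sbs_threshold: float = 0.1,
                          indel_threshold: float = 0.2) -> bool:
    """Keep a variant unless its overdispersion marks a shared artifact
    (strict: rho exactly at the threshold is kept)."""
    thr = sbs_threshold if kind == "SBS" else indel_threshold
    return not rho < thr


def run_filters(matrix: CountMatrix, alpha: float = 1e-5, p0: float = 0.5,
                rho_sbs: float = 0.1, rho_indel: float = 0.2,
                sbs_rules=None, indel_rules=None) -> pd.DataFrame:
    """Full cascade: quality -> germline -> overdispersion.

    Returns one row per variant with mutually exclusive ``status`` in
    {somatic, germline, artifact, low_quality}; rho is estimated only
    for variants passing the germline test.
    """
    qual_ok = quality_filter(matrix.variants, sbs_rules, indel_rules)
    germ = classify_germline(matrix, alpha=alpha, p0=p0)
    kinds = matrix.variants["kind"].to_numpy()

    status = np.full(len(matrix.variants), "somatic", dtype=object)
    rho = np.full(len(matrix.variants), np.nan)
    status[~qual_ok] = "low_quality"
    is_germ = germ["germline"].to_numpy() & qual_ok
    status[is_germ] = "germline"
    candidates = np.flatnonzero(qual_ok & ~is_germ)
    if len(candidates):
        rho[candidates] = estimate_rho_many(matrix.alt[candidates],
                                            matrix.depth[candidates])
        for i in candidates:
            kind = "SBS" if kinds[i] == "SBS" else "indel"
            if np.isnan(rho[i]):
                status[i] = "low_quality"
            elif not overdispersion_filter(rho[i], kind, rho_sbs, rho_indel):
                status[i] = "artifact"
    return pd.DataFrame({
        "id": matrix.variants["id"],
        "kind": kinds,
        "germline_p": germ["germline_p"],
        "germline_q": germ["germline_q"],
        "rho": rho,
        "status": status,
    })


@dataclass
class ClonalitySummary:
    sample: str
    n_variants: int
    median_vaf: float
    histogram: np.ndarray        # counts in bins of width 0.05 over [0, 1]
    is_clonal: bool | None       # None when no somatic variant is present


def clonality_summary(matrix: CountMatrix, sample: str,
                      somatic_mask: np.ndarray | None = None,
                      bin_width: float = 0.05,
                      clonal_median: float = 0.3) -> ClonalitySummary:
    """Median VAF and histogram over somatic variants present in a crypt.

    "Present" means at least one alt read.  A crypt whose median somatic
    VAF exceeds 0.3 is a single clonal unit (the criterion used to
    confirm crypts derive from one stem-cell lineage).
    """
    try:
        s = matrix.sample_ids.index(sample)
    except ValueError:
        raise KeyError(f"unknown sample {sample!r}")
    alt = matrix.alt[:, s]
    depth = matrix.depth[:, s]
    mask = (alt >= 1) & (depth > 0)
    if somatic_mask is not None:
        mask &= np.asarray(somatic_mask, dtype=bool)
    vafs = alt[mask] / depth[mask]
    edges = np.arange(0, 1 + bin_width, bin_width)
    hist, _ = np.histogram(vafs, bins=edges)
    if len(vafs) == 0:
        return ClonalitySummary(sample, 0, float("nan"), hist, None)
    med = float(np.median(vafs))
    return ClonalitySummary(sample, int(len(vafs)), med, hist,
                            med > clonal_median)
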