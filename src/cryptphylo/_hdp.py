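"""Gibbs kernel for the hierarchical Dirichlet process sampler.

Three-level Chinese-restaurant-franchise with direct cluster assignment:
a top-level DP over channel distributions, one DP per patient, one DP
per tree branch.  The inner per-mutation sweep is JIT-compiled; table
counts, stick weights, and concentration parameters are resampled in
numpy between sweeps (see :mod:`.signatures`).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def gibbs_sweep(z, c, branch_of_item, patient_of_branch,
                n_jk, M_kc, M_k, psi, beta, K, alpha0, alpha1, gamma_conc,
                base_conc, Kmax):
    """One sweep of direct-assignment Gibbs over all mutations.

    ``psi`` rows are patient-level cluster weights with the remainder
    mass at index K; ``beta`` is the global stick with remainder at K.
    New clusters split the remainder sticks.  Returns the new K.
    """
    n_items = z.shape[0]
    C = M_kc.shape[1]
    probs = np.empty(Kmax + 1)
    for i in range(n_items):
        j = branch_of_item[i]
        p = patient_of_branch[j]
        k_old = z[i]
        ci = c[i]
        n_jk[j, k_old] -= 1
        M_kc[k_old, ci] -= 1
        M_k[k_old] -= 1

        total = 0.0
        for k in range(K):
            f = (M_kc[k, ci] + base_conc) / (M_k[k] + C * base_conc)
            w = (n_jk[j, k] + alpha1 * psi[p, k]) * f
            probs[k] = w
            total += w
        w_new = alpha1 * psi[p, K] / C
        probs[K] = w_new
        total += w_new

        u = np.random.random() * total
        acc = 0.0
        k_new = K
        for k in range(K + 1):
            acc += probs[k]
            if u <= acc:
                k_new = k
                break

        if k_new == K:
            if K + 1 >= Kmax:
                k_new = k_old  # table full; keep previous assignment
            else:
                nu_g = np.random.beta(1.0, gamma_conc)
                b_new = nu_g * beta[K]
                beta[K + 1] = beta[K] - b_new
                beta[K] = b_new
                for q in range(psi.shape[0]):
                    a1 = alpha0 * b_new
                    a2 = alpha0 * beta[K + 1]
                    if a1 < 1e-8:
                        a1 = 1e-8
                    if a2 < 1e-8:
                        a2 = 1e-8
                    nu_p = np.random.beta(a1, a2)
                    p_new = nu_p * psi[q, K]
                    psi[q, K + 1] = psi[q, K] - p_new
                    psi[q, K] = p_new
                K += 1
        z[i] = k_new
        n_jk[j, k_new] += 1
        M_kc[k_new, ci] += 1
        M_k[k_new] += 1
    return K
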