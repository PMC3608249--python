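"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: kinship is
verified by gene-dropping simulation, GLS coefficients by explicit matrix
inversion, and effective test counts by permutation calibration of the
minimum p-value.
"""

from __future__ import annotations

import numpy as np


def gene_drop_kinship(ped, n_drops: int = 100_000, seed: int = 0):
    """Monte-Carlo kinship by gene dropping.

    Founders receive unique allele labels; each non-founder inherits one
    random allele from each parent.  The kinship estimate for (i, j) is
    the average over drops of the fraction of the four cross-pairs of
    alleles that are identical by descent.  Returns (phi_hat, mc_se) as
    dense arrays in pedigree order.
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    a1 = np.empty((n, n_drops), dtype=np.int32)
    a2 = np.empty((n, n_drops), dtype=np.int32)
    next_label = 0
    for i, iid in enumerate(order):
        ind = ped[iid]
        if ind.is_founder:
            a1[i] = next_label
            a2[i] = next_label + 1
            next_label += 2
        else:
            f, m = pos[ind.father_id], pos[ind.mother_id]
            pick_f = rng.integers(0, 2, n_drops, dtype=np.int8).astype(bool)
            pick_m = rng.integers(0, 2, n_drops, dtype=np.int8).astype(bool)
            a1[i] = np.where(pick_f, a1[f], a2[f])
            a2[i] = np.where(pick_m, a1[m], a2[m])
    phi_hat = np.zeros((n, n))
    mc_se = np.zeros((n, n))
    file_pos = [pos[iid] for iid in ped.ids]
    for ii, i in enumerate(file_pos):
        for jj, j in enumerate(file_pos):
            if jj < ii:
                continue
            s = (
                (a1[i] == a1[j]).astype(np.float64)
                + (a1[i] == a2[j])
                + (a2[i] == a1[j])
                + (a2[i] == a2[j])
            ) / 4.0
            m = s.mean()
            se = s.std(ddof=1) / np.sqrt(n_drops)
            phi_hat[ii, jj] = phi_hat[jj, ii] = m
            mc_se[ii, jj] = mc_se[jj, ii] = se
    return phi_hat, mc_se


def gls_beta(y, X, omega):
    """Generalized least squares by explicit inversion of the covariance."""
    Oi = np.linalg.inv(omega)
    XtOi = X.T @ Oi
    return np.linalg.solve(XtOi @ X, XtOi @ y)


def permutation_meff(corr, alpha: float = 0.05, n_sims: int = 20_000, seed: int = 0):
    """Effective test count calibrated from the null minimum p-value.

    Simulates correlated standard normals, converts to two-sided
    p-values, and solves P(min p < alpha) = 1 - (1 - alpha)^Meff.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(corr.shape[0]))
    z = rng.standard_normal((n_sims, corr.shape[0])) @ L.T
    p = 2.0 * stats.norm.sf(np.abs(z))
    hit = (p.min(axis=1) < alpha).mean()
    return np.log(1.0 - hit) / np.log(1.0 - alpha)
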