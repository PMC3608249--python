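"""Multiple-testing correction: effective test counts, thresholds, BH-FDR.

Correlated methylation units in one genomic region carry fewer than M
independent tests; the Li-Ji eigenvalue estimator converts the unit
correlation matrix into an effective test count Meff, from which per-test
Bonferroni or Sidak thresholds follow.  Benjamini-Hochberg FDR control is
provided for large probe panels (expression detection).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = ["effective_tests", "per_test_threshold", "bh_fdr"]


def effective_tests(corr: np.ndarray, psd_tol: float = 1e-6) -> float:
    """Li-Ji effective number of independent tests.

    From the eigenvalues lambda of the M x M correlation matrix,
    Meff = sum_i [ 1{lambda_i >= 1} + (lambda_i - floor(lambda_i)) ].
    Identity correlation gives M; perfect correlation gives 1.
    """
    C = np.asarray(corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(C)
    if lam.min() < -psd_tol:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)
    meff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return meff


def per_test_threshold(alpha: float, m_tests: float, method: str = "bonferroni") -> float:
    """Per-test significance threshold controlling the family-wise rate.

    ``bonferroni``: alpha / M.  ``sidak``: 1 - (1 - alpha)^(1/M).
    ``m_tests`` may be fractional (an effective test count).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if method == "bonferroni":
        return alpha / m_tests
    if method == "sidak":
        return 1.0 - (1.0 - alpha) ** (1.0 / m_tests)
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    Returns (selected_mask, adjusted_p) in the input order; adjusted
    values are monotone non-decreasing in p-value rank.  The selected set
    is always a prefix of the p-values sorted ascending.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    passing = ranked <= q * np.arange(1, m + 1) / m
    k = int(np.max(np.nonzero(passing)[0]) + 1) if passing.any() else 0
    selected_sorted = np.zeros(m, dtype=bool)
    selected_sorted[:k] = True
    selected = np.zeros(m, dtype=bool)
    adjusted = np.zeros(m)
    selected[order] = selected_sorted
    adjusted[order] = adj
    return selected, adjusted
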