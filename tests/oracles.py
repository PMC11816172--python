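"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written from the defining formula, not from the package's
algorithms: exact rational enumeration for the Hardy-Weinberg test,
recursive coancestry for relationship matrices, dense variance-matrix
algebra for REML/BLUP/GLS, and direct haplotype counting for LD.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hwe_exact_enumeration(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic."""
    n = n_hom_a + n_het + n_hom_b
    n_b = 2 * n_hom_b + n_het
    n_a = 2 * n - n_b
    rare = min(n_a, n_b)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_rare < 0 or hom_common < 0:
            continue
        # multinomial genotype count x 2^het phase factor
        ways = Fraction(
            comb(n, h) * comb(n - h, hom_rare) * 2**h
        )
        weights[h] = ways
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def kinship_recursive(parents: dict) -> dict:
    """Coancestry f(i, j) for all pairs via the classic recursion.

    ``parents`` maps animal -> (sire-or-None, dam-or-None); animals must be
    resolvable to a parents-first order (founders terminate the recursion).
    A[i, j] = 2 f(i, j); A[i, i] = 2 f(i, i) = 1 + F_i.
    """
    memo = {}
    depth = {}

    def _depth(x):
        if x is None:
            return -1
        if x not in depth:
            s, d = parents[x]
            depth[x] = 1 + max(_depth(s), _depth(d))
        return depth[x]

    def f(i, j):
        if i is None or j is None:
            return Fraction(0)
        key = (i, j) if i <= j else (j, i)
        if key in memo:
            return memo[key]
        if i == j:
            s, d = parents[i]
            val = Fraction(1, 2) * (1 + f(s, d))
        else:
            # recurse on the animal further from the founders
            if _depth(i) < _depth(j):
                i, j = j, i
            s, d = parents[i]
            val = Fraction(1, 2) * (f(s, j) + f(d, j))
        memo[key] = val
        return val

    return {(i, j): f(i, j) for i in parents for j in parents}


def a_matrix_recursive(parents: dict, order: list) -> np.ndarray:
    k = kinship_recursive(parents)
    n = len(order)
    a = np.empty((n, n))
    for x, i in zip(order, range(n)):
        for y, j in zip(order, range(n)):
            key = (x, y) if x <= y else (y, x)
            a[i, j] = float(2 * k[key])
    return a


def repeatability_model_v(record_animal, record_pe, a_matrix, theta):
    """Dense phenotypic covariance V for the repeated-records model."""
    sa2, sp2, se2 = theta
    n = len(record_animal)
    za = np.zeros((n, a_matrix.shape[0]))
    za[np.arange(n), record_animal] = 1.0
    n_pe = int(np.max(record_pe)) + 1
    wp = np.zeros((n, n_pe))
    wp[np.arange(n), record_pe] = 1.0
    return za @ a_matrix @ za.T * sa2 + wp @ wp.T * sp2 + np.eye(n) * se2


def restricted_loglik_dense(y, x, v):
    """-2 logL_R = log|V| + log|X'V^-1 X| + y'Py (constant dropped)."""
    vi = np.linalg.inv(v)
    xvx = x.T @ vi @ x
    beta = np.linalg.solve(xvx, x.T @ vi @ y)
    r = y - x @ beta
    ypy = float(r @ vi @ r)
    s1, ld_v = np.linalg.slogdet(v)
    s2, ld_x = np.linalg.slogdet(xvx)
    assert s1 > 0 and s2 > 0
    return -0.5 * (ld_v + ld_x + ypy)


def blup_dense(y, x, v, cross_cov):
    """GLS fixed effects and BLUP u = Cov(u, y) V^-1 (y - X b)."""
    vi = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    u = cross_cov @ vi @ (y - x @ beta)
    return beta, u


def gls_marker_scan(y, covariates, markers, v):
    """Dense GLS effect/SE/p per marker with known covariance V."""
    from scipy import stats

    vi = np.linalg.inv(v)
    out = []
    for j in range(markers.shape[1]):
        x = np.column_stack([covariates, markers[:, j]])
        xvx_inv = np.linalg.inv(x.T @ vi @ x)
        beta = xvx_inv @ (x.T @ vi @ y)
        se = np.sqrt(xvx_inv[-1, -1])
        z = beta[-1] / se
        out.append((beta[-1], se, 2 * stats.norm.sf(abs(z))))
    return np.array(out)


def haplotype_counting_r2(hap_a: np.ndarray, hap_b: np.ndarray):
    """LD r2 from known phased haplotypes by direct counting."""
    n = len(hap_a)
    f11 = np.mean((hap_a == 1) & (hap_b == 1))
    pa = np.mean(hap_a)
    pb = np.mean(hap_b)
    d = f11 - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))
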