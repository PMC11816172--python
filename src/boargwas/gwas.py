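"""Reliability-weighted single-SNP mixed-model association scan.

Model per trait: y = X b + g + e with y the DEBV vector, g ~ N(0, G sg2)
capturing polygenic background through the VanRaden genomic relationship
matrix, and e ~ N(0, R se2) with R = diag(1/weight_i) so high-reliability
DEBVs carry more information. Variance components are estimated once on
the null model (no marker), then each marker effect is tested by
generalized least squares with the covariance fixed at the null fit — a
two-step scheme that costs O(n) per marker after one eigendecomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .types import GenotypeData

__all__ = [
    "Grm",
    "NullModelFit",
    "GwasResult",
    "build_grm",
    "fit_null_model",
    "weighted_gwas",
    "inflation_factor",
    "fdr_qvalues",
    "variance_explained",
]

log = logging.getLogger(__name__)

CHI2_1_MEDIAN = 0.4549364231195724  # median of the 1-df chi-square


def _allele_freqs(d: np.ndarray) -> np.ndarray:
    """Per-column allele-B frequency; NaN for all-missing columns."""
    called = (~np.isnan(d)).sum(axis=0)
    totals = np.nansum(d, axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, totals / np.maximum(called, 1) / 2.0, np.nan)


@dataclass
class Grm:
    """VanRaden genomic relationship matrix with its allele frequencies."""

    values: np.ndarray
    allele_freqs: np.ndarray
    animal_ids: list

    def submatrix(self, ids) -> np.ndarray:
        idx = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [idx[str(a)] for a in ids]
        return self.values[np.ix_(rows, rows)]


@dataclass
class NullModelFit:
    sigma_g2: float
    sigma_e2: float
    eigenvalues: np.ndarray       # of W^{1/2} G W^{1/2} (W = diag(weights))
    eigenvectors: np.ndarray
    sqrt_w: np.ndarray
    animal_ids: list
    log_likelihood: float
    identifiability_warning: bool = False


@dataclass
class GwasResult:
    table: pd.DataFrame           # marker, chrom, pos, maf, beta, se, p, q, gvar_pct
    trait: str
    lambda_gc: float
    sigma_g2: float
    sigma_e2: float
    n_animals: int
    skipped: dict = field(default_factory=dict)

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < fdr]


def build_grm(geno: GenotypeData, ridge: float = 1e-6) -> Grm:
    """VanRaden method-1 GRM: G = M M' / (2 sum p_j (1 - p_j)).

    M is the dosage matrix centered by twice the sample allele frequency;
    missing dosages are mean-imputed (zero after centering); monomorphic
    markers are excluded. A small ridge keeps G invertible.
    """
    d = geno.dosages.copy()
    p = _allele_freqs(d)
    with np.errstate(invalid="ignore"):
        poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic markers; cannot build a GRM")
    d = d[:, poly]
    p = p[poly]
    m = d - 2.0 * p
    m[np.isnan(m)] = 0.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    g = (m @ m.T) / denom
    g[np.diag_indices_from(g)] += ridge
    return Grm(values=g, allele_freqs=p, animal_ids=list(geno.animal_ids))


def fit_null_model(
    debv: np.ndarray,
    weights: np.ndarray,
    grm: Grm | np.ndarray,
    animal_ids: list | None = None,
) -> NullModelFit:
    """REML fit of y = 1 mu + g + e, Var(y) = G sg2 + diag(1/w) se2.

    Whitening by sqrt(w) reduces the problem to a single-kernel mixed model
    solved by one eigendecomposition and a 1-D optimization over the
    variance ratio (the standard spectral trick for one random effect).
    The spectrum is cached for the per-marker tests.
    """
    y = np.asarray(debv, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    g = grm.values if isinstance(grm, Grm) else np.asarray(grm)
    ids = animal_ids or (grm.animal_ids if isinstance(grm, Grm) else list(range(len(y))))
    n = len(y)
    if g.shape != (n, n):
        raise ValueError("GRM shape does not match phenotype length")
    sw = np.sqrt(w)
    g_w = g * sw[:, None] * sw[None, :]
    evals, evecs = np.linalg.eigh(g_w)
    evals = np.maximum(evals, 0.0)
    y_rot = evecs.T @ (sw * y)
    x_rot = evecs.T @ sw  # rotated intercept column

    def neg_restricted_ll(log_delta: float) -> float:
        # delta = se2 / sg2; profile out sg2 and mu
        delta = np.exp(log_delta)
        d = evals + delta
        xvx = np.sum(x_rot**2 / d)
        beta = np.sum(x_rot * y_rot / d) / xvx
        r = y_rot - x_rot * beta
        rss = np.sum(r**2 / d)
        sg2 = rss / (n - 1)
        ll = -0.5 * (
            np.sum(np.log(d)) + np.log(xvx) + (n - 1) * (np.log(sg2) + 1.0)
        )
        return -ll

    grid = np.linspace(-12.0, 12.0, 49)
    vals = np.array([neg_restricted_ll(x) for x in grid])
    flat = vals.max() - vals.min() < 1e-6
    if flat:
        log.warning(
            "null model: variance components unidentifiable (flat likelihood); "
            "returning an even split of the total variance"
        )
        best = 0.0
    else:
        j = int(np.argmin(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        res = minimize_scalar(
            neg_restricted_ll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        best = float(res.x)
    delta = np.exp(best)
    d = evals + delta
    xvx = np.sum(x_rot**2 / d)
    beta = np.sum(x_rot * y_rot / d) / xvx
    r = y_rot - x_rot * beta
    sg2 = float(np.sum(r**2 / d) / (n - 1))
    se2 = float(delta * sg2)
    return NullModelFit(
        sigma_g2=sg2,
        sigma_e2=se2,
        eigenvalues=evals,
        eigenvectors=evecs,
        sqrt_w=sw,
        animal_ids=list(ids),
        log_likelihood=-neg_restricted_ll(best),
        identifiability_warning=bool(flat),
    )


def weighted_gwas(
    debv: np.ndarray,
    weights: np.ndarray,
    geno: GenotypeData,
    grm: Grm,
    trait: str = "",
    fdr_method: str = "storey",
) -> GwasResult:
    """Per-marker GLS scan with covariance fixed at the null REML fit.

    Monomorphic or all-missing markers are skipped (counted). Missing
    dosages are mean-imputed per marker. Returns effects in DEBV units,
    Wald p-values, q-values, the genomic inflation factor, and the
    percentage of genetic variance explained per marker.
    """
    null = fit_null_model(debv, weights, grm, animal_ids=geno.animal_ids)
    y = np.asarray(debv, dtype=float)
    n = len(y)
    d = geno.dosages.copy()
    p_freq = _allele_freqs(d)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p_freq, 1.0 - p_freq)
        all_missing = np.isnan(d).all(axis=0)
        mono = ~all_missing & ((p_freq <= 0) | (p_freq >= 1))
    usable = ~all_missing & ~mono
    skipped = {
        "all_missing": int(all_missing.sum()),
        "monomorphic": int(mono.sum()),
    }
    # mean-impute and rotate into the null model's spectral basis
    inds = np.where(np.isnan(d))
    d[inds] = (2.0 * p_freq)[inds[1]]
    u, evals, sw = null.eigenvectors, null.eigenvalues, null.sqrt_w
    var_diag = null.sigma_g2 * evals + null.sigma_e2
    inv_v = 1.0 / var_diag
    y_rot = u.T @ (sw * y)
    ones_rot = u.T @ sw
    x_rot = u.T @ (sw[:, None] * d[:, usable])

    # GLS for [intercept, marker] per marker, vectorized across markers
    a11 = np.sum(ones_rot**2 * inv_v)
    a12 = x_rot.T @ (ones_rot * inv_v)
    a22 = np.sum(x_rot**2 * inv_v[:, None], axis=0)
    b1 = np.sum(ones_rot * y_rot * inv_v)
    b2 = x_rot.T @ (y_rot * inv_v)
    det = a11 * a22 - a12**2
    beta = (a11 * b2 - a12 * b1) / det
    se_beta = np.sqrt(a11 / det)
    z = beta / se_beta
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.maximum(pvals, np.finfo(float).tiny)

    qvals = fdr_qvalues(pvals, method=fdr_method)
    lam = inflation_factor(pvals)
    gvar = np.array(
        [
            variance_explained(b, mf, null.sigma_g2)
            if 0 < mf <= 0.5
            else np.nan
            for b, mf in zip(beta, maf[usable])
        ]
    )
    table = pd.DataFrame(
        {
            "marker": geno.marker_map.loc[usable, "marker"].to_numpy(),
            "chrom": geno.marker_map.loc[usable, "chrom"].to_numpy(),
            "pos": geno.marker_map.loc[usable, "pos"].to_numpy(),
            "maf": maf[usable],
            "beta": beta,
            "se": se_beta,
            "p": pvals,
            "q": qvals,
            "gvar_pct": gvar,
        }
    )
    return GwasResult(
        table=table,
        trait=trait,
        lambda_gc=lam,
        sigma_g2=null.sigma_g2,
        sigma_e2=null.sigma_e2,
        n_animals=n,
        skipped=skipped,
    )


def inflation_factor(p_values) -> float:
    """Genomic inflation factor: median observed 1-df chi-square / 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def _storey_pi0(p: np.ndarray) -> float:
    """Storey pi0 on the lambda grid 0.05..0.95 with a cubic smoother."""
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > la).mean() / (1.0 - la) for la in lam])
    if np.all(pi0_lam <= 0):
        return 1.0
    coeffs = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, lam.max()))
    return float(np.clip(pi0, 1e-8, 1.0))


def fdr_qvalues(p_values, method: str = "storey") -> np.ndarray:
    """q-values by Benjamini-Hochberg, optionally rescaled by Storey's pi0.

    ``method="bh"`` fixes pi0 = 1 (plain BH step-up). ``method="storey"``
    estimates the null proportion on a lambda grid with cubic-polynomial
    extrapolation and multiplies the BH-adjusted values, enforcing
    monotonicity in the p-value ranking.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, bh, _, _ = multipletests(p, method="fdr_bh")
    if method == "bh":
        return bh
    if method != "storey":
        raise ValueError(f"unknown FDR method {method!r}")
    pi0 = _storey_pi0(p) if p.size >= 20 else 1.0
    q = np.minimum(pi0 * bh, 1.0)
    # enforce monotone non-decreasing q along the p ranking
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate(q[order][::-1])[::-1]
    out = np.empty_like(q)
    out[order] = q_sorted
    return out


def variance_explained(beta: float, maf: float, sigma_g2: float) -> float:
    """Percent of genetic variance from one marker: 100 * 2pq beta^2 / sg2."""
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    return float(100.0 * 2.0 * maf * (1.0 - maf) * beta**2 / sigma_g2)
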