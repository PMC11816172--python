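"""Phenotype and genotype quality control.

Record-level phenotype filters (volume, motility, collection interval)
followed by a per-animal minimum-collection rule; marker filters (unmapped,
call rate, MAF, Hardy-Weinberg exact test) applied in a fixed order; and a
genotype PCA used as a sample-outlier diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
import pandas as pd

from .types import GenotypeData, PhenotypeTable

__all__ = [
    "QcReport",
    "filter_phenotypes",
    "hwe_exact_test",
    "genotype_qc",
    "genotype_pca",
]

# Default marker-QC thresholds (call rate, MAF, HWE exact p).
CALL_RATE_MIN = 0.9
MAF_MIN = 0.01
HWE_MIN = 1e-6
MIN_COLLECTIONS = 5
VOLUME_MIN_ML = 50.0  # records with volume <= this are removed
MOTILITY_MIN_PCT = 10.0  # records with motility < this are removed
INTERVAL_MAX_DAYS = 60  # records with interval > this (or == 0) are removed


@dataclass
class QcReport:
    """Counts removed/retained per rule plus optional per-marker statistics."""

    removed: dict = field(default_factory=dict)  # rule -> count removed
    retained: int = 0
    input_count: int = 0
    marker_stats: pd.DataFrame | None = None  # call_rate, maf, hwe_p per marker
    pca_coordinates: pd.DataFrame | None = None
    pca_variance_fractions: np.ndarray | None = None
    notes: list = field(default_factory=list)

    def check_additive(self) -> bool:
        return self.input_count == self.retained + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed": dict(self.removed),
            "retained": self.retained,
            "notes": list(self.notes),
        }


def filter_phenotypes(records: PhenotypeTable) -> tuple[PhenotypeTable, QcReport]:
    """Apply the semen-record QC rules.

    Record-level rules run first, in order: volume <= 50 mL removed;
    sperm motility < 10% removed; collection interval > 60 days or exactly
    0 days removed (an animal's first record has no interval and is exempt).
    Finally animals with fewer than 5 surviving collections are excluded
    entirely.
    """
    df = records.df.copy()
    report = QcReport(input_count=len(df))
    report.notes.append(
        "min-collections rule applied to post-filter record counts"
    )

    keep = df["volume_ml"] > VOLUME_MIN_ML
    report.removed["volume_le_50ml"] = int((~keep).sum())
    df = df[keep]

    keep = df["spmot"] >= MOTILITY_MIN_PCT
    report.removed["motility_lt_10pct"] = int((~keep).sum())
    df = df[keep]

    # intervals between records surviving the volume/motility rules; the
    # first record per animal has no interval and is exempt
    interval = df.groupby("animal")["date"].diff().dt.days
    bad = (interval > INTERVAL_MAX_DAYS) | (interval == 0)
    report.removed["interval_gt_60d_or_0d"] = int(bad.sum())
    df = df[~bad]

    counts = df.groupby("animal")["date"].transform("size")
    keep = counts >= MIN_COLLECTIONS
    report.removed["animal_lt_5_collections"] = int((~keep).sum())
    df = df[keep]

    df = df.copy()
    df["interval_days"] = df.groupby("animal")["date"].diff().dt.days.astype(float)
    report.retained = len(df)
    return PhenotypeTable(df.reset_index(drop=True)), report


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts; enumerates every heterozygote
    count of the same parity and sums the probabilities of configurations no
    more probable than the observed one (two-sided by probability mass,
    no mid-p).
    """
    counts = (n_aa_hom, n_het, n_bb_hom)
    if any(c < 0 for c in counts):
        raise ValueError("negative genotype count")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_b = 2 * n_bb_hom + n_het  # copies of one allele
    n_a = 2 * n - n_b
    rare = min(n_a, n_b)
    # attainable het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    log_probs = np.empty(len(hets), dtype=float)
    base = (
        lgamma(n + 1)
        + lgamma(n_a + 1)
        + lgamma(n_b + 1)
        - lgamma(2 * n + 1)
    )
    for i, h in enumerate(hets):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        log_probs[i] = (
            base
            + h * log(2.0)
            - lgamma(h + 1)
            - lgamma(hom_rare + 1)
            - lgamma(hom_common + 1)
        )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def genotype_qc(
    geno: GenotypeData,
    call_rate_min: float = CALL_RATE_MIN,
    maf_min: float = MAF_MIN,
    hwe_min: float = HWE_MIN,
) -> tuple[GenotypeData, QcReport]:
    """Marker QC in fixed order: unmapped -> call rate -> MAF -> HWE.

    Call rate, MAF and HWE are computed on non-missing dosages; each filter
    sees only markers surviving the previous ones.
    """
    report = QcReport(input_count=geno.n_markers)
    d = geno.dosages
    mapped = (geno.marker_map["pos"].to_numpy() > 0) & geno.marker_map[
        "chrom"
    ].astype(str).ne("0").to_numpy()
    report.removed["unmapped"] = int((~mapped).sum())

    call_rate = 1.0 - np.isnan(d).mean(axis=0)
    fail_cr = mapped & (call_rate < call_rate_min)
    report.removed["call_rate"] = int(fail_cr.sum())
    alive = mapped & ~fail_cr

    maf = geno.maf()
    with np.errstate(invalid="ignore"):
        fail_maf = alive & ((maf < maf_min) | np.isnan(maf))
    report.removed["maf"] = int(fail_maf.sum())
    alive &= ~fail_maf

    hwe_p = np.ones(geno.n_markers)
    for j in np.flatnonzero(alive):
        col = d[:, j]
        col = col[~np.isnan(col)]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        hwe_p[j] = hwe_exact_test(n0, n1, n2)
    fail_hwe = alive & (hwe_p < hwe_min)
    report.removed["hwe"] = int(fail_hwe.sum())
    alive &= ~fail_hwe

    report.retained = int(alive.sum())
    report.marker_stats = pd.DataFrame(
        {
            "marker": geno.marker_map["marker"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "retained": alive,
        }
    )
    return geno.subset_markers(alive), report


def genotype_pca(geno: GenotypeData, k: int) -> QcReport:
    """Top-k PCA of standardized dosages, for sample-outlier checks.

    Missing dosages are mean-imputed per marker; markers are centered by 2p
    and scaled by sqrt(2p(1-p)); monomorphic markers are skipped. Variance
    fractions are relative to the total variance of the standardized matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(geno.n_animals, geno.n_markers):
        raise ValueError(
            f"k={k} exceeds min(n_animals, n_markers)="
            f"{min(geno.n_animals, geno.n_markers)}"
        )
    d = geno.dosages.copy()
    p = np.nanmean(d, axis=0) / 2.0
    inds = np.where(np.isnan(d))
    d[inds] = (2.0 * p)[inds[1]]
    poly = (p > 0) & (p < 1)
    d = d[:, poly]
    p = p[poly]
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z -= z.mean(axis=0)  # remove residual centering from imputation
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    total = (s**2).sum()
    coords = u[:, :k] * s[:k]
    report = QcReport(input_count=geno.n_animals, retained=geno.n_animals)
    report.pca_coordinates = pd.DataFrame(
        coords,
        index=geno.animal_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    report.pca_variance_fractions = (s[:k] ** 2) / total
    return report
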