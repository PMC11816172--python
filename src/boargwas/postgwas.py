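"""Candidate-gene windows, cis-eQTL scanning, LD, and co-localization.

Significant association signals are annotated with every gene whose body
intersects a +/-1 Mb window around the marker. Genotype-expression
association (cis-eQTL) is a per-gene simple regression of log-transformed
expression on dosage within the cis window. LD between marker pairs is
computed from EM-fitted two-locus haplotype frequencies on unphased
genotypes, and co-localization links a GWAS signal to a gene either
directly (the signal is itself an eQTL) or through a proxy eQTL in high LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, GeneAnnotation, GenotypeData

__all__ = [
    "GeneWindowHit",
    "EqtlRecord",
    "LdPair",
    "LsdResult",
    "annotate_genes",
    "cis_eqtl_scan",
    "ld_r2",
    "lsd_genotype_expression",
    "colocalize",
]

log = logging.getLogger(__name__)

WINDOW_BP = 1_000_000  # candidate-gene window half-width around a marker


@dataclass
class GeneWindowHit:
    marker: str
    chrom: str
    pos: int
    window_start: int
    window_end: int
    genes: pd.DataFrame  # gene_id, gene_name, start_bp, end_bp, distance_bp


@dataclass
class LdPair:
    marker_a: str
    marker_b: str
    r2: float
    d: float
    hap_freqs: dict  # haplotype label (e.g. 'AB') -> frequency
    n: int


@dataclass
class LsdResult:
    omnibus_p: float
    group_means: dict
    group_counts: dict
    pairwise: pd.DataFrame  # group_a, group_b, diff, p, stars
    ms_within: float
    df_within: int
    degenerate: bool = False


def annotate_genes(
    hits: pd.DataFrame,
    genes: GeneAnnotation,
    window_bp: int = WINDOW_BP,
) -> list[GeneWindowHit]:
    """Genes overlapping [max(1, pos - window), pos + window] per hit.

    ``hits`` needs columns marker, chrom, pos. Overlap is 1-based inclusive
    on both sides and strand-agnostic; genes are sorted by distance to the
    marker (0 when the marker lies inside the gene body).
    """
    gdf = genes.df
    out = []
    known_chroms = set(gdf["chrom"])
    for _, hit in hits.iterrows():
        chrom = str(hit["chrom"])
        pos = int(hit["pos"])
        lo = max(1, pos - window_bp)
        hi = pos + window_bp
        if chrom not in known_chroms:
            log.warning("annotate_genes: chromosome %s absent from annotation", chrom)
            sub = gdf.iloc[0:0].copy()
        else:
            on = gdf[gdf["chrom"] == chrom]
            sub = on[(on["end_bp"] >= lo) & (on["start_bp"] <= hi)].copy()
        dist = np.where(
            (sub["start_bp"] <= pos) & (pos <= sub["end_bp"]),
            0,
            np.minimum(
                np.abs(sub["start_bp"] - pos), np.abs(sub["end_bp"] - pos)
            ),
        )
        sub["distance_bp"] = dist.astype(int) if len(sub) else dist
        sub = sub.sort_values(["distance_bp", "start_bp"]).reset_index(drop=True)
        out.append(
            GeneWindowHit(
                marker=str(hit["marker"]),
                chrom=chrom,
                pos=pos,
                window_start=lo,
                window_end=hi,
                genes=sub[
                    ["gene_id", "gene_name", "start_bp", "end_bp", "distance_bp"]
                ],
            )
        )
    return out


def cis_eqtl_scan(
    expr: ExpressionMatrix,
    geno: GenotypeData,
    genes: GeneAnnotation,
    cis_window_bp: int = WINDOW_BP,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene regression of expression on dosage within the cis window.

    Expression is log(x + 1)-transformed by default before regression.
    Samples are matched to genotyped animals by id; genes absent from the
    annotation or with zero expression variance are skipped (counted in the
    log). Returns a table (gene_id, marker, tissue, beta, se, p, n_samples).
    """
    shared = [s for s in expr.samples if s in set(geno.animal_ids)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 expression samples match genotyped animals")
    sub_geno = geno.subset_animals(shared)
    values = expr.values[shared]
    mm = sub_geno.marker_map
    skipped_zero_var = 0
    skipped_unannotated = 0
    rows = []
    gdf = genes.df.set_index("gene_id")
    for gene_id in values.index:
        if gene_id not in gdf.index:
            skipped_unannotated += 1
            continue
        g = gdf.loc[gene_id]
        yv = values.loc[gene_id].to_numpy(dtype=float)
        if log_transform:
            yv = np.log(yv + 1.0)
        if np.var(yv) == 0:
            skipped_zero_var += 1
            continue
        in_cis = (
            (mm["chrom"] == str(g["chrom"]))
            & (mm["pos"] >= g["start_bp"] - cis_window_bp)
            & (mm["pos"] <= g["end_bp"] + cis_window_bp)
        ).to_numpy()
        for j in np.flatnonzero(in_cis):
            x = sub_geno.dosages[:, j]
            ok = ~np.isnan(x)
            if ok.sum() < 3 or np.var(x[ok]) == 0:
                continue
            beta, se, p, n_used = _simple_regression(x[ok], yv[ok])
            rows.append(
                {
                    "gene_id": gene_id,
                    "marker": mm["marker"].iloc[j],
                    "tissue": expr.tissue,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "n_samples": n_used,
                }
            )
    if skipped_zero_var or skipped_unannotated:
        log.info(
            "cis_eqtl_scan: skipped %d zero-variance and %d unannotated genes",
            skipped_zero_var,
            skipped_unannotated,
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "marker", "tissue", "beta", "se", "p", "n_samples"]
    )


def _simple_regression(x: np.ndarray, y: np.ndarray):
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    dof = n - 2
    if dof <= 0:
        return beta, np.nan, np.nan, n
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 / sxx)
    if se == 0:
        p = np.finfo(float).tiny
    else:
        p = float(2.0 * stats.t.sf(abs(beta / se), dof))
        p = max(p, np.finfo(float).tiny)
    return beta, se, p, n


def ld_r2(
    geno: GenotypeData,
    marker_a: str,
    marker_b: str,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LdPair:
    """LD between two markers from EM haplotype frequencies.

    Unphased two-locus genotypes determine haplotype counts exactly except
    for double heterozygotes, whose two phase configurations are resolved
    iteratively (EM from linkage equilibrium). r2 = D^2 / (pA pa pB pb).
    """
    mm = geno.marker_map["marker"]
    try:
        ja = mm[mm == marker_a].index[0]
        jb = mm[mm == marker_b].index[0]
    except IndexError:
        raise KeyError(f"marker not found: {marker_a!r} or {marker_b!r}")
    ga = geno.dosages[:, ja]
    gb = geno.dosages[:, jb]
    ok = ~np.isnan(ga) & ~np.isnan(gb)
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    n = len(ga)
    if n == 0:
        raise ValueError("no animals with both markers called")
    if len(np.unique(ga)) < 2 or len(np.unique(gb)) < 2:
        raise ValueError("monomorphic marker; LD undefined")
    # genotype table counts; alleles: A/a = absent/present copies of allele_B
    counts = np.zeros((3, 3))
    np.add.at(counts, (ga, gb), 1.0)
    p_b1 = ga.mean() / 2.0  # freq of allele coded 1 at marker a
    p_b2 = gb.mean() / 2.0
    # haplotype freqs order: (0,0), (0,1), (1,0), (1,1)
    f = np.array(
        [
            (1 - p_b1) * (1 - p_b2),
            (1 - p_b1) * p_b2,
            p_b1 * (1 - p_b2),
            p_b1 * p_b2,
        ]
    )
    n_dh = counts[1, 1]  # double heterozygotes
    # fixed haplotype contributions from the 8 unambiguous cells
    base = np.zeros(4)
    base[0] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    base[1] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[2] = 2 * counts[2, 0] + counts[1, 0] + counts[2, 1]
    base[3] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    total = 2.0 * n
    for _ in range(max_iter):
        # P(phase = cis | double het): cis carries (0,0)+(1,1)
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        frac = 0.5 if (cis + trans) == 0 else cis / (cis + trans)
        new = base.copy()
        new[0] += n_dh * frac
        new[3] += n_dh * frac
        new[1] += n_dh * (1 - frac)
        new[2] += n_dh * (1 - frac)
        new /= total
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    pa0, pa1 = f[0] + f[1], f[2] + f[3]
    pb0, pb1 = f[0] + f[2], f[1] + f[3]
    d_coef = f[3] - pa1 * pb1
    denom = pa0 * pa1 * pb0 * pb1
    r2 = float(d_coef**2 / denom) if denom > 0 else np.nan
    return LdPair(
        marker_a=marker_a,
        marker_b=marker_b,
        r2=min(r2, 1.0),
        d=float(d_coef),
        hap_freqs={"00": f[0], "01": f[1], "10": f[2], "11": f[3]},
        n=n,
    )


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, mark in _STAR_LEVELS:
        if p < level:
            return mark
    return "ns"


def lsd_genotype_expression(expr_values, dosages) -> LsdResult:
    """One-way ANOVA across genotype classes plus LSD pairwise comparisons.

    The least-significant-difference procedure: pairwise two-sided t-tests
    using the pooled within-group mean square and its degrees of freedom,
    with no multiplicity correction. Classes with fewer than 2 samples are
    skipped pair-wise (flagged with NaN p). Stars follow the
    */**/*** < 0.05/0.01/0.001 convention.
    """
    y = np.asarray(expr_values, dtype=float)
    g = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(g)
    y, g = y[ok], g[ok]
    levels = np.unique(g)
    groups = {lv: y[g == lv] for lv in levels}
    sizable = [lv for lv in levels if len(groups[lv]) >= 2]
    if len(sizable) < 2:
        raise ValueError("need >= 2 genotype classes with >= 2 samples each")
    pooled_n = sum(len(groups[lv]) for lv in levels)
    df_within = pooled_n - len(levels)
    ss_within = sum(
        float(np.sum((groups[lv] - groups[lv].mean()) ** 2)) for lv in levels
    )
    ms_within = ss_within / df_within
    means = {float(lv): float(groups[lv].mean()) for lv in levels}
    counts = {float(lv): int(len(groups[lv])) for lv in levels}
    if ms_within == 0:
        return LsdResult(
            omnibus_p=np.nan,
            group_means=means,
            group_counts=counts,
            pairwise=pd.DataFrame(
                columns=["group_a", "group_b", "diff", "p", "stars"]
            ),
            ms_within=0.0,
            df_within=df_within,
            degenerate=True,
        )
    grand = y.mean()
    ss_between = sum(
        len(groups[lv]) * (groups[lv].mean() - grand) ** 2 for lv in levels
    )
    df_between = len(levels) - 1
    f_stat = (ss_between / df_between) / ms_within
    omnibus_p = float(stats.f.sf(f_stat, df_between, df_within))
    rows = []
    for i, lv_a in enumerate(levels):
        for lv_b in levels[i + 1 :]:
            na, nb = len(groups[lv_a]), len(groups[lv_b])
            if na < 2 or nb < 2:
                rows.append(
                    {
                        "group_a": float(lv_a),
                        "group_b": float(lv_b),
                        "diff": float(groups[lv_b].mean() - groups[lv_a].mean()),
                        "p": np.nan,
                        "stars": "ns",
                    }
                )
                continue
            diff = float(groups[lv_b].mean() - groups[lv_a].mean())
            se = np.sqrt(ms_within * (1.0 / na + 1.0 / nb))
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), df_within))
            rows.append(
                {
                    "group_a": float(lv_a),
                    "group_b": float(lv_b),
                    "diff": diff,
                    "p": p,
                    "stars": _stars(p),
                }
            )
    return LsdResult(
        omnibus_p=omnibus_p,
        group_means=means,
        group_counts=counts,
        pairwise=pd.DataFrame(rows),
        ms_within=ms_within,
        df_within=df_within,
    )


def colocalize(
    gwas_hits: pd.DataFrame,
    eqtls: pd.DataFrame,
    geno: GenotypeData,
    genes: GeneAnnotation,
    ld_threshold: float = 0.8,
    eqtl_fdr: float = 0.05,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Link significant GWAS markers to window genes through eQTL evidence.

    eQTL significance is FDR < ``eqtl_fdr`` per tissue (q-values across all
    tested gene-marker pairs). Mechanisms reported: ``direct`` when the
    GWAS marker is itself a significant eQTL of a window gene (r2 = 1), and
    ``ld`` when a significant eQTL marker of a window gene has
    r2 >= ``ld_threshold`` with the GWAS marker.
    """
    from .gwas import fdr_qvalues

    if eqtls.empty or gwas_hits.empty:
        return pd.DataFrame(
            columns=["marker", "gene_id", "tissue", "mechanism", "eqtl_marker", "r2"]
        )
    eq = eqtls.copy()
    eq["q"] = np.nan
    for tissue, idx in eq.groupby("tissue").groups.items():
        eq.loc[idx, "q"] = fdr_qvalues(eq.loc[idx, "p"].to_numpy())
    sig_eq = eq[eq["q"] < eqtl_fdr]
    windows = annotate_genes(gwas_hits, genes, window_bp=window_bp)
    rows = []
    for hit in windows:
        window_genes = set(hit.genes["gene_id"])
        cand = sig_eq[sig_eq["gene_id"].isin(window_genes)]
        for _, e in cand.iterrows():
            if e["marker"] == hit.marker:
                rows.append(
                    {
                        "marker": hit.marker,
                        "gene_id": e["gene_id"],
                        "tissue": e["tissue"],
                        "mechanism": "direct",
                        "eqtl_marker": e["marker"],
                        "r2": 1.0,
                    }
                )
                continue
            try:
                pair = ld_r2(geno, hit.marker, e["marker"])
            except (KeyError, ValueError):
                continue
            if pair.r2 >= ld_threshold:
                rows.append(
                    {
                        "marker": hit.marker,
                        "gene_id": e["gene_id"],
                        "tissue": e["tissue"],
                        "mechanism": "ld",
                        "eqtl_marker": e["marker"],
                        "r2": pair.r2,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["marker", "gene_id", "tissue", "mechanism", "eqtl_marker", "r2"]
    )
    return out.drop_duplicates().reset_index(drop=True)
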