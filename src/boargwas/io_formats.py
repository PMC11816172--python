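"""Readers and writers for every external format the pipeline touches.

Supported on the way in: PLINK text PED/MAP genotypes, CSV pedigree and
phenotype tables, GFF3 or BED gene annotation, TSV expression matrices.
On the way out: tab-separated result tables with a stable column order and
``NA`` for missing cells. All other modules consume only the in-memory
types from :mod:`boargwas.types`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    FormatError,
    GeneAnnotation,
    GenotypeData,
    PedigreeTable,
    PhenotypeTable,
)

__all__ = [
    "read_plink_text",
    "write_plink_text",
    "read_pedigree_csv",
    "read_phenotypes_csv",
    "read_gene_annotation",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_tables",
    "write_results",
    "read_results",
]

_VALID_ALLELES = frozenset("ACGT0")
_FLOAT_FMT = "%.6g"


def read_plink_text(ped_path, map_path) -> GenotypeData:
    """Read PLINK text PED/MAP into a :class:`GenotypeData`.

    Dosage counts copies of allele_B, the per-file minor allele, recorded in
    the returned marker map so the orientation is reproducible. ``0 0``
    allele pairs become missing. Row order of the PED file is preserved.
    """
    mp = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "marker", "cm", "pos"],
        dtype={"chrom": str, "marker": str},
    )
    n_markers = len(mp)
    animal_ids = []
    a1 = []  # per animal: first allele per marker
    a2 = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} markers, found {len(fields)}"
                )
            alleles = fields[6:]
            bad = set(alleles) - _VALID_ALLELES
            if bad:
                raise FormatError(
                    f"{ped_path}:{lineno}: non-ACGT0 allele code {sorted(bad)[0]!r}"
                )
            animal_ids.append(fields[1])
            a1.append(alleles[0::2])
            a2.append(alleles[1::2])
    a1 = np.array(a1, dtype="U1") if a1 else np.empty((0, n_markers), dtype="U1")
    a2 = np.array(a2, dtype="U1") if a2 else np.empty((0, n_markers), dtype="U1")

    allele_a = np.empty(n_markers, dtype="U1")
    allele_b = np.empty(n_markers, dtype="U1")
    dosages = np.full((len(animal_ids), n_markers), np.nan)
    for j in range(n_markers):
        c1, c2 = a1[:, j], a2[:, j]
        called = (c1 != "0") & (c2 != "0")
        if (c1 == "0").any() or (c2 == "0").any():
            half = ((c1 == "0") ^ (c2 == "0")).any()
            if half:
                raise FormatError(
                    f"{ped_path}: marker {mp['marker'][j]} has a half-missing "
                    "genotype ('0' paired with a called allele)"
                )
        obs = np.concatenate([c1[called], c2[called]])
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) == 0:
            allele_a[j], allele_b[j] = "0", "0"
            continue
        if len(uniq) > 2:
            raise FormatError(
                f"{ped_path}: marker {mp['marker'][j]} has >2 alleles: {list(uniq)}"
            )
        # minor allele = allele_B; ties broken alphabetically for determinism
        order = np.lexsort((uniq, counts))
        if len(uniq) == 1:
            allele_b[j] = uniq[0]
            allele_a[j] = uniq[0]
        else:
            allele_b[j] = uniq[order[0]]
            allele_a[j] = uniq[order[1]]
        dosages[called, j] = (c1[called] == allele_b[j]).astype(float) + (
            c2[called] == allele_b[j]
        )
    marker_map = pd.DataFrame(
        {
            "marker": mp["marker"],
            "chrom": mp["chrom"],
            "pos": mp["pos"].astype(int),
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    return GenotypeData(dosages, marker_map, animal_ids)


def write_plink_text(geno: GenotypeData, ped_path, map_path) -> None:
    """Write genotypes as PLINK text PED/MAP (inverse of read_plink_text)."""
    mm = geno.marker_map
    with open(map_path, "w") as fh:
        for _, row in mm.iterrows():
            fh.write(f"{row['chrom']}\t{row['marker']}\t0\t{row['pos']}\n")
    aa = mm["allele_a"].to_numpy(dtype="U1")
    ab = mm["allele_b"].to_numpy(dtype="U1")
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(geno.animal_ids):
            d = geno.dosages[i]
            first = np.where(d >= 1, ab, aa)
            second = np.where(d == 2, ab, aa)
            miss = np.isnan(d)
            first[miss] = "0"
            second[miss] = "0"
            pairs = " ".join(f"{x} {y}" for x, y in zip(first, second))
            fh.write(f"FAM {animal} 0 0 0 -9 {pairs}\n")


def read_pedigree_csv(path) -> PedigreeTable:
    """Read an animal/sire/dam CSV; blank, 0, '.' or NA parents are unknown."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return PedigreeTable(df[["animal", "sire", "dam"]])


def read_phenotypes_csv(path) -> PhenotypeTable:
    """Read long-format repeated semen records."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return PhenotypeTable(df)


def read_gene_annotation(path) -> GeneAnnotation:
    """Read gene intervals from GFF3 (gene features) or BED.

    BED's 0-based half-open intervals are converted to the internal 1-based
    inclusive convention; GFF3 is already 1-based inclusive.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return _read_gff3_genes(path)
    if path.endswith(".bed"):
        return _read_bed_genes(path)
    raise FormatError(f"cannot infer annotation format from extension: {path}")


def _read_gff3_genes(path) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", ""))
            gene_id = gene_id.removeprefix("gene:")
            rows.append(
                {
                    "gene_id": gene_id,
                    "gene_name": attrs.get("Name", gene_id),
                    "chrom": parts[0],
                    "start_bp": int(parts[3]),
                    "end_bp": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return GeneAnnotation(pd.DataFrame(rows))


def _read_bed_genes(path) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}"
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append(
                {
                    "gene_id": name,
                    "gene_name": name,
                    "chrom": parts[0],
                    # BED 0-based half-open -> 1-based inclusive
                    "start_bp": int(parts[1]) + 1,
                    "end_bp": int(parts[2]),
                    "strand": strand,
                }
            )
    return GeneAnnotation(pd.DataFrame(rows))


def read_expression_tsv(path, tissue: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(tissue=tissue, values=df)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_tables(pedigree_path, phenotype_path, gff_or_bed_path):
    """Convenience loader for the three tabular inputs."""
    return (
        read_pedigree_csv(pedigree_path),
        read_phenotypes_csv(phenotype_path),
        read_gene_annotation(gff_or_bed_path),
    )


def write_results(path, table: pd.DataFrame) -> None:
    """Write a result table as TSV: header row, NA for missing, %.6g floats."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
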