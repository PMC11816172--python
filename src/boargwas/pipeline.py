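"""End-to-end orchestration: simulate -> qc -> reml -> debv -> gwas ->
annotate -> eqtl -> coloc, per breed and trait.

Each stage writes its artifact under ``outdir/<breed>/``; with
``resume=True`` a stage whose artifact already exists is loaded instead of
recomputed. All randomness flows from the config seed (one derived seed
per breed), so the final report is byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from . import qc as qc_mod
from .gwas import GwasResult, build_grm, weighted_gwas
from .postgwas import annotate_genes, cis_eqtl_scan, colocalize
from .quantgen import (
    build_A,
    compute_weights,
    deregress,
    reml_repeatability,
    solve_mme_blup,
)
from .simulate import SimulationConfig, simulate_study
from .types import PhenotypeTable

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("boargwas.pipeline")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    breeds: list = field(default_factory=lambda: ["breed1"])
    traits: list = field(default_factory=lambda: ["spmot"])
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    debv: dict = field(default_factory=lambda: {"c": 0.1})
    gwas: dict = field(default_factory=lambda: {"fdr_method": "storey",
                                                "fdr_threshold": 0.05})
    postgwas: dict = field(default_factory=lambda: {"window_bp": 1_000_000,
                                                    "ld_threshold": 0.8})
    inputs: dict = field(default_factory=dict)  # optional external data paths

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise PipelineError("config must set 'outdir'")
        cfg = cls(**raw)
        for key, value in cfg.inputs.items():
            if not Path(value).exists():
                raise PipelineError(f"input path for {key!r} does not exist: {value}")
        return cfg


def _load_or_simulate(config: PipelineConfig, breed: str, breed_dir: Path, resume):
    inputs = config.inputs
    if inputs:
        pedigree, phenotypes, genes = iof.read_tables(
            inputs["pedigree"], inputs["phenotypes"], inputs["genes"]
        )
        geno = iof.read_plink_text(inputs["ped"], inputs["map"])
        expression = iof.read_expression_tsv(
            inputs["expression"], inputs.get("tissue", "testis")
        )
        return pedigree, geno, phenotypes, genes, expression
    ped_csv = breed_dir / "pedigree.csv"
    if resume and ped_csv.exists():
        pedigree = iof.read_pedigree_csv(ped_csv)
        geno = iof.read_plink_text(breed_dir / "geno.ped", breed_dir / "geno.map")
        phenotypes = iof.read_phenotypes_csv(breed_dir / "phenotypes.csv")
        genes = iof.read_gene_annotation(str(breed_dir / "genes.gff3"))
        expression = iof.read_expression_tsv(breed_dir / "expression.tsv", "testis")
        log.info("[%s] simulate: resumed from existing artifacts", breed)
        return pedigree, geno, phenotypes, genes, expression
    sim_kwargs = dict(config.simulate)
    breed_offset = config.breeds.index(breed)
    sim_kwargs["seed"] = int(sim_kwargs.get("seed", config.seed)) + breed_offset
    sim_kwargs["qtl_spec"] = [tuple(q) for q in sim_kwargs.get("qtl_spec", [])]
    sim_kwargs["eqtl_spec"] = [tuple(e) for e in sim_kwargs.get("eqtl_spec", [])]
    scfg = SimulationConfig(**sim_kwargs)
    pedigree, geno, truth, phenotypes, genes, expression = simulate_study(scfg)
    pedigree.df.to_csv(ped_csv, index=False)
    iof.write_plink_text(geno, breed_dir / "geno.ped", breed_dir / "geno.map")
    phenotypes.df.to_csv(breed_dir / "phenotypes.csv", index=False)
    with open(breed_dir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.df.iterrows():
            fh.write(
                f"{g['chrom']}\t.\tgene\t{g['start_bp']}\t{g['end_bp']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']};Name={g['gene_name']}\n"
            )
    iof.write_expression_tsv(expression, breed_dir / "expression.tsv")
    truth_json = {
        "h2": truth.h2,
        "repeatability": truth.repeatability,
        "clip_rates": truth.clip_rates,
        "causal_markers": truth.causal_markers.to_dict("records"),
        "causal_genes": truth.causal_genes.to_dict("records"),
    }
    (breed_dir / "truth.json").write_text(json.dumps(truth_json, indent=1))
    log.info("[%s] simulate: %d animals, %d records, %d markers",
             breed, len(pedigree), len(phenotypes), geno.n_markers)
    return pedigree, geno, phenotypes, genes, expression


def _run_breed(config: PipelineConfig, breed: str, resume: bool):
    breed_dir = Path(config.outdir) / breed
    breed_dir.mkdir(parents=True, exist_ok=True)
    pedigree, geno, phenotypes, genes, expression = _load_or_simulate(
        config, breed, breed_dir, resume
    )
    n_raw = len(phenotypes)

    phen_qc_path = breed_dir / "phenotypes_qc.csv"
    if resume and phen_qc_path.exists():
        phen_qc = iof.read_phenotypes_csv(phen_qc_path)
    else:
        phen_qc, phen_report = qc_mod.filter_phenotypes(phenotypes)
        phen_qc.df.to_csv(phen_qc_path, index=False)
        (breed_dir / "phenotype_qc.json").write_text(
            json.dumps(phen_report.to_dict(), indent=1)
        )
    log.info("[%s] phenotype qc: %d -> %d records", breed, n_raw, len(phen_qc))

    geno_qc_path = breed_dir / "geno_qc.ped"
    if resume and geno_qc_path.exists():
        geno_qc = iof.read_plink_text(geno_qc_path, breed_dir / "geno_qc.map")
    else:
        geno_qc, geno_report = qc_mod.genotype_qc(geno, **config.qc)
        iof.write_plink_text(geno_qc, geno_qc_path, breed_dir / "geno_qc.map")
        (breed_dir / "genotype_qc.json").write_text(
            json.dumps(geno_report.to_dict(), indent=1)
        )
        pca = qc_mod.genotype_pca(geno_qc, k=2)
        iof.write_results(
            breed_dir / "pca.tsv", pca.pca_coordinates.reset_index(names="animal")
        )
    log.info("[%s] genotype qc: %d -> %d markers", breed,
             geno.n_markers, geno_qc.n_markers)

    a = build_A(pedigree)
    grm = build_grm(geno_qc)
    eqtl_path = breed_dir / "eqtl.tsv"
    if resume and eqtl_path.exists():
        eqtls = iof.read_results(eqtl_path)
    else:
        eqtls = cis_eqtl_scan(
            expression, geno_qc, genes,
            cis_window_bp=config.postgwas.get("window_bp", 1_000_000),
        )
        iof.write_results(eqtl_path, eqtls)
    log.info("[%s] eqtl scan: %d gene-marker tests", breed, len(eqtls))

    table1_rows, table2_rows = [], []
    for trait in config.traits:
        trait_rows = _run_trait(
            config, breed, breed_dir, trait, phen_qc, a, geno_qc, grm,
            genes, eqtls, resume,
        )
        table1_rows.append(trait_rows[0])
        table2_rows.extend(trait_rows[1])
    return table1_rows, table2_rows


def _run_trait(config, breed, breed_dir, trait, phen_qc, a, geno_qc, grm,
               genes, eqtls, resume):
    vc_path = breed_dir / f"vc_{trait}.json"
    if resume and vc_path.exists():
        vc_dict = json.loads(vc_path.read_text())
    else:
        vc = reml_repeatability(phen_qc, a, trait)
        vc_dict = {
            "sigma_a2": vc.sigma_a2, "sigma_p2": vc.sigma_p2,
            "sigma_e2": vc.sigma_e2, "h2": vc.h2,
            "repeatability": vc.repeatability, "se": vc.se,
            "log_likelihood": vc.log_likelihood,
            "n_iterations": vc.n_iterations,
        }
        vc_path.write_text(json.dumps(vc_dict, indent=1))
    log.info("[%s/%s] reml: h2=%.3f re=%.3f", breed, trait,
             vc_dict["h2"], vc_dict["repeatability"])

    debv_path = breed_dir / f"debv_{trait}.tsv"
    if resume and debv_path.exists():
        bv_df = iof.read_results(debv_path)
    else:
        from .quantgen import VarianceComponents

        vc_obj = VarianceComponents(
            sigma_a2=vc_dict["sigma_a2"], sigma_p2=vc_dict["sigma_p2"],
            sigma_e2=vc_dict["sigma_e2"], converged=True, trait=trait,
        )
        bv = solve_mme_blup(phen_qc, a, vc_obj, trait)
        bv = deregress(bv, vc_obj.h2)
        bv = compute_weights(bv, vc_obj.h2, c=config.debv.get("c", 0.1))
        bv_df = bv.df
        iof.write_results(
            debv_path,
            bv_df[["animal", "ebv", "rel", "pa", "debv", "rel_animal",
                   "weight", "excluded"]],
        )

    gwas_path = breed_dir / f"gwas_{trait}.tsv"
    lambda_path = breed_dir / f"lambda_{trait}.json"
    if resume and gwas_path.exists() and lambda_path.exists():
        gwas_table = iof.read_results(gwas_path)
        lam = json.loads(lambda_path.read_text())["lambda"]
    else:
        usable = bv_df[bv_df["excluded"].isna() & bv_df["debv"].notna()]
        usable = usable[usable["animal"].isin(geno_qc.animal_ids)]
        log.info("[%s/%s] debv: %d usable genotyped animals",
                 breed, trait, len(usable))
        geno_scan = geno_qc.subset_animals(usable["animal"])
        grm_sub = grm.submatrix(usable["animal"])
        from .gwas import Grm

        result = weighted_gwas(
            usable["debv"].to_numpy(), usable["weight"].to_numpy(), geno_scan,
            Grm(grm_sub, grm.allele_freqs, list(usable["animal"])),
            trait=trait, fdr_method=config.gwas.get("fdr_method", "storey"),
        )
        iof.write_results(gwas_path, result.table)
        lambda_path.write_text(
            json.dumps({"lambda": result.lambda_gc, "sigma_g2": result.sigma_g2,
                        "sigma_e2": result.sigma_e2}, indent=1)
        )
        gwas_table = iof.read_results(gwas_path)
        lam = result.lambda_gc
        log.info("[%s/%s] gwas: lambda=%.3f", breed, trait, lam)

    fdr_thr = config.gwas.get("fdr_threshold", 0.05)
    sig = gwas_table[gwas_table["q"] < fdr_thr]
    window_bp = config.postgwas.get("window_bp", 1_000_000)
    hits = annotate_genes(sig, genes, window_bp=window_bp)
    genes_path = breed_dir / f"genes_{trait}.tsv"
    coloc_path = breed_dir / f"coloc_{trait}.tsv"
    if not (resume and genes_path.exists() and coloc_path.exists()):
        gene_rows = []
        for hit in hits:
            for _, g in hit.genes.iterrows():
                gene_rows.append({"marker": hit.marker, "chrom": hit.chrom,
                                  "pos": hit.pos, **g.to_dict()})
        iof.write_results(
            genes_path,
            pd.DataFrame(gene_rows, columns=["marker", "chrom", "pos", "gene_id",
                                             "gene_name", "start_bp", "end_bp",
                                             "distance_bp"]),
        )
        coloc = colocalize(
            sig, eqtls, geno_qc, genes,
            ld_threshold=config.postgwas.get("ld_threshold", 0.8),
            eqtl_fdr=fdr_thr, window_bp=window_bp,
        )
        iof.write_results(coloc_path, coloc)
        log.info("[%s/%s] postgwas: %d significant SNPs, %d colocalizations",
                 breed, trait, len(sig), len(coloc))

    records = phen_qc.records_for(trait)
    table1 = {
        "breed": breed, "trait": trait,
        "n_animals": records["animal"].nunique(),
        "n_records": len(records),
        "mean": float(records[trait].mean()),
        "sd": float(records[trait].std()),
        "h2": vc_dict["h2"], "h2_se": vc_dict.get("se", {}).get("h2", np.nan),
        "re": vc_dict["repeatability"],
        "re_se": vc_dict.get("se", {}).get("repeatability", np.nan),
        "lambda": lam,
    }
    gene_counts = {h.marker: len(h.genes) for h in hits}
    table2 = [
        {
            "breed": breed, "trait": trait, "chrom": row["chrom"],
            "pos": row["pos"], "marker": row["marker"], "maf": row["maf"],
            "p": row["p"], "q": row["q"], "gvar_pct": row["gvar_pct"],
            "n_window_genes": gene_counts.get(row["marker"], 0),
        }
        for _, row in sig.iterrows()
    ]
    return table1, table2


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Run all stages per breed x trait; returns a status/report summary.

    A stage failure aborts the remaining stages for that breed only; the
    returned status is nonzero if any breed failed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table1_rows, table2_rows, failures = [], [], {}
    for breed in config.breeds:
        try:
            t1, t2 = _run_breed(config, breed, resume)
            table1_rows.extend(t1)
            table2_rows.extend(t2)
        except Exception as exc:  # keep other breeds running
            log.error("[%s] pipeline failed: %s", breed, exc)
            failures[breed] = str(exc)
    t1_df = pd.DataFrame(table1_rows)
    t2_df = pd.DataFrame(
        table2_rows,
        columns=["breed", "trait", "chrom", "pos", "marker", "maf", "p", "q",
                 "gvar_pct", "n_window_genes"],
    )
    iof.write_results(outdir / "report_traits.tsv", t1_df)
    iof.write_results(outdir / "report_significant_snps.tsv", t2_df)
    return {
        "status": 1 if failures else 0,
        "failures": failures,
        "trait_summaries": table1_rows,
        "n_significant": len(table2_rows),
    }
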