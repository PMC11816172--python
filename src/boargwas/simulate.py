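"""Synthetic pedigrees, genotypes, repeated records, and expression.

The generator mirrors the statistical structure the pipeline assumes:

* a multi-generation pedigree over a closed boar population;
* founder haplotypes from a latent Gaussian AR(1) process, giving a
  realistic MAF spectrum with local LD that decays with distance;
* offspring genotypes by Mendelian gamete dropping with recombination at
  a uniform 1 cM/Mb;
* true breeding values = optional marker QTL effects plus an infinitesimal
  pedigree component, scaled to the target additive variance;
* repeated semen records with year-season and parity fixed effects, age
  and collection-interval covariates, a permanent-environment deviate
  drawn once per animal, and i.i.d. residuals;
* cis-regulated expression (baseline + effect * dosage + noise) in one
  testis-like tissue.

All randomness flows from a single root seed through named
``numpy.random.SeedSequence`` children, so each stage is reproducible in
isolation and the whole study is bit-identical under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeData,
    PedigreeTable,
    PhenotypeTable,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_population",
    "simulate_records",
    "simulate_gene_annotation",
    "simulate_expression",
    "simulate_study",
]

# Trait scales (mean, SD) for the simulated semen traits; the defaults are
# typical Duroc boar-stud values: motility ~81%, progressive motility ~27%,
# abnormality ~28%, total count ~35 billion.
DEFAULT_TRAIT_SCALES = {
    "spmot": (81.25, 12.36),
    "sppmot": (26.64, 18.44),
    "spabr": (28.13, 12.37),
    "spcount": (34.97, 18.85),
}

_STAGES = ("founders", "pedigree", "meiosis", "effects", "records", "expression")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_founders: int = 100
    n_generations: int = 3
    mean_records_per_animal: float = 25.0
    n_chromosomes: int = 5
    chrom_length_bp: int = 50_000_000
    n_markers: int = 5000
    maf_range: tuple = (0.05, 0.5)
    ld_decay_bp: float = 200_000.0
    h2_target: float = 0.33
    pe_ratio: float = 0.06
    n_parities: int = 4
    fixed_effect_sd: float = 0.3   # in trait-SD units
    age_slope: float = 0.05        # trait-SD units per month of age
    interval_slope: float = -0.01  # trait-SD units per interval day
    trait_scales: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SCALES))
    focal_trait: str = "spmot"
    qtl_spec: list = field(default_factory=list)   # (chrom, pos_bp, var_fraction)
    eqtl_spec: list = field(default_factory=list)  # (gene_id, marker, effect, noise_sd)
    n_null_genes: int = 30
    expression_baseline: float = 10.0

    def __post_init__(self):
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must be in (0, 1)")
        if self.pe_ratio < 0:
            raise ValueError("pe_ratio must be >= 0")
        if self.h2_target + self.pe_ratio >= 1:
            raise ValueError("h2_target + pe_ratio must be < 1")
        frac = sum(q[2] for q in self.qtl_spec)
        if frac > 1 + 1e-12:
            raise ValueError("QTL variance fractions must sum to <= 1")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-specific generator derived deterministically from the seed."""
        if stage not in _STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        idx = _STAGES.index(stage)
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(
            len(_STAGES)
        )[idx])


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests.

    ``breeding_values`` are on the standardized scale (additive variance 1
    before trait scaling); per-trait BVs are bv * sd_trait * sqrt(h2).
    """

    breeding_values: pd.Series          # animal -> standardized BV
    sigma_a2: float                     # standardized (= 1 by construction)
    sigma_p2: float
    sigma_e2: float
    h2: float
    repeatability: float
    causal_markers: pd.DataFrame        # marker, chrom, pos, effect, var_fraction
    causal_genes: pd.DataFrame          # gene_id, marker, effect, noise_sd
    clip_rates: dict = field(default_factory=dict)

    def trait_bv(self, trait: str, trait_scales: dict) -> pd.Series:
        sd = trait_scales[trait][1]
        return self.breeding_values * sd * np.sqrt(self.h2)


def _marker_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per_chrom[: config.n_markers % config.n_chromosomes] += 1
    rows = []
    for c in range(config.n_chromosomes):
        # distinct random positions without materializing the full range
        draw = np.unique(
            rng.integers(1, config.chrom_length_bp + 1, size=2 * per_chrom[c] + 16)
        )
        while len(draw) < per_chrom[c]:
            draw = np.unique(
                np.concatenate(
                    [draw, rng.integers(1, config.chrom_length_bp + 1, per_chrom[c])]
                )
            )
        pos = np.sort(rng.choice(draw, size=per_chrom[c], replace=False))
        for p in pos:
            rows.append((f"snp{len(rows) + 1}", str(c + 1), int(p)))
    df = pd.DataFrame(rows, columns=["marker", "chrom", "pos"])
    df["allele_a"] = "A"
    df["allele_b"] = "G"
    return df


def _founder_haplotypes(
    config: SimulationConfig, marker_map: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent-AR(1) haplotypes: alleles correlated along the chromosome."""
    from scipy.stats import norm

    m = len(marker_map)
    freqs = rng.uniform(*config.maf_range, size=m)
    thresholds = norm.ppf(freqs)
    pos = marker_map["pos"].to_numpy()
    chrom = marker_map["chrom"].to_numpy()
    gaps = np.empty(m)
    gaps[0] = np.inf
    gaps[1:] = pos[1:] - pos[:-1]
    gaps[1:][chrom[1:] != chrom[:-1]] = np.inf
    rho = np.exp(-gaps / config.ld_decay_bp)
    n_hap = 2 * config.n_founders
    eps = rng.standard_normal((n_hap, m))
    z = np.empty((n_hap, m))
    z[:, 0] = eps[:, 0]
    for j in range(1, m):
        z[:, j] = rho[j] * z[:, j - 1] + np.sqrt(1.0 - rho[j] ** 2) * eps[:, j]
    haps = (z < thresholds).astype(np.int8)
    return haps, freqs


def _gamete(
    parent_haps: np.ndarray,
    marker_map: pd.DataFrame,
    chrom_bounds: list,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete; crossovers Poisson at 1 cM/Mb, no interference."""
    m = parent_haps.shape[1]
    gamete = np.empty(m, dtype=np.int8)
    for (lo, hi, length_bp, positions) in chrom_bounds:
        morgans = length_bp * 1e-8  # 1 cM/Mb
        n_x = rng.poisson(morgans)
        phase0 = rng.integers(2)
        if n_x == 0:
            gamete[lo:hi] = parent_haps[phase0, lo:hi]
            continue
        xpos = np.sort(rng.uniform(0, length_bp, size=n_x))
        crossings = np.searchsorted(xpos, positions)
        phase = (phase0 + crossings) % 2
        seg = np.where(phase == 0, parent_haps[0, lo:hi], parent_haps[1, lo:hi])
        gamete[lo:hi] = seg
    return gamete


def simulate_population(
    config: SimulationConfig,
) -> tuple[PedigreeTable, GenotypeData, TruthSet]:
    """Pedigree, genotypes and ground truth for one closed population.

    Founders (generation 0) draw haplotypes from the AR(1) model; each
    later generation has ``n_founders`` offspring whose parents are chosen
    at random from the previous generation (sires from males, dams from
    females). True breeding values combine QTL marker effects (scaled to
    the requested variance fractions) with an infinitesimal pedigree
    component filling the remainder, normalized so the standardized
    additive variance is 1.
    """
    mm = _marker_map(config, config.rng("founders"))
    haps, _ = _founder_haplotypes(config, mm, config.rng("founders"))
    m = len(mm)
    pos = mm["pos"].to_numpy()
    chrom = mm["chrom"].to_numpy()
    chrom_bounds = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        chrom_bounds.append(
            (idx[0], idx[-1] + 1, config.chrom_length_bp, pos[idx[0] : idx[-1] + 1])
        )

    ped_rng = config.rng("pedigree")
    mei_rng = config.rng("meiosis")
    animals, sires, dams, sexes = [], [], [], []
    hap_store = np.empty((0, 2, m), dtype=np.int8)

    founders = [f"G0_{i + 1:04d}" for i in range(config.n_founders)]
    animals.extend(founders)
    sires.extend([None] * config.n_founders)
    dams.extend([None] * config.n_founders)
    sexes.extend(["M" if i % 2 == 0 else "F" for i in range(config.n_founders)])
    hap_store = haps.reshape(config.n_founders, 2, m)

    prev_start = 0
    for g in range(1, config.n_generations):
        prev = list(range(prev_start, len(animals)))
        males = [i for i in prev if sexes[i] == "M"]
        females = [i for i in prev if sexes[i] == "F"]
        prev_start = len(animals)
        new_haps = np.empty((config.n_founders, 2, m), dtype=np.int8)
        for k in range(config.n_founders):
            si = int(ped_rng.choice(males))
            di = int(ped_rng.choice(females))
            name = f"G{g}_{k + 1:04d}"
            animals.append(name)
            sires.append(animals[si])
            dams.append(animals[di])
            sexes.append("M" if k % 2 == 0 else "F")
            new_haps[k, 0] = _gamete(hap_store[si], mm, chrom_bounds, mei_rng)
            new_haps[k, 1] = _gamete(hap_store[di], mm, chrom_bounds, mei_rng)
        hap_store = np.concatenate([hap_store, new_haps], axis=0)

    dosages = hap_store.sum(axis=1).astype(float)
    pedigree = PedigreeTable(
        pd.DataFrame({"animal": animals, "sire": sires, "dam": dams})
    )
    geno = GenotypeData(dosages, mm, animals)

    # --- true breeding values ---
    eff_rng = config.rng("effects")
    n = len(animals)
    bv = np.zeros(n)
    causal_rows = []
    qtl_frac_total = sum(q[2] for q in config.qtl_spec)
    for chrom_q, pos_q, frac in config.qtl_spec:
        on = np.flatnonzero(chrom == str(chrom_q))
        if len(on) == 0:
            raise ValueError(f"QTL chromosome {chrom_q!r} has no markers")
        j = on[np.argmin(np.abs(pos[on] - pos_q))]
        x = dosages[:, j]
        if np.var(x) == 0:
            raise ValueError(f"QTL marker {mm['marker'][j]} is monomorphic")
        effect = np.sqrt(frac) / np.std(x)
        if eff_rng.uniform() < 0.5:
            effect = -effect
        bv += effect * (x - x.mean())
        causal_rows.append(
            {
                "marker": mm["marker"][j],
                "chrom": chrom[j],
                "pos": int(pos[j]),
                "effect": effect,
                "var_fraction": frac,
            }
        )
    poly_var = max(1.0 - qtl_frac_total, 0.0)
    if poly_var > 0:
        poly = np.empty(n)
        idx = {a: i for i, a in enumerate(animals)}
        parents = pedigree.parents()
        for i, a in enumerate(animals):
            s, d = parents[a]
            if s is None and d is None:
                poly[i] = eff_rng.normal(0.0, np.sqrt(poly_var))
            else:
                mid = 0.0
                k_par = 0
                for par in (s, d):
                    if par is not None:
                        mid += poly[idx[par]]
                        k_par += 1
                mid /= 2.0
                ms_var = poly_var * (1.0 - k_par / 4.0)
                poly[i] = mid + eff_rng.normal(0.0, np.sqrt(ms_var))
        bv += poly

    sigma_p2 = config.pe_ratio / config.h2_target  # standardized scale
    sigma_e2 = (1.0 - config.h2_target - config.pe_ratio) / config.h2_target
    truth = TruthSet(
        breeding_values=pd.Series(bv, index=animals),
        sigma_a2=1.0,
        sigma_p2=sigma_p2,
        sigma_e2=sigma_e2,
        h2=config.h2_target,
        repeatability=config.h2_target + config.pe_ratio,
        causal_markers=pd.DataFrame(
            causal_rows, columns=["marker", "chrom", "pos", "effect", "var_fraction"]
        ),
        causal_genes=pd.DataFrame(
            [
                {"gene_id": g, "marker": mk, "effect": e, "noise_sd": s}
                for g, mk, e, s in config.eqtl_spec
            ],
            columns=["gene_id", "marker", "effect", "noise_sd"],
        ),
    )
    return pedigree, geno, truth


def simulate_records(
    pedigree: PedigreeTable, truth: TruthSet, config: SimulationConfig
) -> PhenotypeTable:
    """Repeated semen records for every pedigree animal.

    Record counts are 1 + Poisson(mean - 1). Collection dates start at a
    random day in the station's first half-year and advance by 3-14 day
    intervals; year-season is derived from the date (year x quarter) and
    parity is an animal-level category. For each trait,

        record = mu + ys + parity + b_age age + b_intv interval
                 + BV + PE + residual

    with variances sd^2 * (h2, pe_ratio, 1 - h2 - pe_ratio). Percent traits
    are clipped to [0, 100] and counts floored at a small positive value;
    clipping rates are recorded in ``truth.clip_rates``.
    """
    rng = config.rng("records")
    animals = pedigree.animals
    missing = [a for a in animals if a not in truth.breeding_values.index]
    if missing:
        raise ValueError(f"truth lacks breeding values for {len(missing)} animals")
    n_rec = 1 + rng.poisson(max(config.mean_records_per_animal - 1.0, 0.0), len(animals))
    start = pd.Timestamp("2022-08-01")
    ys_effects: dict = {}
    parity_effects = {
        str(p + 1): rng.normal(0.0, config.fixed_effect_sd)
        for p in range(config.n_parities)
    }
    pe_std = rng.standard_normal(len(animals))
    rows = []
    for i, animal in enumerate(animals):
        t0 = start + pd.Timedelta(days=int(rng.integers(0, 180)))
        age0 = float(rng.uniform(6.5, 10.0))
        parity = str(int(rng.integers(1, config.n_parities + 1)))
        date = t0
        age = age0
        for r in range(n_rec[i]):
            if r > 0:
                gap = int(rng.integers(3, 15))
                date = date + pd.Timedelta(days=gap)
                age += gap / 30.44
            ys = f"{date.year}_Q{(date.month - 1) // 3 + 1}"
            if ys not in ys_effects:
                ys_effects[ys] = rng.normal(0.0, config.fixed_effect_sd)
            rows.append(
                {
                    "animal": animal,
                    "date": date,
                    "year_season": ys,
                    "parity": parity,
                    "age_months": age,
                    "pe_std": pe_std[i],
                    "ys_std": ys_effects[ys],
                    "par_std": parity_effects[parity],
                }
            )
    df = pd.DataFrame(rows)
    df["interval_days"] = df.groupby("animal")["date"].diff().dt.days.astype(float)
    intv = df["interval_days"].fillna(0.0).to_numpy()
    age_c = df["age_months"].to_numpy() - df["age_months"].mean()

    h2, pe = config.h2_target, config.pe_ratio
    resid_frac = 1.0 - h2 - pe
    bv_std = truth.breeding_values.reindex(df["animal"]).to_numpy()
    clip_rates = {}
    for trait, (mu, sd) in config.trait_scales.items():
        e = rng.standard_normal(len(df))
        value = (
            mu
            + sd * (df["ys_std"].to_numpy() + df["par_std"].to_numpy())
            + config.age_slope * sd * age_c
            + config.interval_slope * sd * intv
            + np.sqrt(h2) * sd * bv_std
            + np.sqrt(pe) * sd * df["pe_std"].to_numpy()
            + np.sqrt(resid_frac) * sd * e
        )
        if trait in ("spmot", "sppmot", "spabr"):
            clipped = (value < 0) | (value > 100)
            value = np.clip(value, 0.0, 100.0)
        else:
            clipped = value < 0.01
            value = np.maximum(value, 0.01)
        clip_rates[trait] = float(clipped.mean())
        df[trait] = value
    truth.clip_rates.update(clip_rates)
    df["volume_ml"] = np.maximum(rng.normal(250.0, 60.0, len(df)), 1.0)
    out = df.drop(columns=["pe_std", "ys_std", "par_std"])
    return PhenotypeTable(out)


def simulate_gene_annotation(
    geno: GenotypeData, config: SimulationConfig
) -> GeneAnnotation:
    """Gene models for the expression stage.

    Each cis-regulated gene from ``eqtl_spec`` gets a 20 kb body placed
    50-500 kb from its causal marker (inside the cis window); null genes
    are placed uniformly at random.
    """
    rng = config.rng("expression")
    mm = geno.marker_map.set_index("marker")
    rows = []
    for gene_id, marker, _, _ in config.eqtl_spec:
        if marker not in mm.index:
            raise ValueError(f"eQTL marker {marker!r} not in the map")
        pos = int(mm.loc[marker, "pos"])
        offset = int(rng.integers(50_000, 500_000)) * (1 if rng.uniform() < 0.5 else -1)
        start = max(1, pos + offset)
        rows.append(
            {
                "gene_id": gene_id,
                "gene_name": gene_id.upper(),
                "chrom": str(mm.loc[marker, "chrom"]),
                "start_bp": start,
                "end_bp": start + 20_000,
                "strand": "+" if rng.uniform() < 0.5 else "-",
            }
        )
    for k in range(config.n_null_genes):
        c = str(int(rng.integers(1, config.n_chromosomes + 1)))
        start = int(rng.integers(1, max(config.chrom_length_bp - 20_000, 2)))
        rows.append(
            {
                "gene_id": f"nullgene{k + 1}",
                "gene_name": f"NULLGENE{k + 1}",
                "chrom": c,
                "start_bp": start,
                "end_bp": start + 20_000,
                "strand": "+",
            }
        )
    return GeneAnnotation(pd.DataFrame(rows))


def simulate_expression(
    geno: GenotypeData, config: SimulationConfig, genes: GeneAnnotation | None = None
) -> ExpressionMatrix:
    """TPM-like expression with cis-regulation in a testis-like tissue.

    Cis-regulated genes follow baseline + effect * dosage + N(0, noise_sd);
    other genes are pure noise around the baseline. Values are shifted, if
    needed, so the matrix is non-negative.
    """
    rng = config.rng("expression")
    if genes is None:
        genes = simulate_gene_annotation(geno, config)
    # regenerate the annotation rng draws so expression noise is decoupled
    rng = np.random.default_rng(rng.integers(2**31))
    mm = geno.marker_map.set_index("marker")
    marker_col = {m: j for j, m in enumerate(geno.marker_map["marker"])}
    n = geno.n_animals
    eqtl = {g: (mk, eff, nsd) for g, mk, eff, nsd in config.eqtl_spec}
    data = {}
    for gene_id in genes.df["gene_id"]:
        if gene_id in eqtl:
            mk, eff, nsd = eqtl[gene_id]
            x = geno.dosages[:, marker_col[mk]].copy()
            x[np.isnan(x)] = np.nanmean(x)
            vals = config.expression_baseline + eff * x + rng.normal(0.0, nsd, n)
        else:
            vals = config.expression_baseline + rng.normal(0.0, 2.0, n)
        data[gene_id] = vals
    values = pd.DataFrame(data, index=geno.animal_ids).T
    lo = values.values.min()
    if lo < 0:
        values = values - lo
    return ExpressionMatrix(tissue="testis", values=values)


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: population, records, annotation and expression."""
    pedigree, geno, truth = simulate_population(config)
    phenotypes = simulate_records(pedigree, truth, config)
    genes = simulate_gene_annotation(geno, config)
    expression = simulate_expression(geno, config, genes)
    return pedigree, geno, truth, phenotypes, genes, expression
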