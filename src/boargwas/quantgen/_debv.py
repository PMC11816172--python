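"""VanRaden deregression of EBVs and the residual weights for the scan.

Deregression removes the parent-average contribution from an EBV and
undoes BLUP shrinkage using daughter equivalents (DE), the information
content of a proof expressed as an equivalent number of progeny records:

    PA      = (EBV_s + EBV_d) / 2
    REL_PA  = (REL_s + REL_d) / 4
    DE_x    = k REL_x / (1 - REL_x),  k = (1 - h2) / h2
    R_i     = (DE_i - DE_PA) / DE_i
    DEBV_i  = PA + (EBV_i - PA) / R_i

The association-scan weights then convert DEBV reliability back into an
effective own-record count. Two DE conventions coexist in the source
formulas: deregression uses the k-scaled DE above, while the weight
computation uses unscaled DE = Rel / (1 - Rel); both are kept as printed.

    DE_DEBV    = Rel_DEBV / (1 - Rel_DEBV),  DE_PA = Rel_PA / (1 - Rel_PA)
    Rel_Animal = (DE_DEBV - DE_PA) / (DE_DEBV - DE_PA + 1)
    weight     = (1 - h2) / (c + h2 (1 - Rel_Animal) / Rel_Animal)

with c the fraction of genetic variance not captured by markers (0.1 for
high-reliability DEBVs).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._blup import BreedingValueSet

__all__ = ["deregress", "compute_weights"]

log = logging.getLogger(__name__)


def deregress(
    bv: BreedingValueSet, h2: float, rel_debv_from_rel: bool = False
) -> BreedingValueSet:
    """Add PA, daughter equivalents, R_i, DEBV and DEBV reliability.

    A missing parent contributes EBV 0 (the population mean) and REL 0.
    Animals whose parent-average information equals or exceeds their own
    (R_i <= 0) cannot be deregressed; they are flagged and later excluded
    from the scan. ``rel_debv_from_rel`` switches the DEBV reliability
    definition from (DE_i - DE_PA)/(DE_i - DE_PA + k) to plain REL_i.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    df = bv.df.copy()
    if (df["rel"] >= 1.0).any():
        raise ValueError("REL = 1 implies infinite daughter equivalents")
    k = (1.0 - h2) / h2
    ebv = df.set_index("animal")["ebv"]
    rel = df.set_index("animal")["rel"]

    def parent(col, table, default):
        vals = df[col].map(lambda s: table.get(s, default) if s else default)
        return vals.fillna(default).to_numpy(dtype=float)

    ebv_s = parent("sire", ebv, 0.0)
    ebv_d = parent("dam", ebv, 0.0)
    rel_s = parent("sire", rel, 0.0)
    rel_d = parent("dam", rel, 0.0)
    df["pa"] = (ebv_s + ebv_d) / 2.0
    df["rel_pa"] = (rel_s + rel_d) / 4.0
    df["de_i"] = k * df["rel"] / (1.0 - df["rel"])
    df["de_pa"] = k * df["rel_pa"] / (1.0 - df["rel_pa"])
    with np.errstate(divide="ignore", invalid="ignore"):
        df["r_i"] = (df["de_i"] - df["de_pa"]) / df["de_i"]
    df["excluded"] = pd.Series([None] * len(df), dtype=object)
    bad = ~(df["r_i"] > 0.0)
    df.loc[bad, "excluded"] = "r_i_nonpositive"
    if bad.any():
        log.info("deregress: %d animals with R_i <= 0 flagged", int(bad.sum()))
    df["debv"] = np.where(bad, np.nan, df["pa"] + (df["ebv"] - df["pa"]) / df["r_i"])
    if rel_debv_from_rel:
        df["rel_debv"] = df["rel"]
    else:
        span = df["de_i"] - df["de_pa"]
        df["rel_debv"] = np.where(bad, np.nan, span / (span + k))
    out = BreedingValueSet(df=df, trait=bv.trait, h2=h2, meta=dict(bv.meta))
    out.meta["k"] = k
    return out


def compute_weights(bv: BreedingValueSet, h2: float, c: float = 0.1) -> BreedingValueSet:
    """Add Rel_Animal and the residual weight for the association scan.

    Animals with Rel_Animal <= 0 (or already excluded by deregression) are
    flagged; the count is logged. Weight grows monotonically with
    Rel_Animal toward the ceiling (1 - h2) / c.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    if c <= 0:
        raise ValueError("c must be positive")
    df = bv.df.copy()
    if "rel_debv" not in df.columns:
        raise ValueError("run deregress before compute_weights")
    if (df["rel_debv"] >= 1.0).any():
        raise ValueError("Rel_DEBV = 1 implies infinite daughter equivalents")
    with np.errstate(divide="ignore", invalid="ignore"):
        de_debv = df["rel_debv"] / (1.0 - df["rel_debv"])
        de_pa = df["rel_pa"] / (1.0 - df["rel_pa"])
        span = de_debv - de_pa
        df["rel_animal"] = span / (span + 1.0)
    usable = df["excluded"].isna() & (df["rel_animal"] > 0.0)
    newly_bad = df["excluded"].isna() & ~(df["rel_animal"] > 0.0)
    df.loc[newly_bad, "excluded"] = "rel_animal_nonpositive"
    if newly_bad.any():
        log.info(
            "compute_weights: %d animals with Rel_Animal <= 0 excluded",
            int(newly_bad.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        weight = (1.0 - h2) / (
            c + h2 * (1.0 - df["rel_animal"]) / df["rel_animal"]
        )
    df["weight"] = np.where(usable, weight, np.nan)
    out = BreedingValueSet(df=df, trait=bv.trait, h2=h2, meta=dict(bv.meta))
    out.meta["c"] = c
    return out
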