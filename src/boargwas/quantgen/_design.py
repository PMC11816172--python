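"""Design matrices for the repeatability animal model.

The observation model for a repeated semen record is

    y = mu + year_season + parity + b_age * age + b_intv * interval
        + a_animal + p_animal + e

with a ~ N(0, A sigma_a2), p ~ N(0, I sigma_p2) over animals with records,
and e ~ N(0, I sigma_e2). This module turns a PhenotypeTable plus a
RelationshipMatrix into the dense pieces (y, X, record->animal incidence)
that REML and the mixed-model equations consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..types import PhenotypeTable
from ._amatrix import RelationshipMatrix

__all__ = ["ModelFrame", "build_model_frame", "DesignError"]


class DesignError(ValueError):
    """Raised for rank-deficient fixed-effect designs."""


@dataclass
class ModelFrame:
    y: np.ndarray                 # n_records
    x: np.ndarray                 # n_records x p, full column rank
    x_names: list
    record_animal: np.ndarray     # pedigree-animal index per record
    record_pe: np.ndarray         # PE-level index per record
    animals: list                 # all pedigree animals (A order)
    pe_animals: list              # animals with records (PE levels)
    a_matrix: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.y)


def build_model_frame(
    phenotypes: PhenotypeTable, a: RelationshipMatrix, trait: str
) -> ModelFrame:
    df = phenotypes.records_for(trait).copy()
    unknown = set(df["animal"]) - set(a.animals)
    if unknown:
        raise DesignError(
            f"{len(unknown)} phenotyped animals missing from the pedigree, "
            f"e.g. {sorted(unknown)[:3]}"
        )
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for factor in ("year_season", "parity"):
        dummies = pd.get_dummies(df[factor].astype(str), prefix=factor)
        dummies = dummies.reindex(sorted(dummies.columns), axis=1)
        # drop the first level as reference for estimability
        for col in dummies.columns[1:]:
            cols.append(dummies[col].to_numpy(dtype=float))
            names.append(col)
    age = df["age_months"].to_numpy(dtype=float)
    intv = df["interval_days"].to_numpy(dtype=float)
    intv_mean = np.nanmean(intv) if np.isfinite(intv).any() else 0.0
    intv = np.where(np.isnan(intv), intv_mean, intv)
    for name, cov in (("age_months", age), ("interval_days", intv)):
        centered = cov - cov.mean()
        if np.allclose(centered, 0.0):
            continue  # constant covariate carries no information
        cols.append(centered)
        names.append(name)
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the columns involved in the dependency via QR pivoting
        from scipy.linalg import qr

        _, r, piv = qr(x, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[rank:]]
        raise DesignError(f"confounded fixed-effect columns: {bad}")

    animal_idx = {an: i for i, an in enumerate(a.animals)}
    record_animal = df["animal"].map(animal_idx).to_numpy(dtype=int)
    pe_animals = sorted(set(df["animal"]), key=lambda an: animal_idx[an])
    pe_idx = {an: i for i, an in enumerate(pe_animals)}
    record_pe = df["animal"].map(pe_idx).to_numpy(dtype=int)
    return ModelFrame(
        y=df[trait].to_numpy(dtype=float),
        x=x,
        x_names=names,
        record_animal=record_animal,
        record_pe=record_pe,
        animals=list(a.animals),
        pe_animals=pe_animals,
        a_matrix=a.values,
    )
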