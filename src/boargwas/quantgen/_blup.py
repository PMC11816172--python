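"""BLUP breeding values with reliabilities from the mixed-model equations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from ..types import PhenotypeTable
from ._amatrix import RelationshipMatrix
from ._design import build_model_frame
from ._reml import VarianceComponents, RemlError, _MmeWorkspace

__all__ = ["BreedingValueSet", "solve_mme_blup"]


@dataclass
class BreedingValueSet:
    """Per-animal breeding-value table accumulated across pipeline stages.

    ``solve_mme_blup`` fills animal, sire, dam, n_records, ebv, rel;
    ``deregress`` adds pa, rel_pa, de_i, de_pa, r_i, debv, rel_debv;
    ``compute_weights`` adds rel_animal and weight. Animals flagged in
    ``excluded`` (with a reason) carry NaN in downstream columns and are
    dropped from the association scan.
    """

    df: pd.DataFrame
    trait: str = ""
    h2: float = float("nan")
    meta: dict = field(default_factory=dict)

    def usable(self) -> pd.DataFrame:
        """Rows not excluded at any stage."""
        if "excluded" not in self.df.columns:
            return self.df
        return self.df[self.df["excluded"].isna()]

    def __len__(self):
        return len(self.df)


def solve_mme_blup(
    phenotypes: PhenotypeTable,
    a: RelationshipMatrix,
    vc: VarianceComponents,
    trait: str,
) -> BreedingValueSet:
    """Solve Henderson's mixed-model equations at the REML estimates.

    EBVs are the additive solutions for every pedigree animal (animals
    without records are predicted through A). Reliability is
    1 - PEV / sigma_a2 with PEV from the diagonal of the inverted
    coefficient matrix.
    """
    if not vc.converged:
        raise RemlError("variance components have not converged; refusing BLUP")
    frame = build_model_frame(phenotypes, a, trait)
    ws = _MmeWorkspace(frame)
    lam_a = vc.sigma_e2 / vc.sigma_a2
    lam_p = vc.sigma_e2 / vc.sigma_p2
    c = ws.coefficient_matrix(lam_a, lam_p)
    cho = cho_factor(c, lower=True)
    rhs = np.concatenate([ws.xty, ws.zaty, ws.wpty])
    sol = cho_solve(cho, rhs)
    ebv = sol[ws.sl_a]
    c_inv = cho_solve(cho, np.eye(c.shape[0]))
    pev = np.diag(c_inv[ws.sl_a, ws.sl_a]) * vc.sigma_e2
    rel = np.clip(1.0 - pev / vc.sigma_a2, 0.0, 1.0 - 1e-12)
    parents = a.parents or {}
    counts = pd.Series(
        np.bincount(frame.record_animal, minlength=len(a.animals)),
        index=a.animals,
    )
    df = pd.DataFrame(
        {
            "animal": a.animals,
            "sire": [parents.get(an, (None, None))[0] for an in a.animals],
            "dam": [parents.get(an, (None, None))[1] for an in a.animals],
            "n_records": counts.to_numpy(dtype=int),
            "ebv": ebv,
            "rel": rel,
        }
    )
    return BreedingValueSet(
        df=df,
        trait=trait,
        h2=vc.h2,
        meta={"sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2},
    )
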