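import numpy as np
import pandas as pd
import pytest

from boargwas.simulate import SimulationConfig, simulate_population, simulate_records
from boargwas.types import PedigreeTable, PhenotypeTable


@pytest.fixture(scope="session")
def small_study():
    """One small seeded population with records, reused across tests."""
    cfg = SimulationConfig(
        seed=2024,
        n_founders=60,
        n_generations=3,
        n_markers=400,
        mean_records_per_animal=8,
        h2_target=0.30,
        pe_ratio=0.10,
        trait_scales={"spmot": (50.0, 12.0)},
    )
    pedigree, geno, truth = simulate_population(cfg)
    phenotypes = simulate_records(pedigree, truth, cfg)
    return cfg, pedigree, geno, truth, phenotypes


@pytest.fixture
def trio_pedigree():
    return PedigreeTable(
        pd.DataFrame(
            {
                "animal": ["s", "d", "o"],
                "sire": [None, None, "s"],
                "dam": [None, None, "d"],
            }
        )
    )


def make_phenotypes(values_by_animal, start="2023-01-01", gap_days=7):
    """Minimal phenotype table: one trait (spmot), shared fixed levels."""
    rows = []
    for animal, values in values_by_animal.items():
        date = pd.Timestamp(start)
        for v in values:
            rows.append(
                {
                    "animal": animal,
                    "date": date,
                    "year_season": "2023_Q1",
                    "parity": "1",
                    "age_months": 12.0,
                    "volume_ml": 200.0,
                    "spmot": v,
                }
            )
            date += pd.Timedelta(days=gap_days)
    return PhenotypeTable(pd.DataFrame(rows))


def random_pedigree(rng, n):
    """Random valid pedigree: each animal's parents drawn from predecessors."""
    animals = [f"a{i}" for i in range(n)]
    sire, dam = [], []
    for i in range(n):
        choices = [None] + animals[:i]
        sire.append(choices[rng.integers(len(choices))])
        dam.append(choices[rng.integers(len(choices))])
    return PedigreeTable(pd.DataFrame({"animal": animals, "sire": sire, "dam": dam}))
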