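import itertools

import numpy as np
import pandas as pd
import pytest

from boargwas.quantgen import (
    BreedingValueSet,
    build_A,
    compute_weights,
    deregress,
    reml_repeatability,
    solve_mme_blup,
)
from boargwas.quantgen._design import DesignError, build_model_frame
from boargwas.quantgen._reml import RemlError
from boargwas.types import PedigreeTable
from conftest import make_phenotypes, random_pedigree
from oracles import (
    a_matrix_recursive,
    blup_dense,
    repeatability_model_v,
    restricted_loglik_dense,
)


def ped(rows):
    return PedigreeTable(
        pd.DataFrame(rows, columns=["animal", "sire", "dam"])
    )


class TestAMatrix:
    def test_parent_offspring_and_trio(self, trio_pedigree):
        a = build_A(trio_pedigree)
        idx = {an: i for i, an in enumerate(a.animals)}
        assert a.values[idx["s"], idx["o"]] == 0.5
        assert a.values[idx["d"], idx["o"]] == 0.5
        assert a.values[idx["o"], idx["o"]] == 1.0

    def test_full_sibs(self):
        a = build_A(ped([("s", None, None), ("d", None, None),
                         ("x", "s", "d"), ("y", "s", "d")]))
        idx = {an: i for i, an in enumerate(a.animals)}
        assert a.values[idx["x"], idx["y"]] == 0.5

    def test_parent_offspring_mating_inbreeding(self):
        a = build_A(ped([("s", None, None), ("d", None, None),
                         ("o", "s", "d"), ("z", "s", "o")]))
        idx = {an: i for i, an in enumerate(a.animals)}
        # offspring of a parent-offspring mating: F = 0.25
        assert a.values[idx["z"], idx["z"]] == 1.25

    def test_matches_recursive_kinship_on_random_pedigrees(self):
        rng = np.random.default_rng(17)
        for n in (3, 5, 8, 12):
            for _ in range(20):
                pedigree = random_pedigree(rng, n)
                a = build_A(pedigree)
                oracle = a_matrix_recursive(pedigree.parents(), a.animals)
                np.testing.assert_allclose(a.values, oracle, atol=1e-12)

    def test_positive_semidefinite(self, small_study):
        _, pedigree, _, _, _ = small_study
        a = build_A(pedigree)
        evals = np.linalg.eigvalsh(a.values)
        assert evals.min() > -1e-9
        assert np.all(np.diag(a.values) >= 1.0)


class TestReml:
    def _simulate_simple(self, rng, a, n_rec, theta, mu=10.0):
        """Direct draw from the repeatability model over animals in a."""
        sa2, sp2, se2 = theta
        n_animal = a.values.shape[0]
        chol = np.linalg.cholesky(a.values + 1e-10 * np.eye(n_animal))
        bv = chol @ rng.standard_normal(n_animal) * np.sqrt(sa2)
        pe = rng.standard_normal(n_animal) * np.sqrt(sp2)
        values = {}
        for i, animal in enumerate(a.animals):
            e = rng.standard_normal(n_rec) * np.sqrt(se2)
            values[animal] = mu + bv[i] + pe[i] + e
        return values

    def test_loglik_maximum_matches_grid_search(self):
        rng = np.random.default_rng(3)
        pedigree = ped(
            [(f"f{i}", None, None) for i in range(4)]
            + [(f"o{i}", f"f{2 * (i % 2)}", f"f{2 * (i % 2) + 1}") for i in range(6)]
        )
        a = build_A(pedigree)
        values = self._simulate_simple(rng, a, 3, (1.0, 0.6, 1.0))
        phen = make_phenotypes(values)
        vc = reml_repeatability(phen, a, "spmot")
        frame = build_model_frame(phen, a, "spmot")
        # dense-V oracle over a grid around the REML optimum
        best_hat = restricted_loglik_dense(
            frame.y, frame.x,
            repeatability_model_v(
                frame.record_animal, frame.record_pe, a.values,
                (vc.sigma_a2, vc.sigma_p2, vc.sigma_e2),
            ),
        )
        assert best_hat == pytest.approx(vc.log_likelihood, abs=1e-4)
        grid = np.linspace(0.05, 3.0, 12)
        for theta in itertools.product(grid, grid, grid):
            v = repeatability_model_v(
                frame.record_animal, frame.record_pe, a.values, theta
            )
            assert restricted_loglik_dense(frame.y, frame.x, v) <= best_hat + 1e-6

    def test_translation_and_ordering_invariance(self):
        rng = np.random.default_rng(4)
        pedigree = ped(
            [(f"f{i}", None, None) for i in range(6)]
            + [(f"o{i}", "f0", "f1") for i in range(4)]
        )
        a = build_A(pedigree)
        values = self._simulate_simple(rng, a, 4, (1.0, 0.5, 1.5))
        phen = make_phenotypes(values)
        vc = reml_repeatability(phen, a, "spmot")
        shifted = make_phenotypes({k: np.asarray(v) + 100.0 for k, v in values.items()})
        vc_shift = reml_repeatability(shifted, a, "spmot")
        assert vc_shift.sigma_a2 == pytest.approx(vc.sigma_a2, rel=1e-4)
        assert vc_shift.sigma_e2 == pytest.approx(vc.sigma_e2, rel=1e-4)
        # reversed animal ordering in the pedigree rows
        rows = list(zip(pedigree.df["animal"], pedigree.df["sire"],
                        pedigree.df["dam"]))
        a_rev = build_A(PedigreeTable(
            pd.DataFrame(rows[::-1], columns=["animal", "sire", "dam"])
        ))
        vc_rev = reml_repeatability(phen, a_rev, "spmot")
        assert vc_rev.h2 == pytest.approx(vc.h2, rel=1e-4)

    def test_null_heritability_recovered(self):
        # family structure separates additive from permanent-environment
        # variance; with no BV signal the additive share should vanish
        rng = np.random.default_rng(5)
        founders = [(f"f{i}", None, None) for i in range(120)]
        kids = [
            (f"o{i}", f"f{2 * (i % 60)}", f"f{2 * (i % 60) + 1}")
            for i in range(360)
        ]
        pedigree = ped(founders + kids)
        a = build_A(pedigree)
        values = self._simulate_simple(rng, a, 6, (1e-6, 0.5, 1.0))
        vc = reml_repeatability(make_phenotypes(values), a, "spmot")
        assert vc.h2 < 0.05
        assert vc.repeatability == pytest.approx(0.5 / 1.5, abs=0.07)

    def test_single_records_raise(self):
        pedigree = ped([("x", None, None), ("y", None, None)])
        a = build_A(pedigree)
        phen = make_phenotypes({"x": [10.0], "y": [12.0]})
        with pytest.raises(RemlError):
            reml_repeatability(phen, a, "spmot")

    def test_confounded_design_names_columns(self):
        pedigree = ped([("x", None, None), ("y", None, None)])
        a = build_A(pedigree)
        df = make_phenotypes({"x": [10.0, 11.0], "y": [12.0, 13.0]}).df
        # make parity a copy of year_season -> perfectly confounded
        df["year_season"] = ["s1", "s2", "s1", "s2"]
        df["parity"] = df["year_season"]
        from boargwas.types import PhenotypeTable

        with pytest.raises(DesignError, match="confounded"):
            build_model_frame(PhenotypeTable(df), a, "spmot")


class TestBlup:
    def test_matches_dense_gls_oracle(self):
        rng = np.random.default_rng(6)
        pedigree = ped(
            [("f0", None, None), ("f1", None, None), ("f2", None, None),
             ("o0", "f0", "f1"), ("o1", "f0", "f2")]
        )
        a = build_A(pedigree)
        theta = (1.2, 0.4, 0.9)
        values = {an: 10 + rng.standard_normal(3) for an in a.animals}
        phen = make_phenotypes(values)
        from boargwas.quantgen._reml import VarianceComponents

        vc = VarianceComponents(*theta, converged=True)
        bv = solve_mme_blup(phen, a, vc, "spmot")
        frame = build_model_frame(phen, a, "spmot")
        v = repeatability_model_v(
            frame.record_animal, frame.record_pe, a.values, theta
        )
        za = np.zeros((len(frame.y), a.values.shape[0]))
        za[np.arange(len(frame.y)), frame.record_animal] = 1.0
        _, u = blup_dense(frame.y, frame.x, v, theta[0] * a.values @ za.T)
        np.testing.assert_allclose(bv.df["ebv"].to_numpy(), u, atol=1e-8)

    def test_total_shrinkage_limit(self):
        pedigree = ped([("x", None, None), ("y", None, None)])
        a = build_A(pedigree)
        phen = make_phenotypes({"x": [10.0, 11.0], "y": [14.0, 15.0]})
        from boargwas.quantgen._reml import VarianceComponents

        vc = VarianceComponents(1e-10, 0.5, 1.0, converged=True)
        bv = solve_mme_blup(phen, a, vc, "spmot")
        assert np.abs(bv.df["ebv"]).max() < 1e-6
        assert np.all(bv.df["rel"] < 1e-6)

    def test_reliability_increases_with_records(self):
        from boargwas.quantgen._reml import VarianceComponents

        pedigree = ped([("x", None, None), ("y", None, None)])
        a = build_A(pedigree)
        vc = VarianceComponents(1.0, 0.5, 1.0, converged=True)
        rels = []
        for n_rec in (2, 4, 8, 16):
            phen = make_phenotypes(
                {"x": 10 + np.arange(n_rec) * 0.1, "y": 12 + np.arange(n_rec) * 0.1}
            )
            bv = solve_mme_blup(phen, a, vc, "spmot")
            rels.append(bv.df.set_index("animal").loc["x", "rel"])
        assert np.all(np.diff(rels) > 0)

    def test_unphenotyped_animal_predicted_through_pedigree(self):
        from boargwas.quantgen._reml import VarianceComponents

        pedigree = ped([("s", None, None), ("d", None, None), ("o", "s", "d")])
        a = build_A(pedigree)
        phen = make_phenotypes({"s": [14.0, 15.0, 16.0], "d": [12.0, 13.0, 14.0]})
        vc = VarianceComponents(1.0, 0.3, 1.0, converged=True)
        bv = solve_mme_blup(phen, a, vc, "spmot").df.set_index("animal")
        assert bv.loc["o", "n_records"] == 0
        assert bv.loc["o", "ebv"] == pytest.approx(
            (bv.loc["s", "ebv"] + bv.loc["d", "ebv"]) / 2, abs=1e-8
        )


def _bv_table(rows):
    df = pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "n_records", "ebv", "rel"]
    )
    return BreedingValueSet(df=df, trait="spmot")


class TestDeregression:
    def test_hand_worked_case(self):
        bv = _bv_table(
            [
                ("s", None, None, 10, 1.0, 0.4),
                ("d", None, None, 10, 0.6, 0.4),
                ("i", "s", "d", 10, 2.0, 0.5),
            ]
        )
        out = deregress(bv, h2=0.25).df.set_index("animal")
        row = out.loc["i"]
        assert row["pa"] == pytest.approx(0.8)
        assert row["rel_pa"] == pytest.approx(0.2)
        assert row["de_i"] == pytest.approx(3.0)
        assert row["de_pa"] == pytest.approx(0.75)
        assert row["r_i"] == pytest.approx(0.75)
        assert row["debv"] == pytest.approx(2.4)

    def test_unknown_parents_collapse_to_identity(self):
        bv = _bv_table([("x", None, None, 5, 1.7, 0.6)])
        out = deregress(bv, h2=0.3).df.iloc[0]
        assert out["rel_pa"] == 0.0
        assert out["r_i"] == pytest.approx(1.0)
        assert out["debv"] == pytest.approx(out["ebv"])
        # and Rel_DEBV reduces to REL when PA carries no information
        assert out["rel_debv"] == pytest.approx(0.6)

    def test_debv_preserves_sign_of_ebv_minus_pa(self):
        rng = np.random.default_rng(8)
        rows = [("s", None, None, 10, 0.5, 0.5), ("d", None, None, 10, -0.5, 0.5)]
        rows += [
            (f"i{k}", "s", "d", 10, rng.normal(), rng.uniform(0.3, 0.9))
            for k in range(20)
        ]
        out = deregress(_bv_table(rows), h2=0.3).df
        kids = out[out["sire"].notna() & out["excluded"].isna()]
        assert np.all(
            np.sign(kids["debv"] - kids["pa"]) == np.sign(kids["ebv"] - kids["pa"])
        )

    def test_low_information_animal_flagged(self):
        # own REL below parent-average information -> R_i <= 0
        bv = _bv_table(
            [
                ("s", None, None, 50, 1.0, 0.9),
                ("d", None, None, 50, 0.6, 0.9),
                ("i", "s", "d", 0, 0.8, 0.3),
            ]
        )
        out = deregress(bv, h2=0.25).df.set_index("animal")
        assert out.loc["i", "excluded"] == "r_i_nonpositive"
        assert np.isnan(out.loc["i", "debv"])

    def test_rel_one_errors(self):
        bv = _bv_table([("x", None, None, 5, 1.0, 1.0)])
        with pytest.raises(ValueError):
            deregress(bv, h2=0.3)


class TestWeights:
    def _weights_for(self, rel_debv, rel_pa, h2=0.25, c=0.1):
        bv = _bv_table([("x", None, None, 5, 1.0, 0.5)])
        out = deregress(bv, h2=h2)
        out.df["rel_debv"] = rel_debv
        out.df["rel_pa"] = rel_pa
        return compute_weights(out, h2=h2, c=c).df.iloc[0]

    def test_direct_evaluation(self):
        # Rel_Animal = 0.5 at h2 = 0.25, c = 0.1 -> 0.75 / 0.35
        row = self._weights_for(rel_debv=0.5, rel_pa=0.0)
        assert row["rel_animal"] == pytest.approx(0.5)
        assert row["weight"] == pytest.approx(0.75 / 0.35)

    def test_high_reliability_limit(self):
        row = self._weights_for(rel_debv=1 - 1e-12, rel_pa=0.0, h2=0.3)
        assert row["weight"] == pytest.approx((1 - 0.3) / 0.1, rel=1e-6)

    def test_zero_reliability_limit(self):
        row = self._weights_for(rel_debv=1e-12, rel_pa=0.0, h2=0.3)
        assert row["weight"] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_reliability(self):
        weights = [
            self._weights_for(rel_debv=r, rel_pa=0.0)["weight"]
            for r in np.linspace(0.05, 0.95, 12)
        ]
        assert np.all(np.diff(weights) > 0)

    def test_nonpositive_rel_animal_excluded(self):
        row = self._weights_for(rel_debv=0.2, rel_pa=0.4)
        assert row["excluded"] == "rel_animal_nonpositive"
        assert np.isnan(row["weight"])
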