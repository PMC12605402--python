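import numpy as np
import pandas as pd
import pytest

from lethalhap import mixed, synthetic as syn
from lethalhap.data_io import Pedigree
from lethalhap.mixed import (
    MixedModelError,
    ModelSpec,
    VarianceComponents,
    a_inverse,
    build_design,
    corrected_phenotypes_repeatability,
    corrected_phenotypes_stillbirth,
    fit_stillbirth_group,
    heritability,
    inbreeding_coefficients,
    kinship_matrix,
    reml,
    solve_blup,
)

from conftest import random_pedigree


def ped_from_rows(rows, **extra_cols):
    df = pd.DataFrame(rows, columns=["individual", "sire", "dam"])
    for k, v in extra_cols.items():
        df[k] = v
    return Pedigree(df)


class TestAInverse:
    def test_single_founder(self):
        ped = ped_from_rows([("a", "0", "0")])
        Ai, groups = a_inverse(ped)
        assert groups == []
        np.testing.assert_allclose(Ai.toarray(), [[1.0]])

    def test_non_inbred_trio(self):
        ped = ped_from_rows([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])
        Ai, _ = a_inverse(ped)
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(Ai.toarray(), expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_tabular_inverse(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, int(rng.integers(20, 100)))
        sire, dam = ped.parent_indices()
        A = kinship_matrix(sire, dam)
        Ai, _ = a_inverse(ped)
        np.testing.assert_allclose(Ai.toarray() @ A, np.eye(len(ped)), atol=1e-8)

    def test_inbreeding_coefficients_full_sib_offspring(self):
        ped = ped_from_rows(
            [("s", "0", "0"), ("d", "0", "0"), ("a", "s", "d"), ("b", "s", "d"),
             ("x", "a", "b")]
        )
        sire, dam = ped.parent_indices()
        F = inbreeding_coefficients(sire, dam)
        assert F[-1] == pytest.approx(0.25)  # full-sib mating

    def test_upg_adds_group_columns(self):
        ped = ped_from_rows(
            [("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")],
            upg=["G1", "G2", ""],
        )
        Ai, groups = a_inverse(ped, use_upg=True)
        assert sorted(groups) == ["G1", "G2"]
        assert Ai.shape == (5, 5)
        # individual block must still be positive definite
        block = Ai.toarray()[:3, :3]
        assert np.linalg.eigvalsh(block).min() > 0


class TestREML:
    def test_balanced_one_way_matches_anova(self, rng):
        # balanced one-way random-effect layout: REML equals the closed-form
        # ANOVA estimator
        s, n = 40, 6
        s2u, s2e = 0.5, 1.0
        groups = np.repeat(np.arange(s), n)
        u = rng.normal(0, np.sqrt(s2u), s)
        y = 2.0 + u[groups] + rng.normal(0, np.sqrt(s2e), s * n)
        data = pd.DataFrame({"g": groups.astype(str), "y": y})
        spec = ModelSpec(response="y", fixed_terms=[], random_terms=[("g", "g", "identity")])
        yv, X, labels, terms, _ = build_design(data, spec)
        vc, info = reml(yv, X, terms, tol=1e-7)
        gm = data.groupby("g")["y"].mean()
        msb = n * np.sum((gm - y.mean()) ** 2) / (s - 1)
        msw = np.sum((y - gm[data["g"]].to_numpy()) ** 2) / (s * (n - 1))
        assert vc["residual"] == pytest.approx(msw, rel=1e-4)
        assert vc["g"] == pytest.approx((msb - msw) / n, rel=1e-3)
        assert info["converged"]

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        s, n = 30, 5
        groups = np.repeat(np.arange(s), n)
        x = rng.normal(size=s * n)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.7, s)[groups] + rng.normal(0, 1.0, s * n)
        data = pd.DataFrame({"g": groups.astype(str), "x": x, "y": y})
        spec = ModelSpec(response="y", fixed_terms=[("cov", "x")], random_terms=[("g", "g", "identity")])
        yv, X, labels, terms, _ = build_design(data, spec)
        vc, _ = reml(yv, X, terms, tol=1e-7)
        sm_fit = smf.mixedlm("y ~ x", data, groups=data["g"]).fit(reml=True)
        assert vc["g"] == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert vc["residual"] == pytest.approx(float(sm_fit.scale), rel=1e-3)

    def test_zero_signal_hits_floor_flagged(self, rng):
        s, n = 25, 4
        groups = np.repeat(np.arange(s), n)
        y = rng.normal(size=s * n)  # no group signal
        data = pd.DataFrame({"g": groups.astype(str), "y": y})
        spec = ModelSpec(response="y", fixed_terms=[], random_terms=[("g", "g", "identity")])
        yv, X, labels, terms, _ = build_design(data, spec)
        vc, info = reml(yv, X, terms, tol=1e-6)
        assert vc["g"] < 0.05
        # either converged near zero or flagged at the floor
        assert info["converged"]

    def test_invalid_init(self, rng):
        data = pd.DataFrame({"g": ["a", "b"] * 5, "y": rng.normal(size=10)})
        spec = ModelSpec(response="y", fixed_terms=[], random_terms=[("g", "g", "identity")])
        yv, X, labels, terms, _ = build_design(data, spec)
        with pytest.raises(MixedModelError):
            reml(yv, X, terms, init={"g": -1.0, "residual": 1.0})


class TestSolveBLUP:
    def _pedigree_data(self, rng, n_founders=80):
        params = syn.SimulationParams(
            n_founders=n_founders, n_generations=2, sires_per_generation=4,
            daughters_per_sire=12, seed=3,
        )
        ped = syn.simulate_pedigree(params)
        return ped

    def test_shrinks_to_ols_as_s2u_vanishes(self, rng):
        ped = self._pedigree_data(rng)
        u = syn.drop_breeding_values(ped, 0.3, rng)
        rows = [
            {"animal": ind, "x": rng.normal(), "y": 0.0}
            for ind in ped.individuals
        ]
        data = pd.DataFrame(rows)
        data["y"] = 1.0 + 2.0 * data["x"] + u[: len(data)] + rng.normal(0, 0.5, len(data))
        spec = ModelSpec(
            response="y", fixed_terms=[("cov", "x")],
            random_terms=[("animal", "animal", "pedigree-additive")],
        )
        y, X, labels, terms, _ = build_design(data, spec, pedigree=ped)
        vc = VarianceComponents({"animal": 1e-10, "residual": 0.5})
        fit = solve_blup(y, X, terms, vc, fixed_labels=labels)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.fixed_solutions, beta_ols, atol=1e-5)
        _, uhat = fit.random_solutions["animal"]
        assert np.abs(uhat).max() < 1e-6

    def test_ebv_tracks_truth_with_strong_signal(self, rng):
        ped = self._pedigree_data(rng, n_founders=120)
        u = syn.drop_breeding_values(ped, 1.0, rng)
        rows = []
        for i, ind in enumerate(ped.individuals):
            for _ in range(3):
                rows.append({"animal": ind, "y": u[i] + rng.normal(0, 0.1)})
        data = pd.DataFrame(rows)
        spec = ModelSpec(
            response="y", fixed_terms=[],
            random_terms=[("animal", "animal", "pedigree-additive")],
        )
        y, X, labels, terms, _ = build_design(data, spec, pedigree=ped)
        fit = solve_blup(y, X, terms, VarianceComponents({"animal": 1.0, "residual": 0.01}),
                         fixed_labels=labels)
        levels, uhat = fit.random_solutions["animal"]
        est = np.array([uhat[levels.index(i)] for i in ped.individuals])
        assert np.corrcoef(est, u)[0, 1] > 0.95

    def test_mme_residual_norm_invariant(self, rng):
        ped = self._pedigree_data(rng)
        rows = [{"animal": ind, "y": rng.normal()} for ind in ped.individuals]
        data = pd.DataFrame(rows)
        spec = ModelSpec(
            response="y", fixed_terms=[],
            random_terms=[("animal", "animal", "pedigree-additive")],
        )
        y, X, labels, terms, _ = build_design(data, spec, pedigree=ped)
        from lethalhap.mixed import _MME

        mme = _MME(y, X, terms, {"animal": 0.4, "residual": 0.6})
        resid = mme.C @ mme.sol - mme.rhs
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(mme.rhs)

    def test_fitted_plus_residual_reproduces_y(self, rng):
        ped = self._pedigree_data(rng)
        rows = [{"animal": ind, "y": rng.normal()} for ind in ped.individuals]
        data = pd.DataFrame(rows)
        spec = ModelSpec(response="y", fixed_terms=[],
                         random_terms=[("animal", "animal", "pedigree-additive")])
        y, X, labels, terms, _ = build_design(data, spec, pedigree=ped)
        fit = solve_blup(y, X, terms, VarianceComponents({"animal": 0.3, "residual": 0.7}),
                         fixed_labels=labels)
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-10)

    def test_negative_variance_rejected(self, rng):
        ped = self._pedigree_data(rng)
        rows = [{"animal": ind, "y": rng.normal()} for ind in ped.individuals]
        data = pd.DataFrame(rows)
        spec = ModelSpec(response="y", fixed_terms=[],
                         random_terms=[("animal", "animal", "pedigree-additive")])
        y, X, labels, terms, _ = build_design(data, spec, pedigree=ped)
        with pytest.raises(MixedModelError):
            solve_blup(y, X, terms, VarianceComponents({"animal": -0.1, "residual": 0.7}))


class TestMaternalDirectModel:
    def test_shape_contract(self, rng):
        params = syn.SimulationParams(
            n_founders=60, n_generations=2, sires_per_generation=4,
            daughters_per_sire=8, seed=8,
        )
        ped = syn.simulate_pedigree(params)
        calves = ped.table[ped.table["dam"] != "0"]
        records = pd.DataFrame(
            {
                "value": rng.integers(0, 2, len(calves)).astype(float),
                "calf": calves["individual"].to_numpy(),
                "dam": calves["dam"].to_numpy(),
                "calf_sex": calves["sex"].to_numpy(),
            }
        )
        vc = {"maternal": 0.1, "direct": 0.1, "pe": 0.05,
              "residual": 0.8, "cov_direct_maternal": 0.02}
        fit = fit_stillbirth_group(records, ped, vc, with_pe=True)
        for term in ("maternal", "direct"):
            levels, values = fit.random_solutions[term]
            assert len(values) == len(ped)
        assert len(fit.residuals) == len(records)

    def test_non_pd_genetic_covariance_rejected(self, rng):
        ped = syn.simulate_pedigree(
            syn.SimulationParams(n_founders=20, n_generations=1,
                                 sires_per_generation=2, daughters_per_sire=4, seed=1)
        )
        calves = ped.table[ped.table["dam"] != "0"]
        records = pd.DataFrame(
            {"value": np.ones(len(calves)), "calf": calves["individual"].to_numpy(),
             "dam": calves["dam"].to_numpy()}
        )
        vc = {"maternal": 0.1, "direct": 0.1, "pe": 0.05,
              "residual": 0.8, "cov_direct_maternal": 0.5}
        with pytest.raises(MixedModelError, match="positive definite"):
            fit_stillbirth_group(records, ped, vc, with_pe=False)


class TestCorrectedPhenotypes:
    def test_arithmetic(self):
        # EBV 0.1, PE 0.02, residuals (0.3, -0.1) -> y* = 0.22
        fit = mixed.MixedModelFit(
            varcomp=VarianceComponents({"animal": 0.1, "pe": 0.1, "residual": 0.8}),
            fixed_labels=["intercept"],
            fixed_solutions=np.array([0.0]),
            random_solutions={
                "animal": (["cow1"], np.array([0.1])),
                "pe": (["cow1"], np.array([0.02])),
            },
            residuals=np.array([0.3, -0.1]),
            fitted=np.zeros(2),
            y=np.array([0.3, -0.1]),
            n_fixed=1,
        )
        records = pd.DataFrame({"animal": ["cow1", "cow1"]})
        out = corrected_phenotypes_repeatability(fit, records, "animal", "CR")
        assert out.iloc[0]["y_star"] == pytest.approx(0.22)

    def test_single_record_no_pe(self):
        fit = mixed.MixedModelFit(
            varcomp=VarianceComponents({"animal": 0.1, "residual": 0.8}),
            fixed_labels=["intercept"],
            fixed_solutions=np.array([0.0]),
            random_solutions={"animal": (["cow1"], np.array([0.05]))},
            residuals=np.array([0.2]),
            fitted=np.zeros(1),
            y=np.array([0.2]),
            n_fixed=1,
        )
        records = pd.DataFrame({"animal": ["cow1"]})
        out = corrected_phenotypes_repeatability(fit, records, "animal", "IFL")
        assert out.iloc[0]["y_star"] == pytest.approx(0.25)

    def test_animal_without_record_excluded(self):
        fit = mixed.MixedModelFit(
            varcomp=VarianceComponents({"animal": 0.1, "residual": 0.8}),
            fixed_labels=["intercept"],
            fixed_solutions=np.array([0.0]),
            random_solutions={"animal": (["cow1", "cow2"], np.array([0.05, 0.1]))},
            residuals=np.array([0.2]),
            fitted=np.zeros(1),
            y=np.array([0.2]),
            n_fixed=1,
        )
        records = pd.DataFrame({"animal": ["cow1"]})
        out = corrected_phenotypes_repeatability(fit, records, "animal", "AIS")
        assert list(out["animal"]) == ["cow1"]

    def test_stillbirth_variants(self, rng):
        params = syn.SimulationParams(
            n_founders=50, n_generations=2, sires_per_generation=3,
            daughters_per_sire=6, seed=4,
        )
        ped = syn.simulate_pedigree(params)
        calves = ped.table[ped.table["dam"] != "0"].reset_index(drop=True)
        parities = calves.groupby("dam").cumcount()
        records = pd.DataFrame(
            {
                "value": rng.integers(0, 2, len(calves)).astype(float),
                "calf": calves["individual"],
                "dam": calves["dam"],
                "parity": parities,
            }
        )
        first = records[records["parity"] == 0].reset_index(drop=True)
        later = records[records["parity"] > 0].reset_index(drop=True)
        vc = {"maternal": 0.1, "direct": 0.1, "pe": 0.05, "residual": 0.8,
              "cov_direct_maternal": 0.0}
        fit1 = fit_stillbirth_group(first, ped, vc, with_pe=False, fixed_terms=[])
        fit2 = fit_stillbirth_group(later, ped, vc, with_pe=True, fixed_terms=[])
        out = corrected_phenotypes_stillbirth(fit1, first, fit2, later)
        assert set(out["trait"]) == {"DSB1", "SSB1", "DSB2", "SSB2"}
        # DSB2 = maternal EBV + PE + mean of the dam's later residuals
        dam = later["dam"].iloc[0]
        grp = later[later["dam"] == dam]
        lv, mv = fit2.random_solutions["maternal"]
        pe_lv, pe_v = fit2.random_solutions["pe"]
        expected = (
            mv[lv.index(dam)]
            + pe_v[pe_lv.index(dam)]
            + fit2.residuals[grp.index.to_numpy()].mean()
        )
        got = out[(out["animal"] == dam) & (out["trait"] == "DSB2")]["y_star"].iloc[0]
        assert got == pytest.approx(expected)


class TestHeritability:
    def test_basic(self):
        vc = {"maternal": 0.1, "direct": 0.2, "residual": 0.7, "cov_direct_maternal": 0.0}
        assert heritability(vc, "maternal") == pytest.approx(0.1)
        assert heritability(vc, "direct") == pytest.approx(0.2)

    def test_negative_covariance(self):
        vc = {"maternal": 0.1, "direct": 0.2, "residual": 0.7, "cov_direct_maternal": -0.05}
        assert heritability(vc, "maternal") == pytest.approx(0.1 / 0.9)
        assert heritability(vc, "maternal") == pytest.approx(0.111, abs=1e-3)

    def test_zero_maternal(self):
        vc = {"maternal": 0.0, "direct": 0.2, "residual": 0.8, "cov_direct_maternal": 0.0}
        assert heritability(vc, "maternal") == 0.0

    def test_repeatability(self):
        vc = {"animal": 0.2, "pe": 0.1, "residual": 0.7}
        assert heritability(vc, "repeatability") == pytest.approx(0.2)

    def test_bad_denominator(self):
        vc = {"maternal": 0.1, "direct": 0.1, "residual": 0.0, "cov_direct_maternal": -0.2}
        with pytest.raises(MixedModelError):
            heritability(vc, "maternal")

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            heritability({"animal": 1, "residual": 1}, "narrow")
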