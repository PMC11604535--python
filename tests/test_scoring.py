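import numpy as np
import pandas as pd
import pytest

from risi.io import ExpressionMatrix, GeneWeightMap, ValidationError
from risi.scoring import (
    ProgramScorer,
    balance_score,
    biomarker_proxies,
    fit_protein_weight_map,
    infer_levels_from_proteins,
    infer_program_levels,
    standardize_levels,
)

from conftest import make_matrix


def normal_equations_oracle(y, v1, v2):
    """Independent brute-force fit: explicit 3x3 normal-equations solve."""
    X = np.column_stack([np.ones_like(v1), v1, v2])
    return np.linalg.solve(X.T @ X, X.T @ y)


def make_weights(conf, prog, pair="R_T", genes=None):
    conf, prog = np.asarray(conf, float), np.asarray(prog, float)
    genes = genes or [f"g{i}" for i in range(len(conf))]
    return GeneWeightMap(
        pd.DataFrame({"confounder": conf, "program": prog}, index=genes),
        pair,
        min_genes=2,
    )


def orthogonal_pair(n_genes, rng):
    """Zero-mean, exactly orthogonal confounder/program vectors."""
    V = rng.standard_normal((n_genes, 2))
    Q, _ = np.linalg.qr(V - V.mean(axis=0))
    return Q[:, 0], Q[:, 1]


class TestInferProgramLevels:
    def test_null_profile_gives_zeros(self, rng):
        v1, v2 = orthogonal_pair(60, rng)
        W = make_weights(v1, v2)
        Z = make_matrix(np.zeros((60, 2)))
        out = infer_program_levels(Z, W)
        np.testing.assert_allclose(out.to_numpy(), 0, atol=1e-12)

    def test_orthogonal_projection_recovers_coefficient(self, rng):
        v_t, v_r = orthogonal_pair(80, rng)
        W = make_weights(v_t, v_r)
        Z = make_matrix((3.0 * v_r)[:, None])
        out = infer_program_levels(Z, W)
        assert out.loc["s0", "s_program"] == pytest.approx(3.0, abs=1e-10)
        assert out.loc["s0", "s_confounder"] == pytest.approx(0.0, abs=1e-10)
        assert out.loc["s0", "b"] == pytest.approx(0.0, abs=1e-10)

    def test_four_gene_case_matches_normal_equations(self):
        v_t = np.array([0.0, 1.0, 1.0, -1.0])
        v_r = np.array([1.0, -1.0, 2.0, 0.0])
        z = np.array([2.0, 0.0, 5.0, -1.0])
        out = infer_program_levels(
            make_matrix(z[:, None]), make_weights(v_t, v_r), min_overlap=4
        )
        expected = normal_equations_oracle(z, v_t, v_r)
        np.testing.assert_allclose(out.loc["s0"].to_numpy(), expected, atol=1e-10)

    def test_oracle_equivalence_100_random_instances(self, rng):
        for trial in range(100):
            n = int(rng.integers(10, 51))
            v1, v2 = rng.normal(size=n), rng.normal(size=n)
            z = rng.normal(size=(n, 3))
            out = infer_program_levels(
                make_matrix(z), make_weights(v1, v2), min_overlap=n
            )
            for j in range(3):
                expected = normal_equations_oracle(z[:, j], v1, v2)
                np.testing.assert_allclose(
                    out.iloc[j].to_numpy(), expected, atol=1e-8
                )

    def test_affine_stability_intercept_absorbs_shift(self, rng):
        v1, v2 = rng.normal(size=50), rng.normal(size=50)
        z = rng.normal(size=(50, 2))
        W = make_weights(v1, v2)
        base = infer_program_levels(make_matrix(z), W)
        shifted = z.copy()
        shifted[:, 0] += 5.0
        out = infer_program_levels(make_matrix(shifted), W)
        assert out.loc["s0", "b"] == pytest.approx(base.loc["s0", "b"] + 5.0)
        np.testing.assert_allclose(
            out[["s_confounder", "s_program"]], base[["s_confounder", "s_program"]],
            atol=1e-9,
        )

    def test_collinear_weights_rejected(self, rng):
        v = rng.normal(size=60)
        with pytest.raises(ValidationError, match="condition number"):
            infer_program_levels(
                make_matrix(rng.normal(size=(60, 1))), make_weights(v, 2 * v)
            )

    def test_missing_genes_pairwise_deletion(self, rng):
        v1, v2 = rng.normal(size=60), rng.normal(size=60)
        z = rng.normal(size=(60, 2))
        holes = z.copy()
        holes[:5, 1] = np.nan
        out = infer_program_levels(
            make_matrix(holes), make_weights(v1, v2), min_overlap=20
        )
        expected = normal_equations_oracle(z[5:, 1], v1[5:], v2[5:])
        np.testing.assert_allclose(out.iloc[1].to_numpy(), expected, atol=1e-9)
        # complete sample unaffected
        np.testing.assert_allclose(
            out.iloc[0].to_numpy(), normal_equations_oracle(z[:, 0], v1, v2),
            atol=1e-9,
        )


class TestStandardizeAndBalance:
    def _levels(self, s_r, s_si, ids=None):
        ids = ids or [f"p{i}" for i in range(len(s_r))]
        return pd.DataFrame({"s_R": s_r, "s_SI": s_si}, index=ids)

    def test_control_standardization_hand_value(self):
        lev = self._levels([-1.0, 0.0, 1.0, 2.0], [0.0, 1.0, 2.0, 3.0],
                           ids=["c1", "c2", "c3", "p"])
        out = standardize_levels(lev, ["c1", "c2", "c3"])
        assert out.loc["p", "z_R"] == pytest.approx(2.449, abs=1e-3)
        assert out.loc[["c1", "c2", "c3"], "z_R"].mean() == pytest.approx(0, abs=1e-12)
        assert out.loc[["c1", "c2", "c3"], "z_R"].std(ddof=0) == pytest.approx(1)
        assert (out["reference_mode"] == "controls").all()

    def test_control_at_mean_is_zero(self):
        lev = self._levels([1.0, 2.0, 3.0], [0.0, 0.5, 1.0], ids=["c1", "c2", "c3"])
        out = standardize_levels(lev, ["c1", "c2", "c3"])
        assert out.loc["c2", "z_R"] == pytest.approx(0.0, abs=1e-12)

    def test_no_controls_falls_back_to_cohort(self):
        lev = self._levels([0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 2.0, 2.0])
        out = standardize_levels(lev, None)
        assert (out["reference_mode"] == "cohort").all()
        assert out["z_R"].mean() == pytest.approx(0, abs=1e-12)

    def test_too_few_controls_errors(self):
        lev = self._levels([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValidationError, match="3 controls"):
            standardize_levels(lev, ["p0", "p1"])

    def test_balance_subtraction_and_antisymmetry(self):
        lev = pd.DataFrame(
            {"z_R": [1.2, 0.7, -0.5], "z_SI": [0.5, 0.7, 2.0]},
            index=["a", "b", "c"],
        )
        bal = balance_score(lev)
        np.testing.assert_allclose(bal, [0.7, 0.0, -2.5])
        swapped = balance_score(lev.rename(columns={"z_R": "z_SI", "z_SI": "z_R"}))
        np.testing.assert_allclose(swapped, -bal)


class TestProgramScorer:
    def test_recovers_latents_on_synthetic_cohort(self, small_cohort, small_scored):
        bundle, truth, w_rt, w_si = small_cohort
        _, levels = small_scored
        r_r = np.corrcoef(levels["s_R"], truth.latents["R"])[0, 1]
        r_si = np.corrcoef(levels["s_SI"], truth.latents["SI"])[0, 1]
        assert r_r > 0.9 and r_si > 0.9

    def test_sklearn_contract(self, small_cohort):
        bundle, truth, w_rt, w_si = small_cohort
        from risi.preprocess import preprocess_pipeline

        Z, _ = preprocess_pipeline(bundle.expression, bundle.samples.control_ids)
        scorer = ProgramScorer(weights_rt=w_rt, weights_si=w_si)
        assert scorer.get_params()["min_overlap"] == 50
        X = Z.data.T
        out = scorer.fit(X, controls=bundle.samples.control_ids).transform(X)
        ctrl = out.loc[bundle.samples.control_ids]
        assert ctrl["z_R"].mean() == pytest.approx(0, abs=1e-9)
        assert ctrl["z_SI"].std(ddof=0) == pytest.approx(1, abs=1e-9)
        assert np.allclose(out["balance"], out["z_R"] - out["z_SI"])
        with pytest.raises(Exception):
            ProgramScorer(weights_rt=w_rt, weights_si=w_si).transform(X)


class TestProteinLevels:
    def test_protein_equal_to_levels_has_unit_weight(self, rng):
        z_r = rng.normal(size=60)
        z_si = 0.4 * z_r + rng.normal(size=60)
        lev = pd.DataFrame(
            {"z_R": z_r, "z_SI": z_si}, index=[f"p{i}" for i in range(60)]
        )
        prot = pd.DataFrame({"A": z_r, "B": rng.normal(size=60)}, index=lev.index)
        pmap = fit_protein_weight_map(lev, prot)
        assert pmap.loc["A", "w_R"] == pytest.approx(1.0)
        assert pmap.loc["A", "w_SI"] == pytest.approx(
            np.corrcoef(z_r, z_si)[0, 1]
        )

    def test_noise_protein_small_weight(self, rng):
        n = 1000
        lev = pd.DataFrame(
            {"z_R": rng.normal(size=n), "z_SI": rng.normal(size=n)},
            index=[f"p{i}" for i in range(n)],
        )
        prot = pd.DataFrame({"noise": rng.normal(size=n)}, index=lev.index)
        pmap = fit_protein_weight_map(lev, prot)
        assert abs(pmap.loc["noise", "w_R"]) < 0.1

    def test_constant_protein_skipped_with_warning(self, rng):
        lev = pd.DataFrame(
            {"z_R": rng.normal(size=20), "z_SI": rng.normal(size=20)},
            index=[f"p{i}" for i in range(20)],
        )
        prot = pd.DataFrame({"flat": np.ones(20)}, index=lev.index)
        with pytest.warns(UserWarning, match="without weights"):
            pmap = fit_protein_weight_map(lev, prot)
        assert np.isnan(pmap.loc["flat", "w_R"])

    def test_protein_inference_orthogonal_and_oracle(self, rng):
        n_prot = 40
        V = rng.standard_normal((n_prot, 2))
        Q, _ = np.linalg.qr(V - V.mean(axis=0))
        w_r, w_si = Q[:, 0], Q[:, 1]
        pmap = pd.DataFrame(
            {"w_R": w_r, "w_SI": w_si}, index=[f"P{i}" for i in range(n_prot)]
        )
        profile = pd.DataFrame(
            [2.0 * w_r, np.zeros(n_prot)], index=["a", "zero"], columns=pmap.index
        )
        out = infer_levels_from_proteins(profile, pmap, standardize_profiles=False)
        assert out.loc["a", "s_R"] == pytest.approx(2.0, abs=1e-10)
        assert out.loc["a", "s_SI"] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(out.loc["zero"], 0, atol=1e-12)
        # 6-protein worked case vs normal-equations oracle
        pmap6 = pd.DataFrame(
            {"w_R": rng.normal(size=12), "w_SI": rng.normal(size=12)},
            index=[f"Q{i}" for i in range(12)],
        )
        prof6 = pd.DataFrame(
            rng.normal(size=(1, 12)), index=["x"], columns=pmap6.index
        )
        out6 = infer_levels_from_proteins(
            prof6, pmap6, min_overlap=12, standardize_profiles=False
        )
        exp = normal_equations_oracle(
            prof6.loc["x"].to_numpy(), pmap6["w_R"].to_numpy(), pmap6["w_SI"].to_numpy()
        )
        np.testing.assert_allclose(out6.loc["x"].to_numpy(), exp, atol=1e-8)


class TestBiomarkerProxies:
    def _table(self, rng, n=30):
        return pd.DataFrame(
            rng.normal(size=(n, 5)),
            columns=["CXCL11", "IFNg", "IL6", "IL8", "other"],
            index=[f"p{i}" for i in range(n)],
        )

    def test_proxy_is_mean_of_zscores(self, rng):
        t = self._table(rng)
        out = biomarker_proxies(t)
        z = (t - t.mean()) / t.std(ddof=0)
        np.testing.assert_allclose(
            out["R_proxy"], z[["CXCL11", "IFNg"]].mean(axis=1)
        )
        np.testing.assert_allclose(
            out["balance_proxy"], out["R_proxy"] - out["SI_proxy"]
        )

    def test_missing_marker_protein_errors(self, rng):
        t = self._table(rng).drop(columns=["IL8"])
        with pytest.raises(ValidationError, match="IL8"):
            biomarker_proxies(t)

    def test_partial_sample_degrades_to_single_marker(self, rng):
        t = self._table(rng)
        t.loc["p3", "IL8"] = np.nan
        out = biomarker_proxies(t)
        z_il6 = ((t["IL6"] - t["IL6"].mean()) / t["IL6"].std(ddof=0)).loc["p3"]
        assert out.loc["p3", "SI_proxy"] == pytest.approx(z_il6)
        assert bool(out.loc["p3", "partial"])
        assert not out.loc["p0", "partial"]
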