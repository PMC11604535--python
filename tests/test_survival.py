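import numpy as np
import pandas as pd
import pytest

from risi.io import ValidationError
from risi.simulate import GeneratorConfig, generate_survival
from risi.survival import (
    assign_endotypes,
    calibrate_thresholds,
    cox_ph,
    km_logrank,
)


def _levels(rng, n, ids=None):
    z_r, z_si = rng.normal(size=n), rng.normal(size=n)
    return pd.DataFrame(
        {"z_R": z_r, "z_SI": z_si, "balance": z_r - z_si},
        index=ids or [f"p{i}" for i in range(n)],
    )


def _latents(rng, n):
    return pd.DataFrame(
        rng.normal(size=(n, 4)),
        columns=["R", "T", "SI", "IM1"],
        index=[f"p{i}" for i in range(n)],
    )


class TestAssignEndotypes:
    def test_rule_application(self, rng):
        lev = _levels(rng, 100)
        lev.loc["p0", ["balance", "z_SI"]] = [0.5, 0.0]
        lev.loc["p1", ["balance", "z_SI"]] = [-2.0, lev["z_SI"].quantile(0.99)]
        lev.loc["p2", ["balance", "z_SI"]] = [-2.0, lev["z_SI"].quantile(0.10)]
        out = assign_endotypes(lev, balance_thresh=0.0, si_quantile=0.85)
        assert out.loc["p0", "endotype"] == "moderate_imbalance"
        assert out.loc["p1", "endotype"] == "high_SI"
        assert out.loc["p2", "endotype"] == "severe_imbalance"

    def test_partition_covers_and_is_disjoint(self, rng):
        lev = _levels(rng, 200)
        out = assign_endotypes(lev)
        assert out["endotype"].notna().all()
        assert set(out["endotype"]) <= {
            "moderate_imbalance", "severe_imbalance", "high_SI"
        }
        # high_SI implies low balance and high SI
        hi = out[out["endotype"] == "high_SI"]
        th = out.attrs["thresholds_used"]
        assert (hi["balance"] < th["balance_thresh"]).all()
        assert (hi["z_SI"] >= th["si_thresh"]).all()

    def test_missing_levels_listed_unassigned(self, rng):
        lev = _levels(rng, 20)
        lev.loc["p3", "balance"] = np.nan
        with pytest.warns(UserWarning, match="unassigned"):
            out = assign_endotypes(lev)
        assert "p3" in out.attrs["unassigned"]
        assert pd.isna(out.loc["p3", "endotype"])

    def test_calibrated_thresholds_recover_target_shares(self, rng):
        # engineered cohort with the printed 20/62/16% class mix as the
        # simulation design target
        lev = _levels(rng, 1000)
        target = {"moderate_imbalance": 0.20, "severe_imbalance": 0.62, "high_SI": 0.16}
        th = calibrate_thresholds(lev, target)
        out = assign_endotypes(
            lev, balance_thresh=th["balance_thresh"], si_thresh=th["si_thresh"]
        )
        shares = out["endotype"].value_counts(normalize=True)
        for k, v in target.items():
            assert shares[k] == pytest.approx(v, abs=0.05)


class TestKaplanMeierLogrank:
    def _surv(self, times, events, ids):
        return pd.DataFrame(
            {"time_days": times, "event": events}, index=ids
        )

    def _assign(self, groups, ids):
        return pd.DataFrame({"endotype": groups}, index=ids)

    def test_identical_groups_p_near_one(self):
        ids = [f"p{i}" for i in range(20)]
        times = list(range(1, 11)) * 2
        surv = self._surv(times, [1] * 20, ids)
        assign = self._assign(["a"] * 10 + ["b"] * 10, ids)
        # group b has exactly the same event times as group a
        res = km_logrank(assign, surv)
        assert res["overall_p"] > 0.9

    def test_hazard_ratio_3_power(self, rng):
        sig = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            ids = [f"p{i}" for i in range(200)]
            t1 = r.exponential(10.0, size=100)
            t2 = r.exponential(10.0 / 3.0, size=100)
            times = np.clip(np.r_[t1, t2], None, 28.0)
            events = (np.r_[t1, t2] <= 28.0).astype(int)
            res = km_logrank(
                self._assign(["lo"] * 100 + ["hi"] * 100, ids),
                self._surv(times, events, ids),
            )
            sig += res["overall_p"] < 0.01
        assert sig >= 19  # >= 95% power

    def test_hand_worked_small_logrank(self):
        # 3 patients per arm, all events; hand-worked 2x2 risk tables
        ids = list("abcdef")
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        assign = self._assign(["x", "x", "x", "y", "y", "y"], ids)
        surv = self._surv(times, [1] * 6, ids)
        res = km_logrank(assign, surv, min_group=3)
        # observed events in x: 3; expected: 3/6+2/5+1/4 = 1.15
        # variance: sum of hypergeometric variances at each event time
        o_minus_e = 3 - (3 / 6 + 2 / 5 + 1 / 4)
        # at each death time t_i with n at risk, n_x in x, d=1:
        # var = n_x * n_y / n^2 ... (d=1, no ties) over the 5 informative times
        var = 0.0
        at_risk = [(3, 3), (2, 3), (1, 3), (0, 3), (0, 2)]
        for nx, ny in at_risk:
            n = nx + ny
            var += nx * ny / n**2
        chi2 = o_minus_e**2 / var
        assert res["overall_statistic"] == pytest.approx(chi2, rel=1e-6)

    def test_small_group_excluded(self, rng):
        ids = [f"p{i}" for i in range(25)]
        times = rng.exponential(10, size=25)
        assign = self._assign(["a"] * 12 + ["b"] * 11 + ["c"] * 2, ids)
        surv = self._surv(times, [1] * 25, ids)
        with pytest.warns(UserWarning, match="excluding"):
            res = km_logrank(assign, surv)
        assert set(res["curves"]) == {"a", "b"}

    def test_breslow_variant_runs(self, rng):
        ids = [f"p{i}" for i in range(40)]
        times = np.ceil(rng.exponential(8, size=40))
        assign = self._assign(["a"] * 20 + ["b"] * 20, ids)
        surv = self._surv(times, [1] * 40, ids)
        res = km_logrank(assign, surv, test="breslow")
        assert 0 <= res["overall_p"] <= 1

    def test_km_product_limit_hand_case(self):
        # 6 patients, one censored: S(2) = 5/6 * 3/4 after censoring at t=1.5
        ids = list("abcdef")
        times = [1.0, 1.5, 2.0, 3.0, 4.0, 5.0]
        events = [1, 0, 1, 1, 1, 1]
        assign = self._assign(["g"] * 6 + [], ids)
        surv = self._surv(times, events, ids)
        res = km_logrank(
            pd.concat([assign, self._assign(["h"] * 3, ["x", "y", "z"])]),
            pd.concat([surv, self._surv([9.0, 9.0, 9.0], [1, 1, 1], ["x", "y", "z"])]),
            min_group=3,
        )
        curve = res["curves"]["g"]
        assert curve.loc[1.0].iloc[0] == pytest.approx(5 / 6)
        assert curve.loc[2.0].iloc[0] == pytest.approx(5 / 6 * 3 / 4)


class TestCoxPH:
    def test_null_covariate_ci_covers_zero(self):
        cover = 0
        for rep in range(30):
            r = np.random.default_rng(100 + rep)
            n = 150
            ids = [f"p{i}" for i in range(n)]
            x = pd.DataFrame({"x": r.normal(size=n)}, index=ids)
            times = np.clip(r.exponential(10, size=n), None, 28)
            surv = pd.DataFrame(
                {"time_days": times, "event": (times < 28).astype(int)}, index=ids
            )
            res = cox_ph(surv, x)
            cover += res.loc["x", "ci_lower"] <= 0 <= res.loc["x", "ci_upper"]
        assert cover >= 25  # ~95% coverage

    def test_recovers_balance_log_hazard(self, rng):
        n = 500
        ids = [f"p{i}" for i in range(n)]
        bal = rng.normal(size=n)
        lam = 0.05 * np.exp(-0.8 * bal)
        raw = rng.exponential(1 / lam)
        surv = pd.DataFrame(
            {
                "time_days": np.minimum(raw, 28.0),
                "event": (raw <= 28.0).astype(int),
            },
            index=ids,
        )
        res = cox_ph(surv, pd.DataFrame({"balance": bal}, index=ids))
        assert res.loc["balance", "log_HR"] == pytest.approx(-0.8, abs=0.2)

    def test_time_scale_invariance(self, rng):
        n = 120
        ids = [f"p{i}" for i in range(n)]
        x = pd.DataFrame({"x": rng.normal(size=n)}, index=ids)
        times = rng.exponential(10, size=n)
        surv = pd.DataFrame({"time_days": times, "event": 1}, index=ids)
        doubled = surv.assign(time_days=times * 2)
        a = cox_ph(surv, x)
        b = cox_ph(doubled, x)
        assert a.loc["x", "log_HR"] == pytest.approx(b.loc["x", "log_HR"], abs=1e-6)

    def test_too_few_events_rejected(self, rng):
        ids = [f"p{i}" for i in range(40)]
        surv = pd.DataFrame(
            {"time_days": np.full(40, 28.0), "event": [1] * 5 + [0] * 35}, index=ids
        )
        with pytest.raises(ValidationError, match="events"):
            cox_ph(surv, pd.DataFrame({"x": rng.normal(size=40)}, index=ids))


class TestGeneratedSurvival:
    def test_event_rate_matches_design_target(self, rng):
        lat = _latents(rng, 800)
        surv = generate_survival(lat, seed=3)
        assert surv["event"].mean() == pytest.approx(0.59, abs=0.05)
        assert (surv["time_days"] <= 28.0).all()

    def test_cox_recovers_generator_log_hazards(self, rng):
        lat = _latents(rng, 500)
        surv = generate_survival(lat, beta_si=0.7, beta_r=-0.7, seed=8)
        cov = pd.DataFrame({"SI": lat["SI"], "R": lat["R"]}, index=lat.index)
        res = cox_ph(surv, cov)
        assert res.loc["SI", "log_HR"] == pytest.approx(0.7, abs=0.2)
        assert res.loc["R", "log_HR"] == pytest.approx(-0.7, abs=0.2)

    def test_null_betas_indistinguishable_endotypes(self, rng):
        lat = _latents(rng, 300)
        surv = generate_survival(lat, beta_si=0.0, beta_r=0.0, seed=5)
        lev = pd.DataFrame(
            {
                "z_R": lat["R"],
                "z_SI": lat["SI"],
                "balance": lat["R"] - lat["SI"],
            },
            index=lat.index,
        )
        assign = assign_endotypes(lev)
        res = km_logrank(assign, surv)
        assert res["overall_p"] > 0.01

    def test_endotype_survival_ordering_on_default_cohort(self, rng):
        # hazard rises with SI and falls with R: high-SI worst, moderate best
        lat = _latents(rng, 220)
        lat["SI"] = lat["SI"] + 1.0  # sepsis-like elevated SI
        surv = generate_survival(lat, seed=13)
        lev = pd.DataFrame(
            {"z_R": lat["R"], "z_SI": lat["SI"], "balance": lat["R"] - lat["SI"]},
            index=lat.index,
        )
        assign = assign_endotypes(lev, balance_thresh=0.0, si_quantile=0.85)
        res = km_logrank(assign, surv)
        assert res["overall_p"] < 0.05
        death_rate = (
            assign.join(surv).groupby("endotype")["event"].mean()
        )
        assert (
            death_rate["high_SI"]
            > death_rate["severe_imbalance"]
            > death_rate["moderate_imbalance"]
        )
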