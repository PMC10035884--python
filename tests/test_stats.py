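"""Multilevel statistics: ICC, design effect, mixed models, simple
slopes, assumption checks, responder classification."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from fmtheta import stats, synth
from fmtheta.types import SubjectParams


def _clustered_table(tau, sigma2, n_subjects=30, n_obs=30, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, np.sqrt(tau))
        for j in range(n_obs):
            rows.append(dict(subject=f"S{i:02d}", session=j % 5 + 1,
                             modulation=j % 2, y=u + rng.normal(0, np.sqrt(sigma2))))
    return pd.DataFrame(rows)


class TestDesignEffect:
    @pytest.mark.parametrize("icc,expected", [
        (0.78, 23.62), (0.80, 24.20), (0.29, 9.41), (0.10, 3.90), (0.49, 15.21),
    ])
    def test_printed_values_at_cluster_size_30(self, icc, expected):
        assert stats.design_effect(icc, 30) == pytest.approx(expected, abs=0.005)

    def test_boundaries(self):
        assert stats.design_effect(0.0, 17) == 1.0
        assert stats.design_effect(1.0, 17) == 17.0

    def test_monotone_in_both_arguments(self):
        assert stats.design_effect(0.3, 10) < stats.design_effect(0.4, 10)
        assert stats.design_effect(0.3, 10) < stats.design_effect(0.3, 20)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            stats.design_effect(1.5, 10)
        with pytest.raises(ValueError):
            stats.design_effect(0.5, 0)


class TestInterceptsOnly:
    def test_no_clustering_gives_near_zero_icc(self):
        tab = _clustered_table(0.0, 1.0, seed=4)
        res = stats.fit_intercepts_only(tab)
        assert res.icc < 0.05

    def test_icc_recovery_tau3_sigma1(self):
        iccs = [stats.fit_intercepts_only(_clustered_table(3.0, 1.0, seed=s)).icc
                for s in range(25)]
        assert np.mean(iccs) == pytest.approx(0.75, abs=0.05)

    def test_reml_matches_anova_method_of_moments(self):
        # balanced one-way oracle: MS_between/MS_within decomposition
        tab = _clustered_table(3.0, 1.0, n_subjects=60, n_obs=40, seed=9)
        res = stats.fit_intercepts_only(tab)
        g = tab.groupby("subject")["y"]
        n = 40
        ms_within = (g.var(ddof=1)).mean()
        ms_between = n * g.mean().var(ddof=1)
        tau_mm = (ms_between - ms_within) / n
        assert res.sigma2_residual == pytest.approx(ms_within, rel=0.02)
        assert res.tau_intercept == pytest.approx(tau_mm, rel=0.02)

    def test_icc_invariant_under_affine_rescaling(self):
        tab = _clustered_table(2.0, 1.0, seed=5)
        res1 = stats.fit_intercepts_only(tab)
        tab2 = tab.assign(y=3.5 * tab["y"] - 7.0)
        res2 = stats.fit_intercepts_only(tab2)
        assert res1.icc == pytest.approx(res2.icc, abs=1e-4)


def _interaction_cohort(beta, seed, n_inc=15, n_alt=15):
    subs = [SubjectParams(subject_id=f"I{i:02d}", group="INC", down_gain=1.0)
            for i in range(n_inc)]
    subs += [SubjectParams(subject_id=f"A{i:02d}", group="ALT", session_trend=beta)
             for i in range(n_alt)]
    return synth.simulate_cohort_outcomes(subs, seed=seed)


INTERACTION_SPEC = stats.ModelSpec(
    outcome="y",
    fixed=("block", "modulation", "session", "group", "group:session"),
    random_session_slope=True,
)


class TestFitMlm:
    def test_interaction_coverage_two_se(self):
        # 100 replicates: true Group x Session effect 0.5 inside 2-SE band
        hits = 0
        for rep in range(100):
            tab = _interaction_cohort(0.5, seed=300 + rep)
            res = stats.fit_mlm(tab, INTERACTION_SPEC)
            b, se = res.params["group:session"], res.bse["group:session"]
            hits += abs(b - 0.5) < 2 * se
        assert hits >= 93

    def test_zero_slope_variance_matches_intercept_fit(self):
        subs = [SubjectParams(subject_id=f"S{i}", group="ALT") for i in range(20)]
        tab = synth.simulate_cohort_outcomes(subs, slope_sd_db=0.0, seed=2)
        spec_slope = stats.ModelSpec("y", ("block", "modulation"),
                                     random_session_slope=True)
        spec_flat = stats.ModelSpec("y", ("block", "modulation"))
        r1 = stats.fit_mlm(tab, spec_slope)
        r2 = stats.fit_mlm(tab, spec_flat)
        assert r1.tau_session_slope == pytest.approx(0.0, abs=0.02)
        for name in r2.params.index:
            assert r1.params[name] == pytest.approx(r2.params[name], rel=0.01, abs=0.01)

    def test_noise_predictor_barely_moves_pseudo_r2(self):
        tab = _clustered_table(1.0, 1.0, n_subjects=40, n_obs=40, seed=8)
        rng = np.random.default_rng(0)
        tab["noise"] = rng.normal(size=len(tab))
        r_null = stats.fit_mlm(tab, stats.ModelSpec("y"))
        r_noise = stats.fit_mlm(tab, stats.ModelSpec("y", ("noise",)))
        assert abs(r_noise.pseudo_r2 - r_null.pseudo_r2) < 0.01


class TestPseudoR2:
    def test_null_model_zero(self):
        tab = _clustered_table(1.0, 1.0, seed=1)
        res = stats.fit_intercepts_only(tab)
        assert stats.pseudo_r2_fixed(res, tab) == pytest.approx(0.0, abs=1e-6)

    def test_strong_linear_outcome_near_one(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            for s in range(1, 6):
                rows.append(dict(subject=f"S{i}", session=s,
                                 y=2.0 * s + rng.normal(0, 0.05)))
        tab = pd.DataFrame(rows)
        res = stats.fit_mlm(tab, stats.ModelSpec("y", ("session",)))
        assert stats.pseudo_r2_fixed(res, tab) > 0.95

    def test_known_r2_recovered(self):
        rng = np.random.default_rng(7)
        rows = []
        # var(x)=1 slope b: R^2 = b^2/(b^2 + tau + sigma2); b=1.2, tau+sig=2.36
        for i in range(60):
            u = rng.normal(0, 1.0)
            for j in range(30):
                x = rng.normal()
                rows.append(dict(subject=f"S{i}", session=j % 5 + 1, x=x,
                                 y=1.2 * x + u + rng.normal(0, np.sqrt(1.36))))
        tab = pd.DataFrame(rows)
        res = stats.fit_mlm(tab, stats.ModelSpec("y", ("x",)))
        assert stats.pseudo_r2_fixed(res, tab) == pytest.approx(
            1.2**2 / (1.2**2 + 1.0 + 1.36), abs=0.05)


class TestSimpleSlopes:
    def test_slope_difference_equals_interaction_coefficient(self):
        tab = _interaction_cohort(0.4, seed=2)
        res = stats.fit_mlm(tab, INTERACTION_SPEC)
        s0, s1 = stats.simple_slopes(res)
        assert s1.slope - s0.slope == pytest.approx(
            float(res.params["group:session"]), abs=1e-10)

    def test_zero_interaction_identical_slopes(self):
        tab = _interaction_cohort(0.0, seed=3)
        res = stats.fit_mlm(tab, INTERACTION_SPEC)
        s0, s1 = stats.simple_slopes(res)
        assert s1.slope - s0.slope == pytest.approx(
            float(res.params["group:session"]), abs=1e-10)

    def test_group_specific_slopes_recovered(self):
        hits0 = hits1 = 0
        for rep in range(50):
            tab = _interaction_cohort(0.4, seed=700 + rep)
            res = stats.fit_mlm(tab, INTERACTION_SPEC)
            s0, s1 = stats.simple_slopes(res)
            hits0 += abs(s0.slope - 0.0) < 2 * s0.se
            hits1 += abs(s1.slope - 0.4) < 2 * s1.se
        assert hits0 >= 45 and hits1 >= 45

    def test_missing_interaction_rejected(self):
        tab = _clustered_table(1.0, 1.0, seed=0)
        res = stats.fit_intercepts_only(tab)
        with pytest.raises(ValueError):
            stats.simple_slopes(res)


class TestAssumptionChecks:
    def test_normal_sample_flags_off(self):
        tab = _clustered_table(0.5, 1.0, n_subjects=25, n_obs=40, seed=6)
        res = stats.fit_intercepts_only(tab)
        rep = stats.assumption_checks(tab, res)
        assert not rep.skewness_flag and not rep.kurtosis_flag

    def test_extreme_subject_mean_flagged_as_outlier(self):
        tab = _clustered_table(0.1, 0.5, n_subjects=20, n_obs=20, seed=2)
        tab.loc[tab["subject"] == "S00", "y"] += 30.0
        res = stats.fit_intercepts_only(tab)
        rep = stats.assumption_checks(tab, res)
        assert "S00" in rep.outlier_subjects

    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(1)
        n = 400
        tab = pd.DataFrame(dict(
            subject=np.repeat([f"S{i}" for i in range(20)], 20),
            a=np.tile([-1, 1], n // 2),
            b=np.repeat([-1, 1], n // 2),
        ))
        tab["y"] = tab["a"] + tab["b"] + rng.normal(size=n)
        res = stats.fit_mlm(tab, stats.ModelSpec("y", ("a", "b")))
        rep = stats.assumption_checks(tab, res)
        assert rep.vif["a"] == pytest.approx(1.0, abs=1e-6)
        assert rep.vif["b"] == pytest.approx(1.0, abs=1e-6)


class TestResponders:
    def test_strong_session_slope_is_responder(self):
        rng = np.random.default_rng(0)
        rows = [dict(subject="S0", session=s, modulation=b % 2,
                     y=1.0 * s + rng.normal(0, 0.2))
                for s in range(1, 6) for b in range(6)]
        flags = stats.classify_responders(pd.DataFrame(rows))
        assert bool(flags["S0"])

    def test_modulation_locked_theta_is_responder(self):
        rng = np.random.default_rng(1)
        rows = [dict(subject="S0", session=s, modulation=b % 2,
                     y=3.0 * (b % 2) + rng.normal(0, 0.3))
                for s in range(1, 6) for b in range(6)]
        flags = stats.classify_responders(pd.DataFrame(rows))
        assert bool(flags["S0"])

    def test_pure_noise_fraction_at_type_one_level(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(100):
            for s in range(1, 6):
                for b in range(6):
                    rows.append(dict(subject=f"S{i:03d}", session=s,
                                     modulation=b % 2, y=rng.normal()))
        flags = stats.classify_responders(pd.DataFrame(rows))
        # union of two alpha=.05 screens: expected rate < ~.10
        assert flags.mean() <= 0.12

    def test_constant_outcome_non_responder(self):
        rows = [dict(subject="S0", session=s, modulation=b % 2, y=1.0)
                for s in range(1, 6) for b in range(6)]
        flags = stats.classify_responders(pd.DataFrame(rows))
        assert not bool(flags["S0"])


class TestLme4CrossCheck:
    def test_variance_components_match_lme4(self, tmp_path):
        """Independent oracle: R lme4 REML on the same table."""
        tab = _clustered_table(3.0, 1.0, n_subjects=30, n_obs=30, seed=12)
        csv = tmp_path / "tab.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(y ~ 1 + (1|subject), data=d, REML=TRUE)\n"
            "vc <- as.data.frame(VarCorr(m))\n"
            "cat(vc$vcov[1], vc$vcov[2], fixef(m)[1], sep='\\n')\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        tau_r, sigma_r, beta_r = map(float, out.stdout.split())
        res = stats.fit_intercepts_only(tab)
        assert res.tau_intercept == pytest.approx(tau_r, rel=1e-3)
        assert res.sigma2_residual == pytest.approx(sigma_r, rel=1e-3)
        assert float(res.params["Intercept"]) == pytest.approx(beta_r, rel=1e-4)
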