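import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortmed.bayes import MCMCSettings, PosteriorSummary
from cortmed.config import SimulationConfig
from cortmed.mediation import (
    PATHWAYS,
    PipelineError,
    assess_baron_kenny,
    build_analysis_frame,
    derive_priors,
    diffuse_priors,
    grs_moderation,
    mediation_percentage,
    mediation_percentage_interval,
    run_pathway_models,
    stratified_mediation,
)
from cortmed.simulate import generate_cohort
from cortmed.trajectory import TrajectorySpec

from conftest import cfg_with

FAST = MCMCSettings(chains=2, draws=1200, burn_in=500, seed=17)


def diffuse_priors_for(names):
    from cortmed.bayes import PathwayPrior

    return PathwayPrior("total", list(names), np.zeros(len(names)),
                        np.full(len(names), 10.0))


def _summary(point, tail):
    return PosteriorSummary(point=point, interval=(point * 0.8, point * 1.2),
                            tail_prob=tail, median_beta=np.log(point),
                            ess=1000, rhat=1.0, n_draws=2000)


class TestMediationFormula:
    @pytest.mark.parametrize("tot,dire,expected", [
        (2.0, 2.0, 0.0),
        (2.0, 1.0, 100.0),
        (1.94, 1.58, 30.97),
    ])
    def test_printed_formula(self, tot, dire, expected):
        assert mediation_percentage(tot, dire) == pytest.approx(expected, abs=0.01)

    def test_negative_percentage_not_clipped(self):
        assert mediation_percentage(1.47, 1.72) < 0

    def test_null_total_effect_undefined(self):
        with pytest.raises(ValueError):
            mediation_percentage(1.0, 1.5)
        with pytest.raises(ValueError):
            mediation_percentage(2.0, 0.0)

    @given(st.floats(1.01, 20.0), st.floats(0.1, 20.0))
    @settings(max_examples=100, deadline=None)
    def test_identity_and_full_mediation(self, t, d):
        assert mediation_percentage(t, t) == pytest.approx(0.0, abs=1e-9)
        assert mediation_percentage(t, 1.0) == pytest.approx(100.0)

    @given(st.floats(1.05, 10.0), st.floats(0.2, 5.0), st.floats(0.01, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_direct_effect(self, t, d, eps):
        assert mediation_percentage(t, d) > mediation_percentage(t, d + eps)


class TestMediationInterval:
    def test_degenerate_draws_collapse_to_point(self):
        t = np.full(500, np.log(1.94))
        d = np.full(500, np.log(1.58))
        lo, hi = mediation_percentage_interval(t, d)
        assert lo == pytest.approx(30.97, abs=0.01)
        assert hi == pytest.approx(30.97, abs=0.01)

    def test_identical_draws_give_zero_interval(self):
        t = np.random.default_rng(0).normal(0.7, 0.1, 1000)
        lo, hi = mediation_percentage_interval(t, t)
        assert lo == pytest.approx(0.0) and hi == pytest.approx(0.0)

    def test_matches_large_monte_carlo_oracle(self):
        rng = np.random.default_rng(1)
        mu_t, sd_t, mu_d, sd_d = 0.66, 0.10, 0.46, 0.12
        big_t = rng.normal(mu_t, sd_t, 10**6)
        big_d = rng.normal(mu_d, sd_d, 10**6)
        oracle = np.percentile(100 * (big_t - big_d) / big_t, [2.5, 97.5])
        rng2 = np.random.default_rng(2)
        t = rng2.normal(mu_t, sd_t, 40_000)
        d = rng2.normal(mu_d, sd_d, 40_000)
        lo, hi = mediation_percentage_interval(t, d)
        assert lo == pytest.approx(oracle[0], abs=1.0)
        assert hi == pytest.approx(oracle[1], abs=1.0)

    def test_near_null_totals_warn(self):
        rng = np.random.default_rng(3)
        t = rng.normal(0.0, 0.005, 1000)
        d = rng.normal(0.3, 0.1, 1000)
        with pytest.warns(UserWarning, match="unstable"):
            mediation_percentage_interval(t, d)

    def test_unpaired_draws_rejected(self):
        with pytest.raises(ValueError):
            mediation_percentage_interval(np.ones(10), np.ones(11))


class TestBaronKenny:
    def test_partial_mediation_when_all_paths_significant(self):
        summaries = {
            "bdnf_total": _summary(1.94, 0.011),
            "bdnf_to_cortisol": _summary(4.12, 0.001),
            "cortisol_to_mortality": _summary(3.05, 0.001),
            "bdnf_direct": _summary(1.58, 0.106),
        }
        crit, cls, pct = assess_baron_kenny(summaries)
        assert crit == {1: True, 2: True, 3: True, 4: True}
        assert cls == "partial"
        assert pct == pytest.approx(30.97, abs=0.01)

    def test_failed_gate_gives_none(self):
        summaries = {
            "bdnf_total": _summary(1.94, 0.011),
            "bdnf_to_cortisol": _summary(1.10, 0.60),  # criterion 2 fails
            "cortisol_to_mortality": _summary(3.05, 0.001),
            "bdnf_direct": _summary(1.58, 0.106),
        }
        crit, cls, _ = assess_baron_kenny(summaries)
        assert not crit[2] and cls == "none"

    def test_no_attenuation_fails_criterion_four(self):
        summaries = {
            "bdnf_total": _summary(1.94, 0.01),
            "bdnf_to_cortisol": _summary(4.0, 0.001),
            "cortisol_to_mortality": _summary(3.0, 0.001),
            "bdnf_direct": _summary(1.94, 0.01),
        }
        crit, cls, pct = assess_baron_kenny(summaries)
        assert not crit[4] and cls == "partial" and pct == pytest.approx(0.0)

    def test_full_mediation_requires_high_percentage(self):
        summaries = {
            "bdnf_total": _summary(2.0, 0.01),
            "bdnf_to_cortisol": _summary(4.0, 0.001),
            "cortisol_to_mortality": _summary(3.0, 0.001),
            "bdnf_direct": _summary(1.05, 0.80),  # ~93% mediated, non-significant
        }
        _, cls, pct = assess_baron_kenny(summaries)
        assert pct > 80 and cls == "full"


class TestPathwayModels:
    def test_posterior_medians_recover_generating_structure(self, default_cfg):
        """Diffuse-prior posteriors at n=2000 sit near the generating values.

        The exposure->mediator odds ratio and the conditional hazard ratios
        are generative constants; the marginal total effect is checked against
        its own large-n value (hazard ratios do not collapse over the
        mediator, so it exceeds the conditional direct effect).
        """
        cfg = cfg_with(default_cfg, n_subjects=2000)
        subj, bio = generate_cohort(cfg, np.random.default_rng(31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frame, _ = build_analysis_frame(subj, bio, TrajectorySpec(seed=31))
            res = run_pathway_models(frame, diffuse_priors(frame), FAST)
        assert res["bdnf_to_cortisol"]["summary"].point == pytest.approx(4.12, rel=0.25)
        assert res["cortisol_to_mortality"]["summary"].point == pytest.approx(3.05, rel=0.20)
        assert res["bdnf_direct"]["summary"].point == pytest.approx(1.58, rel=0.20)
        assert res["bdnf_total"]["summary"].point == pytest.approx(2.27, rel=0.20)

    def test_null_exposure_total_effect_covers_one(self, default_cfg):
        """With BDNF unlinked from everything, the total-effect CI covers 1.

        Only the total-effect pathway is sampled; the subjects' latent BDNF
        group stands in for the percentile dichotomization (identical under
        the null) so no trajectory fit is needed.
        """
        from cortmed.bayes import mcmc_sample, summarize_posterior
        from cortmed.regression import CoxProblem, fit_cox

        # trajectory hazard is also nulled: a strong latent class omitted from
        # the marginal model deflates its nominal coverage to ~92% (omitted
        # heterogeneity), which would test the scenario rather than the
        # interval machinery
        cfg = cfg_with(
            default_cfg, n_subjects=400,
            log_or_bdnf_to_class=0.0,
            log_hr={"bdnf_high": 0.0, "traj_high": 0.0,
                    "age_high": np.log(2.5), "gcs": -0.25},
        )
        covered = 0
        n_rep = 40
        rng = np.random.default_rng(5)
        for rep in range(n_rep):
            seed = int(rng.integers(2**31))
            subj, _ = generate_cohort(cfg, np.random.default_rng(seed))
            grs = ((subj["rs6265"] == "Met-carrier").astype(int)
                   + (subj["rs7124442"] == "C-carrier").astype(int))
            X = np.column_stack([subj["true_bdnf_high"], subj["age_high"],
                                 subj["gcs"] - 5.5, grs]).astype(float)
            names = ["bdnf_high", "age_high", "gcs_c", "grs"]
            mle = fit_cox(subj["time"], subj["event"], X, names)
            prob = CoxProblem(subj["time"], subj["event"], X)
            prior = diffuse_priors_for(names)
            out = mcmc_sample(prob.loglik, prior,
                              MCMCSettings(chains=2, draws=800, burn_in=400,
                                           seed=seed),
                              init=mle.coef, base_scales=mle.se)
            lo, hi = summarize_posterior(out["draws"][:, :, 0]).interval
            covered += lo <= 1.0 <= hi
        assert covered >= 0.9 * n_rep

    def test_prior_cohort_recovers_generating_log_odds(self, default_cfg):
        """Prior location for the BDNF->trajectory path lands near ln(4.12)."""
        cfg = cfg_with(default_cfg, n_subjects=185)
        subj, bio = generate_cohort(cfg, np.random.default_rng(8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frame, _ = build_analysis_frame(subj, bio, TrajectorySpec(seed=8))
        priors = derive_priors(frame)
        i = priors["bdnf_to_cortisol"].names.index("bdnf_high")
        assert priors["bdnf_to_cortisol"].loc[i] == pytest.approx(np.log(4.12), abs=0.5)
        # nuisance coefficients stay diffuse
        j = priors["bdnf_to_cortisol"].names.index("gcs_c")
        assert priors["bdnf_to_cortisol"].scale[j] == 10.0

    def test_prior_mismatch_detected(self, analysis_frame):
        frame, _ = analysis_frame
        priors = diffuse_priors(frame)
        priors["bdnf_total"].names[0] = "wrong"
        with pytest.raises(PipelineError):
            run_pathway_models(frame, priors, FAST)


class TestStratifiedAndModeration:
    def test_empty_older_stratum_skipped(self, default_cfg):
        cfg = cfg_with(default_cfg, n_subjects=150, age_range=(16.0, 45.0))
        subj, bio = generate_cohort(cfg, np.random.default_rng(12))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frame, _ = build_analysis_frame(subj, bio, TrajectorySpec(seed=12))
            res = stratified_mediation(frame, diffuse_priors(frame), settings=FAST)
        assert "age<48" in res and "age>=48" not in res

    def test_moderation_tables_partition_cohort(self, analysis_frame):
        frame, _ = analysis_frame
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = grs_moderation(frame)
        assert mod.per_grs["n"].sum() == len(frame)
        assert set(mod.interaction["stratum"]) <= {"age<48", "age>=48"}

    def test_single_grs_value_inestimable(self, analysis_frame):
        frame, _ = analysis_frame
        frame = frame.copy()
        frame["grs"] = 1
        with pytest.raises(PipelineError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                grs_moderation(frame)

    def test_sparse_stratum_warned(self, analysis_frame):
        frame, _ = analysis_frame
        frame = frame.copy()
        frame.loc[frame["grs"] == 2, "grs"] = 1
        frame.loc[frame.index[:2], "grs"] = 2  # tiny GRS=2 stratum
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = grs_moderation(frame)
        assert any("GRS=2" in w for w in mod.warnings)


class TestPreprocessing:
    def test_frame_columns_and_exclusions(self, analysis_frame, cohort):
        frame, log = analysis_frame
        subjects, _ = cohort
        for col in ("traj_high", "bdnf_high", "grs", "age_high", "gcs_c"):
            assert col in frame.columns
        assert len(frame) + len(log["excluded_no_cortisol"]) == len(subjects)
        assert log["trajectory_balanced"] in (True, False)
        # ~25% of subjects flagged BDNF-high by the percentile rule
        assert abs(frame["bdnf_high"].mean() - 0.25) < 0.05
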