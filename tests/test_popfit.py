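"""Population estimator: error model, likelihood, NPAG, posteriors, screen."""

import io
import math

import numpy as np
import pytest
from scipy.stats import norm

from caspopk.pk_core import Covariates, PKParameters, Regimen, concentration_profile
from caspopk.popfit import (
    ErrorModel,
    NPDistribution,
    NpagConfig,
    ObservationRecord,
    Subject,
    SupportPoint,
    bayes_posterior,
    covariate_screen,
    npag_fit,
    observation_sd,
    read_dataset,
    subject_loglik,
    summarize_distribution,
    write_dataset,
)

from .conftest import DAY3_TIMES, make_subject


@pytest.mark.parametrize(
    "em, conc, expected",
    [
        (ErrorModel(mode="gamma", scale=1.0), 0.0, 0.05),
        (ErrorModel(mode="gamma", scale=0.654), 10.0, 0.654 * (0.05 + 0.8)),
        (ErrorModel(mode="lambda", scale=0.0), 5.0, 0.45),
        (ErrorModel(mode="lambda", scale=0.2), 5.0, 0.65),
    ],
)
def test_observation_sd(em, conc, expected):
    assert observation_sd(em, conc) == pytest.approx(expected, rel=1e-12)


def test_observation_sd_rejects_negative_concentration(gamma_error):
    with pytest.raises(ValueError):
        observation_sd(gamma_error, -0.1)


def test_error_model_validation():
    with pytest.raises(ValueError):
        ErrorModel(mode="gamma", scale=0.0)
    with pytest.raises(ValueError):
        ErrorModel(mode="lambda", scale=-0.1)
    with pytest.raises(ValueError):
        ErrorModel(c0=-0.01)


class TestSubjectLoglik:
    def _subject(self, params, times, conc):
        reg = Regimen.daily(70.0, 50.0, 3)
        obs = [ObservationRecord(float(t), float(c)) for t, c in zip(times, conc)]
        return Subject("toy", reg, obs, Covariates(weight=78.0))

    def test_exact_prediction_hits_gaussian_mode(self, median_params, gamma_error):
        times = np.array([2.0])
        pred = concentration_profile(
            median_params, Covariates(weight=78.0), Regimen.daily(70, 50, 3), times
        ).concentrations
        s = self._subject(median_params, times, pred)
        sd = observation_sd(gamma_error, pred[0])
        expected = math.log(1.0 / (sd * math.sqrt(2 * math.pi)))
        assert subject_loglik(s, median_params, gamma_error) == pytest.approx(expected)

    def test_additivity_over_observations(self, median_params, gamma_error):
        times = np.array([2.0, 24.0])
        s = self._subject(median_params, times, [5.0, 3.0])
        s1 = self._subject(median_params, times[:1], [5.0])
        s2 = self._subject(median_params, times[1:], [3.0])
        total = subject_loglik(s, median_params, gamma_error)
        assert total == pytest.approx(
            subject_loglik(s1, median_params, gamma_error)
            + subject_loglik(s2, median_params, gamma_error)
        )

    def test_matches_independent_density_computation(self, median_params, gamma_error):
        """Oracle: scipy normal log-density at model predictions."""
        times = np.array([2.0, 24.0])
        reg = Regimen.daily(70.0, 50.0, 3)
        cov = Covariates(weight=78.0)
        pred = concentration_profile(median_params, cov, reg, times).concentrations
        obs_vals = pred * [1.1, 0.9]
        s = self._subject(median_params, times, obs_vals)
        sd = np.array([observation_sd(gamma_error, c) for c in obs_vals])
        expected = norm.logpdf(obs_vals, loc=pred, scale=sd).sum()
        assert subject_loglik(s, median_params, gamma_error) == pytest.approx(expected)


class TestNpag:
    def test_noise_free_subject_concentrates_on_truth(self, median_params, gamma_error):
        """With the generating point in the initial grid, a single noise-free
        subject pulls >= 0.99 of the mass onto it (degenerate mixture)."""
        reg = Regimen.daily(70.0, 50.0, 3)
        s = make_subject("s1", median_params, reg, DAY3_TIMES, gamma_error, rng=None)
        res = npag_fit(
            [s], em=gamma_error,
            config=NpagConfig(grid_size=128, max_cycles=40, seed=1),
            init_points=median_params.as_array(),
        )
        j = int(np.argmax(res.distribution.weights))
        assert res.distribution.weights[j] >= 0.99
        np.testing.assert_allclose(
            res.distribution.support[j], median_params.as_array(), rtol=0.02
        )

    def test_objective_trace_is_monotone(self, gamma_error):
        rng = np.random.default_rng(3)
        reg = Regimen.daily(70.0, 50.0, 3)
        subs = [
            make_subject(
                f"s{i}",
                PKParameters(ke=0.05 + 0.02 * i, v0=7.2, kcp=0.28, kpc=0.34),
                reg, DAY3_TIMES, gamma_error, rng=rng,
            )
            for i in range(5)
        ]
        res = npag_fit(
            subs, em=gamma_error,
            config=NpagConfig(grid_size=128, max_cycles=30, seed=2),
        )
        trace = res.objective_trace
        assert len(trace) >= 2
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_weights_sum_to_one(self, gamma_error):
        rng = np.random.default_rng(4)
        reg = Regimen.daily(70.0, 50.0, 3)
        subs = [
            make_subject(
                f"s{i}", PKParameters(0.08, 7.2, 0.28, 0.34), reg, DAY3_TIMES,
                gamma_error, rng=rng,
            )
            for i in range(4)
        ]
        res = npag_fit(
            subs, em=gamma_error,
            config=NpagConfig(grid_size=64, max_cycles=10, seed=5),
        )
        assert res.distribution.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.aic == pytest.approx(res.neg2ll + 2 * res.n_parameters)

    def test_impossible_subject_is_named(self):
        """A subject with zero likelihood under every grid point is reported
        by id rather than silently propagated."""
        reg = Regimen.daily(70.0, 50.0, 3)
        obs = [ObservationRecord(49.0, 1e160)]  # unfittable at additive SD
        bad = Subject("ghost", reg, obs, Covariates(weight=78.0))
        em = ErrorModel(c0=0.05, c1=0.0, mode="gamma", scale=1.0)
        with pytest.raises(ValueError, match="ghost"):
            npag_fit(
                [bad], em=em,
                config=NpagConfig(grid_size=16, max_cycles=2, polish=False, seed=6),
            )

    def test_invalid_bounds_rejected(self, gamma_error):
        with pytest.raises(ValueError):
            npag_fit([], em=gamma_error)
        s = make_subject(
            "s", PKParameters(0.08, 7.2, 0.28, 0.34), Regimen.daily(70, 50, 3),
            DAY3_TIMES, gamma_error,
        )
        with pytest.raises(ValueError):
            npag_fit([s], bounds={"ke": (0.5, 0.1), "v0": (1, 30),
                                  "kcp": (0.01, 5), "kpc": (0.01, 5)})


class TestBayesPosterior:
    def test_two_atom_bayes_rule(self, gamma_error):
        """Posterior odds equal likelihood ratio under a flat two-atom prior."""
        p_a = PKParameters(0.06, 7.2, 0.28, 0.34)
        p_b = PKParameters(0.12, 7.2, 0.28, 0.34)
        reg = Regimen.daily(70.0, 50.0, 3)
        s = make_subject("s", p_a, reg, DAY3_TIMES, gamma_error,
                         rng=np.random.default_rng(7))
        prior = NPDistribution([SupportPoint(p_a, 0.5), SupportPoint(p_b, 0.5)])
        post, _ = bayes_posterior(s, prior, gamma_error)
        la = subject_loglik(s, p_a, gamma_error)
        lb = subject_loglik(s, p_b, gamma_error)
        expected_a = 1.0 / (1.0 + math.exp(lb - la))
        w = {pt.params.ke: pt.prob for pt in post.points}
        assert w[p_a.ke] == pytest.approx(expected_a, rel=1e-9)

    def test_single_atom_prior_is_identity(self, median_params, gamma_error):
        reg = Regimen.daily(70.0, 50.0, 3)
        s = make_subject("s", median_params, reg, DAY3_TIMES, gamma_error,
                         rng=np.random.default_rng(8))
        prior = NPDistribution([SupportPoint(median_params, 1.0)])
        post, mean = bayes_posterior(s, prior, gamma_error)
        assert len(post.points) == 1
        assert post.points[0].prob == pytest.approx(1.0)
        np.testing.assert_allclose(mean.as_array(), median_params.as_array())

    def test_enumeration_oracle(self, gamma_error):
        """Posterior equals brute-force normalisation of prior x likelihood."""
        rng = np.random.default_rng(9)
        pts = [PKParameters(k, 7.2, 0.28, 0.34) for k in (0.05, 0.08, 0.13)]
        prior_w = np.array([0.2, 0.5, 0.3])
        reg = Regimen.daily(70.0, 50.0, 3)
        s = make_subject("s", pts[1], reg, DAY3_TIMES, gamma_error, rng=rng)
        dist = NPDistribution(
            [SupportPoint(p, w) for p, w in zip(pts, prior_w)]
        )
        post, mean = bayes_posterior(s, dist, gamma_error)
        brute = prior_w * np.exp(
            [subject_loglik(s, p, gamma_error) for p in pts]
        )
        brute /= brute.sum()
        got = np.array([pt.prob for pt in post.points])
        np.testing.assert_allclose(got, brute[brute > 0], rtol=1e-9)
        np.testing.assert_allclose(
            mean.as_array(),
            (brute[:, None] * np.array([p.as_array() for p in pts])).sum(axis=0),
            rtol=1e-9,
        )


class TestSummaries:
    def test_single_point(self, median_params):
        d = NPDistribution([SupportPoint(median_params, 1.0)])
        s = summarize_distribution(d)
        assert s["ke"]["sd"] == 0.0
        assert s["ke"]["cv_pct"] == 0.0
        assert s["ke"]["mean"] == s["ke"]["median"] == median_params.ke

    def test_two_atom_moments(self):
        a = PKParameters(0.05, 7.2, 0.28, 0.34)
        b = PKParameters(0.15, 7.2, 0.28, 0.34)
        d = NPDistribution([SupportPoint(a, 0.5), SupportPoint(b, 0.5)])
        s = summarize_distribution(d)
        assert s["ke"]["mean"] == pytest.approx(0.10)
        assert s["ke"]["sd"] == pytest.approx(0.05)
        assert s["ke"]["cv_pct"] == pytest.approx(50.0)
        assert s["ke"]["median"] == pytest.approx(0.05)  # lower weighted quantile

    def test_random_distribution_matches_brute_force(self):
        rng = np.random.default_rng(10)
        support = rng.uniform(0.1, 2.0, size=(20, 4))
        w = rng.dirichlet(np.ones(20))
        d = NPDistribution.from_arrays(support, w)
        s = summarize_distribution(d)
        for k, name in enumerate(("ke", "v0", "kcp", "kpc")):
            mean = (w * support[:, k]).sum()
            sd = math.sqrt((w * (support[:, k] - mean) ** 2).sum())
            assert s[name]["mean"] == pytest.approx(mean, rel=1e-9)
            assert s[name]["sd"] == pytest.approx(sd, rel=1e-9)
            assert s[name]["cv_pct"] == pytest.approx(100 * sd / mean, rel=1e-9)


class TestCovariateScreen:
    def _posteriors(self, rng, n=24):
        weights = rng.uniform(48, 139, n)
        subjects, posts = [], {}
        for i, w in enumerate(weights):
            sid = f"s{i}"
            reg = Regimen.daily(70.0, 50.0, 3)
            obs = [ObservationRecord(49.0, 5.0)]
            extra = {"noise_cov": float(rng.normal())}
            subjects.append(
                Subject(sid, reg, obs, Covariates(weight=float(w), extra=extra))
            )
            # planted signal: V tracks V0*weight/78 with 10% noise
            v = 7.2 * w / 78.0 * (1 + 0.1 * rng.standard_normal())
            posts[sid] = PKParameters(
                ke=float(rng.lognormal(math.log(0.08), 0.3)),
                v0=float(max(v, 0.5)), kcp=0.28, kpc=0.34,
            )
        return subjects, posts

    def test_planted_weight_signal_is_selected(self):
        rng = np.random.default_rng(11)
        subjects, posts = self._posteriors(rng)
        report = covariate_screen(subjects, posts, ["weight", "noise_cov"])
        row = report[(report.parameter == "v0") & (report.covariate == "weight")]
        assert bool(row["selected"].iloc[0])
        assert float(row["p_value"].iloc[0]) < 0.05
        assert float(row["delta_aic"].iloc[0]) < 0.0

    def test_constant_covariate_untestable(self):
        rng = np.random.default_rng(12)
        subjects, posts = self._posteriors(rng, n=8)
        for s in subjects:
            s.covariates.extra["flat"] = 1.0
        report = covariate_screen(subjects, posts, ["flat"])
        assert not report["testable"].any()
        assert not report["selected"].any()

    def test_pure_noise_false_positive_rate(self):
        """Permuted covariate selected ~5% of the time (binomial 95% band)."""
        rng = np.random.default_rng(13)
        hits = 0
        reps = 100
        subjects, posts = self._posteriors(rng, n=30)
        ke_vals = np.array([posts[s.id].ke for s in subjects])
        for _ in range(reps):
            for s, v in zip(subjects, rng.permutation(ke_vals)):
                s.covariates.extra["perm"] = float(v)
            report = covariate_screen(subjects, posts, ["perm"])
            row = report[(report.parameter == "ke") & (report.covariate == "perm")]
            hits += int(row["p_value"].iloc[0] < 0.05)
        # binomial(100, 0.05) central 95% interval is about [1, 10]
        assert 0 <= hits <= 12


class TestDatasetIO:
    def test_round_trip(self, median_params, gamma_error):
        rng = np.random.default_rng(14)
        reg = Regimen.daily(70.0, 50.0, 3)
        subs = [
            make_subject(f"s{i}", median_params, reg, DAY3_TIMES, gamma_error,
                         rng=rng, weight=60.0 + i)
            for i in range(3)
        ]
        buf = io.StringIO()
        write_dataset(subs, buf)
        buf.seek(0)
        back = read_dataset(buf)
        assert len(back) == 3
        for a, b in zip(subs, back):
            assert a.id == b.id
            assert a.covariates.weight == b.covariates.weight
            np.testing.assert_allclose(a.concentrations, b.concentrations)
            assert a.regimen.events == b.regimen.events

    def test_errors_report_row_numbers(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,time,dose,duration,conc,weight\n"
            "A,0,70,1,,78\n"
            "A,2,,,5.1,78\n"
            "B,0,70,,,78\n"   # dose row without a duration
            "B,2,,,4.0,78\n"
        )
        with pytest.raises(ValueError, match="row"):
            read_dataset(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("id,time\nA,0\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_dataset(path)
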