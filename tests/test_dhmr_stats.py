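import numpy as np
import pytest

from twindhmr.dhmr_stats import (
    LEUKOCYTE_FRACTIONS,
    ModelSpec,
    TwinSample,
    anodev_group_test,
    benjamini_hochberg,
    build_design,
    check_pairing,
    discover_phase1,
    estimate_common_dispersion,
    estimate_dispersion,
    fit_nb_glm,
)
from twindhmr.simulate import simulate_region_counts, synthesize_pair_samples
from twindhmr.windows import GenomicInterval

from conftest import make_samples


class TestTwinSample:
    def test_validation(self):
        kw = dict(sample_id="s", pair_id="p", zygosity="MZ", role="case",
                  cd8t=0.1, cd4t=0.1, nk=0.1, bcell=0.1, mono=0.1, age=60.0)
        TwinSample(**kw)
        with pytest.raises(ValueError):
            TwinSample(**{**kw, "cd8t": 1.5})
        with pytest.raises(ValueError):
            TwinSample(**{**kw, "cd8t": 0.9, "cd4t": 0.9})
        with pytest.raises(ValueError):
            TwinSample(**{**kw, "zygosity": "XX"})
        with pytest.raises(ValueError):
            TwinSample(**{**kw, "role": "patient"})
        with pytest.raises(ValueError):
            TwinSample(**{**kw, "size_factor": 0.0})

    def test_check_pairing(self):
        samples = make_samples(3)
        check_pairing(samples)
        with pytest.raises(ValueError, match="exactly one case"):
            check_pairing(samples[:3])


class TestBuildDesign:
    def test_shapes_and_names(self):
        samples = make_samples(4)
        X, names = build_design(samples, ModelSpec.model(2))
        # intercept + 3 pair dummies + 5 fractions + group
        assert X.shape == (8, 10)
        assert names[0] == "intercept"
        assert names[-1] == "group[case]"
        assert sum(n.startswith("pair[") for n in names) == 3
        assert set(LEUKOCYTE_FRACTIONS) <= set(names)

    def test_pair_constant_covariate_dropped_with_warning(self):
        samples = make_samples(4)  # co-twins share age
        with pytest.warns(UserWarning, match="age is constant within"):
            X, names = build_design(samples, ModelSpec.model(3))
        assert "age" not in names

    def test_pair_constant_covariate_kept_without_pair_factor(self):
        samples = make_samples(4)
        X, names = build_design(
            samples, ModelSpec.model(3, include_pair_factor=False)
        )
        assert "age" in names
        assert not any(n.startswith("pair[") for n in names)

    def test_unknown_model_id(self):
        with pytest.raises(ValueError, match="unknown model id"):
            ModelSpec.model(4)


class TestFitNbGlm:
    def test_poisson_group_means_closed_form(self, rng):
        # one-way design: MLE fitted values equal the group sample means
        y = rng.poisson([10.0] * 6 + [40.0] * 6)
        X = np.column_stack([np.ones(12), [0.0] * 6 + [1.0] * 6])
        fit = fit_nb_glm(y, X, alpha=0.0)
        assert fit.converged
        np.testing.assert_allclose(
            fit.fitted[:6], np.full(6, y[:6].mean()), rtol=1e-6
        )
        np.testing.assert_allclose(
            fit.fitted[6:], np.full(6, y[6:].mean()), rtol=1e-6
        )

    def test_score_equations_hold_at_convergence(self, rng):
        # NB2 log-link score: X' (y - mu) / (1 + alpha mu) = 0
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n),
                             rng.integers(0, 2, n).astype(float)])
        beta_true = np.array([3.0, 0.4, -0.6])
        mu = np.exp(X @ beta_true)
        alpha = 0.2
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu))
        fit = fit_nb_glm(y, X, alpha=alpha)
        assert fit.converged
        score = X.T @ ((y - fit.fitted) / (1 + alpha * fit.fitted))
        np.testing.assert_allclose(score, 0.0, atol=1e-4)

    def test_coefficient_recovery_large_sample(self, rng):
        n = 4000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_true = np.array([2.0, 0.5])
        mu = np.exp(X @ beta_true)
        r = 1 / 0.3
        y = rng.negative_binomial(r, r / (r + mu))
        fit = fit_nb_glm(y, X, alpha=0.3)
        np.testing.assert_allclose(fit.coefficients, beta_true, atol=0.05)

    def test_offsets_shift_intercept(self, rng):
        y = rng.poisson(20.0, 30)
        X = np.ones((30, 1))
        off = np.full(30, np.log(2.0))
        fit0 = fit_nb_glm(y, X, alpha=0.0)
        fit1 = fit_nb_glm(y, X, offsets=off, alpha=0.0)
        assert fit1.coefficients[0] == pytest.approx(
            fit0.coefficients[0] - np.log(2.0), abs=1e-6
        )

    def test_rank_deficient_names_columns(self):
        X = np.column_stack([np.ones(8), np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_nb_glm(
                np.ones(8), X, columns=["intercept", "x", "dup"]
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_nb_glm(np.array([-1.0, 2.0]), np.ones((2, 1)))


class TestDispersion:
    def test_mom_dispersion_order_of_magnitude(self, rng):
        n = 2000
        X = np.ones((n, 1))
        r = 1 / 0.3
        y = rng.negative_binomial(r, r / (r + 50.0), n)
        a = estimate_dispersion(y, X)
        assert 0.2 < a < 0.4

    def test_poisson_data_floors_near_zero(self, rng):
        y = rng.poisson(50.0, 2000)
        a = estimate_dispersion(y, np.ones((2000, 1)))
        assert a < 0.02

    def test_common_dispersion_recovers_truth(self):
        rng = np.random.default_rng(5)
        samples = synthesize_pair_samples(12, "MZ", rng)
        counts = simulate_region_counts(
            samples, 150, baseline_mean=100.0, dispersion=0.3, rng=rng
        )
        X, _ = build_design(samples, ModelSpec.model(1))
        a = estimate_common_dispersion(counts, X, np.zeros(24))
        assert 0.2 < a < 0.4


class TestAnodevGroupTest:
    def test_four_fold_excess_detected(self):
        rng = np.random.default_rng(42)
        samples = make_samples(12)
        case = np.array([s.role == "case" for s in samples])
        mu = np.where(case, 400.0, 100.0)
        r = 1 / 0.2
        y = rng.negative_binomial(r, r / (r + mu))
        res = anodev_group_test(y, samples, ModelSpec.model(1))
        assert res["p_value"] < 1e-4
        assert res["log2fc"] == pytest.approx(2.0, abs=0.3)
        assert res["flagged"] == 0.0

    def test_identical_groups_large_p(self):
        rng = np.random.default_rng(3)
        samples = make_samples(12)
        y = rng.poisson(100.0, 24)
        res = anodev_group_test(y, samples, ModelSpec.model(1))
        assert res["p_value"] > 0.01

    def test_group_coefficient_sign_matches_log2fc(self):
        rng = np.random.default_rng(8)
        samples = make_samples(12)
        case = np.array([s.role == "case" for s in samples])
        y = rng.poisson(np.where(case, 50.0, 200.0))
        res = anodev_group_test(y, samples, ModelSpec.model(1))
        assert res["log2fc"] < 0
        assert res["group_coefficient"] < 0

    def test_requires_both_groups(self):
        samples = [s for s in make_samples(4) if s.role == "case"]
        with pytest.raises(ValueError, match="case and control"):
            anodev_group_test(np.ones(4), samples, ModelSpec.model(1))

    def test_chisq_reference_with_pooled_alpha(self):
        rng = np.random.default_rng(9)
        samples = make_samples(12)
        y = rng.poisson(100.0, 24)
        res = anodev_group_test(
            y, samples, ModelSpec.model(1), alpha=0.1, reference="chisq"
        )
        from scipy import stats

        assert res["p_value"] == pytest.approx(
            float(stats.chi2.sf(res["deviance"], 1))
        )


class TestBenjaminiHochberg:
    @staticmethod
    def _brute_force(p):
        p = np.asarray(p, float)
        m = p.size
        q = np.empty(m)
        for i in range(m):
            # smallest adjusted value over all thresholds t >= p_i
            candidates = [
                m * t / int((p <= t).sum()) for t in p if t >= p[i]
            ]
            q[i] = min(1.0, min(candidates))
        return q

    def test_matches_brute_force_small(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(
                benjamini_hochberg(p), self._brute_force(p), rtol=1e-12
            )

    def test_ties_and_duplicates(self):
        p = np.array([0.01, 0.01, 0.5, 0.5, 1.0])
        np.testing.assert_allclose(
            benjamini_hochberg(p), self._brute_force(p)
        )

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=100)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, np.nan])

    def test_empty(self):
        assert benjamini_hochberg([]).size == 0


class TestDiscoverPhase1:
    def test_spiked_regions_selected(self):
        rng = np.random.default_rng(21)
        samples = synthesize_pair_samples(12, "MZ", rng)
        spikes = {0: 2.5, 1: -2.5}
        counts = simulate_region_counts(
            samples, 40, spikes, baseline_mean=200.0, dispersion=0.1, rng=rng
        )
        regions = [GenomicInterval("c", i * 1000, i * 1000 + 500)
                   for i in range(40)]
        records = discover_phase1(counts, regions, samples)
        assert records[0].phase1_selected and records[0].pattern == "hyper"
        assert records[1].phase1_selected and records[1].pattern == "hypo"
        false_pos = [r for r in records[2:] if r.phase1_selected]
        assert len(false_pos) <= 1
        for rec in records:
            for key in rec.q_values:
                assert rec.q_values[key] >= rec.p_values[key] - 1e-12

    def test_selection_requires_all_models(self):
        rng = np.random.default_rng(22)
        samples = synthesize_pair_samples(8, "MZ", rng)
        counts = simulate_region_counts(
            samples, 10, {0: 3.0}, baseline_mean=200.0, dispersion=0.1,
            rng=rng,
        )
        regions = [GenomicInterval("c", i * 1000, i * 1000 + 500)
                   for i in range(10)]
        records = discover_phase1(
            counts, regions, samples, models=(ModelSpec.model(1),)
        )
        assert records[0].phase1_selected
        assert set(records[0].q_values) == {"m1"}
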