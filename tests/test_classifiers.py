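"""The seven classifier families and their shared fit/predict contract."""

import numpy as np
import pytest

from ecgdetect import classifiers as clf


def two_gaussians(rng, sep=8.0, n=200, d=2):
    x = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    y = np.array([0] * n + [1] * n)
    return x, y


FAST_CONFIGS = {
    "firefly": clf.FireflyConfig(population=15, max_iter=25, seed=0),
}


class TestContract:
    @pytest.mark.parametrize("family", clf.FAMILIES)
    def test_fit_predict_shapes_and_determinism(self, family, rng):
        if family == "dfa":
            x = np.vstack([
                np.cumsum(rng.normal(size=(30, 120)), axis=1),  # persistent
                rng.normal(size=(30, 120)),                      # white
            ])
            y = np.array([1] * 30 + [0] * 30)
        else:
            x, y = two_gaussians(rng, sep=4.0, n=60)
        cfg = FAST_CONFIGS.get(family)
        m1 = clf.fit(x, y, family, cfg)
        m2 = clf.fit(x, y, family, cfg)
        s1, p1 = m1.predict(x)
        s2, p2 = m2.predict(x)
        assert s1.shape == (len(y),)
        assert set(np.unique(p1)) <= {0, 1}
        assert np.array_equal(s1, s2) and np.array_equal(p1, p2)

    @pytest.mark.parametrize("family", clf.FAMILIES)
    def test_boundary_score_breaks_toward_arrhythmia(self, family, rng):
        if family == "dfa":
            x = np.vstack([
                np.cumsum(rng.normal(size=(20, 120)), axis=1),
                rng.normal(size=(20, 120)),
            ])
            y = np.array([1] * 20 + [0] * 20)
        else:
            x, y = two_gaussians(rng, sep=4.0, n=40)
        model = clf.fit(x, y, family, FAST_CONFIGS.get(family))
        # a score exactly at the threshold is labelled positive
        scores = np.array([model.threshold])

        class _Stub:
            def score(self, _):
                return scores

        stub = clf.TrainedClassifier(family, model.threshold, 1, _Stub())
        _, labels = stub.predict(np.zeros((1, 1)))
        assert labels[0] == 1

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="both classes"):
            clf.fit(x, np.ones(20), "gmm")

    def test_nonfinite_features_rejected(self, rng):
        x = rng.normal(size=(20, 2))
        x[3, 1] = np.inf
        y = np.array([0] * 10 + [1] * 10)
        with pytest.raises(ValueError):
            clf.fit(x, y, "lr")

    def test_dimension_mismatch_rejected(self, rng):
        x, y = two_gaussians(rng, n=30)
        model = clf.fit(x, y, "bdlc")
        with pytest.raises(ValueError, match="dimension"):
            model.predict(rng.normal(size=(5, 7)))

    def test_unknown_family_rejected(self, rng):
        x, y = two_gaussians(rng, n=10)
        with pytest.raises(ValueError, match="unknown classifier family"):
            clf.fit(x, y, "svm")


class TestGMM:
    def test_single_component_mean_recovery(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 1, (500, 1)), rng.normal(5, 1, (500, 1))])
        y = np.array([0] * 500 + [1] * 500)
        m = clf.fit(x, y, "gmm", clf.GMMConfig(n_components=1))
        assert abs(float(m.model.mixtures[0].means[0, 0]) - 0.0) < 0.1
        assert abs(float(m.model.mixtures[1].means[0, 0]) - 5.0) < 0.1

    def test_loglik_nondecreasing_and_weights_normalized(self, rng):
        x, y = two_gaussians(rng, sep=3.0, n=150)
        m = clf.fit(x, y, "gmm", clf.GMMConfig(n_components=3))
        for mix in m.model.mixtures.values():
            tr = np.array(mix.loglik_trace)
            assert np.all(np.diff(tr) >= -1e-6 * np.abs(tr[:-1]))
            assert mix.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(mix.covs > 0)

    def test_well_separated_classes_near_perfect_holdout(self):
        rng = np.random.default_rng(5)
        xtr, ytr = two_gaussians(rng, sep=8.0, n=200)
        xte, yte = two_gaussians(rng, sep=8.0, n=200)
        m = clf.fit(xtr, ytr, "gmm")
        _, pred = m.predict(xte)
        assert (pred == yte).mean() >= 0.99


class TestEMClassifier:
    def test_missing_entries_supported_and_loglik_monotone(self, rng):
        x, y = two_gaussians(rng, sep=5.0, n=100)
        x[rng.uniform(size=x.shape) < 0.15] = np.nan
        m = clf.fit(x, y, "em")
        for g in m.model.gaussians.values():
            tr = np.array(g.loglik_trace)
            assert np.all(np.diff(tr) >= -1e-6 * np.maximum(1, np.abs(tr[:-1])))
        xt, yt = two_gaussians(rng, sep=5.0, n=50)
        _, pred = m.predict(xt)
        assert (pred == yt).mean() > 0.9

    def test_no_missing_degenerates_to_closed_form(self, rng):
        x, y = two_gaussians(rng, sep=5.0, n=80)
        m = clf.fit(x, y, "em")
        g = m.model.gaussians[1]
        assert np.allclose(g.mean, x[y == 1].mean(axis=0))
        assert np.allclose(g.var, x[y == 1].var(axis=0) + 1e-6)


class TestNLR:
    def test_saturation_fit_separates_classes(self, rng):
        x, y = two_gaussians(rng, sep=6.0, n=150)
        m = clf.fit(x, y, "nlr")
        _, pred = m.predict(x)
        assert (pred == y).mean() > 0.95
        assert np.isfinite([m.model.g1, m.model.g2, m.model.sigma2]).all()
        assert m.model.sigma2 >= 0


class TestLR:
    def test_coefficient_recovery_within_three_se(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2000, 2))
        true = np.array([1.5, -2.0])
        p = 1 / (1 + np.exp(-(x @ true)))
        y = (rng.uniform(size=2000) < p).astype(int)
        m = clf.fit(x, y, "lr", clf.LRConfig(alpha=0.01))
        se = m.model.standard_errors[1:]
        assert np.all(np.abs(m.model.coef - true) < 3 * se)

    def test_penalized_deviance_strictly_decreases(self, rng):
        x, y = two_gaussians(rng, sep=2.0, n=100)
        m = clf.fit(x, y, "lr")
        assert np.all(np.diff(m.model.deviance_trace) < 0)
        assert m.model.deviance >= 0


class TestBDLC:
    def test_no_signal_means_chance_level(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(400, 3))
        y = np.array([0, 1] * 200)
        m = clf.fit(x, y, "bdlc")
        _, pred = m.predict(x)
        assert abs((pred == y).mean() - 0.5) < 0.05

    def test_raising_threshold_never_adds_positives(self, rng):
        x, y = two_gaussians(rng, sep=2.0, n=100)
        m = clf.fit(x, y, "bdlc")
        scores, _ = m.predict(x)
        counts = [
            int((scores >= t).sum()) for t in np.linspace(-5, 5, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDFA:
    def test_white_noise_exponent(self):
        vals = [
            clf.dfa_exponent(np.random.default_rng(s).standard_normal(4096))
            for s in range(20)
        ]
        assert abs(np.mean(vals) - 0.5) < 0.1

    def test_random_walk_exponent(self):
        vals = [
            clf.dfa_exponent(
                np.cumsum(np.random.default_rng(100 + s).standard_normal(4096))
            )
            for s in range(20)
        ]
        assert abs(np.mean(vals) - 1.5) < 0.15

    def test_fluctuations_non_negative(self, rng):
        _, scales, flucts = clf.dfa_exponent(
            rng.normal(size=512), return_fluctuations=True
        )
        assert np.all(flucts >= 0)

    def test_oversized_scale_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds series length"):
            clf.dfa_exponent(rng.normal(size=64), scales=[4, 8, 16, 128])

    def test_classifier_matches_bruteforce_exponents(self, rng):
        x = np.vstack([
            np.cumsum(rng.normal(size=(25, 160)), axis=1),
            rng.normal(size=(25, 160)),
        ])
        y = np.array([1] * 25 + [0] * 25)
        m = clf.fit(x, y, "dfa")
        scores, pred = m.predict(x)
        # independent recomputation per epoch
        exps = np.array([clf.dfa_exponent(row) for row in x])
        mid = m.threshold if m.model.sign == 1 else -m.threshold
        expect = (m.model.sign * exps >= m.model.sign * mid).astype(int)
        assert np.array_equal(pred, expect)


class TestFirefly:
    def test_attractiveness_closed_form(self):
        assert clf.attractiveness(0.0, alpha0=0.7, beta=2.0) == pytest.approx(0.7)
        p = np.linspace(0, 3, 50)
        vals = clf.attractiveness(p, alpha0=0.7, beta=2.0)
        assert np.all(np.diff(vals) < 0)

    def test_sphere_convergence_over_seeds(self):
        for seed in range(5):
            cfg = clf.FireflyConfig(population=40, max_iter=1000, seed=seed)
            _, best, trace = clf.firefly_optimize(
                lambda x: float(np.sum(x ** 2)), cfg, 2
            )
            assert best < 1e-3
            assert np.all(np.diff(trace) <= 0)

    def test_others_contract_toward_single_brightest(self):
        """gamma=0, small absorption: every firefly strictly reduces its
        distance to the unique brightest one in one generation."""
        rng = np.random.default_rng(8)
        z = rng.uniform(0, 1, (6, 2))
        best = z[3]
        for m in range(6):
            if m == 3:
                continue
            d0 = np.linalg.norm(z[m] - best)
            a = clf.attractiveness(d0, alpha0=0.9, beta=0.01)
            moved = z[m] + a * (best - z[m])  # gamma = 0: no random term
            assert np.linalg.norm(moved - best) < d0

    def test_training_error_equals_trace_value(self, rng):
        x, y = two_gaussians(rng, sep=5.0, n=60)
        m = clf.fit(x, y, "firefly",
                    clf.FireflyConfig(population=12, max_iter=20, seed=1))
        _, pred = m.predict(x)
        assert (pred != y).mean() == pytest.approx(m.model.training_error)
        assert m.model.trace[-1] == pytest.approx(m.model.training_error)
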