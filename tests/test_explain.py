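"""Shapley attribution: axioms, estimators, instance explanations."""

import itertools
import math

import numpy as np
import pytest

import glucodss as gd
from glucodss.explain import CoalitionalGame, _channel_exposures

from conftest import make_series


def random_game(rng, n_players):
    value = {frozenset(): 0.0}
    for r in range(1, n_players + 1):
        for c in itertools.combinations(range(n_players), r):
            value[frozenset(c)] = float(rng.normal(0, 5))
    return CoalitionalGame(n_players, value)


def permutation_shapley(game):
    """Independent oracle: average marginal contribution over all orderings."""
    M = game.n_players
    phi = np.zeros(M)
    perms = list(itertools.permutations(range(M)))
    for perm in perms:
        seen = set()
        for j in perm:
            phi[j] += game.v(seen | {j}) - game.v(seen)
            seen.add(j)
    return phi / len(perms)


class TestShapleyExact:
    def test_worked_three_player_game(self):
        value = {frozenset(): 0.0, frozenset({0}): 1.0, frozenset({1}): 2.0,
                 frozenset({2}): 0.0, frozenset({0, 1}): 4.0,
                 frozenset({0, 2}): 1.0, frozenset({1, 2}): 2.0,
                 frozenset({0, 1, 2}): 4.0}
        game = CoalitionalGame(3, value)
        phi = gd.shapley_exact(game)
        assert np.allclose(phi, [1.5, 2.5, 0.0])
        assert np.allclose(phi, permutation_shapley(game))

    @pytest.mark.parametrize("n_players", [3, 4, 5, 6])
    def test_matches_permutation_oracle(self, n_players):
        rng = np.random.default_rng(n_players)
        for _ in range(10):
            game = random_game(rng, n_players)
            assert np.allclose(gd.shapley_exact(game), permutation_shapley(game))

    def test_efficiency_axiom(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            game = random_game(rng, 4)
            phi = gd.shapley_exact(game)
            assert phi.sum() == pytest.approx(
                game.v(range(4)) - game.v(()), abs=1e-9)

    def test_null_player_axiom(self):
        rng = np.random.default_rng(1)
        game = random_game(rng, 3)
        # make player 2 null: v(S + 2) = v(S) for every S
        for c in [frozenset(), frozenset({0}), frozenset({1}), frozenset({0, 1})]:
            game.value[c | {2}] = game.value[c]
        assert gd.shapley_exact(game)[2] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_axiom(self):
        rng = np.random.default_rng(2)
        # players 0 and 1 interchangeable in v
        v0, v01, v2, v02, v012 = rng.normal(0, 3, 5)
        value = {frozenset(): 0.0, frozenset({0}): v0, frozenset({1}): v0,
                 frozenset({2}): v2, frozenset({0, 1}): v01,
                 frozenset({0, 2}): v02, frozenset({1, 2}): v02,
                 frozenset({0, 1, 2}): v012}
        phi = gd.shapley_exact(CoalitionalGame(3, value))
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_linearity_in_v(self):
        rng = np.random.default_rng(3)
        g1, g2 = random_game(rng, 4), random_game(rng, 4)
        a, b = 1.7, -0.4
        combo = CoalitionalGame(4, {k: a * g1.value[k] + b * g2.value[k]
                                    for k in g1.value})
        assert np.allclose(gd.shapley_exact(combo),
                           a * gd.shapley_exact(g1) + b * gd.shapley_exact(g2))

    def test_missing_coalition_reported(self):
        game = CoalitionalGame(3, {frozenset(): 0.0})
        with pytest.raises(KeyError, match=r"\[0\]"):
            gd.shapley_exact(game)


class TestShapleyKernel:
    def test_full_enumeration_equals_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            game = random_game(rng, 3)
            assert np.allclose(gd.shapley_kernel(game), gd.shapley_exact(game),
                               atol=1e-9)

    def test_additive_game_recovers_coefficients(self):
        c = np.array([2.0, -1.0, 0.5, 3.0])
        value = {frozenset(S): float(sum(c[j] for j in S))
                 for r in range(5) for S in itertools.combinations(range(4), r)}
        game = CoalitionalGame(4, value)
        assert np.allclose(gd.shapley_kernel(game), c, atol=1e-9)

    def test_sampled_estimator_is_seeded_and_consistent(self):
        rng = np.random.default_rng(5)
        game = random_game(rng, 5)
        exact = gd.shapley_exact(game)
        a = gd.shapley_kernel(game, n_coalition_samples=4000, seed=1)
        b = gd.shapley_kernel(game, n_coalition_samples=4000, seed=1)
        c = gd.shapley_kernel(game, n_coalition_samples=4000, seed=2)
        assert np.array_equal(a, b)          # reproducible
        assert np.allclose(a, exact, atol=0.5)   # Monte-Carlo tolerance
        assert np.allclose(c, exact, atol=0.5)

    def test_degenerate_design_rejected(self):
        rng = np.random.default_rng(6)
        game = random_game(rng, 5)
        with pytest.raises(ValueError, match="coalitions"):
            gd.shapley_kernel(game, n_coalition_samples=2, seed=0)


class TestLinearClosedForm:
    def test_worked_substitution(self):
        # beta1 = 1.5, g(k) = 120, E[g] = 100 -> phi_g = 30
        phi = gd.linear_shap_closed_form([1.5], [120.0], [100.0])
        assert phi[0] == pytest.approx(30.0)

    def test_feature_at_mean_gets_zero(self):
        phi = gd.linear_shap_closed_form([2.0, -3.0], [5.0, 7.0], [5.0, 7.0])
        assert np.allclose(phi, 0.0)

    def test_completeness_identity(self):
        rng = np.random.default_rng(7)
        beta0 = 1.2
        beta = rng.normal(0, 2, 4)
        x = rng.normal(0, 3, 4)
        means = rng.normal(0, 3, 4)
        phi = gd.linear_shap_closed_form(beta, x, means)
        full = beta0 + float(beta @ x)
        base = beta0 + float(beta @ means)
        assert phi.sum() + base == pytest.approx(full)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            gd.linear_shap_closed_form([1.0], [1.0, 2.0], [0.0])


class LinearStub:
    """Predictor stub reading only the anchor sample: b0 + b . x[t]."""

    def __init__(self, beta0, beta, ph=30):
        self.config = gd.ModelConfig(variant="np", ph=ph, lookback=1)
        self.curves = None
        self.beta0 = float(beta0)
        self.beta = np.asarray(beta, dtype=float)

    def channels(self, cgm, insulin, cho, insulin_warmup=None):
        return np.column_stack([np.asarray(cgm, float),
                                np.asarray(insulin, float),
                                np.asarray(cho, float)])

    def forecast_at_anchors(self, ch, anchors):
        x = ch[np.asarray(anchors, dtype=int)]
        return self.beta0 + x @ self.beta


class TestExplainInstance:
    def _random_series(self, rng, n=120):
        return make_series(rng.uniform(80, 250, n),
                           insulin=rng.uniform(0, 0.5, n),
                           cho=rng.uniform(0, 5, n))

    def test_linear_stub_matches_closed_form(self):
        """Channel masking on a linear model reproduces beta_j (x_j - E[x_j])."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            beta0 = float(rng.normal(100, 20))
            beta = rng.normal(0, 2, 3)
            stub = LinearStub(beta0, beta)
            s = self._random_series(rng, n=30)
            background = np.array([float(rng.uniform(80, 250)),
                                   float(rng.uniform(0, 0.5)),
                                   float(rng.uniform(0, 5))])
            t = int(rng.integers(0, 30))
            e = gd.explain_instance(stub, s, t, background)
            x = np.array([s.cgm[t], s.insulin[t], s.cho[t]])
            expected = gd.linear_shap_closed_form(beta, x, background)
            assert np.allclose(e.phi, expected, atol=1e-9)
            assert e.base + e.phi.sum() == pytest.approx(e.prediction, abs=1e-9)

    def test_all_channels_at_background_gives_zero(self):
        stub = LinearStub(50.0, [0.5, -20.0, 3.0])
        bg = np.array([130.0, 0.02, 0.0])
        s = make_series(np.full(50, 130.0), insulin=np.full(50, 0.02))
        e = gd.explain_instance(stub, s, 25, bg)
        assert np.allclose(e.phi, 0.0, atol=1e-12)
        assert e.prediction == pytest.approx(e.base)

    def test_efficiency_on_trained_model(self, small_corpus, trained_p):
        test = small_corpus.split.test
        from glucodss.pipeline import raw_channel_means
        bg = raw_channel_means(small_corpus.split.train)
        from glucodss.explain import default_summary_anchors
        anc = default_summary_anchors(trained_p, test, max_anchors=100, seed=0)
        exps = gd.explain_anchors(trained_p, test, anc, bg)
        for e in exps:
            assert e.base + e.phi.sum() == pytest.approx(e.prediction, abs=1e-6)

    def test_background_shape_checked(self, small_corpus, trained_p):
        with pytest.raises(ValueError, match="channel"):
            gd.explain_instance(trained_p, small_corpus.split.test, 50,
                                np.array([1.0, 2.0]))


class TestSummarize:
    def _stub_explanations(self, beta, n=60, seed=0):
        rng = np.random.default_rng(seed)
        stub = LinearStub(120.0, beta)
        s = make_series(rng.uniform(80, 250, n),
                        insulin=rng.uniform(0, 0.5, n),
                        cho=rng.uniform(0, 5, n))
        bg = np.array([150.0, 0.25, 2.5])
        return gd.explain_anchors(stub, s, np.arange(n), bg)

    def test_cho_only_model(self):
        exps = self._stub_explanations([0.0, 0.0, 4.0])
        stats = gd.summarize(exps, value_source="raw")
        assert stats.sign_consistency["cho"] == pytest.approx(1.0)
        assert stats.importance["cgm"] == pytest.approx(0.0, abs=1e-12)
        assert stats.importance["insulin"] == pytest.approx(0.0, abs=1e-12)
        assert stats.rank["cho"] == 1

    def test_insulin_decreasing_model(self):
        exps = self._stub_explanations([0.1, -30.0, 0.0])
        stats = gd.summarize(exps, value_source="raw")
        assert stats.sign_consistency["insulin"] == pytest.approx(-1.0)

    def test_duplicated_list_identical_stats(self):
        exps = self._stub_explanations([1.0, -2.0, 3.0])
        a = gd.summarize(exps)
        b = gd.summarize(exps + exps)
        for ch in a.importance:
            assert a.importance[ch] == pytest.approx(b.importance[ch], rel=1e-12)
            assert a.sign_consistency[ch] == pytest.approx(
                b.sign_consistency[ch], rel=1e-9)

    def test_constant_feature_reported_absent(self):
        rng = np.random.default_rng(1)
        stub = LinearStub(100.0, [1.0, 0.0, 0.0])
        s = make_series(rng.uniform(80, 250, 40),
                        insulin=np.full(40, 0.02))  # constant, cho all zero
        exps = gd.explain_anchors(stub, s, np.arange(40),
                                  np.array([150.0, 0.02, 0.0]))
        stats = gd.summarize(exps)
        assert stats.sign_consistency["insulin"] is None
        assert stats.sign_consistency["cho"] is None

    def test_too_few_instances(self):
        exps = self._stub_explanations([1.0, 1.0, 1.0], n=10)
        with pytest.raises(ValueError, match="explanations"):
            gd.summarize(exps)

    def test_exposures_recorded(self, small_corpus, trained_p):
        test = small_corpus.split.test
        from glucodss.explain import default_summary_anchors
        from glucodss.pipeline import raw_channel_means
        anc = default_summary_anchors(trained_p, test, max_anchors=40, seed=0)
        exps = gd.explain_anchors(trained_p, test,  anc,
                                  raw_channel_means(small_corpus.split.train))
        iob_ref, cob_ref = _channel_exposures(trained_p, test)
        for e in exps:
            assert e.exposures[1] == pytest.approx(iob_ref[e.anchor])
            assert e.exposures[2] == pytest.approx(cob_ref[e.anchor])
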