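"""Functional NER building blocks against independent oracles."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp

from hichkit import ner


def random_crf(rng, n, L):
    emis = rng.normal(size=(n, L))
    params = ner.CrfParams(rng.normal(size=(L, L)), rng.normal(size=L),
                           rng.normal(size=L))
    return emis, params


def enumerate_scores(emis, params):
    n, L = emis.shape
    return {tags: ner.crf_path_score(emis, params, tags)
            for tags in itertools.product(range(L), repeat=n)}


class TestAttention:
    def test_scalar_identity(self):
        out = ner.attention([[1.0]], [[1.0]], [[1.0]], 1)
        assert np.allclose(out, [[1.0]])

    def test_identical_keys_give_uniform_mean(self, rng):
        K = np.ones((4, 3))
        V = rng.normal(size=(4, 5))
        Q = rng.normal(size=(2, 3))
        assert np.allclose(ner.attention(Q, K, V, 3), np.tile(V.mean(0), (2, 1)))

    def test_small_integer_case_matches_elementwise_evaluation(self):
        Q = np.array([[1.0, 0.0], [0.0, 2.0]])
        K = np.array([[1.0, 1.0], [2.0, 0.0]])
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        d_k = 2
        # independent elementwise softmax(QK^T/sqrt(d_k))V
        expected = np.empty((2, 2))
        for i in range(2):
            s = [sum(Q[i, k] * K[j, k] for k in range(2)) / np.sqrt(d_k)
                 for j in range(2)]
            w = np.exp(s) / np.exp(s).sum()
            for c in range(2):
                expected[i, c] = sum(w[j] * V[j, c] for j in range(2))
        assert np.allclose(ner.attention(Q, K, V, d_k), expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ner.attention(np.ones((2, 3)), np.ones((4, 3)), np.ones((5, 2)), 3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 16))
    def test_rows_are_convex_combinations(self, seed):
        rng = np.random.default_rng(seed)
        Q, K = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        V = rng.normal(size=(5, 2))
        scores = Q @ K.T / 2.0
        w = np.exp(scores - scores.max(1, keepdims=True))
        w /= w.sum(1, keepdims=True)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(ner.attention(Q, K, V, 4), w @ V)


class TestReceptiveField:
    @staticmethod
    def support_oracle(kernel, dilations, layer):
        """Count inputs influencing one output by pushing an influence mask
        through the stacked dilated kernels."""
        half = kernel // 2
        n = 4 * sum(dilations[:layer]) + 9
        influence = np.zeros((n, n))
        np.fill_diagonal(influence, 1.0)
        for d in dilations[:layer]:
            new = np.zeros_like(influence)
            for off in range(-half, half + 1):
                shift = off * d
                for t in range(n):
                    if 0 <= t + shift < n:
                        new[t] += influence[t + shift]
            influence = new
        return int((influence[n // 2] != 0).sum())

    @pytest.mark.parametrize("dilations,layer,expected", [
        ((1,), 1, 3), ((1, 2), 2, 7), ((1, 2, 4), 3, 15)])
    def test_kernel3_doubling_schedule(self, dilations, layer, expected):
        sched = ner.DilationSchedule(3, dilations)
        assert ner.receptive_field(sched, layer) == expected
        assert self.support_oracle(3, dilations, layer) == expected

    def test_arbitrary_schedules_match_support_enumeration(self, rng):
        for _ in range(10):
            kernel = int(rng.choice([3, 5]))
            dil = tuple(int(d) for d in rng.integers(1, 5, size=3))
            sched = ner.DilationSchedule(kernel, dil)
            for layer in (1, 2, 3):
                assert ner.receptive_field(sched, layer) == \
                    self.support_oracle(kernel, dil, layer)

    def test_strictly_increasing_and_range_checked(self):
        sched = ner.DilationSchedule(3, (1, 2, 4))
        rf = [ner.receptive_field(sched, i) for i in (1, 2, 3)]
        assert rf == sorted(set(rf))
        with pytest.raises(IndexError):
            ner.receptive_field(sched, 4)
        with pytest.raises(ValueError):
            ner.receptive_field(sched, 0)


def make_cell(rng, hidden, inp, scale=1.0):
    w = lambda: rng.normal(scale=scale, size=(hidden, hidden + inp))
    b = lambda: rng.normal(scale=scale, size=hidden)
    return ner.RecurrentCell(w(), w(), w(), w(), b(), b(), b(), b())


class TestLstmStep:
    def test_all_zero_parameters(self):
        z = np.zeros((2, 3))
        cell = ner.RecurrentCell(z, z, z, z, *([np.zeros(2)] * 4))
        h, c = ner.lstm_step(cell, np.zeros(1), np.zeros(2), np.zeros(2))
        assert np.allclose(c, 0) and np.allclose(h, 0)
        # gates at zero pre-activation are exactly 1/2
        f = 1 / (1 + np.exp(-(cell.w_f @ np.zeros(3) + cell.b_f)))
        assert np.allclose(f, 0.5)

    def test_gate_saturation_limit(self):
        """Large positive biases drive f,i -> 1 so C_t -> C_prev + tanh(b_c)."""
        z = np.zeros((1, 2))
        big = np.array([50.0])
        cell = ner.RecurrentCell(z, z, z, z, big, big, big, big)
        c_prev = np.array([0.7])
        h, c = ner.lstm_step(cell, np.zeros(1), np.zeros(1), c_prev)
        assert np.allclose(c, c_prev + np.tanh(50.0), atol=1e-8)
        assert np.allclose(h, np.tanh(c), atol=1e-8)

    def test_one_dimensional_pencil_arithmetic(self):
        cell = ner.RecurrentCell(
            np.array([[0.5, 1.0]]), np.array([[-0.5, 0.5]]),
            np.array([[1.0, -1.0]]), np.array([[0.2, 0.3]]),
            np.array([0.1]), np.array([-0.1]), np.array([0.0]), np.array([0.05]))
        u, h0, c0 = np.array([2.0]), np.array([0.4]), np.array([-0.3])
        sig = lambda x: 1 / (1 + np.exp(-x))
        f = sig(0.5 * 0.4 + 1.0 * 2.0 + 0.1)
        i = sig(-0.5 * 0.4 + 0.5 * 2.0 - 0.1)
        o = sig(1.0 * 0.4 - 1.0 * 2.0 + 0.0)
        ct = np.tanh(0.2 * 0.4 + 0.3 * 2.0 + 0.05)
        c1 = f * (-0.3) + i * ct
        h1 = o * np.tanh(c1)
        h, c = ner.lstm_step(cell, u, h0, c0)
        assert np.allclose(h, h1) and np.allclose(c, c1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 16))
    def test_gates_strictly_inside_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        cell = make_cell(rng, 4, 3, scale=2.0)
        u, h0, c0 = rng.normal(size=3), rng.normal(size=4), rng.normal(size=4)
        hu = np.concatenate([h0, u])
        for w, b in [(cell.w_f, cell.b_f), (cell.w_i, cell.b_i),
                     (cell.w_o, cell.b_o)]:
            g = 1 / (1 + np.exp(-(w @ hu + b)))
            assert np.all(g > 0) and np.all(g < 1)
        h, _ = ner.lstm_step(cell, u, h0, c0)
        assert np.all(np.abs(h) < 1)


class TestCrf:
    def test_uniform_scores_partition_is_n_log_L(self):
        params = ner.CrfParams.zeros(3)
        for n in (1, 2, 5):
            assert ner.crf_partition(np.zeros((n, 3)), params) == \
                pytest.approx(n * np.log(3), abs=1e-12)

    def test_single_tag_alphabet(self, rng):
        emis = rng.normal(size=(4, 1))
        params = ner.CrfParams(rng.normal(size=(1, 1)), rng.normal(size=1),
                               rng.normal(size=1))
        path_score = ner.crf_path_score(emis, params, [0, 0, 0, 0])
        assert ner.crf_partition(emis, params) == pytest.approx(path_score)
        assert ner.crf_log_likelihood(emis, params, [0, 0, 0, 0]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_partition_and_likelihood_match_enumeration(self, rng):
        for _ in range(25):
            n, L = int(rng.integers(1, 6)), int(rng.integers(2, 5))
            emis, params = random_crf(rng, n, L)
            scores = enumerate_scores(emis, params)
            log_z = logsumexp(list(scores.values()))
            assert ner.crf_partition(emis, params) == pytest.approx(log_z, abs=1e-8)
            tags = tuple(rng.integers(0, L, size=n))
            ll = ner.crf_log_likelihood(emis, params, tags)
            assert ll <= 1e-12
            assert ll == pytest.approx(scores[tags] - log_z, abs=1e-8)

    def test_probabilities_normalize_over_enumerated_sequences(self, rng):
        emis, params = random_crf(rng, 3, 3)
        total = sum(np.exp(ner.crf_log_likelihood(emis, params, tags))
                    for tags in itertools.product(range(3), repeat=3))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_viterbi_attains_enumerated_maximum(self, rng):
        emis, params = random_crf(rng, 4, 3)
        scores = enumerate_scores(emis, params)
        best = ner.viterbi_decode(emis, params)
        assert ner.crf_path_score(emis, params, best) == \
            pytest.approx(max(scores.values()), abs=1e-10)

    def test_viterbi_dominates_random_paths(self, rng):
        emis, params = random_crf(rng, 8, 4)
        v = ner.crf_path_score(emis, params, ner.viterbi_decode(emis, params))
        for _ in range(100):
            path = rng.integers(0, 4, size=8)
            assert v >= ner.crf_path_score(emis, params, path) - 1e-10

    def test_viterbi_tiebreak_prefers_low_tag_at_latest_difference(self):
        """With fully symmetric scores every path ties; the decode must pick
        the path that is minimal when compared from the end backwards."""
        emis = np.zeros((3, 2))
        params = ner.CrfParams.zeros(2)
        assert ner.viterbi_decode(emis, params) == [0, 0, 0]
        # oracle: enumerate ties and apply the latest-difference order
        scores = enumerate_scores(emis, params)
        best_score = max(scores.values())
        tied = [t for t, s in scores.items() if abs(s - best_score) < 1e-12]
        expected = min(tied, key=lambda t: t[::-1])
        assert tuple(ner.viterbi_decode(emis, params)) == expected

    def test_zero_argmax_on_strong_emissions(self):
        emis = np.array([[10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])
        params = ner.CrfParams.zeros(3)
        assert ner.viterbi_decode(emis, params) == [0, 1, 2]

    def test_contract_errors(self):
        params = ner.CrfParams.zeros(2)
        with pytest.raises(ValueError):
            ner.crf_partition(np.zeros((0, 2)), params)
        with pytest.raises(ValueError):
            ner.crf_log_likelihood(np.zeros((2, 2)), params, [0, 5])
        with pytest.raises(ValueError):
            ner.crf_log_likelihood(np.zeros((2, 2)), params, [0])


class TestSpansAndMetrics:
    def test_adjacent_b_tags_make_two_spans(self):
        spans = ner.spans_from_bio(["B-GCS", "B-GCS", "O"])
        assert spans == [((0, 1), "GCS"), ((1, 2), "GCS")]

    def test_all_o_gives_no_spans(self):
        assert ner.spans_from_bio(["O", "O"]) == []

    def test_perfect_prediction_scores_100(self):
        gold = [{((0, 2), "GCS")}, {((1, 3), "VOLUME")}]
        assert ner.ner_metrics(gold, gold) == (100.0, 100.0, 100.0)

    def test_half_right_prediction(self):
        gold = [{((0, 1), "A"), ((2, 3), "B")}]
        pred = [{((0, 1), "A"), ((4, 5), "C")}]
        assert ner.ner_metrics(gold, pred) == (50.0, 50.0, 50.0)

    def test_zero_denominators_warn_and_define_zero(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            p, r, f1 = ner.ner_metrics([{((0, 1), "A")}], [set()])
        assert (p, r, f1) == (0.0, 100.0 * 0, 0.0)
        assert any("precision" in str(x.message) for x in w)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=st.floats(0, 100), r=st.floats(0, 100))
    def test_f1_is_harmonic_mean(self, p, r):
        f1 = ner.f1_score(p, r)
        assert min(p, r) - 1e-9 <= f1 <= max(p, r) + 1e-9
        if p == r:
            assert f1 == pytest.approx(p)
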