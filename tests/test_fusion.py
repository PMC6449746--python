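"""Quantile normalization (with tie adjustment) and weighted-mean fusion."""

import numpy as np
import pytest

from simfuse.fusion import FusionConfig, fuse, normalize_and_fuse, quantile_normalize
from simfuse.similarity import SimilarityMatrix
from simfuse.spaces import ValidationError


def qn_oracle(vectors):
    """Brute-force quantile normalization: explicit sort/rank/tie-average loops."""
    k, m = len(vectors), len(vectors[0])
    sorted_cols = [sorted(v) for v in vectors]
    reference = [sum(col[i] for col in sorted_cols) / k for i in range(m)]
    out = []
    for v in vectors:
        order = sorted(range(m), key=lambda i: v[i])
        res = [0.0] * m
        i = 0
        while i < m:
            j = i
            while j < m and v[order[j]] == v[order[i]]:
                j += 1
            tie_mean = sum(reference[i:j]) / (j - i)
            for t in range(i, j):
                res[order[t]] = tie_mean
            i = j
        out.append(res)
    return out


def _matrices(vectors, n_diseases):
    diseases = tuple(f"d{i}" for i in range(n_diseases))
    return [
        SimilarityMatrix.from_pair_vector(diseases, np.asarray(v, float), f"s{i}")
        for i, v in enumerate(vectors)
    ]


class TestQuantileNormalize:
    def test_no_tie_example(self):
        out = quantile_normalize(_matrices([[1, 2, 3], [4, 5, 6]], 3))
        for m in out:
            assert np.allclose(m.pair_vector(), [2.5, 3.5, 4.5])
            assert m.normalized

    def test_tie_adjustment_example(self):
        out = quantile_normalize(_matrices([[1, 1, 2], [3, 4, 5]], 3))
        assert np.allclose(out[0].pair_vector(), [2.25, 2.25, 3.5])
        assert np.allclose(out[1].pair_vector(), [2.0, 2.5, 3.5])

    def test_identical_matrices_unchanged(self):
        vec = [0.3, 0.1, 0.7]
        out = quantile_normalize(_matrices([vec, vec], 3))
        for m in out:
            assert np.allclose(m.pair_vector(), vec)

    def test_sorted_vectors_identical_after_normalization(self, rng):
        # tie-free continuous inputs: sorted vectors must agree exactly
        vectors = rng.random((4, 45))
        out = quantile_normalize(_matrices(vectors, 10))
        sorted_vecs = np.sort(np.vstack([m.pair_vector() for m in out]), axis=1)
        assert np.max(np.abs(sorted_vecs - sorted_vecs[0])) == 0.0

    def test_preserves_within_space_rank_order(self, rng):
        values = rng.integers(0, 8, size=(3, 15)) / 8.0  # plenty of ties
        out = quantile_normalize(_matrices(values, 6))
        for raw, norm in zip(values, out):
            nvec = norm.pair_vector()
            for i in range(len(raw)):
                for j in range(len(raw)):
                    if raw[i] < raw[j]:
                        assert nvec[i] <= nvec[j]
                    if raw[i] == raw[j]:
                        assert nvec[i] == nvec[j]

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_matches_bruteforce_oracle(self, rng, with_ties):
        for _ in range(100):
            if with_ties:
                vectors = rng.integers(0, 6, size=(3, 15)) / 6.0
            else:
                vectors = rng.random((3, 15))
            out = quantile_normalize(_matrices(vectors, 6))
            expected = qn_oracle([list(v) for v in vectors])
            for m, exp in zip(out, expected):
                assert np.allclose(m.pair_vector(), exp, atol=1e-12)

    def test_single_matrix_is_identity_up_to_tie_averaging(self):
        out = quantile_normalize(_matrices([[0.2, 0.2, 0.9]], 3))
        assert np.allclose(out[0].pair_vector(), [0.2, 0.2, 0.9])

    def test_rejects_mismatched_disease_lists(self):
        a = SimilarityMatrix.from_pair_vector(("x", "y", "z"), [1, 2, 3], "a")
        b = SimilarityMatrix.from_pair_vector(("x", "y", "w"), [1, 2, 3], "b")
        with pytest.raises(ValidationError, match="disease"):
            quantile_normalize([a, b])

    def test_rejects_already_normalized_input(self):
        (m,) = quantile_normalize(_matrices([[1, 2, 3]], 3))
        with pytest.raises(ValidationError, match="normalized"):
            quantile_normalize([m])


class TestFuse:
    def _normalized(self, vectors, n):
        return quantile_normalize(_matrices(vectors, n))

    def test_unit_weight_returns_that_space(self, rng):
        mats = self._normalized(rng.random((2, 6)), 4)
        config = FusionConfig(("s0", "s1"), (1.0, 0.0))
        fused = fuse(mats, config)
        assert np.allclose(fused.pair_vector(), mats[0].pair_vector())

    def test_equal_weights_average(self):
        diseases = ("a", "b", "c")
        mats = [
            SimilarityMatrix.from_pair_vector(diseases, [0.2, 0.2, 0.2], "s0", normalized=True),
            SimilarityMatrix.from_pair_vector(diseases, [0.4, 0.4, 0.4], "s1", normalized=True),
        ]
        fused = fuse(mats, FusionConfig.uniform(["s0", "s1"]))
        assert np.allclose(fused.pair_vector(), 0.3)

    def test_downweighting_scheme_sums_to_one(self):
        # three "traditional" spaces jointly one-third, three others two-thirds
        config = FusionConfig(
            ("ont", "phe", "lit", "gen", "exp", "drug"),
            (1 / 9, 1 / 9, 1 / 9, 2 / 9, 2 / 9, 2 / 9),
        )
        assert sum(config.weights) == pytest.approx(1.0)
        assert sum(config.weights[:3]) == pytest.approx(1 / 3)

    def test_linear_in_inputs_vs_bruteforce_loop(self, rng):
        vectors = rng.random((3, 10))
        mats = self._normalized(vectors, 5)
        weights = (0.5, 0.3, 0.2)
        fused = fuse(mats, FusionConfig(("s0", "s1", "s2"), weights))
        normalized_vecs = [m.pair_vector() for m in mats]
        for k in range(10):
            expected = sum(w * v[k] for w, v in zip(weights, normalized_vecs))
            assert fused.pair_vector()[k] == pytest.approx(expected)

    def test_rejects_unnormalized_matrix(self):
        raw = _matrices([[1, 2, 3]], 3)
        with pytest.raises(ValidationError, match="not quantile-normalized"):
            fuse(raw, FusionConfig.uniform(["s0"]))

    def test_rejects_weight_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            FusionConfig(("a", "b"), (1.0,))

    def test_weights_normalized_at_construction(self):
        config = FusionConfig(("a", "b"), (2.0, 6.0))
        assert config.weights == (0.25, 0.75)


class TestNormalizeAndFuse:
    def test_subset_renormalizes_by_default(self, rng):
        vectors = rng.random((3, 6))
        raw = _matrices(vectors, 4)
        config = FusionConfig.uniform(["s0", "s1"])
        fused_sub, normalized = normalize_and_fuse(raw, config)
        # reference must come from the two selected spaces only
        expected_ref = np.sort(np.vstack([vectors[0], vectors[1]]), axis=1).mean(0)
        assert np.allclose(np.sort(normalized[0].pair_vector()), expected_ref)

    def test_reuse_mode_inherits_full_normalization(self, rng):
        vectors = rng.random((3, 6))
        raw = _matrices(vectors, 4)
        config = FusionConfig.uniform(["s0", "s1"])
        _, normalized = normalize_and_fuse(raw, config, renormalize=False)
        full = quantile_normalize(raw)
        assert np.allclose(normalized[0].pair_vector(), full[0].pair_vector())
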