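"""Multi-scale fusion: branch transforms, soft attention and merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinediff.msfm import (MSFM, compress, fuse_sum, global_pool,
                            soft_attention, weighted_merge)
from spinediff.nn import Tensor


@pytest.fixture
def msfm():
    return MSFM(4, np.random.default_rng(0))


class TestBranchTransform:
    def test_zero_input_gives_zero_branches(self, msfm):
        z = Tensor(np.zeros((1, 4, 12, 12), dtype=np.float32))
        for out in msfm.branch_transform(z):
            np.testing.assert_array_equal(out.data, 0.0)

    def test_same_padding_preserves_shape(self, msfm):
        x = Tensor(np.random.default_rng(1).random((1, 4, 9, 7)).astype(np.float32))
        for out in msfm.branch_transform(x):
            assert out.shape == (1, 4, 9, 7)

    def test_all_ones_kernel_interior_sum(self):
        m = MSFM(1, np.random.default_rng(0))
        m.conv3.weight.data[...] = 1.0
        x = Tensor(np.ones((1, 1, 8, 8), dtype=np.float32))
        out = m.conv3(x)
        assert out.data[0, 0, 4, 4] == pytest.approx(9.0)


class TestFuseSum:
    def test_examples(self):
        z = np.zeros((2, 2))
        np.testing.assert_array_equal(fuse_sum(z, z, z), z)
        np.testing.assert_allclose(
            fuse_sum(np.full((2, 2), 1.0), np.full((2, 2), 2.0),
                     np.full((2, 2), 3.0)), 6.0)

    def test_commutative(self):
        rng = np.random.default_rng(0)
        a, b, c = (rng.random((3, 4)) for _ in range(3))
        np.testing.assert_allclose(fuse_sum(a, b, c), fuse_sum(c, a, b),
                                   rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_sum(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((2, 2)))


class TestGlobalPool:
    def test_examples(self):
        grid = np.array([[[1.0, 2.0], [3.0, 4.0]]])  # one channel, 2x2
        assert global_pool(grid)[0] == pytest.approx(2.5)
        np.testing.assert_array_equal(global_pool(np.zeros((3, 4, 4))), 0.0)
        np.testing.assert_allclose(global_pool(np.full((2, 5, 5), 7.0)), 7.0)


class TestCompress:
    def test_identity_on_nonnegative(self):
        s = np.array([0.0, 1.0, 2.5])
        np.testing.assert_allclose(compress(s, np.eye(3)), s)

    def test_elu_on_negative_scalar(self):
        z = compress(np.array([-1.0]), np.array([[1.0]]))
        assert z[0] == pytest.approx(np.exp(-1.0) - 1.0, abs=1e-9)

    def test_zero_propagates(self):
        np.testing.assert_allclose(compress(np.zeros(4), np.ones((2, 4))), 0.0)


class TestSoftAttention:
    def test_symmetric_logits_give_thirds(self):
        z = np.array([1.0, 2.0])
        A = np.ones((3, 2))
        a, b, c = soft_attention(z, A, A, A)
        np.testing.assert_allclose(a, 1 / 3)
        np.testing.assert_allclose(b, 1 / 3)
        np.testing.assert_allclose(c, 1 / 3)

    def test_log2_logit_oracle(self):
        z = np.array([1.0])
        a, b, c = soft_attention(z, np.array([[np.log(2.0)]]),
                                 np.array([[0.0]]), np.array([[0.0]]))
        assert a[0] == pytest.approx(0.5, abs=1e-12)
        assert b[0] == pytest.approx(0.25, abs=1e-12)
        assert c[0] == pytest.approx(0.25, abs=1e-12)

    def test_invariant_to_common_logit_shift(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(4)
        A, B, C = (rng.standard_normal((5, 4)) for _ in range(3))
        ref = soft_attention(z, A, B, C)
        # adding a constant row shift to all three logit matrices leaves the
        # weights unchanged (softmax shift invariance, overflow-guarded)
        shift = np.full((5, 4), 250.0) @ np.diag(z != 0)  # constant in A_n z
        shifted = soft_attention(z, A + 100.0 * np.outer(np.ones(5), z) / (z @ z),
                                 B + 100.0 * np.outer(np.ones(5), z) / (z @ z),
                                 C + 100.0 * np.outer(np.ones(5), z) / (z @ z))
        for w_ref, w_new in zip(ref, shifted):
            np.testing.assert_allclose(w_ref, w_new, atol=1e-6)

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_weights_normalise(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(3)
        mats = [rng.standard_normal((6, 3)) * 3 for _ in range(3)]
        a, b, c = soft_attention(z, *mats)
        np.testing.assert_allclose(a + b + c, 1.0, atol=1e-6)
        for w in (a, b, c):
            assert np.all((w > 0) & (w < 1))


class TestWeightedMerge:
    def test_uniform_weights_fixed_point(self):
        g = np.random.default_rng(0).random((2, 3, 3))
        w = (np.full(2, 1 / 3),) * 3
        np.testing.assert_allclose(weighted_merge(g, g, g, w), g, rtol=1e-12)

    def test_vertex_weight_selects_branch(self):
        rng = np.random.default_rng(1)
        a, b, c = (rng.random((2, 3, 3)) for _ in range(3))
        w = (np.ones(2), np.zeros(2), np.zeros(2))
        np.testing.assert_allclose(weighted_merge(a, b, c, w), a)

    def test_scalar_oracle(self):
        out = weighted_merge(np.array(2.0), np.array(4.0), np.array(6.0),
                             (0.5, 0.25, 0.25))
        assert float(out) == pytest.approx(3.5)


class TestModuleForward:
    @pytest.mark.parametrize("h,w,c", [(8, 8, 2), (9, 7, 4), (16, 12, 1)])
    def test_shape_preserved(self, h, w, c):
        m = MSFM(c, np.random.default_rng(0))
        m.norm.test_mode = True
        x = Tensor(np.random.default_rng(2).random((1, c, h, w)).astype(np.float32))
        assert m(x).shape == (1, c, h, w)

    def test_output_bounded_by_branch_extremes(self):
        m = MSFM(4, np.random.default_rng(3))
        m.norm.test_mode = True
        x = Tensor(np.random.default_rng(4).standard_normal((1, 4, 10, 10))
                   .astype(np.float32))
        a, b, c = (t.data for t in m.branch_transform(x))
        out = m(x).data
        lo = np.minimum(np.minimum(a, b), c)
        hi = np.maximum(np.maximum(a, b), c)
        assert np.all(out >= lo - 1e-5) and np.all(out <= hi + 1e-5)
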