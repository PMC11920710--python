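"""PCA/axis canonical ordering and the grid encoding round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tawssnet.ordering import (
    DegenerateCloudError,
    OrderedGrid,
    axis_order,
    from_grid,
    pca_order,
    to_grid,
)


def _random_cloud(n=200, seed=0):
    rng = np.random.default_rng(seed)
    # anisotropic cloud with a distinct eigenvalue spectrum and skewness
    x = rng.normal(size=(n, 3)) * [5.0, 2.0, 0.7]
    x[:, 0] += 0.5 * x[:, 0] ** 2 / 5.0
    return x


class TestPcaOrder:
    def test_collinear_cloud_sorted_by_projection(self):
        d = np.array([1.0, 2.0, 2.0]) / 3.0
        coords = np.array([3.0, 1.0, 2.0])[:, None] * d
        o = pca_order(coords)
        assert o.permutation.tolist() == [1, 2, 0]

    def test_permutation_invariance_of_ordered_sequence(self):
        coords = _random_cloud()
        o1 = pca_order(coords)
        rng = np.random.default_rng(3)
        shuffle = rng.permutation(len(coords))
        o2 = pca_order(coords[shuffle])
        assert np.allclose(coords[o1.permutation], coords[shuffle][o2.permutation])

    def test_leading_axis_matches_bruteforce_covariance_oracle(self):
        coords = _random_cloud(seed=5)
        o = pca_order(coords)
        # explicit covariance assembly, element by element
        c = coords - coords.mean(axis=0)
        cov = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                cov[i, j] = np.mean(c[:, i] * c[:, j])
        evals, evecs = np.linalg.eig(cov)
        lead = evecs[:, np.argmax(evals)]
        cosang = abs(np.dot(lead / np.linalg.norm(lead), o.basis[:, 0]))
        assert cosang == pytest.approx(1.0, abs=1e-9)

    def test_rotation_robustness_same_permutation(self):
        coords = _random_cloud(seed=8)
        o1 = pca_order(coords)
        rng = np.random.default_rng(1)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        o2 = pca_order(coords @ rot.T + np.array([4.0, -1.0, 2.0]))
        assert np.array_equal(o1.permutation, o2.permutation)
        # aligned coordinates are pose-independent too
        assert np.allclose(
            o1.aligned(coords), o2.aligned(coords @ rot.T + np.array([4.0, -1.0, 2.0])), atol=1e-9
        )

    def test_rank0_cloud_rejected(self):
        with pytest.raises(DegenerateCloudError):
            pca_order(np.ones((10, 3)))

    def test_determinism(self):
        coords = _random_cloud(seed=2)
        assert np.array_equal(pca_order(coords).permutation, pca_order(coords).permutation)


class TestAxisOrder:
    def test_scalar_sort_on_x(self):
        coords = np.array([[2.0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]])
        assert axis_order(coords, "x").permutation.tolist() == [1, 2, 0]

    def test_sorted_input_gives_identity(self):
        coords = np.array([[0.0, 5, 1], [1.0, 4, 2], [2.0, 3, 3]])
        assert axis_order(coords, "X").permutation.tolist() == [0, 1, 2]

    @pytest.mark.parametrize("axis,col", [("x", 0), ("y", 1), ("z", 2)])
    def test_nondecreasing_against_naive_sort(self, axis, col):
        for seed in range(10):
            coords = np.random.default_rng(seed).normal(size=(50, 3))
            o = axis_order(coords, axis)
            sorted_vals = coords[o.permutation][:, col]
            assert np.all(np.diff(sorted_vals) >= 0)
            assert np.allclose(sorted_vals, np.sort(coords[:, col]))


class TestGridEncoding:
    def test_shapes(self):
        feats = np.arange(4096 * 3, dtype=float).reshape(4096, 3)
        o = axis_order(np.random.default_rng(0).normal(size=(4096, 3)), "x")
        g = to_grid(feats, o, 64, 64)
        assert g.tensor.shape == (64, 64, 3)

    def test_row_major_layout(self):
        from tawssnet.ordering import Ordering

        o = Ordering(permutation=np.arange(4), method="X")
        g = to_grid(np.array([0.0, 1.0, 2.0, 3.0]), o, 2, 2)
        assert np.array_equal(g.tensor[..., 0], [[0.0, 1.0], [2.0, 3.0]])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_bitwise(self, seed):
        rng = np.random.default_rng(seed)
        n, c = 64, 4
        feats = rng.normal(size=(n, c))
        coords = rng.normal(size=(n, 3))
        o = pca_order(coords)
        back = from_grid(to_grid(feats, o, 8, 8), o)
        assert np.array_equal(back, feats)

    def test_shape_mismatch_rejected(self):
        o = axis_order(np.random.default_rng(0).normal(size=(10, 3)), "x")
        with pytest.raises(ValueError):
            to_grid(np.zeros((10, 1)), o, 3, 3)
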