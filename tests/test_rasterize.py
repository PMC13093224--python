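import numpy as np
import pytest

from gala.io_formats import HistologyImage, PointDataset
from gala.rasterize import (RasterGrid, RasterTensor, bilinear_sample,
                            concat_modalities, make_grid, normalize_pair,
                            rasterize_expression, rasterize_histology,
                            sobel_magnitude)


def brute_force_raster(coords, values, grid, sigma):
    """O(pixels × points) reference splatting without truncation."""
    out = np.zeros((values.shape[1], grid.H, grid.W))
    X, Y = grid.world_coords()
    for i in range(coords.shape[0]):
        k = np.exp(-((X - coords[i, 0]) ** 2 + (Y - coords[i, 1]) ** 2)
                   / (2 * sigma ** 2))
        out += values[i][:, None, None] * k
    return out


class TestMakeGrid:
    def test_box_formula(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0]])
        g = make_grid([pts], dx=1.0, pad_fraction=0.1)
        assert (g.W, g.H) == (13, 13)
        assert g.origin == (-1.0, -1.0)

    def test_single_point_minimum_size(self):
        g = make_grid([np.array([[3.0, 4.0]])], dx=1.0, pad_fraction=0.0)
        assert g.W >= 4 and g.H >= 4

    def test_world_grid_roundtrip(self):
        g = make_grid([np.array([[0, 0], [30, 30.0]])], dx=30.0)
        p = np.array([[7.0, 13.0]])
        np.testing.assert_allclose(g.grid_to_world(g.world_to_grid(p)), p,
                                   atol=1e-12)

    def test_empty_coords_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_grid([np.zeros((0, 2))], dx=1.0)


class TestRasterizeExpression:
    def test_point_at_pixel_center(self):
        ds = PointDataset(np.array([[2.0, 2.0]]), np.array([[1.0]]), ["g"])
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=5, W=5)
        t = rasterize_expression(ds, ["g"], g, sigma=1.0)
        assert t.data[0, 2, 2] == pytest.approx(1.0)
        # neighbouring pixel at distance 1
        assert t.data[0, 2, 3] == pytest.approx(np.exp(-0.5))

    def test_matches_brute_force(self, rng):
        coords = rng.uniform(1, 7, size=(3, 2))
        expr = rng.uniform(0, 2, size=(3, 2))
        ds = PointDataset(coords, expr, ["a", "b"])
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=8, W=8)
        sigma = 1.5
        t = rasterize_expression(ds, ["a", "b"], g, sigma, truncate=50.0)
        ref = brute_force_raster(coords, expr, g, sigma)
        np.testing.assert_allclose(t.data[:2], ref, atol=1e-10)

    def test_truncation_error_bound(self, rng):
        coords = rng.uniform(2, 14, size=(10, 2))
        expr = rng.uniform(0, 3, size=(10, 1))
        ds = PointDataset(coords, expr, ["a"])
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=16, W=16)
        trunc = rasterize_expression(ds, ["a"], g, 1.0).data[0]
        full = brute_force_raster(coords, expr, g, 1.0)[0]
        assert np.abs(trunc - full).max() <= np.exp(-8.0) * expr.max() * 10

    def test_total_channel_is_all_gene_sum(self, rng):
        coords = rng.uniform(0, 8, size=(6, 2))
        expr = rng.uniform(0, 1, size=(6, 3))
        ds = PointDataset(coords, expr, ["a", "b", "c"])
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=10, W=10)
        t = rasterize_expression(ds, ["a"], g, 1.0, truncate=50.0)
        ref = brute_force_raster(coords, expr.sum(axis=1, keepdims=True),
                                 g, 1.0)[0]
        np.testing.assert_allclose(t.total_channel, ref, atol=1e-10)

    def test_translation_equivariance(self, rng):
        coords = rng.uniform(4, 8, size=(5, 2))
        expr = rng.uniform(0, 1, size=(5, 1))
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=16, W=16)
        a = rasterize_expression(PointDataset(coords, expr, ["a"]),
                                 ["a"], g, 1.0).data[0]
        b = rasterize_expression(PointDataset(coords + [2.0, 3.0], expr,
                                              ["a"]), ["a"], g, 1.0).data[0]
        np.testing.assert_allclose(b[3 + 4:, 2 + 4:], a[4:-3, 4:-2],
                                   atol=1e-12)

    def test_zero_expression_gives_zero_raster(self):
        ds = PointDataset(np.array([[1.0, 1]]), np.array([[0.0]]), ["g"])
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=4, W=4)
        t = rasterize_expression(ds, ["g"], g, 1.0)
        assert not t.data.any()

    def test_unknown_gene_rejected(self, tiny_dataset):
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=12, W=12)
        with pytest.raises(KeyError):
            rasterize_expression(tiny_dataset, ["nope"], g, 1.0)


class TestHistology:
    def test_constant_image_zero_gradient(self):
        img = HistologyImage(np.full((20, 20), 0.5), scale=0.5,
                             offset=np.zeros(2))
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=8, W=8)
        t = rasterize_histology(img, g, sigma_h=0.5)
        np.testing.assert_allclose(t.data, 0.0, atol=1e-12)

    def test_ramp_sobel_response(self):
        # slope s per pixel → interior magnitude s with /4 normalization
        s = 0.013
        img = np.outer(np.ones(12), np.arange(12)) * s
        mag = sobel_magnitude(img)
        np.testing.assert_allclose(mag[2:-2, 2:-2], s, atol=1e-12)
        # cross-check against direct convolution
        from scipy.ndimage import convolve
        kx = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]]) / 8.0
        ref = np.abs(convolve(img, kx, mode="nearest"))
        np.testing.assert_allclose(mag[1:-1, 1:-1], ref[1:-1, 1:-1],
                                   atol=1e-12)

    def test_step_edge_symmetric_response(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        h = HistologyImage(img, scale=1.0, offset=np.zeros(2))
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=16, W=16)
        t = rasterize_histology(h, g, sigma_h=0.0)
        row = t.data[0, 8]
        assert row.argmax() in (7, 8)
        np.testing.assert_allclose(row[6], row[9], atol=1e-12)

    def test_no_overlap_rejected(self):
        img = HistologyImage(np.ones((4, 4)), scale=1.0,
                             offset=np.array([100.0, 100.0]))
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=8, W=8)
        with pytest.raises(ValueError, match="overlap"):
            rasterize_histology(img, g, sigma_h=1.0)


class TestConcatAndNormalize:
    def _st(self, c=2):
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=4, W=4)
        data = np.arange(c * 16, dtype=float).reshape(c, 4, 4)
        roles = [("gene", f"g{k}") for k in range(c - 1)] + [("total",)]
        return RasterTensor(data, g, roles)

    def test_channel_roles_preserved(self):
        st = self._st(4)
        histo = RasterTensor(np.ones((1, 4, 4)), st.grid,
                             [("histology", "gradient_grey")])
        out = concat_modalities(st, histo)
        assert out.c == 5
        assert out.channel_roles[-1][0] == "histology"
        assert out.data.max() == pytest.approx(1.0)

    def test_absent_histology_rescales_only(self):
        out = concat_modalities(self._st())
        assert out.c == 2
        assert out.data.max() == pytest.approx(1.0)

    def test_zero_channel_left_as_zeros(self):
        st = self._st()
        st.data[0] = 0.0
        out = concat_modalities(st)
        assert not out.data[0].any()

    def test_grid_mismatch_rejected(self):
        st = self._st()
        other = RasterGrid(origin=(1.0, 0.0), dx=1.0, H=4, W=4)
        histo = RasterTensor(np.ones((1, 4, 4)), other, [("histology", 0)])
        with pytest.raises(ValueError, match="grid"):
            concat_modalities(st, histo)

    def test_pair_normalization_uses_joint_max(self):
        a, b = self._st(), self._st()
        b.data = b.data * 0.5  # dimmer copy must stay dimmer
        na, nb = normalize_pair(a, b)
        assert na.data.max() == pytest.approx(1.0)
        assert nb.data.max() == pytest.approx(0.5)


class TestBilinearSample:
    def test_exact_at_pixel_centers(self, rng):
        g = RasterGrid(origin=(0.0, 0.0), dx=2.0, H=5, W=6)
        data = rng.random((3, 5, 6))
        X, Y = g.world_coords()
        pts = np.stack([X, Y], axis=-1)
        vals, valid = bilinear_sample(data, g, pts)
        np.testing.assert_allclose(vals, data, atol=1e-12)
        assert valid.all()

    def test_out_of_bounds_zero_and_flagged(self):
        g = RasterGrid(origin=(0.0, 0.0), dx=1.0, H=4, W=4)
        vals, valid = bilinear_sample(np.ones((1, 4, 4)), g,
                                      np.array([[10.0, 10.0]]))
        assert vals[0, 0] == 0.0
        assert not valid[0]
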