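import numpy as np
import pytest
from scipy import ndimage as ndi

import myoseg as m
from myoseg.config import ErosionConfig, RidgeConfig, ValidationError
from myoseg.ridge import elliptical_kernel

from test_features import dense_separable, gaussian_kernel_1d


def ridge_oracle(image, cfg):
    """Brute-force ridge likelihood: dense Hessian convolution and explicit
    2x2 eigen-decomposition per pixel."""
    norm = np.asarray(image) / 255.0
    s = cfg.sigma_star
    h_rr = dense_separable(norm, gaussian_kernel_1d(s, 2), gaussian_kernel_1d(s, 0))
    h_cc = dense_separable(norm, gaussian_kernel_1d(s, 0), gaussian_kernel_1d(s, 2))
    h_rc = dense_separable(norm, gaussian_kernel_1d(s, 1), gaussian_kernel_1d(s, 1))
    out = np.zeros(norm.shape)
    for r in range(norm.shape[0]):
        for c in range(norm.shape[1]):
            H = np.array([[h_rr[r, c], h_rc[r, c]], [h_rc[r, c], h_cc[r, c]]])
            ev = np.linalg.eigvalsh(H)
            l1, l2 = (ev[1], ev[0]) if abs(ev[1]) >= abs(ev[0]) else (ev[0], ev[1])
            s2 = l1**2 + l2**2
            if l1 > 0 or s2 == 0:
                continue
            rb = abs(l2 / l1)
            out[r, c] = np.exp(-rb / cfg.alpha_r**2) * (1 - np.exp(-(s2**2) / cfg.beta_r**2))
    return out


class TestRidgeLikelihood:
    def test_constant_image_zero(self):
        assert np.all(m.ridge_likelihood(np.full((10, 10), 99, np.uint8)) == 0)

    def test_dark_line_zero_on_centre(self):
        img = np.full((20, 20), 200, np.uint8)
        img[9:11, :] = 0  # dark ridge: lambda1 > 0 on the line
        r = m.ridge_likelihood(img)
        assert np.all(r[9:11, 5:15] == 0)

    def test_bright_line_matches_brute_force_oracle(self):
        img = np.zeros((24, 24), np.uint8)
        img[11:13, :] = 255
        cfg = RidgeConfig()
        r = m.ridge_likelihood(img, cfg)
        oracle = ridge_oracle(img, cfg)
        assert np.abs(r - oracle).max() < 1e-6
        # the most ridge-like pixels sit on the line
        rows = np.argwhere(r == r.max())[:, 0]
        assert set(rows) <= {11, 12}

    def test_range_invariant(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        r = m.ridge_likelihood(img)
        assert (r >= 0).all() and (r < 1).all()

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValidationError):
            RidgeConfig(sigma_star=0)


class TestOtsu:
    def brute_force_threshold(self, scaled):
        # exhaustive between-class-variance maximisation over 256 cut points
        hist, edges = np.histogram(scaled, bins=256, range=(0, 255))
        best_t, best_v = None, -1.0
        centers = 0.5 * (edges[:-1] + edges[1:])
        for k in range(1, 256):
            w0, w1 = hist[:k].sum(), hist[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:k] * centers[:k]).sum() / w0
            m1 = (hist[k:] * centers[k:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best_v:
                best_v, best_t = v, centers[k - 1]
        return best_t

    def test_bimodal_map(self):
        r = np.zeros((100, 10))
        r.ravel()[:100] = 0.9
        mask = m.otsu_binarize(r)
        assert mask.sum() == 100
        assert np.array_equal(mask, r == 0.9)

    def test_all_zero_is_all_false(self, caplog):
        with caplog.at_level("WARNING"):
            assert not m.otsu_binarize(np.zeros((5, 5))).any()
        assert "constant" in caplog.text

    def test_threshold_matches_brute_force(self):
        rng = np.random.default_rng(3)
        r = np.concatenate([rng.normal(0.1, 0.02, 300), rng.normal(0.7, 0.05, 100)])
        r = np.clip(r, 0, 0.99).reshape(20, 20)
        mask = m.otsu_binarize(r)
        scaled = (r - r.min()) * 255.0 / (r.max() - r.min())
        t = self.brute_force_threshold(scaled)
        assert np.array_equal(mask, scaled > t)


class TestClusterExtraction:
    def test_ring_with_hole_sealed(self):
        n = 41
        rr, cc = np.mgrid[0:n, 0:n]
        rad = np.sqrt((rr - 20) ** 2 + (cc - 20) ** 2)
        ring = (rad >= 13) & (rad < 15)
        ring[18:23, 33:38] = False  # ~5 px hole in the wall
        lab = m.extract_clusters_closing(ring)
        assert lab.max() == 1
        oracle = ndi.binary_closing(ring, np.ones((11, 11), bool))
        assert oracle[20, 34]  # the closing oracle seals the hole

    def test_all_false_border_zero_clusters(self):
        assert m.extract_clusters_closing(np.zeros((30, 30), bool)).max() == 0

    def test_grid_clusters_smaller_than_undilated(self):
        # cells must be wider than the 11x11 closing kernel to survive it
        n = 125
        border = np.zeros((n, n), bool)
        for line in (2, 42, 82, 122):
            border[line, 2:123] = True
            border[2:123, line] = True
        lab = m.extract_clusters_closing(border)
        plain = m.initial_clusters(border)
        assert lab.max() == 9
        for i in range(1, 10):
            assert (lab == i).sum() < (plain == i).sum()


class TestIterativeErosion:
    def test_small_disc_unchanged(self):
        n = 100
        rr, cc = np.mgrid[0:n, 0:n]
        disc = (((rr - 50) ** 2 + (cc - 50) ** 2) <= 35**2).astype(np.int32)
        assert disc.sum() < 5000
        out = m.iterative_erosion(disc)
        assert np.array_equal(out > 0, disc > 0)

    def test_large_disc_eroded_below_threshold(self):
        n = 180
        rr, cc = np.mgrid[0:n, 0:n]
        disc = (((rr - 90) ** 2 + (cc - 90) ** 2) <= 80**2).astype(np.int32)
        assert disc.sum() > 20000
        out = m.iterative_erosion(disc)
        ids, counts = np.unique(out[out > 0], return_counts=True)
        assert len(ids) == 1
        assert 500 <= counts[0] < 5000
        # erosion oracle: area decreases monotonically per iteration
        se = elliptical_kernel(8)
        piece, areas = disc > 0, []
        while piece.sum() >= 5000:
            piece = ndi.binary_erosion(piece, se)
            areas.append(int(piece.sum()))
        assert all(b < a for a, b in zip(areas, areas[1:]))
        assert counts[0] == areas[-1]

    def test_dumbbell_splits_into_two(self):
        h, w = 120, 230
        rr, cc = np.mgrid[0:h, 0:w]
        d1 = ((rr - 60) ** 2 + (cc - 60) ** 2) <= 44**2
        d2 = ((rr - 60) ** 2 + (cc - 170) ** 2) <= 44**2
        neck = (np.abs(rr - 60) <= 6) & (cc >= 60) & (cc <= 170)
        db = (d1 | d2 | neck).astype(np.int32)
        assert 11000 < db.sum() < 13500
        out = m.iterative_erosion(db)
        ids, counts = np.unique(out[out > 0], return_counts=True)
        assert len(ids) == 2
        assert all(500 <= c < 5000 for c in counts)

    def test_never_grows_never_merges(self):
        h, w = 120, 230
        rr, cc = np.mgrid[0:h, 0:w]
        lab = np.zeros((h, w), np.int32)
        lab[((rr - 60) ** 2 + (cc - 60) ** 2) <= 44**2] = 1
        lab[((rr - 60) ** 2 + (cc - 170) ** 2) <= 44**2] = 2
        out = m.iterative_erosion(lab)
        for piece in range(1, out.max() + 1):
            parents = np.unique(lab[out == piece])
            assert len(parents) == 1 and parents[0] > 0
        assert (out > 0).sum() <= (lab > 0).sum()

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError):
            ErosionConfig(size_threshold=400, min_cluster_size=500)


class TestReferencePipeline:
    def test_blank_image_zero_fibres(self):
        assert m.run_reference_pipeline(np.zeros((64, 64), np.uint8)) == []

    def test_clean_sample_end_to_end(self, clean_sample):
        fibres = m.run_reference_pipeline(clean_sample.image)
        # every interior groundtruth cell recovered, one fibre each
        interior = set(np.unique(clean_sample.groundtruth)) - {0} \
            - set(clean_sample.boundary_cell_ids)
        det = m.fibres_to_labels(fibres, clean_sample.image.shape)
        match = m.match_detections(det, clean_sample.groundtruth)
        assert interior <= match.matched_groundtruth()

    def test_faint_wall_separates_fewer_than_hybrid(
        self, moderate_sample, trained_classifier
    ):
        # on a sample with border holes, the vision-only pipeline separates
        # no more cells than the hybrid pipeline
        from myoseg.pipeline import HybridSegmenter

        hyb = HybridSegmenter().set_classifier(trained_classifier)
        det_h = m.fibres_to_labels(
            hyb.segment(moderate_sample.image)[0], moderate_sample.image.shape
        )
        det_r = m.fibres_to_labels(
            m.run_reference_pipeline(moderate_sample.image),
            moderate_sample.image.shape,
        )
        gt = moderate_sample.groundtruth
        n_h = len(m.match_detections(det_h, gt).pairs)
        n_r = len(m.match_detections(det_r, gt).pairs)
        assert n_r <= n_h
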