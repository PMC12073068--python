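import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from retinagaze import (
    AOIAnnotation,
    RetinalGeometry,
    clusters_to_aoi_report,
    expand_annotation,
    fit_gaze_hmm,
    label_fixation,
    macula_mask,
)
from retinagaze.aoi import GazeHMM, core_masks


def single_pixel_annotation(px, py, radius=70.0, size=(300, 300)):
    mask = np.zeros((size[1], size[0]), dtype=bool)
    mask[py, px] = True
    return AOIAnnotation(
        image_id="t",
        image_width=size[0],
        image_height=size[1],
        masks={"D": mask},
        expansion_radius_px=radius,
    )


class TestMaculaMask:
    def test_scale_and_radius_from_disc_fovea_distance(self):
        geom = RetinalGeometry(disc_center=(876.0, 300.0), foveola=(400.0, 300.0))
        assert geom.px_per_mm == pytest.approx(100.0)  # 476 px / 4.76 mm
        mask = macula_mask(geom, 900, 700)
        # radius = 2.75 mm * 100 px/mm = 275 px; area check within the
        # rasterization perimeter allowance
        assert mask.sum() == pytest.approx(np.pi * 275**2, rel=0.01)
        # clipping: shrinking the image must only remove out-of-bounds pixels
        clipped = macula_mask(geom, 900, 400)
        assert clipped.sum() < mask.sum()
        assert np.array_equal(clipped, mask[:400, :])

    def test_zero_disc_fovea_distance_rejected(self):
        geom = RetinalGeometry(disc_center=(100.0, 100.0), foveola=(100.0, 100.0))
        with pytest.raises(ValueError, match="scale"):
            geom.px_per_mm


class TestExpansion:
    def test_zero_radius_is_identity(self, layout):
        annotation, _ = layout
        ann0 = AOIAnnotation(
            image_id=annotation.image_id,
            image_width=annotation.image_width,
            image_height=annotation.image_height,
            masks=annotation.masks,
            expansion_radius_px=0.0,
        )
        out = expand_annotation(ann0)
        for sym in annotation.masks:
            assert np.array_equal(out.masks[sym], annotation.masks[sym])

    def test_single_pixel_grows_to_euclidean_disc(self):
        ann = single_pixel_annotation(150, 150, radius=70.0)
        out = expand_annotation(ann)
        # brute-force distance scan is the ground truth
        yy, xx = np.mgrid[0:300, 0:300]
        disc = (xx - 150) ** 2 + (yy - 150) ** 2 <= 70**2
        assert np.array_equal(out.masks["D"], disc)
        assert out.masks["D"].sum() == pytest.approx(np.pi * 70**2, rel=0.01)

    def test_expanded_mask_is_superset(self, layout):
        annotation, _ = layout
        out = expand_annotation(annotation)
        for sym, m in annotation.masks.items():
            assert (out.masks[sym] & m).sum() == m.sum()

    @given(radii=st.tuples(st.integers(0, 25), st.integers(0, 25)))
    @settings(max_examples=10)
    def test_dilation_monotone_in_radius(self, radii):
        r1, r2 = sorted(radii)
        rng = np.random.default_rng(7)
        mask = np.zeros((80, 80), dtype=bool)
        pts = rng.integers(10, 70, size=(5, 2))
        mask[pts[:, 0], pts[:, 1]] = True
        base = AOIAnnotation("t", 80, 80, {"D": mask}, expansion_radius_px=r1)
        small = expand_annotation(base).masks["D"]
        base.expansion_radius_px = r2
        large = expand_annotation(base).masks["D"]
        assert not (small & ~large).any()


class TestLabelFixation:
    def test_unambiguous_overlap_and_background(self, expanded):
        d = expanded.geometry.disc_center
        assert label_fixation(d[0], d[1], expanded) == {"D"}
        # far corner is unannotated periphery
        assert label_fixation(2.0, 2.0, expanded) == {"B"}
        # off image entirely
        assert label_fixation(-50.0, 10.0, expanded) == {"B"}

    def test_overlap_region_returns_both_labels(self, expanded):
        overlap = expanded.masks["D"] & expanded.masks["S"]
        assert overlap.any(), "expanded disc and superior arcade should overlap"
        row, col = np.argwhere(overlap)[0]
        labels = label_fixation(float(col), float(row), expanded)
        assert {"D", "S"} <= labels

    def test_agrees_with_brute_force_distance_check(self, layout, rng):
        """Mask membership after expansion == within-radius of a raw pixel."""
        annotation, _ = layout
        expanded = expand_annotation(annotation)
        raw_pts = {
            sym: np.argwhere(annotation.masks[sym]) for sym in annotation.masks
        }
        for _ in range(25):
            x = float(rng.uniform(0, annotation.image_width - 1))
            y = float(rng.uniform(0, annotation.image_height - 1))
            got = label_fixation(x, y, expanded)
            px, py = round(x), round(y)
            expect = set()
            for sym, pts in raw_pts.items():
                d2 = (pts[:, 0] - py) ** 2 + (pts[:, 1] - px) ** 2
                if (d2 <= annotation.expansion_radius_px**2).any():
                    expect.add(sym)
            assert got == (frozenset(expect) if expect else frozenset({"B"}))

    def test_core_pixels_are_unambiguous(self, layout):
        annotation, _ = layout
        expanded = expand_annotation(annotation)
        cores = core_masks(annotation)
        for sym, core in cores.items():
            assert core.any()
            row, col = np.argwhere(core)[0]
            assert label_fixation(float(col), float(row), expanded) == {sym}


def planted_clusters(rng, k=4, n_per=75, sep=300.0, sd=25.0):
    centers = np.array([[200, 200], [200 + sep, 200], [200, 200 + sep], [200 + sep, 200 + sep]])[:k]
    pts, labels = [], []
    state = 0
    for _ in range(k * n_per):
        # sticky state sequence so the transition structure is informative
        if rng.random() < 0.1:
            state = int(rng.integers(k))
        pts.append(centers[state] + rng.normal(0, sd, 2))
        labels.append(state)
    return np.array(pts), np.array(labels)


class TestGazeHMM:
    def test_recovers_planted_four_cluster_structure(self, rng):
        pts, truth = planted_clusters(rng)
        model, assign = fit_gaze_hmm(pts, range(2, 7), seed=5)
        assert model.n_states == 4
        assert adjusted_rand_score(truth, assign) >= 0.9

    def test_single_cluster_selects_one_state(self, rng):
        pts = rng.normal([300, 300], 20, size=(60, 2))
        model, _ = fit_gaze_hmm(pts, [1, 2, 3], seed=2)
        assert model.n_states == 1

    def test_stochasticity_constraints(self, rng):
        pts, _ = planted_clusters(rng, k=2, n_per=60)
        model, _ = fit_gaze_hmm(pts, [2], seed=0)
        assert np.allclose(model.transition_matrix.sum(axis=1), 1.0, atol=1e-9)
        assert model.initial_distribution.sum() == pytest.approx(1.0, abs=1e-9)
        # positive-definite covariances
        for cov in model.covariances:
            assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_em_loglik_history_is_nondecreasing(self, rng):
        pts, _ = planted_clusters(rng, k=3, n_per=60)
        model, _ = fit_gaze_hmm(pts, [3], seed=1)
        hist = model.loglik_history
        assert len(hist) >= 2
        assert all(b - a > -1e-6 for a, b in zip(hist, hist[1:]))

    def test_degenerate_identical_points_warns(self):
        pts = np.tile([100.0, 100.0], (50, 1))
        with pytest.warns(UserWarning, match="identical"):
            model, assign = fit_gaze_hmm(pts, [1, 2], seed=0)
        assert model.n_states == 1 and model.degenerate
        assert (assign == 0).all()

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="10 x max"):
            fit_gaze_hmm(rng.normal(size=(30, 2)), [4], seed=0)


class TestClusterReport:
    @staticmethod
    def model_with_means(means):
        k = len(means)
        return GazeHMM(
            n_states=k,
            means=np.asarray(means, dtype=float),
            covariances=np.tile(np.eye(2), (k, 1, 1)),
            transition_matrix=np.full((k, k), 1.0 / k),
            initial_distribution=np.full(k, 1.0 / k),
            log_likelihood=0.0,
            bic=0.0,
        )

    def centre_of(self, expanded, sym):
        pts = np.argwhere(expanded.masks[sym] & ~sum(
            (expanded.masks[o] for o in expanded.masks if o != sym),
            np.zeros_like(expanded.masks[sym]),
        ).astype(bool))
        row, col = pts[len(pts) // 2]
        return [float(col), float(row)]

    def test_all_four_landmarks_covered(self, expanded):
        means = [self.centre_of(expanded, s) for s in ("D", "M", "S", "I")]
        report = clusters_to_aoi_report(self.model_with_means(means), expanded)
        assert report["all_four_covered"]
        assert sorted(report["state_labels"]) == ["D", "I", "M", "S"]

    def test_missing_landmark_detected(self, expanded):
        means = [self.centre_of(expanded, s) for s in ("D", "M", "I")]
        report = clusters_to_aoi_report(self.model_with_means(means), expanded)
        assert not report["all_four_covered"]
        assert not report["covered"]["S"]

    def test_off_image_mean_is_background(self, expanded):
        report = clusters_to_aoi_report(
            self.model_with_means([[-100.0, -100.0]]), expanded
        )
        assert report["state_labels"] == ["B"]
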