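"""Graphetic metrics: alignment, Jaccard, exact OT, GW, invariance, RDMs."""

import itertools

import numpy as np
import pytest
from scipy import stats

from graphot.glyphs import IntensityImage, MassDistribution, render_glyph, to_mass_distribution
from graphot.graphetic import (
    RDM,
    TransformBounds,
    align_by_crosscorr,
    build_model_rdm,
    gromov_wasserstein_distance,
    invariant_distance,
    jaccard_distance,
    rank_transform_rdm,
    rdm_from_csv,
    rdm_from_hdf5,
    rdm_to_csv,
    rdm_to_hdf5,
    wasserstein_distance,
)
from graphot.graphetic import _transform_image  # noqa: PLC2701 - oracle support


from oracles import gw_permutation_oracle, ot_bruteforce

def _point_images(points, shape):
    """Images with unit intensity at the given (row, col) points."""
    out = np.zeros(shape)
    for r, c in points:
        out[r, c] = 1.0
    return IntensityImage(out)


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

class TestAlignment:
    def test_self_alignment_offset_zero(self):
        img = render_glyph("k", max_height_px=24)
        off, a_pad, b_pad = align_by_crosscorr(img, img)
        assert off == (0, 0)
        assert np.array_equal(a_pad.pixels, b_pad.pixels)

    def test_single_pixel_offsets(self):
        a = _point_images([(2, 3)], (6, 6))
        b = _point_images([(4, 1)], (6, 6))
        off, a_pad, b_pad = align_by_crosscorr(a, b)
        assert off == (2 - 4, 3 - 1)
        # after padding the two single pixels coincide
        assert np.array_equal(a_pad.pixels > 0, b_pad.pixels > 0)

    def test_peak_matches_exhaustive_shift_enumeration(self, rng):
        """The returned offset attains the maximum cross-correlation over
        every possible integer shift (brute-force oracle)."""
        for _ in range(5):
            pa = rng.random((8, 8))
            pb = rng.random((8, 8))
            off, _, _ = align_by_crosscorr(IntensityImage(pa), IntensityImage(pb))
            best = -np.inf
            best_off = None
            for dr in range(-7, 8):
                for dc in range(-7, 8):
                    v = 0.0
                    for r in range(8):
                        for c in range(8):
                            rr, cc = r - dr, c - dc
                            if 0 <= rr < 8 and 0 <= cc < 8:
                                v += pa[r, c] * pb[rr, cc]
                    if v > best:
                        best, best_off = v, (dr, dc)
            assert off == best_off

    def test_empty_image_rejected(self):
        blank = IntensityImage(np.zeros((3, 3)))
        inked = _point_images([(1, 1)], (3, 3))
        with pytest.raises(ValueError, match="empty"):
            align_by_crosscorr(blank, inked)


# --------------------------------------------------------------------------
# Jaccard
# --------------------------------------------------------------------------

class TestJaccard:
    def test_identity_is_zero(self):
        img = render_glyph("s", max_height_px=24)
        assert jaccard_distance(img, img) == 0.0

    def test_disjoint_supports_are_one(self):
        a = _point_images([(0, 0)], (2, 2))
        b = _point_images([(1, 1)], (2, 2))
        assert jaccard_distance(a, b) == 1.0

    def test_hand_computed_example(self):
        a = IntensityImage(np.array([[1.0, 0.0], [1.0, 0.0]]))
        b = IntensityImage(np.array([[1.0, 1.0], [0.0, 0.0]]))
        assert jaccard_distance(a, b) == pytest.approx(2 / 3)

    def test_fuzzy_intensities(self):
        a = IntensityImage(np.array([[0.5, 0.2]]))
        b = IntensityImage(np.array([[0.3, 0.4]]))
        expected = 1 - (0.3 + 0.2) / (0.5 + 0.4)
        assert jaccard_distance(a, b) == pytest.approx(expected)

    def test_range_and_symmetry(self, rng):
        for _ in range(10):
            a = IntensityImage(rng.random((5, 5)))
            b = IntensityImage(rng.random((5, 5)))
            d = jaccard_distance(a, b)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(jaccard_distance(b, a))

    def test_mismatched_canvases_rejected(self):
        with pytest.raises(ValueError, match="common canvas"):
            jaccard_distance(
                IntensityImage(np.ones((2, 2))), IntensityImage(np.ones((3, 3)))
            )


# --------------------------------------------------------------------------
# Wasserstein
# --------------------------------------------------------------------------

class TestWasserstein:
    def test_identity_is_zero(self):
        p = to_mass_distribution(render_glyph("x", max_height_px=16))
        d, plan = wasserstein_distance(p, p)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_two_point_masses(self):
        p = MassDistribution(np.array([[0, 0]]), np.array([1.0]))
        q = MassDistribution(np.array([[3, 4]]), np.array([1.0]))
        d, _ = wasserstein_distance(p, q)
        assert d == pytest.approx(5.0)

    def test_two_by_two_vertex_enumeration(self):
        """2x2 instance equals the minimum over the transport polytope's
        two vertices, enumerated directly."""
        p = MassDistribution(np.array([[0, 0], [0, 4]]), np.array([0.3, 0.7]))
        q = MassDistribution(np.array([[2, 0], [2, 4]]), np.array([0.6, 0.4]))
        cost = np.linalg.norm(
            p.coords[:, None].astype(float) - q.coords[None, :].astype(float), axis=-1
        )
        # feasible couplings are parameterised by t = T[0,0]
        lo = max(0.0, 0.3 + 0.6 - 1.0)
        hi = min(0.3, 0.6)
        vertex_costs = []
        for t in (lo, hi):
            plan = np.array([[t, 0.3 - t], [0.6 - t, 0.4 - (0.3 - t)]])
            vertex_costs.append(float(np.sum(plan * cost)))
        d, _ = wasserstein_distance(p, q)
        assert d == pytest.approx(min(vertex_costs), abs=1e-10)

    @pytest.mark.parametrize("shape", [(2, 3), (3, 3), (4, 4), (3, 5)])
    def test_matches_bruteforce_lp_oracle(self, shape, rng):
        n, m = shape
        xs = rng.integers(0, 12, (n, 2))
        xt = rng.integers(0, 12, (m, 2))
        while len(np.unique(xs, axis=0)) < n:
            xs = rng.integers(0, 12, (n, 2))
        while len(np.unique(xt, axis=0)) < m:
            xt = rng.integers(0, 12, (m, 2))
        a = rng.random(n)
        a /= a.sum()
        b = rng.random(m)
        b /= b.sum()
        p = MassDistribution(xs, a)
        q = MassDistribution(xt, b)
        cost = np.linalg.norm(
            xs[:, None].astype(float) - xt[None, :].astype(float), axis=-1
        )
        d, plan = wasserstein_distance(p, q)
        assert d == pytest.approx(ot_bruteforce(cost, a, b), abs=1e-8)

    def test_plan_marginals(self, rng):
        p = MassDistribution(rng.integers(0, 9, (5, 2)), np.full(5, 0.2))
        xt = np.array([[0, 0], [8, 8], [0, 8]])
        q = MassDistribution(xt, np.array([0.5, 0.25, 0.25]))
        _, plan = wasserstein_distance(p, q)
        row = np.zeros(5)
        col = np.zeros(3)
        for i, j, f in plan.couplings:
            row[int(i)] += f
            col[int(j)] += f
        assert np.allclose(row, p.masses, atol=1e-8)
        assert np.allclose(col, q.masses, atol=1e-8)

    def test_translation_equals_shift_magnitude(self):
        """Offsetting a distribution by t pixels costs exactly |t| without
        alignment, and 0 after cross-correlation alignment."""
        img = render_glyph("n", max_height_px=16)
        p = to_mass_distribution(img)
        shifted = MassDistribution(p.coords + np.array([[0, 7]]), p.masses)
        d, _ = wasserstein_distance(p, shifted)
        assert d == pytest.approx(7.0, abs=1e-9)
        canvas = np.zeros((img.shape[0], img.shape[1] + 7))
        canvas[:, 7:] = img.pixels
        _, a_pad, b_pad = align_by_crosscorr(img, IntensityImage(canvas))
        d2, _ = wasserstein_distance(
            to_mass_distribution(a_pad), to_mass_distribution(b_pad)
        )
        assert d2 == pytest.approx(0.0, abs=1e-12)

    def test_support_guard(self):
        big = MassDistribution(
            np.stack(np.unravel_index(np.arange(10_001), (101, 101)), axis=1),
            np.full(10_001, 1 / 10_001),
        )
        with pytest.raises(ValueError, match="downscale"):
            wasserstein_distance(big, big)


# --------------------------------------------------------------------------
# Gromov-Wasserstein
# --------------------------------------------------------------------------

class TestGromovWasserstein:
    def test_identity_is_zero(self):
        p = to_mass_distribution(render_glyph("v", max_height_px=14), 0.05)
        assert gromov_wasserstein_distance(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_invariance(self, rng):
        """Rotating (by a quarter turn), reflecting and translating a
        distribution leaves the distance at zero."""
        pts = np.unique(rng.integers(0, 15, (9, 2)), axis=0)
        n = len(pts)
        masses = rng.random(n)
        masses /= masses.sum()
        p = MassDistribution(pts, masses)
        rotated = np.stack([-pts[:, 1] + 40, pts[:, 0] + 11], axis=1)
        reflected = np.stack([pts[:, 0] + 3, -pts[:, 1] + 25], axis=1)
        for other in (rotated, reflected):
            d = gromov_wasserstein_distance(p, MassDistribution(other, masses), seed=0)
            assert d <= 1e-6

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_permutation_oracle(self, n, rng):
        for _ in range(3):
            xs = rng.integers(0, 25, (n, 2))
            xt = rng.integers(0, 25, (n, 2))
            while len(np.unique(xs, axis=0)) < n:
                xs = rng.integers(0, 25, (n, 2))
            while len(np.unique(xt, axis=0)) < n:
                xt = rng.integers(0, 25, (n, 2))
            m = np.full(n, 1 / n)
            got = gromov_wasserstein_distance(
                MassDistribution(xs, m), MassDistribution(xt, m), seed=0
            )
            exp = gw_permutation_oracle(xs.astype(float), xt.astype(float))
            assert got == pytest.approx(exp, abs=1e-8)

    def test_subsampling_cap(self, rng):
        pts = np.unique(rng.integers(0, 40, (60, 2)), axis=0)
        masses = rng.random(len(pts))
        masses /= masses.sum()
        p = MassDistribution(pts, masses)
        d = gromov_wasserstein_distance(p, p, max_support=20, seed=1)
        assert np.isfinite(d)

    def test_max_support_validation(self):
        p = MassDistribution(np.array([[0, 0], [1, 1]]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="max_support"):
            gromov_wasserstein_distance(p, p, max_support=1)


# --------------------------------------------------------------------------
# geometric invariance
# --------------------------------------------------------------------------

class TestInvariantDistance:
    def test_translated_copy_recovered(self):
        img = render_glyph("t", max_height_px=20)
        canvas = np.zeros((34, 30))
        canvas[3 : 3 + img.shape[0], 2 : 2 + img.shape[1]] = img.pixels
        shifted = np.zeros((34, 30))
        shifted[9 : 9 + img.shape[0], 7 : 7 + img.shape[1]] = img.pixels
        d, _ = invariant_distance(
            IntensityImage(canvas),
            IntensityImage(shifted),
            metric="jaccard",
            transforms={"translation"},
            work_height_px=40,
        )
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_never_worse_than_aligned_metric(self):
        a = render_glyph("m", max_height_px=20)
        b = render_glyph("w", max_height_px=20)
        _, a_pad, b_pad = align_by_crosscorr(a, b)
        aligned = jaccard_distance(a_pad, b_pad)
        bounds = TransformBounds(starts_per_dim=3)
        d, _ = invariant_distance(
            a, b, metric="jaccard", transforms={"scale", "rotation"},
            bounds=bounds, work_height_px=20,
        )
        assert d <= aligned + 1e-9

    def test_grid_oracle_upper_bounds_optimum(self):
        """A 10x10 (scale x rotation) grid search cannot beat the
        multi-start optimiser by more than numerical tolerance."""
        a = render_glyph("c", max_height_px=18)
        b = render_glyph("e", max_height_px=18)
        bounds = TransformBounds(starts_per_dim=3)
        d_opt, _ = invariant_distance(
            a, b, metric="jaccard", transforms={"scale", "rotation"},
            bounds=bounds, work_height_px=18,
        )
        _, a_pad, b_pad = align_by_crosscorr(a, b)
        grid_best = np.inf
        for ls in np.linspace(np.log(0.5), np.log(2), 10):
            for rot in np.linspace(-180, 180, 10):
                tb = _transform_image(b_pad.pixels, rot, ls, (0.0, 0.0))
                if not tb.any():
                    continue
                _, ga, gb = align_by_crosscorr(a_pad, IntensityImage(tb))
                grid_best = min(grid_best, jaccard_distance(ga, gb))
        assert grid_best >= d_opt - 1e-6

    def test_nested_transform_dominance(self):
        """Enlarging the transform set (with the smaller set's optimum as a
        warm start) can only lower the minimum."""
        a = render_glyph("a", max_height_px=18)
        b = render_glyph("o", max_height_px=18)
        bounds = TransformBounds(starts_per_dim=3)
        d_s, params_s = invariant_distance(
            a, b, metric="jaccard", transforms={"scale"},
            bounds=bounds, work_height_px=18,
        )
        d_sr, _ = invariant_distance(
            a, b, metric="jaccard", transforms={"scale", "rotation"},
            bounds=bounds, work_height_px=18,
            extra_starts=[params_s],
        )
        assert d_sr <= d_s + 1e-6

    def test_empty_transforms_delegates_to_plain_metric(self):
        a = render_glyph("f", max_height_px=18)
        b = render_glyph("j", max_height_px=18)
        d, params = invariant_distance(a, b, metric="jaccard", transforms=set())
        _, a_pad, b_pad = align_by_crosscorr(a, b)
        assert d == pytest.approx(jaccard_distance(a_pad, b_pad))
        assert params == {}

    def test_invalid_inputs(self):
        a = render_glyph("a", max_height_px=16)
        with pytest.raises(ValueError, match="unknown transforms"):
            invariant_distance(a, a, transforms={"shear"})
        with pytest.raises(ValueError, match="identity"):
            TransformBounds(log_scale_range=(0.1, 0.5))


# --------------------------------------------------------------------------
# RDM assembly and rank transform
# --------------------------------------------------------------------------

class TestModelRDM:
    def test_symmetry_and_zero_diagonal(self, jaccard_rdm, wasserstein_rdm):
        for rdm in (jaccard_rdm, wasserstein_rdm):
            assert np.allclose(rdm.values, rdm.values.T)
            assert np.allclose(np.diag(rdm.values), 0.0)
            assert rdm.values.min() >= 0.0
        assert jaccard_rdm.values.max() <= 1.0

    def test_pair_count(self, jaccard_rdm):
        n = jaccard_rdm.n
        assert jaccard_rdm.lower_triangle().size == n * (n - 1) // 2

    def test_metrics_positively_related(self, jaccard_rank, wasserstein_rank):
        # both measure letter-shape dissimilarity; their rank profiles
        # agree far better than chance
        rho = np.corrcoef(
            jaccard_rank.lower_triangle(), wasserstein_rank.lower_triangle()
        )[0, 1]
        assert rho > 0.3

    def test_needs_two_letters(self, letter_images):
        with pytest.raises(ValueError, match="at least 2"):
            build_model_rdm({"a": letter_images["a"]})


class TestRankTransform:
    def test_distinct_values_are_a_permutation(self, wasserstein_rdm):
        ranks = rank_transform_rdm(wasserstein_rdm).lower_triangle()
        n_pairs = ranks.size
        assert sorted(ranks) == list(range(1, n_pairs + 1))

    def test_constant_rdm_gets_average_ranks(self):
        labels = tuple("abcd")
        vals = np.full((4, 4), 0.7)
        np.fill_diagonal(vals, 0.0)
        ranks = rank_transform_rdm(RDM(labels, vals)).lower_triangle()
        assert np.allclose(ranks, (6 + 1) / 2)

    def test_matches_sorting_oracle(self, rng):
        """Average-tie ranks agree with an independent sort-then-index
        midrank computation."""
        labels = tuple("abcde")
        tri = rng.integers(0, 4, 10).astype(float)  # forces ties
        vals = np.zeros((5, 5))
        i, j = np.tril_indices(5, k=-1)
        vals[i, j] = tri
        vals[j, i] = tri
        got = rank_transform_rdm(RDM(labels, vals)).lower_triangle()
        order = np.argsort(tri, kind="stable")
        expected = np.empty(10)
        pos = 0
        while pos < 10:
            end = pos
            while end < 10 and tri[order[end]] == tri[order[pos]]:
                end += 1
            midrank = (pos + 1 + end) / 2
            for k in range(pos, end):
                expected[order[k]] = midrank
            pos = end
        assert np.allclose(got, expected)


class TestRDMSerialisation:
    def test_csv_roundtrip(self, jaccard_rdm, tmp_path):
        path = str(tmp_path / "rdm.csv")
        rdm_to_csv(jaccard_rdm, path)
        back = rdm_from_csv(path, metric_id=jaccard_rdm.metric_id)
        assert back.labels == jaccard_rdm.labels
        assert np.allclose(back.values, jaccard_rdm.values)

    def test_hdf5_roundtrip(self, wasserstein_rdm, tmp_path):
        path = str(tmp_path / "rdm.h5")
        rdm_to_hdf5(wasserstein_rdm, path)
        back = rdm_from_hdf5(path)
        assert back.labels == wasserstein_rdm.labels
        assert np.allclose(back.values, wasserstein_rdm.values)
        assert back.metric_id == wasserstein_rdm.metric_id
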