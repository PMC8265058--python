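"""Box counting, log-log regression and stack aggregation."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.draw import line

from lvfractal.fractal import (
    AggregationError,
    BoxCountCurve,
    DegenerateFitError,
    EmptyEdgeMapError,
    analyze_stack,
    box_count,
    default_size_schedule,
    fit_fd,
    partition_thirds,
)


def brute_force_box_count(edge_map, size, offset):
    """Independent oracle: explicit double loop over grid cells."""
    count = 0
    h, w = edge_map.shape
    off_r, off_c = offset
    # cell index of pixel (r, c) is floor((r + off_r)/size); enumerate cells
    max_ir = int(np.floor((h - 1 + off_r) / size))
    max_ic = int(np.floor((w - 1 + off_c) / size))
    for ir in range(int(np.floor(off_r / size)) - 1, max_ir + 1):
        for ic in range(int(np.floor(off_c / size)) - 1, max_ic + 1):
            r0 = ir * size - off_r
            c0 = ic * size - off_c
            r_start = max(0, int(np.ceil(r0)))
            r_stop = max(r_start, min(h, int(np.ceil(r0 + size))))
            c_start = max(0, int(np.ceil(c0)))
            c_stop = max(c_start, min(w, int(np.ceil(c0 + size))))
            if edge_map[r_start:r_stop, c_start:c_stop].any():
                count += 1
    return count


class TestBoxCount:
    def test_single_pixel_always_one_box(self):
        img = np.zeros((32, 32), dtype=bool)
        img[10, 20] = True
        for size in (1, 2, 3.5, 7, 16):
            assert box_count(img, size) == 1

    def test_unit_boxes_count_pixels(self):
        rng = np.random.default_rng(4)
        img = rng.random((40, 40)) < 0.2
        img[0, 0] = True
        assert box_count(img, 1, grid_offsets=[(0.0, 0.0)]) == int(img.sum())

    def test_full_grid_at_aligned_size(self):
        img = np.ones((64, 64), dtype=bool)
        assert box_count(img, 8, grid_offsets=[(0.0, 0.0)]) == 64

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("size", [2, 3, 4.76, 7, 11.3, 16])
    def test_matches_brute_force_enumeration(self, seed, size):
        """Vectorized counting equals the exhaustive cell-by-cell oracle."""
        rng = np.random.default_rng(seed)
        img = rng.random((64, 64)) < 0.07
        img[5, 5] = True
        for frac in [(0.0, 0.0), (0.5, 0.0), (0.0, 0.5), (0.5, 0.5)]:
            off = (frac[0] * size, frac[1] * size)
            ours = box_count(img, size, grid_offsets=[off])
            assert ours == brute_force_box_count(img, size, off)

    def test_empty_map_rejected(self):
        with pytest.raises(EmptyEdgeMapError):
            box_count(np.zeros((16, 16), dtype=bool), 2)


class TestFitFD:
    def test_straight_line_dimension_one(self):
        img = np.zeros((1024, 1024), dtype=bool)
        rr, cc = line(8, 8, 1015, 1015)
        img[rr, cc] = True
        curve = fit_fd(img)
        assert 0.95 <= curve.fd <= 1.05
        assert curve.r_squared > 0.98

    def test_counts_monotone_and_curve_valid(self):
        rng = np.random.default_rng(7)
        img = rng.random((128, 128)) < 0.1
        curve = fit_fd(img)
        assert np.all(np.diff(curve.counts) >= 0)
        assert np.all(np.diff(curve.box_sizes_px) < 0)
        assert 0.0 <= curve.r_squared <= 1.0

    def test_scale_invariance_of_dimension(self):
        """The same curve rasterized at 2x scale has nearly the same FD."""
        from lvfractal.phantom import KnownFractalSpec, rasterize_known_fractal

        small = rasterize_known_fractal(KnownFractalSpec("koch_curve", 4, 512))
        big = rasterize_known_fractal(KnownFractalSpec("koch_curve", 4, 1024))
        assert abs(fit_fd(small).fd - fit_fd(big).fd) < 0.05

    def test_translation_robustness(self):
        rng = np.random.default_rng(3)
        img = np.zeros((160, 160), dtype=bool)
        img[40:120, 40:120] = rng.random((80, 80)) < 0.15
        base = fit_fd(img).fd
        for shift in ((1, 0), (0, 2), (3, 3)):
            rolled = np.roll(img, shift, axis=(0, 1))
            assert abs(fit_fd(rolled).fd - base) < 0.02

    def test_schedule_requirements(self):
        img = np.zeros((64, 64), dtype=bool)
        img[10:50, 10:50] = True
        with pytest.raises(DegenerateFitError):
            fit_fd(img, size_schedule=[2, 3, 4, 5])  # too few sizes
        with pytest.raises(DegenerateFitError):
            fit_fd(img, size_schedule=[4, 4, 4, 4, 4])  # zero size variance
        with pytest.raises(EmptyEdgeMapError):
            fit_fd(np.zeros((32, 32), dtype=bool))

    def test_default_schedule_spans_sizes(self):
        img = np.zeros((256, 256), dtype=bool)
        img[16:240, 16:240] = True
        sizes = default_size_schedule(img)
        assert len(sizes) >= 5
        assert sizes[-1] == pytest.approx(2.0)
        assert sizes[0] <= 0.45 * 224

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            BoxCountCurve(
                box_sizes_px=np.array([8.0, 4.0, 2.0]),
                counts=np.array([10, 5, 20]),  # non-monotone
                log_fit_slope=-1.0,
                log_fit_intercept=0.0,
                r_squared=0.9,
            )


class _Seg:
    def __init__(self, edge, converged=True):
        self.edge_map = edge
        self.converged = converged


def _noisy_edge(seed, density=0.1):
    rng = np.random.default_rng(seed)
    img = np.zeros((96, 96), dtype=bool)
    img[16:80, 16:80] = rng.random((64, 64)) < density
    return img


class TestAnalyzeStack:
    def test_most_apical_slice_always_excluded(self):
        segs = [_Seg(_noisy_edge(i)) for i in range(6)]
        res = analyze_stack(segs)
        apical = res.per_slice[-1]
        assert not apical.included and apical.exclusion_reason == "most_apical"
        assert res.n_included == 5

    def test_aggregate_identities(self):
        segs = [_Seg(_noisy_edge(i, 0.05 + 0.03 * i)) for i in range(8)]
        res = analyze_stack(segs)
        fds = [r.fd for r in res.per_slice if r.included]
        assert res.global_fd == pytest.approx(np.mean(fds))
        assert res.max_fd == pytest.approx(np.max(fds))
        assert max(res.third_max_fd.values()) == pytest.approx(res.max_fd)

    def test_failed_slices_excluded_with_reason(self):
        segs = [_Seg(_noisy_edge(i)) for i in range(6)]
        segs[2] = _Seg(np.zeros((96, 96), dtype=bool))
        segs[3] = _Seg(_noisy_edge(3), converged=False)
        res = analyze_stack(segs)
        assert res.per_slice[2].exclusion_reason == "empty_segmentation"
        assert res.per_slice[3].exclusion_reason == "not_converged"
        assert res.n_included == 3

    def test_too_few_slices_or_included(self):
        with pytest.raises(AggregationError):
            analyze_stack([_Seg(_noisy_edge(0))] * 3)
        segs = [_Seg(np.zeros((96, 96), dtype=bool)) for _ in range(5)]
        segs[0] = _Seg(_noisy_edge(0))
        with pytest.raises(AggregationError):
            analyze_stack(segs)

    def test_two_slice_aggregation_without_thirds(self):
        e1, e2 = _noisy_edge(1, 0.04), _noisy_edge(2, 0.25)
        segs = [_Seg(e1), _Seg(e2), _Seg(e1), _Seg(_noisy_edge(9))]
        res = analyze_stack(segs, compute_thirds=False, exclude_most_apical=True)
        fds = [r.fd for r in res.per_slice if r.included]
        assert len(fds) == 3
        assert res.global_fd == pytest.approx(np.mean(fds))
        assert res.third_max_fd == {}

    @pytest.mark.parametrize(
        "n,expected",
        [(3, (1, 1, 1)), (4, (1, 2, 1)), (5, (1, 2, 2)), (9, (3, 3, 3)), (10, (3, 4, 3))],
    )
    def test_thirds_partition_rule(self, n, expected):
        assert partition_thirds(n) == expected
        assert sum(partition_thirds(n)) == n
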