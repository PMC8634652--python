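import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synseek as ss
from synseek.roi import (
    AlignmentTransform,
    Box,
    CandidateROI,
    bind_series,
    continuity_filter,
    detect_overlaps,
    full_frame_target_area,
    make_fov_boxes,
    merge_fov_boxes,
    reject_interior,
    to_global,
    to_local,
)
from synseek.segment import BinaryMask


def mask(pixels):
    return BinaryMask(section=0, channel="", pixels=np.asarray(pixels, bool))


def flood_fill_components(grid):
    """Brute-force 8-connected component labelling by BFS."""
    grid = np.asarray(grid, bool)
    seen = np.zeros_like(grid)
    comps = []
    for y, x in zip(*np.nonzero(grid)):
        if seen[y, x]:
            continue
        queue, comp = [(y, x)], []
        seen[y, x] = True
        while queue:
            cy, cx = queue.pop()
            comp.append((cy, cx))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = cy + dy, cx + dx
                    if (
                        0 <= ny < grid.shape[0]
                        and 0 <= nx < grid.shape[1]
                        and grid[ny, nx]
                        and not seen[ny, nx]
                    ):
                        seen[ny, nx] = True
                        queue.append((ny, nx))
        comps.append(frozenset(comp))
    return set(comps)


def brute_force_min_cover(pixels, fov, shape):
    """Smallest number of fov x fov boxes covering all pixels (exhaustive).

    Candidate anchors are clamped pixel-coordinate pairs: any box can be
    shifted right/down onto one without losing coverage.
    """
    h, w = shape
    ys = sorted({min(max(p[0] - 0, 0), h - fov) for p in pixels})
    xs = sorted({min(max(p[1] - 0, 0), w - fov) for p in pixels})
    anchors = [(y, x) for y in ys for x in xs]
    cover_sets = []
    for (y0, x0) in anchors:
        covered = frozenset(
            i for i, (py, px) in enumerate(pixels)
            if y0 <= py < y0 + fov and x0 <= px < x0 + fov
        )
        if covered:
            cover_sets.append(covered)
    universe = frozenset(range(len(pixels)))
    for k in range(1, len(pixels) + 1):
        for combo in itertools.combinations(cover_sets, k):
            if frozenset().union(*combo) == universe:
                return k
    raise AssertionError("unreachable: singleton boxes always cover")


class TestDetectOverlaps:
    def test_disjoint_masks_give_empty_list(self):
        a = np.zeros((10, 10), bool)
        d = np.zeros((10, 10), bool)
        a[2, 2] = True
        d[7, 7] = True
        assert detect_overlaps(mask(a), mask(d)) == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_overlaps(mask(np.zeros((4, 4), bool)), mask(np.zeros((5, 5), bool)))

    def test_components_match_flood_fill_oracle(self, rng):
        for _ in range(25):
            a = rng.random((30, 30)) > 0.6
            d = rng.random((30, 30)) > 0.6
            comps = detect_overlaps(mask(a), mask(d))
            got = {frozenset(map(tuple, c)) for c in comps}
            assert got == flood_fill_components(a & d)

    def test_restricted_to_target_area(self):
        a = np.ones((10, 10), bool)
        d = np.ones((10, 10), bool)
        region = np.zeros((10, 10), bool)
        region[:5, :5] = True
        comps = detect_overlaps(mask(a), mask(d), region)
        assert len(comps) == 1 and len(comps[0]) == 25

    def test_finds_phantom_contact(self, small_phantom, small_detection, small_config):
        # every ground-truth synapse has a detected candidate nearby
        _, truth = small_phantom
        px = small_config.pixel_size_um
        for _, row in truth.synapses[truth.synapses.is_true_synapse].iterrows():
            tx, ty = row.x_um / px, row.y_um / px
            near = [
                c for c in small_detection.candidates
                if abs(c.section - row.section) <= 1
                and np.hypot(c.centroid[0] - tx, c.centroid[1] - ty) <= 6
            ]
            assert near, f"no candidate near ground-truth synapse {row.id}"


class TestMakeFovBoxes:
    def test_centering_arithmetic(self):
        comp = np.array([[100, 100]])  # (y, x)
        (box,) = make_fov_boxes([comp], 32, (200, 200))
        assert (box.x0, box.y0, box.x1, box.y1) == (84, 84, 116, 116)

    def test_corner_clamping_keeps_size(self):
        comp = np.array([[0, 0]])
        (box,) = make_fov_boxes([comp], 32, (200, 200))
        assert (box.x0, box.y0, box.x1, box.y1) == (0, 0, 32, 32)

    def test_oversized_fov_rejected(self):
        with pytest.raises(ValueError):
            make_fov_boxes([np.array([[1, 1]])], 300, (200, 200))

    def test_stable_order(self):
        comps = [np.array([[10, 10]]), np.array([[50, 50]])]
        boxes = make_fov_boxes(comps, 16, (100, 100))
        assert boxes[0].y0 < boxes[1].y0


class TestMergeFovBoxes:
    def run(self, pixels, fov=32, shape=(200, 200)):
        pixels = np.asarray(pixels)
        comps = [pixels[i : i + 1] for i in range(len(pixels))]
        boxes = make_fov_boxes(comps, fov, shape)
        return merge_fov_boxes(boxes, pixels, fov, shape)

    def test_close_pixels_share_one_box(self):
        assert len(self.run([[100, 100], [100, 105]])) == 1

    def test_distant_pixels_need_two_boxes(self):
        assert len(self.run([[100, 20], [100, 150]])) == 2

    def test_empty_input(self):
        assert merge_fov_boxes([], np.empty((0, 2)), 32, (100, 100)) == []

    def test_uncoverable_pixel_rejected(self):
        with pytest.raises(ValueError):
            merge_fov_boxes([], np.array([[500, 500]]), 32, (100, 100))

    def test_precondition_pixels_covered_by_inputs(self):
        boxes = [Box(0, 0, 32, 32)]
        with pytest.raises(ValueError):
            merge_fov_boxes(boxes, np.array([[100, 100]]), 32, (200, 200))

    def test_random_instances_near_optimal_and_complete(self, rng):
        fov, shape = 32, (200, 200)
        for _ in range(40):
            n = int(rng.integers(1, 11))
            pixels = np.column_stack(
                [rng.integers(0, shape[0], n), rng.integers(0, shape[1], n)]
            )
            cover = self.run(pixels, fov, shape)
            for py, px in pixels:
                assert any(b.y0 <= py < b.y1 and b.x0 <= px < b.x1 for b in cover)
            optimum = brute_force_min_cover([tuple(p) for p in pixels], fov, shape)
            assert len(cover) <= optimum + 1

    def test_deterministic(self, rng):
        pixels = np.column_stack([rng.integers(0, 200, 8), rng.integers(0, 200, 8)])
        a = self.run(pixels)
        b = self.run(pixels)
        assert a == b


class TestRejectInterior:
    def test_blob_center_overlap_is_flagged(self):
        a = np.zeros((40, 40), bool)
        a[5:35, 5:35] = True  # large blob in both channels
        cand = CandidateROI(
            id=0, section=0, pixels=np.array([[20, 20]]), centroid=(20.0, 20.0),
            fov_box=Box(10, 10, 30, 30),
        )
        assert reject_interior(cand, mask(a), mask(a), interior_margin=5.0)

    def test_surface_contact_is_kept(self):
        a = np.zeros((40, 40), bool)
        d = np.zeros((40, 40), bool)
        a[18:22, :] = True   # thin horizontal tube
        d[:, 18:22] = True   # thin vertical tube
        cand = CandidateROI(
            id=0, section=0, pixels=np.array([[20, 20]]), centroid=(20.0, 20.0),
            fov_box=Box(10, 10, 30, 30),
        )
        assert not reject_interior(cand, mask(a), mask(d), interior_margin=5.0)

    def test_margin_limits(self):
        a = np.ones((30, 30), bool)
        cand = CandidateROI(
            id=0, section=0, pixels=np.array([[15, 15]]), centroid=(15.0, 15.0),
            fov_box=Box(5, 5, 25, 25),
        )
        assert not reject_interior(cand, mask(a), mask(a), interior_margin=0.0)
        assert reject_interior(cand, mask(a), mask(a), interior_margin=10.0)

    def test_phantom_true_synapses_not_interior(self, small_detection, small_phantom, small_config):
        _, truth = small_phantom
        px = small_config.pixel_size_um
        for _, row in truth.synapses[truth.synapses.is_true_synapse].iterrows():
            tx, ty = row.x_um / px, row.y_um / px
            near = [
                c for c in small_detection.candidates
                if abs(c.section - row.section) <= 1
                and np.hypot(c.centroid[0] - tx, c.centroid[1] - ty) <= 6
            ]
            assert any(not c.interior_of_large_structure for c in near)


def _candidate(section, y, x):
    return CandidateROI(
        id=section * 1000 + y,
        section=section,
        pixels=np.array([[y, x]]),
        centroid=(float(x), float(y)),
        fov_box=Box(0, 0, 8, 8),
    )


class TestContinuityFilter:
    def setup_masks(self, n_sections, shape=(40, 40)):
        return (
            [mask(np.zeros(shape, bool)) for _ in range(n_sections)],
            [mask(np.zeros(shape, bool)) for _ in range(n_sections)],
            [AlignmentTransform.identity() for _ in range(n_sections)],
        )

    def test_single_section_noise_removed(self):
        axon, dend, tf = self.setup_masks(3)
        axon[1].pixels[20, 20] = True
        dend[1].pixels[20, 20] = True
        cand = _candidate(1, 20, 20)
        kept = continuity_filter([cand], axon, dend, tf, match_radius=3.0)
        assert kept == [] and cand.has_continuity is False

    def test_continuous_signal_kept(self):
        axon, dend, tf = self.setup_masks(3)
        for z in (0, 1, 2):
            axon[z].pixels[20, 20] = True
            dend[z].pixels[21, 20] = True
        cand = _candidate(1, 20, 20)
        kept = continuity_filter([cand], axon, dend, tf, match_radius=3.0)
        assert kept == [cand] and cand.has_continuity

    def test_needs_both_channels_in_neighbor(self):
        axon, dend, tf = self.setup_masks(2)
        axon[0].pixels[20, 20] = True
        dend[0].pixels[20, 20] = True
        axon[1].pixels[20, 20] = True  # axon reappears, dendrite does not
        cand = _candidate(0, 20, 20)
        assert continuity_filter([cand], axon, dend, tf, match_radius=3.0) == []

    def test_end_sections_use_single_neighbor(self):
        axon, dend, tf = self.setup_masks(2)
        for z in (0, 1):
            axon[z].pixels[20, 20] = True
            dend[z].pixels[20, 20] = True
        cand = _candidate(0, 20, 20)
        assert continuity_filter([cand], axon, dend, tf, match_radius=3.0) == [cand]

    def test_single_section_stack_removes_everything(self, caplog):
        axon, dend, tf = self.setup_masks(1)
        axon[0].pixels[20, 20] = True
        dend[0].pixels[20, 20] = True
        cand = _candidate(0, 20, 20)
        import logging

        with caplog.at_level(logging.WARNING, logger="synseek.roi"):
            kept = continuity_filter([cand], axon, dend, tf, match_radius=3.0)
        assert kept == []
        assert any("single-section" in r.message for r in caplog.records)

    def test_wider_neighbor_span(self):
        axon, dend, tf = self.setup_masks(5)
        axon[2].pixels[20, 20] = True
        dend[2].pixels[20, 20] = True
        axon[4].pixels[20, 20] = True  # reappears two sections away only
        dend[4].pixels[20, 20] = True
        cand = _candidate(2, 20, 20)
        assert continuity_filter([cand], axon, dend, tf, match_radius=3.0, neighbor_span=1) == []
        cand2 = _candidate(2, 20, 20)
        assert continuity_filter([cand2], axon, dend, tf, match_radius=3.0, neighbor_span=2) == [cand2]

    def test_phantom_synapse_spanning_sections_kept(self, small_detection, small_phantom, small_config):
        _, truth = small_phantom
        px = small_config.pixel_size_um
        for _, row in truth.synapses[truth.synapses.is_true_synapse].iterrows():
            tx, ty = row.x_um / px, row.y_um / px
            near = [
                c for c in small_detection.shortlisted
                if abs(c.section - row.section) <= 1
                and np.hypot(c.centroid[0] - tx, c.centroid[1] - ty) <= 6
            ]
            assert near, f"ground-truth synapse {row.id} lost in shortlisting"


class TestBindSeries:
    def _transforms(self, n):
        return [AlignmentTransform.identity() for _ in range(n)]

    def test_interior_candidate_one_neighbor(self):
        cand = _candidate(3, 50, 50)
        cand = CandidateROI(**{**cand.__dict__, "fov_box": Box(40, 40, 60, 60)})
        series = bind_series(cand, 1, 10, self._transforms(10), (100, 100))
        assert [z for z, _ in series.entries] == [2, 3, 4]
        assert series.length == 3

    def test_truncated_at_stack_start(self):
        cand = _candidate(0, 50, 50)
        series = bind_series(cand, 2, 10, self._transforms(10), (100, 100))
        assert [z for z, _ in series.entries] == [0, 1, 2]

    def test_two_neighbors_interior_gives_five(self):
        cand = _candidate(5, 50, 50)
        series = bind_series(cand, 2, 10, self._transforms(10), (100, 100))
        assert series.length == 5

    def test_invalid_neighbor_count(self):
        with pytest.raises(ValueError):
            bind_series(_candidate(0, 1, 1), 3, 5, self._transforms(5), (100, 100))


class TestAlignmentTransform:
    def test_identity_and_translation(self):
        assert to_global((3.0, 4.0), AlignmentTransform.identity()) == (3.0, 4.0)
        t = AlignmentTransform((1, 0, 10, 0, 1, -5))
        assert to_global((3.0, 4.0), t) == (13.0, -1.0)

    def test_singular_rejected(self):
        with pytest.raises(ValueError):
            AlignmentTransform((1, 2, 0, 2, 4, 0))

    @given(
        coeffs=st.tuples(
            st.floats(0.5, 2), st.floats(-0.4, 0.4), st.floats(-50, 50),
            st.floats(-0.4, 0.4), st.floats(0.5, 2), st.floats(-50, 50),
        ),
        point=st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_residual(self, coeffs, point):
        t = AlignmentTransform(coeffs)
        gx, gy = to_global(point, t)
        x, y = to_local((gx, gy), t)
        assert abs(x - point[0]) < 1e-6 and abs(y - point[1]) < 1e-6


class TestTargetAreaIO:
    def test_round_trip(self, tmp_path):
        from synseek.roi import load_target_areas, save_target_areas

        area = full_frame_target_area("L4", (100, 100), AlignmentTransform.scaling(0.31))
        area.section_range = (0, 10)
        save_target_areas([area], tmp_path / "areas.json")
        (loaded,) = load_target_areas(tmp_path / "areas.json")
        assert loaded.name == "L4"
        assert loaded.section_range == (0, 10)
        assert loaded.polygon.equals(area.polygon)

    def test_transforms_round_trip(self, tmp_path):
        from synseek.roi import load_transforms, save_transforms

        tfs = [AlignmentTransform.scaling(0.31), AlignmentTransform((1, 0.1, 5, -0.1, 1, 2))]
        save_transforms(tfs, tmp_path / "t.json")
        assert load_transforms(tmp_path / "t.json") == tfs
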