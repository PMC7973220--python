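"""Seed lattices, Voronoi partition, shape matching and relaxation."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from astroca.morphology import build_library, generate_synthetic_astrocyte
from astroca.tiling import (
    DraftTiling,
    Placement,
    VoronoiPatch,
    assemble_network,
    build_draft,
    make_seed_lattice,
    match_template,
    relax_boundaries,
    resample_closed,
    shape_dissimilarity,
    tiling_energy,
    voronoi_patches,
)


class TestLattice:
    def test_zero_jitter_regular_grid(self):
        lat = make_seed_lattice(200.0, spacing=50.0, jitter_sigma=0.0, seed=0)
        assert lat.points.shape == (16, 2)
        xs = np.unique(lat.points[:, 0])
        assert np.allclose(xs, [25, 75, 125, 175])

    def test_jitter_statistics(self):
        """Sampled displacement std matches the requested sigma within 3%."""
        lat = make_seed_lattice(5000.0, spacing=50.0, jitter_sigma=10.0,
                                seed=1)
        ref = make_seed_lattice(5000.0, spacing=50.0, jitter_sigma=0.0)
        disp = (lat.points - ref.points).ravel()
        disp = disp[np.abs(disp) < 49]  # drop clipped boundary points
        assert disp.std() == pytest.approx(10.0, rel=0.03)
        assert abs(disp.mean()) < 0.2

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            make_seed_lattice(60.0, spacing=50.0)


class TestVoronoi:
    def test_2x2_grid_gives_congruent_quadrants(self):
        lat = make_seed_lattice(100.0, spacing=50.0, jitter_sigma=0.0)
        patches = voronoi_patches(lat)
        assert len(patches) == 4
        for p in patches:
            assert p.shapely.area == pytest.approx(2500.0)
            assert p.shapely.covers(Point(p.seed_point))
        assert sorted(len(p.neighbor_ids) for p in patches) == [2, 2, 2, 2]

    def test_brute_force_nearest_seed_assignment(self):
        """Random pixels belong to the patch of their nearest seed."""
        lat = make_seed_lattice(200.0, spacing=50.0, jitter_sigma=10.0, seed=3)
        patches = voronoi_patches(lat)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 200, size=(2000, 2))
        d = np.linalg.norm(pts[:, None, :] - lat.points[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        margin = np.partition(d, 1, axis=1)
        clear = margin[:, 1] - margin[:, 0] > 1e-6
        polys = [p.shapely.buffer(1e-9) for p in patches]
        for pt, k in zip(pts[clear], nearest[clear]):
            assert polys[k].covers(Point(pt))

    def test_union_area_conserved(self):
        lat = make_seed_lattice(150.0, spacing=50.0, jitter_sigma=8.0, seed=5)
        patches = voronoi_patches(lat)
        total = sum(p.shapely.area for p in patches)
        assert total == pytest.approx(150.0 * 150.0, rel=1e-9)
        areas = [p.shapely.area for p in patches]
        assert np.mean(areas) == pytest.approx(150.0**2 / len(patches))
        assert np.std(areas) > 0  # jitter makes them unequal

    def test_degenerate_seeds_rejected(self):
        lat = make_seed_lattice(100.0, spacing=50.0, jitter_sigma=0.0)
        lat.points = np.array([[10.0, 10.0], [10.0, 10.0], [20.0, 20.0]])
        with pytest.raises(ValueError):
            voronoi_patches(lat, extent=(100.0, 100.0))


@pytest.fixture(scope="module")
def small_library():
    cells = [generate_synthetic_astrocyte(extent=40.0, pixel_size=1.0,
                                          soma_radius=4.0, seed=s)
             for s in range(2)]
    return build_library(cells, n_augment=10, seed=7)


class TestMatching:
    def test_exact_hull_match_is_zero(self, small_library):
        off = small_library.offsprings[3]
        patch = VoronoiPatch(polygon=off.hull.copy(),
                             seed_point=off.hull.mean(axis=0))
        best, shift = match_template(patch, small_library)
        assert best == 3
        assert shape_dissimilarity(off.hull, patch.polygon) < 1e-9
        assert np.allclose(shift, 0.0, atol=1e-9)

    def test_rotation_and_translation_invariance(self, small_library):
        hull = small_library.offsprings[0].hull
        th = np.deg2rad(40.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = hull @ rot.T + [120.0, -30.0]
        assert shape_dissimilarity(hull, moved) < 0.1

    def test_singleton_library(self, small_library):
        lib_one = type(small_library)(progenitors=small_library.progenitors,
                                      offsprings=[small_library.offsprings[5]])
        patch = VoronoiPatch(polygon=np.array([[0, 0], [30, 0], [30, 30],
                                               [0, 30.0]]),
                             seed_point=np.array([15.0, 15.0]))
        best, _ = match_template(patch, lib_one)
        assert best == 0

    def test_ranking_matches_exhaustive_oracle(self, small_library):
        patch = VoronoiPatch(polygon=np.array([[0, 0], [45, 5], [50, 40],
                                               [5, 45.0]]),
                             seed_point=np.array([25.0, 25.0]))
        scores = [shape_dissimilarity(off.hull, patch.polygon)
                  for off in small_library.offsprings]
        best, _ = match_template(patch, small_library)
        assert best == int(np.argmin(scores))

    def test_empty_library_rejected(self, small_library):
        empty = type(small_library)(progenitors=[], offsprings=[])
        patch = VoronoiPatch(polygon=np.array([[0, 0], [1, 0], [1, 1.0]]),
                             seed_point=np.zeros(2))
        with pytest.raises(ValueError):
            match_template(patch, empty)


def disc(cx, cy, radius, k=48):
    th = np.linspace(0, 2 * np.pi, k, endpoint=False)
    return np.column_stack([cx + radius * np.cos(th),
                            cy + radius * np.sin(th)])


def two_disc_draft(gap=-6.0):
    """Two discs whose overlap is controlled by ``gap`` (negative overlaps)."""
    r = 20.0
    d = 2 * r + gap
    patches = [
        VoronoiPatch(polygon=np.array([[0, 0], [40, 0], [40, 80], [0, 80.0]]),
                     seed_point=np.array([20.0, 40.0]), neighbor_ids=[1]),
        VoronoiPatch(polygon=np.array([[40, 0], [80, 0], [80, 80],
                                       [40, 80.0]]),
                     seed_point=np.array([60.0, 40.0]), neighbor_ids=[0]),
    ]
    placements = [
        Placement(offspring_id=0, translation=np.zeros(2),
                  contour=disc(40 - d / 2, 40, r),
                  contour0=disc(40 - d / 2, 40, r), patch_id=0),
        Placement(offspring_id=1, translation=np.zeros(2),
                  contour=disc(40 + d / 2, 40, r),
                  contour0=disc(40 + d / 2, 40, r), patch_id=1),
    ]
    return DraftTiling(placements=placements, patches=patches,
                       extent=(80.0, 80.0))


class TestRelaxation:
    def test_perfect_tiling_is_fixed_point(self):
        """Zero overlap, zero gap: contours stay put."""
        patches = [
            VoronoiPatch(polygon=np.array([[0, 0], [40, 0], [40, 40],
                                           [0, 40.0]]),
                         seed_point=np.array([20.0, 20.0]), neighbor_ids=[1]),
            VoronoiPatch(polygon=np.array([[40, 0], [80, 0], [80, 40],
                                           [40, 40.0]]),
                         seed_point=np.array([60.0, 20.0]), neighbor_ids=[0]),
        ]
        sq1 = resample_closed(patches[0].polygon, 40)
        sq2 = resample_closed(patches[1].polygon, 40)
        placements = [
            Placement(0, np.zeros(2), sq1.copy(), sq1.copy(), 0),
            Placement(1, np.zeros(2), sq2.copy(), sq2.copy(), 1),
        ]
        draft = DraftTiling(placements, patches, (80.0, 40.0))
        out = relax_boundaries(draft, n_iter=5, step=0.5)
        for a, b in zip(out.placements, placements):
            assert np.allclose(a.contour, b.contour, atol=1e-9)

    def test_overlap_decreases_monotonically(self):
        draft = two_disc_draft(gap=-6.0)
        overlaps = []
        cur = draft
        for _ in range(8):
            _, terms = tiling_energy(cur, (1.0, 0.0, 0.1))
            overlaps.append(terms["overlap"])
            cur = relax_boundaries(cur, weights=(1.0, 0.0, 0.1), n_iter=1,
                                   step=0.4)
        _, terms = tiling_energy(cur, (1.0, 0.0, 0.1))
        overlaps.append(terms["overlap"])
        assert overlaps[0] > 1.0
        diffs = np.diff(overlaps)
        assert np.all(diffs <= 1e-9)
        assert overlaps[-1] < 0.5 * overlaps[0]

    def test_energy_non_increasing(self):
        draft = two_disc_draft(gap=-6.0)
        out = relax_boundaries(draft, weights=(1.0, 1.0, 1.0), n_iter=15,
                               step=0.4)
        e = np.array(out.energy_history)
        assert np.all(np.diff(e) <= 1e-9)

    def test_zero_repulsion_keeps_overlap_constant(self):
        """With only the shape term active there is no force at start."""
        draft = two_disc_draft(gap=-6.0)
        _, t0 = tiling_energy(draft, (0.0, 0.0, 1.0))
        out = relax_boundaries(draft, weights=(0.0, 0.0, 1.0), n_iter=5,
                               step=0.4)
        _, t1 = tiling_energy(out, (0.0, 0.0, 1.0))
        assert t1["overlap"] == pytest.approx(t0["overlap"], rel=1e-9)

    def test_self_intersecting_input_rejected(self):
        draft = two_disc_draft()
        draft.placements[0].contour = np.array([[0, 0], [10, 10], [10, 0],
                                                [0, 10.0]])
        with pytest.raises(ValueError):
            relax_boundaries(draft)


class TestAssembly:
    def test_single_cell_identity_warp(self, small_library):
        """Warping into the unmodified contour reproduces the template."""
        off = small_library.offsprings[0]
        hull = off.hull
        shift = np.array([5.0, 5.0])  # margin inside the canvas
        contour = resample_closed(hull + shift, 64)
        patch = VoronoiPatch(polygon=hull + shift,
                             seed_point=hull.mean(axis=0) + shift)
        pl = Placement(0, shift, contour.copy(), contour.copy(), 0)
        ex = float((hull[:, 0] + shift[0]).max() + 5)
        ey = float((hull[:, 1] + shift[1]).max() + 5)
        draft = DraftTiling([pl], [patch], (ex, ey))
        tpl = assemble_network(draft, small_library, pixel_size=1.0)
        assert tpl.n_cells == 1
        from astroca.morphology import decode_template, intensity_to_avf

        dec, labels = decode_template(tpl)
        src = intensity_to_avf(off.image)
        # compare AVF inside the contour on the common support
        h = min(dec.r.shape[0] - 5, src.r.shape[0])
        w = min(dec.r.shape[1] - 5, src.r.shape[1])
        a = dec.r[5:5 + h, 5:5 + w]
        b = src.r[:h, :w]
        inter = ((a > 0) & (b > 0)).sum()
        union = ((a > 0) | (b > 0)).sum()
        assert inter / union > 0.6
        both = (a > 0) & (b > 0)
        assert np.corrcoef(a[both], b[both])[0, 1] > 0.7

    def test_every_pixel_single_label(self, small_library):
        lat = make_seed_lattice(80.0, spacing=30.0, jitter_sigma=4.0, seed=2)
        patches = voronoi_patches(lat)
        draft = build_draft(patches, small_library)
        relaxed = relax_boundaries(draft, n_iter=10, step=0.5)
        tpl = assemble_network(relaxed, small_library, pixel_size=1.0,
                               max_overlap=1.0)
        labels = tpl.domain_labels
        assert np.array_equal(labels > 0, tpl.mask)
        assert tpl.n_cells >= 2

    def test_unresolved_overlap_rejected(self, small_library):
        draft = two_disc_draft(gap=-12.0)
        with pytest.raises(ValueError, match="overlap"):
            assemble_network(draft, small_library, pixel_size=1.0,
                             max_overlap=0.001)
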