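"""Multicellular network templates.

Astrocytes tile the tissue into non-overlapping domains.  The generator
follows that logic: a jittered regular lattice of seed points (spacing ~
cell density, default 50 um, Gaussian jitter sigma = 10 um) is partitioned
into Voronoi patches; each patch is filled with the library offspring whose
convex hull best matches the patch shape; the resulting draft tiling (with
overlaps and gaps) is relaxed by an active-contour scheme whose energy
promotes repulsion of overlapping domains, adhesion of neighbours along
shared Voronoi edges and penalises deformation away from the original cell
shape; finally each offspring's AVF map is warped into its settled contour
and rasterised into a labelled network template.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.validation import make_valid

from .morphology import (
    AVFMap,
    SpatialTemplate,
    TemplateLibrary,
    encode_template,
    intensity_to_avf,
)

__all__ = ["SeedLattice", "VoronoiPatch", "DraftTiling", "Placement",
           "make_seed_lattice", "voronoi_patches", "match_template",
           "build_draft", "relax_boundaries", "assemble_network",
           "tiling_energy"]


@dataclass
class SeedLattice:
    """Jittered regular lattice of astrocyte seed points."""

    points: np.ndarray          # (N, 2) x, y in um
    spacing: float
    jitter_sigma: float
    extent: tuple[float, float]
    seed: int | None = None


@dataclass
class VoronoiPatch:
    polygon: np.ndarray         # (K, 2) vertices, um, CCW, open ring
    seed_point: np.ndarray
    neighbor_ids: list[int] = field(default_factory=list)

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class Placement:
    """One library offspring placed into a Voronoi patch."""

    offspring_id: int
    translation: np.ndarray     # hull centroid -> patch centroid shift, um
    contour: np.ndarray         # (K, 2) current boundary, um
    contour0: np.ndarray        # boundary before relaxation
    patch_id: int = 0


@dataclass
class DraftTiling:
    placements: list[Placement]
    patches: list[VoronoiPatch]
    extent: tuple[float, float]


def make_seed_lattice(extent, spacing: float = 50.0,
                      jitter_sigma: float = 10.0, seed: int = 0
                      ) -> SeedLattice:
    """Regular grid of seed points plus i.i.d. Gaussian jitter.

    Grid points sit at cell centres (spacing/2 offset); jittered points are
    clipped to the extent.
    """
    if np.isscalar(extent):
        extent = (float(extent), float(extent))
    ex, ey = extent
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if ex < 2 * spacing or ey < 2 * spacing:
        raise ValueError("extent must cover at least 2 lattice cells per axis")
    nx, ny = int(ex // spacing), int(ey // spacing)
    xs = (np.arange(nx) + 0.5) * spacing
    ys = (np.arange(ny) + 0.5) * spacing
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    rng = np.random.default_rng(seed)
    pts = pts + rng.normal(0.0, jitter_sigma, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0, ex)
    pts[:, 1] = np.clip(pts[:, 1], 0, ey)
    return SeedLattice(points=pts, spacing=spacing, jitter_sigma=jitter_sigma,
                       extent=(ex, ey), seed=seed)


def voronoi_patches(lattice: SeedLattice, extent=None) -> list[VoronoiPatch]:
    """Voronoi partition of the extent, clipped to the bounding box.

    Implemented by mirroring the seed set across the four box edges so
    every original seed's region is finite, then clipping.  Patches tile
    the extent exactly (up to shared edges); neighbour ids are filled for
    patches sharing a boundary segment.
    """
    from scipy.spatial import QhullError, Voronoi

    if extent is None:
        extent = lattice.extent
    if np.isscalar(extent):
        extent = (float(extent), float(extent))
    ex, ey = extent
    pts = np.asarray(lattice.points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 seed points")
    if len(np.unique(pts.round(9), axis=0)) < len(pts):
        raise ValueError("duplicate seed points")
    mirrored = [pts]
    for axis, bound in ((0, 0.0), (0, ex), (1, 0.0), (1, ey)):
        m = pts.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    allpts = np.vstack(mirrored)
    try:
        vor = Voronoi(allpts)
    except QhullError as err:
        raise ValueError(f"degenerate seed configuration: {err}") from err
    box = Polygon([(0, 0), (ex, 0), (ex, ey), (0, ey)])
    patches = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise ValueError("unbounded region survived mirroring")
        poly = Polygon(vor.vertices[region])
        poly = make_valid(poly).intersection(box)
        if poly.is_empty or poly.geom_type != "Polygon":
            raise ValueError("degenerate clipped patch")
        coords = np.asarray(poly.exterior.coords[:-1])
        patches.append(VoronoiPatch(polygon=coords, seed_point=pts[i]))
    for i, pi in enumerate(patches):
        a = pi.shapely
        for j in range(i + 1, len(patches)):
            inter = a.intersection(patches[j].shapely)
            if inter.length > 1e-9:
                pi.neighbor_ids.append(j)
                patches[j].neighbor_ids.append(i)
    return patches


# ---------------------------------------------------------------------------
# shape matching


def resample_closed(poly: np.ndarray, k: int = 64) -> np.ndarray:
    """Arc-length resample a closed polygon to k points, CCW orientation."""
    poly = np.asarray(poly, dtype=float)
    if _signed_area(poly) < 0:
        poly = poly[::-1]
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0, total, k, endpoint=False)
    out = np.empty((k, 2))
    for d in range(2):
        out[:, d] = np.interp(targets, cum, closed[:, d])
    return out


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def shape_dissimilarity(a: np.ndarray, b: np.ndarray, k: int = 64) -> float:
    """Procrustes-style residual between two closed boundaries.

    Both are arc-length resampled to ``k`` points and centred; the residual
    is minimised over rotation and cyclic starting-point shift (no
    scaling - size differences count against the match).  Returns the RMS
    point distance (um).
    """
    za = _as_complex(resample_closed(a, k))
    zb = _as_complex(resample_closed(b, k))
    # cross-correlation over cyclic shifts via FFT
    corr = np.fft.ifft(np.fft.fft(zb) * np.conj(np.fft.fft(za)))
    best = np.max(np.abs(corr))
    resid2 = (np.sum(np.abs(za) ** 2) + np.sum(np.abs(zb) ** 2) - 2 * best) / k
    return float(np.sqrt(max(resid2, 0.0)))


def _as_complex(p: np.ndarray) -> np.ndarray:
    z = p[:, 0] + 1j * p[:, 1]
    return z - z.mean()


def match_template(patch: VoronoiPatch, library: TemplateLibrary,
                   k: int = 64):
    """Best-shape offspring for a Voronoi patch.

    Returns ``(offspring_id, placement_translation)`` minimising
    :func:`shape_dissimilarity` between the offspring convex hull and the
    patch polygon; the translation aligns the hull centroid with the patch
    centroid.
    """
    if len(library) == 0:
        raise ValueError("empty template library")
    scores = [shape_dissimilarity(off.hull, patch.polygon, k)
              for off in library.offsprings]
    best = int(np.argmin(scores))
    hull = library.offsprings[best].hull
    translation = patch.polygon.mean(axis=0) - hull.mean(axis=0)
    return best, translation


def build_draft(patches: list[VoronoiPatch], library: TemplateLibrary,
                k: int = 64, n_contour: int = 64) -> DraftTiling:
    """Match an offspring to every patch -> preliminary (overlapping) tiling."""
    placements = []
    for pid, patch in enumerate(patches):
        off_id, shift = match_template(patch, library, k)
        hull = library.offsprings[off_id].hull + shift
        contour = resample_closed(hull, n_contour)
        placements.append(Placement(
            offspring_id=off_id, translation=shift,
            contour=contour.copy(), contour0=contour.copy(), patch_id=pid,
        ))
    ex = max(p.polygon[:, 0].max() for p in patches)
    ey = max(p.polygon[:, 1].max() for p in patches)
    return DraftTiling(placements=placements, patches=patches,
                       extent=(ex, ey))


# ---------------------------------------------------------------------------
# active-contour relaxation


def _contour_polys(draft: DraftTiling) -> list[Polygon]:
    return [make_valid(Polygon(p.contour)) for p in draft.placements]


def tiling_energy(draft: DraftTiling, weights=(1.0, 1.0, 1.0),
                  n_edge_samples: int = 24) -> tuple[float, dict]:
    """Total tiling energy and its terms.

    overlap: summed pairwise intersection area of neighbouring domains;
    adhesion: summed length of shared Voronoi edges not covered by either
    neighbour (gap length); deformation: mean squared deviation of contour
    second differences from the undeformed contour plus relative area
    change, summed over cells.
    """
    w_rep, w_adh, w_def = weights
    polys = _contour_polys(draft)
    overlap = 0.0
    seen = set()
    for i, patch in enumerate(draft.patches):
        for j in patch.neighbor_ids:
            if (min(i, j), max(i, j)) in seen:
                continue
            seen.add((min(i, j), max(i, j)))
            overlap += polys[i].intersection(polys[j]).area
    gap = 0.0
    for i, patch in enumerate(draft.patches):
        a = patch.shapely
        for j in patch.neighbor_ids:
            if j < i:
                continue
            edge = a.intersection(draft.patches[j].shapely)
            if edge.length <= 0:
                continue
            ts = np.linspace(0.05, 0.95, n_edge_samples)
            pts = [edge.interpolate(t, normalized=True) for t in ts]
            out = sum(1 for pt in pts
                      if not (polys[i].covers(pt) or polys[j].covers(pt)))
            gap += edge.length * out / n_edge_samples
    deform = 0.0
    for pl, poly in zip(draft.placements, polys):
        d2 = np.diff(np.vstack([pl.contour, pl.contour[:2]]), n=2, axis=0)
        d2o = np.diff(np.vstack([pl.contour0, pl.contour0[:2]]), n=2, axis=0)
        bend = float(np.mean(np.sum((d2 - d2o) ** 2, axis=1)))
        a0 = abs(_signed_area(pl.contour0))
        deform += bend + ((poly.area - a0) / max(a0, 1e-9)) ** 2
    terms = {"overlap": overlap, "gap": gap, "deform": deform}
    total = w_rep * overlap + w_adh * gap + w_def * deform
    return total, terms


def _outward_normals(contour: np.ndarray) -> np.ndarray:
    nxt = np.roll(contour, -1, axis=0)
    prv = np.roll(contour, 1, axis=0)
    tang = nxt - prv
    nrm = np.column_stack([tang[:, 1], -tang[:, 0]])  # outward for CCW
    ln = np.linalg.norm(nrm, axis=1, keepdims=True)
    return nrm / np.maximum(ln, 1e-12)


def relax_boundaries(draft: DraftTiling, weights=(1.0, 1.0, 1.0),
                     n_iter: int = 40, step: float = 0.5,
                     probe: float = 0.75, tol_overlap: float = 1e-3
                     ) -> DraftTiling:
    """Relax domain contours to remove overlaps and close gaps.

    Vertex forces: repulsion (inward where a vertex lies inside a
    neighbouring domain), adhesion (outward where just outside the contour
    lies uncovered territory of the cell's own Voronoi patch) and shape
    regularisation (spring towards the undeformed contour plus curvature
    smoothing), scaled by ``weights``.  A backtracking step control accepts
    a proposed move only if the total energy does not increase and all
    contours stay simple, so the energy is non-increasing across accepted
    iterations.
    """
    for pl in draft.placements:
        if not LineString(np.vstack([pl.contour, pl.contour[:1]])).is_simple:
            raise ValueError("self-intersecting input contour")
    w_rep, w_adh, w_def = weights
    if min(weights) < 0:
        raise ValueError("weights must be non-negative")
    draft = replace(draft, placements=[replace(pl, contour=pl.contour.copy())
                                       for pl in draft.placements])
    energy, _ = tiling_energy(draft, weights)
    history = [energy]
    for _ in range(n_iter):
        polys = _contour_polys(draft)
        moves = []
        for i, pl in enumerate(draft.placements):
            patch = draft.patches[pl.patch_id]
            nbrs = patch.neighbor_ids
            normals = _outward_normals(pl.contour)
            force = np.zeros_like(pl.contour)
            for k, v in enumerate(pl.contour):
                pt = Point(v)
                if w_rep and any(polys[j].contains(pt) for j in nbrs):
                    force[k] -= w_rep * normals[k]
                elif w_adh:
                    out_pt = Point(v + probe * normals[k])
                    if patch.shapely.covers(out_pt) and not any(
                            polys[j].covers(out_pt) for j in nbrs):
                        force[k] += w_adh * normals[k]
            if w_def:
                force += w_def * 0.2 * (pl.contour0 - pl.contour)
                lap = (np.roll(pl.contour, 1, 0) + np.roll(pl.contour, -1, 0)
                       - 2 * pl.contour)
                lap0 = (np.roll(pl.contour0, 1, 0) + np.roll(pl.contour0, -1, 0)
                        - 2 * pl.contour0)
                force += w_def * 0.2 * (lap - lap0)
            moves.append(force)
        accepted = False
        trial_step = step
        for _try in range(4):
            trial = [pl.contour + trial_step * f
                     for pl, f in zip(draft.placements, moves)]
            if any(not LineString(np.vstack([c, c[:1]])).is_simple
                   for c in trial):
                trial_step *= 0.5
                continue
            cand = replace(draft, placements=[
                replace(pl, contour=c)
                for pl, c in zip(draft.placements, trial)])
            e_new, terms = tiling_energy(cand, weights)
            if e_new <= energy + 1e-12:
                draft = cand
                energy = e_new
                accepted = True
                break
            trial_step *= 0.5
        history.append(energy)
        if not accepted:
            break
        if w_rep and terms["overlap"] < tol_overlap and terms["gap"] < step:
            break
    draft.energy_history = history  # type: ignore[attr-defined]
    return draft


# ---------------------------------------------------------------------------
# assembly


def _radius_table(contour: np.ndarray, center: np.ndarray,
                  n_bins: int = 360) -> np.ndarray:
    """Radius as a function of polar angle (periodic linear interpolation)."""
    d = contour - center
    ang = np.arctan2(d[:, 1], d[:, 0])
    rad = np.linalg.norm(d, axis=1)
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]
    grid = np.linspace(-np.pi, np.pi, n_bins, endpoint=False)
    ang_ext = np.concatenate([ang - 2 * np.pi, ang, ang + 2 * np.pi])
    rad_ext = np.concatenate([rad, rad, rad])
    return np.interp(grid, ang_ext, rad_ext)


def assemble_network(relaxed: DraftTiling, library: TemplateLibrary,
                     pixel_size: float = 0.55,
                     r_min: float = 0.085,
                     background_threshold: float = 0.02,
                     max_overlap: float = 0.05) -> SpatialTemplate:
    """Warp each placed offspring into its relaxed contour and rasterise.

    The warp is radial, anchored at the contour centroid: a target pixel at
    fraction rho of the final contour radius along angle theta samples the
    offspring AVF at the same (theta, rho) relative to the undeformed
    contour.  Contested pixels (residual contour overlap) go to the lowest
    cell id.  Raises if the residual pairwise overlap area exceeds
    ``max_overlap`` of the mean cell area.
    """
    polys = _contour_polys(relaxed)
    mean_area = np.mean([p.area for p in polys])
    seen = set()
    for i, patch in enumerate(relaxed.patches):
        for j in patch.neighbor_ids:
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            if polys[i].intersection(polys[j]).area > max_overlap * mean_area:
                raise ValueError("unresolved overlaps above tolerance; "
                                 "run relax_boundaries further")
    ex, ey = relaxed.extent
    w = int(round(ex / pixel_size))
    h = int(round(ey / pixel_size))
    r_out = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)

    for cell_id, pl in enumerate(relaxed.placements, start=1):
        off = library.offsprings[pl.offspring_id]
        avf = intensity_to_avf(off.image, r_min=r_min,
                               background_threshold=background_threshold)
        src_px = off.image.pixel_size
        c_fin = pl.contour.mean(axis=0)
        c_src = pl.contour0.mean(axis=0)
        rad_fin = _radius_table(pl.contour, c_fin)
        rad_src = _radius_table(pl.contour0, c_src)
        # bounding box of the final contour in pixels
        x0 = max(0, int(pl.contour[:, 0].min() / pixel_size) - 1)
        x1 = min(w, int(pl.contour[:, 0].max() / pixel_size) + 2)
        y0 = max(0, int(pl.contour[:, 1].min() / pixel_size) - 1)
        y1 = min(h, int(pl.contour[:, 1].max() / pixel_size) + 2)
        if x0 >= x1 or y0 >= y1:
            continue
        # pixel centres at index * pixel_size, matching the hull convention
        yy, xx = np.mgrid[y0:y1, x0:x1]
        px = xx * pixel_size - c_fin[0]
        py = yy * pixel_size - c_fin[1]
        theta = np.arctan2(py, px)
        rho_abs = np.hypot(px, py)
        bins = ((theta + np.pi) / (2 * np.pi) * rad_fin.size).astype(int) \
            % rad_fin.size
        inside = rho_abs <= rad_fin[bins]
        rho = np.where(rad_fin[bins] > 0, rho_abs / np.maximum(rad_fin[bins],
                                                               1e-9), 0.0)
        src_rad = rad_src[bins] * rho
        # contour0 is in placed (translated) coordinates; the offspring
        # image lives in its own frame
        sx = (c_src[0] - pl.translation[0] + src_rad * np.cos(theta)) / src_px
        sy = (c_src[1] - pl.translation[1] + src_rad * np.sin(theta)) / src_px
        from scipy.ndimage import map_coordinates

        sampled = map_coordinates(avf.r, [sy.ravel(), sx.ravel()], order=1,
                                  mode="constant", cval=0.0).reshape(sx.shape)
        keep = inside & (sampled > 0)
        sub_r = r_out[y0:y1, x0:x1]
        sub_l = labels[y0:y1, x0:x1]
        assign = keep & (sub_l == 0)  # contested pixels: lowest id wins
        sub_r[assign] = np.clip(sampled[assign], r_min, 1.0)
        sub_l[assign] = cell_id
    avf_map = AVFMap(r=r_out, pixel_size=pixel_size, r_min=r_min)
    return encode_template(avf_map, labels)
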