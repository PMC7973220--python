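"""Single-astrocyte spatial templates.

An astrocyte is represented on a raster as a fluorescence-like intensity
image.  Normalising intensity by the somatic maximum gives the local
astrocyte volume fraction (AVF, symbol ``r``): the fraction of a pixel's
volume occupied by astrocyte cytosol.  AVF in turn fixes the local
surface-to-volume-ratio (SVR) weight ``s`` that partitions calcium handling
between plasma-membrane fluxes (leaflets, ``s ~ 1``) and ER fluxes
(soma/thick branches, ``s ~ 0``).

Templates are stored as 8-bit RGB rasters: a non-zero blue channel marks
astrocyte-occupied pixels, the red channel encodes AVF as ``round(255*r)``,
and the green channel carries the cell-domain label (0 = extracellular).
A template can therefore be drawn or retouched in any image editor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

__all__ = [
    "IntensityImage",
    "AVFMap",
    "SpatialTemplate",
    "TemplateLibrary",
    "generate_synthetic_astrocyte",
    "augment_image",
    "build_library",
    "intensity_to_avf",
    "avf_to_svr",
    "svr_to_avf",
    "encode_template",
    "decode_template",
    "save_template_png",
    "load_template_png",
    "flatten_stack",
    "downsample",
]

#: default minimal AVF on astrocyte pixels (dimensionless)
R_MIN_DEFAULT = 0.085
#: default intensity fraction below which a pixel is extracellular (class III)
BACKGROUND_THRESHOLD_DEFAULT = 0.02
#: slope constant of the logistic AVF -> SVR link
SVR_SLOPE_DEFAULT = 0.1


@dataclass
class IntensityImage:
    """Grayscale fluorescence-like image of a single astrocyte.

    Parameters
    ----------
    pixels :
        2D array of non-negative intensities (arbitrary units).
    pixel_size :
        Lateral resolution in micrometres per pixel.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("IntensityImage requires a 2D pixel array")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_intensity(self) -> float:
        return float(self.pixels.max())


@dataclass
class AVFMap:
    """Per-pixel astrocyte volume fraction r in {0} | [r_min, 1]."""

    r: np.ndarray
    pixel_size: float
    r_min: float = R_MIN_DEFAULT

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        inside = self.r > 0
        if np.any(self.r[inside] < self.r_min - 1e-12) or np.any(self.r > 1 + 1e-12):
            raise ValueError("astrocyte pixels must satisfy r_min <= r <= 1")

    @property
    def mask(self) -> np.ndarray:
        """Boolean astrocyte-occupied mask."""
        return self.r > 0


@dataclass
class SpatialTemplate:
    """RGB raster template plus cell-domain labels.

    ``rgb`` is a (H, W, 3) uint8 array; blue > 0 on astrocyte pixels, red
    encodes AVF, green holds the domain label (clipped at 255 for display,
    the authoritative labels live in ``domain_labels``).
    """

    rgb: np.ndarray
    domain_labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.uint8)
        self.domain_labels = np.asarray(self.domain_labels, dtype=np.int32)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        if self.domain_labels.shape != self.rgb.shape[:2]:
            raise ValueError("domain_labels shape mismatch")
        blue = self.rgb[:, :, 2] > 0
        if not np.array_equal(blue, self.domain_labels > 0):
            raise ValueError("blue channel and domain labels disagree on the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    @property
    def mask(self) -> np.ndarray:
        return self.rgb[:, :, 2] > 0

    @property
    def n_cells(self) -> int:
        return int(self.domain_labels.max())


@dataclass
class Offspring:
    """A randomized augmentation of a progenitor image."""

    image: IntensityImage
    hull: np.ndarray  # (K, 2) convex-hull vertices in um, CCW
    provenance: dict = field(default_factory=dict)


@dataclass
class TemplateLibrary:
    """Collection of progenitor images and their augmented offsprings."""

    progenitors: list[IntensityImage]
    offsprings: list[Offspring]

    def __len__(self) -> int:
        return len(self.offsprings)

    def manifest(self) -> str:
        """JSON manifest with transform provenance per offspring."""
        return json.dumps(
            [o.provenance for o in self.offsprings], indent=1, sort_keys=True
        )


# ---------------------------------------------------------------------------
# synthetic progenitors


def _stamp_disc(img: np.ndarray, cy: float, cx: float, radius: float,
                value: float) -> None:
    """Paint max(img, value) over a disc; coordinates in pixels."""
    r_i = int(np.ceil(radius))
    y0, y1 = max(0, int(cy) - r_i - 1), min(img.shape[0], int(cy) + r_i + 2)
    x0, x1 = max(0, int(cx) - r_i - 1), min(img.shape[1], int(cx) + r_i + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    sub = img[y0:y1, x0:x1]
    np.maximum(sub, np.where(d2 <= radius**2, value, 0.0), out=sub)


def _random_walk_branch(img, rng, start, direction, length_px, w0, w1, i0, i1,
                        persistence=0.88, step=1.0):
    """Persistent random walk stamping tapering discs; returns visited points."""
    pos = np.array(start, dtype=float)
    ang0 = ang = float(direction)
    pts = []
    n = max(2, int(length_px / step))
    for k in range(n):
        f = k / (n - 1)
        width = w0 + (w1 - w0) * f
        inten = i0 + (i1 - i0) * f
        _stamp_disc(img, pos[0], pos[1], max(width, 0.5), inten)
        pts.append((pos[0], pos[1], f))
        ang = persistence * ang + (1 - persistence) * ang0 + rng.normal(0.0, 0.25)
        pos += step * np.array([np.sin(ang), np.cos(ang)])
        if not (0 <= pos[0] < img.shape[0] and 0 <= pos[1] < img.shape[1]):
            break
    return pts


def generate_synthetic_astrocyte(
    soma_radius: float = 4.0,
    n_primary_branches: int = 5,
    branch_decay: float = 0.85,
    mesh_density: float = 1.0,
    extent: float = 40.0,
    pixel_size: float = 0.275,
    seed: int = 0,
) -> IntensityImage:
    """Procedurally generate a single-astrocyte intensity image.

    The image emulates a max-projected confocal stack of a dye-filled
    astrocyte: a bright, approximately flat soma; tapering primary branches
    drawn as persistent random walks with intensity decaying towards the
    tips; and a dim Gaussian-blurred "gliapil" halo of thin secondary walks
    filling the territory between branches.  After ``intensity_to_avf`` this
    yields the full class I (soma, r = 1) to class II (leaflet mesh,
    r = r_min) continuum.

    Parameters
    ----------
    soma_radius : um
    n_primary_branches : count (0 gives a bare soma disc)
    branch_decay : intensity at the branch tip relative to the soma, in (0, 1)
    mesh_density : relative density of the gliapil walk mesh
    extent : side of the square canvas, um
    pixel_size : um per pixel
    seed : fixes all randomness
    """
    if soma_radius <= 0 or extent <= 0 or pixel_size <= 0:
        raise ValueError("geometry parameters must be positive")
    if n_primary_branches < 0:
        raise ValueError("n_primary_branches must be >= 0")
    if not 0 < branch_decay < 1:
        raise ValueError("branch_decay must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_px = int(round(extent / pixel_size))
    img = np.zeros((n_px, n_px))
    c = (n_px - 1) / 2.0
    soma_px = soma_radius / pixel_size
    _stamp_disc(img, c, c, soma_px, 1.0)

    reach = 0.5 * extent - soma_radius
    branch_points = []
    for b in range(n_primary_branches):
        ang = 2 * np.pi * (b + rng.uniform(-0.25, 0.25)) / n_primary_branches
        start = (c + soma_px * np.sin(ang) * 0.8, c + soma_px * np.cos(ang) * 0.8)
        length = rng.uniform(0.75, 0.98) * reach / pixel_size
        tip_intensity = 1.0 - branch_decay
        pts = _random_walk_branch(
            img, rng, start, ang, length,
            w0=1.4 / pixel_size * 0.5, w1=0.35 / pixel_size,
            i0=1.0, i1=max(tip_intensity, 0.12),
        )
        branch_points.extend((y, x) for (y, x, f) in pts if f > 0.15)

    # secondary processes: medium-intensity walks off the primaries, giving
    # the intermediate part of the class I -> II intensity continuum
    for _ in range(int(mesh_density * 4 * max(n_primary_branches, 1))):
        if not branch_points:
            break
        y0, x0 = branch_points[rng.integers(len(branch_points))]
        ang = rng.uniform(0, 2 * np.pi)
        base = rng.uniform(0.3, 0.6)
        _random_walk_branch(
            img, rng, (y0, x0), ang,
            length_px=rng.uniform(3.0, 9.0) / pixel_size,
            w0=0.9 / pixel_size * 0.5, w1=0.5,
            i0=base, i1=0.4 * base, persistence=0.8,
        )

    # gliapil: thin dim walks seeded on the branches, blurred into a halo
    halo = np.zeros_like(img)
    n_mesh = int(mesh_density * 14 * max(n_primary_branches, 1))
    for _ in range(n_mesh):
        if branch_points:
            y0, x0 = branch_points[rng.integers(len(branch_points))]
        else:
            y0, x0 = c, c
        ang = rng.uniform(0, 2 * np.pi)
        _random_walk_branch(
            halo, rng, (y0, x0), ang,
            length_px=rng.uniform(2.0, 7.0) / pixel_size,
            w0=0.6 / pixel_size * 0.5, w1=0.5,
            i0=1.0, i1=0.5, persistence=0.7,
        )
    halo = ndimage.gaussian_filter(halo, sigma=1.2 / pixel_size)
    if halo.max() > 0:
        halo *= rng.uniform(0.25, 0.35) / halo.max()
    img = np.maximum(img, halo)
    return IntensityImage(pixels=img, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# augmentation


def augment_image(
    img: IntensityImage,
    rotation: float = 0.0,
    shear: float = 0.0,
    stretch_x: float = 1.0,
    stretch_y: float = 1.0,
    order: int = 1,
) -> IntensityImage:
    """Apply rotation (degrees), shear and axis stretches to an image.

    The output canvas is re-fit to the transformed content; interpolation is
    linear and clipped at zero so intensities stay non-negative.
    """
    if img.max_intensity <= 0:
        raise ValueError("cannot augment an empty image")
    from skimage import transform as sktf

    h, w = img.shape
    center = np.array([w, h]) / 2.0
    tf = (
        sktf.AffineTransform(translation=-center)
        + sktf.AffineTransform(
            rotation=np.deg2rad(rotation),
            shear=shear,
            scale=(stretch_x, stretch_y),
        )
        + sktf.AffineTransform(translation=center)
    )
    # re-fit canvas: transform the corners, pad to the new bounding box
    corners = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
    warped_corners = tf(corners)
    mins = warped_corners.min(axis=0)
    maxs = warped_corners.max(axis=0)
    out_w = int(np.ceil(maxs[0] - mins[0]))
    out_h = int(np.ceil(maxs[1] - mins[1]))
    shift = sktf.AffineTransform(translation=-mins)
    out = sktf.warp(
        img.pixels, (tf + shift).inverse, output_shape=(out_h, out_w),
        order=order, mode="constant", cval=0.0, preserve_range=True,
    )
    return IntensityImage(pixels=np.clip(out, 0.0, None), pixel_size=img.pixel_size)


def _mask_hull(img: IntensityImage, threshold: float) -> np.ndarray:
    """Convex hull (in um, (x, y) CCW) of the suprathreshold mask."""
    mask = img.pixels > threshold * img.max_intensity
    ys, xs = np.nonzero(mask)
    if len(xs) < 3:
        raise ValueError("mask too small for a convex hull")
    pts = np.column_stack([xs, ys]).astype(float) * img.pixel_size
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def build_library(
    progenitors: Sequence[IntensityImage],
    n_augment: int,
    rotation_range: tuple[float, float] = (0.0, 360.0),
    shear_range: tuple[float, float] = (-0.2, 0.2),
    stretch_range: tuple[float, float] = (0.8, 1.2),
    mask_threshold: float = BACKGROUND_THRESHOLD_DEFAULT,
    seed: int = 0,
) -> TemplateLibrary:
    """Expand progenitors into a library of randomized offsprings.

    Each progenitor receives ``n_augment`` independent random rotations,
    shears and stretches (uniform within the given bounds, defaults: full
    rotation, +/-20% stretch).  Every offspring stores the convex hull of
    its astrocyte mask and the transform parameters used.
    """
    progenitors = list(progenitors)
    if not progenitors:
        raise ValueError("at least one progenitor required")
    if n_augment < 1:
        raise ValueError("n_augment must be >= 1")
    rng = np.random.default_rng(seed)
    offsprings: list[Offspring] = []
    for ip, prog in enumerate(progenitors):
        for k in range(n_augment):
            params = dict(
                progenitor=ip,
                rotation=float(rng.uniform(*rotation_range)),
                shear=float(rng.uniform(*shear_range)),
                stretch_x=float(rng.uniform(*stretch_range)),
                stretch_y=float(rng.uniform(*stretch_range)),
            )
            child = augment_image(
                prog,
                rotation=params["rotation"],
                shear=params["shear"],
                stretch_x=params["stretch_x"],
                stretch_y=params["stretch_y"],
            )
            hull = _mask_hull(child, mask_threshold)
            offsprings.append(Offspring(image=child, hull=hull, provenance=params))
    return TemplateLibrary(progenitors=progenitors, offsprings=offsprings)


# ---------------------------------------------------------------------------
# AVF / SVR


def intensity_to_avf(
    img: IntensityImage,
    r_min: float = R_MIN_DEFAULT,
    background_threshold: float = BACKGROUND_THRESHOLD_DEFAULT,
) -> AVFMap:
    """Map fluorescence intensity to astrocyte volume fraction.

    Astrocyte pixels (``I/I_max > background_threshold``) receive
    ``r = max(I/I_max, r_min)``; all other pixels are extracellular (r = 0).
    """
    if not 0 < r_min < 1:
        raise ValueError("r_min must lie in (0, 1)")
    if not 0 <= background_threshold < r_min:
        raise ValueError("background_threshold must lie in [0, r_min)")
    if img.max_intensity <= 0:
        raise ValueError("all-zero image has no astrocyte")
    rel = img.pixels / img.max_intensity
    r = np.where(rel > background_threshold, np.maximum(rel, r_min), 0.0)
    return AVFMap(r=r, pixel_size=img.pixel_size, r_min=r_min)


def avf_to_svr(r, slope: float = SVR_SLOPE_DEFAULT):
    """SVR weight s as a decreasing logistic function of AVF.

    ``s = 1 / (1 + exp[(r - 0.5)/slope])``: s ~ 1 in the leaflet mesh
    (r = r_min), s = 0.5 at r = 0.5 and s ~ 0 in the soma (r = 1).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0) or np.any(r_arr > 1):
        raise ValueError("r must lie in (0, 1]")
    s = 1.0 / (1.0 + np.exp((r_arr - 0.5) / slope))
    return s if isinstance(r, np.ndarray) else float(s)

def svr_to_avf(s, slope: float = SVR_SLOPE_DEFAULT):
    """Inverse of :func:`avf_to_svr` on (0, 1)."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr <= 0) or np.any(s_arr >= 1):
        raise ValueError("s must lie in (0, 1)")
    r = 0.5 + slope * np.log(1.0 / s_arr - 1.0)
    return r if isinstance(s, np.ndarray) else float(r)


# ---------------------------------------------------------------------------
# template encode/decode and I/O


def encode_template(avf: AVFMap, domain_labels: np.ndarray | None = None) -> SpatialTemplate:
    """Encode an AVF map (and optional labels) as an RGB raster template."""
    r = avf.r
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("r values outside [0, 1]")
    if domain_labels is None:
        domain_labels = (r > 0).astype(np.int32)
    domain_labels = np.asarray(domain_labels, dtype=np.int32)
    if domain_labels.shape != r.shape:
        raise ValueError("domain_labels shape mismatch")
    if not np.array_equal(domain_labels > 0, r > 0):
        raise ValueError("labels must cover exactly the astrocyte mask")
    rgb = np.zeros(r.shape + (3,), dtype=np.uint8)
    rgb[:, :, 0] = np.round(255.0 * r).astype(np.uint8)
    rgb[:, :, 2] = np.where(r > 0, 255, 0).astype(np.uint8)
    rgb[:, :, 1] = np.clip(domain_labels, 0, 255).astype(np.uint8)
    return SpatialTemplate(rgb=rgb, domain_labels=domain_labels,
                           pixel_size=avf.pixel_size)


def decode_template(template: SpatialTemplate,
                    r_min: float = R_MIN_DEFAULT) -> tuple[AVFMap, np.ndarray]:
    """Decode an RGB template back to (AVFMap, domain_labels).

    Round trip through :func:`encode_template` reproduces r within the
    8-bit quantization error of 1/255; decoded astrocyte values below
    ``r_min`` (quantization of r_min itself) are clipped up to ``r_min``.
    """
    mask = template.rgb[:, :, 2] > 0
    r = template.rgb[:, :, 0].astype(float) / 255.0
    r = np.where(mask, np.maximum(r, r_min), 0.0)
    return (
        AVFMap(r=r, pixel_size=template.pixel_size, r_min=r_min),
        template.domain_labels.copy(),
    )


def save_template_png(template: SpatialTemplate, path) -> None:
    """Write the template as a lossless RGB PNG (bit-exact round trip)."""
    import imageio.v3 as iio

    iio.imwrite(str(path), template.rgb, extension=".png")


def load_template_png(path, pixel_size: float) -> SpatialTemplate:
    """Read an RGB PNG template; green channel is taken as domain labels."""
    import imageio.v3 as iio

    rgb = np.asarray(iio.imread(str(path)))
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("template PNG must be RGB")
    rgb = rgb[:, :, :3].astype(np.uint8)
    labels = rgb[:, :, 1].astype(np.int32)
    labels[rgb[:, :, 2] == 0] = 0
    # blue without a label: single unnamed cell
    labels[(rgb[:, :, 2] > 0) & (labels == 0)] = labels.max() + 1 if labels.max() else 1
    return SpatialTemplate(rgb=rgb, domain_labels=labels, pixel_size=pixel_size)


def flatten_stack(stack: np.ndarray, pixel_size: float) -> IntensityImage:
    """Max-project a 3D (Z, Y, X) stack into a 2D intensity image."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return IntensityImage(pixels=stack, pixel_size=pixel_size)
    if stack.ndim != 3:
        raise ValueError("expected a 2D image or 3D stack")
    return IntensityImage(pixels=stack.max(axis=0), pixel_size=pixel_size)


def downsample(img: IntensityImage, factor: int = 4) -> IntensityImage:
    """Downsample by an integer factor using block max.

    Block max (rather than mean) preserves thin processes whose width falls
    below the output pixel size.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    h, w = img.shape
    hh, ww = h // factor * factor, w // factor * factor
    blocks = img.pixels[:hh, :ww].reshape(hh // factor, factor, ww // factor, factor)
    return IntensityImage(pixels=blocks.max(axis=(1, 3)),
                          pixel_size=img.pixel_size * factor)
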