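"""Network-level pattern analyses and template perturbations.

Cell domains act as large regions of interest: domain-averaged Ca2+/IP3
traces, spike detection, spike-triggered averages (STA) and a patch-based
repeatability score quantifying how stereotypically activity in one place
is followed by activity elsewhere.  Template perturbations (unlinking cells
from the gap-junction network, flattening the AVF landscape inside a
region, ablating cell content) probe how morphology shapes these patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import SpatialTemplate, decode_template, encode_template

__all__ = ["CellTrace", "RepeatabilityMap", "cellwise_traces",
           "activity_fraction_map", "detect_spikes",
           "spike_triggered_average", "repeatability_score",
           "perturb_template", "unlink_cells", "flatten_avf", "ablate_region"]


@dataclass
class CellTrace:
    """Domain-averaged time series for one cell."""

    cell_id: int
    times: np.ndarray
    ca: np.ndarray
    ip3: np.ndarray
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))


def detect_spikes(trace: np.ndarray, times: np.ndarray, threshold: float,
                  refractory: float = 5.0) -> np.ndarray:
    """Upward threshold crossings, merged within a refractory window (s)."""
    above = trace > threshold
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if idx.size == 0:
        return np.empty(0)
    out = [times[idx[0]]]
    for i in idx[1:]:
        if times[i] - out[-1] > refractory:
            out.append(times[i])
    return np.array(out)


def cellwise_traces(recording, spike_threshold: float = 0.5,
                    weight: str = "avf", refractory: float = 5.0
                    ) -> list[CellTrace]:
    """One AVF-weighted mean trace per cell domain, with detected spikes.

    ``weight='avf'`` weights each pixel by its astrocyte volume fraction (a
    half-filled pixel contributes half); ``weight='plain'`` uses the
    unweighted mean.
    """
    grid = recording.grid
    labels = grid.cell_labels
    ca = recording.fields["ca_c"]
    ip3 = recording.fields["ip3"]
    w = grid.r if weight == "avf" else np.ones_like(grid.r)
    traces = []
    for cell in np.unique(labels[labels > 0]):
        sel = labels == cell
        ws = w[sel] / w[sel].sum()
        tca = ca[:, sel] @ ws
        tip = ip3[:, sel] @ ws
        traces.append(CellTrace(
            cell_id=int(cell), times=recording.times, ca=tca, ip3=tip,
            spike_times=detect_spikes(tca, recording.times, spike_threshold,
                                      refractory),
        ))
    return traces


def activity_fraction_map(recording, level: float = 0.1) -> np.ndarray:
    """Fraction of recorded frames with Ca2+ above ``level``, per pixel.

    Returns a dense (H, W) map; NaN outside the astrocyte mask.
    """
    ca = recording.fields["ca_c"]
    if ca.shape[0] == 0:
        raise ValueError("empty recording")
    frac = (ca > level).mean(axis=0)
    out = np.full(recording.grid.shape, np.nan)
    out.reshape(-1)[recording.grid.mask_idx] = frac
    return out


def spike_triggered_average(raster: np.ndarray, times: np.ndarray,
                            spike_times: np.ndarray, window: float,
                            center: bool = True):
    """Average of spike-aligned windows of a (T, n_roi) raster.

    Windows of ``window`` seconds are placed around each spike (centred by
    default); windows truncated by the recording edges are dropped.
    Returns (averaged (W, n_roi) raster, number of contributing windows).
    """
    if spike_times.size == 0:
        raise ValueError("seed has no spikes")
    dt = times[1] - times[0]
    w = int(round(window / dt))
    if w < 1 or w > len(times):
        raise ValueError("window does not fit the recording")
    half = w // 2 if center else 0
    acc = np.zeros((w,) + raster.shape[1:])
    n = 0
    for ts in spike_times:
        i = int(round((ts - times[0]) / dt)) - half
        if i < 0 or i + w > raster.shape[0]:
            continue
        acc += raster[i:i + w]
        n += 1
    if n == 0:
        raise ValueError("no complete spike window inside the recording")
    return acc / n, n


@dataclass
class RepeatabilityMap:
    """Per-pixel stereotyped-activation score in [0, 1].

    NaN where no qualifying patch covers the pixel.  ``patch_scores`` maps
    patch index -> score for the qualifying patches.
    """

    score: np.ndarray
    patch_size: float
    stride: float
    min_spikes: int
    spike_level: float
    point_level: float
    window: float
    patch_scores: dict = field(default_factory=dict)
    patch_boxes: list = field(default_factory=list)


def repeatability_score(recording, patch: float = 5.0, stride: float = 2.5,
                        min_spikes: int = 10, spike_level: float = 0.5,
                        window: float = 50.0, point_level: float = 0.2,
                        refractory: float = 5.0) -> RepeatabilityMap:
    """Patch-based repeatability of downstream activation.

    The template is tiled with overlapping square patches (``patch`` um,
    50% overlap by default); each patch's mean Ca2+ trace is scanned for
    spikes reaching ``spike_level``.  For every patch with more than
    ``min_spikes`` spikes, windows of ``window`` seconds around its spikes
    are averaged over the raster of *all* patches, and the fraction of
    points of that averaged raster exceeding ``point_level`` is the patch's
    repeatability score.  Scores are projected back to pixels, averaging
    over overlapping patches; an empty map (all NaN) is returned when no
    patch qualifies.
    """
    grid = recording.grid
    dx = grid.dx
    p_px = max(1, int(round(patch / dx)))
    s_px = max(1, int(round(stride / dx)))
    h, w = grid.shape
    mask = grid.mask
    dense = recording.dense("ca_c")

    boxes = []
    for y0 in range(0, max(h - p_px, 0) + 1, s_px):
        for x0 in range(0, max(w - p_px, 0) + 1, s_px):
            sub = mask[y0:y0 + p_px, x0:x0 + p_px]
            if sub.any():
                boxes.append((y0, x0))
    if not boxes:
        raise ValueError("no patches overlap the astrocyte mask")

    raster = np.empty((dense.shape[0], len(boxes)))
    for k, (y0, x0) in enumerate(boxes):
        sub_mask = mask[y0:y0 + p_px, x0:x0 + p_px]
        sub = dense[:, y0:y0 + p_px, x0:x0 + p_px]
        raster[:, k] = sub[:, sub_mask].mean(axis=1)

    times = recording.times
    patch_scores: dict[int, float] = {}
    for k in range(len(boxes)):
        spikes = detect_spikes(raster[:, k], times, spike_level, refractory)
        if spikes.size <= min_spikes:
            continue
        try:
            sta, _ = spike_triggered_average(raster, times, spikes, window)
        except ValueError:
            continue
        patch_scores[k] = float((sta > point_level).mean())

    score = np.full((h, w), np.nan)
    counts = np.zeros((h, w))
    acc = np.zeros((h, w))
    for k, sc in patch_scores.items():
        y0, x0 = boxes[k]
        acc[y0:y0 + p_px, x0:x0 + p_px] += sc
        counts[y0:y0 + p_px, x0:x0 + p_px] += 1
    covered = counts > 0
    score[covered] = acc[covered] / counts[covered]
    return RepeatabilityMap(
        score=score, patch_size=patch, stride=stride, min_spikes=min_spikes,
        spike_level=spike_level, point_level=point_level, window=window,
        patch_scores=patch_scores, patch_boxes=boxes,
    )


# ---------------------------------------------------------------------------
# template perturbations


def unlink_cells(template: SpatialTemplate, params, cells) -> "CompiledGrid":
    """Compile the template with the given cells severed from the
    gap-junction (Ca2+/IP3) network; glutamate diffusion is untouched."""
    from .solver import compile as _compile

    missing = set(int(c) for c in cells) - set(
        np.unique(template.domain_labels[template.domain_labels > 0]).tolist())
    if missing:
        raise ValueError(f"cells not present in template: {sorted(missing)}")
    return _compile(template, params, severed_cells=frozenset(cells))


def flatten_avf(template: SpatialTemplate, region: np.ndarray,
                r_min: float | None = None) -> SpatialTemplate:
    """Replace the AVF inside ``region`` (bool mask) by its regional mean."""
    if region.shape != template.shape:
        raise ValueError("region shape mismatch")
    avf, labels = decode_template(template)
    sel = region & (avf.r > 0)
    if not sel.any():
        raise ValueError("region contains no astrocyte pixels")
    r = avf.r.copy()
    r[sel] = r[sel].mean()
    avf.r = r
    return encode_template(avf, labels)


def ablate_region(template: SpatialTemplate, region: np.ndarray
                  ) -> SpatialTemplate:
    """Remove cell content inside ``region``: pixels become extracellular."""
    if region.shape != template.shape:
        raise ValueError("region shape mismatch")
    avf, labels = decode_template(template)
    r = avf.r.copy()
    r[region] = 0.0
    labels = labels.copy()
    labels[region] = 0
    avf.r = r
    return encode_template(avf, labels)


def perturb_template(template: SpatialTemplate, mode: str, *, params=None,
                     cells=None, region=None):
    """Dispatch to one of the three template perturbations.

    mode='unlink' (requires params, cells) -> CompiledGrid;
    mode='flatten_avf' / 'ablate' (require region) -> SpatialTemplate.
    """
    if mode == "unlink":
        return unlink_cells(template, params, cells)
    if mode == "flatten_avf":
        return flatten_avf(template, region)
    if mode == "ablate":
        return ablate_region(template, region)
    raise ValueError(f"unknown perturbation mode {mode!r}")
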