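"""Discrete Ca2+ events and their statistics.

A Ca2+ event is a contiguous suprathreshold component of the recorded
TXY movie: pixels whose cytosolic Ca2+ exceeds the local baseline by a
relative threshold (default 25%), grouped by 26-connectivity in (t, y, x).
Event area is the spatial footprint (union over time) times the pixel
area; duration is frame-inclusive at the recording stride.

Size and duration statistics are summarised by complementary cumulative
distribution functions (CCDF, survival functions).  A power-law PDF
``P(x) ~ x^-alpha`` appears in the CCDF as a straight line of slope
``-(alpha - 1)`` in log-log coordinates; slopes are fitted by least squares
over a configurable window, by default the 10th-90th percentile of the
sample, which excludes the whole-cell saturation bend at large areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["CaEvent", "EventCatalog", "CCDFCurve", "baseline_map",
           "detect_events", "classify_events", "ccdf", "fit_slope",
           "initiation_map", "peak_delay_map"]


@dataclass
class CaEvent:
    """One contiguous suprathreshold TXY component."""

    label: int
    t_slice: slice              # frame range (bounding box)
    bbox: tuple[slice, slice]   # spatial bounding box
    footprint: np.ndarray       # 2D bool, spatial union over time (in bbox)
    n_voxels: int
    area_um2: float
    duration_s: float
    onset_s: float
    init_pixels: np.ndarray     # (k, 2) array of (y, x) in full-frame coords
    peak_times: np.ndarray      # 2D float (in bbox), NaN outside footprint

    @property
    def initiation_site(self) -> tuple[float, float]:
        """Centroid (y, x) of the first-frame suprathreshold pixels."""
        return tuple(self.init_pixels.mean(axis=0))


@dataclass
class EventCatalog:
    """All events of one recording plus the detection settings used."""

    events: list[CaEvent]
    rel_threshold: float
    connectivity: int
    baseline: np.ndarray        # per-mask-pixel baseline, uM
    frame_dt: float
    pixel_size: float
    source: str = ""

    def __len__(self) -> int:
        return len(self.events)

    @property
    def areas(self) -> np.ndarray:
        return np.array([e.area_um2 for e in self.events])

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration_s for e in self.events])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for e in self.events:
            cy, cx = e.initiation_site
            rows.append(dict(id=e.label, onset_s=e.onset_s,
                             duration_s=e.duration_s, area_um2=e.area_um2,
                             n_voxels=e.n_voxels, init_y=cy, init_x=cx))
        return pd.DataFrame(rows)


def baseline_map(recording, method: str = "percentile",
                 percentile: float = 20.0) -> np.ndarray:
    """Per-pixel baseline Ca2+ over the recorded (post-burn-in) frames.

    The default estimator is the temporal 20th percentile, robust to sparse
    transients of low duty cycle.  Alternatives: "median", or
    "burn_state" (the state at the end of the burn-in).
    """
    ca = recording.fields["ca_c"]
    if ca.shape[0] < 2:
        raise ValueError("recording too short for a baseline")
    if method == "percentile":
        base = np.percentile(ca, percentile, axis=0)
    elif method == "median":
        base = np.median(ca, axis=0)
    elif method == "burn_state":
        if recording.burn_state is None:
            raise ValueError("recording carries no burn-in state")
        base = recording.burn_state[0]
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    if np.any(base <= 0):
        raise ValueError("baseline must be strictly positive on astrocyte pixels")
    return np.asarray(base, dtype=float)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def detect_events(recording, baseline: np.ndarray | None = None,
                  rel_threshold: float = 0.25, connectivity: int = 26,
                  min_voxels: int = 1) -> EventCatalog:
    """Threshold the movie at ``(1 + rel_threshold) * baseline`` and label
    contiguous TXY components as discrete events.

    The decomposition partitions the suprathreshold voxel set; detection is
    invariant to uniform rescaling of recording and baseline together.
    """
    if rel_threshold <= -1:
        raise ValueError("rel_threshold must exceed -1")
    if baseline is None:
        baseline = baseline_map(recording)
    ca = recording.fields["ca_c"]
    if baseline.shape != (ca.shape[1],):
        raise ValueError("baseline computed on a different grid")
    grid = recording.grid
    supra_flat = ca > (1.0 + rel_threshold) * baseline[None, :]
    movie = np.zeros((ca.shape[0], *grid.shape), dtype=bool)
    movie.reshape(ca.shape[0], -1)[:, grid.mask_idx] = supra_flat

    labels, n = ndimage.label(movie, structure=_structure(connectivity))
    frame_dt = recording.frame_dt
    dx = grid.dx
    dense_ca = None
    events: list[CaEvent] = []
    slices = ndimage.find_objects(labels)
    if n and dense_ca is None:
        dense_ca = recording.dense("ca_c")
    times = recording.times
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        tsl, ysl, xsl = sl
        sub = labels[sl] == lab
        nvox = int(sub.sum())
        if nvox < min_voxels:
            continue
        footprint = sub.any(axis=0)
        area = float(footprint.sum()) * dx**2
        duration = (tsl.stop - tsl.start) * frame_dt
        first = sub[0]
        iy, ix = np.nonzero(first)
        init = np.column_stack([iy + ysl.start, ix + xsl.start])
        sub_ca = np.where(sub, dense_ca[sl], -np.inf)
        peak_idx = sub_ca.argmax(axis=0).astype(float)
        peak_t = times[tsl.start] + peak_idx * frame_dt
        peak_t[~footprint] = np.nan
        events.append(CaEvent(
            label=lab, t_slice=tsl, bbox=(ysl, xsl), footprint=footprint,
            n_voxels=nvox, area_um2=area, duration_s=duration,
            onset_s=float(times[tsl.start]), init_pixels=init,
            peak_times=peak_t,
        ))
    return EventCatalog(events=events, rel_threshold=rel_threshold,
                        connectivity=connectivity, baseline=baseline,
                        frame_dt=frame_dt, pixel_size=dx)


def classify_events(catalog: EventCatalog, cell_area: float,
                    cutoff: float = 0.25):
    """Split events into (large, small) by footprint relative to cell area.

    "Large" events cover more than ``cutoff`` (default 25%) of the cell
    area; an event covering exactly the full cell is large.
    """
    if cell_area <= 0:
        raise ValueError("cell area must be positive")
    large = [e for e in catalog.events if e.area_um2 / cell_area > cutoff]
    small = [e for e in catalog.events if e.area_um2 / cell_area <= cutoff]
    return large, small


@dataclass
class CCDFCurve:
    """Empirical survival function with an optional log-log line fit."""

    x: np.ndarray              # sorted sample values
    survival: np.ndarray       # P[X >= x_k], from 1 down to 1/n
    fit_window: tuple[float, float] | None = None
    slope: float | None = None        # CCDF exponent (positive)
    intercept: float | None = None

    @property
    def pdf_exponent(self) -> float | None:
        """Implied power-law PDF exponent alpha = slope + 1."""
        return None if self.slope is None else self.slope + 1.0

    def evaluate(self, x) -> np.ndarray:
        """Exact empirical P[X > x]."""
        n = self.x.size
        return (n - np.searchsorted(self.x, np.atleast_1d(x), side="right")) / n


def ccdf(samples) -> CCDFCurve:
    """Empirical CCDF of a sample (plotted at sample points as P[X >= x])."""
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    n = x.size
    surv = (n - np.arange(n)) / n
    return CCDFCurve(x=x, survival=surv)


def fit_slope(curve: CCDFCurve, window: tuple[float, float] | None = None
              ) -> float:
    """Least-squares log-log line through the CCDF inside ``window``.

    Default window: 10th to 90th percentile of the positive sample values,
    excluding both the discreteness floor and the whole-cell saturation
    bend.  Returns the (positive) CCDF slope and stores it, the intercept
    and the window on the curve.
    """
    pos = curve.x[curve.x > 0]
    if pos.size == 0:
        raise ValueError("log-log fit requires positive samples")
    if window is None:
        window = (float(np.percentile(pos, 10)), float(np.percentile(pos, 90)))
    lo, hi = window
    # one point per distinct sample value (the survival step locations);
    # repeated values would otherwise enter as vertical tie columns and
    # bias the least-squares slope towards zero
    ux, first = np.unique(curve.x, return_index=True)
    us = curve.survival[first]
    sel = (ux >= lo) & (ux <= hi) & (ux > 0)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 CCDF points in the fit window")
    lx = np.log10(ux[sel])
    ly = np.log10(us[sel])
    coef = np.polyfit(lx, ly, 1)
    curve.fit_window = (lo, hi)
    curve.slope = float(-coef[0])
    curve.intercept = float(coef[1])
    return curve.slope


def initiation_map(catalog: EventCatalog, top_n: int = 25):
    """Initiation sites and max-span contours of the ``top_n`` largest events.

    Returns a list (largest first) of dicts with the event, its first-frame
    pixel set and the contour(s) of its temporal-union footprint in
    full-frame pixel coordinates.
    """
    if not catalog.events:
        raise ValueError("catalog is empty")
    from skimage import measure

    order = np.argsort([-e.area_um2 for e in catalog.events])
    out = []
    for k in order[:top_n]:
        e = catalog.events[k]
        padded = np.pad(e.footprint.astype(float), 1)
        contours = [c + [[e.bbox[0].start - 1, e.bbox[1].start - 1]]
                    for c in measure.find_contours(padded, 0.5)]
        out.append(dict(event=e, init_pixels=e.init_pixels, contours=contours))
    return out


def peak_delay_map(event: CaEvent, recording) -> np.ndarray:
    """Per-pixel delay (s) of the Ca2+ peak relative to the initiation site.

    The reference is the pixel nearest the centroid of the first
    suprathreshold frame; its delay is exactly 0.  Pixels outside the event
    footprint are NaN.  Returned in full-frame coordinates.
    """
    if event.t_slice.stop - event.t_slice.start < 2:
        raise ValueError("event must span at least 2 frames")
    cy, cx = event.initiation_site
    d2 = (event.init_pixels[:, 0] - cy) ** 2 + (event.init_pixels[:, 1] - cx) ** 2
    ry, rx = event.init_pixels[np.argmin(d2)]
    ref_t = event.peak_times[ry - event.bbox[0].start, rx - event.bbox[1].start]
    out = np.full(recording.grid.shape, np.nan)
    out[event.bbox] = event.peak_times - ref_t
    return out
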