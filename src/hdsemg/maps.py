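"""Activation maps: per-epoch RMS images, averaging, interpolation, h-dome
segmentation and the normalized anatomical reference system.

An activation map (AM) is the 2-D image whose pixel (i, j) is the RMS of the
monopolar signal at electrode row i, column j over one epoch (500 ms, 1024
samples at 2048 Hz). Maps for analysis average six consecutive non-overlapping
epochs (3 s), taken from the most torque-stable interval of the contraction.
Active areas are segmented with an h-dome transformation (grayscale geodesic
reconstruction), which discards low-intensity areas and, on the forearm
array, separates the three muscle regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from skimage.morphology import reconstruction

from .grids import ElectrodeGrid

__all__ = ["ActivationMap", "SegmentedRegions", "compute_am", "average_maps",
           "interpolate_map", "hdome", "hdome_segment", "segment_for_muscles",
           "to_reference_coords"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class ActivationMap:
    """Non-negative rows x cols RMS image with provenance.

    ``x_axis``/``y_axis`` are electrode coordinates; after
    :func:`to_reference_coords` they are fractions of the limb circumference
    (x) and segment length (y), with ``origin`` marking the anatomical
    reference point in those coordinates.
    """
    values: np.ndarray
    grid: ElectrodeGrid | None = None
    epoch_start: int | None = None
    epoch_length: int | None = None
    x_axis: np.ndarray | None = None
    y_axis: np.ndarray | None = None
    origin: tuple[float, float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activation map must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("activation map values must be non-negative")
        if self.grid is not None and self.values.shape != self.grid.shape:
            raise ValueError("map shape must equal grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SegmentedRegions:
    """Disjoint region masks labeled by muscle, from one h-dome segmentation."""
    masks: dict  # muscle/label -> boolean mask
    h: float
    dome: np.ndarray | None = None
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        total = None
        for name, m in self.masks.items():
            m = np.asarray(m, bool)
            if not m.any():
                raise ValueError(f"region {name!r} is empty")
            total = m.astype(int) if total is None else total + m
        if total is not None and (total > 1).any():
            raise ValueError("region masks must be disjoint")

    @property
    def pixel_counts(self) -> dict:
        return {name: int(np.sum(m)) for name, m in self.masks.items()}


def compute_am(grid_epoch_signals: np.ndarray, n_samples: int | None = None,
               grid: ElectrodeGrid | None = None,
               epoch_start: int | None = None) -> ActivationMap:
    """RMS per electrode over one epoch: input (rows, cols, n_samples)."""
    x = np.asarray(grid_epoch_signals, dtype=float)
    if x.ndim != 3 or x.shape[-1] < 1:
        raise ValueError("expected a non-empty (rows, cols, samples) epoch")
    if n_samples is not None and x.shape[-1] != n_samples:
        raise ValueError(f"epoch has {x.shape[-1]} samples, expected {n_samples}")
    return ActivationMap(values=np.sqrt(np.mean(x**2, axis=-1)), grid=grid,
                         epoch_start=epoch_start, epoch_length=x.shape[-1])


def average_maps(maps: list[ActivationMap]) -> ActivationMap:
    """Pixel-wise arithmetic mean of consecutive maps (typically six)."""
    if not maps:
        raise ValueError("need at least one map to average")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("maps to average must share their shape")
    values = np.mean([m.values for m in maps], axis=0)
    first = maps[0]
    return ActivationMap(values=values, grid=first.grid,
                         epoch_start=first.epoch_start,
                         epoch_length=sum(m.epoch_length or 0 for m in maps) or None)


def interpolate_map(am: ActivationMap, factor: int = 100) -> ActivationMap:
    """Smooth-spline upsampling for display, clipped at zero.

    Output shape is ((rows-1)*factor + 1, (cols-1)*factor + 1) so the
    original electrode sites fall exactly on output pixels (an interpolating
    spline preserves their values).
    """
    if factor < 1:
        raise ValueError("interpolation factor must be >= 1")
    v = am.values
    if factor == 1:
        return ActivationMap(values=v.copy(), grid=am.grid,
                             epoch_start=am.epoch_start,
                             epoch_length=am.epoch_length)
    r, c = v.shape
    spl = RectBivariateSpline(np.arange(r), np.arange(c), v,
                              kx=min(3, r - 1), ky=min(3, c - 1))
    fy = np.linspace(0, r - 1, (r - 1) * factor + 1)
    fx = np.linspace(0, c - 1, (c - 1) * factor + 1)
    out = np.clip(spl(fy, fx), 0.0, None)
    return ActivationMap(values=out, epoch_start=am.epoch_start,
                         epoch_length=am.epoch_length)


def hdome(values: np.ndarray, h: float) -> np.ndarray:
    """h-dome transform: domes of ``values`` taller than ``h``.

    D = values - geodesic_reconstruction(values - h under values); satisfies
    0 <= D <= h, with D = 0 outside peaks.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    v = np.asarray(values, dtype=float)
    rec = reconstruction(v - h, v, method="dilation")
    return v - rec


def hdome_segment(am: ActivationMap, h: float | None = None, *,
                  alpha: float = 0.2, min_pixels: int = 2,
                  dome_floor: float = 0.25,
                  reference_x: dict | None = None,
                  eps: float = 1e-12) -> SegmentedRegions:
    """Segment the active (highest-intensity) areas of a map.

    ``h`` defaults to ``alpha * (max - min)`` of the map, a scale-free choice
    that behaves consistently across effort levels. Regions are 8-connected
    components of the positive dome. Low-intensity areas are discarded:
    components smaller than ``min_pixels``, or whose dome prominence is
    below ``dome_floor * h`` (a genuine peak taller than h reaches dome
    height h exactly, while noise bumps stay far below it), are dropped and
    logged. With ``reference_x`` (muscle -> column of its anatomical
    reference), each component is assigned to the muscle whose reference
    column is nearest its centroid — components sharing a muscle are merged
    — so a forearm map yields at most three labeled regions.
    """
    v = am.values
    if h is None:
        h = alpha * float(v.max() - v.min())
        if h <= 0:  # constant map: no dome exceeds any h
            return SegmentedRegions(masks={}, h=0.0, dome=np.zeros_like(v))
    dome = hdome(v, h)
    labeled, n = ndimage.label(dome > eps, structure=_EIGHT)
    masks: dict = {}
    dropped = []
    comps = []
    for lab in range(1, n + 1):
        m = labeled == lab
        prominence = float(dome[m].max())
        if m.sum() < min_pixels or prominence < dome_floor * h:
            dropped.append({"pixels": int(m.sum()), "prominence": prominence})
            continue
        comps.append(m)
    if reference_x is None:
        for i, m in enumerate(comps):
            masks[f"region_{i}"] = m
    else:
        order = sorted(reference_x)  # deterministic tie-break: lexicographic
        for m in comps:
            cols = np.nonzero(m)[1]
            centroid_x = float(np.mean(cols))
            muscle = min(order,
                         key=lambda k: (abs(reference_x[k] - centroid_x), order.index(k)))
            masks[muscle] = masks.get(muscle, np.zeros_like(m)) | m
    return SegmentedRegions(masks=masks, h=float(h), dome=dome, dropped=dropped)


def segment_for_muscles(am: ActivationMap, muscle_cols: dict, *,
                        h: float | None = None, alpha: float = 0.2,
                        min_pixels: int = 2, strict: bool = True
                        ) -> SegmentedRegions:
    """h-dome segmentation dividing the map into one region per muscle.

    The positive dome (active area) is intersected with each muscle's
    column band — the columns nearer its anatomical reference column than
    any other muscle's — so a dome bridging two overlapping muscles is cut
    at their midline instead of being attributed wholesale to one of them.
    With ``strict=True`` a muscle whose band holds no dome raises. With
    ``strict=False`` (used for feature extraction at low effort, where a
    weakly active muscle may contribute no dome) the missing muscle falls
    back to a 3x3 patch around the map maximum inside its band, trimmed to
    stay disjoint from already-assigned regions.
    """
    seg = hdome_segment(am, h=h, alpha=alpha, min_pixels=min_pixels)
    v = am.values
    rows, cols = v.shape
    active = np.zeros((rows, cols), dtype=bool)
    for m in seg.masks.values():
        active |= m
    bounds = _column_bands(muscle_cols, cols)
    masks: dict = {}
    missing = []
    for muscle, (lo, hi) in bounds.items():
        band = np.zeros((rows, cols), dtype=bool)
        band[:, lo:hi] = True
        region = active & band
        if region.any():
            masks[muscle] = region
        else:
            missing.append(muscle)
    if missing and strict:
        raise ValueError(f"no segmented region for muscle(s): {missing}")
    taken = np.zeros((rows, cols), dtype=bool)
    for m in masks.values():
        taken |= m
    for muscle in missing:
        lo, hi = bounds[muscle]
        band = np.full_like(v, -np.inf)
        band[:, lo:hi] = v[:, lo:hi]
        band[taken] = -np.inf
        r0, c0 = np.unravel_index(int(np.argmax(band)), v.shape)
        patch = np.zeros((rows, cols), dtype=bool)
        patch[max(0, r0 - 1):r0 + 2, max(0, c0 - 1):c0 + 2] = True
        patch &= ~taken
        masks[muscle] = patch
        taken |= patch
    return SegmentedRegions(masks=masks, h=seg.h, dome=seg.dome,
                            dropped=seg.dropped)


def _column_bands(muscle_cols: dict, n_cols: int) -> dict:
    """Partition columns into bands by nearest muscle reference column."""
    order = sorted(muscle_cols, key=muscle_cols.get)
    edges = [0]
    for a, b in zip(order, order[1:]):
        edges.append(int(round((muscle_cols[a] + muscle_cols[b]) / 2)))
    edges.append(n_cols)
    return {m: (edges[i], edges[i + 1]) for i, m in enumerate(order)}


def to_reference_coords(am: ActivationMap, origin_offset_cm: tuple[float, float],
                        circumference_cm: float, length_cm: float,
                        ied_mm: float | None = None) -> ActivationMap:
    """Express a map's axes in the normalized anatomical reference system.

    x = (offset_x + col * ied) / circumference, y = (offset_y + row * ied) /
    segment length; the anatomical origin (the SENIAM-recommended sensor
    site) lands at normalized (0, 0) minus the offset, stored in ``origin``.
    """
    if circumference_cm <= 0 or length_cm <= 0:
        raise ValueError("circumference and length must be positive")
    if ied_mm is None:
        if am.grid is None:
            raise ValueError("need ied_mm when the map has no grid")
        ied_mm = am.grid.ied_mm
    ied_cm = ied_mm / 10.0
    rows, cols = am.shape
    x = (origin_offset_cm[0] + np.arange(cols) * ied_cm) / circumference_cm
    y = (origin_offset_cm[1] + np.arange(rows) * ied_cm) / length_cm
    return ActivationMap(values=am.values.copy(), grid=am.grid,
                         epoch_start=am.epoch_start,
                         epoch_length=am.epoch_length,
                         x_axis=x, y_axis=y, origin=(0.0, 0.0))
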