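"""Canonical and arbitrary-angle plane extraction with thickness projection.

The atlas imagery is bright-field Nissl: somata are dark on a bright
background, so slabs are collapsed by *minimum*-intensity projection by
default (a maximum mode serves fluorescence polarity; mean is also offered).
Label volumes are sampled by nearest neighbour and never projected — a
"minimum of ids" is meaningless, so label mode reads the slab centre plane.

Plane orientation: the base (zero-angle) plane is coronal, with in-plane
axes u = grid axis 0 (medio-lateral) and v = grid axis 1 (dorso-ventral) and
normal n = grid axis 2 (antero-posterior). Angles are intrinsic, applied
yaw (about v) → pitch (about u) → roll (about n), right-handed, in degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "PlaneSpec",
    "SliceImage",
    "CANONICAL_AXES",
    "extract_canonical",
    "extract_oblique",
    "canonical_plane_spec",
    "count_levels",
    "gli_profile",
    "rotation_from_angles",
]

#: section name -> grid axis the plane is transverse to
CANONICAL_AXES = {"sagittal": 0, "horizontal": 1, "coronal": 2}

MODES = ("min", "max", "mean", "label")


def rotation_from_angles(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """Intrinsic yaw (about grid axis 1) → pitch (about axis 0) → roll (about
    the base normal, axis 2); degrees, right-handed."""
    cy, sy = math.cos(math.radians(yaw)), math.sin(math.radians(yaw))
    cp, sp = math.cos(math.radians(pitch)), math.sin(math.radians(pitch))
    cr, sr = math.cos(math.radians(roll)), math.sin(math.radians(roll))
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])   # about axis 1
    rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])   # about axis 0
    rz = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1]])   # about axis 2
    return ry @ rx @ rz


@dataclass
class PlaneSpec:
    """Geometry of a resliced plane.

    ``center`` is the μm point the plane pivots around; ``width``/``height``
    are in-plane extents (μm) sampled at ``pixel_size`` μm; ``thickness`` is
    the slab depth collapsed by ``mode`` (1–20 μm is the intended working
    range for the atlas imagery, but any positive value is accepted).
    ``rotation`` may override the yaw/pitch/roll angles with an explicit
    rotation matrix.
    """

    center: tuple[float, float, float]
    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    width: float = 1000.0
    height: float = 1000.0
    pixel_size: float = 10.0
    thickness: float = 10.0
    mode: str = "min"
    rotation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """In-plane unit vectors (u: columns, v: rows) and plane normal n."""
        rot = self.rotation if self.rotation is not None else rotation_from_angles(
            self.yaw, self.pitch, self.roll
        )
        rot = np.asarray(rot, dtype=float)
        return rot[:, 0], rot[:, 1], rot[:, 2]

    @property
    def shape(self) -> tuple[int, int]:
        return (max(1, round(self.height / self.pixel_size)),
                max(1, round(self.width / self.pixel_size)))


@dataclass
class SliceImage:
    """A 2D resliced image with the geometry to recover every pixel's μm
    position: ``point(i, j) = origin_um + j*pixel_size*u + i*pixel_size*v``."""

    pixels: np.ndarray
    origin_um: np.ndarray
    u: np.ndarray
    v: np.ndarray
    pixel_size: float
    spec: PlaneSpec | None = None

    def pixel_to_um(self, rows, cols) -> np.ndarray:
        r = np.asarray(rows, dtype=float)
        c = np.asarray(cols, dtype=float)
        return (self.origin_um
                + c[..., None] * self.pixel_size * self.u
                + r[..., None] * self.pixel_size * self.v)


def count_levels(extent_um: float, thickness_um: float) -> int:
    """Number of consecutive, non-overlapping projection levels of the given
    thickness that fit in the extent: floor(extent / thickness)."""
    if extent_um <= 0 or thickness_um <= 0:
        raise ValueError("extent and thickness must be positive")
    return int(math.floor(extent_um / thickness_um + 1e-9))


def _slab_indices(volume: Volume, axis: int, position: float, thickness: float) -> np.ndarray:
    """Voxel indices along ``axis`` whose centres fall in
    [position - thickness/2, position + thickness/2)."""
    vs = volume.voxel_size[axis]
    centers = volume.origin[axis] + (np.arange(volume.dims[axis]) + 0.5) * vs
    lo, hi = position - thickness / 2, position + thickness / 2
    idx = np.nonzero((centers >= lo - 1e-9) & (centers < hi - 1e-9))[0]
    if idx.size == 0:
        # Sub-voxel slab: fall back to the voxel containing the position.
        k = int(math.floor((position - volume.origin[axis]) / vs))
        idx = np.asarray([min(max(k, 0), volume.dims[axis] - 1)])
    return idx


def extract_canonical(
    volume: Volume,
    axis: str,
    position_um: float,
    thickness_um: float | None = None,
    mode: str = "min",
) -> SliceImage:
    """Extract a coronal/sagittal/horizontal slice at ``position_um`` along
    the section axis, collapsing a ``thickness_um`` slab with ``mode``.

    With thickness equal to one voxel the result is the raw grid slice.
    """
    if axis not in CANONICAL_AXES:
        raise ValueError(f"axis must be one of {sorted(CANONICAL_AXES)}, got {axis!r}")
    ax = CANONICAL_AXES[axis]
    lo = volume.origin[ax]
    hi = lo + volume.extent_um[ax]
    if not (lo <= position_um < hi):
        raise ValueError(
            f"position {position_um} μm outside the volume extent [{lo}, {hi}) on the {axis} axis"
        )
    if thickness_um is None:
        thickness_um = float(volume.voxel_size[ax])
    if mode == "label":
        k = int(math.floor((position_um - lo) / volume.voxel_size[ax]))
        pixels = np.moveaxis(np.take(volume.data, [k], axis=ax), ax, 0)[0]
    else:
        idx = _slab_indices(volume, ax, position_um, thickness_um)
        slab = np.take(volume.data, idx, axis=ax)
        reducer = {"min": np.min, "max": np.max, "mean": np.mean}[mode]
        pixels = reducer(np.moveaxis(slab, ax, 0), axis=0)
    # Image orientation (cols axis, rows axis) per section, matching the
    # zero-angle oblique frame for coronal sections:
    #   coronal: ML cols, DV rows; sagittal: AP cols, DV rows;
    #   horizontal: ML cols, AP rows.
    col_ax, row_ax = {2: (0, 1), 0: (2, 1), 1: (0, 2)}[ax]
    remaining = [a for a in range(3) if a != ax]
    if (remaining[0], remaining[1]) != (row_ax, col_ax):
        pixels = pixels.T
    u = np.zeros(3)
    u[col_ax] = 1.0
    v = np.zeros(3)
    v[row_ax] = 1.0
    origin = volume.origin + 0.5 * volume.voxel_size
    origin = origin * (u + v) + np.eye(3)[ax] * position_um
    return SliceImage(
        pixels=pixels,
        origin_um=origin,
        u=u,
        v=v,
        pixel_size=float(volume.voxel_size[col_ax]),
        spec=None,
    )


def canonical_plane_spec(
    volume: Volume,
    axis: str,
    position_um: float,
    thickness_um: float | None = None,
    mode: str = "min",
) -> PlaneSpec:
    """PlaneSpec whose zero-angle oblique extraction samples exactly the voxel
    centres of the corresponding canonical slice (useful as an oracle bridge
    between the two extraction paths; coronal axis only for nonzero angles)."""
    ax = CANONICAL_AXES[axis]
    if thickness_um is None:
        thickness_um = float(volume.voxel_size[ax])
    center = volume.origin + volume.extent_um / 2.0
    center[ax] = position_um
    # zero-angle frame is coronal; 90° yaw gives sagittal (u = -AP axis, so
    # columns are flipped vs extract_canonical), 90° pitch gives horizontal.
    yaw, pitch = {"coronal": (0.0, 0.0), "sagittal": (90.0, 0.0), "horizontal": (0.0, 90.0)}[axis]
    width_ax, height_ax = {"coronal": (0, 1), "sagittal": (2, 1), "horizontal": (0, 2)}[axis]
    return PlaneSpec(
        center=tuple(center),
        yaw=yaw,
        pitch=pitch,
        roll=0.0,
        width=float(volume.extent_um[width_ax]),
        height=float(volume.extent_um[height_ax]),
        pixel_size=float(volume.voxel_size[width_ax]),
        thickness=float(thickness_um),
        mode=mode,
    )


def _sample_intensity(volume: Volume, points: np.ndarray) -> np.ndarray:
    """Trilinear sampling at μm points; out-of-volume samples become NaN."""
    coords = (points - volume.origin) / volume.voxel_size - 0.5
    return ndimage.map_coordinates(
        volume.data.astype(np.float64), coords.T, order=1, mode="constant", cval=np.nan
    )


def extract_oblique(volume: Volume, spec: PlaneSpec) -> SliceImage:
    """Arbitrary-angle reslice.

    Intensity modes sample by trilinear interpolation and collapse the slab
    along the plane normal (sampling step = min(voxel size, pixel size));
    out-of-volume samples are ignored in the projection, and pixels whose
    samples all fall outside are 0. Label mode samples the slab centre plane
    by nearest voxel (floor convention), so label images contain only ids
    present in the source volume.
    """
    u, v, n = spec.axes()
    nrows, ncols = spec.shape
    jj, ii = np.meshgrid(np.arange(ncols), np.arange(nrows))
    center = np.asarray(spec.center, dtype=float)
    base = (
        center
        + (jj[..., None] - (ncols - 1) / 2.0) * spec.pixel_size * u
        + (ii[..., None] - (nrows - 1) / 2.0) * spec.pixel_size * v
    )
    origin = base[0, 0].copy()

    if spec.mode == "label":
        idx = volume.voxel_of(base.reshape(-1, 3))
        if not np.any(np.all((idx >= 0) & (idx < np.asarray(volume.dims)), axis=1)):
            raise ValueError("plane lies fully outside the volume")
        img = volume.values_at(base.reshape(-1, 3)).reshape(nrows, ncols)
    else:
        step = float(min(np.min(volume.voxel_size), spec.pixel_size))
        m = max(1, int(round(spec.thickness / step)))
        offsets = (np.arange(m) - (m - 1) / 2.0) * step
        stack = np.empty((m, nrows, ncols), dtype=np.float64)
        for k, off in enumerate(offsets):
            pts = (base + off * n).reshape(-1, 3)
            stack[k] = _sample_intensity(volume, pts).reshape(nrows, ncols)
        if np.all(np.isnan(stack)):
            raise ValueError("plane lies fully outside the volume")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            reducer = {"min": np.nanmin, "max": np.nanmax, "mean": np.nanmean}[spec.mode]
            img = reducer(stack, axis=0)
        img = np.where(np.isnan(img), 0.0, img)
    return SliceImage(
        pixels=img,
        origin_um=origin,
        u=u,
        v=v,
        pixel_size=spec.pixel_size,
        spec=spec,
    )


def gli_profile(
    image: SliceImage,
    start_um,
    end_um,
    bin_um: float,
    threshold: float | None = None,
    band_um: float = 50.0,
    dark_somata: bool = True,
):
    """Grey-level-index profile: fraction of stained (soma) pixels per depth
    bin along a line from ``start_um`` (pial) to ``end_um`` (deep).

    ``start_um``/``end_um`` are in-plane μm coordinates (2D, in the image's
    (u, v) frame relative to pixel (0, 0)). Pixels within ``band_um``/2 of the
    line contribute; a pixel is "stained" when its intensity is below the
    threshold (bright-field polarity; set ``dark_somata=False`` for
    fluorescence). The default threshold is Otsu's on the sampled band.
    Returns ``(bin_centers_um, fractions, counts)``.
    """
    if bin_um <= 0:
        raise ValueError("bin_um must be positive")
    p0 = np.asarray(start_um, dtype=float)
    p1 = np.asarray(end_um, dtype=float)
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    if length < 1e-9:
        raise ValueError("degenerate profile line: start and end coincide")
    axis = axis / length

    nrows, ncols = image.pixels.shape
    jj, ii = np.meshgrid(np.arange(ncols), np.arange(nrows))
    xy = np.stack([jj * image.pixel_size, ii * image.pixel_size], axis=-1)
    rel = xy - p0
    t = rel @ axis
    d = np.abs(rel[..., 0] * (-axis[1]) + rel[..., 1] * axis[0])
    band = (d <= band_um / 2.0) & (t >= 0) & (t < length)
    if not band.any():
        raise ValueError("profile line does not overlap the image")

    values = np.asarray(image.pixels, dtype=float)[band]
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(values))
    stained = values < threshold if dark_somata else values > threshold

    nbins = int(math.ceil(length / bin_um - 1e-9))
    bins = np.minimum((t[band] / bin_um).astype(int), nbins - 1)
    counts = np.bincount(bins, minlength=nbins)
    hits = np.bincount(bins, weights=stained.astype(float), minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(counts > 0, hits / np.maximum(counts, 1), 0.0)
    centers = (np.arange(nbins) + 0.5) * bin_um
    return centers, fractions, counts
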