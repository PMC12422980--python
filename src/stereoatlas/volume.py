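"""3D volume containers and file I/O (NRRD and NIfTI-1).

Coordinate conventions used throughout the package:

* physical coordinates are micrometres (μm);
* voxel indexing is 0-based; the voxel ``(i, j, k)`` occupies the half-open
  cell ``[i*s0, (i+1)*s0) x ...`` shifted by the volume origin, so a point
  maps to voxel ``floor((p - origin) / voxel_size)`` and points exactly on a
  cell boundary belong to the higher-index voxel;
* the centre of voxel ``(i, j, k)`` sits at ``origin + (index + 0.5) * s``.

NRRD support is a small self-contained codec (raw and gzip encodings, data in
Fortran order with ``sizes`` equal to the array shape, matching the common
NRRD tooling convention). NIfTI-1 goes through nibabel; voxel pitch is kept
in μm in both directions of the round trip.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "AnnotationVolume",
    "BinaryMask",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "read_nrrd",
    "write_nrrd",
]


class VolumeIOError(IOError):
    """Raised when a volume file cannot be parsed or written."""


def _as_triple(value, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (3,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


@dataclass
class Volume:
    """A 3D grid of values with physical geometry.

    Parameters
    ----------
    data:
        3D array (intensity or labels).
    voxel_size:
        μm per voxel along each axis; scalars are broadcast.
    origin:
        μm coordinate of the corner of voxel (0, 0, 0). Defaults to 0.
    """

    data: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.voxel_size = _as_triple(self.voxel_size, "voxel_size")
        if np.any(self.voxel_size <= 0):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> np.ndarray:
        """Physical size along each axis in μm."""
        return np.asarray(self.dims) * self.voxel_size

    def voxel_of(self, points_um: np.ndarray) -> np.ndarray:
        """Voxel index of each point under the floor convention (no clipping)."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return np.floor((pts - self.origin) / self.voxel_size).astype(np.int64)

    def values_at(self, points_um: np.ndarray, outside=0) -> np.ndarray:
        """Nearest-voxel values at physical points; out-of-volume -> ``outside``."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        idx = self.voxel_of(pts)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)
        out = np.full(len(pts), outside, dtype=self.data.dtype)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def same_geometry(self, other: "Volume") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class AnnotationVolume(Volume):
    """Integer label grid: value 0 is outside/background, other values are
    most-detailed structure ids from a companion ontology."""

    axis_names: tuple[str, str, str] = ("right-left", "dorsal-ventral", "anterior-posterior")
    provenance: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"annotation labels must be integers, got {self.data.dtype}")

    @property
    def labels(self) -> np.ndarray:
        return self.data

    def label_values(self) -> set[int]:
        """Distinct nonzero labels present in the grid."""
        return set(int(v) for v in np.unique(self.data) if v != 0)


@dataclass
class BinaryMask(Volume):
    """Boolean grid sharing the geometry of its parent volume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_um3(self) -> float:
        return self.voxel_count * float(np.prod(self.voxel_size))


# ---------------------------------------------------------------------------
# NRRD codec
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "uint8": np.uint8, "uchar": np.uint8, "unsigned char": np.uint8,
    "int8": np.int8, "signed char": np.int8,
    "uint16": np.uint16, "unsigned short": np.uint16,
    "int16": np.int16, "short": np.int16, "signed short": np.int16,
    "uint32": np.uint32, "unsigned int": np.uint32,
    "int32": np.int32, "int": np.int32, "signed int": np.int32,
    "uint64": np.uint64, "int64": np.int64,
    "float": np.float32, "double": np.float64,
}
_NRRD_NAMES = {
    np.dtype(np.uint8): "uint8", np.dtype(np.int8): "int8",
    np.dtype(np.uint16): "uint16", np.dtype(np.int16): "int16",
    np.dtype(np.uint32): "uint32", np.dtype(np.int32): "int32",
    np.dtype(np.uint64): "uint64", np.dtype(np.int64): "int64",
    np.dtype(np.float32): "float", np.dtype(np.float64): "double",
}


def write_nrrd(path: str | Path, data: np.ndarray, voxel_size, *, encoding: str = "gzip") -> None:
    data = np.asarray(data)
    if data.dtype not in _NRRD_NAMES:
        raise VolumeIOError(f"unsupported dtype for NRRD: {data.dtype}")
    if encoding not in ("raw", "gzip"):
        raise VolumeIOError(f"unsupported NRRD encoding {encoding!r}")
    vs = _as_triple(voxel_size, "voxel_size")
    # space directions as an axis-aligned frame in μm
    directions = " ".join(
        "(" + ",".join(str(vs[a]) if a == ax else "0" for a in range(3)) + ")"
        for ax in range(3)
    )
    header = (
        "NRRD0004\n"
        f"type: {_NRRD_NAMES[data.dtype]}\n"
        "dimension: 3\n"
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}\n"
        f"encoding: {encoding}\n"
        "endian: little\n"
        "space dimension: 3\n"
        f"space directions: {directions}\n"
        "space units: \"microns\" \"microns\" \"microns\"\n"
        "\n"
    )
    payload = np.ascontiguousarray(data.T).tobytes()  # Fortran order of `data`
    if encoding == "gzip":
        payload = gzip.compress(payload, compresslevel=1)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


def _parse_directions(text: str) -> np.ndarray:
    vecs = []
    for chunk in text.replace(") ", ")|").split("|"):
        chunk = chunk.strip().strip("()")
        if chunk.lower() == "none":
            continue
        vecs.append([float(v) for v in chunk.split(",")])
    return np.asarray(vecs)


def read_nrrd(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an NRRD volume; returns ``(data, voxel_size_um)``."""
    raw = Path(path).read_bytes()
    nl = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or nl < 0:
        raise VolumeIOError(f"{path} is not an attached-data NRRD file")
    fields: dict[str, str] = {}
    for line in raw[:nl].decode("ascii", "replace").splitlines()[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip().lower()] = value.strip()
    try:
        dtype = _NRRD_TYPES[fields["type"]]
        sizes = tuple(int(v) for v in fields["sizes"].split())
        encoding = fields.get("encoding", "raw")
    except KeyError as exc:
        raise VolumeIOError(f"{path}: missing NRRD header field {exc}") from exc
    if len(sizes) != 3:
        raise VolumeIOError(f"{path}: expected a 3D NRRD, got sizes {sizes}")
    if fields.get("endian", "little") != "little":
        raise VolumeIOError(f"{path}: only little-endian NRRD is supported")
    payload = raw[nl + 2:]
    if encoding == "gzip":
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise VolumeIOError(f"{path}: unsupported encoding {encoding!r}")
    expected = int(np.prod(sizes)) * np.dtype(dtype).itemsize
    if len(payload) < expected:
        raise VolumeIOError(f"{path}: truncated data ({len(payload)} < {expected} bytes)")
    data = np.frombuffer(payload[:expected], dtype=dtype).reshape(sizes, order="F")
    if "space directions" in fields:
        dirs = _parse_directions(fields["space directions"])
        voxel_size = np.linalg.norm(dirs, axis=1)
    elif "spacings" in fields:
        voxel_size = np.asarray([float(v) for v in fields["spacings"].split()])
    else:
        voxel_size = np.ones(3)
    return data.copy(), voxel_size


# ---------------------------------------------------------------------------
# NIfTI via nibabel (affine kept in μm)
# ---------------------------------------------------------------------------

def _write_nifti(path: Path, data: np.ndarray, voxel_size: np.ndarray) -> None:
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_xyzt_units("micron")
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, voxel_size


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def write_volume(path: str | Path, volume: Volume) -> None:
    """Write a volume as NRRD (``.nrrd``) or NIfTI-1 (``.nii``/``.nii.gz``)."""
    path = Path(path)
    if _is_nifti(path):
        _write_nifti(path, volume.data, volume.voxel_size)
    elif path.suffix.lower() == ".nrrd":
        write_nrrd(path, volume.data, volume.voxel_size)
    else:
        raise VolumeIOError(f"unrecognized volume extension: {path.name}")


def read_volume(path: str | Path) -> Volume:
    """Read an NRRD or NIfTI volume with voxel size taken from the header."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    if _is_nifti(path):
        data, voxel_size = _read_nifti(path)
    elif path.suffix.lower() == ".nrrd":
        data, voxel_size = read_nrrd(path)
    else:
        raise VolumeIOError(f"unrecognized volume extension: {path.name}")
    return Volume(data=data, voxel_size=voxel_size)
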