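"""The brain-wide positioning system.

Named cranial (bregma, lambda) and intracranial datum marks anchor a family
of stereotaxic coordinate frames: any mark can serve as origin, and atlas
grid coordinates are mapped to surgical (AP, ML, DV) axes.

Axis convention (configurable, defaults below): atlas grid axis 0 runs
right→left across the hemispheres, axis 1 dorsal→ventral, axis 2
anterior→posterior. Stereotaxic AP is positive anterior of the origin, ML
positive toward the animal's right, DV positive ventral (depth below the
origin). This signed permutation has determinant +1, so frames are proper
rotations.

Also here: the flat-skull pitch correction (rotate about the ML axis through
bregma until bregma and lambda share a DV height) and landmark-based linear
(12-parameter affine) inter-atlas alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .volume import AnnotationVolume, Volume

__all__ = [
    "DatumMark",
    "DatumMarkRegistry",
    "CoordinateFrame",
    "RigidTransform",
    "AffineMap",
    "load_datum_marks",
    "default_registry",
    "make_frame",
    "flat_skull_transform",
    "fit_affine_landmarks",
    "apply_map",
    "DEFAULT_AXES",
]

KINDS = ("cranial", "intracranial")

#: stereotaxic axis -> (grid axis, sign): AP+ anterior, ML+ right, DV+ ventral
DEFAULT_AXES = {"AP": "-z", "ML": "-x", "DV": "+y"}


@dataclass(frozen=True)
class DatumMark:
    """A named reference point in the atlas frame (μm)."""

    name: str
    kind: str  # "cranial" | "intracranial"
    structure: str  # acronym of the host anatomical structure
    position_um: tuple[float, float, float]
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"datum mark kind must be one of {KINDS}, got {self.kind!r}")
        if not np.all(np.isfinite(self.position_um)):
            raise ValueError(f"datum mark {self.name!r} has non-finite position")

    @property
    def position(self) -> np.ndarray:
        return np.asarray(self.position_um, dtype=float)


@dataclass
class DatumMarkRegistry:
    marks: dict[str, DatumMark] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.marks)

    def __contains__(self, name: str) -> bool:
        return name in self.marks

    def __getitem__(self, name: str) -> DatumMark:
        try:
            return self.marks[name]
        except KeyError:
            raise KeyError(f"unknown datum mark {name!r}") from None

    def add(self, mark: DatumMark) -> None:
        if mark.name in self.marks:
            raise ValueError(f"duplicate datum mark name {mark.name!r}")
        self.marks[mark.name] = mark

    def of_kind(self, kind: str) -> list[DatumMark]:
        return [m for m in self.marks.values() if m.kind == kind]

    def structures(self) -> set[str]:
        """Host structures of the intracranial marks."""
        return {m.structure for m in self.of_kind("intracranial")}

    def to_dict(self) -> dict:
        return {
            "marks": [
                {
                    "name": m.name,
                    "kind": m.kind,
                    "structure": m.structure,
                    "position_um": list(m.position_um),
                    "description": m.description,
                }
                for m in self.marks.values()
            ]
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def load_datum_marks(path: str | Path) -> DatumMarkRegistry:
    """Load a JSON datum-mark registry; duplicate names are rejected."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse datum-mark registry {path}: {exc}") from exc
    registry = DatumMarkRegistry()
    for rec in payload.get("marks", []):
        registry.add(
            DatumMark(
                name=str(rec["name"]),
                kind=str(rec["kind"]),
                structure=str(rec.get("structure", "")),
                position_um=tuple(float(v) for v in rec["position_um"]),  # type: ignore[arg-type]
                description=str(rec.get("description", "")),
            )
        )
    return registry


def default_registry() -> DatumMarkRegistry:
    """The packaged registry: 18 intracranial marks drawn from 8 structures
    plus the two cranial marks bregma and lambda (synthetic coordinates from
    the packaged phantom world; a released registry file can be dropped in)."""
    with resources.as_file(resources.files("stereoatlas.data") / "datum_marks.json") as p:
        return load_datum_marks(p)


# ---------------------------------------------------------------------------
# Rigid transforms and frames
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """p ↦ R p + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation part is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation part must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points_um) -> np.ndarray:
        pts = np.asarray(points_um, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def _axes_rotation(axes: dict[str, str]) -> np.ndarray:
    """Rows (AP, ML, DV) of the signed permutation described by e.g.
    ``{"AP": "-z", "ML": "-x", "DV": "+y"}``."""
    rows = []
    cols = {"x": 0, "y": 1, "z": 2}
    for key in ("AP", "ML", "DV"):
        spec = axes[key]
        sign = {"+": 1.0, "-": -1.0}[spec[0]]
        row = np.zeros(3)
        row[cols[spec[1]]] = sign
        rows.append(row)
    rot = np.stack(rows)
    if not np.allclose(rot @ rot.T, np.eye(3)):
        raise ValueError(f"axis spec {axes} does not use each grid axis exactly once")
    if not np.isclose(np.linalg.det(rot), 1.0):
        raise ValueError(
            f"axis spec {axes} is a reflection (determinant −1); stereotaxic "
            "frames must be proper rotations"
        )
    return rot


@dataclass
class CoordinateFrame:
    """Maps atlas μm coordinates to stereotaxic (AP, ML, DV) μm relative to a
    datum-mark origin: s = R (p − origin)."""

    origin_mark: str
    origin_um: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.origin_um = np.asarray(self.origin_um, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("frame rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("frame rotation must have determinant +1")

    def to_stereotaxic(self, points_um) -> np.ndarray:
        pts = np.asarray(points_um, dtype=float)
        single = pts.ndim == 1
        out = (np.atleast_2d(pts) - self.origin_um) @ self.rotation.T
        return out[0] if single else out

    def from_stereotaxic(self, points_apmldv) -> np.ndarray:
        pts = np.asarray(points_apmldv, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation + self.origin_um
        return out[0] if single else out

    def compose(self, transform: RigidTransform) -> "CoordinateFrame":
        """Frame that first applies ``transform`` to atlas points, so that
        ``(frame∘T).to_stereotaxic(p) == frame.to_stereotaxic(T(p))``."""
        # s = R (T p - o) = (R Rt) p - R (o - t)  ->  new origin solves R Rt (p - o') form
        rot = self.rotation @ transform.rotation
        origin = transform.inverse().apply(self.origin_um)
        return CoordinateFrame(self.origin_mark, origin, rot)


def make_frame(
    registry: DatumMarkRegistry,
    origin: str,
    axes: dict[str, str] | None = None,
) -> CoordinateFrame:
    """Build a stereotaxic frame with the named datum mark at (0, 0, 0)."""
    mark = registry[origin]
    rot = _axes_rotation(DEFAULT_AXES if axes is None else axes)
    return CoordinateFrame(origin_mark=origin, origin_um=mark.position, rotation=rot)


def to_stereotaxic(frame: CoordinateFrame, point_um) -> np.ndarray:
    return frame.to_stereotaxic(point_um)


def from_stereotaxic(frame: CoordinateFrame, point_apmldv) -> np.ndarray:
    return frame.from_stereotaxic(point_apmldv)


def flat_skull_transform(bregma_um, lambda_um, *, dv_axis: int = 1, ml_axis: int = 0) -> RigidTransform:
    """Pitch about the ML axis through bregma that brings lambda to bregma's
    DV height (the flat-skull position). Bregma is a fixed point; the
    bregma–lambda distance is preserved."""
    b = np.asarray(bregma_um, dtype=float)
    l = np.asarray(lambda_um, dtype=float)
    v = l - b
    if np.linalg.norm(v) < 1e-9:
        raise ValueError("bregma and lambda coincide; flat-skull pitch is undefined")
    ap_axis = 3 - dv_axis - ml_axis
    theta = np.arctan2(v[dv_axis], v[ap_axis])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.eye(3)
    # rotate the (dv, ap) plane so the DV component of lambda-bregma vanishes
    rot[dv_axis, dv_axis] = c
    rot[dv_axis, ap_axis] = -s
    rot[ap_axis, dv_axis] = s
    rot[ap_axis, ap_axis] = c
    return RigidTransform(rot, b - rot @ b)


# ---------------------------------------------------------------------------
# Landmark-based linear alignment
# ---------------------------------------------------------------------------


@dataclass
class AffineMap:
    """12-parameter affine y = A x + t as a 3×4 matrix with per-landmark fit
    residuals (μm)."""

    matrix: np.ndarray  # 3x4
    source: str = ""
    target: str = ""
    residuals_um: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 4)
        if abs(np.linalg.det(self.matrix[:, :3])) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 3]

    def apply(self, points_um) -> np.ndarray:
        pts = np.asarray(points_um, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.linear.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.linear)
        return AffineMap(
            np.hstack([inv, (-inv @ self.translation)[:, None]]),
            source=self.target,
            target=self.source,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix.tolist(),
                "source": self.source,
                "target": self.target,
                "residuals_um": self.residuals_um.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AffineMap":
        rec = json.loads(text)
        return cls(
            np.asarray(rec["matrix"]),
            source=rec.get("source", ""),
            target=rec.get("target", ""),
            residuals_um=np.asarray(rec.get("residuals_um", [])),
        )


def fit_affine_landmarks(pairs, *, source: str = "", target: str = "") -> AffineMap:
    """Least-squares affine from ≥4 non-coplanar (source, target) μm pairs.

    With exactly 4 non-degenerate pairs the fit interpolates (residuals ~0);
    more pairs give the usual least-squares solution with per-pair residuals
    reported in μm.
    """
    src = np.asarray([p[0] for p in pairs], dtype=float)
    dst = np.asarray([p[1] for p in pairs], dtype=float)
    if len(src) < 4:
        raise ValueError(f"need at least 4 landmark pairs, got {len(src)}")
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design, tol=1e-6 * max(1.0, np.abs(src).max())) < 4:
        raise ValueError("landmark configuration is degenerate (coplanar or collinear)")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = np.hstack([coef[:3].T, coef[3][:, None]])
    fitted = design @ coef
    residuals = np.linalg.norm(fitted - dst, axis=1)
    return AffineMap(matrix, source=source, target=target, residuals_um=residuals)


def apply_map(
    affine: AffineMap,
    points_um=None,
    volume: AnnotationVolume | Volume | None = None,
    target_dims=None,
    target_voxel_size=None,
    target_origin=(0.0, 0.0, 0.0),
):
    """Transform μm points exactly, or resample a label volume onto a target
    grid by nearest-neighbour pull-back through the inverse map."""
    if (points_um is None) == (volume is None):
        raise ValueError("pass exactly one of points_um or volume")
    if points_um is not None:
        return affine.apply(points_um)

    assert volume is not None
    dims = volume.dims if target_dims is None else tuple(int(d) for d in target_dims)
    vs = volume.voxel_size if target_voxel_size is None else np.broadcast_to(
        np.asarray(target_voxel_size, dtype=float), (3,)
    )
    origin = np.asarray(target_origin, dtype=float)
    inv = affine.inverse()
    idx = np.indices(dims).reshape(3, -1).T
    centers = origin + (idx + 0.5) * vs
    src_pts = inv.apply(centers)
    values = volume.values_at(src_pts).reshape(dims)
    if isinstance(volume, AnnotationVolume):
        return AnnotationVolume(data=values, voxel_size=vs, origin=origin,
                                provenance=f"resampled:{volume.provenance}")
    return Volume(data=values, voxel_size=vs, origin=origin)
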