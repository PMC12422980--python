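"""Core annotation-volume services: loading/validation, hierarchical masks,
the 10-μm region-lookup table, label-completeness ("seamlessness") checks and
Dice overlap evaluation.

The lookup table is the workhorse behind path planning and neuron
localization: it answers "which most-detailed structure contains this μm
point" for arbitrary points, returning 0 (outside) instead of raising for
points beyond the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ontology import Ontology, OntologyError
from .volume import AnnotationVolume, BinaryMask, Volume, read_volume

__all__ = [
    "RegionLookup",
    "SeamlessReport",
    "load_annotation",
    "structure_mask",
    "build_lookup",
    "lookup_point",
    "check_seamless",
    "dice",
    "dice_mean",
]

OUTSIDE = 0


class LabelValidationError(ValueError):
    """Raised when an annotation volume contains ids the ontology lacks."""

    def __init__(self, unknown_ids):
        self.unknown_ids = sorted(int(i) for i in unknown_ids)
        super().__init__(
            "annotation volume contains label ids absent from the ontology's "
            f"most-detailed structures: {self.unknown_ids}"
        )


def validate_labels(volume: AnnotationVolume, ontology: Ontology) -> None:
    """Check every nonzero label is a most-detailed ontology structure."""
    present = volume.label_values()
    unknown = present - ontology.leaves()
    if unknown:
        raise LabelValidationError(unknown)


def load_annotation(path: str | Path, ontology: Ontology) -> AnnotationVolume:
    """Read an integer NRRD/NIfTI label volume and validate it against the
    ontology. Unknown label ids raise :class:`LabelValidationError` naming the
    offending ids rather than being dropped."""
    vol = read_volume(path)
    if not np.issubdtype(vol.data.dtype, np.integer):
        raise ValueError(
            f"{path}: annotation volume must hold integers, got {vol.data.dtype}"
        )
    ann = AnnotationVolume(
        data=vol.data,
        voxel_size=vol.voxel_size,
        origin=vol.origin,
        provenance=str(path),
    )
    validate_labels(ann, ontology)
    return ann


def structure_mask(volume: AnnotationVolume, ontology: Ontology, structure_id: int) -> BinaryMask:
    """Binary mask of a structure, resolved hierarchically: true wherever the
    voxel label is the structure itself or any descendant. The mask of a
    parent therefore equals the voxelwise union of its children's masks."""
    ids = ontology.descendants(structure_id)  # raises OntologyError for unknown ids
    grid = np.isin(volume.data, sorted(ids))
    return BinaryMask(data=grid, voxel_size=volume.voxel_size, origin=volume.origin)


@dataclass
class RegionLookup:
    """Most-detailed structure id per lattice cell at ``grid_step`` μm.

    The table stores, for each grid-step cell, the label of the source voxel
    containing the cell centre; a point query maps the point to its containing
    cell (floor convention) and returns that label, 0 for points outside the
    table.
    """

    table: np.ndarray
    grid_step: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def labels_at(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        idx = np.floor((pts - self.origin) / self.grid_step).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.table.shape)), axis=1)
        out = np.zeros(len(pts), dtype=self.table.dtype)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.table[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def build_lookup(volume: AnnotationVolume, grid_step: float | None = None) -> RegionLookup:
    """Build the region-lookup table at ``grid_step`` μm (default: the
    annotation voxel size, i.e. an identity lookup).

    ``grid_step`` must be at least the voxel size; cells record the label of
    the source voxel containing their centre.
    """
    vs = volume.voxel_size
    if grid_step is None:
        if not np.allclose(vs, vs[0]):
            raise ValueError("grid_step must be given for anisotropic volumes")
        grid_step = float(vs[0])
    grid_step = float(grid_step)
    if grid_step < np.max(vs) - 1e-9:
        raise ValueError(f"grid_step {grid_step} μm is smaller than the voxel size {vs}")
    if np.allclose(grid_step, vs):
        table = volume.data
    else:
        shape = np.ceil(volume.extent_um / grid_step).astype(int)
        ax = [np.minimum(
            np.floor((np.arange(n) + 0.5) * grid_step / vs[d]).astype(int),
            volume.dims[d] - 1,
        ) for d, n in enumerate(shape)]
        table = volume.data[np.ix_(ax[0], ax[1], ax[2])]
    return RegionLookup(table=table, grid_step=grid_step, origin=volume.origin.copy())


def lookup_point(lookup: RegionLookup, point_um, ontology: Ontology) -> tuple[int, list[int]]:
    """Most-detailed structure id at a μm point plus its ancestor chain to the
    root. Total function: out-of-volume or background points return
    ``(0, [])``."""
    label = int(lookup.labels_at(np.asarray(point_um, dtype=float))[0])
    if label == OUTSIDE or label not in ontology:
        return OUTSIDE, []
    return label, ontology.ancestors(label)


@dataclass
class SeamlessReport:
    """Result of the terra-nullius check: voxels inside the brain outline that
    carry label 0."""

    violation_count: int
    example_voxels: np.ndarray  # (n, 3) indices, capped

    @property
    def seamless(self) -> bool:
        return self.violation_count == 0

    def summary(self) -> str:
        if self.seamless:
            return "seamless: no unlabeled voxels inside the outline"
        return (
            f"{self.violation_count} unlabeled voxels inside the outline; "
            f"first {len(self.example_voxels)} at {self.example_voxels.tolist()}"
        )


def check_seamless(volume: AnnotationVolume, outline: BinaryMask, *, cap: int = 100) -> SeamlessReport:
    """Report voxels inside the outline mask with label 0 (``terra nullius``)."""
    if not volume.same_geometry(outline):
        raise ValueError("outline mask geometry does not match the annotation volume")
    holes = outline.data & (volume.data == OUTSIDE)
    count = int(holes.sum())
    coords = np.argwhere(holes)[:cap]
    return SeamlessReport(violation_count=count, example_voxels=coords)


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Sørensen–Dice overlap 2|A∩B|/(|A|+|B|) in [0, 1].

    Two empty masks agree perfectly on absence and score 1.0 (keeps
    per-structure averages NaN-free)."""
    ga = a.data if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    gb = b.data if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    if isinstance(a, BinaryMask) and isinstance(b, BinaryMask) and not a.same_geometry(b):
        raise ValueError("dice operands must share geometry")
    if ga.shape != gb.shape:
        raise ValueError(f"dice operands must share shape, got {ga.shape} vs {gb.shape}")
    na, nb = int(ga.sum()), int(gb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ga & gb).sum()) / (na + nb)


def dice_mean(
    a: AnnotationVolume,
    b: AnnotationVolume,
    ontology: Ontology,
    structure_ids,
) -> float:
    """Unweighted mean Dice over an explicit list of structures, each resolved
    hierarchically in both volumes."""
    ids = list(structure_ids)
    if not ids:
        raise ValueError("structure_ids must be non-empty")
    scores = [
        dice(structure_mask(a, ontology, i), structure_mask(b, ontology, i))
        for i in ids
    ]
    return float(np.mean(scores))
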