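"""Virtual stereotaxic surgery: traversal analysis and path planning.

A straight injection trajectory is sampled at a fine μm step through the
region-lookup table to enumerate the structures it passes through. The
planner searches for an entry ray that reaches a target while avoiding a
user-given set of forbidden structures: rays are emitted from the target in
seeded random directions within an entry cone (default: the full dorsal
hemisphere, the surgical approach from above), and the first ray whose
traversal between the brain surface and the target contains no forbidden
structure is returned. The target's own structure and extracranial space are
always exempt — the needle must reach the target through its host structure.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .core import OUTSIDE, RegionLookup
from .ontology import Ontology
from .positioning import CoordinateFrame

__all__ = [
    "Trajectory",
    "TraversalInterval",
    "TraversalRecord",
    "PlanConfig",
    "PlanFailure",
    "InsertionReport",
    "path_structures",
    "plan_avoiding",
    "trajectory_report",
    "trajectory_from_report",
]

#: unit vector pointing dorsally (grid axis 1 runs dorsal→ventral)
DORSAL = np.array([0.0, -1.0, 0.0])


@dataclass(frozen=True)
class Trajectory:
    """Straight injection path from an entry point (on/above the brain
    surface) to a target, both in atlas μm coordinates."""

    entry: tuple[float, float, float]
    target: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("entry and target coincide; trajectory has zero length")

    @property
    def entry_um(self) -> np.ndarray:
        return np.asarray(self.entry, dtype=float)

    @property
    def target_um(self) -> np.ndarray:
        return np.asarray(self.target, dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.target_um - self.entry_um))

    @property
    def direction(self) -> np.ndarray:
        return (self.target_um - self.entry_um) / self.length


@dataclass(frozen=True)
class TraversalInterval:
    structure_id: int
    entry_depth_um: float
    exit_depth_um: float

    @property
    def length_um(self) -> float:
        return self.exit_depth_um - self.entry_depth_um


@dataclass
class TraversalRecord:
    """Ordered structure intervals along a trajectory, measured as depth (μm)
    from the entry point. Extracranial portions carry structure id 0."""

    trajectory: Trajectory
    intervals: list[TraversalInterval]
    step_um: float

    def structure_ids(self, include_outside: bool = False) -> list[int]:
        return [iv.structure_id for iv in self.intervals
                if include_outside or iv.structure_id != OUTSIDE]

    def contains(self, structure_ids) -> bool:
        wanted = set(structure_ids)
        return any(iv.structure_id in wanted for iv in self.intervals)

    def in_brain_length(self) -> float:
        return sum(iv.length_um for iv in self.intervals if iv.structure_id != OUTSIDE)


def path_structures(
    lookup: RegionLookup,
    trajectory: Trajectory,
    ontology: Ontology,
    step_um: float = 5.0,
) -> TraversalRecord:
    """Sample the trajectory every ``step_um`` from entry to target and merge
    consecutive identical labels into intervals (boundaries accurate to
    ±step). Intervals tile [0, length]; extracranial runs are kept with id 0."""
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    length = trajectory.length
    n = int(math.floor(length / step_um)) + 1
    depths = np.minimum(np.arange(n) * step_um, length)
    points = trajectory.entry_um + depths[:, None] * trajectory.direction
    labels = lookup.labels_at(points)

    intervals: list[TraversalInterval] = []
    run_start = 0.0
    current = int(labels[0])
    for i in range(1, n):
        if int(labels[i]) != current:
            boundary = float(depths[i - 1] + step_um / 2.0)  # midpoint estimate
            boundary = min(boundary, length)
            intervals.append(TraversalInterval(current, run_start, boundary))
            run_start = boundary
            current = int(labels[i])
    intervals.append(TraversalInterval(current, run_start, length))
    return TraversalRecord(trajectory=trajectory, intervals=intervals, step_um=step_um)


@dataclass
class PlanConfig:
    """Planner parameters.

    ``entry_cone_deg`` is the half-angle about the dorsal direction within
    which entry rays are drawn (90° = the full upper hemisphere). ``step_um``
    defaults to 5 μm, half the 10-μm lookup grid, so no lookup cell on a ray
    can be skipped.
    """

    seed: int = 0
    max_rays: int = 10_000
    time_limit_s: float | None = None
    step_um: float = 5.0
    entry_cone_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        if self.max_rays < 1:
            raise ValueError("max_rays must be >= 1")


@dataclass
class PlanFailure:
    """Why no qualifying path was found."""

    rays_tried: int
    reason: str  # "max_rays" | "time_limit"

    def __bool__(self) -> bool:
        return False


def _sample_directions(rng: np.random.Generator, count: int, cone_deg: float) -> np.ndarray:
    """Directions uniform on the spherical cap of half-angle ``cone_deg``
    about the dorsal axis."""
    cos_min = math.cos(math.radians(cone_deg))
    cos_t = rng.uniform(cos_min, 1.0, size=count)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=count)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    return (cos_t[:, None] * DORSAL
            + (sin_t * np.cos(phi))[:, None] * e1
            + (sin_t * np.sin(phi))[:, None] * e2)


def _surface_exit(lookup: RegionLookup, target: np.ndarray, direction: np.ndarray,
                  step: float) -> float | None:
    """Depth (from the target, along ``direction``) of the last in-brain
    sample before the ray leaves the labelled volume for good."""
    extent = np.asarray(lookup.table.shape) * lookup.grid_step
    # max path length: volume diagonal from the target
    t_max = float(np.linalg.norm(extent)) + step
    n = int(math.ceil(t_max / step)) + 1
    ts = np.arange(n) * step
    pts = target + ts[:, None] * direction
    labels = lookup.labels_at(pts)
    inside = np.nonzero(labels != OUTSIDE)[0]
    if inside.size == 0:
        return None
    return float(ts[inside[-1]])


def plan_avoiding(
    lookup: RegionLookup,
    target_um,
    forbidden_ids,
    ontology: Ontology,
    config: PlanConfig | None = None,
) -> Trajectory | PlanFailure:
    """Find an injection path to ``target_um`` that avoids the forbidden
    structures (resolved hierarchically through the ontology).

    Rays are emitted from the target within the entry cone using a seeded
    generator, so identical configs return identical trajectories. A ray
    qualifies when no sample strictly between the brain-surface crossing and
    the target lies in a forbidden structure; the target's own most-detailed
    structure and extracranial space are exempt. The first qualifying ray is
    returned; otherwise a :class:`PlanFailure` reports the rays tried and the
    stopping reason.
    """
    config = config or PlanConfig()
    target = np.asarray(target_um, dtype=float)
    target_label = int(lookup.labels_at(target)[0])
    if target_label == OUTSIDE:
        raise ValueError(f"target {target.tolist()} lies outside the brain")

    forbidden: set[int] = set()
    for fid in forbidden_ids:
        forbidden |= ontology.descendants(fid)
    forbidden.discard(target_label)
    forbidden.discard(OUTSIDE)

    rng = np.random.default_rng(config.seed)
    t_start = time.monotonic()
    tried = 0
    batch = 64
    while tried < config.max_rays:
        if config.time_limit_s is not None and time.monotonic() - t_start > config.time_limit_s:
            return PlanFailure(rays_tried=tried, reason="time_limit")
        count = min(batch, config.max_rays - tried)
        for direction in _sample_directions(rng, count, config.entry_cone_deg):
            tried += 1
            exit_t = _surface_exit(lookup, target, direction, config.step_um)
            if exit_t is None or exit_t <= 0:
                continue
            ts = np.arange(0.0, exit_t, config.step_um)[1:]  # strictly between
            pts = target + ts[:, None] * direction
            labels = lookup.labels_at(pts)
            if forbidden and np.any(np.isin(labels, sorted(forbidden))):
                continue
            entry = target + exit_t * direction
            return Trajectory(entry=tuple(entry), target=tuple(target))
    return PlanFailure(rays_tried=tried, reason="max_rays")


@dataclass
class InsertionReport:
    """Bregma-referenced (or any datum-mark-referenced) insertion parameters:
    stereotaxic entry coordinates, depth along the needle and the insertion
    angles. ``tilt_deg`` is measured from the vertical (DV) axis;
    ``azimuth_deg`` is the compass angle of the tilt, measured from the AP+
    axis toward ML+."""

    origin_mark: str
    entry_ap_um: float
    entry_ml_um: float
    entry_dv_um: float
    depth_um: float
    tilt_deg: float
    azimuth_deg: float

    def to_dict(self) -> dict:
        return {
            "origin_mark": self.origin_mark,
            "entry_ap_um": self.entry_ap_um,
            "entry_ml_um": self.entry_ml_um,
            "entry_dv_um": self.entry_dv_um,
            "depth_um": self.depth_um,
            "tilt_deg": self.tilt_deg,
            "azimuth_deg": self.azimuth_deg,
        }


def trajectory_report(frame: CoordinateFrame, trajectory: Trajectory) -> InsertionReport:
    """Insertion parameters of a trajectory in the given stereotaxic frame."""
    entry_s = frame.to_stereotaxic(trajectory.entry_um)
    target_s = frame.to_stereotaxic(trajectory.target_um)
    delta = target_s - entry_s
    depth = float(np.linalg.norm(delta))
    if depth <= 0:
        raise ValueError("zero-length trajectory")
    tilt = math.degrees(math.acos(np.clip(delta[2] / depth, -1.0, 1.0)))
    azimuth = 0.0 if tilt < 1e-9 else math.degrees(math.atan2(delta[1], delta[0]))
    return InsertionReport(
        origin_mark=frame.origin_mark,
        entry_ap_um=float(entry_s[0]),
        entry_ml_um=float(entry_s[1]),
        entry_dv_um=float(entry_s[2]),
        depth_um=depth,
        tilt_deg=tilt,
        azimuth_deg=azimuth,
    )


def trajectory_from_report(frame: CoordinateFrame, report: InsertionReport) -> Trajectory:
    """Rebuild the trajectory a report describes (inverse of
    :func:`trajectory_report` to within numerical round-off)."""
    entry_s = np.array([report.entry_ap_um, report.entry_ml_um, report.entry_dv_um])
    tilt = math.radians(report.tilt_deg)
    azimuth = math.radians(report.azimuth_deg)
    direction_s = np.array(
        [math.sin(tilt) * math.cos(azimuth), math.sin(tilt) * math.sin(azimuth), math.cos(tilt)]
    )
    target_s = entry_s + report.depth_um * direction_s
    return Trajectory(
        entry=tuple(frame.from_stereotaxic(entry_s)),
        target=tuple(frame.from_stereotaxic(target_s)),
    )
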