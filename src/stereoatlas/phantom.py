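"""Seeded synthetic atlas world for testing every service without downloads.

The phantom emulates the data the real pipeline assumes: a seamlessly
labelled annotation volume with a hierarchical ontology, a bright-field
Nissl-like intensity volume (bright background, dark somata), an outline
mask, cranial + intracranial datum marks, and SWC neurons with recorded
ground truth. The default world is a 1/5-scale brain: 256×200×300 voxels at
10 μm (≈ 2.56×2.0×3.0 mm), so full test suites run in seconds.

Default anatomy (all analytic, all recorded in :class:`PhantomTruth`):

* an ellipsoidal brain outline with two concentric shell layers (L1 thin and
  cell-sparse, L2 thick and cell-dense — a laminated "cortex");
* a deep "matrix" filling the rest of the interior;
* three ellipsoidal nuclei (NucA under the dorsal pole, NucB anterior-
  lateral, NucC posterior-lateral);
* a cell-free fibre tube running antero-posteriorly;
* a cell-free plate ("Shield") capping NucA dorsally with one 200-μm gap —
  the feasible corridor for the surgery planner;
* a cluster of micro-islands a few tens of μm across, one thin enough to be
  missed by coarse path sampling.

Grid axes follow the package convention: axis 0 right→left (ML), axis 1
dorsal→ventral (DV), axis 2 anterior→posterior (AP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import build_lookup
from .neuron_mapper import NeuronMorphology
from .ontology import Ontology, StructureNode
from .positioning import DatumMark, DatumMarkRegistry
from .volume import AnnotationVolume, BinaryMask, Volume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "PhantomWorld",
    "make_phantom_atlas",
    "make_phantom_neurons",
    "make_phantom_datum_marks",
    "phantom_ontology",
]


class PhantomConfigError(ValueError):
    """A phantom recipe that cannot be generated (shape outside the grid,
    empty target structure...)."""


# ---------------------------------------------------------------------------
# Default world geometry (μm)
# ---------------------------------------------------------------------------

OUTLINE_CENTER = np.array([1280.0, 1000.0, 1500.0])
OUTLINE_SEMI = np.array([1200.0, 920.0, 1450.0])
#: normalized radii of the shell boundaries: L1 = (S1, 1], L2 = (S2, S1]
S1 = 72.0 / 92.0
S2 = 42.0 / 92.0

NUC_A = {"center": np.array([1280.0, 900.0, 1500.0]), "semi": np.array([180.0, 150.0, 200.0])}
NUC_B = {"center": np.array([1550.0, 1080.0, 1220.0]), "semi": np.array([120.0, 100.0, 130.0])}
NUC_C = {"center": np.array([1520.0, 1080.0, 1900.0]), "semi": np.array([90.0, 80.0, 100.0])}
TUBE = {"axis_ml": 1000.0, "axis_dv": 1150.0, "radius": 50.0, "ap": (1200.0, 1800.0)}
PLATE = {"ml": (1120.0, 1450.0), "dv": (700.0, 730.0), "ap": (1300.0, 1710.0),
         "gap_ml": (1180.0, 1380.0), "gap_ap": (1400.0, 1600.0)}
ISLANDS = [
    {"center": np.array([1200.0, 1180.0, 1000.0]), "radius": 25.0},
    {"center": np.array([1280.0, 1220.0, 950.0]), "radius": 15.0},  # thin island
    {"center": np.array([1360.0, 1180.0, 1050.0]), "radius": 25.0},
]

BREGMA = np.array([1280.0, 80.0, 950.0])
LAMBDA = np.array([1280.0, 260.0, 2450.0])

#: structure ids
BRAIN, CORTEX, L1, L2 = 1, 10, 11, 12
DEEP, NUCA, NUCB, NUCC = 20, 21, 22, 23
FIBER, TUBET, SHIELD = 30, 31, 32
ISLGRP, ISL = 40, 41
INTERIOR, MATRIX = 50, 51

DEFAULT_DENSITIES = {
    # cells per mm³; fibre structures are cell-free
    "L1": 20_000.0,
    "L2": 150_000.0,
    "Mx": 50_000.0,
    "NucA": 100_000.0,
    "NucB": 100_000.0,
    "NucC": 100_000.0,
    "TubeT": 0.0,
    "Shield": 0.0,
    "Isl": 400_000.0,
}

DEFAULT_NEURON_RECIPES = [
    {"name": "n1", "soma": "NucA", "targets": ["NucB"] * 3},
    {"name": "n2", "soma": "NucA", "targets": ["NucB", "NucC"]},
    {"name": "n3", "soma": "NucA", "targets": ["NucC"] * 2},
    {"name": "n4", "soma": "NucB", "targets": ["NucA"]},
    {"name": "n5", "soma": "NucB", "targets": ["NucC"] * 2},
]


@dataclass
class PhantomConfig:
    dims: tuple[int, int, int] = (256, 200, 300)
    voxel_size_um: float = 10.0
    seed: int = 7
    densities: dict = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    soma_radius_um: float = 5.0
    soma_intensity: int = 40
    background_intensity: int = 255
    neuron_recipes: list = field(default_factory=lambda: [dict(r) for r in DEFAULT_NEURON_RECIPES])

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.dims, dtype=float) * self.voxel_size_um

    def validate(self) -> None:
        for name, density in self.densities.items():
            if density < 0:
                raise PhantomConfigError(f"negative soma density for {name!r}")
        lo = OUTLINE_CENTER - OUTLINE_SEMI
        hi = OUTLINE_CENTER + OUTLINE_SEMI
        if np.any(lo < 0) or np.any(hi > self.extent_um):
            raise PhantomConfigError(
                f"brain outline [{lo.tolist()}, {hi.tolist()}] μm exceeds the "
                f"grid extent {self.extent_um.tolist()} μm"
            )


def phantom_ontology() -> Ontology:
    n = StructureNode
    return Ontology.from_nodes([
        n(BRAIN, "Brain", "whole brain", None, (240, 240, 240)),
        n(CORTEX, "Ctx", "cortical shell", BRAIN, (70, 160, 60)),
        n(L1, "L1", "cortical shell layer 1", CORTEX, (120, 200, 110)),
        n(L2, "L2", "cortical shell layer 2", CORTEX, (40, 120, 40)),
        n(DEEP, "Deep", "deep nuclear group", BRAIN, (200, 120, 40)),
        n(NUCA, "NucA", "nucleus A", DEEP, (230, 150, 60)),
        n(NUCB, "NucB", "nucleus B", DEEP, (210, 100, 50)),
        n(NUCC, "NucC", "nucleus C", DEEP, (180, 90, 70)),
        n(FIBER, "fib", "fibre tracts", BRAIN, (200, 200, 200)),
        n(TUBET, "TubeT", "fibre tube", FIBER, (220, 220, 220)),
        n(SHIELD, "Shield", "fibre plate with gap", FIBER, (180, 180, 190)),
        n(ISLGRP, "IslGrp", "island group", BRAIN, (90, 90, 200)),
        n(ISL, "Isl", "micro-island cluster", ISLGRP, (120, 120, 230)),
        n(INTERIOR, "Int", "interior zone", BRAIN, (150, 120, 150)),
        n(MATRIX, "Mx", "deep matrix", INTERIOR, (170, 140, 170)),
    ])


@dataclass
class PhantomTruth:
    """Analytic bookkeeping the generator guarantees by construction."""

    analytic_volumes_um3: dict  # acronym -> μm³ (analytic, pre-rasterization)
    structure_geometry: dict    # acronym -> shape parameters (μm)
    datum_marks_um: dict        # mark name -> (x, y, z) μm
    corridor: dict              # planner corridor geometry (gap in the Shield)
    soma_counts: dict = field(default_factory=dict)        # acronym -> drawn somata
    neuron_nodes: pd.DataFrame | None = None  # per key node: neuron, kind, structure


@dataclass
class PhantomWorld:
    annotation: AnnotationVolume
    intensity: Volume
    outline: BinaryMask
    ontology: Ontology
    truth: PhantomTruth
    config: PhantomConfig


def _rho2(centers: tuple[np.ndarray, np.ndarray, np.ndarray],
          center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    x, y, z = centers
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2)


def make_phantom_atlas(config: PhantomConfig | None = None) -> PhantomWorld:
    """Generate the phantom world (pure function of config + seed)."""
    config = config or PhantomConfig()
    config.validate()
    ontology = phantom_ontology()
    vs = config.voxel_size_um
    nx, ny, nz = config.dims
    # voxel-centre coordinate axes (μm), broadcast as an open grid
    cx = ((np.arange(nx) + 0.5) * vs)[:, None, None]
    cy = ((np.arange(ny) + 0.5) * vs)[None, :, None]
    cz = ((np.arange(nz) + 0.5) * vs)[None, None, :]
    grid = (cx, cy, cz)

    rho2 = _rho2(grid, OUTLINE_CENTER, OUTLINE_SEMI)
    outline = rho2 <= 1.0
    labels = np.zeros(config.dims, dtype=np.int32)
    labels[outline & (rho2 > S1 ** 2)] = L1
    labels[(rho2 <= S1 ** 2) & (rho2 > S2 ** 2)] = L2
    labels[rho2 <= S2 ** 2] = MATRIX

    # fibre plate with its gap (the planner corridor)
    in_plate = (
        (cx >= PLATE["ml"][0]) & (cx < PLATE["ml"][1])
        & (cy >= PLATE["dv"][0]) & (cy < PLATE["dv"][1])
        & (cz >= PLATE["ap"][0]) & (cz < PLATE["ap"][1])
    )
    in_gap = (
        (cx >= PLATE["gap_ml"][0]) & (cx < PLATE["gap_ml"][1])
        & (cz >= PLATE["gap_ap"][0]) & (cz < PLATE["gap_ap"][1])
    )
    labels[in_plate & ~in_gap] = SHIELD

    # fibre tube along the AP axis
    in_tube = (
        ((cx - TUBE["axis_ml"]) ** 2 + (cy - TUBE["axis_dv"]) ** 2 <= TUBE["radius"] ** 2)
        & (cz >= TUBE["ap"][0]) & (cz < TUBE["ap"][1])
    )
    labels[in_tube] = TUBET

    for nid, shape in ((NUCA, NUC_A), (NUCB, NUC_B), (NUCC, NUC_C)):
        labels[_rho2(grid, shape["center"], shape["semi"]) <= 1.0] = nid
    for isl in ISLANDS:
        labels[_rho2(grid, isl["center"], np.full(3, isl["radius"])) <= 1.0] = ISL

    annotation = AnnotationVolume(data=labels, voxel_size=vs, provenance="phantom")
    outline_mask = BinaryMask(data=outline, voxel_size=vs)

    # --- Nissl-like intensity: bright background, dark Poisson somata -----
    rng = np.random.default_rng(config.seed)
    intensity = np.full(config.dims, config.background_intensity, dtype=np.uint8)
    voxel_mm3 = (vs ** 3) * 1e-9
    soma_counts: dict[str, int] = {}
    for acronym, density in sorted(config.densities.items()):
        sid = ontology.id_of(acronym)
        flat = np.flatnonzero(labels == sid)
        if flat.size == 0:
            raise PhantomConfigError(f"structure {acronym!r} rasterized to zero voxels")
        n_somata = int(rng.poisson(density * flat.size * voxel_mm3))
        soma_counts[acronym] = n_somata
        if n_somata:
            chosen = rng.choice(flat, size=n_somata, replace=True)
            if config.soma_radius_um <= vs / 2.0:
                intensity.flat[chosen] = config.soma_intensity
            else:  # stamp small balls for somata larger than a voxel
                r_vox = int(math.ceil(config.soma_radius_um / vs))
                idx = np.stack(np.unravel_index(chosen, config.dims), axis=1)
                for center_idx in idx:
                    sl = tuple(
                        slice(max(c - r_vox, 0), min(c + r_vox + 1, d))
                        for c, d in zip(center_idx, config.dims)
                    )
                    sub = tuple(
                        (np.arange(s.start, s.stop) + 0.5) * vs - c
                        for s, c in zip(sl, center_idx * vs + vs / 2.0)
                    )
                    # distances from the soma centre at this voxel's centre
                    dx, dy, dz = np.meshgrid(*sub, indexing="ij")
                    ball = dx ** 2 + dy ** 2 + dz ** 2 <= config.soma_radius_um ** 2
                    intensity[sl][ball] = config.soma_intensity

    truth = PhantomTruth(
        analytic_volumes_um3=_analytic_volumes(),
        structure_geometry={
            "outline": {"center": OUTLINE_CENTER.tolist(), "semi": OUTLINE_SEMI.tolist(),
                        "s1": S1, "s2": S2},
            "NucA": {k: v.tolist() for k, v in NUC_A.items()},
            "NucB": {k: v.tolist() for k, v in NUC_B.items()},
            "NucC": {k: v.tolist() for k, v in NUC_C.items()},
            "TubeT": dict(TUBE),
            "Shield": dict(PLATE),
            "Isl": [{"center": i["center"].tolist(), "radius": i["radius"]} for i in ISLANDS],
        },
        datum_marks_um={m.name: list(m.position_um) for m in _default_marks()},
        corridor={
            "gap_center_um": [
                float(np.mean(PLATE["gap_ml"])),
                float(np.mean(PLATE["dv"])),
                float(np.mean(PLATE["gap_ap"])),
            ],
            "gap_width_um": float(PLATE["gap_ml"][1] - PLATE["gap_ml"][0]),
            "plate_dv_um": list(PLATE["dv"]),
        },
        soma_counts=soma_counts,
    )
    return PhantomWorld(
        annotation=annotation,
        intensity=Volume(data=intensity, voxel_size=vs),
        outline=outline_mask,
        ontology=ontology,
        truth=truth,
        config=config,
    )


def _analytic_volumes() -> dict:
    def ell(semi):
        return 4.0 / 3.0 * math.pi * float(np.prod(semi))

    outline = ell(OUTLINE_SEMI)
    plate = ((PLATE["ml"][1] - PLATE["ml"][0]) * (PLATE["dv"][1] - PLATE["dv"][0])
             * (PLATE["ap"][1] - PLATE["ap"][0]))
    gap = ((PLATE["gap_ml"][1] - PLATE["gap_ml"][0]) * (PLATE["dv"][1] - PLATE["dv"][0])
           * (PLATE["gap_ap"][1] - PLATE["gap_ap"][0]))
    vols = {
        "Brain": outline,
        "L1": outline * (1.0 - S1 ** 3),
        "L2": outline * (S1 ** 3 - S2 ** 3),
        "NucA": ell(NUC_A["semi"]),
        "NucB": ell(NUC_B["semi"]),
        "NucC": ell(NUC_C["semi"]),
        "TubeT": math.pi * TUBE["radius"] ** 2 * (TUBE["ap"][1] - TUBE["ap"][0]),
        "Shield": plate - gap,
        "Isl": sum(4.0 / 3.0 * math.pi * i["radius"] ** 3 for i in ISLANDS),
    }
    interior = outline * S2 ** 3
    vols["Mx"] = interior - sum(vols[k] for k in ("NucA", "NucB", "NucC", "TubeT", "Shield", "Isl"))
    return vols


# ---------------------------------------------------------------------------
# Datum marks
# ---------------------------------------------------------------------------


def _default_marks() -> list[DatumMark]:
    ic = "intracranial"

    def mk(name, structure, pos, desc):
        return DatumMark(name=name, kind=ic, structure=structure,
                         position_um=tuple(float(v) for v in pos), description=desc)

    a_c, a_s = NUC_A["center"], NUC_A["semi"]
    b_c, b_s = NUC_B["center"], NUC_B["semi"]
    c_c, c_s = NUC_C["center"], NUC_C["semi"]
    l2_mid_dv = OUTLINE_CENTER[1] - OUTLINE_SEMI[1] * (S1 + S2) / 2.0
    l2_mid_ap = OUTLINE_SEMI[2] * (S1 + S2) / 2.0
    marks = [
        mk("NucA-center", "NucA", a_c, "centre of nucleus A"),
        mk("NucA-dorsal-pole", "NucA", a_c - [0, a_s[1], 0], "dorsal pole of nucleus A"),
        mk("NucA-ventral-pole", "NucA", a_c + [0, a_s[1], 0], "ventral pole of nucleus A"),
        mk("NucB-center", "NucB", b_c, "centre of nucleus B"),
        mk("NucB-anterior-pole", "NucB", b_c - [0, 0, b_s[2]], "anterior pole of nucleus B"),
        mk("NucB-posterior-pole", "NucB", b_c + [0, 0, b_s[2]], "posterior pole of nucleus B"),
        mk("NucC-center", "NucC", c_c, "centre of nucleus C"),
        mk("NucC-anterior-pole", "NucC", c_c - [0, 0, c_s[2]], "anterior pole of nucleus C"),
        mk("TubeT-anterior-end", "TubeT",
           [TUBE["axis_ml"], TUBE["axis_dv"], TUBE["ap"][0]], "anterior endpoint of the fibre tube"),
        mk("TubeT-posterior-end", "TubeT",
           [TUBE["axis_ml"], TUBE["axis_dv"], TUBE["ap"][1]], "posterior endpoint of the fibre tube"),
        mk("TubeT-mid", "TubeT",
           [TUBE["axis_ml"], TUBE["axis_dv"], float(np.mean(TUBE["ap"]))], "midpoint of the fibre tube"),
        mk("Shield-left-edge", "Shield",
           [PLATE["ml"][0] + 10.0, float(np.mean(PLATE["dv"])), float(np.mean(PLATE["ap"]))],
           "midpoint of the plate's medial edge"),
        mk("Shield-right-edge", "Shield",
           [PLATE["ml"][1] - 10.0, float(np.mean(PLATE["dv"])), float(np.mean(PLATE["ap"]))],
           "midpoint of the plate's lateral edge"),
        mk("L2-dorsal-pole", "L2",
           [OUTLINE_CENTER[0], l2_mid_dv, OUTLINE_CENTER[2]], "mid-thickness of L2 at the dorsal pole"),
        mk("L2-anterior-pole", "L2",
           [OUTLINE_CENTER[0], OUTLINE_CENTER[1], OUTLINE_CENTER[2] - l2_mid_ap],
           "mid-thickness of L2 at the anterior pole"),
        mk("L2-posterior-pole", "L2",
           [OUTLINE_CENTER[0], OUTLINE_CENTER[1], OUTLINE_CENTER[2] + l2_mid_ap],
           "mid-thickness of L2 at the posterior pole"),
        mk("Isl-1-center", "Isl", ISLANDS[0]["center"], "centre of the first micro-island"),
        mk("Mx-anchor", "Mx",
           [OUTLINE_CENTER[0], OUTLINE_CENTER[1] + 350.0, OUTLINE_CENTER[2]],
           "deep matrix anchor point on the midline"),
    ]
    marks.append(DatumMark(name="bregma", kind="cranial", structure="skull",
                           position_um=tuple(BREGMA), description="bregma (skull midline suture)"))
    marks.append(DatumMark(name="lambda", kind="cranial", structure="skull",
                           position_um=tuple(LAMBDA), description="lambda (skull midline suture)"))
    return marks


def make_phantom_datum_marks(config: PhantomConfig | None = None) -> DatumMarkRegistry:
    """Registry of 18 intracranial marks (8 host structures) plus bregma and
    lambda, mirroring the shape of the released registry. Analytic — no
    volume rasterization needed."""
    registry = DatumMarkRegistry()
    for mark in _default_marks():
        registry.add(mark)
    return registry


# ---------------------------------------------------------------------------
# Neurons
# ---------------------------------------------------------------------------


def _sample_voxel_center(rng: np.random.Generator, labels: np.ndarray,
                         sid: int, vs: float) -> np.ndarray:
    flat = np.flatnonzero(labels == sid)
    if flat.size == 0:
        raise PhantomConfigError(f"structure id {sid} has no voxels to place a node in")
    idx = np.unravel_index(rng.choice(flat), labels.shape)
    return (np.asarray(idx, dtype=float) + 0.5) * vs


def _polyline_nodes(rows, start_id, parent_id, p0, p1, node_type, step_um=100.0):
    """Append chain nodes from (exclusive) p0 to (inclusive) p1; returns the
    id of the final node."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(1, int(math.ceil(length / step_um)))
    nid = start_id
    for k in range(1, n + 1):
        p = p0 + (p1 - p0) * (k / n)
        rows.append((nid, node_type, p[0], p[1], p[2], 1.0, parent_id))
        parent_id = nid
        nid += 1
    return nid, parent_id


def make_phantom_neurons(
    world: PhantomWorld,
    recipes: list[dict] | None = None,
) -> tuple[list[NeuronMorphology], pd.DataFrame]:
    """Generate SWC neurons per recipe with ground-truth key-node regions.

    Each neuron has its soma (SWC type 1) at a voxel centre inside the recipe
    soma structure, an axonal trunk (type 2) to a hub at 30 % of the way to
    the first target, and one branch from the hub to a terminal voxel centre
    inside each recipe target. With ≥2 targets the hub is a branch point.

    Returns the morphologies and a truth table with one row per key node:
    ``(neuron_id, node_kind, structure_id)``.
    """
    config = world.config
    recipes = config.neuron_recipes if recipes is None else recipes
    labels = world.annotation.data
    vs = config.voxel_size_um
    ontology = world.ontology
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    neurons: list[NeuronMorphology] = []
    truth_rows = []
    for recipe in recipes:
        soma_sid = ontology.id_of(recipe["soma"])
        targets = list(recipe["targets"])
        if not targets:
            raise PhantomConfigError(f"neuron {recipe['name']!r} has no targets")
        soma_p = _sample_voxel_center(rng, labels, soma_sid, vs)
        first_target_sid = ontology.id_of(targets[0])
        first_target_p = _sample_voxel_center(rng, labels, first_target_sid, vs)
        hub_p = soma_p + 0.3 * (first_target_p - soma_p)

        rows = [(1, 1, soma_p[0], soma_p[1], soma_p[2], 8.0, -1)]
        next_id, hub_id = _polyline_nodes(rows, 2, 1, soma_p, hub_p, 2)
        terminal_sids = []
        term_points = [first_target_p]
        for acronym in targets[1:]:
            term_points.append(_sample_voxel_center(rng, labels, ontology.id_of(acronym), vs))
        for acronym, term_p in zip(targets, term_points):
            next_id, _last = _polyline_nodes(rows, next_id, hub_id, hub_p, term_p, 2)
            terminal_sids.append(ontology.id_of(acronym))
        frame = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
        neuron = NeuronMorphology(nodes=frame, neuron_id=recipe["name"])
        neurons.append(neuron)

        truth_rows.append((recipe["name"], "soma", soma_sid))
        if len(targets) >= 2:
            hub_idx = np.floor(hub_p / vs).astype(int)
            hub_sid = int(labels[tuple(hub_idx)])
            truth_rows.append((recipe["name"], "branch", hub_sid))
        for sid in terminal_sids:
            truth_rows.append((recipe["name"], "terminal", sid))
    truth = pd.DataFrame(truth_rows, columns=["neuron_id", "node_kind", "structure_id"])
    return neurons, truth


def ground_truth_connectivity(truth: pd.DataFrame, structure_ids) -> dict:
    """Tally the generator's truth table into the same (source, target) →
    neuron-count dictionary the connectivity map produces (leaf level)."""
    counts: dict[tuple[int, int], int] = {}
    for neuron_id, group in truth.groupby("neuron_id", sort=False):
        soma = int(group.loc[group["node_kind"] == "soma", "structure_id"].iloc[0])
        term = set(int(s) for s in group.loc[group["node_kind"] == "terminal", "structure_id"])
        for dst in term:
            if soma in structure_ids and dst in structure_ids:
                counts[(soma, dst)] = counts.get((soma, dst), 0) + 1
    return counts


def phantom_lookup(world: PhantomWorld, grid_step: float | None = None):
    """Region lookup over the phantom annotation (default: voxel-size step)."""
    return build_lookup(world.annotation, grid_step)
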