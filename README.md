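# stereoatlas

Computational services behind a 3D stereotaxic mouse-brain atlas, for
neuroinformatics developers and surgical-planning tool builders. The package
covers the server-side machinery such an atlas needs once the anatomy has
been delineated:

- **atlas core** — hierarchically organized annotation volumes (NRRD /
  NIfTI-1) with a structure ontology, hierarchical mask resolution
  (`mask(parent) = ⋃ mask(children)`), a 10-μm region-lookup table,
  label-completeness ("no terra nullius") validation and Sørensen–Dice
  overlap evaluation, `D(A,B) = 2|A∩B| / (|A|+|B|)`;
- **positioning** — a brain-wide positioning system built on named cranial
  (bregma, lambda) and intracranial datum marks: stereotaxic frames
  `s = R(p − o)` with any mark as origin and (AP, ML, DV) axes, the
  flat-skull pitch correction (rotate about the ML axis through bregma until
  bregma and lambda share a dorsoventral height), and landmark-based
  12-parameter affine alignment between atlas spaces;
- **reslicer** — canonical (coronal / sagittal / horizontal) and
  arbitrary-angle plane extraction with configurable projection thickness;
  bright-field Nissl semantics by default (dark somata on a bright
  background ⇒ minimum-intensity projection), plus grey-level-index (GLI)
  cortical-depth profiles;
- **chunk_store** — a chunked multi-resolution volume format (power-of-2
  pyramid diced into 256³ cubes) with bit-exact region-of-interest cropping
  and reslicing that reads only the cubes under a plane's footprint;
- **surgery** — virtual stereotaxic surgery: enumerate the structures a
  straight injection path traverses, search (seeded random rays from the
  target) for a path that avoids forbidden structures, and report
  bregma-referenced insertion coordinates and angles;
- **neuron_mapper** — SWC morphology ingestion, key-node extraction (soma,
  branch points, terminals), region assignment, and directional
  region-to-region connectivity: `count(A→B)` = number of neurons with soma
  in A and ≥1 axonal terminal in B;
- **mesher** — rasterization of per-plane vector boundaries into a 10-μm
  annotation stack, marching-cubes surface reconstruction, Laplacian
  smoothing, and hierarchical assembly of parent surfaces from the union
  mask of their parts;
- **phantom** — a seeded synthetic atlas world (labelled ellipsoidal brain
  with shell layers, nuclei, fibre tube, gapped plate and micro-islands,
  Nissl-like intensity, datum marks, SWC neurons) with analytic ground
  truth, so every service is testable without downloading any released
  dataset.

See `docs/methods.md` for the conventions (axes, half-open voxel cells,
projection semantics) and the design decisions.

## Worked example

Plan an injection into the phantom's deep nucleus `NucA`, which is capped
dorsally by a cell-free fibre plate (`Shield`) with a single 200-μm gap:

```python
import numpy as np
from stereoatlas import core, phantom, positioning, surgery

world = phantom.make_phantom_atlas(phantom.PhantomConfig(seed=7))
lookup = core.build_lookup(world.annotation)          # 10-μm region table

target = world.truth.structure_geometry["NucA"]["center"]   # (1280, 900, 1500) μm
plan = surgery.plan_avoiding(
    lookup, target, [world.ontology.id_of("Shield")], world.ontology,
    surgery.PlanConfig(seed=5, max_rays=5000),
)
frame = positioning.make_frame(positioning.default_registry(), "bregma")
report = surgery.trajectory_report(frame, plan)
print({k: round(v, 1) for k, v in report.to_dict().items() if k != "origin_mark"})

record = surgery.path_structures(lookup, plan, world.ontology, step_um=5.0)
for iv in record.intervals:
    name = "outside" if iv.structure_id == 0 else world.ontology.node(iv.structure_id).acronym
    print(f"{iv.entry_depth_um:7.1f} – {iv.exit_depth_um:7.1f} μm  {name}")
```

prints

```
{'entry_ap_um': 149.0, 'entry_ml_um': 613.2, 'entry_dv_um': 260.9, 'depth_um': 1085.0, 'tilt_deg': 59.0, 'azimuth_deg': -138.7}
    0.0 –   252.5 μm  L1
  252.5 –   642.5 μm  L2
  642.5 –   912.5 μm  Mx
  912.5 –  1085.0 μm  NucA
```

Reading: the planner's first qualifying ray enters 149 μm anterior and
613 μm right of bregma and comes in steeply (59° from vertical) — it clears
the forbidden plate laterally rather than through its gap. The 1,085-μm
path crosses the two cortical shell layers and the deep matrix into the
nucleus, and — re-checked against the lookup table — never touches the
forbidden structure.
The same services run from the shell (`atlas plan`, `atlas path`,
`atlas slice`, `atlas store build/crop`, `atlas neurons map/query`,
`atlas mesh`, `atlas phantom`; see `atlas --help`).

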