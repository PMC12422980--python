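# Methods

This note documents the models, conventions and design decisions behind the
package, in the order a user meets them.

## Coordinate conventions

All physical coordinates are micrometres. Voxel indexing is 0-based and
cells are half-open: a point `p` belongs to voxel `floor((p − origin) /
voxel_size)`, so points exactly on a cell boundary belong to the
higher-index voxel. The centre of voxel `i` is at `origin + (i + 0.5) ·
voxel_size`. This single rule makes point lookup, label reslicing, neuron
assignment and path sampling mutually consistent and bit-reproducible.

Grid axes carry anatomical meaning: axis 0 runs right→left across the
hemispheres (medio-lateral), axis 1 dorsal→ventral, axis 2
anterior→posterior. Stereotaxic frames map a point to (AP, ML, DV) relative
to a datum-mark origin, with AP positive anterior, ML positive toward the
animal's right and DV positive ventral (insertion depth). With the grid
directions above this axis assignment is a *proper* rotation (determinant
+1), which is why the right→left direction of axis 0 was chosen; frames
validate orthonormality and reject reflections. Alternative sign
conventions can be passed to `make_frame`, subject to the same properness
check.

Background / extracranial space is structure id 0 everywhere. It is not an
ontology node, and spatial queries are total functions: out-of-volume
points return 0 rather than raising, because path planning and neuron
mapping must probe space freely.

## Ontology and hierarchical masks

The ontology is a forest (unique ids and acronyms, cycle-checked). Only
most-detailed (leaf) structures may label voxels; a parent's mask is
defined as the voxelwise union of its descendants' voxels, so hierarchical
roll-up identities are exact by construction and are asserted in tests. The
ontology file is a flat JSON id/parent table — round-trippable and
diff-friendly.

## Region lookup

`build_lookup` tabulates, at a grid step that defaults to the annotation
voxel size (10 μm in the phantom), the most-detailed structure containing
each lattice cell's centre. The step must not be finer than the voxel size.
At the default (identity) step a point query is exactly nearest-voxel
indexing — the oracle-equivalence test compares 10⁴ random points against
direct indexing bitwise.

## Dice evaluation

Standard Sørensen–Dice, `2|A∩B| / (|A| + |B|)`. Two empty masks score 1.0
(perfect agreement on absence), which keeps per-structure averages NaN-free
when a structure is missing from both volumes. `dice_mean` averages,
unweighted, over an explicit caller-chosen structure list — the averaging
set is a reporting decision, not something the library should guess.

## Reslicing and projections

The imagery these tools target is bright-field Nissl: somata are dark on a
bright background, so a slab is collapsed by **minimum**-intensity
projection by default (maximum serves fluorescence polarity; mean is also
available). The intended projection thickness range is 1–20 μm.

The base (zero-angle) oblique plane is coronal, in-plane axes u =
medio-lateral, v = dorso-ventral, normal n = antero-posterior. Angles are
intrinsic and applied yaw (about the DV axis) → pitch (about the ML axis) →
roll (about the plane normal), right-handed, in degrees; an explicit
rotation matrix can override the angles. Intensity is sampled trilinearly;
samples outside the volume are excluded from the projection (pixels with no
in-volume sample are 0). The sampling step along the normal is
`min(voxel_size, pixel_size)`, which avoids skipping voxels without
oversampling. Label volumes are sampled by nearest voxel under the floor
convention and are **never** projected — a "minimum of ids" is meaningless —
so label mode reads the slab centre plane only, and label slices can
contain only ids present in the source.

With zero angles, a grid-aligned position and pixels on voxel centres, the
oblique extractor reproduces the canonical slice pixel-for-pixel
(`canonical_plane_spec` constructs exactly that geometry); a 90° yaw
reproduces the sagittal slice up to the documented column flip (u = −AP).

`count_levels(extent, thickness) = floor(extent / thickness)` — e.g. a
14,000-μm antero-posterior extent at 20-μm thickness gives 700 coronal
levels. No comparable closed form is claimed for other axes' published
level counts, which do not arise from a uniform partition.

**Grey-level index.** The GLI profile along a cortical-depth line is the
fraction of "stained" pixels per depth bin within a band (default 50 μm)
around the line; stained = below threshold for bright-field (above, for
fluorescence), with Otsu's threshold on the sampled band as default. Bin
fractions weighted by bin pixel counts conserve the band's overall stained
fraction by construction. This is the classical area-fraction definition;
all parameters are exposed.

## Chunked multi-resolution store

Volumes are stored as a power-of-2 pyramid diced into fixed-edge cubes
(256 voxels per edge by default), raw little-endian C-order, one file per
cube (`level_k/z{zi}_y{yi}_x{xi}.bin`) plus a `meta.json`. The dialect is
self-defined and documented in the module; byte-level compatibility with
any released chunked format is explicitly not attempted. Level 0 is
lossless (edge cubes zero-padded; round trips are bit-exact for any dtype
and any dims). Level k halves level k−1: block mean for intensity (edge
blocks average only existing voxels, conserving means), stride-2 nearest
for labels (ids are categorical and must not be averaged). Down-sampling
factors are powers of 2 only, so every level has an exact level-0 preimage.

ROI reads touch only the cubes the request overlaps (an instrumented
counter makes this assertable). Reslicing from the store bounds the plane's
sampling slab, pads by two voxels for interpolation support, reads that box
and runs the ordinary reslicer on it — pixel-identical to reslicing the
materialized level.

## Virtual surgery

A trajectory's traversal record samples the path every `step` μm (default
5 μm — half the 10-μm lookup grid, so no lookup cell on the path can be
skipped) and merges consecutive identical labels; interval boundaries are
placed at run midpoints and are accurate to ±step. Intervals tile the whole
path; extracranial runs are kept with id 0. Structures thinner than the
step can still be missed at coarser user-chosen steps — the phantom
contains a 30-μm micro-island that documents exactly this sensitivity.

The planner emits rays *from the target* in seeded random directions,
uniform on a spherical cap about the dorsal direction (default half-angle
90°, i.e. the full upper hemisphere — surgical access is from above; the
cone is configurable). A ray qualifies when no sample strictly between the
brain-surface crossing and the target lies in a forbidden structure, with
forbidden sets resolved hierarchically through the ontology; the target's
own most-detailed structure and extracranial space are always exempt (the
needle must reach the target through its host structure). The first
qualifying ray is returned — no optimality is claimed — and identical seeds
return identical plans. On failure the report carries the number of rays
tried and the stopping reason (ray budget or time limit).

Insertion reports are stereotaxic: entry (AP, ML, DV), depth along the
needle, tilt from vertical and azimuth (from AP+ toward ML+). A report
regenerates its trajectory to within 1e−3 μm.

## Neuron mapping

SWC trees are validated strictly: one root, parents declared before
children, 7 columns, errors with line numbers. Key nodes: the soma is the
first type-1 node (falling back to the root — SWC typing conventions vary
across repositories); branch points are nodes with ≥2 children; terminals
are childless nodes. The soma is excluded from the other two kinds whatever
its degree, keeping the three kinds disjoint. Every key node is localized
through the lookup; out-of-volume nodes are kept as "outside", never
dropped, so row counts are conserved.

Connectivity counts **neurons**, not terminals: soma in A and ≥1 terminal
in B contributes 1 to (A, B), however many terminals land in B (a
terminal-weighted variant sits behind a flag). By default only axonal
(type-2) terminals count toward connectivity — projection semantics — while
the relation table keeps all leaves for broader queries; when a morphology
carries no type information, all terminals are used. Efferents of a region
are neurons with soma in it; afferents have ≥1 terminal in it and soma
elsewhere. No minimum-terminal threshold is applied to weak projections.

## Meshing

Per-plane closed polygons are filled with the nonzero-winding rule at
pixel centres, later polygon winning on overlap with a logged conflict
count, and each plane is replicated across its `spacing / voxel` axial
slabs (20-μm planes → two 10-μm slabs). Marching cubes runs at iso-level
0.5 on the binary mask with no pre-blur (reproducibility over cosmetics),
with a one-voxel zero pad so surfaces close even at the grid border.
Parent surfaces are meshed from the union mask of their descendants —
never by concatenating child meshes — so abutting children leave no
interior walls.

Laplacian smoothing uses uniform weights (default 20 iterations, relaxation
0.1): vertices move a fixed fraction toward their edge-neighbour mean, and
vertex/face sets — hence connectivity, components and genus — are unchanged;
zero iterations or zero relaxation is the identity. Decimation is a
separate concern and deliberately out of scope. Known bias: very small
blobs are under-estimated by marching cubes (a lone voxel meshes to an
octahedron of 1/6 the voxel volume); for blobs ≥ ~10 voxels across, mesh
volume tracks the analytic volume to within a few per cent (0.05 % for a
50-voxel-radius sphere), converging as size grows, although consecutive
radii can tie within rasterization phase noise.

## The phantom world

The generator is a pure function of its config and seed (byte-identical
reruns). The default world is a 1/5-scale brain — 256×200×300 voxels at
10 μm — chosen so the full suite runs in about a minute on one core, with:
an ellipsoidal outline (semi-axes 1200 × 920 × 1450 μm); two concentric
shell layers whose thicknesses at the dorsal pole are 200 μm (L1, sparse)
and 300 μm (L2, dense), giving a laminated profile for GLI tests; a deep
matrix; three nuclei; a cell-free fibre tube; a cell-free plate capping the
dorsal approach to nucleus A with one 200-μm gap (the planner's feasible
corridor, well over twice the 5-μm sampling step); and three micro-islands
25/15/25 μm in radius. The interior is fully labelled, so seamlessness
holds by construction and is asserted, not assumed.

Somata are Poisson-sampled per structure (counts ~ Poisson(density ×
volume), centres uniform over the structure's voxels, collisions allowed)
and drawn dark (intensity 40) on a bright background (255), exercising
minimum-intensity projection. Default densities are in the range of rodent
cytoarchitecture at this voxel size: 2×10⁴ /mm³ (L1), 1.5×10⁵ /mm³ (dense
L2), 5×10⁴ /mm³ (matrix), 10⁵ /mm³ (nuclei), 0 for fibre structures,
4×10⁵ /mm³ (islands). At 10-μm voxels a 5-μm-radius soma occupies one
voxel; larger radii are stamped as balls.

Datum marks are analytic (shape centres, poles, endpoints): 18 intracranial
marks drawn from 8 structures plus bregma and lambda placed above the
outline on the midline, with lambda 180 μm ventral of bregma so the
flat-skull correction has a non-trivial pitch. The packaged registry file
is generated from this geometry; a released registry can be dropped into
the same JSON dialect without code changes.

Phantom neurons place the soma and each terminal at voxel centres inside
their recipe structures (so region assignment is exact by construction),
with an axonal trunk to a hub at 30 % of the way to the first target and
one branch per target; with ≥2 targets the hub is a branch point, whose
containing structure is recorded from the label volume.

**What the phantom does not emulate:** real neuroanatomy (shapes are
parametric solids), imaging physics (no noise, shading or sectioning
artefacts), non-convex brain outlines, and partial-volume effects at
boundaries. Passing tests therefore demonstrate the correctness of the
geometry, bookkeeping and algorithms — not robustness to real-data
artefacts or registration error, which live upstream of this package.

## Numerical choices and degenerate inputs

- Affine fits require ≥4 landmark pairs with full-rank (non-coplanar)
  design; residuals are reported per pair in μm. Exact pairs are recovered
  to ~1e−12 μm.
- The flat-skull transform is a single pitch about the ML axis through
  bregma (bregma and lambda are midline points, so one angle is the minimal
  transform; no roll correction is applied for off-midline asymmetry).
  Coincident bregma/lambda is rejected as degenerate.
- Zero-length trajectories, empty masks, empty plane lists, sub-voxel
  lookup steps, planes fully outside the volume and disjoint ROI boxes all
  raise with specific messages rather than returning empty results.
- Slab membership for projections uses half-open μm intervals with a 1e−9
  tolerance so that one-voxel-thick slabs reproduce raw grid slices
  exactly.

## Problem sizes used in the checks

The shipped verification runs use: the 256×200×300 phantom; 10⁴ random
points for lookup equivalence; a 512³ random volume (2×2×2 cube grid) for
store conformance with 20 random oblique planes; 100 seeded planner runs;
a radius-50-voxel sphere for mesh volume. These sizes make the whole suite
and the reproduction script each finish in about a minute on one core
while still exercising multi-cube access paths and statistical checks.
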