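"""Single-neuron morphology ingestion and region-to-region connectivity.

Neurons arrive as SWC trees already registered to the atlas frame. The key
nodes of a morphology are its soma, its branching points (≥2 children) and
its terminals (childless nodes); each key node is localized through the
region lookup into a relation table, and directional connectivity between
brain structures is counted as: neuron soma in A, at least one terminal in
B ⇒ one count on A→B (per neuron, not per terminal).

SWC conventions: `#` comment lines; 7 whitespace-separated columns
(id, type, x, y, z, radius, parent); exactly one root (parent −1); parents
declared before children. Type 1 marks the soma, type 2 axon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .core import OUTSIDE, RegionLookup, lookup_point
from .ontology import Ontology

__all__ = [
    "NeuronMorphology",
    "KeyNodes",
    "SwcParseError",
    "read_swc",
    "write_swc",
    "key_nodes",
    "assign_regions",
    "connectivity_map",
    "query_connections",
]

SWC_SOMA = 1
SWC_AXON = 2

NODE_KINDS = ("soma", "branch", "terminal")


class SwcParseError(ValueError):
    """Malformed SWC content (bad row, dangling parent, multiple roots...)."""


@dataclass
class NeuronMorphology:
    """An SWC tree: one row per node, exactly one root."""

    nodes: pd.DataFrame  # columns: id, type, x, y, z, radius, parent
    neuron_id: str

    def __post_init__(self) -> None:
        roots = self.nodes[self.nodes["parent"] == -1]
        if len(roots) != 1:
            raise SwcParseError(
                f"neuron {self.neuron_id!r}: expected exactly one root, found {len(roots)}"
            )
        declared: set[int] = set()
        for row in self.nodes.itertuples(index=False):
            if row.parent != -1 and row.parent not in declared:
                raise SwcParseError(
                    f"neuron {self.neuron_id!r}: node {row.id} references parent "
                    f"{row.parent} not declared earlier"
                )
            declared.add(row.id)
        coords = self.nodes[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise SwcParseError(f"neuron {self.neuron_id!r}: non-finite coordinates")

    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent"] == -1, "id"].iloc[0])

    def child_counts(self) -> pd.Series:
        counts = self.nodes["parent"].value_counts()
        counts = counts.reindex(self.nodes["id"], fill_value=0)
        counts.index.name = "id"
        return counts

    def position_of(self, node_id: int) -> np.ndarray:
        row = self.nodes.set_index("id").loc[node_id]
        return np.asarray([row["x"], row["y"], row["z"]], dtype=float)


@dataclass
class KeyNodes:
    """Soma, branch points and terminals of one morphology (node-id lists;
    the three kinds are disjoint — the soma is never also a branch point or
    terminal, whatever its degree)."""

    soma: int
    branch_points: list[int]
    terminals: list[int]


def read_swc(path: str | Path, neuron_id: str | None = None) -> NeuronMorphology:
    """Parse an SWC file, validating topology; errors carry the line number."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 7:
            raise SwcParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            rows.append(
                (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                 float(parts[4]), float(parts[5]), int(parts[6]))
            )
        except ValueError as exc:
            raise SwcParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise SwcParseError(f"{path}: no SWC node rows")
    frame = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    if frame["id"].duplicated().any():
        dup = int(frame.loc[frame["id"].duplicated(), "id"].iloc[0])
        raise SwcParseError(f"{path}: duplicate node id {dup}")
    return NeuronMorphology(nodes=frame, neuron_id=neuron_id or path.stem)


def write_swc(path: str | Path, neuron: NeuronMorphology) -> None:
    buf = StringIO()
    buf.write(f"# {neuron.neuron_id}\n# id type x y z radius parent\n")
    for row in neuron.nodes.itertuples(index=False):
        buf.write(f"{row.id} {row.type} {row.x:.3f} {row.y:.3f} {row.z:.3f} "
                  f"{row.radius:.3f} {row.parent}\n")
    Path(path).write_text(buf.getvalue())


def key_nodes(neuron: NeuronMorphology) -> KeyNodes:
    """Extract the key nodes: soma = first node of SWC type 1 (falling back
    to the root), branch points = nodes with ≥2 children, terminals =
    childless nodes; the soma is excluded from the other two kinds."""
    typed = neuron.nodes.loc[neuron.nodes["type"] == SWC_SOMA, "id"]
    soma = int(typed.iloc[0]) if len(typed) else neuron.root_id
    counts = neuron.child_counts()
    branch = [int(i) for i in counts[counts >= 2].index if i != soma]
    terminal = [int(i) for i in counts[counts == 0].index if i != soma]
    return KeyNodes(soma=soma, branch_points=branch, terminals=terminal)


TABLE_COLUMNS = ["neuron_id", "node_kind", "node_id", "swc_type", "structure_id", "acronym"]


def assign_regions(
    lookup: RegionLookup,
    ontology: Ontology,
    neuron: NeuronMorphology,
) -> pd.DataFrame:
    """Localize every key node through the lookup into relation-table rows.

    Out-of-volume nodes are kept with structure id 0 and acronym "outside",
    never dropped. One row per key node: 1 soma + #branch + #terminals.
    """
    keys = key_nodes(neuron)
    swc_types = neuron.nodes.set_index("id")["type"]
    rows = []
    for kind, ids in (("soma", [keys.soma]), ("branch", keys.branch_points),
                      ("terminal", keys.terminals)):
        for node_id in ids:
            sid, _chain = lookup_point(lookup, neuron.position_of(node_id), ontology)
            acr = "outside" if sid == OUTSIDE else ontology.node(sid).acronym
            rows.append((neuron.neuron_id, kind, node_id, int(swc_types.loc[node_id]), sid, acr))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _soma_structures(tables: pd.DataFrame) -> pd.Series:
    somata = tables[tables["node_kind"] == "soma"]
    return somata.set_index("neuron_id")["structure_id"]


def _terminal_rows(tables: pd.DataFrame, axon_only: bool) -> pd.DataFrame:
    term = tables[tables["node_kind"] == "terminal"]
    if axon_only and (term["swc_type"] == SWC_AXON).any():
        term = term[term["swc_type"] == SWC_AXON]
    return term


@dataclass
class ConnectivityMap:
    """Directed neuron counts between structures at a chosen ontology level.

    ``counts[(source, target)]`` is the number of neurons with soma in
    (a descendant of) ``source`` and ≥1 terminal in ``target``; a neuron with
    terminals in k regions contributes to k pairs, once each. The optional
    terminal-weighted variant counts terminals instead of neurons.
    """

    counts: dict[tuple[int, int], int]
    structure_ids: list[int]
    weighted: bool = False

    def count(self, source_id: int, target_id: int) -> int:
        return self.counts.get((source_id, target_id), 0)

    def to_frame(self) -> pd.DataFrame:
        mat = pd.DataFrame(0, index=self.structure_ids, columns=self.structure_ids, dtype=int)
        for (src, dst), n in self.counts.items():
            mat.loc[src, dst] = n
        return mat


def connectivity_map(
    tables: pd.DataFrame,
    ontology: Ontology,
    structure_ids,
    *,
    axon_only: bool = True,
    weighted: bool = False,
) -> ConnectivityMap:
    """Build the region-to-region connectivity map over an explicit structure
    set (e.g. all leaves, or one hierarchy level). Source/target membership
    is resolved hierarchically: soma/terminal structures are matched against
    each requested structure's descendants."""
    ids = [int(i) for i in structure_ids]
    desc = {i: ontology.descendants(i) for i in ids}  # raises for unknown ids
    soma_by_neuron = _soma_structures(tables)
    terms = _terminal_rows(tables, axon_only)
    counts: dict[tuple[int, int], int] = {}
    for neuron_id, soma_sid in soma_by_neuron.items():
        neuron_terms = terms.loc[terms["neuron_id"] == neuron_id, "structure_id"]
        term_sids = set(int(s) for s in neuron_terms)
        for src in ids:
            if int(soma_sid) not in desc[src]:
                continue
            for dst in ids:
                if weighted:
                    w = int(sum(1 for s in neuron_terms if int(s) in desc[dst]))
                else:
                    w = int(bool(term_sids & desc[dst]))
                if w:
                    counts[(src, dst)] = counts.get((src, dst), 0) + w
    return ConnectivityMap(counts=counts, structure_ids=ids, weighted=weighted)


def query_connections(
    tables: pd.DataFrame,
    ontology: Ontology,
    region_id: int,
    direction: str,
    *,
    axon_only: bool = True,
) -> pd.DataFrame:
    """Neurons afferent to / efferent from a region.

    Efferents: neurons with soma in the region (resolved hierarchically).
    Afferents: neurons with ≥1 terminal in the region and soma elsewhere.
    Returns one row per neuron with its soma structure and the sorted list of
    terminal structures.
    """
    if direction not in ("afferent", "efferent"):
        raise ValueError(f"direction must be 'afferent' or 'efferent', got {direction!r}")
    members = ontology.descendants(region_id)
    soma_by_neuron = _soma_structures(tables)
    terms = _terminal_rows(tables, axon_only)
    rows = []
    for neuron_id, soma_sid in soma_by_neuron.items():
        term_sids = sorted(
            int(s) for s in terms.loc[terms["neuron_id"] == neuron_id, "structure_id"]
        )
        soma_in = int(soma_sid) in members
        term_in = any(s in members for s in term_sids)
        selected = soma_in if direction == "efferent" else (term_in and not soma_in)
        if selected:
            rows.append((neuron_id, int(soma_sid), term_sids))
    return pd.DataFrame(rows, columns=["neuron_id", "soma_structure_id", "terminal_structure_ids"])
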