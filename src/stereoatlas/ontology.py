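"""Hierarchical ontology of named brain structures.

The ontology is a forest of structures: every node has an integer id, a short
acronym, a display name, an optional parent and an RGB colour. Leaves are the
"most-detailed" structures — the only ids that may appear in an annotation
volume. Parent regions are, by definition, the union of their children.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class OntologyError(ValueError):
    """Raised for malformed ontologies or unknown structure ids."""


@dataclass(frozen=True)
class StructureNode:
    id: int
    acronym: str
    name: str
    parent_id: int | None = None
    color: tuple[int, int, int] = (128, 128, 128)


@dataclass
class Ontology:
    """A forest of brain structures with fast id/acronym access.

    Background/outside space carries id 0 and is deliberately *not* a node:
    spatial queries return 0 for points outside any labelled structure and
    never raise.
    """

    nodes: dict[int, StructureNode] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._children: dict[int, list[int]] = {i: [] for i in self.nodes}
        acronyms: dict[str, int] = {}
        for node in self.nodes.values():
            if node.id == 0:
                raise OntologyError("structure id 0 is reserved for background")
            if node.acronym in acronyms:
                raise OntologyError(f"duplicate acronym {node.acronym!r}")
            acronyms[node.acronym] = node.id
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise OntologyError(
                        f"node {node.id} references unknown parent {node.parent_id}"
                    )
                self._children[node.parent_id].append(node.id)
        self._by_acronym = acronyms
        self._check_forest()

    def _check_forest(self) -> None:
        # Walk each node to its root; a revisit along one chain is a cycle.
        for start in self.nodes:
            seen = set()
            cur: int | None = start
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"parent links contain a cycle through {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id

    # -- access ---------------------------------------------------------

    def __contains__(self, structure_id: int) -> bool:
        return structure_id in self.nodes

    def __iter__(self) -> Iterator[StructureNode]:
        return iter(self.nodes.values())

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, structure_id: int) -> StructureNode:
        try:
            return self.nodes[structure_id]
        except KeyError:
            raise OntologyError(f"unknown structure id {structure_id}") from None

    def id_of(self, acronym: str) -> int:
        try:
            return self._by_acronym[acronym]
        except KeyError:
            raise OntologyError(f"unknown acronym {acronym!r}") from None

    @property
    def roots(self) -> list[int]:
        return [n.id for n in self.nodes.values() if n.parent_id is None]

    def children(self, structure_id: int) -> list[int]:
        self.node(structure_id)
        return list(self._children[structure_id])

    def leaves(self) -> set[int]:
        """Ids of most-detailed structures (nodes without children)."""
        return {i for i in self.nodes if not self._children[i]}

    def descendants(self, structure_id: int) -> set[int]:
        """The structure itself plus all transitive children."""
        self.node(structure_id)
        out: set[int] = set()
        stack = [structure_id]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(self._children[cur])
        return out

    def ancestors(self, structure_id: int) -> list[int]:
        """Path from the structure up to (and including) its root."""
        node = self.node(structure_id)
        chain = [node.id]
        while node.parent_id is not None:
            node = self.nodes[node.parent_id]
            chain.append(node.id)
        return chain

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "id": n.id,
                    "acronym": n.acronym,
                    "name": n.name,
                    "parent_id": n.parent_id,
                    "color": list(n.color),
                }
                for n in self.nodes.values()
            ]
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_nodes(cls, nodes: Iterable[StructureNode]) -> "Ontology":
        table: dict[int, StructureNode] = {}
        for node in nodes:
            if node.id in table:
                raise OntologyError(f"duplicate structure id {node.id}")
            table[node.id] = node
        return cls(table)

    @classmethod
    def load(cls, path: str | Path) -> "Ontology":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise OntologyError(f"cannot parse ontology file {path}: {exc}") from exc
        return cls.from_records(payload["nodes"])

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "Ontology":
        """Build from a flat id/parent table (list of dicts)."""
        nodes = []
        for rec in records:
            nodes.append(
                StructureNode(
                    id=int(rec["id"]),
                    acronym=str(rec["acronym"]),
                    name=str(rec.get("name", rec["acronym"])),
                    parent_id=None if rec.get("parent_id") is None else int(rec["parent_id"]),
                    color=tuple(rec.get("color", (128, 128, 128))),  # type: ignore[arg-type]
                )
            )
        return cls.from_nodes(nodes)


def descendants(ontology: Ontology, structure_id: int) -> set[int]:
    """Functional alias for :meth:`Ontology.descendants`."""
    return ontology.descendants(structure_id)
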