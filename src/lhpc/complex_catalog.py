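"""Selection and pruning of protein complexes from the ontology.

A protein complex (PC) is any non-obsolete cellular-component term whose
name contains the substring "complex" (case-insensitive), with its directly
annotated gene products as members. Gene annotations are NOT propagated up
the is_a/part_of hierarchy: many complex terms naturally nest (a receptor
complex inside the channel complex containing it), and propagation would
turn every parent into the union of its children, defeating the
parent-removal step below.

Pruning removes, in order: parents of parents (terms with a kept child that
itself has a kept child), unless all their direct kept children are devoid
of proteins, in which case removal would lose the parent's own annotations;
the three generic umbrella terms (protein complex, transcription factor
complex, macromolecular complex); and complexes left with fewer than two
members.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .types import AnnotationRow, OntologyTerm, ProteinGroup

logger = logging.getLogger(__name__)

#: umbrella terms too generic to be meaningful complexes
GENERIC_TERMS = frozenset({"GO:0043234", "GO:0005667", "GO:0032991"})


@dataclass
class ComplexCatalog:
    """Pruned complex set plus the hierarchy over every selected term.

    ``hierarchy`` is a child -> parent digraph over all selected
    complex-named terms, kept and removed alike: redundancy analysis needs
    parent links through pruned terms.
    """

    complexes: dict[str, ProteinGroup]
    hierarchy: nx.DiGraph
    removal_log: dict[str, str] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)
    n_selected: int = 0

    @property
    def n_kept(self) -> int:
        return len(self.complexes)

    def class_counts(self) -> dict[str, int]:
        from collections import Counter

        return dict(Counter(self.classification.values()))

    def groups(self) -> list[ProteinGroup]:
        return [self.complexes[t] for t in sorted(self.complexes)]

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive is_a/part_of ancestors of a selected term."""
        if term_id not in self.hierarchy:
            return set()
        return set(nx.descendants(self.hierarchy, term_id))

    def parents(self, term_id: str) -> set[str]:
        if term_id not in self.hierarchy:
            return set()
        return set(self.hierarchy.successors(term_id))


def select_and_prune_complexes(
    terms: Sequence[OntologyTerm],
    annotations: Sequence[AnnotationRow],
    namespace: str = "cellular_component",
) -> ComplexCatalog:
    by_id = {t.term_id: t for t in terms}
    selected = sorted(
        t.term_id
        for t in terms
        if not t.obsolete
        and t.namespace == namespace
        and "complex" in t.name.lower()
    )
    selected_set = set(selected)

    members: dict[str, set[str]] = {t: set() for t in selected}
    for ann in annotations:
        if ann.term_id not in by_id:
            logger.warning("annotation %s -> %s references an unknown term; dropped",
                           ann.entrez_id, ann.term_id)
            continue
        if ann.term_id in members:
            members[ann.term_id].add(ann.entrez_id)

    # child -> parent edges restricted to the selected complex-named set
    hier = nx.DiGraph()
    hier.add_nodes_from(selected)
    for tid in selected:
        for _, pid in by_id[tid].parents:
            if pid in selected_set:
                hier.add_edge(tid, pid)

    # three-way classification: a parent of a parent has a kept child that
    # itself has a kept child (depth 2, not transitive closure)
    has_child = {t: hier.in_degree(t) > 0 for t in selected}
    classification: dict[str, str] = {}
    for tid in selected:
        children = list(hier.predecessors(tid))
        if not children:
            classification[tid] = "non_parent"
        elif any(has_child[c] for c in children):
            classification[tid] = "parent_of_parent"
        else:
            classification[tid] = "parent"

    removal: dict[str, str] = {}
    for tid in selected:
        if classification[tid] == "parent_of_parent":
            children = list(hier.predecessors(tid))
            if any(members[c] for c in children):
                removal[tid] = "parent_of_parent"
    for tid in selected:
        if tid in GENERIC_TERMS and tid not in removal:
            removal[tid] = "generic"
    for tid in selected:
        if tid not in removal and len(members[tid]) <= 1:
            removal[tid] = "singleton"

    complexes = {
        tid: ProteinGroup(group_id=tid, role="complex",
                          proteins=frozenset(members[tid]), name=by_id[tid].name)
        for tid in selected
        if tid not in removal
    }
    logger.info(
        "selected %d complex terms -> kept %d (removed: %s); classes %s",
        len(selected), len(complexes),
        {r: sum(1 for v in removal.values() if v == r) for r in set(removal.values())},
        {c: sum(1 for v in classification.values() if v == c) for c in set(classification.values())},
    )
    return ComplexCatalog(
        complexes=complexes,
        hierarchy=hier,
        removal_log=removal,
        classification=classification,
        n_selected=len(selected),
    )


def write_complexes(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tname\tn_proteins\tproteins\n")
        for tid in sorted(catalog.complexes):
            g = catalog.complexes[tid]
            fh.write(f"{tid}\t{g.name}\t{g.size}\t{';'.join(sorted(g.proteins))}\n")


def write_removals(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\treason\n")
        for tid in sorted(catalog.removal_log):
            fh.write(f"{tid}\t{catalog.removal_log[tid]}\n")
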