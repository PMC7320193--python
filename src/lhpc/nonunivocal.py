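"""Univocity analysis of the group-complex relation.

A phenotypic series ideally pairs with exactly one complex (a univocal 1:1
relation). Two kinds of apparent exceptions are mostly annotation
redundancy, and are filtered out:

* one PS intersecting several complexes, where the complexes are (in
  precedence order) in a parent-child relation, children of a shared
  parent complex, or variants sharing more than half the smaller
  complex's protein content;
* several PS intersecting one complex while annotating a common protein —
  allele heterogeneity of that protein rather than two independent series.

Parent-child detection uses the transitive closure of is_a/part_of over
ALL selected complex-named terms, including ones pruned from the analysis
set (the shared parent itself may have been pruned). Common-parent
detection uses direct parents, excluding the three generic umbrella terms
every complex ultimately descends from.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx

from .complex_catalog import GENERIC_TERMS, ComplexCatalog
from .types import DiseaseGenePair, IntersectionRecord

ONE_TO_MANY_REASONS = ("parent_child", "common_parent", "majority_shared")


@dataclass(frozen=True)
class PcPairRecord:
    group_id: str
    term_a: str
    term_b: str
    status: str             # kept | discarded
    reason: str = ""        # one of ONE_TO_MANY_REASONS when discarded


@dataclass(frozen=True)
class PsPairRecord:
    term_id: str
    group_a: str
    group_b: str
    status: str             # kept | discarded
    reason: str = ""        # allele_heterogeneity when discarded


@dataclass
class RelationClassification:
    univocal: list[str] = field(default_factory=list)          # group ids
    non_univocal: list[str] = field(default_factory=list)      # group ids
    one_to_many_kept: list[PcPairRecord] = field(default_factory=list)
    one_to_many_discarded: list[PcPairRecord] = field(default_factory=list)
    many_to_one_kept: list[PsPairRecord] = field(default_factory=list)
    many_to_one_discarded: list[PsPairRecord] = field(default_factory=list)


def _is_parent_child(catalog: ComplexCatalog, a: str, b: str) -> bool:
    return b in catalog.ancestors(a) or a in catalog.ancestors(b)


def _share_direct_parent(catalog: ComplexCatalog, a: str, b: str) -> bool:
    common = (catalog.parents(a) & catalog.parents(b)) - GENERIC_TERMS - {a, b}
    return bool(common)


def _majority_shared(catalog: ComplexCatalog, a: str, b: str) -> bool:
    pa = catalog.complexes[a].proteins
    pb = catalog.complexes[b].proteins
    return len(pa & pb) > 0.5 * min(len(pa), len(pb))


def classify_pc_pair(catalog: ComplexCatalog, a: str, b: str) -> str:
    """First matching redundancy reason for a complex pair, or '' if genuine."""
    if _is_parent_child(catalog, a, b):
        return "parent_child"
    if _share_direct_parent(catalog, a, b):
        return "common_parent"
    if _majority_shared(catalog, a, b):
        return "majority_shared"
    return ""


def filter_one_to_many(
    records: Sequence[IntersectionRecord], catalog: ComplexCatalog
) -> RelationClassification:
    """Classify, per group, every pair of its intersecting complexes.

    A group is univocal when the redundancy graph over its complexes
    (edges = discarded pairs) collapses to a single connected component —
    i.e. its apparent multi-complex footprint is one biochemical entity.
    """
    pcs_of: dict[str, list[str]] = defaultdict(list)
    for rec in records:
        pcs_of[rec.group_id].append(rec.term_id)
    cls = RelationClassification()
    for gid in sorted(pcs_of):
        pcs = sorted(set(pcs_of[gid]))
        merge = nx.Graph()
        merge.add_nodes_from(pcs)
        for a, b in combinations(pcs, 2):
            reason = classify_pc_pair(catalog, a, b)
            rec = PcPairRecord(
                group_id=gid, term_a=a, term_b=b,
                status="discarded" if reason else "kept", reason=reason,
            )
            if reason:
                cls.one_to_many_discarded.append(rec)
                merge.add_edge(a, b)
            else:
                cls.one_to_many_kept.append(rec)
        n_effective = nx.number_connected_components(merge)
        (cls.univocal if n_effective == 1 else cls.non_univocal).append(gid)
    return cls


def filter_many_to_one(
    records: Sequence[IntersectionRecord], pairs: Sequence[DiseaseGenePair]
) -> RelationClassification:
    """Classify, per complex, every pair of intersecting groups.

    Two series intersecting the same complex are discarded as allele
    heterogeneity when they annotate >=1 protein in common.
    """
    prot_of_ps: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        if p.ps_id is not None:
            prot_of_ps[p.ps_id].add(p.entrez_id)
    groups_of: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        groups_of[rec.term_id].add(rec.group_id)
    cls = RelationClassification()
    for tid in sorted(groups_of):
        for a, b in combinations(sorted(groups_of[tid]), 2):
            shared = prot_of_ps.get(a, set()) & prot_of_ps.get(b, set())
            rec = PsPairRecord(
                term_id=tid, group_a=a, group_b=b,
                status="discarded" if shared else "kept",
                reason="allele_heterogeneity" if shared else "",
            )
            (cls.many_to_one_discarded if shared else cls.many_to_one_kept).append(rec)
    return cls


def export_relation_graph(
    records: Sequence[IntersectionRecord],
    classification: RelationClassification,
    jc_floor: float = 0.0,
) -> list[dict]:
    """Bipartite (group, complex) edge list, thresholded at ``jc >= jc_floor``.

    An edge is marked discarded when its complex is redundant within the
    group — every pair involving it was discarded — with the first such
    pair's reason; edges of univocal or fully kept relations are kept.
    """
    pair_status: dict[tuple[str, str], str] = {}
    pair_reason: dict[tuple[str, str], str] = {}
    for rec in classification.one_to_many_discarded:
        for term in (rec.term_a, rec.term_b):
            key = (rec.group_id, term)
            pair_status.setdefault(key, "discarded")
            pair_reason.setdefault(key, rec.reason)
    for rec in classification.one_to_many_kept:
        for term in (rec.term_a, rec.term_b):
            pair_status[(rec.group_id, term)] = "kept"
            pair_reason.pop((rec.group_id, term), None)
    edges = []
    for rec in sorted(records, key=lambda r: (r.group_id, r.term_id)):
        if rec.jc < jc_floor:
            continue
        key = (rec.group_id, rec.term_id)
        edges.append(
            {
                "group_id": rec.group_id,
                "term_id": rec.term_id,
                "jc": round(rec.jc, 3),
                "status": pair_status.get(key, "kept"),
                "reason": pair_reason.get(key, ""),
            }
        )
    return edges


def write_pc_pairs(records: Sequence[PcPairRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tterm_a\tterm_b\tstatus\treason\n")
        for r in sorted(records, key=lambda r: (r.group_id, r.term_a, r.term_b)):
            fh.write(f"{r.group_id}\t{r.term_a}\t{r.term_b}\t{r.status}\t{r.reason}\n")


def write_ps_pairs(records: Sequence[PsPairRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tgroup_a\tgroup_b\tstatus\treason\n")
        for r in sorted(records, key=lambda r: (r.term_id, r.group_a, r.group_b)):
            fh.write(f"{r.term_id}\t{r.group_a}\t{r.group_b}\t{r.status}\t{r.reason}\n")


def write_relation_graph(edges: Sequence[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tterm_id\tjc\tstatus\treason\n")
        for e in edges:
            fh.write(f"{e['group_id']}\t{e['term_id']}\t{e['jc']:.3f}\t"
                     f"{e['status']}\t{e['reason']}\n")
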