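"""Disease-gene pair filtering and assembly of the locus-heterogeneity groups.

A "disease" here is any morbid-map phenotype that (i) carries none of the
OMIM uncertainty markers, (ii) has a known molecular basis (mapping key 3),
(iii) has its own phenotype identifier, and (iv) is caused by mutation of a
protein-coding gene with a live Entrez mapping. Locus heterogeneity (LH) is
then read off two group families: diseases annotated by >=2 distinct
proteins (disease-based) and phenotypic series (PS) pooling the proteins of
>=2 molecularly characterized member diseases (PS-based).
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .types import DiseaseGenePair, GeneCatalogRow, MorbidMapRow, ProteinGroup, PsMembershipRow

logger = logging.getLogger(__name__)

#: discard reasons, in the order the filters run; a row failing several
#: rules is counted once, under the first.
FILTER_REASONS = (
    "unconfirmed",        # leading "?"
    "non_disease",        # [ ] label
    "susceptibility",     # { } label
    "mapping_key",        # keys 1, 2, 4
    "no_phenotype_mim",
    "gene_not_mapped",    # moved / removed / no Entrez id
    "non_coding",
)


@dataclass
class FilterResult:
    """Surviving pairs plus an audit of every discard."""

    pairs: list[DiseaseGenePair]
    discards: Counter = field(default_factory=Counter)
    n_input: int = 0

    @property
    def n_discarded(self) -> int:
        return sum(self.discards.values())


def filter_disease_gene_pairs(
    rows: Sequence[MorbidMapRow], genes: Sequence[GeneCatalogRow]
) -> FilterResult:
    """Apply the disease-definition filters, in fixed order, to morbid-map rows.

    Discards, in order: marker-carrying labels (unconfirmed "?", non-disease
    "[ ]", susceptibility "{ }"); mapping keys 1, 2 and 4; phenotypes with no
    phenotype MIM; gene MIMs that are moved/removed or lack an Entrez id;
    non-protein-coding genes. Each discard is counted under the first
    matching reason. Surviving (phenotype, protein) pairs are deduplicated.
    """
    by_mim = {g.gene_mim: g for g in genes}
    discards: Counter = Counter()
    seen: set[tuple[str, str]] = set()
    pairs: list[DiseaseGenePair] = []
    for row in rows:
        marker = row.marker
        if marker is not None:
            discards[marker] += 1
            continue
        if row.mapping_key != 3:
            discards["mapping_key"] += 1
            continue
        if row.phenotype_mim is None:
            discards["no_phenotype_mim"] += 1
            continue
        gene = by_mim.get(row.gene_mim)
        if gene is None or gene.status != "active" or gene.entrez_id is None:
            discards["gene_not_mapped"] += 1
            continue
        if not gene.protein_coding:
            discards["non_coding"] += 1
            continue
        key = (row.phenotype_mim, gene.entrez_id)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(DiseaseGenePair(phenotype_mim=key[0], entrez_id=key[1]))
    result = FilterResult(pairs=pairs, discards=discards, n_input=len(rows))
    logger.info(
        "filtered %d morbid rows -> %d pairs (%d discarded: %s)",
        len(rows), len(pairs), result.n_discarded, dict(discards),
    )
    return result


@dataclass
class GroupFamily:
    """LH groups plus the entities excluded from the LH set."""

    lh_groups: list[ProteinGroup]
    non_lh_groups: list[ProteinGroup]       # single-protein diseases (disease-based)
    degenerate_groups: list[ProteinGroup] = field(default_factory=list)  # 1-protein PS

    @property
    def non_lh_proteins(self) -> frozenset[str]:
        """Disease proteins appearing only outside the LH groups."""
        in_lh = frozenset().union(*(g.proteins for g in self.lh_groups)) if self.lh_groups else frozenset()
        out = set()
        for g in self.non_lh_groups:
            out |= g.proteins
        return frozenset(out - in_lh)


def build_disease_groups(pairs: Sequence[DiseaseGenePair]) -> GroupFamily:
    """One group per phenotype MIM; >=2 distinct proteins marks an LH instance."""
    proteins: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        proteins[p.phenotype_mim].add(p.entrez_id)
    lh, non_lh = [], []
    for mim in sorted(proteins):
        group = ProteinGroup(group_id=mim, role="disease", proteins=frozenset(proteins[mim]))
        (lh if group.size >= 2 else non_lh).append(group)
    logger.info("%d diseases: %d LH, %d single-protein", len(proteins), len(lh), len(non_lh))
    return GroupFamily(lh_groups=lh, non_lh_groups=non_lh)


def build_ps_groups(
    pairs: Sequence[DiseaseGenePair], ps: Sequence[PsMembershipRow]
) -> GroupFamily:
    """One group per phenotypic series with >=2 molecularly characterized diseases.

    A group's protein set is the union over its member diseases; a disease
    belonging to several PS contributes its proteins to each. A PS whose >=2
    diseases collapse onto a single shared protein stays a valid PS but is
    flagged degenerate (it cannot enter the intersection analysis). A PS with
    <2 characterized diseases is dropped.
    """
    disease_proteins: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        disease_proteins[p.phenotype_mim].add(p.entrez_id)
    members: dict[str, set[str]] = defaultdict(set)
    for row in ps:
        members[row.ps_id].add(row.phenotype_mim)
    lh, degenerate = [], []
    for ps_id in sorted(members):
        characterized = sorted(d for d in members[ps_id] if d in disease_proteins)
        if len(characterized) < 2:
            logger.warning("PS %s has %d characterized diseases; dropped",
                           ps_id, len(characterized))
            continue
        prots: set[str] = set()
        for d in characterized:
            prots |= disease_proteins[d]
        group = ProteinGroup(
            group_id=ps_id, role="ps", proteins=frozenset(prots),
            n_diseases=len(characterized),
        )
        (lh if group.size >= 2 else degenerate).append(group)
    logger.info("%d PS groups (%d degenerate single-protein)", len(lh) + len(degenerate),
                len(degenerate))
    return GroupFamily(lh_groups=lh, non_lh_groups=[], degenerate_groups=degenerate)


def ps_assignments(
    pairs: Sequence[DiseaseGenePair], ps: Sequence[PsMembershipRow]
) -> list[DiseaseGenePair]:
    """Expand pairs with their PS membership (one output pair per PS a disease is in)."""
    ps_of: dict[str, list[str]] = defaultdict(list)
    for row in ps:
        ps_of[row.phenotype_mim].append(row.ps_id)
    out = []
    for p in pairs:
        for ps_id in sorted(set(ps_of.get(p.phenotype_mim, []))):
            out.append(DiseaseGenePair(p.phenotype_mim, p.entrez_id, ps_id=ps_id))
    return out


def size_histogram(groups: Iterable[ProteinGroup]) -> dict[int, int]:
    """Protein-count histogram of a group family (the shape behind the bar charts)."""
    return dict(sorted(Counter(g.size for g in groups).items()))


def write_groups(groups: Sequence[ProteinGroup], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tn_proteins\tproteins\n")
        for g in groups:
            fh.write(f"{g.group_id}\t{g.size}\t{';'.join(sorted(g.proteins))}\n")


def write_filter_report(result: FilterResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reason\tcount\n")
        for reason in FILTER_REASONS:
            fh.write(f"{reason}\t{result.discards.get(reason, 0)}\n")
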