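"""Mouse-ortholog augmentation of group-complex intersections.

Complex members never reported as human disease proteins may still be
candidate disease genes: if knocking out the mouse ortholog produces a
phenotype that, translated through the MP -> HP best-match table, matches
a clinical phenotype of a disease in the phenotypic series, the protein is
promoted to a *presumptive* disease protein and added to the intersection.
The recalculated JC keeps the original group size in the denominator — the
presumptive proteins enlarge only the intersection term:

    JC' = (i + m) / (|PS| + |PC| - (i + m))

with i the original shared count and m the number of presumptive proteins.
Phenotype resemblance is an exact term match after MP -> HP translation;
no ontology-ancestor expansion is attempted.

The module also emits two annotation tables explaining residual partial
intersections: gain-of-function disease proteins outside the complex, and
complex members whose mouse ortholog dies before birth (and so may never
surface as an OMIM disease gene).
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .complex_catalog import ComplexCatalog
from .lh_intersection import jaccard
from .types import (
    DiseasePhenotypeRow,
    GofAnnotation,
    IntersectionRecord,
    LethalityAnnotation,
    OrthologPhenotypeRow,
    PhenotypeMatchRow,
    ProteinGroup,
    PsMembershipRow,
)


@dataclass(frozen=True)
class AugmentedRecord:
    base: IntersectionRecord
    presumptive: frozenset[str]
    jc_augmented: float
    is_new: bool = False  # base overlap was < 2 shared; record exists only augmented


def _hp_terms_per_protein(
    orthologs: Sequence[OrthologPhenotypeRow], matches: Sequence[PhenotypeMatchRow]
) -> dict[str, frozenset[str]]:
    """Human-phenotype translation of each protein's mouse-ortholog phenotypes."""
    hp_of_mp: dict[str, set[str]] = defaultdict(set)
    for m in matches:
        hp_of_mp[m.mp_term].add(m.hp_term)
    out: dict[str, set[str]] = defaultdict(set)
    for row in orthologs:
        for mp in row.mp_terms:
            out[row.human_entrez_id] |= hp_of_mp.get(mp, set())
    return {k: frozenset(v) for k, v in out.items()}


def _ps_hp_terms(
    ps_memberships: Sequence[PsMembershipRow],
    disease_hp: Sequence[DiseasePhenotypeRow],
) -> dict[str, frozenset[str]]:
    """Union of clinical HP terms over each phenotypic series' diseases."""
    hp_of_disease = {d.phenotype_mim: d.hp_terms for d in disease_hp}
    out: dict[str, set[str]] = defaultdict(set)
    for row in ps_memberships:
        out[row.ps_id] |= hp_of_disease.get(row.phenotype_mim, frozenset())
    return {k: frozenset(v) for k, v in out.items()}


def find_presumptive_proteins(
    group_proteins: frozenset[str],
    pc_proteins: frozenset[str],
    ps_hp: frozenset[str],
    protein_hp: dict[str, frozenset[str]],
) -> frozenset[str]:
    """Complex members outside the group whose mouse phenotype matches the PS.

    A candidate qualifies when >=1 of its ortholog's translated HP terms is
    among the HP terms annotated to any disease of the series.
    """
    return frozenset(
        p
        for p in pc_proteins - group_proteins
        if protein_hp.get(p, frozenset()) & ps_hp
    )


def augmented_jaccard(rec: IntersectionRecord, presumptive: frozenset[str]) -> float:
    """JC recomputed with the presumptive proteins added to the intersection."""
    if presumptive & rec.shared:
        raise ValueError("presumptive proteins must be disjoint from the shared set")
    total = len(rec.shared) + len(presumptive)
    if total > rec.pc_size:
        raise ValueError("augmented intersection cannot exceed the complex size")
    return total / (rec.group_size + rec.pc_size - total)


@dataclass
class AugmentationResult:
    records: list[AugmentedRecord]
    n_groups_hit_base: int
    n_groups_hit_augmented: int

    def mean_jc(self, augmented: bool = True) -> float:
        recs = [r for r in self.records if not r.is_new]
        if not recs:
            return float("nan")
        vals = [r.jc_augmented if augmented else r.base.jc for r in recs]
        return sum(vals) / len(vals)


def augment_records(
    groups: Sequence[ProteinGroup],
    catalog: ComplexCatalog,
    orthologs: Sequence[OrthologPhenotypeRow],
    matches: Sequence[PhenotypeMatchRow],
    ps_memberships: Sequence[PsMembershipRow],
    disease_hp: Sequence[DiseasePhenotypeRow],
    base_records: Sequence[IntersectionRecord],
) -> AugmentationResult:
    """Recompute every group-complex overlap with presumptive proteins included.

    Besides augmenting the existing records, pairs whose base overlap was
    below two shared proteins can cross the threshold once presumptive
    proteins are counted (i + m >= 2); these enter as new records, which is
    how augmentation raises the number of groups intersecting a complex.
    """
    protein_hp = _hp_terms_per_protein(orthologs, matches)
    ps_hp = _ps_hp_terms(ps_memberships, disease_hp)
    base_keys = {(r.group_id, r.term_id): r for r in base_records}
    out: list[AugmentedRecord] = []
    groups_hit: set[str] = set()
    for g in groups:
        hp = ps_hp.get(g.group_id, frozenset())
        for tid in sorted(catalog.complexes):
            pc = catalog.complexes[tid]
            shared = frozenset(g.proteins & pc.proteins)
            presumptive = find_presumptive_proteins(g.proteins, pc.proteins, hp, protein_hp)
            if len(shared) + len(presumptive) < 2:
                continue
            base = base_keys.get((g.group_id, tid))
            is_new = base is None
            if base is None:
                base = IntersectionRecord(
                    group_id=g.group_id, term_id=tid, shared=shared,
                    jc=jaccard(g.proteins, pc.proteins),
                    group_size=g.size, pc_size=pc.size,
                )
            out.append(
                AugmentedRecord(
                    base=base,
                    presumptive=presumptive,
                    jc_augmented=augmented_jaccard(base, presumptive),
                    is_new=is_new,
                )
            )
            groups_hit.add(g.group_id)
    return AugmentationResult(
        records=out,
        n_groups_hit_base=len({r.group_id for r in base_records}),
        n_groups_hit_augmented=len(groups_hit),
    )


def annotate_gof(
    records: Sequence[IntersectionRecord],
    groups: Sequence[ProteinGroup],
    catalog: ComplexCatalog,
    gof_flags: frozenset[str],
) -> list[GofAnnotation]:
    """Per intersection, the group's gain-of-function proteins outside the complex."""
    by_id = {g.group_id: g for g in groups}
    out = []
    for rec in sorted(records, key=lambda r: (r.group_id, r.term_id)):
        group = by_id[rec.group_id]
        pc = catalog.complexes[rec.term_id]
        outside = frozenset((group.proteins & gof_flags) - pc.proteins)
        out.append(
            GofAnnotation(group_id=rec.group_id, term_id=rec.term_id,
                          gof_proteins_outside_pc=outside)
        )
    return out


def groups_without_complex(
    groups: Sequence[ProteinGroup],
    records: Sequence[IntersectionRecord],
    gof_flags: Optional[frozenset[str]] = None,
) -> list[str]:
    """Groups intersecting no complex at all (optionally only those with GoF proteins)."""
    hit = {r.group_id for r in records}
    out = []
    for g in groups:
        if g.group_id in hit:
            continue
        if gof_flags is not None and not (g.proteins & gof_flags):
            continue
        out.append(g.group_id)
    return sorted(out)


def annotate_lethality(
    catalog: ComplexCatalog, orthologs: Sequence[OrthologPhenotypeRow]
) -> list[LethalityAnnotation]:
    """Complexes with >=1 member whose mouse ortholog is pre-birth lethal."""
    stage_of: dict[str, str] = {}
    for row in orthologs:
        if row.lethality_stage is not None:
            stage_of[row.human_entrez_id] = row.lethality_stage
    out = []
    for tid in sorted(catalog.complexes):
        essential = sorted(p for p in catalog.complexes[tid].proteins if p in stage_of)
        if essential:
            out.append(
                LethalityAnnotation(
                    term_id=tid,
                    essential_proteins=frozenset(essential),
                    stages=tuple((p, stage_of[p]) for p in essential),
                )
            )
    return out


def write_augmented(result: AugmentationResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tterm_id\tn_shared\tn_presumptive\tpresumptive\tjc\tjc_augmented\tnew\n")
        for r in sorted(result.records, key=lambda r: (r.base.group_id, r.base.term_id)):
            fh.write(
                f"{r.base.group_id}\t{r.base.term_id}\t{len(r.base.shared)}\t"
                f"{len(r.presumptive)}\t{';'.join(sorted(r.presumptive))}\t"
                f"{r.base.jc:.3f}\t{r.jc_augmented:.3f}\t{int(r.is_new)}\n"
            )


def write_gof_annotations(annotations: Sequence[GofAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tterm_id\tn_gof_outside\tgof_proteins_outside_pc\n")
        for a in annotations:
            fh.write(
                f"{a.group_id}\t{a.term_id}\t{len(a.gof_proteins_outside_pc)}\t"
                f"{';'.join(sorted(a.gof_proteins_outside_pc))}\n"
            )


def write_lethality_annotations(
    annotations: Sequence[LethalityAnnotation], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tn_essential\tessential_proteins\tstages\n")
        for a in annotations:
            stages = ";".join(f"{p}:{s}" for p, s in a.stages)
            fh.write(
                f"{a.term_id}\t{len(a.essential_proteins)}\t"
                f"{';'.join(sorted(a.essential_proteins))}\t{stages}\n"
            )
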