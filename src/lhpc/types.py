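"""Shared domain records for the locus-heterogeneity / protein-complex analysis.

Protein identity throughout the package is the Entrez-style gene identifier
(an opaque string); gene symbols are carried for display only.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

# ---------------------------------------------------------------------------
# parsed input records (catalog_io)
# ---------------------------------------------------------------------------

#: phenotype labels may carry a leading "?" (unconfirmed), enclosing
#: "[ ]" (non-disease) or "{ }" (susceptibility to multifactorial disorder)
_MARKER_RE = re.compile(r"^(\?|\[|\{)")


@dataclass(frozen=True)
class MorbidMapRow:
    """One line of the morbid-map dialect, markers detected but not stripped."""

    phenotype_label: str
    phenotype_mim: Optional[str]
    mapping_key: int
    gene_symbols: tuple[str, ...]
    gene_mim: str
    cyto_location: str = ""
    line_no: int = 0

    def __post_init__(self) -> None:
        if self.mapping_key not in (1, 2, 3, 4):
            raise ValueError(f"mapping key must be 1-4, got {self.mapping_key}")

    @property
    def marker(self) -> Optional[str]:
        """Which phenotype marker the label carries, if any.

        Returns ``"unconfirmed"`` for a leading "?", ``"non_disease"`` for
        square brackets, ``"susceptibility"`` for braces, else ``None``.
        """
        label = self.phenotype_label.strip()
        if label.startswith("?"):
            return "unconfirmed"
        if label.startswith("[") and "]" in label:
            return "non_disease"
        if label.startswith("{") and "}" in label:
            return "susceptibility"
        return None


@dataclass(frozen=True)
class GeneCatalogRow:
    gene_mim: str
    entrez_id: Optional[str]
    status: str  # active | moved | removed
    protein_coding: bool

    def __post_init__(self) -> None:
        if self.status not in ("active", "moved", "removed"):
            raise ValueError(f"unknown gene status {self.status!r}")
        if self.entrez_id is not None and self.status != "active":
            raise ValueError("an Entrez-mapped gene must have status 'active'")


@dataclass(frozen=True)
class PsMembershipRow:
    ps_id: str
    phenotype_mim: str


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term with its is_a / part_of parent edges."""

    term_id: str
    name: str
    parents: tuple[tuple[str, str], ...]  # (relation, parent term id)
    obsolete: bool = False
    namespace: str = "cellular_component"
    unresolved_parents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for rel, pid in self.parents:
            if rel not in ("is_a", "part_of"):
                raise ValueError(f"unknown relation {rel!r}")
            if pid == self.term_id:
                raise ValueError(f"self-loop on {self.term_id}")


@dataclass(frozen=True)
class AnnotationRow:
    entrez_id: str
    term_id: str

    def __post_init__(self) -> None:
        if not self.entrez_id or not self.term_id:
            raise ValueError("annotation identifiers must be non-empty")


@dataclass(frozen=True)
class OrthologPhenotypeRow:
    human_entrez_id: str
    mouse_gene_id: str
    mp_terms: frozenset[str]
    lethality_stage: Optional[str] = None  # embryonic | fetal | prenatal | None

    def __post_init__(self) -> None:
        if self.lethality_stage not in (None, "embryonic", "fetal", "prenatal"):
            raise ValueError(f"unknown lethality stage {self.lethality_stage!r}")
        if not self.mp_terms and self.lethality_stage is None:
            raise ValueError(
                f"ortholog {self.mouse_gene_id} carries neither phenotype terms "
                "nor a lethality stage"
            )


@dataclass(frozen=True)
class PhenotypeMatchRow:
    mp_term: str
    hp_term: str


@dataclass(frozen=True)
class DiseasePhenotypeRow:
    phenotype_mim: str
    hp_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.hp_terms:
            raise ValueError(f"disease {self.phenotype_mim} has no phenotype terms")


# ---------------------------------------------------------------------------
# derived records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseGenePair:
    """A validated disease-protein annotation surviving all filters."""

    phenotype_mim: str
    entrez_id: str
    ps_id: Optional[str] = None


@dataclass(frozen=True)
class ProteinGroup:
    """A named protein set: a disease's, a phenotypic series', or a complex's."""

    group_id: str
    role: str  # disease | ps | complex
    proteins: frozenset[str]
    name: str = ""
    n_diseases: Optional[int] = None  # member-disease count, PS groups only

    def __post_init__(self) -> None:
        if self.role not in ("disease", "ps", "complex"):
            raise ValueError(f"unknown group role {self.role!r}")
        if not self.proteins:
            raise ValueError(f"group {self.group_id} has an empty protein set")

    @property
    def size(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class IntersectionRecord:
    """One (group, complex) overlap with at least two shared proteins."""

    group_id: str
    term_id: str
    shared: frozenset[str]
    jc: float
    group_size: int
    pc_size: int


@dataclass
class TripleTuple:
    """One (group, protein, complex) co-membership fact."""

    group_id: str
    entrez_id: str
    term_id: str


@dataclass(frozen=True)
class GofAnnotation:
    """Gain-of-function disease proteins of a group absent from the complex."""

    group_id: str
    term_id: str
    gof_proteins_outside_pc: frozenset[str]


@dataclass(frozen=True)
class LethalityAnnotation:
    """Complex members whose mouse ortholog is pre-birth lethal."""

    term_id: str
    essential_proteins: frozenset[str]
    stages: tuple[tuple[str, str], ...]  # (protein, stage), sorted


class ParseError(ValueError):
    """A malformed input line; carries the file and 1-based line number."""

    def __init__(self, message: str, path: str = "", line_no: int = 0):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}" if line_no else message)
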