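"""Readers and writers for every input dialect the analysis consumes.

All tabular inputs are UTF-8 TSV files with a documented header; lines
starting with ``#`` are comments. The ontology is plain OBO (read through
:mod:`obonet`). Everything downstream consumes only the typed records
produced here.

The morbid-map dialect is a 4-column TSV (phenotype, gene symbols, gene
MIM, cytogenetic location) with the mapping key parenthesized at the end
of the phenotype field, e.g.::

    Tuberous sclerosis-1, 191100 (3)\tTSC1\t605284\t9q34.13
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import obonet
import pandas as pd

from .types import (
    AnnotationRow,
    DiseasePhenotypeRow,
    GeneCatalogRow,
    MorbidMapRow,
    OntologyTerm,
    OrthologPhenotypeRow,
    ParseError,
    PhenotypeMatchRow,
    PsMembershipRow,
)

logger = logging.getLogger(__name__)

# phenotype field: "<label>[, <6-digit MIM>] (<key>)"
_PHENO_RE = re.compile(r"^(?P<label>.*?)(?:,\s*(?P<mim>\d{6}))?\s*\((?P<key>[^)]*)\)\s*$")
_SET_SEP = ";"


# ---------------------------------------------------------------------------
# morbid map
# ---------------------------------------------------------------------------

def _parse_morbid_line(line: str, line_no: int, path: str) -> MorbidMapRow:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 3:
        raise ParseError(f"expected >=3 tab-separated columns, got {len(cols)}", path, line_no)
    pheno, symbols, gene_mim = cols[0], cols[1], cols[2]
    cyto = cols[3] if len(cols) > 3 else ""
    m = _PHENO_RE.match(pheno)
    if m is None or not m.group("key").strip():
        raise ParseError("phenotype field lacks a trailing mapping key '(k)'", path, line_no)
    key_text = m.group("key").strip()
    try:
        key = int(key_text)
    except ValueError:
        raise ParseError(f"mapping key {key_text!r} is not an integer", path, line_no) from None
    if key not in (1, 2, 3, 4):
        raise ParseError(f"mapping key must be 1-4, got {key}", path, line_no)
    return MorbidMapRow(
        phenotype_label=m.group("label").strip(),
        phenotype_mim=m.group("mim"),
        mapping_key=key,
        gene_symbols=tuple(s.strip() for s in symbols.split(",") if s.strip()),
        gene_mim=gene_mim.strip(),
        cyto_location=cyto.strip(),
        line_no=line_no,
    )


def scan_morbid_map(path: str | Path) -> tuple[list[MorbidMapRow], list[tuple[int, str]]]:
    """Parse a morbid-map file, collecting rejects instead of raising.

    Returns ``(rows, rejects)`` with rejects as ``(line_no, message)`` pairs;
    every non-comment, non-blank input line lands in exactly one of the two.
    """
    rows: list[MorbidMapRow] = []
    rejects: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                rows.append(_parse_morbid_line(line, line_no, str(path)))
            except ParseError as exc:
                rejects.append((line_no, str(exc)))
    logger.info("%s: %d rows, %d rejects", path, len(rows), len(rejects))
    return rows, rejects


def read_morbid_map(path: str | Path) -> list[MorbidMapRow]:
    """Strict morbid-map reader; raises :class:`ParseError` on the first bad line."""
    rows, rejects = scan_morbid_map(path)
    if rejects:
        raise ParseError(rejects[0][1])  # message already carries path:line
    return rows


def write_morbid_map(rows: Iterable[MorbidMapRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# phenotype\tgene_symbols\tgene_mim\tcyto_location\n")
        for r in rows:
            pheno = r.phenotype_label
            if r.phenotype_mim is not None:
                pheno += f", {r.phenotype_mim}"
            pheno += f" ({r.mapping_key})"
            fh.write(f"{pheno}\t{','.join(r.gene_symbols)}\t{r.gene_mim}\t{r.cyto_location}\n")


# ---------------------------------------------------------------------------
# ontology (OBO)
# ---------------------------------------------------------------------------

def read_ontology(path: str | Path) -> list[OntologyTerm]:
    """Parse an OBO file into :class:`OntologyTerm` records.

    Both ``is_a:`` and ``relationship: part_of`` lines become parent edges.
    Obsolete terms are kept and flagged. A parent id with no [Term] stanza
    of its own is kept on the edge but flagged unresolved (with a warning).
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    defined = {n for n, d in graph.nodes(data=True) if "name" in d}
    terms: list[OntologyTerm] = []
    for node in sorted(defined):
        data = graph.nodes[node]
        parents: list[tuple[str, str]] = []
        unresolved: set[str] = set()
        for pid in data.get("is_a", []):
            parents.append(("is_a", pid))
        for rel_line in data.get("relationship", []):
            rel, _, pid = rel_line.partition(" ")
            if rel == "part_of":
                parents.append(("part_of", pid.strip()))
        for _, pid in parents:
            if pid not in defined:
                unresolved.add(pid)
                logger.warning("%s: parent %s of %s is not defined in the file", path, pid, node)
        terms.append(
            OntologyTerm(
                term_id=node,
                name=data["name"],
                parents=tuple(parents),
                obsolete=str(data.get("is_obsolete", "")).lower() == "true",
                namespace=data.get("namespace", "cellular_component"),
                unresolved_parents=frozenset(unresolved),
            )
        )
    logger.info("%s: %d terms", path, len(terms))
    return terms


def write_ontology(terms: Iterable[OntologyTerm], path: str | Path) -> None:
    """Emit terms as a minimal OBO file (the dialect :func:`read_ontology` reads)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-cc\n")
        for t in terms:
            fh.write(f"\n[Term]\nid: {t.term_id}\nname: {t.name}\n")
            fh.write(f"namespace: {t.namespace}\n")
            for rel, pid in t.parents:
                if rel == "is_a":
                    fh.write(f"is_a: {pid}\n")
                else:
                    fh.write(f"relationship: part_of {pid}\n")
            if t.obsolete:
                fh.write("is_obsolete: true\n")


# ---------------------------------------------------------------------------
# auxiliary TSV tables
# ---------------------------------------------------------------------------

@dataclass
class AuxTables:
    """The six auxiliary tables, plus the optional gain-of-function flag list."""

    genes: list[GeneCatalogRow] = field(default_factory=list)
    ps_memberships: list[PsMembershipRow] = field(default_factory=list)
    annotations: list[AnnotationRow] = field(default_factory=list)
    orthologs: list[OrthologPhenotypeRow] = field(default_factory=list)
    phenotype_matches: list[PhenotypeMatchRow] = field(default_factory=list)
    disease_phenotypes: list[DiseasePhenotypeRow] = field(default_factory=list)
    gof_proteins: frozenset[str] = frozenset()


_EXPECTED_COLUMNS = {
    "genes": ["gene_mim", "entrez_id", "status", "protein_coding"],
    "ps_memberships": ["ps_id", "phenotype_mim"],
    "annotations": ["entrez_id", "term_id"],
    "orthologs": ["human_entrez_id", "mouse_gene_id", "mp_terms", "lethality_stage"],
    "phenotype_matches": ["mp_term", "hp_term"],
    "disease_phenotypes": ["phenotype_mim", "hp_terms"],
    "gof": ["entrez_id"],
}


def _read_tsv(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    expected = _EXPECTED_COLUMNS[kind]
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ParseError(f"unknown column {unknown[0]!r} in {kind} table", str(path))
    missing = [c for c in expected if c not in df.columns and c != "lethality_stage"]
    if missing:
        raise ParseError(f"missing column {missing[0]!r} in {kind} table", str(path))
    logger.info("%s: %d rows", path, len(df))
    return df


def _split_terms(cell: str) -> frozenset[str]:
    return frozenset(t.strip() for t in cell.split(_SET_SEP) if t.strip())


def read_aux_tables(paths: Mapping[str, str | Path]) -> AuxTables:
    """Read whichever auxiliary tables are present in ``paths``.

    Keys follow :class:`AuxTables` field names (``genes``, ``ps_memberships``,
    ``annotations``, ``orthologs``, ``phenotype_matches``,
    ``disease_phenotypes``, ``gof``). Missing keys yield empty tables, so a
    world without e.g. ortholog data simply makes augmentation a no-op.
    Duplicate (MP, HP) match pairs are deduplicated.
    """
    out = AuxTables()
    if "genes" in paths:
        df = _read_tsv(paths["genes"], "genes")
        out.genes = [
            GeneCatalogRow(
                gene_mim=r.gene_mim,
                entrez_id=r.entrez_id or None,
                status=r.status,
                protein_coding=r.protein_coding in ("1", "true", "True", "yes"),
            )
            for r in df.itertuples()
        ]
    if "ps_memberships" in paths:
        df = _read_tsv(paths["ps_memberships"], "ps_memberships")
        out.ps_memberships = [
            PsMembershipRow(ps_id=r.ps_id, phenotype_mim=r.phenotype_mim)
            for r in df.itertuples()
        ]
    if "annotations" in paths:
        df = _read_tsv(paths["annotations"], "annotations")
        out.annotations = [
            AnnotationRow(entrez_id=r.entrez_id, term_id=r.term_id) for r in df.itertuples()
        ]
    if "orthologs" in paths:
        df = _read_tsv(paths["orthologs"], "orthologs")
        out.orthologs = [
            OrthologPhenotypeRow(
                human_entrez_id=r.human_entrez_id,
                mouse_gene_id=r.mouse_gene_id,
                mp_terms=_split_terms(r.mp_terms),
                lethality_stage=(getattr(r, "lethality_stage", "") or None),
            )
            for r in df.itertuples()
        ]
    if "phenotype_matches" in paths:
        df = _read_tsv(paths["phenotype_matches"], "phenotype_matches")
        seen: set[tuple[str, str]] = set()
        rows = []
        for r in df.itertuples():
            pair = (r.mp_term, r.hp_term)
            if pair not in seen:
                seen.add(pair)
                rows.append(PhenotypeMatchRow(mp_term=pair[0], hp_term=pair[1]))
        out.phenotype_matches = rows
    if "disease_phenotypes" in paths:
        df = _read_tsv(paths["disease_phenotypes"], "disease_phenotypes")
        out.disease_phenotypes = [
            DiseasePhenotypeRow(phenotype_mim=r.phenotype_mim, hp_terms=_split_terms(r.hp_terms))
            for r in df.itertuples()
        ]
    if "gof" in paths:
        df = _read_tsv(paths["gof"], "gof")
        out.gof_proteins = frozenset(df["entrez_id"])
    return out


# ---------------------------------------------------------------------------
# writers for the auxiliary dialects (used by the generator and round-trips)
# ---------------------------------------------------------------------------

def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_gene_catalog(rows: Iterable[GeneCatalogRow], path: str | Path) -> None:
    _write_tsv(
        path,
        _EXPECTED_COLUMNS["genes"],
        (
            (r.gene_mim, r.entrez_id or "", r.status, "1" if r.protein_coding else "0")
            for r in rows
        ),
    )


def write_ps_memberships(rows: Iterable[PsMembershipRow], path: str | Path) -> None:
    _write_tsv(path, _EXPECTED_COLUMNS["ps_memberships"],
               ((r.ps_id, r.phenotype_mim) for r in rows))


def write_annotations(rows: Iterable[AnnotationRow], path: str | Path) -> None:
    _write_tsv(path, _EXPECTED_COLUMNS["annotations"],
               ((r.entrez_id, r.term_id) for r in rows))


def write_orthologs(rows: Iterable[OrthologPhenotypeRow], path: str | Path) -> None:
    _write_tsv(
        path,
        _EXPECTED_COLUMNS["orthologs"],
        (
            (r.human_entrez_id, r.mouse_gene_id, _SET_SEP.join(sorted(r.mp_terms)),
             r.lethality_stage or "")
            for r in rows
        ),
    )


def write_phenotype_matches(rows: Iterable[PhenotypeMatchRow], path: str | Path) -> None:
    _write_tsv(path, _EXPECTED_COLUMNS["phenotype_matches"],
               ((r.mp_term, r.hp_term) for r in rows))


def write_disease_phenotypes(rows: Iterable[DiseasePhenotypeRow], path: str | Path) -> None:
    _write_tsv(path, _EXPECTED_COLUMNS["disease_phenotypes"],
               ((r.phenotype_mim, _SET_SEP.join(sorted(r.hp_terms))) for r in rows))


def write_gof_proteins(proteins: Iterable[str], path: str | Path) -> None:
    _write_tsv(path, _EXPECTED_COLUMNS["gof"], ((p,) for p in sorted(proteins)))
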