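"""Synthetic input universes with planted, machine-checkable ground truth.

The generator emits a complete, internally consistent bundle of input
files in the dialects of :mod:`lhpc.catalog_io` — morbid map, gene
catalog, PS memberships, OBO ontology, complex annotations, mouse-ortholog
phenotypes, MP->HP best matches, disease phenotypes and gain-of-function
flags — together with a truth manifest stating every planted fact:
exact group-complex overlaps and their (augmented) Jaccard coefficients,
complex-pruning outcomes, morbid-row discard tallies, and redundancy
classifications. Running the full pipeline on a generated world must
reproduce the manifest exactly.

Planted entities use dedicated identifiers that background structure never
touches, so planted facts are exact, not statistical. Background
phenotypic series and complexes draw their proteins uniformly from a
shared background gene pool: with no planted overlaps the world carries no
group-complex association beyond chance, which is what the permutation
nulls are calibrated against.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .lh_intersection import jaccard
from .types import (
    AnnotationRow,
    DiseasePhenotypeRow,
    GeneCatalogRow,
    MorbidMapRow,
    OntologyTerm,
    OrthologPhenotypeRow,
    PhenotypeMatchRow,
    PsMembershipRow,
)
from . import catalog_io

#: canonical planted overlap quadruples (group size, complex size, shared,
#: presumptive) reproducing the worked examples: full 4-in-12 overlap that
#: augments from JC 0.33 to 0.60; a 12-protein series sharing 5 proteins
#: with a 14- and an 88-protein channel complex (JC 0.238 vs 0.053); and a
#: 3-protein series fully inside an 88-protein complex (JC 0.034).
CANONICAL_OVERLAPS: tuple[tuple[int, int, int, int], ...] = (
    (4, 12, 4, 2),
    (12, 14, 5, 0),
    (12, 88, 5, 0),
    (3, 88, 3, 0),
)

GENERIC_PROTEIN_COMPLEX = "GO:0043234"
GENERIC_TF_COMPLEX = "GO:0005667"
GENERIC_MACROMOLECULAR = "GO:0032991"


@dataclass
class WorldConfig:
    """Shape and noise parameters of a synthetic universe.

    Size samplers default to discrete log-normals matching the published
    per-series protein moments (mean 6.6, SD 8.1) and per-complex median
    of 13 within the printed 2-116 range.
    """

    n_genes: int = 800
    n_diseases: int = 60          # background diseases outside any PS
    n_ps: int = 25                # background phenotypic series
    n_complexes: int = 40         # background complexes
    ps_size_mean: float = 6.6
    ps_size_sd: float = 8.1
    ps_size_clip: tuple[int, int] = (2, 30)
    pc_size_median: float = 13.0
    pc_size_sigma: float = 0.8
    pc_size_clip: tuple[int, int] = (2, 116)
    planted_overlaps: tuple[tuple[int, int, int, int], ...] = CANONICAL_OVERLAPS
    plant_redundancy: bool = True
    plant_decoys: bool = True
    disease_group_sizes: tuple[int, ...] = (2, 2, 3)
    frac_gof: float = 0.1
    frac_lethal: float = 0.1
    frac_noncoding: float = 0.1
    frac_susceptibility: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for g, p, i, m in self.planted_overlaps:
            if not (2 <= g and 2 <= p and 0 <= i <= min(g, p)):
                raise ValueError(f"infeasible planted overlap ({g},{p},{i},{m})")
            if m < 0 or i + m > p:
                raise ValueError(
                    f"planted overlap ({g},{p},{i},{m}): i+m exceeds the complex size"
                )
        for frac in ("frac_gof", "frac_lethal", "frac_noncoding", "frac_susceptibility"):
            v = getattr(self, frac)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac} must be in [0,1], got {v}")
        if self.frac_susceptibility >= 1.0 and (
            self.planted_overlaps or self.plant_redundancy or self.plant_decoys
            or self.disease_group_sizes
        ):
            raise ValueError(
                "frac_susceptibility=1 marks every disease row; planted facts "
                "cannot survive — drop the plants for an all-susceptibility world"
            )


@dataclass
class TruthManifest:
    """Every planted fact, stated independently of the pipeline."""

    planted_overlaps: list[dict] = field(default_factory=list)
    complex_removals: dict[str, str] = field(default_factory=dict)
    kept_complexes: list[str] = field(default_factory=list)
    filter_discards: dict[str, int] = field(default_factory=dict)
    n_pairs_expected: int = 0
    disease_lh_sizes: list[int] = field(default_factory=list)
    one_to_many: list[dict] = field(default_factory=list)
    many_to_one: list[dict] = field(default_factory=list)
    univocal_expected: dict[str, bool] = field(default_factory=dict)
    gof_expected: list[dict] = field(default_factory=list)
    noonan_like_ps: Optional[str] = None
    lethality_expected: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def sample_ps_sizes(cfg: WorldConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Discrete log-normal protein counts per series, clipped to the config range."""
    m, s = cfg.ps_size_mean, cfg.ps_size_sd
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    draws = np.rint(rng.lognormal(mu, np.sqrt(sigma2), size=n)).astype(int)
    return np.clip(draws, *cfg.ps_size_clip)


def sample_pc_sizes(cfg: WorldConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Discrete log-normal complex sizes around the configured median."""
    mu = np.log(cfg.pc_size_median)
    draws = np.rint(rng.lognormal(mu, cfg.pc_size_sigma, size=n)).astype(int)
    return np.clip(draws, *cfg.pc_size_clip)


class _IdFactory:
    """Format-valid synthetic identifiers (parsers cannot special-case them)."""

    def __init__(self) -> None:
        self._gene_mim = 600000
        self._entrez = 10000
        self._disease = 100000
        self._ps = 500000
        self._go = 1000000
        self._hp = 1
        self._mp = 1

    def gene(self) -> tuple[str, str]:
        self._gene_mim += 1
        self._entrez += 1
        return str(self._gene_mim), str(self._entrez)

    def disease(self) -> str:
        self._disease += 1
        return str(self._disease)

    def ps(self) -> str:
        self._ps += 1
        return f"PS{self._ps}"

    def go(self) -> str:
        self._go += 1
        return f"GO:{self._go}"

    def hp(self) -> str:
        self._hp += 1
        return f"HP:{self._hp:07d}"

    def mp(self) -> str:
        self._mp += 1
        return f"MP:{self._mp:07d}"


class _WorldBuilder:
    def __init__(self, cfg: WorldConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.ids = _IdFactory()
        self.genes: list[GeneCatalogRow] = []
        self.morbid: list[MorbidMapRow] = []
        self.ps_rows: list[PsMembershipRow] = []
        self.terms: list[OntologyTerm] = []
        self.annotations: list[AnnotationRow] = []
        self.orthologs: list[OrthologPhenotypeRow] = []
        self.matches: list[PhenotypeMatchRow] = []
        self.disease_hp: list[DiseasePhenotypeRow] = []
        self.gof: set[str] = set()
        self.truth = TruthManifest()
        self._discards = {r: 0 for r in (
            "unconfirmed", "non_disease", "susceptibility", "mapping_key",
            "no_phenotype_mim", "gene_not_mapped", "non_coding")}
        self._n_pairs = 0
        self._symbol_n = 0
        self._lethal_cycle = 0
        self.background_genes: list[tuple[str, str]] = []  # (gene_mim, entrez)

    # -- low-level helpers --------------------------------------------------

    def _symbol(self) -> str:
        self._symbol_n += 1
        return f"SYN{self._symbol_n}"

    def new_gene(self, coding: bool = True, status: str = "active",
                 mapped: bool = True) -> tuple[str, str]:
        gene_mim, entrez = self.ids.gene()
        self.genes.append(GeneCatalogRow(
            gene_mim=gene_mim,
            entrez_id=entrez if (mapped and status == "active") else None,
            status=status, protein_coding=coding,
        ))
        return gene_mim, entrez

    def add_disease_row(self, label: str, disease_mim: Optional[str],
                        gene_mim: str, key: int = 3) -> None:
        self.morbid.append(MorbidMapRow(
            phenotype_label=label, phenotype_mim=disease_mim, mapping_key=key,
            gene_symbols=(self._symbol(),), gene_mim=gene_mim,
            cyto_location=f"{self.rng.integers(1, 23)}q{self.rng.integers(11, 44)}",
        ))

    def simple_disease(self, gene: tuple[str, str], label: str = "") -> str:
        """One surviving single-gene disease; returns its phenotype MIM."""
        mim = self.ids.disease()
        self.add_disease_row(label or f"Synthetic disease {mim}", mim, gene[0])
        self._n_pairs += 1
        return mim

    def new_ps(self, proteins: Sequence[tuple[str, str]], label: str) -> tuple[str, list[str]]:
        """A phenotypic series with one disease per protein."""
        ps_id = self.ids.ps()
        diseases = []
        for k, gene in enumerate(proteins):
            mim = self.simple_disease(gene, f"{label}, type {k + 1}")
            self.ps_rows.append(PsMembershipRow(ps_id=ps_id, phenotype_mim=mim))
            diseases.append(mim)
        return ps_id, diseases

    def new_complex(self, name: str, members: Sequence[str],
                    parents: Sequence[tuple[str, str]] = ()) -> str:
        tid = self.ids.go()
        self.terms.append(OntologyTerm(term_id=tid, name=name, parents=tuple(parents)))
        for entrez in members:
            self.annotations.append(AnnotationRow(entrez_id=entrez, term_id=tid))
        return tid

    # -- structural ontology plants ----------------------------------------

    def plant_ontology_scaffold(self) -> None:
        root = GENERIC_MACROMOLECULAR
        self.terms.append(OntologyTerm(term_id=root, name="macromolecular complex",
                                       parents=()))
        self.terms.append(OntologyTerm(
            term_id=GENERIC_PROTEIN_COMPLEX, name="protein complex",
            parents=(("is_a", root),)))
        self.terms.append(OntologyTerm(
            term_id=GENERIC_TF_COMPLEX, name="transcription factor complex",
            parents=(("is_a", root),)))
        # the generics carry their own direct members, so removing them is a
        # real decision rather than a vacuous one
        for tid in (GENERIC_PROTEIN_COMPLEX, GENERIC_TF_COMPLEX):
            for _ in range(2):
                _, entrez = self.new_gene()
                self.annotations.append(AnnotationRow(entrez_id=entrez, term_id=tid))
        tf_members = [self.new_gene()[1] for _ in range(2)]
        self.new_complex("general transcription complex", tf_members,
                         parents=(("is_a", GENERIC_TF_COMPLEX),))
        self.truth.complex_removals[root] = "parent_of_parent"
        self.truth.complex_removals[GENERIC_PROTEIN_COMPLEX] = "generic"
        self.truth.complex_removals[GENERIC_TF_COMPLEX] = "generic"

        # pruning chain: a parent of a parent with protein-bearing children
        chain_c = self.new_complex("assembly leaf complex",
                                   [self.new_gene()[1] for _ in range(2)])
        chain_b_members = [self.new_gene()[1] for _ in range(3)]
        chain_b = self.new_complex("assembly middle complex", chain_b_members,
                                   parents=(("is_a", GENERIC_MACROMOLECULAR),))
        chain_a = self.new_complex("assembly parent complex",
                                   [self.new_gene()[1] for _ in range(2)],
                                   parents=(("is_a", GENERIC_MACROMOLECULAR),))
        self._reparent(chain_b, chain_a)
        self._reparent(chain_c, chain_b)
        self.truth.complex_removals[chain_a] = "parent_of_parent"
        self.truth.kept_complexes += [chain_b, chain_c]

        # parent of a parent retained because its children are devoid of proteins
        sparse_f = self.new_complex("sparse leaf complex",
                                    [self.new_gene()[1] for _ in range(2)])
        sparse_e = self.new_complex("empty middle complex", [])
        sparse_d = self.new_complex("sparse parent complex",
                                    [self.new_gene()[1] for _ in range(2)],
                                    parents=(("is_a", GENERIC_MACROMOLECULAR),))
        self._reparent(sparse_e, sparse_d)
        self._reparent(sparse_f, sparse_e)
        self.truth.complex_removals[sparse_e] = "singleton"
        self.truth.kept_complexes += [sparse_d, sparse_f]

        # a one-protein complex, dropped as a singleton
        lonely = self.new_complex("lonely complex", [self.new_gene()[1]],
                                  parents=(("is_a", GENERIC_MACROMOLECULAR),))
        self.truth.complex_removals[lonely] = "singleton"

        # decoys the selection must ignore
        self.terms.append(OntologyTerm(
            term_id=self.ids.go(), name="ribosome assembly site",
            parents=(("is_a", GENERIC_MACROMOLECULAR),)))
        self.terms.append(OntologyTerm(
            term_id=self.ids.go(), name="defunct complex",
            parents=(("is_a", GENERIC_MACROMOLECULAR),), obsolete=True))
        self.terms.append(OntologyTerm(
            term_id=self.ids.go(), name="signaling complex assembly",
            parents=(), namespace="biological_process"))

    def _reparent(self, child: str, parent: str) -> None:
        for i, t in enumerate(self.terms):
            if t.term_id == child:
                parents = tuple(p for p in t.parents) + (("is_a", parent),)
                parents = tuple(p for p in parents if p[1] != GENERIC_MACROMOLECULAR)
                self.terms[i] = OntologyTerm(
                    term_id=t.term_id, name=t.name, parents=parents,
                    obsolete=t.obsolete, namespace=t.namespace)
                return
        raise KeyError(child)

    # -- planted overlaps ---------------------------------------------------

    def plant_overlaps(self) -> None:
        lethal_done = False
        for g, p, i, m in self.cfg.planted_overlaps:
            ps_genes = [self.new_gene() for _ in range(g)]
            ps_id, diseases = self.new_ps(ps_genes, "Planted series")
            shared = [e for _, e in ps_genes[:i]]
            fillers = [self.new_gene()[1] for _ in range(p - i)]
            tid = self.new_complex(
                f"planted complex {len(self.truth.planted_overlaps) + 1}",
                shared + fillers, parents=(("is_a", GENERIC_MACROMOLECULAR),))
            # series-wide clinical phenotype, shared by every member disease
            hp = self.ids.hp()
            for mim in diseases:
                self.disease_hp.append(DiseasePhenotypeRow(
                    phenotype_mim=mim, hp_terms=frozenset({hp, self.ids.hp()})))
            presumptive = fillers[:m]
            if m:
                mp = self.ids.mp()
                self.matches.append(PhenotypeMatchRow(mp_term=mp, hp_term=hp))
                for entrez in presumptive:
                    self.orthologs.append(OrthologPhenotypeRow(
                        human_entrez_id=entrez, mouse_gene_id=f"Mgi{entrez}",
                        mp_terms=frozenset({mp})))
            rest = fillers[m:]
            if rest:
                # negative control: a mouse phenotype translating to a human
                # phenotype the series' diseases never show
                mp_neg, hp_neg = self.ids.mp(), self.ids.hp()
                self.matches.append(PhenotypeMatchRow(mp_term=mp_neg, hp_term=hp_neg))
                self.orthologs.append(OrthologPhenotypeRow(
                    human_entrez_id=rest[0], mouse_gene_id=f"Mgi{rest[0]}",
                    mp_terms=frozenset({mp_neg})))
            if not lethal_done and len(rest) > 1:
                # one complex member with a pre-birth-lethal mouse knockout
                self.orthologs.append(OrthologPhenotypeRow(
                    human_entrez_id=rest[1], mouse_gene_id=f"Mgi{rest[1]}",
                    mp_terms=frozenset(), lethality_stage="embryonic"))
                self.truth.lethality_expected.append(
                    {"term_id": tid, "protein": rest[1], "stage": "embryonic"})
                lethal_done = True
            jc = i / (g + p - i)
            jc_aug = (i + m) / (g + p - (i + m))
            self.truth.planted_overlaps.append({
                "ps_id": ps_id, "term_id": tid, "group_size": g, "pc_size": p,
                "shared": sorted(shared), "jc": jc,
                "presumptive": sorted(presumptive), "jc_augmented": jc_aug,
            })
            if i < g and not self.truth.gof_expected:
                # a gain-of-function disease protein outside the complex
                outside = ps_genes[i][1]
                self.gof.add(outside)
                self.truth.gof_expected.append(
                    {"group_id": ps_id, "term_id": tid, "proteins": [outside]})
            self.truth.univocal_expected[ps_id] = True

    # -- redundancy plants --------------------------------------------------

    def plant_redundancy_cases(self) -> None:
        t = self.truth
        root = (("is_a", GENERIC_MACROMOLECULAR),)

        # parent-child complex pair intersecting one series
        x = [self.new_gene() for _ in range(3)]
        q_tid = self.new_complex("ion channel child complex",
                                 [x[0][1], x[1][1]] + [self.new_gene()[1] for _ in range(2)])
        p_tid = self.new_complex("ion channel parent complex",
                                 [e for _, e in x] + [self.new_gene()[1]], parents=root)
        self._reparent(q_tid, p_tid)
        ps_pc, _ = self.new_ps(x, "Channelopathy series")
        self._add_ps_hp(ps_pc)
        t.one_to_many.append({"group_id": ps_pc, "term_a": min(p_tid, q_tid),
                              "term_b": max(p_tid, q_tid), "status": "discarded",
                              "reason": "parent_child"})
        t.univocal_expected[ps_pc] = True
        t.kept_complexes += [p_tid, q_tid]

        # two complexes that are children of a shared (pruned) parent
        b = [self.new_gene() for _ in range(4)]
        bloc = self.new_complex("granule parent complex", [self.new_gene()[1]],
                                parents=root)
        b1 = self.new_complex("granule one complex",
                              [b[0][1], b[1][1], self.new_gene()[1]],
                              parents=(("is_a", bloc),))
        b2 = self.new_complex("granule two complex",
                              [b[2][1], b[3][1], self.new_gene()[1]],
                              parents=(("part_of", bloc),))
        ps_cp, _ = self.new_ps(b, "Granule disorder series")
        self._add_ps_hp(ps_cp)
        t.complex_removals[bloc] = "singleton"
        t.one_to_many.append({"group_id": ps_cp, "term_a": min(b1, b2),
                              "term_b": max(b1, b2), "status": "discarded",
                              "reason": "common_parent"})
        t.univocal_expected[ps_cp] = True
        t.kept_complexes += [b1, b2]

        # unrelated complexes sharing most of the smaller one's proteins
        s = [self.new_gene() for _ in range(5)]
        small = self.new_complex("receptor small complex", [e for _, e in s],
                                 parents=root)
        large = self.new_complex("receptor large complex",
                                 [e for _, e in s] + [self.new_gene()[1] for _ in range(7)],
                                 parents=root)
        ps_ms, _ = self.new_ps(s[:3], "Receptor disorder series")
        self._add_ps_hp(ps_ms)
        t.one_to_many.append({"group_id": ps_ms, "term_a": min(small, large),
                              "term_b": max(small, large), "status": "discarded",
                              "reason": "majority_shared"})
        t.univocal_expected[ps_ms] = True
        t.kept_complexes += [small, large]

        # three disjoint, unrelated complexes: a genuine one-to-many relation
        trio_tids, trio_genes = [], []
        for name in ("repair alpha complex", "repair beta complex",
                     "repair gamma complex"):
            members = [self.new_gene() for _ in range(3)]
            trio_genes += members[:2]
            trio_tids.append(self.new_complex(name, [e for _, e in members],
                                              parents=root))
        ps_trio, _ = self.new_ps(trio_genes, "Repair deficiency series")
        self._add_ps_hp(ps_trio)
        for a_i in range(3):
            for b_i in range(a_i + 1, 3):
                t.one_to_many.append({
                    "group_id": ps_trio, "term_a": min(trio_tids[a_i], trio_tids[b_i]),
                    "term_b": max(trio_tids[a_i], trio_tids[b_i]),
                    "status": "kept", "reason": ""})
        t.univocal_expected[ps_trio] = False
        t.kept_complexes += trio_tids

        # allele heterogeneity: two series annotating the same protein
        shared_gene = self.new_gene()
        ya, yb = self.new_gene(), self.new_gene()
        ah_tid = self.new_complex(
            "growth factor receptor complex",
            [shared_gene[1], ya[1], yb[1], self.new_gene()[1]], parents=root)
        ps_a, _ = self.new_ps([shared_gene, ya], "Aneurysm series")
        ps_b, _ = self.new_ps([shared_gene, yb], "Connective tissue series")
        self._add_ps_hp(ps_a)
        self._add_ps_hp(ps_b)
        t.many_to_one.append({"term_id": ah_tid, "group_a": min(ps_a, ps_b),
                              "group_b": max(ps_a, ps_b), "status": "discarded",
                              "reason": "allele_heterogeneity"})
        t.kept_complexes.append(ah_tid)

        # two series with disjoint proteins on one complex: genuine many-to-one
        u = [self.new_gene() for _ in range(2)]
        v = [self.new_gene() for _ in range(2)]
        mk_tid = self.new_complex(
            "arrhythmia channel complex",
            [e for _, e in u + v] + [self.new_gene()[1]], parents=root)
        ps_u, _ = self.new_ps(u, "Arrhythmia one series")
        ps_v, _ = self.new_ps(v, "Arrhythmia two series")
        self._add_ps_hp(ps_u)
        self._add_ps_hp(ps_v)
        t.many_to_one.append({"term_id": mk_tid, "group_a": min(ps_u, ps_v),
                              "group_b": max(ps_u, ps_v), "status": "kept",
                              "reason": ""})
        t.kept_complexes.append(mk_tid)

        # an all-gain-of-function series that intersects no complex at all
        noonan = [self.new_gene() for _ in range(3)]
        ps_noonan, _ = self.new_ps(noonan, "Overgrowth signaling series")
        self._add_ps_hp(ps_noonan)
        for _, entrez in noonan:
            self.gof.add(entrez)
        t.noonan_like_ps = ps_noonan

    def _add_ps_hp(self, ps_id: str) -> None:
        hp = self.ids.hp()
        for row in self.ps_rows:
            if row.ps_id == ps_id:
                self.disease_hp.append(DiseasePhenotypeRow(
                    phenotype_mim=row.phenotype_mim, hp_terms=frozenset({hp})))

    # -- disease-based LH plants and decoys ---------------------------------

    def plant_disease_groups(self) -> None:
        for size in self.cfg.disease_group_sizes:
            mim = self.ids.disease()
            for k in range(size):
                gene = self.new_gene()
                self.add_disease_row(f"Multigene disease {mim}", mim, gene[0])
                self._n_pairs += 1
        self.truth.disease_lh_sizes = sorted(self.cfg.disease_group_sizes)

    def plant_decoys(self) -> None:
        d = self._discards
        g = self.new_gene()
        self.add_disease_row("?Unconfirmed disorder", self.ids.disease(), g[0])
        d["unconfirmed"] += 1
        self.add_disease_row("[Blood group variant]", self.ids.disease(), g[0])
        d["non_disease"] += 1
        self.add_disease_row("{Multifactorial susceptibility}", self.ids.disease(), g[0])
        d["susceptibility"] += 1
        for key in (1, 2, 4):
            self.add_disease_row(f"Keyed-out disorder {key}", self.ids.disease(),
                                 g[0], key=key)
            d["mapping_key"] += 1
        self.add_disease_row("Unnumbered disorder", None, g[0])
        d["no_phenotype_mim"] += 1
        for status, mapped in (("moved", False), ("removed", False), ("active", False)):
            bad = self.new_gene(status=status, mapped=mapped)
            self.add_disease_row("Orphaned disorder", self.ids.disease(), bad[0])
            d["gene_not_mapped"] += 1
        rna = self.new_gene(coding=False)
        self.add_disease_row("Noncoding disorder", self.ids.disease(), rna[0])
        d["non_coding"] += 1
        # the first decoy gene also supports one surviving disease, so the
        # survivor/discard bookkeeping covers a mixed-outcome gene
        self.simple_disease(g, "Confirmed decoy-gene disorder")

    # -- random background --------------------------------------------------

    def build_background(self) -> None:
        cfg, rng = self.cfg, self.rng
        n_used = len(self.genes)
        n_background = cfg.n_genes - n_used
        if n_background < 20:
            raise ValueError(
                f"n_genes={cfg.n_genes} leaves only {n_background} background genes"
            )
        pool: list[tuple[str, str]] = []
        for _ in range(n_background):
            coding = bool(rng.random() >= cfg.frac_noncoding)
            gene = self.new_gene(coding=coding)
            if coding:
                pool.append(gene)
        self.background_genes = pool
        entrez_pool = np.array([e for _, e in pool])

        # background phenotypic series: one single-gene disease per protein
        sizes = sample_ps_sizes(cfg, cfg.n_ps, rng)
        for s in sizes:
            s = int(min(s, len(pool)))
            chosen = rng.choice(len(pool), size=s, replace=False)
            ps_id = self.ids.ps()
            hp = self.ids.hp()
            for gi in chosen:
                if rng.random() < cfg.frac_susceptibility:
                    self.add_disease_row("{Background susceptibility}",
                                         self.ids.disease(), pool[gi][0])
                    self._discards["susceptibility"] += 1
                    continue
                mim = self.simple_disease(pool[gi])
                self.ps_rows.append(PsMembershipRow(ps_id=ps_id, phenotype_mim=mim))
                self.disease_hp.append(DiseasePhenotypeRow(
                    phenotype_mim=mim, hp_terms=frozenset({hp})))
                if rng.random() < cfg.frac_gof:
                    self.gof.add(pool[gi][1])

        # background diseases outside any series
        for _ in range(cfg.n_diseases):
            gi = int(rng.integers(len(pool)))
            if rng.random() < cfg.frac_susceptibility:
                self.add_disease_row("{Background susceptibility}",
                                     self.ids.disease(), pool[gi][0])
                self._discards["susceptibility"] += 1
            else:
                self.simple_disease(pool[gi])

        # background complexes draw uniformly from the background pool only,
        # so planted overlaps stay exact
        pc_sizes = sample_pc_sizes(cfg, cfg.n_complexes, rng)
        for k, s in enumerate(pc_sizes):
            s = int(min(s, len(entrez_pool)))
            members = rng.choice(entrez_pool, size=s, replace=False)
            tid = self.new_complex(f"background complex {k + 1}",
                                   members.tolist(),
                                   parents=(("is_a", GENERIC_MACROMOLECULAR),))
            if rng.random() < cfg.frac_lethal:
                stage = ("embryonic", "fetal", "prenatal")[self._lethal_cycle % 3]
                self._lethal_cycle += 1
                self.orthologs.append(OrthologPhenotypeRow(
                    human_entrez_id=str(members[0]), mouse_gene_id=f"Mgi{members[0]}",
                    mp_terms=frozenset(), lethality_stage=stage))

    # -- assembly -----------------------------------------------------------

    def build(self) -> None:
        self.plant_ontology_scaffold()
        self.plant_overlaps()
        if self.cfg.plant_redundancy:
            self.plant_redundancy_cases()
        self.plant_disease_groups()
        if self.cfg.plant_decoys:
            self.plant_decoys()
        self.build_background()
        self.truth.filter_discards = dict(self._discards)
        self.truth.n_pairs_expected = self._n_pairs
        self.truth.kept_complexes = sorted(set(self.truth.kept_complexes))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "morbid_map": outdir / "morbid_map.tsv",
            "genes": outdir / "genes.tsv",
            "ps_memberships": outdir / "ps_memberships.tsv",
            "ontology": outdir / "ontology.obo",
            "annotations": outdir / "annotations.tsv",
            "orthologs": outdir / "orthologs.tsv",
            "phenotype_matches": outdir / "phenotype_matches.tsv",
            "disease_phenotypes": outdir / "disease_phenotypes.tsv",
            "gof": outdir / "gof.tsv",
        }
        catalog_io.write_morbid_map(self.morbid, paths["morbid_map"])
        catalog_io.write_gene_catalog(self.genes, paths["genes"])
        catalog_io.write_ps_memberships(self.ps_rows, paths["ps_memberships"])
        catalog_io.write_ontology(sorted(self.terms, key=lambda t: t.term_id),
                                  paths["ontology"])
        catalog_io.write_annotations(self.annotations, paths["annotations"])
        catalog_io.write_orthologs(self.orthologs, paths["orthologs"])
        catalog_io.write_phenotype_matches(self.matches, paths["phenotype_matches"])
        catalog_io.write_disease_phenotypes(self.disease_hp, paths["disease_phenotypes"])
        catalog_io.write_gof_proteins(self.gof, paths["gof"])
        self.truth.to_json(outdir / "truth.json")
        return paths


def generate_universe(cfg: WorldConfig, outdir: str | Path) -> tuple[dict[str, Path], TruthManifest]:
    """Build a synthetic world and write its file bundle plus ``truth.json``.

    Infeasible planted specifications raise before any file is written.
    The same config (seed included) always produces a byte-identical bundle.
    """
    builder = _WorldBuilder(cfg)
    builder.build()
    paths = builder.write(outdir)
    # self-check: planted coefficients match an independent recomputation
    for fact in builder.truth.planted_overlaps:
        a = set(range(fact["group_size"]))
        b = set(range(fact["group_size"] - len(fact["shared"]),
                      fact["group_size"] - len(fact["shared"]) + fact["pc_size"]))
        assert abs(jaccard(a, b) - fact["jc"]) < 1e-12
    return paths, builder.truth
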