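"""End-to-end orchestration: files in, report bundle out.

Stages run in fixed order — parsing, disease filtering, group assembly,
complex pruning, intersection, permutation controls, ortholog
augmentation, univocity filtering — and every stage's table lands in the
output directory next to a ``report.json`` with the headline counts,
percentages and JC moments plus a full echo of the configuration.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import (
    catalog_io,
    complex_catalog,
    disease_catalog,
    lh_intersection,
    nonunivocal,
    ortholog_augmentation,
    randomization,
)

logger = logging.getLogger(__name__)

MODES = ("ps_based", "disease_based")


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    mode: str = "ps_based"
    reps: int = 1000
    seed: int = 0
    jc_floor: float = 0.1
    run_nulls: bool = True
    run_pairwise: bool = True

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        indir = Path(self.input_dir)
        for name in ("morbid_map.tsv", "genes.tsv", "ontology.obo", "annotations.tsv"):
            if not (indir / name).exists():
                raise FileNotFoundError(indir / name)


def _input_paths(indir: Path) -> dict[str, Path]:
    names = {
        "genes": "genes.tsv",
        "ps_memberships": "ps_memberships.tsv",
        "annotations": "annotations.tsv",
        "orthologs": "orthologs.tsv",
        "phenotype_matches": "phenotype_matches.tsv",
        "disease_phenotypes": "disease_phenotypes.tsv",
        "gof": "gof.tsv",
    }
    return {k: indir / v for k, v in names.items() if (indir / v).exists()}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the contents of ``report.json``.

    On a stage failure the partial outputs are retained and a ``FAILED``
    marker file names the stage.
    """
    cfg.validate()
    indir, outdir = Path(cfg.input_dir), Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "catalog_io"
    try:
        morbid = catalog_io.read_morbid_map(indir / "morbid_map.tsv")
        terms = catalog_io.read_ontology(indir / "ontology.obo")
        aux = catalog_io.read_aux_tables(_input_paths(indir))

        stage = "disease_catalog"
        filt = disease_catalog.filter_disease_gene_pairs(morbid, aux.genes)
        disease_catalog.write_filter_report(filt, outdir / "filter_report.tsv")
        disease_family = disease_catalog.build_disease_groups(filt.pairs)
        disease_catalog.write_groups(disease_family.lh_groups, outdir / "disease_groups.tsv")
        if cfg.mode == "ps_based":
            family = disease_catalog.build_ps_groups(filt.pairs, aux.ps_memberships)
            disease_catalog.write_groups(family.lh_groups, outdir / "ps_groups.tsv")
            pairs = disease_catalog.ps_assignments(filt.pairs, aux.ps_memberships)
        else:
            family = disease_family
            pairs = [
                dataclasses.replace(p, ps_id=p.phenotype_mim) for p in filt.pairs
            ]
        groups = family.lh_groups

        stage = "complex_catalog"
        catalog = complex_catalog.select_and_prune_complexes(terms, aux.annotations)
        complex_catalog.write_complexes(catalog, outdir / "complexes.tsv")
        complex_catalog.write_removals(catalog, outdir / "complex_removals.tsv")

        stage = "lh_intersection"
        records = lh_intersection.find_intersections(groups, catalog)
        lh_intersection.write_intersections(records, outdir / "intersections.tsv")
        # degenerate single-protein series stay in the denominator: they are
        # valid series that simply cannot share two proteins with anything
        stats = lh_intersection.summarize(
            records, groups + family.degenerate_groups, catalog)
        lh_intersection.write_summary(stats, outdir / "summary.json")

        stage = "randomization"
        nulls: dict[str, dict] = {}
        if cfg.run_nulls and groups:
            group_pool = frozenset().union(*(g.proteins for g in groups))
            all_disease_proteins = frozenset(p.entrez_id for p in filt.pairs)
            non_lh_pool = all_disease_proteins - group_pool
            kinds = ["pseudo_ps", "pseudo_pc"]
            if non_lh_pool:
                kinds.append("non_lh")
            for i, kind in enumerate(kinds):
                res = randomization.run_null_control(
                    randomization.NullModelConfig(kind=kind, reps=cfg.reps,
                                                  seed=cfg.seed + i),
                    groups, catalog, non_lh_pool=non_lh_pool or None,
                )
                randomization.write_null_result(res, outdir / f"null_{kind}.json")
                nulls[kind] = res.to_dict()
            if cfg.run_pairwise:
                res = randomization.pairwise_control(pairs, catalog,
                                                     reps=cfg.reps, seed=cfg.seed + 10)
                randomization.write_null_result(res, outdir / "null_pairwise.json")
                nulls["pairwise"] = res.to_dict()

        stage = "ortholog_augmentation"
        augmentation: Optional[dict] = None
        if cfg.mode == "ps_based":
            aug = ortholog_augmentation.augment_records(
                groups, catalog, aux.orthologs, aux.phenotype_matches,
                aux.ps_memberships, aux.disease_phenotypes, records,
            )
            ortholog_augmentation.write_augmented(aug, outdir / "augmented.tsv")
            augmentation = {
                "n_groups_hit_base": aug.n_groups_hit_base,
                "n_groups_hit_augmented": aug.n_groups_hit_augmented,
                "mean_jc_base": aug.mean_jc(augmented=False),
                "mean_jc_augmented": aug.mean_jc(augmented=True),
            }
        gofs = ortholog_augmentation.annotate_gof(records, groups, catalog,
                                                  aux.gof_proteins)
        ortholog_augmentation.write_gof_annotations(gofs, outdir / "gof_annotations.tsv")
        lethal = ortholog_augmentation.annotate_lethality(catalog, aux.orthologs)
        ortholog_augmentation.write_lethality_annotations(
            lethal, outdir / "lethality_annotations.tsv")

        stage = "nonunivocal"
        otm = nonunivocal.filter_one_to_many(records, catalog)
        mto = nonunivocal.filter_many_to_one(records, pairs)
        nonunivocal.write_pc_pairs(otm.one_to_many_kept + otm.one_to_many_discarded,
                                   outdir / "relations_one_to_many.tsv")
        nonunivocal.write_ps_pairs(mto.many_to_one_kept + mto.many_to_one_discarded,
                                   outdir / "relations_many_to_one.tsv")
        edges = nonunivocal.export_relation_graph(records, otm, jc_floor=cfg.jc_floor)
        nonunivocal.write_relation_graph(edges, outdir / "relation_graph.tsv")

        report = {
            "config": dataclasses.asdict(cfg),
            "n_morbid_rows": len(morbid),
            "filter": {"n_pairs": len(filt.pairs),
                       "discards": dict(filt.discards)},
            "n_lh_groups": len(groups),
            "n_disease_lh_groups": len(disease_family.lh_groups),
            "disease_lh_size_histogram": disease_catalog.size_histogram(
                disease_family.lh_groups),
            "complexes": {"n_selected": catalog.n_selected, "n_kept": catalog.n_kept,
                          "classes": catalog.class_counts()},
            "intersection": stats.to_dict(),
            "nulls": nulls,
            "augmentation": augmentation,
            "relations": {
                "n_univocal": len(otm.univocal),
                "n_non_univocal": len(otm.non_univocal),
                "one_to_many_kept": len(otm.one_to_many_kept),
                "one_to_many_discarded": len(otm.one_to_many_discarded),
                "many_to_one_kept": len(mto.many_to_one_kept),
                "many_to_one_discarded": len(mto.many_to_one_discarded),
            },
        }
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    return report
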