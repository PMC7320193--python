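"""Presumptive disease proteins, augmented JCs and annotation tables."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_catalog, make_group
from lhpc.lh_intersection import find_intersections
from lhpc.ortholog_augmentation import (
    annotate_gof,
    annotate_lethality,
    augment_records,
    augmented_jaccard,
    find_presumptive_proteins,
    groups_without_complex,
)
from lhpc.types import (
    DiseasePhenotypeRow,
    IntersectionRecord,
    OrthologPhenotypeRow,
    PhenotypeMatchRow,
    PsMembershipRow,
)


def _rec(i, group_size, pc_size, gid="ps1", tid="GO:1"):
    return IntersectionRecord(
        group_id=gid, term_id=tid, shared=frozenset(f"s{k}" for k in range(i)),
        jc=i / (group_size + pc_size - i), group_size=group_size, pc_size=pc_size)


class TestAugmentedJaccard:
    def test_nadph_oxidase_case(self):
        # 4 disease proteins in a 12-member complex, 2 presumptive: 0.33 -> 0.60
        rec = _rec(4, 4, 12)
        assert round(rec.jc, 2) == 0.33
        assert round(augmented_jaccard(rec, frozenset({"n4", "nox4"})), 2) == 0.60

    def test_no_presumptive_keeps_base(self):
        rec = _rec(3, 5, 9)
        assert augmented_jaccard(rec, frozenset()) == rec.jc

    def test_small_hand_computed_case(self):
        rec = _rec(2, 2, 4)
        assert augmented_jaccard(rec, frozenset({"m"})) == 1.0

    def test_overflowing_intersection_is_error(self):
        rec = _rec(2, 2, 3)
        with pytest.raises(ValueError, match="exceed"):
            augmented_jaccard(rec, frozenset({"a", "b"}))

    def test_overlap_with_shared_is_error(self):
        rec = _rec(2, 2, 4)
        with pytest.raises(ValueError, match="disjoint"):
            augmented_jaccard(rec, frozenset({"s0"}))

    @given(
        st.integers(2, 8),   # i
        st.integers(0, 6),   # extra group proteins
        st.integers(0, 5),   # m
        st.integers(0, 20),  # extra complex proteins beyond i+m
    )
    @settings(deadline=None)
    def test_never_below_base_equality_iff_empty(self, i, g_extra, m, pc_extra):
        rec = _rec(i, i + g_extra, i + m + pc_extra)
        pres = frozenset(f"m{k}" for k in range(m))
        aug = augmented_jaccard(rec, pres)
        if m == 0:
            assert aug == rec.jc
        else:
            assert aug > rec.jc


def _mouse_world():
    """One series of 4 disease proteins inside a 12-member oxidase-like complex."""
    disease = {f"cyb{i}" for i in range(4)}
    fillers = {f"ncf{i}" for i in range(8)}
    pc = disease | fillers
    group = make_group("PS1", disease)
    catalog = make_catalog({"GO:1": pc})
    ps_rows = [PsMembershipRow("PS1", f"d{i}") for i in range(4)]
    disease_hp = [DiseasePhenotypeRow(f"d{i}", frozenset({"HP:recinf"})) for i in range(4)]
    matches = [PhenotypeMatchRow("MP:susinf", "HP:recinf"),
               PhenotypeMatchRow("MP:other", "HP:other")]
    orthologs = [
        OrthologPhenotypeRow("ncf0", "Ncf4", frozenset({"MP:susinf"})),
        OrthologPhenotypeRow("ncf1", "Nox4", frozenset({"MP:susinf", "MP:other"})),
        OrthologPhenotypeRow("ncf2", "Xdh", frozenset({"MP:other"})),  # wrong phenotype
        OrthologPhenotypeRow("ncf3", "Lethal1", frozenset(), lethality_stage="fetal"),
    ]
    return group, catalog, ps_rows, disease_hp, matches, orthologs


class TestPresumptive:
    def test_matching_orthologs_promoted(self):
        group, catalog, ps_rows, disease_hp, matches, orthologs = _mouse_world()
        records = find_intersections([group], catalog)
        res = augment_records([group], catalog, orthologs, matches, ps_rows,
                              disease_hp, records)
        (rec,) = res.records
        assert rec.presumptive == {"ncf0", "ncf1"}
        assert round(rec.base.jc, 2) == 0.33
        assert round(rec.jc_augmented, 2) == 0.60

    def test_no_mp_terms_never_presumptive(self):
        group, catalog, *_ = _mouse_world()
        pres = find_presumptive_proteins(
            group.proteins, catalog.complexes["GO:1"].proteins,
            frozenset({"HP:recinf"}),
            {"ncf3": frozenset()},
        )
        assert pres == frozenset()

    def test_non_matching_hp_not_presumptive(self):
        group, catalog, *_ = _mouse_world()
        pres = find_presumptive_proteins(
            group.proteins, catalog.complexes["GO:1"].proteins,
            frozenset({"HP:recinf"}),
            {"ncf2": frozenset({"HP:other"})},
        )
        assert pres == frozenset()

    def test_monotone_in_match_table(self):
        group, catalog, ps_rows, disease_hp, matches, orthologs = _mouse_world()
        records = find_intersections([group], catalog)

        def presumptive_with(match_rows):
            res = augment_records([group], catalog, orthologs, match_rows, ps_rows,
                                  disease_hp, records)
            return res.records[0].presumptive

        base = presumptive_with(matches[:1])
        more = presumptive_with(matches[:1] + [PhenotypeMatchRow("MP:other", "HP:recinf")])
        assert base <= more
        assert more == {"ncf0", "ncf1", "ncf2"}

    def test_augmentation_can_create_new_intersections(self):
        # one shared protein only; a presumptive member lifts the pair over
        # the two-protein threshold, raising the count of intersecting groups
        group = make_group("PS1", {"a", "z1", "z2"})
        catalog = make_catalog({"GO:1": {"a", "b", "c"}})
        records = find_intersections([group], catalog)
        assert records == []
        res = augment_records(
            [group], catalog,
            [OrthologPhenotypeRow("b", "B", frozenset({"MP:1"}))],
            [PhenotypeMatchRow("MP:1", "HP:1")],
            [PsMembershipRow("PS1", "d1")],
            [DiseasePhenotypeRow("d1", frozenset({"HP:1"}))],
            records,
        )
        (rec,) = res.records
        assert rec.is_new and rec.presumptive == {"b"}
        assert res.n_groups_hit_augmented == 1 > res.n_groups_hit_base

    def test_world_augmentation_never_decreases(self, world_report):
        aug = world_report["report"]["augmentation"]
        assert aug["n_groups_hit_augmented"] >= aug["n_groups_hit_base"]
        assert aug["mean_jc_augmented"] >= aug["mean_jc_base"]


class TestAnnotations:
    def test_gof_outside_pc_listed(self):
        group = make_group("PS1", {"a", "b", "g"})
        catalog = make_catalog({"GO:1": {"a", "b", "x"}})
        records = find_intersections([group], catalog)
        (annotation,) = annotate_gof(records, [group], catalog, frozenset({"g", "x"}))
        assert annotation.gof_proteins_outside_pc == {"g"}

    def test_all_proteins_inside_pc_gives_empty_annotation(self):
        group = make_group("PS1", {"a", "b"})
        catalog = make_catalog({"GO:1": {"a", "b"}})
        records = find_intersections([group], catalog)
        (annotation,) = annotate_gof(records, [group], catalog, frozenset({"a"}))
        assert annotation.gof_proteins_outside_pc == frozenset()

    def test_all_gof_group_reported_complexless(self):
        groups = [make_group("PSnoonan", {"ras1", "ras2"}),
                  make_group("PShit", {"a", "b"})]
        catalog = make_catalog({"GO:1": {"a", "b"}})
        records = find_intersections(groups, catalog)
        assert groups_without_complex(groups, records,
                                      frozenset({"ras1", "ras2"})) == ["PSnoonan"]

    def test_lethality_per_complex(self):
        catalog = make_catalog({"GO:1": {"a", "b"}, "GO:2": {"c", "d"}})
        orthologs = [
            OrthologPhenotypeRow("a", "A", frozenset(), lethality_stage="embryonic"),
            OrthologPhenotypeRow("b", "B", frozenset({"MP:1"})),  # viable
        ]
        (annotation,) = annotate_lethality(catalog, orthologs)
        assert annotation.term_id == "GO:1"
        assert annotation.stages == (("a", "embryonic"),)

    def test_all_members_lethal_all_listed(self):
        catalog = make_catalog({"GO:1": {"a", "b"}})
        orthologs = [
            OrthologPhenotypeRow("a", "A", frozenset(), lethality_stage="fetal"),
            OrthologPhenotypeRow("b", "B", frozenset(), lethality_stage="prenatal"),
        ]
        (annotation,) = annotate_lethality(catalog, orthologs)
        assert annotation.essential_proteins == {"a", "b"}
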