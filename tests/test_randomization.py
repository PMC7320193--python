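"""Permutation controls: reproducibility, calibration and signal detection."""
import math

import numpy as np
import pytest

from conftest import make_catalog, make_group
from lhpc.randomization import (
    NullModelConfig,
    make_pseudo_groups,
    pairwise_control,
    run_null_control,
    z_score,
)
from lhpc.types import DiseaseGenePair


class TestPseudoGroups:
    def test_sizes_preserved(self):
        rng = np.random.default_rng(0)
        pool = {f"p{i}" for i in range(10)}
        groups = make_pseudo_groups(pool, [2, 3], rng)
        assert sorted(g.size for g in groups) == [2, 3]
        for g in groups:
            assert g.proteins <= pool

    def test_forced_outcome_when_pool_equals_size(self):
        rng = np.random.default_rng(0)
        (g,) = make_pseudo_groups({"a", "b", "c"}, [3], rng)
        assert g.proteins == {"a", "b", "c"}

    def test_oversized_group_is_error(self):
        with pytest.raises(ValueError):
            make_pseudo_groups({"a"}, [2], np.random.default_rng(0))

    def test_seed_reproducibility(self):
        pool = {f"p{i}" for i in range(30)}
        a = make_pseudo_groups(pool, [4, 5, 6], np.random.default_rng(42))
        b = make_pseudo_groups(pool, [4, 5, 6], np.random.default_rng(42))
        assert [g.proteins for g in a] == [g.proteins for g in b]


class TestZScore:
    def test_zero_when_observed_equals_mean(self):
        assert z_score(2, [1, 2, 3]) == 0.0

    def test_direct_formula(self):
        counts = [10, 12, 14]  # mean 12, sample sd 2
        assert z_score(18, counts) == pytest.approx(3.0)

    def test_published_moment_arithmetic(self):
        # a null of 10.4 +/- 2.7 against 95 observed: (95-10.4)/2.7 = 31.3
        assert (95 - 10.4) / 2.7 == pytest.approx(31.33, abs=0.005)

    def test_constant_null_is_undefined(self):
        assert math.isnan(z_score(5, [3, 3, 3]))


def _random_world(seed: int = 0, n_pool: int = 120, n_groups: int = 12, n_pcs: int = 15):
    """Groups and complexes drawn independently from one pool (chance overlap only)."""
    rng = np.random.default_rng(seed)
    pool = [f"p{i}" for i in range(n_pool)]
    members = {
        f"GO:{k}": set(rng.choice(pool, size=8, replace=False)) for k in range(n_pcs)
    }
    groups = [
        make_group(f"g{k}", set(rng.choice(pool, size=5, replace=False)))
        for k in range(n_groups)
    ]
    return groups, make_catalog(members)


def _planted_world(n_pcs: int = 12, pc_size: int = 5, n_decoys: int = 20):
    """Each complex copied verbatim by a group, plus protein-disjoint decoy groups."""
    members = {
        f"GO:{k:02d}": {f"p{pc_size * k + j}" for j in range(pc_size)}
        for k in range(n_pcs)
    }
    groups = [make_group(f"g{k:02d}", members[f"GO:{k:02d}"]) for k in range(n_pcs)]
    offset = n_pcs * pc_size
    groups += [
        make_group(f"d{k:02d}", {f"p{offset + pc_size * k + j}" for j in range(pc_size)})
        for k in range(n_decoys)
    ]
    return groups, make_catalog(members)


class TestNullControls:
    def test_planted_copies_give_large_positive_z(self):
        groups, catalog = _planted_world()
        res = run_null_control(
            NullModelConfig(kind="pseudo_ps", reps=300, seed=1), groups, catalog)
        assert res.observed == len(catalog.complexes)  # every copy group hits
        assert res.null_mean < res.observed
        assert res.z > 3

    def test_uniform_groups_give_small_z(self):
        zs = []
        for w in range(8):
            groups, catalog = _random_world(seed=w)
            res = run_null_control(
                NullModelConfig(kind="pseudo_ps", reps=250, seed=w), groups, catalog)
            if res.z_defined:
                zs.append(abs(res.z))
        assert np.median(zs) < 3

    def test_pseudo_pc_randomizes_complex_side(self):
        groups, catalog = _planted_world()
        res = run_null_control(
            NullModelConfig(kind="pseudo_pc", reps=300, seed=2), groups, catalog)
        assert res.observed == len(catalog.complexes)  # every PC copied by a group
        assert res.z > 3

    def test_non_lh_pool_used(self):
        groups, catalog = _planted_world()
        # a disjoint pool can never reproduce the planted overlap
        pool = frozenset(f"q{i}" for i in range(50))
        res = run_null_control(
            NullModelConfig(kind="non_lh", reps=100, seed=3),
            groups, catalog, non_lh_pool=pool)
        assert res.null_mean == 0.0

    def test_fixed_seed_bit_identical(self):
        groups, catalog = _random_world(seed=5)
        cfg = NullModelConfig(kind="pseudo_ps", reps=150, seed=9)
        a = run_null_control(cfg, groups, catalog)
        b = run_null_control(cfg, groups, catalog)
        assert np.array_equal(a.null_counts, b.null_counts)
        assert a.observed == b.observed and a.z == b.z or (
            math.isnan(a.z) and math.isnan(b.z))

    def test_null_mean_grows_with_overlap_density(self):
        # denser complexes raise the chance a pseudo-group hits one
        means = []
        for size in (4, 8, 16):
            rng = np.random.default_rng(0)
            pool = [f"p{i}" for i in range(80)]
            catalog = make_catalog({
                f"GO:{k}": set(rng.choice(pool, size=size, replace=False))
                for k in range(10)
            })
            groups = [make_group(f"g{k}", set(rng.choice(pool, size=6, replace=False)))
                      for k in range(10)]
            res = run_null_control(
                NullModelConfig(kind="pseudo_ps", reps=150, seed=4), groups, catalog)
            means.append(res.null_mean)
        assert means[0] < means[1] < means[2]


class TestPairwise:
    def test_single_coincident_pair(self):
        pairs = [
            DiseaseGenePair("d1", "a", ps_id="PS1"),
            DiseaseGenePair("d2", "b", ps_id="PS1"),
            DiseaseGenePair("d3", "c", ps_id="PS2"),
        ]
        catalog = make_catalog({"GO:1": {"a", "b"}})
        res = pairwise_control(pairs, catalog, reps=50, seed=0)
        assert res.observed == 1
        assert res.config["n_pairs_per_rep"] == 1

    def test_same_protein_two_ps_not_counted(self):
        # allele heterogeneity alone (one shared protein, single disease per PS)
        pairs = [
            DiseaseGenePair("d1", "a", ps_id="PS1"),
            DiseaseGenePair("d1", "b", ps_id="PS1"),
        ]
        catalog = make_catalog({"GO:1": {"a", "b"}})
        # both proteins cause the SAME disease: not two diseases in one PS
        res = pairwise_control(pairs, catalog, reps=20, seed=0)
        assert res.observed == 0

    def test_recovers_planted_enrichment_ratio(self):
        # same-complex pairs always same-PS; random pairs rarely so
        rng = np.random.default_rng(7)
        pairs, members = [], {}
        for k in range(12):
            a, b = f"x{k}", f"y{k}"
            pairs += [DiseaseGenePair(f"d{k}a", a, ps_id=f"PS{k}"),
                      DiseaseGenePair(f"d{k}b", b, ps_id=f"PS{k}")]
            members[f"GO:{k}"] = {a, b}
        catalog = make_catalog(members)
        res = pairwise_control(pairs, catalog, reps=4000, seed=1)
        assert res.observed == 12
        # 24 proteins, 12 matched pairs: P(random pair same PS) = 1/23,
        # so the expected enrichment ratio is 23
        assert res.ratio == pytest.approx(23, rel=0.15)
        assert res.z > 5
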