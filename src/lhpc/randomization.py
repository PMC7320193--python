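"""Permutation controls for the group-complex intersection counts.

Four controls assess whether the observed number of intersecting entities
exceeds chance: (i) pseudo-PS — disease proteins reshuffled into groups of
the real sizes, scored against the real complexes; (ii) pseudo-PC — complex
proteins reshuffled into complexes of the real sizes, scored against the
real groups; (iii) non-LH — pseudo-groups drawn from the disease proteins
that never enter an LH group; (iv) pairwise — protein pairs co-resident in
a complex, scored for also causing two different diseases of one
phenotypic series. Each control reports the observed count, the null mean
and sample SD over replicates, and Z = (observed - mean) / SD.

Pseudo-groups are independent uniform subsets of the pool (a protein may
land in several pseudo-groups): real group sizes sum to more than the
number of distinct disease proteins, so a partition is impossible, and the
independent-subset scheme is the minimal one preserving the size multiset.
"""
from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .complex_catalog import ComplexCatalog
from .types import DiseaseGenePair, ProteinGroup

NULL_KINDS = ("pseudo_ps", "pseudo_pc", "non_lh", "pairwise")


@dataclass
class NullModelConfig:
    kind: str
    reps: int = 100_000
    seed: int = 0
    protein_pool: Optional[frozenset[str]] = None
    group_sizes: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in NULL_KINDS:
            raise ValueError(f"unknown control kind {self.kind!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.group_sizes is not None and any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 1")


@dataclass
class NullResult:
    kind: str
    observed: int
    null_counts: np.ndarray
    null_mean: float
    null_sd: float
    z: float                      # nan when undefined (sd == 0)
    ratio: Optional[float] = None  # observed / null_mean, pairwise control only
    config: dict = field(default_factory=dict)

    @property
    def z_defined(self) -> bool:
        return not math.isnan(self.z)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "observed": self.observed,
            "reps": len(self.null_counts),
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if not self.z_defined else self.z,
            "ratio": self.ratio,
            "config": self.config,
        }


def z_score(observed: float, null_counts: Sequence[float]) -> float:
    """(observed - mean) / sample SD of the null counts; NaN when SD is zero."""
    counts = np.asarray(null_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("z-score needs at least two replicates")
    sd = counts.std(ddof=1)
    if sd == 0:
        return math.nan
    return float((observed - counts.mean()) / sd)


def make_pseudo_groups(
    pool: Sequence[str] | frozenset[str], sizes: Sequence[int], rng: np.random.Generator
) -> list[ProteinGroup]:
    """Uniform random subsets of ``pool`` matching the real size multiset.

    Draws are without replacement within a group and independent across
    groups; ``pool`` is sorted internally so results depend only on its
    content and the generator state.
    """
    pool_arr = np.array(sorted(pool))
    for size in sizes:
        if size > pool_arr.size:
            raise ValueError(f"group size {size} exceeds pool of {pool_arr.size}")
    groups = []
    for i, size in enumerate(sizes):
        chosen = rng.choice(pool_arr, size=size, replace=False)
        groups.append(
            ProteinGroup(group_id=f"pseudo{i:05d}", role="ps",
                         proteins=frozenset(chosen.tolist()))
        )
    return groups


def _index_by_protein(side: Sequence[frozenset[str]]) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i, prots in enumerate(side):
        for p in prots:
            idx[p].append(i)
    return idx


def _count_hits(random_sets: Sequence[frozenset[str]], fixed_index: dict[str, list[int]]) -> int:
    """Number of random sets sharing >=2 proteins with at least one fixed set."""
    n_hit = 0
    for prots in random_sets:
        counts: dict[int, int] = defaultdict(int)
        hit = False
        for p in prots:
            for j in fixed_index.get(p, ()):
                counts[j] += 1
                if counts[j] >= 2:
                    hit = True
                    break
            if hit:
                break
        n_hit += hit
    return n_hit


def count_entities_hit(
    varying: Sequence[ProteinGroup], fixed: Sequence[ProteinGroup]
) -> int:
    """How many of ``varying`` share >=2 proteins with some member of ``fixed``."""
    idx = _index_by_protein([g.proteins for g in fixed])
    return _count_hits([g.proteins for g in varying], idx)


def run_null_control(
    cfg: NullModelConfig,
    groups: Sequence[ProteinGroup],
    catalog: ComplexCatalog,
    non_lh_pool: Optional[frozenset[str]] = None,
) -> NullResult:
    """Run one of the three reshuffling controls.

    ``pseudo_ps`` and ``non_lh`` randomize the group side and score against
    the real complexes; ``pseudo_pc`` randomizes the complex side and
    scores against the real groups. The observed count is always computed
    on the real data for the same side.
    """
    if cfg.kind == "pairwise":
        raise ValueError("use pairwise_control for the pairwise analysis")
    pcs = catalog.groups()
    if cfg.kind == "pseudo_pc":
        sizes = cfg.group_sizes or tuple(p.size for p in pcs)
        pool = cfg.protein_pool or frozenset().union(*(p.proteins for p in pcs))
        fixed, observed_side = groups, pcs
    else:
        sizes = cfg.group_sizes or tuple(g.size for g in groups)
        if cfg.kind == "non_lh":
            if cfg.protein_pool is None and non_lh_pool is None:
                raise ValueError("non_lh control needs the non-LH protein pool")
            pool = cfg.protein_pool or non_lh_pool
        else:
            pool = cfg.protein_pool or frozenset().union(*(g.proteins for g in groups))
        fixed, observed_side = pcs, groups

    observed = count_entities_hit(observed_side, fixed)
    fixed_idx = _index_by_protein([g.proteins for g in fixed])
    rng = np.random.default_rng(cfg.seed)
    pool_arr = np.array(sorted(pool))
    for size in sizes:
        if size > pool_arr.size:
            raise ValueError(f"group size {size} exceeds pool of {pool_arr.size}")
    counts = np.empty(cfg.reps, dtype=np.int64)
    for rep in range(cfg.reps):
        pseudo = [
            frozenset(rng.choice(pool_arr, size=s, replace=False).tolist()) for s in sizes
        ]
        counts[rep] = _count_hits(pseudo, fixed_idx)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if cfg.reps > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else math.nan
    return NullResult(
        kind=cfg.kind, observed=observed, null_counts=counts,
        null_mean=mean, null_sd=sd, z=z,
        config={"reps": cfg.reps, "seed": cfg.seed, "n_groups": len(sizes),
                "pool_size": int(pool_arr.size)},
    )


def _same_ps_different_diseases(
    p: str, q: str, ps_diseases_of: dict[str, dict[str, set[str]]]
) -> bool:
    """Do proteins p and q cause two different diseases within one PS?"""
    ps_p, ps_q = ps_diseases_of.get(p), ps_diseases_of.get(q)
    if not ps_p or not ps_q:
        return False
    for ps_id in ps_p.keys() & ps_q.keys():
        if len(ps_p[ps_id] | ps_q[ps_id]) >= 2:
            return True
    return False


def pairwise_control(
    pairs: Sequence[DiseaseGenePair],
    catalog: ComplexCatalog,
    reps: int = 100_000,
    seed: int = 0,
) -> NullResult:
    """Pairwise enrichment of same-complex proteins for same-PS disease causation.

    Observed: among unordered pairs of disease proteins co-resident in at
    least one complex, those whose members cause two different diseases of
    the same PS. Null: per replicate, the same number of uniform random
    distinct-protein pairs from the disease-protein pool, scored the same
    way. Also reports the enrichment ratio observed / null mean.
    """
    ps_diseases_of: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    proteins: set[str] = set()
    for pr in pairs:
        proteins.add(pr.entrez_id)
        if pr.ps_id is not None:
            ps_diseases_of[pr.entrez_id][pr.ps_id].add(pr.phenotype_mim)
    ps_diseases_of = {p: dict(v) for p, v in ps_diseases_of.items()}
    if len(proteins) < 2:
        raise ValueError("pairwise control needs at least two disease proteins")

    # unordered same-complex pairs restricted to disease proteins
    same_pc_pairs: set[tuple[str, str]] = set()
    for pc in catalog.groups():
        members = sorted(pc.proteins & proteins)
        same_pc_pairs.update(combinations(members, 2))
    n_draw = len(same_pc_pairs)
    observed = sum(
        _same_ps_different_diseases(p, q, ps_diseases_of) for p, q in same_pc_pairs
    )

    rng = np.random.default_rng(seed)
    pool_arr = np.array(sorted(proteins))
    n = pool_arr.size
    counts = np.empty(reps, dtype=np.int64)
    for rep in range(reps):
        # distinct indices within a pair: shift the second past the first
        i = rng.integers(0, n, size=n_draw)
        j = rng.integers(0, n - 1, size=n_draw)
        j = j + (j >= i)
        counts[rep] = sum(
            _same_ps_different_diseases(pool_arr[a], pool_arr[b], ps_diseases_of)
            for a, b in zip(i, j)
        )
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if reps > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else math.nan
    return NullResult(
        kind="pairwise", observed=observed, null_counts=counts,
        null_mean=mean, null_sd=sd, z=z,
        ratio=(observed / mean) if mean > 0 else None,
        config={"reps": reps, "seed": seed, "n_pairs_per_rep": n_draw,
                "pool_size": int(pool_arr.size)},
    )


def write_null_result(result: NullResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")
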