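"""Group-complex intersections and their Jaccard coefficients.

For each disease or phenotypic-series protein group and each complex, the
overlap is kept when at least two proteins are shared — the minimal
footprint of locus heterogeneity acting through one complex. The Jaccard
coefficient JC = |A ∩ B| / |A ∪ B| quantifies the overlap (0 disjoint,
1 identical); when a group hits several complexes, summaries use the
per-group maximum (JC_MAX).
"""
from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .complex_catalog import ComplexCatalog
from .types import IntersectionRecord, ProteinGroup, TripleTuple

#: right-closed histogram bins of width 0.1 over (0, 1]
JC_BIN_EDGES = [round(0.1 * i, 1) for i in range(11)]


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|a ∩ b| / |a ∪ b|; symmetric, in [0, 1]; undefined for two empty sets."""
    if not a and not b:
        raise ValueError("Jaccard coefficient undefined for two empty sets")
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def iter_triples(
    groups: Sequence[ProteinGroup], catalog: ComplexCatalog
) -> Iterable[TripleTuple]:
    """Materialize the (group, protein, complex) co-membership tuples."""
    for g in groups:
        for tid in sorted(catalog.complexes):
            for prot in sorted(g.proteins & catalog.complexes[tid].proteins):
                yield TripleTuple(group_id=g.group_id, entrez_id=prot, term_id=tid)


def find_intersections(
    groups: Sequence[ProteinGroup], catalog: ComplexCatalog, min_shared: int = 2
) -> list[IntersectionRecord]:
    """All (group, complex) pairs sharing >= ``min_shared`` proteins.

    Equivalent to self-joining the 3-tuples of :func:`iter_triples` on
    (group, complex) and keeping pairs with two distinct proteins, but runs
    through an inverted protein -> complex index.
    """
    pc_of: dict[str, list[str]] = defaultdict(list)
    for tid in sorted(catalog.complexes):
        for prot in catalog.complexes[tid].proteins:
            pc_of[prot].append(tid)
    records: list[IntersectionRecord] = []
    for g in groups:
        counts: dict[str, int] = defaultdict(int)
        for prot in g.proteins:
            for tid in pc_of.get(prot, ()):
                counts[tid] += 1
        for tid in sorted(t for t, c in counts.items() if c >= min_shared):
            pc = catalog.complexes[tid]
            shared = frozenset(g.proteins & pc.proteins)
            records.append(
                IntersectionRecord(
                    group_id=g.group_id,
                    term_id=tid,
                    shared=shared,
                    jc=jaccard(g.proteins, pc.proteins),
                    group_size=g.size,
                    pc_size=pc.size,
                )
            )
    return records


@dataclass
class SummaryStats:
    n_groups: int = 0
    n_pcs: int = 0
    n_groups_hit: int = 0
    n_pcs_hit: int = 0
    pct_groups_hit: float = 0.0
    pct_pcs_hit: float = 0.0
    mean_jc: float = math.nan
    sd_jc: float = math.nan
    median_jc: float = math.nan
    jc_histogram: dict[str, int] = field(default_factory=dict)
    jc_max_per_group: dict[str, IntersectionRecord] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("n_groups", "n_pcs", "n_groups_hit", "n_pcs_hit",
                      "pct_groups_hit", "pct_pcs_hit", "mean_jc", "sd_jc", "median_jc")
        }
        d["jc_histogram"] = self.jc_histogram
        d["jc_max_per_group"] = {
            g: round(r.jc, 3) for g, r in sorted(self.jc_max_per_group.items())
        }
        return d


def jc_histogram(values: Iterable[float]) -> dict[str, int]:
    """Counts per right-closed bin of width 0.1 over (0, 1]."""
    bins = {
        f"({JC_BIN_EDGES[i]:.1f},{JC_BIN_EDGES[i + 1]:.1f}]": 0 for i in range(10)
    }
    for v in values:
        # right-closed: ceil(v * 10) gives the 1-based bin; JC > 0 always here
        idx = min(max(int(math.ceil(v * 10 - 1e-12)), 1), 10) - 1
        bins[f"({JC_BIN_EDGES[idx]:.1f},{JC_BIN_EDGES[idx + 1]:.1f}]"] += 1
    return bins


def summarize(
    records: Sequence[IntersectionRecord],
    groups: Sequence[ProteinGroup],
    catalog: ComplexCatalog,
) -> SummaryStats:
    """Headline hit rates and JC moments.

    Percentages run over all eligible groups and all kept complexes; the
    histogram runs over per-group JC_MAX values (ties broken toward the
    smallest complex id for the reported record); mean/SD/median run over
    all intersection records (SD is the sample SD).
    """
    stats = SummaryStats(n_groups=len(groups), n_pcs=catalog.n_kept)
    if not records:
        stats.mean_jc = stats.sd_jc = stats.median_jc = 0.0
        stats.jc_histogram = jc_histogram([])
        return stats
    best: dict[str, IntersectionRecord] = {}
    for rec in records:
        cur = best.get(rec.group_id)
        if cur is None or rec.jc > cur.jc or (rec.jc == cur.jc and rec.term_id < cur.term_id):
            best[rec.group_id] = rec
    jcs = np.array([r.jc for r in records])
    stats.n_groups_hit = len(best)
    stats.n_pcs_hit = len({r.term_id for r in records})
    stats.pct_groups_hit = 100.0 * stats.n_groups_hit / stats.n_groups if stats.n_groups else 0.0
    stats.pct_pcs_hit = 100.0 * stats.n_pcs_hit / stats.n_pcs if stats.n_pcs else 0.0
    stats.mean_jc = float(jcs.mean())
    stats.sd_jc = float(jcs.std(ddof=1)) if len(jcs) > 1 else 0.0
    stats.median_jc = float(np.median(jcs))
    stats.jc_histogram = jc_histogram(r.jc for r in best.values())
    stats.jc_max_per_group = best
    return stats


def write_intersections(records: Sequence[IntersectionRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tterm_id\tn_shared\tshared\tjc\tgroup_size\tpc_size\n")
        for r in sorted(records, key=lambda r: (r.group_id, r.term_id)):
            fh.write(
                f"{r.group_id}\t{r.term_id}\t{len(r.shared)}\t"
                f"{';'.join(sorted(r.shared))}\t{r.jc:.3f}\t{r.group_size}\t{r.pc_size}\n"
            )


def write_summary(stats: SummaryStats, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(stats.to_dict(), fh, indent=2)
        fh.write("\n")
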