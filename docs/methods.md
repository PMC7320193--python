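# Methods

## The question and the model

Locus heterogeneity (LH) is the observation that mutations in different
genes produce clinically similar or identical diseases. `lhpc` quantifies
one mechanistic explanation: that the proteins encoded by LH genes are
members of the same protein complex, so the different mutations are
alternative ways of disabling one molecular machine.

The analysis is purely set-theoretic. Two families of protein sets are
built:

* **disease-side groups** — either all proteins annotated to one disease
  identifier (disease-based LH) or the union of proteins over the diseases
  of one phenotypic series (PS-based LH);
* **complex-side groups** — the gene products directly annotated to each
  ontology cellular-component term whose name contains "complex".

A group and a complex *intersect* when they share at least two proteins —
the minimal footprint of LH acting through one complex (one shared protein
is just a disease gene that happens to sit in a complex). Overlap strength
is the Jaccard coefficient

    JC = |A ∩ B| / |A ∪ B|,

0 for disjoint sets, 1 for identity. When a group intersects several
complexes, summaries use its maximum (JC_MAX). The per-record mean, sample
SD and median are also reported, with a width-0.1, right-closed histogram
over (0, 1].

Several printed statements describe the union loosely as the *sum* of the
two sets' sizes; only the standard union (sum minus intersection)
reproduces the worked coefficients (4 shared of 4 vs 12 → 0.33; 5 shared of
12 vs 14 → 0.238; 5 of 12 vs 88 → 0.053; 3 of 3 vs 88 → 0.034), so the
standard form is used throughout.

## Disease definition (filtering)

Morbid-map rows pass five filters, in a fixed order so that discard-reason
counts are reproducible (a row failing several rules is counted under the
first):

1. marker labels dropped — leading `?` (unconfirmed), `[ ]` (non-disease),
   `{ }` (susceptibility to multifactorial disease);
2. mapping keys 1, 2 and 4 dropped; only key 3 (molecular basis known)
   survives, which is what "known molecular basis" means here;
3. phenotypes without their own identifier dropped;
4. gene entries that are moved, removed, or not mapped to an Entrez-style
   identifier dropped;
5. non-protein-coding genes dropped.

Protein identity everywhere is the Entrez-style gene identifier; symbols
are display-only. Surviving (disease, protein) pairs are deduplicated.
Disease-based LH groups are diseases with ≥ 2 distinct proteins. PS groups
require ≥ 2 member diseases that each retained a pair; a PS whose diseases
collapse onto a single shared protein remains a valid series but is flagged
degenerate — it stays in the denominators yet can never intersect anything.
A disease belonging to several series contributes its proteins to each.

## Complex selection and pruning

Complex terms are non-obsolete cellular-component terms whose name contains
"complex" (case-insensitive, anywhere in the name — ontology names are
lower-case, but robustness costs nothing). Members are **direct**
annotations only; nothing is propagated up `is_a`/`part_of`, because
propagation would make every parent the union of its children and the
parent-removal step below vacuous. Terms are classified within the selected
set as non-parent, parent, or parent-of-parent (a term with a selected
child that itself has a selected child — depth 2, not transitive closure).

Pruning removes, in order:

1. parents of parents — *unless* all their direct selected children carry
   zero direct annotations, in which case removing the term would lose its
   own annotation information. (The source rule is phrased for a single
   child; with several children this all-devoid reading is the one under
   which removal never destroys information.)
2. the three generic umbrella terms (protein complex, transcription factor
   complex, macromolecular complex), by identifier;
3. complexes left with ≤ 1 member.

Removal reasons partition the removed set; selected = kept + removed, and
re-running the pruning on its own output removes nothing further.

## Permutation controls

Four controls ask whether the observed intersection counts exceed chance;
all are simulation-based (no analytic p-values), each with its own seeded
generator, reporting observed, null mean ± sample SD (n − 1 denominator)
and Z = (observed − mean)/SD (undefined, reported as null, when SD = 0).

* **pseudo-PS** — disease proteins redistributed into groups matching the
  real size multiset, scored against the real complexes for the number of
  groups sharing ≥ 2 proteins with some complex;
* **pseudo-PC** — the complexes' proteins redistributed into complexes of
  the real sizes, scored against the real groups;
* **non-LH** — pseudo-groups drawn from the disease proteins that belong
  to no LH group;
* **pairwise** — among unordered pairs of disease proteins co-resident in
  ≥ 1 complex, the number whose members cause two *different* diseases of
  one series, compared with the same number of uniformly drawn
  distinct-protein pairs per replicate; also reported as the enrichment
  ratio observed/null-mean.

Pseudo-groups are independent uniform subsets (without replacement within a
group, independent across groups). A partition is impossible — the real
group sizes sum to more than the number of distinct disease proteins — and
the independent-subset scheme is the minimal one preserving sizes. The
default is 100,000 replicates; tests and the bundled worlds use 200–1,000,
which already pin the null mean to a few percent at these problem sizes.

## Mouse-ortholog augmentation

A complex member never reported as a human disease protein is promoted to a
*presumptive* disease protein when its mouse ortholog carries a phenotype
term that, translated through the MP→HP best-match table, exactly matches a
clinical phenotype term of **any** disease of the series (no
ontology-ancestor expansion; exact term identity after translation). The
augmented coefficient keeps the original series size and enlarges only the
intersection:

    JC' = (i + m) / (|PS| + |PC| − (i + m)),

i the original shared count, m the presumptive count. This is the only
reading of "added to the intersection" that reproduces the printed 0.33 →
0.60 example (recomputing a set union would give 0.50). It follows that
JC' ≥ JC with equality iff m = 0, and pairs whose base overlap was below
two shared proteins can cross the threshold once i + m ≥ 2, which is how
augmentation raises the number of intersecting series. Two annotation
tables complete the picture: gain-of-function disease proteins outside the
complex (an input flag table — mining mutation mechanisms from free text is
out of scope), and complexes containing members whose mouse knockout dies
before birth (embryonic/fetal/prenatal).

## Univocity

For a series intersecting several complexes, each complex pair is discarded
with the first matching reason: **parent_child** (transitive
`is_a`/`part_of` closure over all selected complex terms, including ones
pruned from the analysis set, since the linking parent may itself have been
pruned), then **common_parent** (a shared *direct* parent, excluding the
three generic terms — every complex descends transitively from the
umbrella terms, so a transitive reading would discard everything; the
motivating examples are direct children of one parent), then
**majority_shared** (shared proteins strictly exceeding half the *smaller*
complex's membership — the reading consistent with the full-enclosure
example, and symmetric). A series is **univocal** when the discarded pairs
merge its complexes into a single connected component, i.e. its apparent
multi-complex footprint is one biochemical entity; univocal + non-univocal
counts cover exactly the series with ≥ 1 intersection. For a complex
intersecting several series, a series pair is discarded as
**allele_heterogeneity** when the two series annotate a common protein.
A bipartite edge list (group, complex, JC, kept/discarded, reason) is
exported with a configurable JC floor (default 0.1).

## The synthetic-data generator

Real inputs (OMIM, Gene Ontology, MGI snapshots) are versioned, licensed
and too large to ship; the generator emits structurally faithful worlds in
the same dialects, with a truth manifest listing every planted fact.

* **Planted overlaps** use dedicated identifiers that background structure
  never touches, so the planted shared sets, presumptive sets and
  coefficients are exact. Defaults plant the four canonical configurations
  (4, 12, 4, 2), (12, 14, 5, 0), (12, 88, 5, 0), (3, 88, 3, 0).
* **Structural plants** exercise every pruning and redundancy rule:
  a parent-of-parent chain (removed), a parent-of-parent with annotation-free
  children (retained), a singleton complex, the three generic terms, a
  parent–child intersecting pair, a common-parent pair under a pruned
  parent, a majority-shared pair, a disjoint kept trio, an
  allele-heterogeneity series pair, a disjoint kept series pair, an
  all-gain-of-function series intersecting nothing, and a pre-birth-lethal
  complex member. Decoy morbid rows exercise every discard reason.
* **Background** series and complexes draw proteins uniformly from a
  background gene pool (default 800 genes, 25 series, 40 complexes, 10%
  non-coding, 5% susceptibility-marked rows, 10% gain-of-function and
  lethality rates). Series protein counts follow a discrete log-normal with
  mean 6.6 and SD 8.1, complex sizes a discrete log-normal with median 13
  clipped to 2–116 — the published per-series and per-complex moments.
  With no planted overlaps the world carries no group–complex association
  beyond chance, which is what the null calibration checks measure.

What the generator does **not** emulate: correlated gene membership across
complexes, realistic ontology depth, annotation noise, or any biological
plausibility of which proteins co-occur. Passing tests therefore
demonstrate algorithmic correctness on structurally faithful inputs, not
that the published snapshot counts would be reproduced from live databases
(those are version-dependent by nature).

Susceptibility marking applies to background rows only, so planted facts
are deterministic; a fully susceptibility-marked world (fraction 1.0) is
only accepted with all plants disabled, since no planted row could survive
it. Infeasible planted specifications fail before any file is written, and
a fixed configuration (seed included) always yields a byte-identical
bundle.

## Numerical and design notes

* Coefficients are stored at full precision; reports round to 3 decimals.
* JC_MAX ties break toward the smallest complex identifier for
  deterministic reports; tied records are all still emitted.
* Sampling uses `numpy.random.default_rng`; pools are sorted before
  drawing so results depend only on content and seed, not set order.
* Empty record sets summarize to zeros rather than NaNs; a zero-SD null
  reports its Z as undefined rather than infinite.
* Problem sizes in the test suite (worlds of ~800 genes, ≤ 70 series,
  ≤ 70 complexes; 200–1,000 null replicates; 20 calibration worlds) were
  chosen so the whole suite runs in well under a minute of compute per
  module while leaving the null means determined to a few percent.
* The strong-association positive-control world plants 44 series inside
  complexes (most of the world's series): at desk scale the
  entities-hit count saturates quickly, so an unambiguous positive control
  needs most groups planted; mildly planted worlds (a dozen series) sit
  near Z ≈ 8–10, which is expected detection behaviour, not a defect.

## Known limitations

* Direct-annotation membership understates complexes whose curation
  annotates leaf terms only; the no-propagation choice is deliberate (see
  above) but means parent complexes can look sparse.
* The common-parent rule uses direct parents; two complexes linked only
  through a grandparent are not merged unless the parent-child or
  majority-shared rules catch them.
* The pairwise control draws null pairs with replacement across replicates;
  at the default replicate counts the repeated-pair probability is
  negligible.
* Gain-of-function status is consumed, never inferred.
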