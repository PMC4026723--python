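# Methods

## The model

A human CpG dinucleotide observed on a methylation array either arose on
some branch of the lineage leading to humans or predates the sampled
phylogeny. We treat CpG presence as a binary character (1 = the focal
two alignment columns read `CG`, 0 = ungapped non-CG) at the tips of a
fixed rooted tree of 12 amniotes: chicken (outgroup), platypus, opossum,
Laurasiatheria (cow, (horse, dog)), rodents (mouse, rat), macaque,
orangutan, chimpanzee and human. The internal topology of
Laurasiatheria is not resolvable from the branch model and is fixed to
(cow,(horse,dog)); since the three taxa form a single clade sister to
Euarchontoglires, human-descent origin assignment is insensitive to this
choice.

The path from the root to the human tip is partitioned into eight stem
lineages with fixed divergence-time calibration (Mya): 324.5, 217.8,
190.0, 92.0, 83.3, 25.4, 18.0, 7.2, 0. The resulting durations are
mammal 106.7, Theria 27.8, placental 98.0, Euarchontoglires 8.7, primate
57.9, ape 7.4, human/chimpanzee 10.8 and human terminal 7.2 Myr; the
segments tile the interval exactly, so each moment of human descent
belongs to one stem. The human/macaque age is taken as 25.4 Mya, which
is the value consistent with both adjacent stem durations (7.4 =
25.4 − 18.0 and 57.9 = 83.3 − 25.4). The human terminal "branch" runs
to the present (age 0).

## Presence calling and the concordance filter

Each site is represented by a 122-column window: 60 flank columns, the
CpG at columns 61–62, 60 flank columns. Calling reads only the focal
columns; soft-masked lowercase bases count as their nucleotide, and a
gap or `N` in either focal column (or a missing row) gives state
`missing`. Windows come from two alignment sources; in the only
supported mode (`strict`) a site survives when both sources assign an
identical state to every taxon and no taxon is missing. Every dropped
site carries exactly one reason code (`single-source`, `missing-data`,
`discordant`, with missing data taking precedence over discordance
because a missing taxon makes agreement untestable), and the drop log is
exhaustive: retained + dropped = input at every stage boundary. Missing
data is excluded rather than propagated into parsimony as `{0,1}`; the
downstream analyses require unambiguous ancestral states, and missing
tips create ambiguity by construction.

## Parsimony, ACCTRAN and the unambiguity filter

A standard Fitch downpass yields the minimum change count `s`. Among
the most-parsimonious reconstructions (MPRs) we resolve by accelerated
transformation: changes are placed as close to the root as possible, so
derived states arise early and homoplasy appears as later reversal. We
formalise this as an exact dynamic programme that, among assignments
attaining `s` changes, maximises the total weight of change-bearing
edges with an edge into a depth-`d` node weighing `2^(D−d)` (`D` = tree
depth). Powers of two make the objective lexicographic in depth: moving
a single change one level rootward dominates any rearrangement below
it. Remaining ties prefer the derived (presence) state. The same
programme counts MPRs exactly; an exhaustive enumeration over all
internal assignments (≤ 2^11 on this tree) serves as an independent
oracle in the tests and agrees with both the change counts and the
maximal-weight property.

Root-state ambiguity is resolved by outgroup comparison: when the
chicken tip's state is attainable at the root at minimum cost, the root
is fixed to it, and MPR uniqueness is judged among those
reconstructions. This matters for exactly one pattern class — present
in every mammal, absent in chicken — where unconstrained parsimony
cannot distinguish a gain on the mammal stem from root presence with a
chicken-edge loss. Outgroup polarisation assigns the gain to the mammal
stem, which is the standard reading and the only way mammal-stem
origins are identifiable at all with a single outgroup.

The consistency index is `CI = m/s` with `m = (observed states − 1)`,
and `CI = 1` for invariant characters by convention. Downstream
analyses use only sites with `CI = 1` **and** a unique MPR; drops are
logged as `homoplasy` or `ambiguous-mpr` separately, since the two
conditions are distinct (our reading couples them, and both flags are
reported).

## Origin assignment and cumulative presence

A retained non-invariant character carries exactly one change. If it is
a 0→1 gain on a root→human edge, the origin is the corresponding stem.
If the single change lies off the human path it must be a loss from
ancestral presence (a gain off-path would leave human CpG-absent), and
the site is classed `pre_mammal`, as are invariant-present sites.
`pre_mammal` is kept distinct rather than folded into the mammal stem:
such sites predate the human/chicken ancestor and did not evolve on any
named stem. They are therefore excluded from the eight-branch count
tables and chi-square tests, but included in cumulative presence.

Cumulative presence at the ancestor closing stem `i` is the percentage
of sites with origin on stem `i` or older (including `pre_mammal`),
stored to one decimal; the curve is non-decreasing and ends at 100% at
the present.

## Branch statistics

Rates are gains per Myr (count/duration, reported to one decimal).
Three Pearson chi-square designs are provided, all without Yates
continuity correction (an expected cell below 5 sets a warning flag but
never switches the method):

* even distribution over the eight stems (df = 7);
* flagged subset vs. background-proportional expectation (df = 7);
* all 28 pairwise stem comparisons (df = 1), with expected counts split
  evenly (`count` mode) or proportionally to stem durations (`rate`
  mode). Duration-proportional expectation is our formalisation of a
  rate comparison as a count test; the count-mode variant is also
  emitted. Raw p-values are reported (no multiplicity correction); a
  Bonferroni column is written for transparency but not used for flags.

The subset-vs-total association is summarised by OLS of per-stem subset
counts on total counts; R² = 1 − SS_res/SS_tot, defined as 0 when the
response has no variance.

## Motif scanning

A count matrix over ACGT yields per-column frequencies `f(i,b)`, the
consensus index `Ci(i) = (100/ln 4) Σ_b f(i,b) ln f(i,b) + 100`
(0 for uniform, 100 for single-base columns), and a core: the
contiguous run of four columns with maximal ΣCi (leftmost on ties).
Similarity of a W-mer is
`Σ_i Ci(i) f(i,b_i) / Σ_i Ci(i) max_b f(i,b)`; `core_sim` is the same
ratio over the core columns and is checked first (default threshold
0.75) before `mat_sim` (default threshold 0.80, strict inequality).
A matrix whose columns are all uniform has a zero denominator and
scores 0. Both strands are scanned; minus-strand hits are mapped to
plus-strand window coordinates, and hits sharing (matrix, interval) are
deduplicated keeping the higher-scoring strand, plus strand on ties. A
hit overlaps the CpG iff its interval covers column 61 or 62; only
overlapping hits enter the stringency tiers (>0.80, >0.90, >0.95, =1,
the last with tolerance 1e-9 to absorb floating error). Matrices are
user-supplied in a minimal TRANSFAC-like count format (`ID`/`NA`/`P0`
rows); no proprietary matrix library is bundled, so absolute hit totals
depend entirely on the matrices provided — the summarisation logic, not
any particular total, is the product surface.

## Enrichment

Branch-wise enrichment uses a defined, reproducible statistic: for each
term, the one-sided hypergeometric upper tail of the overlap between a
stem's proximal-gene set and the term's genes, within the universe of
genes proximal to all retained sites, with Benjamini–Hochberg FDR across
terms within a branch. Annotation-cluster approaches that depend on a
private knowledge base and fuzzy clustering are deliberately out of
scope; annotations are taken as given, with no term-hierarchy
propagation.

## The simulator

`simulate_sites` draws each site's origin with probability proportional
to gain intensity × stem duration (plus a `pre_mammal` weight), builds a
random 122-bp human window with `CG` at 61–62, sets every descendant of
the gain point CpG-present, and writes deamination-style losses (CG→TG)
into individual non-human taxa with a per-taxon probability. Flank
columns mutate independently per taxon (default 0.05 per column) and
never touch the focal columns, so the focal character stays well
defined; a human-lineage loss is never simulated, since array sites are
human CpGs by definition. The second alignment source is identical
except that, with the configured discordance probability, one random
non-human taxon's focal state is flipped. All randomness flows through
one seeded generator, so identical configurations give byte-identical
outputs.

Default origin weights (pre_mammal 0.02; mammal 0.015; Theria 0.01;
placental 0.015; Euarchontoglires 0.01; primate 0.41; ape 0.25;
human/chimpanzee 0.20; human terminal 0.07) reproduce the reported
cumulative presence profile of trauma-associated array CpGs — 7% before
the human/rodent ancestor, 48% before human/macaque, 73% before
human/orangutan, 93% before human/chimpanzee — with loss and discordance
off by default and a flagged-subset fraction of 0.3.

What the simulator does **not** emulate: realistic substitution models
(no HKY/GTR, no rate heterogeneity), indels and alignment error beyond
the single-taxon discordance flip, linked sites, CpG-island structure,
and biased gene–site assignment. Passing the recovery tests therefore
shows that the inference chain is internally correct under the stated
generative model, not that real alignments are this clean; on real data
the concordance and unambiguity filters are expected to remove a large
fraction of sites.

## Problem sizes and numerical choices

The test suite validates parsimony against exhaustive enumeration on
1000 random trees of up to 8 tips and on every two-state tip pattern of
the 12-taxon tree (4094 patterns against a vectorised brute-force
oracle). Parameter recovery uses 500 sites for the exact-recovery check
and 5000 sites for frequency calibration, judged against binomial 99%
intervals. The end-to-end demonstration runs at 500 sites. Hypergeometric
p-values are checked against direct combinatorial summation for
universes up to 25 genes at 1e-12; chi-squares against an independent
reference implementation at 1e-9.

Degenerate inputs are contracts, not silent fallbacks: empty selections,
zero-duration stems, all-zero count vectors, zero-variance regressors,
non-monotonic calibrations and oversized enumeration requests all raise
typed errors. Output tables carry the run seed and a configuration hash
in a header comment, and the drop log accounts for every input site.

## Known limitations

* A single outgroup makes mammal-stem gains identifiable only via the
  polarisation convention described above; a basal loss on the entire
  mammal clade is indistinguishable from that gain pattern.
* Gains cannot be dated within a stem, and CpG loss dynamics are
  handled only through the homoplasy filter, not modelled.
* With one outgroup and strict filters, sites with any missing taxon are
  discarded wholesale; there is no partial-information mode.
* The eight-branch model is fixed; trees whose root→human path does not
  have exactly eight edges are rejected rather than re-segmented.
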