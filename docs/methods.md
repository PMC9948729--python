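# Methods

## Scope and data model

`pingovir` implements the computational core of a paired starter/cheese
virome study: viral contig triage, vOTU dereplication, breadth-masked
abundance quantification, community ecology, and phage–host linking.
Upstream steps that require raw reads or external databases — read QC,
assembly, read mapping, HMM searches, taxonomy — are out of scope;
their outputs enter as inputs (evidence tables, per-base depth
profiles, count matrices).

All coordinates are 0-based half-open on the forward strand. Sequences
are restricted to A/C/G/T/N (U is converted to T at read time; other
ambiguity codes are rejected); N never counts as a match anywhere.

## Triage

A contig is included in the viral catalog when at least one of four
criteria holds (detector flag, qualifying reference alignment, ≥3
viral-orthologous-group ORF hits, circularity). Decisions are
monotone: adding evidence can only add criteria. An rRNA signal is
recorded but never used for exclusion — it is a computed signal, not
an inclusion criterion, and excluding on it would silently discard
phages carried inside cellular fractions.

*ORF calling* is a deterministic six-frame maximal-ORF scan (starts
ATG/GTG/TTG, first in-frame stop, longest ORF per stop). Triage only
consumes ORF counts as hit denominators, so a trained gene model would
add a statistical dependency without changing any decision.

*Circularity* is an exact terminal direct repeat of ≥ `tr_min_len`
(default 20) nt, found in linear time via the KMP border chain and
capped at half the sequence. Exact matching makes the contract
testable; assembled terminal repeats are exact by construction. A
random sequence carries a ≥20 nt border with probability ~4⁻²⁰ per
boundary, so false circularity calls are effectively impossible.

*Redundancy removal* drops contigs under 1,000 nt, then visits the
rest longest-first and discards any contig that a retained longer
contig covers at ≥90% identity over ≥90% of the shorter length. Ties
in length break by id; the operation is idempotent.

## vOTU dereplication

Pairwise similarity is summarized as ANI (percent identity over
aligned columns) and AF (percent of the shorter sequence covered by
aligned columns). AF denominates on the shorter sequence so a contained
fragment merges into its parent instead of founding a spurious OTU.

The ANI engine indexes 15-mers, merges per-diagonal runs into maximal
exact anchors, chains anchors greedily (longest first, collinear and
non-overlapping on both sequences), and closes inter-anchor and
terminal gaps of ≤200 nt by exact global alignment (match +1, mismatch
−1, gap −2). Longer gaps break the chain and stay unaligned — that is
what keeps the AF of a contained fragment at 100 while preventing
non-homologous tails from being dragged into the alignment. Full
quadratic DP is reserved for the short gap windows; on sequences ≤2 kb
the chained estimate stays within ~0.7 percentage points of full-DP
identity in the worst observed case (tested bound: 2 points, checked
against an edlib oracle in the suite).

Clustering is greedy longest-first centroid clustering: each contig
joins the first cluster whose representative it matches at ANI ≥ 95
and AF > 85, else founds a cluster. This is the standard dereplication
semantics, deterministic, and makes the chain case (C matches B but
not A) well-defined: C founds its own cluster. The 85% boundary is
strict-greater; the threshold sharpness (84.9 never merges, 85.1 with
ANI ≥ 95 always merges) is asserted in tests. Merging two namespaced
catalogs reports `n_merges = n_vlp + n_mg − n_clusters`, the
bookkeeping identity that lets a reader audit cross-catalog collapses.

## Quantification

Breadth is the exact fraction of contig positions at depth ≥ 1×,
computed from run-length-encoded depth intervals. A count is zeroed
when breadth < 0.75. The sentence defining this filter can be read in
two directions; the default requires ≥75% of the contig covered, the
stricter and more common viromics convention. The opposite reading
(zero only when <25% covered) sits behind
`breadth_rule_inverted`.

Masking precedes normalization, since the filter applies to read
counts. Size factors are median-of-ratios: geometric means over
features positive in all samples; when no such feature exists the
geometric means fall back to positive entries only and a warning is
raised. Normalized values are not re-rounded. Zeros are preserved, so
every masked (contig, sample) pair stays exactly zero downstream.

## Ecology

Shannon diversity defaults to log base 2 (bits); Simpson is reported
in Gini–Simpson form 1 − Σp², the only form consistent with index
values like 0.94/0.78/0.39 on real tables. Jensen–Shannon divergence
(not its square root) is the default ordination input; JSD is not a
metric, so when negative PCoA inertia exceeds 5% of positive a warning
suggests the metric √JSD switch (`jsd_sqrt`). PCoA is classical
scaling with negative axes dropped (no Cailliez correction) and signs
fixed so each axis's first nonzero loading is positive.

PROTEST centers and unit-scales both configurations, truncates to
common rank, and takes m² = 1 − (Σσ)² from the SVD of X'Y;
correlation = √(1 − m²). The p-value uses the add-one estimator over
row permutations of the second configuration, counting strict
exceedances only: a permutation that reproduces the observed labelling
(the identity is drawn with probability 1/n!, non-negligible at n = 7)
ties the observed statistic and is already represented by the add-one
term. With ≥ counting, a perfectly concordant pair could not reach the
floor p = 1/(n_perm+1). Default 999 permutations; p-values below
10⁻³ require raising `n_permutations` (e.g. 1,999 for a floor of
5×10⁻⁴).

The within- vs between-group distance comparison is a two-sided
Mann–Whitney rank-sum test, enumerated exactly (ties via average
ranks) when the pooled size is ≤12 and normal-approximated with tie
correction otherwise.

## Host linking

*CRISPR detection.* Arrays are found by seeded tandem-repeat scanning:
≥3 exact occurrences of a 16-mer whose successive start gaps lie in
[41, 103] nt (repeat 21–48 + spacer 20–55), extended to the maximal
identical repeat across all occurrences. Spacers must be mutually
distinct — identical "spacers" indicate a satellite repeat, not a
CRISPR array. All candidate arrays are enumerated first and overlaps
resolved in favor of more repeats (ties leftmost): a seed starting one
base before a repeat can otherwise form a shorter sub-run that claims
the region and truncates the true array. With exact-repeat semantics
the false-positive rate on random 100-kb genomes is zero (the expected
number of 16-mer triples is ~10⁻⁵ per genome before the gap
constraint). A mismatch-tolerant modal-consensus extension is
available via `crispr_repeat_identity_min` but off by default.

*Spacer matching* is ungapped (protospacers rarely gap, and it keeps
identity = matches/columns and coverage semantics exact), on both
strands, best hit per (spacer, target), reported when identity > 90%
over ≥80% of the spacer. On a 32-nt spacer this passes 2 mismatches
(93.75%) and rejects 4 (87.5%).

*Markov host models.* Order-k transition probabilities (default k = 3)
with add-one smoothing, trained on both strands. Order 3 rather than a
higher order because desk-scale genomes (tens of kb) cannot populate
4⁸ contexts; the order is configurable to 8 for real bacterial
genomes. The null is the per-nucleotide log-likelihood of decoy phage
genomes under the host model, summarized as a Gaussian (μ, σ); a
query's p-value is the upper tail. In the synthetic setting the decoy
set is generated alongside the community; in a real analysis any
phage collection known not to infect the candidate hosts serves.

*Network.* For each (phage, host) pair, abundances are paired across
producers either within a stage (`same_stage`) or as starter-phage
versus cheese-host (`starter_vs_cheese`, the default: phages in the
starter are expected to depress their host during production). Both
modes exist because the two pairings answer slightly different
questions and real studies report both. Correlation evidence requires
Spearman ρ ≤ −0.8 and p ≤ 0.05 with p computed exactly (all n!
permutations, cached per rank multiset) for n ≤ 8. Exactness matters
at this scale: at n = 7 the t-approximation gives p = 0.014 for
ρ = −0.857 where the exact value is 0.024, and the exact per-pair null
probability of passing the double threshold is 86/5040 ≈ 0.017.
Spacer hits and top-ranked significant Markov predictions attach as
independent evidence; an edge needs at least one evidence type.
Constant abundance vectors leave ρ undefined and the pair is excluded
from correlation evidence.

## Synthetic community generator

The generator emulates the study design the pipeline targets: 7
producers × 2 stages, a phage catalog (default 5–60 kb, 20% circular
via planted 40-nt terminal repeats, 10% temperate via an "integrase"
annotation), non-viral decoy contigs failing all triage criteria, host
genomes with 0–5 planted CRISPR arrays whose spacers are copied from
catalog phages (per-base substitution rate configurable; provenance
recorded), and a ground-truth ledger from which every planted artifact
is recoverable.

Predation is modeled as rank-based multiplicative attenuation rather
than a dynamical model: for a planted edge (v, h, β), the host's
log-normal baseline in producer p is multiplied by
exp(−β · rank_norm(V_vp)), where rank_norm scales the phage's
abundance rank across producers to [0, 1]. The pipeline's claim is
detection of monotone negative association, so the generator plants
exactly that and nothing stronger; β = 0 yields exact independence and
a calibrated null. Phage abundance is drawn once per (phage, producer)
and shared by both stages — the cheese inherits its starter's phage
load — while host baselines are redrawn per stage. Counts are scaled
to a library size of 10⁵ per sample and floored, large enough that the
breadth rule rather than sampling noise dominates masking tests.

Depth profiles cover non-dropout positive counts at ≥1× over ≥90% of
positions; planted dropout pairs get a covered fraction uniform in
[0.30, 0.70], guaranteed below the 0.75 threshold. Array flanks are
adjusted so the planted repeat is exactly maximal (no accidental
one-base extension), keeping detector recovery exact.

What the generator does not emulate: read-level noise, sequencing
error, GC bias, strain microdiversity, repeat-degenerate CRISPR
arrays, and real genome composition (backbones are i.i.d. uniform).
Passing tests therefore demonstrate correctness of the inference
machinery under the stated model, not robustness to real-data
artifacts such as conserved-region cross-mapping or mosaic phage
genomes.

## Study conditions used by tests and acceptance

Fixed once, as the package's own experimental design:

* Triage exactness: 50 phages, 20 decoys (decoy fraction 0.4), 2
  planted false negatives chosen among non-circular phages
  (circularity is intrinsic and cannot be suppressed by evidence).
* ANI oracle: 200 pairs of 0.3–2 kb at 0–10% substitution divergence
  plus 1% indels, compared against edlib full-DP identity.
* Network recovery: 15 phages × 16 hosts with 6 planted couplings
  (the scale of a complete/high-quality phage set against a refined
  MAG set, with a handful of true interactions), β = 8, σ = 0.2,
  7 producers; recovery target ≥80% of planted edges. The β = 0 null
  runs at 6 phages × 4 hosts over a few hundred seeds against the
  exact 86/5040 per-pair expectation.
* Markov prediction: hosts of 50 kb, query phages of 20 kb sampled
  from the true host's order-2 model, 5 random decoys, 50 seeds,
  top-1 accuracy target ≥95%.

These sizes keep the full suite under ~2 minutes on one CPU while
leaving every statistical target comfortably inside its Monte-Carlo
tolerance.

## Numerical and degenerate-input choices

* Unknown config keys are errors, not warnings; all thresholds are
  bounds-checked at load time.
* Matrix TSVs round-trip to 12 significant digits; non-finite entries
  require an explicit NA flag.
* PCoA keeps eigenvalues > 10⁻¹⁰; Procrustes correlation is clamped to
  ≤1 against floating-point overshoot.
* An all-zero sample is an error in diversity and normalization (it
  has no composition to speak of); an all-zero feature is fine.
* Dedupe and clustering tie-breaks are length-descending, then id
  ascending, everywhere, making every pipeline output byte-stable for
  a fixed seed.

## Known limitations

* The chained ANI engine's 2-point contract is validated up to ~10%
  divergence; beyond ~15% anchors become sparse and AF degrades before
  ANI does. Dereplication thresholds (90/95%) sit well inside the
  validated regime.
* The CRISPR detector requires exact repeat copies by default and at
  least three of them; degenerate-repeat arrays in real genomes need
  the tolerant mode, which has no exactness guarantee.
* Markov host prediction discriminates composition, not infection;
  on real data it should be treated as supporting evidence only, which
  is how the network stage uses it.
* The Gaussian decoy null is a convenience; with few decoys σ is
  poorly estimated (a minimum of ~20 decoys is sensible in practice).
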