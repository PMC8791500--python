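# Methods

## Distances

Distances are Kimura two-parameter (K2P) estimates,
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`, with `P` and `Q` the transition
and transversion proportions over the sites compared for that pair.
Comparison uses **pairwise deletion**: any site where either sequence
carries a gap or *any* IUPAC ambiguity code is dropped for that pair only.
Ambiguity codes are never partially matched (an `R` is not counted as a
half-match to `A`): full exclusion is deterministic and avoids fractional
counts. When a log argument is non-positive (saturation) or no sites
overlap, the pair is *undefined*: stored as NaN, listed in
`DistanceMatrix.undefined_pairs`, excluded from every summary with a
logged count, and never silently zeroed.

Standard errors are site bootstraps: alignment columns are resampled with
replacement (same length), the matrix is rebuilt per replicate (as column
weights in the indicator-matrix products, so replicates cost one matrix
build each), and the SE is the standard deviation of the statistic across
replicates. A statistic undefined in more than half the replicates is
itself reported undefined. The pipeline caps summary-table SEs at 200
replicates — the Monte-Carlo error of an SE stabilises well below that —
while tree supports use the configured replicate count (default 1000).

Survey-wide aggregates are reported under **two averaging conventions**,
because published tables rarely state which they use: `unweighted` (mean
of per-group means over groups with ≥ 2 members; the default) and
`pooled` (mean over all within-group pairs). Both appear in
`summary_statistics.tsv` so either convention can be matched.

## Species identification

The decision rules operate on per-genus distance matrices, each truncated
to that genus' maximal left-anchored common window (barcode fragments are
5'-anchored, so trimming removes trailing positions only; sequences are
assumed pre-aligned and indel-free, as protein-coding *COI* is).

A **barcoding gap** between groups g and h exists (min/max rule) when
`min_between(g,h) > max(max_within(g), max_within(h))`, with strict
inequality — equality is not a gap — and singleton groups contributing a
within-maximum of 0, since one sequence cannot overlap itself. The
tenfold rule (`mean_between ≥ 10 × max of within means`) is provided as an
option; it is known to be harsher and is not the default.

A species S **fails** identification iff some congener T satisfies all
three of: `mean_between(S,T) < threshold` (default 0.0200, compared on the
mean, not the minimum), no barcoding gap between S and T, and S is not
*diagnosable* from T. Diagnosability operationalises the case of a tight
exclusive cluster nested inside a variable congener: every sequence of S
has its nearest non-self neighbour (strictly) inside S, and S shares no
haplotype with T. A `gap_only` mode disables diagnosability for
sensitivity analysis. The sole species of a genus is identified by
definition.

Report flags: `a` — mean within-species distance above the threshold
(candidate cryptic split); `b` — closest congener below the threshold with
no gap and no diagnosability (the actual failures; `b` implies not
identified); `c` — closest congener below the threshold but gapped
(identified). A diagnosable-but-gapless species carries neither `b` nor
`c`: it is identified, and its gap status is visible in the
`barcoding_gap` column. `b` and `c` are mutually exclusive by
construction.

**Split proposals** apply the same threshold + gap criterion to
(species, region) populations: a population pair is proposed as
potentially separate species when its mean between-population distance
exceeds the threshold and the gap test passes. Populations are the
(species, sampling region) pairs encoded in the headers; multi-river
regions are not merged.

Success summaries count a sole-member genus as exhibiting a gap (there is
no congener comparison to fail), so the "% of identified species with a
gap" statistic is defined for every survey.

## ABGD

The partitioner re-implements Automatic Barcode Gap Discovery as a
concrete, documented variant (the published description leaves the gap
statistic's windowing open; exact numerical agreement with the original
binary is a validation goal, not a guarantee):

- **Prior grid**: geometric from `pmin` (0.001) to `pmax` (0.1) inclusive,
  `steps` (10) values.
- **Gap detection**: over the ascending pairwise distances, scan the
  inter-rank intervals whose *upper* rank exceeds the prior — the prior is
  an upper bound on intraspecific divergence, so the gap must end above
  it; this also finds the gap when the prior itself falls inside the empty
  interval. The local spacing scale at rank i is the mean of the last up
  to 10 strictly positive spacings before i; the first interval wider than
  `x` (1.5) times that scale is the gap, and the returned threshold is its
  midpoint (symmetric and tie-free).
- **Clustering**: single-linkage connected components with an edge where
  `d < threshold` (strict, so samples exactly at the edge separate;
  undefined distances are treated as above threshold). Groups are
  numbered 1..k by smallest member label.
- **Recursion**: within each multi-member group, gap detection and
  clustering are re-applied on that group's distances alone until no gap
  is found; each recursive call works on a strictly smaller set or stops,
  so termination is guaranteed.
- **Consensus**: the partition produced by the longest run of consecutive
  priors; ties break toward fewer groups, then toward smaller priors. The
  headline gap distance is the top-level gap at the first prior of that
  run — which prior "the" published gap of a survey comes from is
  generally unstated, and this rule pins one down deterministically.

## Haplotypes and geography

Haplotypes are exact case-insensitive string identity over the common
window; sequences containing ambiguity codes form their own haplotypes
rather than being merged into compatible ones (no merging rule is standard,
and exact identity is conservative and deterministic). A
(species, region) population is **region-specific** when *every* haplotype
observed there occurs in no other region for that species — the strong
reading under which a matching barcode pins a specimen's origin; species
sampled in a single region are excluded as vacuous. Published counts of
region-specific populations depend on this definitional choice, so
agreement with any particular survey table is approximate by nature.

## Trees

Trees are Saitou–Nei neighbor joining on the K2P matrix. NJ is used as
the distance-native tree surface — the identification rules above draw on
distances and haplotypes, never on tree topology, so the tree choice does
not affect the verdicts. Q-criterion ties break toward the pair of
clusters containing the smallest leaf labels (deterministic under label
permutation); negative branch-length estimates are clamped to zero with
the count logged. Support is the percentage of site-bootstrap replicates
whose NJ tree contains each bipartition of the point-estimate tree (not a
majority-rule consensus, keeping one canonical output); replicates with
saturated pairs are skipped and counted. Genera with fewer than 3
sequences or a single haplotype get no tree — there is no differentiation
to draw.

## Simulator

The generator emulates a barcode survey's structure: star phylogenies with
group ancestors at `inter_div/2` from a uniform-random root and tips at
`intra_div/2` from their ancestor, so expected tip-to-tip distances are
`intra_div` within and ≈`inter_div` between groups. Each site evolves by
one draw from the exact K2P transition matrix at the target distance —
transition probability `P(d)`, each transversion `Q(d)/2`, with rates set
by the TS/TV ratio (default 2.0) — and because those matrices form a
semigroup, composing branches is exact with no repeated-hit bookkeeping.
Defaults are survey-realistic: 624-site fragments, within-species
divergence 0.003, between-species 0.06, two regions per species. A
two-level mode nests populations (with their own divergence and one region
each) inside species for split-proposal experiments; a three-level
community generator adds genera (between-genus divergence 0.16) for
pipeline-scale runs. An optional rate injects `N`s to exercise pairwise
deletion.

What the simulator does *not* emulate — coalescent genealogies, rate
variation among sites and lineages, selection, indels, uneven and sparse
sampling, introgression — is exactly what makes real surveys hard, so
passing parameter-recovery tests shows the decision rules are implemented
correctly under their own model, not that they are robust on real data.

## Problem sizes and numerics

The test suite and the acceptance script run on simulated datasets of
50–120 sequences × 624 sites with 100–200 bootstrap replicates — sizes
chosen so the whole validation executes in seconds while leaving every
code path identical to a full-survey run; the distance engine itself
builds a 1000-sequence matrix in a few seconds via indicator-matrix
products. Distance comparisons in tests use absolute tolerances of 1e−6
(closed forms) and 1e−9 (additive-tree recovery); Monte-Carlo checks use
the bands stated in each test. Degenerate inputs are defined, not
special-cased: singleton groups (within-statistics NaN, gap contribution
0), identical sequences (distance 0, always co-clustered), empty overlap
(undefined pair), and a prior grid with `pmin == pmax` (single prior).
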