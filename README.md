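# barcodegap

Distance-based species identification for DNA-barcode surveys.

Barcode surveys sequence a short standardized marker — typically ~600 bp of
the mitochondrial *COI* gene — from many specimens and ask whether nominal
species can be told apart from sequence alone. `barcodegap` implements the
full analysis such a survey needs, for researchers who have an aligned
multi-FASTA of barcodes with structured headers
(`Genus_species_region_accession`) and want reproducible, scriptable
answers rather than point-and-click runs:

- **K2P distances** with pairwise deletion and site-bootstrap standard
  errors, summarised within and between species, genera and families;
- **species identification** by the 0.02 substitutions/site threshold and
  the barcoding gap (minimum between-group distance strictly greater than
  both within-group maxima; the classical tenfold-mean rule is available),
  with per-species flags and split proposals for divergent populations;
- **Automatic Barcode Gap Discovery (ABGD)**: threshold-free partitioning
  that locates the gap in the ranked pairwise distances for each prior
  bound on intraspecific divergence and recursively clusters below it;
- **haplotype reports**: collapsing, sharing between species, and
  (species, region) populations whose haplotypes are all region-private —
  the case where a barcode also reveals geographic origin;
- **neighbor-joining trees** on the K2P matrix with site-bootstrap clade
  support, written as newick;
- a **K2P forward simulator** that generates barcode datasets with known
  species/population/region structure, so every stage can be validated
  against truth with no external data.

## The model

For a sequence pair, let *P* and *Q* be the proportions of compared sites
(both unambiguous) showing a transition (A↔G, C↔T) and a transversion.
The Kimura two-parameter distance is

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)   [substitutions/site]

undefined (and excluded, never zeroed) when a log argument is
non-positive. A species fails identification only when some congener is
simultaneously *close* (mean between-species distance < 0.02), *gapless*
(min between ≤ max within), and *non-diagnosable* (the species does not
form an exclusive nearest-neighbour cluster free of shared haplotypes).
ABGD scans the sorted pairwise distances above each prior *p* from a
geometric grid for the first inter-rank spacing wider than *x* times the
local mean spacing, clusters by single linkage below the gap midpoint, and
recurses within groups; the partition stable over the widest run of priors
is the consensus.

## Worked example

```python
from barcodegap import SimConfig, simulate_dataset, build_matrix, abgd_partition

sset, truth = simulate_dataset(SimConfig(
    n_groups=5, seqs_per_group=10, intra_div=0.003, inter_div=0.06, seed=3))
result = abgd_partition(build_matrix(sset))
```

Running `python examples/03_abgd_partitioning.py` (the same computation)
prints:

```
prior      gap        groups
0.0010    0.0024    20
0.0017    0.0024    20
0.0028    0.0024    20
0.0046    0.0040    9
0.0077    0.0073    5
0.0129    0.0272    5
0.0215    0.0272    5
0.0359    0.0272    5
0.0599    0.0594    1
0.1000      -       1

consensus: 5 groups (true: 5), stable over priors 0.0077-0.0359, barcode gap distance 0.0073
```

Tiny priors over-split the five simulated species into haplotype clusters
and huge priors merge everything, but across the middle of the grid ABGD
finds the gap between the within-species distances (~0.003) and the
between-species distances (~0.06) and recovers exactly the five true
groups; the reported gap distance 0.0073 is the midpoint of that empty
interval. The other scripts in `examples/` demonstrate distance
summaries, threshold identification, haplotype geography, bootstrap NJ
trees, and the end-to-end pipeline (`run_pipeline`, also exposed as the
`barcodegap` command-line tool).

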