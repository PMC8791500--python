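"""Neighbor-joining tree with site-bootstrap clade support.

Builds the NJ tree from K2P distances for three simulated species and
annotates every internal split with the percentage of 200 site-bootstrap
replicates that recover it.  Species-level splits should come out near
100; splits among near-identical haplotypes carry little signal and get
low support.
"""

from barcodegap import SimConfig, bootstrap_support, simulate_dataset, write_newick

sset, _ = simulate_dataset(SimConfig(
    n_groups=3, seqs_per_group=5, intra_div=0.002, inter_div=0.10, seed=8,
))
tree = bootstrap_support(sset, reps=200, seed=1)

supports = sorted(
    (n.support for n in tree.root.walk() if n.support is not None),
    reverse=True,
)
print(f"{len(sset)} leaves, {len(supports)} internal splits")
print("supports (%):", ", ".join(f"{s:.0f}" for s in supports))
print("\nnewick (support as internal-node labels):")
print(write_newick(tree))
print("\nthe three deep species splits are the ~100s; shallow haplotype "
      "splits are resampling noise.")
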