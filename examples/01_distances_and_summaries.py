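"""K2P distances and within/between-species summaries on simulated barcodes.

Simulates five species of ten barcodes each, builds the pairwise K2P
matrix with pairwise deletion, and summarises distances per species.  The
mean within-species distance should sit near the simulated 0.003 and the
mean between-species distance near 0.06 — the classic barcode separation
that makes threshold identification work.
"""

from barcodegap import SimConfig, build_matrix, simulate_dataset, summarize_groups
from barcodegap.distances import bootstrap_se, overall_mean_distance

sset, truth = simulate_dataset(SimConfig(
    n_groups=5, seqs_per_group=10, intra_div=0.003, inter_div=0.06, seed=42,
))
matrix = build_matrix(sset)
summary = summarize_groups(matrix, sset.species_grouping())

print(f"{len(sset)} sequences, {matrix.n * (matrix.n - 1) // 2} pairs, "
      f"{len(matrix.undefined_pairs)} undefined")
print(f"mean within-species distance : {summary.overall_mean_within():.4f}")
print(f"mean between-species distance: {summary.overall_mean_between():.4f}")

se = bootstrap_se(sset, overall_mean_distance, reps=200, seed=1)
print(f"overall mean distance        : {overall_mean_distance(matrix):.4f} "
      f"(site-bootstrap SE {se:.4f})")
print("within ~= the simulated 0.003 and between ~= 0.06: the gap between "
      "the two distributions is what species identification exploits.")
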