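"""Generate a synthetic paired GEX + V(D)J droplet dataset.

The simulator emulates a raw 10x matrix: live singlets, doublets (summed
transcriptomes, unioned chain sets), dead cells (low UMI, high mito) and
ambient-only droplets, with realistic dual TCR-chain frequencies.
"""

from collections import Counter

from tcrqc import SimConfig, simulate_droplets, write_simulation

config = SimConfig(seed=1)
matrix, contigs, truth = simulate_droplets(config)
write_simulation("scratch/example_sim", matrix, contigs, truth)

composition = Counter(t.label for t in truth)
print(f"droplets: {len(matrix.barcodes)}, genes: {len(matrix.feature_ids)}")
print(f"composition: {dict(composition)}")
print(f"productive contigs emitted: {len(contigs)}")

singlets = [t for t in truth if t.label == "singlet"]
dual_a = sum(t.true_n_tra == 2 for t in singlets) / len(singlets)
dual_b = sum(t.true_n_trb == 2 for t in singlets) / len(singlets)
print(f"dual TCRa fraction among live singlets: {dual_a:.3f} (expected ~0.15)")
print(f"dual TCRb fraction among live singlets: {dual_b:.3f} (expected ~0.065)")
# Files written under scratch/example_sim/ are exactly what the readers
# consume: matrix.mtx + barcodes.tsv + features.tsv and the contig CSV.
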