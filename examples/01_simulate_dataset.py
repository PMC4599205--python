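"""Simulate a two-group RNA-seq count dataset with zero-in-one-condition DE.

Builds a joint (mean, dispersion) parameter pool, draws NB counts for a
5 vs 5 design with no differential expression, then creates "true" DE genes
by zeroing one randomly chosen condition of 5% of the features, favoring
low-expression genes. Prints the truth-set size and how the zeroed genes
distribute across the expression range.
"""

import zicbench as z

pool = z.make_surrogate_pool(10_000, seed=1)
config = z.SimulationConfig(n_features=3000, seed=1)
dataset = z.simulate_dataset(pool, config)

print(f"features: {config.n_features}, samples: {dataset.data.counts.shape[1]}")
print(f"true DE genes (all-zero in one condition): {int(dataset.truth.sum())}")
print(f"realized library sizes: {dataset.data.libsizes.min():,} - "
      f"{dataset.data.libsizes.max():,}")

profile = z.empirical_zero_profile(dataset.data, n_bins=6)
print("\nfraction of zero-in-one-condition genes per expression bin")
print("(low to high expression; the injection favors low expression):")
print(profile[["bin", "n_genes", "frac_zero_in_one"]].to_string(index=False))
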