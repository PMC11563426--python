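"""Balance an imbalanced peptide dataset with ADASYN and inspect provenance.

ADASYN generates synthetic minority-class rows by interpolating between
minority neighbours, allotting more synthetics to points whose neighbourhoods
are dominated by the majority class (the hard, boundary-adjacent examples).
"""

from pepstack import EncoderSpec, SyntheticSpec, adasyn_oversample, encode_dataset, generate

# 394 positive vs 848 negative: the imbalance the toolkit is built around
dataset = generate(SyntheticSpec(delta=0.15, seed=7))
matrix = encode_dataset(dataset, [EncoderSpec("AAC")])

balanced = adasyn_oversample(matrix, dataset.labels, k=5, seed=7)
n_orig = matrix.shape[0]
print(f"before: {int(dataset.labels.sum())} positive / "
      f"{int((dataset.labels == 0).sum())} negative")
print(f"ADASYN added {balanced.n_synthetic} synthetic positives "
      f"-> {int((balanced.labels == 1).sum())} vs {int((balanced.labels == 0).sum())}")

# every synthetic row logs its generating pair (x_i, x_k) and weight lambda
i, k = balanced.pairs[0]
print(f"\nfirst synthetic row interpolates rows {balanced.matrix.row_ids[i]!r} "
      f"and {balanced.matrix.row_ids[k]!r} with lambda={balanced.lams[0]:.3f}")
# the synthetic count equals 848 - 394 = 454: the classes end up exactly equal.
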