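"""Encode two example peptides (one per class) into named composition features.

The amino-acid composition (AAC) is each residue's frequency in the peptide;
dipeptide composition (DPC) is the frequency of each ordered adjacent pair.
Concatenated AAC+DPC (420 columns) is the default feature set for the
classifier.
"""

import numpy as np

from pepstack import EncoderSpec, LabeledDataset, PeptideSequence, encode_dataset

dataset = LabeledDataset(
    [
        PeptideSequence("inducer", "RPFERDISNVPFS"),
        PeptideSequence("non_inducer", "SHLVEALYLVAGERG"),
    ],
    np.array([1, 0]),
)

matrix = encode_dataset(dataset, [EncoderSpec("AAC"), EncoderSpec("DPC")])
print(f"feature matrix: {matrix.shape[0]} peptides x {matrix.shape[1]} features")

df = matrix.to_dataframe()
row = df.loc["inducer"]
nonzero = row[row > 0].sort_values(ascending=False)
print("\nlargest features of the inducing peptide (frequency units):")
print(nonzero.head(8).round(4).to_string())
# AAC.R = 2/13 = 0.1538 because R occurs twice in the 13-residue peptide;
# DPC.PF = 2/12 because the pair PF occurs twice among its 12 adjacent pairs.
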