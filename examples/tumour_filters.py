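"""Mutation and expression filters for tumour-sample clustering.

Simulates a small mutation matrix and an expression matrix, keeps mutations
recurring in at least two samples (then drops samples left with none), and
selects the most variable expression features by combined rank of
coefficient of variation and standard deviation.
"""

import numpy as np

from bgmix import filter_mutations, select_variable_features

rng = np.random.default_rng(3)
n_samples, n_genes = 40, 120
M = (rng.random((n_samples, n_genes)) < 0.03).astype(float)

M2, kept_mut, kept_samples = filter_mutations(M, min_recurrence=2)
print(f"mutations: kept {kept_mut.size}/{n_genes} recurring in >= 2 samples")
print(f"samples:   kept {kept_samples.size}/{n_samples} with >= 1 retained "
      "mutation")

E = rng.normal(loc=rng.uniform(2, 10, size=200),
               scale=rng.uniform(0.1, 3.0, size=200),
               size=(kept_samples.size, 200))
top = select_variable_features(E, k=25)
sd = E.std(axis=0, ddof=1)
print(f"selected {top.size} most variable of 200 expression features; "
      f"their SD range is [{sd[top].min():.2f}, {sd[top].max():.2f}] vs "
      f"overall [{sd.min():.2f}, {sd.max():.2f}]")
print("These filtered matrices are what the joint clustering consumes: "
      "binary mutation recurrence plus the most informative expression "
      "features.")
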