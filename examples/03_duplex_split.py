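"""Split samples into representative train/test sets with Duplex.

Duplex alternately assigns mutually distant points to the training and test
sets so both span the data space.  Samples are collapsed to subject
centroids first, so a subject contributing two samples never straddles the
split — the constraint that makes cross-validation honest when subjects
repeat.
"""

import numpy as np

from mbomics import SimConfig, duplex_split, fit_sum_pca, generate_multiblock, preprocess_dataset

dataset, _ = generate_multiblock(
    SimConfig(n_case=60, n_control=64, within_subject_repeats=8, seed=42)
)
scaled, _ = preprocess_dataset(dataset)
super_scores = fit_sum_pca(scaled.subset(scaled.non_qc_ids), k=3).super_scores

plan = duplex_split(super_scores, dataset.subjects(dataset.non_qc_ids), test_fraction=0.30)
print(f"train: {len(plan.train_samples)} samples / {len(plan.train_subjects)} subjects")
print(f"test:  {len(plan.test_samples)} samples / {len(plan.test_subjects)} subjects")

centroid = super_scores.mean(axis=0)
d_test = np.linalg.norm(super_scores.loc[plan.test_samples].mean(axis=0) - centroid)
print(f"test-set centroid distance from global centroid: {d_test:.3f}")
# A small distance means the held-out set is representative of the whole
# score space rather than an extreme corner of it.
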