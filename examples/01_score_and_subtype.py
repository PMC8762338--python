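"""Score a synthetic cohort with ssGSEA and assign ordered immune subtypes.

Generates a 150-tumor cohort with three planted infiltration levels,
scores the 28 immune-cell-type signatures per sample, clusters the score
matrix hierarchically (Ward/Euclidean on z-scored signatures) and labels
the clusters ImH/ImM/ImL by mean signature score.
"""
from sklearn.metrics import adjusted_rand_score

import immsub as im

dataset = im.generate_bulk_dataset(im.SyntheticConfig(seed=1, n_samples=150))
scores = im.ssgsea_matrix(dataset.expression, dataset.marker_sets)
assignment = im.subtype_samples(scores, k=3)

print("cluster sizes:", assignment.labels.value_counts().to_dict())
print("cluster mean scores:",
      {k: round(v, 1) for k, v in assignment.cluster_means.items()})
ari = adjusted_rand_score(dataset.truth.levels.values, assignment.labels.values)
print(f"adjusted Rand index vs planted levels: {ari:.3f}")
# The mean-score ordering ImH > ImM > ImL holds by construction; an ARI of
# 1.0 means every sample was returned to its planted infiltration level.
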