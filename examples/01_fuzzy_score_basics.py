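"""Score a single microarray with the Gene Fuzzy Score and read the result.

Builds one tie-free 1000-gene sample, applies GFS with the default
thresholds (theta1 = 5%, theta2 = 15%), and prints the scores of a few
landmark genes. A score of 1 means "in the top 5% of this sample's
ranking", 0 means "below the top 15%", and 0.5 marks the top-10%
boundary — the score is directly interpretable as a rank statement.
"""

import numpy as np

from gfscore import ExpressionMatrix, gfs_transform, rank_within_sample

rng = np.random.default_rng(0)
values = rng.permutation(1000).astype(float) + 1.0
matrix = ExpressionMatrix.from_arrays(
    [f"g{i:04d}" for i in range(1000)], ["patient1"], values[:, None]
)

scores = gfs_transform(matrix).values[:, 0]
ranks = rank_within_sample(values)

for rank in (1000, 950, 900, 850, 500, 1):
    gene = np.flatnonzero(ranks == rank)[0]
    print(f"rank {rank:4d} (top {100 * (1 - rank / 1000):4.1f}%) -> score {scores[gene]:.3f}")
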