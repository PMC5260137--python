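"""Do two halves of the same dataset nominate the same high-variance genes?

Repeatedly splits the samples in half (stratified by phenotype),
processes each half independently, and measures the Jaccard overlap of
the two top-15%-variance gene lists. A reliable transform gives similar
gene lists from similar data.
"""

import numpy as np

from gfscore import consistency_jaccard
from gfscore.synthetic import generate_dataset, preset

ds = generate_dataset(preset("two-batch", seed=0))

for method in ("raw", "zscore", "quantile", "gfs"):
    report = consistency_jaccard(
        ds.matrix, ds.annotation, method,
        n_splits=20, components="pc23", seed=2,
    )
    print(
        f"{method:9s} median jaccard = {np.median(report.jaccard_values):.3f} "
        f"(IQR {np.percentile(report.jaccard_values, 25):.3f}"
        f"-{np.percentile(report.jaccard_values, 75):.3f})"
    )
print("higher overlap = the transform nominates the same genes from either half.")
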