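"""Low-impact probe removal."""
from __future__ import annotations

import numpy as np

from .matrix import ExpressionMatrix


def median_variance_filter(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop probes whose across-sample variance falls below the median.

    Probes with variance greater than or equal to the median of all probe
    variances are retained, in their original order.  Variance is the
    population variance (denominator n).  With all variances distinct this
    keeps ceil(n/2) of n probes.
    """
    if matrix.n_samples < 2:
        raise ValueError("variance filter needs at least 2 samples")
    variances = matrix.data.to_numpy().var(axis=1, ddof=0)
    median = np.median(variances)
    keep = variances >= median
    return ExpressionMatrix(matrix.data.loc[keep], matrix.sample_meta)
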