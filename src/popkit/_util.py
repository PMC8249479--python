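"""Internal helpers shared across statistic modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix


def window_index(matrix: GenotypeMatrix, window_bp: int):
    """Factorize sites into (scaffold, window) groups.

    Returns (scaffold_names, scaffold_idx_per_group, window_per_group,
    inverse_per_site, n_groups); groups are ordered by (scaffold, window).
    """
    scaffolds = matrix.sites["scaffold"].to_numpy()
    codes, scaffold_names = pd.factorize(scaffolds, sort=True)
    win = (matrix.sites["pos"].to_numpy() - 1) // window_bp
    stride = int(win.max()) + 1 if len(win) else 1
    key = codes.astype(np.int64) * stride + win
    uniq, inverse = np.unique(key, return_inverse=True)
    return (
        list(scaffold_names),
        (uniq // stride).astype(int),
        uniq % stride,
        inverse,
        len(uniq),
    )
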