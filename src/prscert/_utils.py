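"""Small shared helpers: covariate design matrices and seed derivation."""

from __future__ import annotations

import numpy as np
import pandas as pd


def design_matrix(covariates: pd.DataFrame, add_intercept: bool = False) -> np.ndarray:
    """Numeric design matrix from a covariate table.

    Numeric columns pass through; string/categorical columns (e.g. smoking
    status) are dummy-coded with the first level (alphabetical) as reference.
    """
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "biufc":
            parts.append(s.to_numpy(dtype=float).reshape(-1, 1))
        else:
            dummies = pd.get_dummies(s, drop_first=True).sort_index(axis=1)
            parts.append(dummies.to_numpy(dtype=float))
    x = np.hstack(parts) if parts else np.empty((len(covariates), 0))
    if add_intercept:
        x = np.hstack([np.ones((x.shape[0], 1)), x])
    return x


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]
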