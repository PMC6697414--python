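"""Permutation tests and multiple-comparison correction.

The permutation test is the workhorse of the responsiveness and tuning
analyses: two samples are pooled, group labels are reshuffled preserving
group sizes, and the observed difference in means is ranked against the
permuted differences.  The reported p-value uses the add-one convention
``(1 + #{permuted >= observed}) / (n_perm + 1)``, which never returns
exactly zero and, at alpha = 0.05, matches the 95th-percentile rejection
rule.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

_REL_TOL = 1e-9  # absorb round-off when ranking permuted statistics


def permutation_mean_test(
    x,
    y,
    n_perm: int = 10000,
    alternative: str = "greater",
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation test for a difference in means between two samples.

    ``alternative="greater"`` tests mean(x) > mean(y); ``"two_sided"``
    ranks absolute differences.  Degenerate pooled samples (all values
    identical) return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    if rng is None:
        rng = np.random.default_rng(seed)

    nx, ny = x.size, y.size
    n = nx + ny
    total = pooled.sum()
    observed = x.mean() - y.mean()

    # random nx-subsets via partial sort of uniform keys
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, nx - 1, axis=1)[:, :nx]
    sum_x = pooled[idx].sum(axis=1)
    diffs = sum_x / nx - (total - sum_x) / ny

    tol = _REL_TOL * max(1.0, abs(observed))
    if alternative == "greater":
        count = int(np.sum(diffs >= observed - tol))
    else:
        count = int(np.sum(np.abs(diffs) >= abs(observed) - tol))
    return (1 + count) / (n_perm + 1)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
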