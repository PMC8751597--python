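"""Sample distance correlation and its permutation significance test.

Distance correlation (dCor) is a dependence measure built from doubly-
centered pairwise-distance matrices; for the population quantity it is zero
exactly when the two variables are independent, which makes it a natural
screen when no functional form can be assumed.  For samples x, y of length
n with distance matrices a_kl = |x_k - x_l| and b_kl = |y_k - y_l|,
double-center each (subtract row and column means, add the grand mean) to
get A, B; then

    dCov^2 = mean(A * B),  dVar_x^2 = mean(A * A),  dVar_y^2 = mean(B * B),
    dCor   = sqrt(dCov^2 / sqrt(dVar_x^2 * dVar_y^2)),

with the convention dCor = 0 when either dVar is zero (a constant sample).

Significance is assessed by permuting y: simultaneously permuting rows and
columns of the centered matrix B is equivalent to recentering the permuted
sample, so the null statistics cost one O(n^2) product each rather than a
full recomputation.
"""

from __future__ import annotations

import numpy as np


def _centered_distances(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return x, y


def distance_correlation(x, y) -> float:
    """Sample distance correlation of two 1-d samples, in [0, 1]."""
    x, y = _validate_pair(x, y)
    A = _centered_distances(x)
    B = _centered_distances(y)
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    dcov2 = (A * B).mean()
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def dcor_resample_test(x, y, n_resamples: int = 300,
                       seed: int | np.random.Generator | None = None) -> float:
    """Permutation p-value for independence based on distance correlation.

    The null distribution is built by permuting y ``n_resamples`` times;
    the add-one estimator p = (1 + #{null >= observed}) / (1 + n_resamples)
    keeps p in (0, 1].
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    x, y = _validate_pair(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.shape[0]
    A = _centered_distances(x)
    B = _centered_distances(y)
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 1.0
    denom = np.sqrt(dvar_x * dvar_y)
    observed = max((A * B).mean(), 0.0) / denom  # dCor^2; monotone in dCor
    exceed = 0
    for _ in range(n_resamples):
        p = rng.permutation(n)
        null = max((A * B[np.ix_(p, p)]).mean(), 0.0) / denom
        if null >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_resamples)
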