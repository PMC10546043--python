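"""Count normalization (RPMPM), log scores, subsampling, MAPQ calibration.

The region score is reads per million per motif:

    RPMPM_i = 1e6 * (c_i / m_i) / D

where c_i is the region's hit count, m_i its motif count, and D the
library-wide total of hits assigned to all sites of the analysis pattern
(not merely those falling in the region set).  For display and clustering
the score is log-transformed as log10(RPMPM + 1).
"""

from __future__ import annotations

import numpy as np


def rpmpm(
    c: np.ndarray,
    m: np.ndarray,
    denominator: float | None = None,
) -> np.ndarray:
    """Reads per million per motif for each region.

    ``denominator`` defaults to c.sum() but should be the genome-wide total
    of assigned hits when the regions do not cover every site.  Regions with
    no motifs and no hits score 0; a hit in a region with no motifs is an
    impossible assignment and raises.
    """
    c = np.asarray(c, dtype=float)
    m = np.asarray(m, dtype=float)
    if c.shape != m.shape:
        raise ValueError("c and m must have the same shape")
    if np.any((c > 0) & (m == 0)):
        raise ValueError("hit count > 0 in a region with zero motif sites")
    if np.any(c < 0) or np.any(m < 0):
        raise ValueError("counts must be non-negative")
    D = float(c.sum()) if denominator is None else float(denominator)
    if D <= 0:
        raise ValueError("library total of assigned hits must be > 0")
    out = np.zeros_like(c)
    nz = m > 0
    out[nz] = 1e6 * (c[nz] / m[nz]) / D
    return out


def log_score(x: np.ndarray) -> np.ndarray:
    """log10(RPMPM + 1); monotone, 0 at 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("scores must be non-negative")
    return np.log10(x + 1.0)


def subsample_counts(
    counts: np.ndarray, target: int, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rarefy a count vector to ``target`` total hits.

    Draws without replacement over the individual hit events (multivariate
    hypergeometric), emulating sequencing the same library to lower depth.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if target > total:
        raise ValueError(f"target depth {target} exceeds total {total}")
    if target == total:
        return counts.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, target)


def mapq_to_posterior(mapq: float) -> float:
    """Posterior probability an alignment is correct: 1 - 10^(-MAPQ/10)."""
    if mapq < 0:
        raise ValueError("MAPQ must be >= 0")
    return 1.0 - 10.0 ** (-mapq / 10.0)
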