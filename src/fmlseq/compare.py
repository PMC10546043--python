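"""Cross-platform comparison statistics.

Region-level methylation scores for the other profiling platforms
(coverage-weighted percent methylation for base-conversion sequencing,
fragment-center counts for immunoprecipitation, mean probe beta for arrays),
chi-square selection of the most variable regions, unit-interval scaling,
UPGMA clustering on Pearson distances, and the ratio silhouette used to
judge whether replicate samples cluster by biological class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enzyme import Region


@dataclass(frozen=True)
class BaseCall:
    """Methylated/total read counts at one cytosine (base conversion data)."""

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_meth <= self.n_total:
            raise ValueError(
                f"need 0 <= n_meth <= n_total at {self.chrom}:{self.pos}, "
                f"got {self.n_meth}/{self.n_total}"
            )


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        df = calls
    else:
        df = pd.DataFrame(
            [(c.chrom, c.pos, c.n_meth, c.n_total) for c in calls],
            columns=["chrom", "pos", "n_meth", "n_total"],
        )
    if len(df) and ((df.n_meth < 0) | (df.n_meth > df.n_total)).any():
        raise ValueError("n_meth must lie in [0, n_total]")
    return df


def region_percent_methylation(calls, regions: Sequence[Region]) -> np.ndarray:
    """Coverage-weighted percent methylation per region.

    score_i = sum(n_meth) / sum(n_total) over positions inside the region,
    i.e. the per-position methylation proportions weighted by coverage.
    Regions with no covered position are NaN (missing, not 0).
    """
    df = _calls_frame(calls)
    out = np.full(len(regions), np.nan)
    for i, r in enumerate(regions):
        sub = df[(df.chrom == r.chrom) & (df.pos >= r.start) & (df.pos < r.end)]
        tot = int(sub.n_total.sum())
        if tot > 0:
            out[i] = float(sub.n_meth.sum()) / tot
    return out


def fragment_center_counts(fragments, regions: Sequence[Region]) -> np.ndarray:
    """Count fragments whose center falls inside each region.

    The center of a half-open interval [start, end) is floor((start+end)/2).
    Accepts (chrom, start, end) triples or objects with those attributes.
    """
    centers: dict[str, list[int]] = {}
    for f in fragments:
        chrom, start, end = (
            (f[0], f[1], f[2]) if isinstance(f, (tuple, list))
            else (f.chrom, f.start, f.end)
        )
        centers.setdefault(chrom, []).append((start + end) // 2)
    centers = {c: np.sort(np.asarray(v)) for c, v in centers.items()}
    out = np.zeros(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        pos = centers.get(r.chrom)
        if pos is not None:
            out[i] = np.searchsorted(pos, r.end, "left") - np.searchsorted(pos, r.start, "left")
    return out


def beta_region_score(probes, regions: Sequence[Region]) -> np.ndarray:
    """Unweighted mean probe beta per region; NaN where no probe falls inside.

    ``probes``: DataFrame with chrom/pos/beta columns or (chrom, pos, beta)
    triples, pos being the 0-based coordinate of the measured cytosine.
    """
    if not isinstance(probes, pd.DataFrame):
        probes = pd.DataFrame(list(probes), columns=["chrom", "pos", "beta"])
    if len(probes) and ((probes.beta < 0) | (probes.beta > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    out = np.full(len(regions), np.nan)
    for i, r in enumerate(regions):
        sub = probes[(probes.chrom == r.chrom) & (probes.pos >= r.start) & (probes.pos < r.end)]
        if len(sub):
            out[i] = float(sub.beta.mean())
    return out


def chi2_scores(meth: np.ndarray, unmeth: np.ndarray) -> np.ndarray:
    """Pearson chi-square per region of the groups x (meth, unmeth) table.

    ``meth``/``unmeth``: arrays of shape (n_regions, n_groups).  Regions
    whose table has a zero row or column total score 0.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if meth.shape != unmeth.shape or meth.ndim != 2 or meth.shape[1] < 2:
        raise ValueError("need matching (n_regions, n_groups>=2) count arrays")
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("counts must be non-negative")
    O = np.stack([meth, unmeth], axis=2)          # regions x groups x 2
    n = O.sum(axis=(1, 2))
    row = O.sum(axis=2)                           # group totals
    col = O.sum(axis=1)                           # meth/unmeth totals
    ok = (n > 0) & (row > 0).all(axis=1) & (col > 0).all(axis=1)
    scores = np.zeros(len(O))
    if ok.any():
        E = row[ok, :, None] * col[ok, None, :] / n[ok, None, None]
        scores[ok] = ((O[ok] - E) ** 2 / E).sum(axis=(1, 2))
    return scores


def chi2_select_top(
    meth: np.ndarray,
    unmeth: np.ndarray,
    region_ids: Sequence[str],
    k: int = 500,
) -> list[str]:
    """Ids of the k regions most variable among groups by chi-square score.

    Ties are broken by original region order; if k exceeds the number of
    regions all are returned with a warning.
    """
    scores = chi2_scores(meth, unmeth)
    if k > len(scores):
        warnings.warn(f"k={k} exceeds {len(scores)} regions; returning all")
        k = len(scores)
    if k == 0:
        return []
    order = np.argsort(-scores, kind="stable")[:k]
    return [region_ids[i] for i in order]


def scale_unit_interval(matrix: np.ndarray, per_feature: bool = False) -> np.ndarray:
    """Linearly scale a score matrix to (0, 1).

    Default is whole-matrix scaling (one min/max per platform matrix); the
    per-feature alternative scales each column independently.
    """
    M = np.asarray(matrix, dtype=float)
    axis = 0 if per_feature else None
    lo, hi = np.nanmin(M, axis=axis), np.nanmax(M, axis=axis)
    if np.any(hi - lo == 0):
        raise ValueError("cannot scale a constant matrix to (0, 1)")
    return (M - lo) / (hi - lo)


def pearson_distance_matrix(X: np.ndarray, labels: Sequence[str] | None = None) -> np.ndarray:
    """Pairwise Pearson distances 1 - r between sample rows."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] if labels else str(i) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance sample(s): {bad}")
    return 1.0 - np.corrcoef(X)


def upgma_pearson(
    X: np.ndarray, labels: Sequence[str] | None = None
) -> np.ndarray:
    """UPGMA (average linkage, cluster-size weighted) on Pearson distances.

    Returns a scipy-style linkage matrix: each row (a, b, height, size)
    merges clusters a and b (original samples are 0..n-1, merged clusters
    n, n+1, ...).  Ties are broken by the lexicographically lowest index
    pair, so the dendrogram is deterministic.
    """
    return upgma(pearson_distance_matrix(X, labels))


def upgma(D: np.ndarray) -> np.ndarray:
    """UPGMA on a square distance matrix (see :func:`upgma_pearson`)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    active = list(range(n))                       # cluster ids in creation order
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (min(a, b), max(a, b))
                d = dist[key]
                if best is None or d < best[0] - 1e-15:
                    best = (d, key)
        d, (a, b) = best
        merged = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            dist[(c, merged)] = (size[a] * da + size[b] * db) / (size[a] + size[b])
        size[merged] = size[a] + size[b]
        active = [c for c in active if c not in (a, b)] + [merged]
        Z[step] = [a, b, d, size[merged]]
    return Z


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage matrix as an ultrametric Newick string."""
    n = Z.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for step in range(Z.shape[0]):
        a, b, h, _ = Z[step]
        a, b = int(a), int(b)
        la = (h - height[a]) / 2.0
        lb = (h - height[b]) / 2.0
        node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + step] = h
    return node[n + Z.shape[0] - 1] + ";"


def silhouette_ratio(
    X: np.ndarray | None,
    classes: Sequence[str],
    labels: Sequence[str] | None = None,
    distances: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample cluster-separation ratio on Pearson distances.

    score(s) = (nearest other-class distance) / (mean same-class distance,
    excluding self).  Unlike the classical silhouette this is a ratio:
    values above 1 indicate the sample sits closer to its own class than to
    any other.  Every class needs at least 2 members.  A precomputed square
    distance matrix may be supplied instead of the sample matrix.
    """
    classes = np.asarray(classes)
    D = pearson_distance_matrix(X, labels) if distances is None else np.asarray(distances, float)
    vals, counts = np.unique(classes, return_counts=True)
    if np.any(counts < 2):
        bad = list(vals[counts < 2])
        raise ValueError(f"singleton class(es): {bad}")
    if len(vals) < 2:
        raise ValueError("need at least two classes")
    n = len(classes)
    out = np.zeros(n)
    for i in range(n):
        same = (classes == classes[i]) & (np.arange(n) != i)
        other = classes != classes[i]
        out[i] = D[i, other].min() / D[i, same].mean()
    return out
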