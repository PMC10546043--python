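"""Motif-anchored hit counting from aligned read pairs.

Each end of a sequenced fragment is the product of one enzymatic cut, so the
5' base of a confidently aligned read is expected exactly 10 bp from the
near edge of the recognition motif whose cytosine caused the cut: to the
right of a forward-strand motif, to the left of a reverse-strand motif.
A read end is counted as a hit at a site when its 5' coordinate sits at that
exact offset (equivalently, cut_near bp from the methylated C itself);
per-region counts sum the hits of all sites whose mC coordinate falls inside
the region.  Read pairs are first triaged into the standard library classes:
adapter dimer (insert <= 10 bp), too short to align (insert below the
aligner's 19-bp minimum seed), unaligned, poorly aligned (MAPQ below 10,
i.e. posterior probability of correct alignment below 0.9), and confidently
aligned.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enzyme import FORWARD, MSPJI, REVERSE, EnzymeSpec, MotifSite, Region


class ReadClass(enum.Enum):
    ADAPTER_DIMER = "adapter_dimer"
    TOO_SHORT = "too_short"
    UNALIGNED = "unaligned"
    POORLY_ALIGNED = "poorly_aligned"
    CONFIDENTLY_ALIGNED = "confidently_aligned"


@dataclass(frozen=True)
class AlignedEnd:
    """The 5' end of one aligned read.

    ``five_prime_pos`` is the top-strand coordinate of the read's 5' base:
    the leftmost aligned base of a forward read, the rightmost of a reverse
    read.
    """

    chrom: str
    five_prime_pos: int
    orientation: str  # '+' or '-'
    mapq: int = 60
    insert_len: int | None = None

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("MAPQ must be >= 0")


def classify_read_pair(
    insert_len: int | None,
    mapq: int,
    aligned: bool,
    min_insert_dimer: int = 10,
    min_seed: int = 19,
    min_mapq: int = 10,
) -> ReadClass:
    """Triage one read pair into its library class (see module docstring)."""
    if insert_len is not None:
        if insert_len < 0:
            raise ValueError("insert length must be >= 0")
        if insert_len <= min_insert_dimer:
            return ReadClass.ADAPTER_DIMER
        if insert_len < min_seed:
            return ReadClass.TOO_SHORT
    if not aligned:
        return ReadClass.UNALIGNED
    if mapq < min_mapq:
        return ReadClass.POORLY_ALIGNED
    return ReadClass.CONFIDENTLY_ALIGNED


class SiteIndex:
    """Lookup from an aligned end's 5' coordinate to its generating site.

    A forward end at x matches a forward site with mc_pos = x - cut_near
    (motif near edge at x - countable_offset); a reverse end at y matches a
    reverse site with mc_pos = y + cut_near.  An optional tolerance widens
    the match window by +/- that many bp (default 0: strictly exact).
    """

    def __init__(self, sites: Sequence[MotifSite], tolerance: int = 0) -> None:
        self.sites = list(sites)
        self.tolerance = int(tolerance)
        self._lut: dict[tuple[str, str, int], int] = {}
        for i, s in enumerate(self.sites):
            self._lut[(s.chrom, s.strand, s.countable_start)] = i

    def lookup(self, end: AlignedEnd) -> int | None:
        for delta in range(-self.tolerance, self.tolerance + 1):
            i = self._lut.get((end.chrom, end.orientation, end.five_prime_pos + delta))
            if i is not None:
                return i
        return None


def assign_end_to_site(end: AlignedEnd, index: SiteIndex) -> MotifSite | None:
    """Return the motif site this read end is a hit for, or None."""
    i = index.lookup(end)
    return None if i is None else index.sites[i]


@dataclass
class HitCounts:
    """Per-site hits plus per-region aggregates and the class tally."""

    sites: list[MotifSite]
    site_hits: np.ndarray
    regions: list[Region]
    region_hits: np.ndarray      # c_i
    region_motifs: np.ndarray    # m_i
    class_tally: dict[str, int]

    @property
    def total_assigned(self) -> int:
        return int(self.site_hits.sum())


def _pairs_from_sam(path, contigs: set[str]):
    """Yield (chrom, pos1, rev1, pos2, rev2, mapq_pair, insert, aligned) per
    name-grouped primary pair from a SAM/BAM file.  Streaming: mates are
    buffered by name until both are seen."""
    import pysam

    pending: dict[str, object] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        sam_contigs = set(fh.references or [])
        if sam_contigs and contigs and not (sam_contigs & contigs):
            raise ValueError(
                f"alignment contigs {sorted(sam_contigs)[:3]} do not match the "
                f"site registry contigs {sorted(contigs)[:3]}"
            )
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            yield (mate, rec) if mate.is_read1 else (rec, mate)
    for rec in pending.values():
        yield (rec, None)


def count_hits(
    alignments,
    sites: Sequence[MotifSite],
    regions: Sequence[Region] = (),
    analysis_sites: Sequence[MotifSite] | None = None,
    min_mapq: int = 10,
    min_seed: int = 19,
    min_insert_dimer: int = 10,
    tolerance: int = 0,
) -> HitCounts:
    """Count motif-site hits from paired alignments (SAM/BAM path or an
    iterable of AlignedEnd).

    Both mates of a confidently aligned pair are assigned independently.
    The pair MAPQ is the minimum of the mates'; insert length comes from the
    template length.  Region counts c_i sum hits over sites whose mC lies
    inside the region; motif counts m_i count those sites.
    """
    if analysis_sites is None:
        analysis_sites = sites
    index = SiteIndex(analysis_sites, tolerance=tolerance)
    site_hits = np.zeros(len(index.sites), dtype=np.int64)
    tally = {c.value: 0 for c in ReadClass}

    def handle_pair(ends: list[AlignedEnd], insert, mapq, aligned):
        cls = classify_read_pair(insert, mapq, aligned, min_insert_dimer,
                                 min_seed, min_mapq)
        tally[cls.value] += 1
        if cls is ReadClass.CONFIDENTLY_ALIGNED:
            for end in ends:
                i = index.lookup(end)
                if i is not None:
                    site_hits[i] += 1

    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        contigs = {s.chrom for s in index.sites}
        for r1, r2 in _pairs_from_sam(alignments, contigs):
            recs = [r for r in (r1, r2) if r is not None]
            aligned = all(not r.is_unmapped for r in recs) and len(recs) == 2
            mapq = min(r.mapping_quality for r in recs)
            tlens = [abs(r.template_length) for r in recs if r.template_length]
            insert = tlens[0] if tlens else None
            ends = []
            if aligned:
                for r in recs:
                    if r.is_reverse:
                        ends.append(AlignedEnd(r.reference_name, r.reference_end - 1,
                                               REVERSE, r.mapping_quality, insert))
                    else:
                        ends.append(AlignedEnd(r.reference_name, r.reference_start,
                                               FORWARD, r.mapping_quality, insert))
            handle_pair(ends, insert, mapq, aligned)
    else:
        for item in alignments:
            ends = list(item) if isinstance(item, (tuple, list)) else [item]
            aligned = all(isinstance(e, AlignedEnd) for e in ends) and bool(ends)
            mapq = min((e.mapq for e in ends), default=0)
            insert = next((e.insert_len for e in ends if e.insert_len is not None), None)
            handle_pair(ends if aligned else [], insert, mapq, aligned)

    regions = list(regions)
    region_hits = np.zeros(len(regions), dtype=np.int64)
    region_motifs = np.zeros(len(regions), dtype=np.int64)
    if regions:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for i, s in enumerate(index.sites):
            by_chrom.setdefault(s.chrom, []).append((s.mc_pos, i))
        for c in by_chrom:
            by_chrom[c].sort()
        for j, r in enumerate(regions):
            members = by_chrom.get(r.chrom, [])
            lo = np.searchsorted([m[0] for m in members], r.start, "left")
            hi = np.searchsorted([m[0] for m in members], r.end, "left")
            idx = [members[k][1] for k in range(lo, hi)]
            region_motifs[j] = len(idx)
            region_hits[j] = site_hits[idx].sum() if idx else 0

    return HitCounts(list(index.sites), site_hits, regions,
                     region_hits, region_motifs, tally)
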