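"""Enzyme cut geometry and motif-site scanning.

A methylation-dependent restriction endonuclease such as MspJI binds a short
recognition motif anchored on a (potentially) methylated cytosine and cuts
both strands downstream of the motif's 3' end, at fixed distances from the
methylated C, leaving a 4-nt 5' overhang.  Every occurrence of the motif on
either genomic strand is therefore a potential cut site; each cut produces a
fragment end whose 5' base lies at a fixed, countable distance from the
motif.  This module scans reference sequences for such sites and counts
motifs (and CpG dinucleotides) within genomic regions.

All coordinates are 0-based, half-open, expressed on the top strand
(BED-compatible).  A strand scission "after index i" means the backbone bond
between positions i and i+1 is broken.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

FORWARD = "+"
REVERSE = "-"

# IUPAC nucleotide codes -> concrete base sets.  N in a *reference* sequence
# never matches any code: the classes below only contain ACGT, so an
# ambiguous reference base cannot satisfy them.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern to an overlapping-match regex."""
    try:
        body = "".join(
            f"[{IUPAC[sym]}]" if len(IUPAC[sym]) > 1 else IUPAC[sym]
            for sym in pattern.upper()
        )
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in pattern {pattern!r}")
    # lookahead so overlapping and nested occurrences all match
    return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class EnzymeSpec:
    """Cut geometry of a methylation-dependent restriction endonuclease.

    Defaults describe MspJI: recognition mCNNR (analysis restricted to the
    CpG-context subset CGNR), double-strand cut 13 and 17 bp downstream of
    the methylated C, 4-nt 5' overhang.  ``countable_offset`` is the
    distance from the motif's far edge to the 5' base of a countable read:
    cut_near − (len(recognition) − 1) = 13 − 3 = 10 for the 4-bp motif.
    """

    name: str = "MspJI"
    recognition: str = "CNNR"
    analysis_pattern: str = "CGNR"
    cut_near: int = 13
    cut_far: int = 17
    overhang: int = 4

    def __post_init__(self) -> None:
        if self.cut_far - self.cut_near != self.overhang:
            raise ValueError("cut_far - cut_near must equal the overhang length")
        if not self.recognition or self.recognition[0].upper() != "C":
            raise ValueError("recognition motif must be anchored on C")
        if not self.analysis_pattern or self.analysis_pattern[0].upper() != "C":
            raise ValueError("analysis pattern must be anchored on C")
        for p in (self.recognition, self.analysis_pattern):
            iupac_regex(p)  # validates symbols

    @property
    def countable_offset(self) -> int:
        return self.cut_near - (len(self.recognition) - 1)


MSPJI = EnzymeSpec()


@dataclass(frozen=True)
class MotifSite:
    """One potential cut locus.

    ``mc_pos`` is the top-strand coordinate of the potentially methylated
    cytosine (for a reverse site this is the position of the G whose paired
    bottom-strand base is the C).  ``cut_top``/``cut_bottom`` are scission
    positions: the bond after that top-strand index is broken on the named
    strand.  ``countable_start`` is the top-strand coordinate of the 5' base
    of the read that a cut at this site makes countable.
    """

    chrom: str
    mc_pos: int
    strand: str
    motif_interval: tuple[int, int]
    countable_start: int
    cut_top: int
    cut_bottom: int
    in_bounds: bool = True

    @property
    def fragment_right_start(self) -> int:
        """Start (0-based) of the filled-in insert right of this cut."""
        return min(self.cut_top, self.cut_bottom) + 1

    @property
    def fragment_left_end(self) -> int:
        """Half-open end of the filled-in insert left of this cut."""
        return max(self.cut_top, self.cut_bottom) + 1

    @property
    def overhang_interval(self) -> tuple[int, int]:
        """Top-strand span of the 4-nt single-stranded 5' overhang."""
        return (self.fragment_right_start, self.fragment_left_end)

    @property
    def footprint(self) -> tuple[int, int]:
        """Duplex span the enzyme needs intact: motif through far scission."""
        lo = min(self.motif_interval[0], self.fragment_right_start)
        hi = max(self.motif_interval[1], self.fragment_left_end)
        return (lo, hi)


@dataclass(frozen=True)
class Region:
    """A genomic interval (0-based, half-open), e.g. a promoter."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.id!r}: start must be < end")


def _forward_site(chrom: str, pos: int, enzyme: EnzymeSpec, length: int,
                  contig_len: int) -> MotifSite:
    cut_top = pos + enzyme.cut_near - 1
    cut_bottom = pos + enzyme.cut_far - 1
    return MotifSite(
        chrom=chrom,
        mc_pos=pos,
        strand=FORWARD,
        motif_interval=(pos, pos + length),
        countable_start=pos + enzyme.cut_near,
        cut_top=cut_top,
        cut_bottom=cut_bottom,
        in_bounds=cut_bottom + 1 < contig_len,
    )


def _reverse_site(chrom: str, mc_pos: int, enzyme: EnzymeSpec, length: int,
                  contig_len: int) -> MotifSite:
    # mirror image: the bottom-strand enzyme reads leftward on top coordinates
    cut_top = mc_pos - enzyme.cut_far
    cut_bottom = mc_pos - enzyme.cut_near
    return MotifSite(
        chrom=chrom,
        mc_pos=mc_pos,
        strand=REVERSE,
        motif_interval=(mc_pos - (length - 1), mc_pos + 1),
        countable_start=mc_pos - enzyme.cut_near,
        cut_top=cut_top,
        cut_bottom=cut_bottom,
        in_bounds=cut_top >= 0,
    )


def scan_motifs(
    genome: Mapping[str, str],
    enzyme: EnzymeSpec = MSPJI,
    pattern: str | None = None,
) -> list[MotifSite]:
    """Find every potential cut site of ``pattern`` on both strands.

    Forward sites are direct occurrences of the pattern on the top strand;
    reverse sites are occurrences on the bottom strand, which appear on the
    top strand as the reverse complement (e.g. YNCG for CGNR) with the
    methylated C paired to the top-strand base at the match's last position.
    Sites whose cut coordinates fall off the contig are returned with
    ``in_bounds=False``.
    """
    if pattern is None:
        pattern = enzyme.recognition
    pattern = pattern.upper()
    if pattern[0] != "C":
        raise ValueError("scan pattern must be anchored on C")
    fwd_re = iupac_regex(pattern)
    rev_re = iupac_regex(reverse_complement(pattern))
    L = len(pattern)

    sites: list[MotifSite] = []
    for chrom, seq in genome.items():
        seq = str(seq).upper()
        n = len(seq)
        for m in fwd_re.finditer(seq):
            sites.append(_forward_site(chrom, m.start(), enzyme, L, n))
        for m in rev_re.finditer(seq):
            sites.append(_reverse_site(chrom, m.start() + L - 1, enzyme, L, n))
    sites.sort(key=lambda s: (s.chrom, s.mc_pos, s.strand))
    return sites


def count_motifs_in_regions(
    sites: Sequence[MotifSite], regions: Sequence[Region]
) -> np.ndarray:
    """Motif count m_i per region: sites whose mC coordinate is inside.

    A site is counted when ``start <= mc_pos < end``; both orientations of a
    palindromic context count separately, so a CpG straddling a boundary
    contributes an odd count.  Regions on chromosomes absent from the site
    registry get 0 with a warning.
    """
    by_chrom: dict[str, np.ndarray] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.mc_pos)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}

    site_chroms = set(by_chrom)
    missing = sorted({r.chrom for r in regions} - site_chroms)
    if missing and sites:
        warnings.warn(f"regions on chromosomes with no sites: {missing}")

    counts = np.zeros(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        pos = by_chrom.get(r.chrom)
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, r.end, "left") - np.searchsorted(pos, r.start, "left")
    return counts


def count_cpg_in_regions(
    genome: Mapping[str, str], regions: Sequence[Region]
) -> np.ndarray:
    """CpG target count per region, both strands.

    Each CG dinucleotide holds two cytosines (top-strand C and the
    bottom-strand C paired with the G); each is counted only if its own
    coordinate lies inside the region, so a boundary-straddling CpG counts 1.
    """
    cyt_by_chrom: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        seq = str(seq).upper()
        starts = np.array([m.start() for m in re.finditer("(?=CG)", seq)], dtype=np.int64)
        cyt_by_chrom[chrom] = np.sort(np.concatenate([starts, starts + 1]))

    counts = np.zeros(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        pos = cyt_by_chrom.get(r.chrom)
        if pos is None or pos.size == 0:
            continue
        counts[i] = np.searchsorted(pos, r.end, "left") - np.searchsorted(pos, r.start, "left")
    return counts
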