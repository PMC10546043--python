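"""Synthetic-data generator: methylation-dependent digestion of genome copies.

The simulator emulates a library preparation in which a methylation-dependent
endonuclease digests many copies of a genome, each copy's cytosines
methylated independently according to a per-site methylation fraction, and
the resulting fragments are ligated to sticky-end adapters and sequenced
paired-end.  Fragment boundaries follow the fixed cut geometry of the
enzyme (see :mod:`fmlseq.enzyme`); fragments bounded by a contig end lack
the enzymatic 4-nt 5'-phosphorylated overhang and are unligatable, so an
entirely unmethylated genome yields no library at all.

Two chemical constraints shape the fragment population:

* an enzyme can only cut while its footprint (motif through the far
  scission) is intact duplex, so a cut whose footprint overlaps the
  single-stranded overhang zone left by an earlier cut is suppressed; the
  shortest insert two motif-flanking cuts can produce is therefore 21 bp;
* symmetric digestion of a fully methylated CpG inside a YNCGNR palindrome
  excises a canonical 32-bp insert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enzyme import (FORWARD, MSPJI, REVERSE, EnzymeSpec, MotifSite,
                     reverse_complement, scan_motifs)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration and domain types


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the digestion/sequencing simulator.

    digestion_prob is the per-cut enzymatic efficiency, applied on top of the
    per-copy Bernoulli methylation state, so the expected number of cuts at a
    site is n_copies * fraction * digestion_prob.  adapter_dimer_rate is the
    fraction of read pairs replaced by 4-bp random inserts (adapter dimers
    carry only the random sticky-end overhang).  Defaults: 100 copies, 90%
    digestion efficiency, 61-nt reads (short-read run), 1% adapter dimers.
    """

    n_copies: int = 100
    digestion_prob: float = 0.9
    read_length: int = 61
    adapter_dimer_rate: float = 0.01
    insert_min: int | None = None
    insert_max: int | None = None
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("digestion_prob", "adapter_dimer_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 19:
            raise ValueError("read_length must be >= 19 (aligner minimum seed)")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


@dataclass
class MethylationProfile:
    """Per-cytosine, per-strand methylation fractions.

    Keys are (chrom, mc_pos, strand) with strand '+' for a top-strand C and
    '-' for a bottom-strand C (top strand shows G at mc_pos).  Sites absent
    from the table are treated as unmethylated.
    """

    fractions: dict[tuple[str, int, str], float]

    def __post_init__(self) -> None:
        for key, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"methylation fraction out of [0, 1] at {key}: {f}")

    def fraction_of(self, site: MotifSite) -> float:
        return self.fractions.get((site.chrom, site.mc_pos, site.strand), 0.0)

    def validate_against(self, genome: Mapping[str, str]) -> None:
        """Check every key names an actual cytosine in the genome."""
        for chrom, pos, strand in self.fractions:
            seq = str(genome[chrom]).upper()
            base = seq[pos]
            want = "C" if strand == FORWARD else "G"
            if base != want:
                raise ValueError(
                    f"profile key ({chrom}, {pos}, {strand}) is not a cytosine "
                    f"(top-strand base {base!r})"
                )

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class Fragment:
    """A filled-in library insert produced by digestion of one genome copy.

    ``left_site``/``right_site`` are indices into the site registry that cut
    the corresponding boundary, or None where the boundary is a contig end.
    Contig-end fragments have no enzymatic 5'-phosphorylated overhang there
    and are unligatable; so are degenerate pieces whose two 4-nt overhangs
    would leave no duplex (length < 2*overhang + 1).
    """

    chrom: str
    start: int
    end: int
    left_site: int | None
    right_site: int | None
    copy_id: int
    ligatable: bool

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("fragment length must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadPair:
    """A simulated read pair with its ground-truth alignment."""

    name: str
    seq1: str
    seq2: str
    chrom: str | None  # None for adapter dimers (no genomic origin)
    start: int         # insert start; read 1 aligns forward here
    end: int           # insert end; read 2's 5' base is at end - 1
    insert_len: int
    is_dimer: bool = False


# ---------------------------------------------------------------------------
# generators


def generate_genome(
    length: int,
    cpg_enrichment: float = 0.0,
    seed: int | None = None,
    gc: float = 0.5,
    name: str = "chrS",
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Random genome with tunable CpG dinucleotide abundance.

    Bases are drawn from a first-order Markov chain: after a C, the
    probability of G is scaled by (1 + cpg_enrichment) and the remaining
    bases renormalized.  At cpg_enrichment 0 the chain is i.i.d., so the CpG
    frequency equals the product of the C and G frequencies; the frequency
    is monotone increasing in the enrichment factor.
    """
    if length < 100:
        raise ValueError("genome length must be >= 100")
    if cpg_enrichment < -1.0:
        raise ValueError("cpg_enrichment must be >= -1")
    if rng is None:
        rng = np.random.default_rng(seed)

    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    after_c = base_p.copy()
    after_c[2] = min(base_p[2] * (1.0 + cpg_enrichment), 0.97)
    rest = 1.0 - after_c[2]
    others = base_p.copy()
    others[2] = 0.0
    after_c[[0, 1, 3]] = base_p[[0, 1, 3]] / others.sum() * rest

    cum_base = np.cumsum(base_p)
    cum_after_c = np.cumsum(after_c)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    prev_c = False
    for i in range(length):
        cum = cum_after_c if prev_c else cum_base
        b = int(np.searchsorted(cum, u[i], side="right"))
        b = min(b, 3)
        out[i] = b
        prev_c = b == 1
    seq = "".join(BASES[b] for b in out)
    return {name: seq}


def generate_profile(
    sites: Sequence[MotifSite],
    mode: str = "beta",
    a: float = 2.0,
    b: float = 2.0,
    fraction_table: Mapping[tuple[str, int, str], float] | None = None,
    seed: int | None = None,
    symmetric_cpg: bool = True,
    rng: np.random.Generator | None = None,
) -> MethylationProfile:
    """Methylation fractions for a site registry.

    Modes: ``all_methylated`` (1.0 everywhere), ``all_unmethylated`` (0.0),
    ``beta`` (Beta(a, b) draw per site), or ``table`` (explicit per-site
    fractions).  With ``symmetric_cpg`` (default) the forward and reverse
    sites of one CpG (forward mC at p, reverse mC at p+1) share a single
    draw, emulating symmetric CpG methylation; the enzyme still recognizes
    each strand's mC independently.
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    keys = [(s.chrom, s.mc_pos, s.strand) for s in sites]
    if mode == "all_methylated":
        return MethylationProfile({k: 1.0 for k in keys})
    if mode == "all_unmethylated":
        return MethylationProfile({k: 0.0 for k in keys})
    if mode == "table":
        if fraction_table is None:
            raise ValueError("mode 'table' requires fraction_table")
        bad = [k for k, v in fraction_table.items() if not 0.0 <= v <= 1.0]
        if bad:
            raise ValueError(f"fractions outside [0, 1] at {bad[:3]}")
        return MethylationProfile({k: fraction_table.get(k, 0.0) for k in keys})
    if mode != "beta":
        raise ValueError(f"unknown profile mode {mode!r}")

    # group complementary CpG sites so one fraction covers both strands
    groups: dict[tuple[str, int], list[tuple[str, int, str]]] = {}
    for chrom, pos, strand in keys:
        anchor = pos if strand == FORWARD else pos - 1
        group_key = (chrom, anchor) if symmetric_cpg else (chrom, pos if strand == FORWARD else -pos - 1)
        groups.setdefault(group_key, []).append((chrom, pos, strand))

    fractions: dict[tuple[str, int, str], float] = {}
    for group_key in sorted(groups):
        f = float(rng.beta(a, b))
        for k in groups[group_key]:
            fractions[k] = f
    return MethylationProfile(fractions)


# ---------------------------------------------------------------------------
# digestion


def _select_cuts(
    cand: np.ndarray,
    fp_lo: np.ndarray,
    fp_hi: np.ndarray,
    zone_lo: np.ndarray,
    zone_hi: np.ndarray,
    overhang: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resolve footprint conflicts among candidate cuts.

    A cut is blocked if its required duplex footprint overlaps the
    single-stranded overhang zone of a cut already made; candidates are
    attempted in a uniformly random order (enzymes act concurrently, with no
    positional preference).  Applied zones are kept sorted so each check is a
    bisect; all zones share the overhang width.
    """
    import bisect

    if cand.size == 0:
        return cand
    order = rng.permutation(cand.size)
    applied_zlo: list[int] = []
    chosen: list[int] = []
    for j in order:
        i = int(cand[j])
        lo, hi = int(fp_lo[i]), int(fp_hi[i])
        # a zone [zlo, zlo+overhang) overlaps [lo, hi) iff zlo in (lo-overhang, hi)
        a = bisect.bisect_right(applied_zlo, lo - overhang)
        if a < len(applied_zlo) and applied_zlo[a] < hi:
            continue
        bisect.insort(applied_zlo, int(zone_lo[i]))
        chosen.append(i)
    return np.sort(np.asarray(chosen, dtype=np.int64))


def digest(
    genome: Mapping[str, str],
    profile: MethylationProfile,
    enzyme: EnzymeSpec = MSPJI,
    config: SimConfig | None = None,
    sites: Sequence[MotifSite] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Digest ``config.n_copies`` copies of the genome.

    On each copy every site is methylated independently with its profile
    fraction and, if methylated, cut with probability digestion_prob.
    Fragments are the maximal filled-in intervals between consecutive cuts
    and contig ends; only fragments with two enzymatic boundaries and at
    least 1 bp of duplex are ligatable.
    """
    if config is None:
        config = SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if sites is None:
        sites = scan_motifs(genome, enzyme, enzyme.recognition)

    min_ligatable = 2 * enzyme.overhang + 1
    fragments: list[Fragment] = []

    # per-chromosome site arrays
    by_chrom: dict[str, list[int]] = {}
    for idx, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(idx)

    for chrom, seq in genome.items():
        n = len(str(seq))
        idxs = by_chrom.get(chrom, [])
        # order sites by cut position along the chromosome
        idxs = sorted(idxs, key=lambda i: sites[i].fragment_right_start)
        k = len(idxs)
        fracs = np.array([profile.fraction_of(sites[i]) for i in idxs])
        usable = np.array([sites[i].in_bounds for i in idxs], dtype=bool)
        fp = np.array([sites[i].footprint for i in idxs], dtype=np.int64).reshape(k, 2)
        zone = np.array([sites[i].overhang_interval for i in idxs], dtype=np.int64).reshape(k, 2)
        r_start = np.array([sites[i].fragment_right_start for i in idxs], dtype=np.int64)
        l_end = np.array([sites[i].fragment_left_end for i in idxs], dtype=np.int64)

        for copy_id in range(config.n_copies):
            if k:
                cut_mask = (
                    usable
                    & (rng.random(k) < fracs)
                    & (rng.random(k) < config.digestion_prob)
                )
                cand = np.flatnonzero(cut_mask)
                chosen = _select_cuts(cand, fp[:, 0], fp[:, 1],
                                      zone[:, 0], zone[:, 1], enzyme.overhang, rng)
            else:
                chosen = np.array([], dtype=np.int64)

            bounds_start = np.concatenate([[0], r_start[chosen]])
            bounds_end = np.concatenate([l_end[chosen], [n]])
            left_src = [None] + [idxs[int(c)] for c in chosen]
            right_src = [idxs[int(c)] for c in chosen] + [None]
            for j in range(len(bounds_start)):
                a, b = int(bounds_start[j]), int(bounds_end[j])
                if b - a < 1:
                    continue
                ligatable = (
                    left_src[j] is not None
                    and right_src[j] is not None
                    and b - a >= min_ligatable
                )
                fragments.append(
                    Fragment(chrom, a, b, left_src[j], right_src[j], copy_id, ligatable)
                )
    return fragments


# ---------------------------------------------------------------------------
# sequencing


def fragments_to_reads(
    genome: Mapping[str, str],
    fragments: Iterable[Fragment],
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[ReadPair]:
    """Sequence ligatable fragments as error-free paired-end reads.

    Read 1 is the top-strand prefix of the insert, read 2 the bottom-strand
    prefix from the right end (5' base at insert end - 1); both are
    truncated to the read length.  A fraction ``adapter_dimer_rate`` of
    pairs is replaced by 4-bp random inserts with no genomic origin, and
    optional insert_min/insert_max size selection is applied first.
    """
    if config is None:
        config = SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length

    pairs: list[ReadPair] = []
    i = 0
    for frag in fragments:
        if not frag.ligatable:
            continue
        if config.insert_min is not None and frag.length < config.insert_min:
            continue
        if config.insert_max is not None and frag.length > config.insert_max:
            continue
        i += 1
        if rng.random() < config.adapter_dimer_rate:
            insert = "".join(BASES[b] for b in rng.integers(0, 4, size=4))
            pairs.append(
                ReadPair(f"dimer_{i}", insert, reverse_complement(insert),
                         None, 0, 4, 4, is_dimer=True)
            )
            continue
        seq = str(genome[frag.chrom]).upper()
        insert = seq[frag.start:frag.end]
        r1 = insert[:rl]
        r2 = reverse_complement(insert)[:rl]
        if config.error_rate > 0.0:
            r1 = _mutate(r1, config.error_rate, rng)
            r2 = _mutate(r2, config.error_rate, rng)
        pairs.append(
            ReadPair(f"frag_{i}_{frag.chrom}_{frag.start}_{frag.end}",
                     r1, r2, frag.chrom, frag.start, frag.end, frag.length)
        )
    return pairs


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def palindromic_insert_length(enzyme: EnzymeSpec = MSPJI) -> int:
    """Insert excised by symmetric digestion of a fully methylated CpG.

    Places a YNCGNR palindrome (complementary CGNR motifs on both strands)
    at the center of a 200-bp sequence with no other sites and digests with
    probability 1; the central fragment between the two cuts is the
    canonical insert (32 bp for the default 13/17 geometry).
    """
    seq = ["A"] * 200
    for i, b in zip(range(98, 104), "TACGAG"):  # Y N C G N R, mC fwd @100
        seq[i] = b
    genome = {"chrP": "".join(seq)}
    sites = scan_motifs(genome, enzyme, enzyme.analysis_pattern)
    profile = generate_profile(sites, mode="all_methylated")
    cfg = SimConfig(n_copies=1, digestion_prob=1.0, adapter_dimer_rate=0.0, seed=0)
    frags = digest(genome, profile, enzyme, cfg, sites=sites)
    lig = [f.length for f in frags if f.ligatable]
    if len(lig) != 1:
        raise RuntimeError(f"expected one ligatable central fragment, got {lig}")
    return lig[0]


def minimum_flanking_insert(enzyme: EnzymeSpec = MSPJI) -> int:
    """Shortest ligatable insert when a second recognition site immediately
    flanks the first cut's 4-nt overhang.

    Enumerates both orientations of the first motif and both orientations of
    a second motif placed with its near edge abutting the duplex end of the
    first cut's overhang, digests each configuration completely, and returns
    the minimum ligatable fragment length over all configurations that yield
    one (21 bp for the default geometry: interleaved orientation pairs
    cannot both cut, tandem pairs leave cut_near + cut_far - overhang + 4).
    """
    # motif instantiations whose CpG does not create the complementary site
    # on an all-A background: CGAG has no Y one base left of the C; TACG is
    # followed by a forced C so the top-strand CG lacks a purine at +3
    best: int | None = None
    L = 400
    for first in (FORWARD, REVERSE):
        for second in (FORWARD, REVERSE):
            seq = ["A"] * L

            def place(orient: str, motif_start: int) -> None:
                if orient == FORWARD:
                    for i, b in zip(range(motif_start, motif_start + 4), "CGAG"):
                        seq[i] = b
                else:
                    for i, b in zip(range(motif_start, motif_start + 4), "TACG"):
                        seq[i] = b
                    seq[motif_start + 5] = "C"  # break the CGNR on the top strand

            if first == FORWARD:
                p = 150
                place(first, p)
                overhang_end = p + enzyme.cut_far  # duplex resumes here
                place(second, overhang_end)
            else:
                r = 250  # reverse mC position; motif occupies [r-3, r+1)
                place(first, r - 3)
                # duplex left of the overhang ends at r - cut_far (half-open);
                # the flanking motif's 4-bp interval must end exactly there
                place(second, r - enzyme.cut_far - 3)
            genome = {"chrF": "".join(seq)}
            sites = scan_motifs(genome, enzyme, enzyme.analysis_pattern)
            profile = generate_profile(sites, mode="all_methylated")
            cfg = SimConfig(n_copies=1, digestion_prob=1.0,
                            adapter_dimer_rate=0.0, seed=0)
            frags = digest(genome, profile, enzyme, cfg, sites=sites)
            for f in frags:
                if f.ligatable and (best is None or f.length < best):
                    best = f.length
    if best is None:
        raise RuntimeError("no flanking configuration produced a ligatable insert")
    return best


def insert_length_histogram(items: Iterable) -> dict[int, int]:
    """Multiset of insert lengths from fragments, read pairs, or ints."""
    hist: dict[int, int] = {}
    for it in items:
        if isinstance(it, Fragment):
            length = it.length
        elif isinstance(it, ReadPair):
            length = it.insert_len
        else:
            length = int(it)
        hist[length] = hist.get(length, 0) + 1
    return dict(sorted(hist.items()))
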