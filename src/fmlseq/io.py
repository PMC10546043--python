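"""File formats: FASTA/FASTQ via Biopython, SAM via pysam, BED/TSV tables.

Conventions: BED and all internal coordinates are 0-based half-open on the
top strand; SAM's 1-based POS is converted at the boundary.  All tabular
outputs are plain TSV so a pipeline run is fully text-based.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enzyme import FORWARD, MotifSite, Region
from .simulate import Fragment, MethylationProfile, ReadPair

SITE_COLUMNS = ["chrom", "start", "end", "strand", "countable_start"]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def write_fastq_pair(pairs: Sequence[ReadPair], path_r1, path_r2) -> None:
    def records(which: int):
        for p in pairs:
            seq = p.seq1 if which == 1 else p.seq2
            rec = SeqRecord(Seq(seq), id=p.name, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    with _open_text(path_r1, "wt") as fh:
        SeqIO.write(records(1), fh, "fastq")
    with _open_text(path_r2, "wt") as fh:
        SeqIO.write(records(2), fh, "fastq")


# ---------------------------------------------------------------------------
# truth SAM


def write_truth_sam(pairs: Sequence[ReadPair], genome: Mapping[str, str], path) -> None:
    """Ground-truth alignments for simulated pairs (adapter dimers unmapped).

    Read 1 aligns forward at the insert start; read 2 aligns reverse with
    its rightmost base at insert end - 1.  Unique truth gets MAPQ 60.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": name, "LN": len(str(seq))} for name, seq in genome.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for p in pairs:
            tid = out.get_tid(p.chrom) if p.chrom is not None else -1
            for which in (1, 2):
                a = pysam.AlignedSegment(out.header)
                a.query_name = p.name
                a.query_sequence = p.seq1 if which == 1 else p.seq2
                a.query_qualities = pysam.qualitystring_to_array("I" * len(a.query_sequence))
                flag = 0x1 | (0x40 if which == 1 else 0x80)
                if p.is_dimer:
                    a.flag = flag | 0x4 | 0x8
                    a.mapping_quality = 0
                    # dimer insert length is known pre-alignment (adapter
                    # trimming), so the truth record carries it in TLEN
                    a.template_length = p.insert_len
                    out.write(a)
                    continue
                rlen = len(a.query_sequence)
                if which == 1:
                    a.reference_start = p.start
                    a.flag = flag | 0x2 | 0x20
                    a.template_length = p.insert_len
                else:
                    a.reference_start = p.end - rlen
                    a.flag = flag | 0x2 | 0x10
                    a.template_length = -p.insert_len
                a.reference_id = tid
                a.mapping_quality = 60
                a.cigarstring = f"{rlen}M"
                a.next_reference_id = tid
                a.next_reference_start = p.end - rlen if which == 1 else p.start
                out.write(a)


# ---------------------------------------------------------------------------
# BED / TSV tables


def read_bed(path) -> list[Region]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    regions = []
    for i, row in df.iterrows():
        rid = str(row[3]) if df.shape[1] > 3 else f"region_{i}"
        regions.append(Region(str(row[0]), int(row[1]), int(row[2]), rid))
    return regions


def write_bed(regions: Sequence[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


def write_sites(sites: Sequence[MotifSite], path) -> None:
    """Site registry as BED-like TSV: chrom, mc_pos, mc_pos+1, strand,
    countable_start."""
    rows = [
        (s.chrom, s.mc_pos, s.mc_pos + 1, s.strand, s.countable_start)
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites(path, enzyme=None) -> list[MotifSite]:
    from .enzyme import MSPJI, _forward_site, _reverse_site

    if enzyme is None:
        enzyme = MSPJI
    df = pd.read_csv(path, sep="\t")
    L = len(enzyme.recognition)
    big = 10 ** 12  # registry files carry no contig length; trust in-bounds
    sites = []
    for _, row in df.iterrows():
        maker = _forward_site if row.strand == FORWARD else _reverse_site
        sites.append(maker(str(row.chrom), int(row.start), enzyme, L, big))
    return sites


def write_profile(profile: MethylationProfile, path) -> None:
    rows = [(c, p, s, f) for (c, p, s), f in sorted(profile.fractions.items())]
    pd.DataFrame(rows, columns=["chrom", "pos", "strand", "fraction"]).to_csv(
        path, sep="\t", index=False
    )


def read_profile(path) -> MethylationProfile:
    df = pd.read_csv(path, sep="\t")
    return MethylationProfile(
        {(str(r.chrom), int(r.pos), str(r.strand)): float(r.fraction) for r in df.itertuples()}
    )


def write_fragments(fragments: Sequence[Fragment], path) -> None:
    rows = [
        (f.chrom, f.start, f.end, f.copy_id, int(f.ligatable))
        for f in fragments
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "copy", "ligatable"]).to_csv(
        path, sep="\t", index=False
    )


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
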