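"""File IO: FASTA/FASTQ via Biopython, BED/BEDPE/TSV/JSON tables.

All genomic records use 0-based half-open coordinates (BED convention).
Gzipped FASTQ is handled transparently by file extension.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contacts import Loop
from .intervals import Interval, Peak
from .linker import PET, Alignment, AlignedPair, ReadPair, Tag


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


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def write_fastq_pair(read_pairs: Iterable[ReadPair], path1, path2,
                     quality_char: str = "I") -> None:
    """Write paired reads to two FASTQ files (constant quality string)."""
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for rp in read_pairs:
            f1.write(f"@{rp.read_id}/1\n{rp.seq1}\n+\n{quality_char * len(rp.seq1)}\n")
            f2.write(f"@{rp.read_id}/2\n{rp.seq2}\n+\n{quality_char * len(rp.seq2)}\n")


def read_fastq_pair(path1, path2) -> list[ReadPair]:
    with _open_text(path1) as f1, _open_text(path2) as f2:
        recs1 = list(SeqIO.parse(f1, "fastq"))
        recs2 = list(SeqIO.parse(f2, "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError("mate files have different read counts")
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        rid = r1.id.rsplit("/", 1)[0]
        pairs.append(ReadPair(rid, str(r1.seq).upper(), str(r2.seq).upper()))
    return pairs


# ---------------------------------------------------------------------------
# BED / BEDPE / chrom sizes


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path) -> list[Interval]:
    """Read BED3/BED6 into Intervals (score column as float when present)."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 and f[5] in "+-" else None
            out.append(Interval(f[0], int(f[1]), int(f[2]), name, score, strand))
    return out


def write_bed(intervals: Sequence[Interval], path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(
                "\t".join([
                    iv.chrom, str(iv.start), str(iv.end),
                    iv.name or ".",
                    "." if iv.score is None else f"{iv.score:g}",
                    iv.strand or ".",
                ]) + "\n"
            )


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """BED6+1 with the summit coordinate in column 7."""
    with _open_text(path, "wt") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t"
                f"{'.' if p.score is None else f'{p.score:g}'}\t.\t"
                f"{'.' if p.summit is None else p.summit}\n"
            )


def write_pets_bedpe(pets: Sequence[PET], path) -> None:
    """PETs as BEDPE with 1-bp tag intervals."""
    with _open_text(path, "wt") as fh:
        for i, p in enumerate(pets):
            fh.write(
                f"{p.chrom1}\t{p.pos1}\t{p.pos1 + 1}\t"
                f"{p.chrom2}\t{p.pos2}\t{p.pos2 + 1}\t"
                f"{p.read_id or f'pet_{i}'}\t1\t{p.strand1}\t{p.strand2}\n"
            )


def read_pets_bedpe(path) -> list[PET]:
    pets = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            strand1 = f[8] if len(f) > 8 else "+"
            strand2 = f[9] if len(f) > 9 else "+"
            name = f[6] if len(f) > 6 else None
            pets.append(
                PET(f[0], int(f[1]), strand1, f[3], int(f[4]), strand2, name).canonical()
            )
    return pets


def write_loops_bedpe(loops: Sequence[Loop], path) -> None:
    with _open_text(path, "wt") as fh:
        for i, lp in enumerate(loops):
            fh.write(
                f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}\t"
                f"{lp.name or f'loop_{i}'}\t{lp.pet_count}\t.\t.\n"
            )


def read_loops_bedpe(path) -> list[Loop]:
    loops = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            count = int(float(f[7])) if len(f) > 7 and f[7] != "." else 1
            name = f[6] if len(f) > 6 else None
            loops.append(
                Loop(
                    Interval(f[0], int(f[1]), int(f[2])),
                    Interval(f[3], int(f[4]), int(f[5])),
                    pet_count=count, name=name,
                )
            )
    return loops


def write_bedgraph(clusters: Sequence[tuple[Interval, int]], path) -> None:
    """Visual-4C cluster track as bedGraph (value = PET count)."""
    with _open_text(path, "wt") as fh:
        for iv, count in clusters:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{count}\n")


# ---------------------------------------------------------------------------
# External aligned-tag import (real-data interop)


def read_aligned_tags(path, mapq_min: int = 30) -> list[AlignedPair]:
    """Import externally aligned tags from a TSV for PET formation.

    Columns: read_id, mate (1|2), chrom, pos (0-based 5' coordinate),
    strand, mapq. A mate with mapq below ``mapq_min`` is treated as
    multi-mapping; a mate with chrom '*' as unmapped; a missing mate makes
    the pair non-unique. This is the interop path for reads aligned with a
    published aligner upstream.
    """
    mates: dict[str, dict[int, Alignment]] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, mate, chrom, pos, strand, mapq = line.split("\t")[:6]
            if rid not in mates:
                mates[rid] = {}
                order.append(rid)
            if chrom == "*":
                aln = Alignment(None, None, None, "unmapped")
            elif int(mapq) < mapq_min:
                aln = Alignment(None, None, None, "multi", "low mapq")
            else:
                aln = Alignment(chrom, int(pos), strand, "unique")
            mates[rid][int(mate)] = aln
    out = []
    missing = Alignment(None, None, None, "unmapped", "mate missing")
    for rid in order:
        a1 = mates[rid].get(1, missing)
        a2 = mates[rid].get(2, missing)
        t1 = Tag(rid, "", 1, False, True)
        t2 = Tag(rid, "", 2, False, True)
        out.append(AlignedPair(rid, t1, a1, t2, a2))
    return out


def write_stats_json(stats, path) -> None:
    from dataclasses import asdict, is_dataclass

    obj = asdict(stats) if is_dataclass(stats) else dict(stats)
    with _open_text(path, "wt") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
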