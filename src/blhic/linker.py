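"""Bridge-linker read processing: fuzzy linker detection, tag trimming,
exact-match alignment for synthetic genomes, PET formation and library stats.

In two-step proximity ligation a 20-bp biotinylated bridge linker sits at
the ligation junction, so each sequencing read is (genomic tag)(linker)(...).
Detection uses the bitap bit-parallel fuzzy search under a Hamming
(substitution-only) distance, with both half-linkers and their reverse
complements as patterns; the genomic prefix upstream of the leftmost hit
becomes the tag. Pairs of uniquely aligned tags become paired-end tags
(PETs), deduplicated on exact coordinates, with cis/trans accounting.

Real-data interop: externally aligned tags can be imported as a TSV
(``blhic.io.read_aligned_tags``) and fed straight to :func:`form_pets`;
the built-in aligner is an exact matcher intended for synthetic genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .intervals import Peak

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Two-step half-linker search sequences and the one-step full linker.
HALF_LINKER_A = "ACGCGATATCTTATC"
HALF_LINKER_B = "AGTCAGATAAGATAT"
FULL_LINKER_ONE_STEP = "AGCTGAGGGATCCCTCAGCT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LinkerSet:
    """Linker sequences and matching tolerances for one library mode."""

    mode: Literal["two-step", "one-step"] = "two-step"
    half_a: str = HALF_LINKER_A
    half_b: str = HALF_LINKER_B
    full_one_step: str = FULL_LINKER_ONE_STEP
    max_mismatch: int = 1
    min_tag_len: int = 15

    @property
    def search_patterns(self) -> list[tuple[str, str]]:
        """Ordered (pattern_id, sequence) pairs; leftmost hit wins, ties by
        this order."""
        if self.mode == "two-step":
            pats = [
                ("A", self.half_a),
                ("B", self.half_b),
                ("rcA", revcomp(self.half_a)),
                ("rcB", revcomp(self.half_b)),
            ]
        elif self.mode == "one-step":
            pats = [("full", self.full_one_step), ("rcFull", revcomp(self.full_one_step))]
        else:
            raise ValueError(f"unknown linker mode {self.mode!r}")
        seen: set[str] = set()
        out = []
        for pid, seq in pats:  # the one-step linker is its own revcomp
            if seq not in seen:
                seen.add(seq)
                out.append((pid, seq))
        return out


@dataclass(frozen=True)
class LinkerHit:
    pattern_id: str
    position: int
    mismatches: int


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str


@dataclass(frozen=True)
class Tag:
    """The genomic portion of one mate after linker trimming."""

    read_id: str
    sequence: str
    mate: int
    linker_found: bool
    usable: bool
    hit: Optional[LinkerHit] = None


@dataclass(frozen=True)
class Alignment:
    chrom: Optional[str]
    pos: Optional[int]  # 5'-most genomic coordinate of the tag
    strand: Optional[str]
    status: Literal["unique", "multi", "unmapped"]
    reason: Optional[str] = None


@dataclass(frozen=True)
class PET:
    """One chromatin contact: two mapped tag anchors in canonical order."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    read_id: Optional[str] = None

    @property
    def cis(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def category(self) -> str:
        return "cis" if self.cis else "trans"

    @property
    def coords(self) -> tuple:
        return (self.chrom1, self.pos1, self.strand1, self.chrom2, self.pos2, self.strand2)

    def canonical(self) -> "PET":
        if (self.chrom2, self.pos2) < (self.chrom1, self.pos1):
            return PET(
                self.chrom2, self.pos2, self.strand2,
                self.chrom1, self.pos1, self.strand1, self.read_id,
            )
        return self


@dataclass
class LibraryStats:
    total_read_pairs: int
    pairs_with_linker: int
    unique_pets: int
    duplicate_rate: float
    cis_unique: int
    trans_unique: int
    cis_trans_ratio: float
    unique_pet_fraction: float
    #: exact partition of all input pairs by fate
    partition: dict = field(default_factory=dict)


def bitap_search(text: str, pattern: str, max_mismatch: int = 1) -> Optional[LinkerHit]:
    """Leftmost occurrence of ``pattern`` in ``text`` with <= ``max_mismatch``
    substitutions (Hamming distance; no indels), via bit-parallel bitap.

    Among qualifying positions the smallest start position wins regardless of
    mismatch count further right; the reported mismatch count is the minimum
    at that position. Bases outside ACGT (e.g. N) never match.
    """
    m = len(pattern)
    if m == 0:
        raise ValueError("empty pattern")
    if m > 64:
        raise ValueError(
            "pattern longer than 64 bases exceeds machine-word capacity; "
            "split the pattern into chunks and search each"
        )
    if not (0 <= max_mismatch <= 3):
        raise ValueError("max_mismatch must be in [0, 3]")
    if len(text) < m:
        return None
    masks: dict[str, int] = {}
    for i, ch in enumerate(pattern):
        masks[ch] = masks.get(ch, 0) | (1 << i)
    goal = 1 << (m - 1)
    k = max_mismatch
    if k == 1:
        # unrolled two-row recurrence (the common "-e 1" case)
        r0 = r1 = 0
        get = masks.get
        for j, ch in enumerate(text):
            pm = get(ch, 0)
            sub = (r0 << 1) | 1
            r0 = sub & pm
            r1 = (((r1 << 1) | 1) & pm) | sub
            if (r0 | r1) & goal:
                d = 0 if r0 & goal else 1
                return LinkerHit("", j - m + 1, d)
        return None
    rows = [0] * (k + 1)
    get = masks.get
    for j, ch in enumerate(text):
        pm = get(ch, 0)
        prev = 0
        for d in range(k + 1):
            old = rows[d]
            cur = ((old << 1) | 1) & pm
            if d > 0:
                cur |= (prev << 1) | 1  # substitution consumes ch
            rows[d] = cur
            prev = old
        if rows[k] & goal:
            for d in range(k + 1):
                if rows[d] & goal:
                    return LinkerHit("", j - m + 1, d)
    return None


def _hamming_leq(a: str, b: str, k: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > k:
                return False
    return True


def _suffix_overlap(seq: str, pattern: str, min_overlap: int = 8, max_mm: int = 1
                    ) -> Optional[tuple[int, int]]:
    """Longest pattern *prefix* (>= min_overlap) matching the read end with
    <= max_mm mismatches; returns (trim position, mismatches) or None."""
    top = min(len(pattern) - 1, len(seq))
    for ov in range(top, min_overlap - 1, -1):
        if _hamming_leq(seq[-ov:], pattern[:ov], max_mm):
            mm = sum(a != b for a, b in zip(seq[-ov:], pattern[:ov]))
            return len(seq) - ov, mm
    return None


def _trim_one(seq: str, mate: int, read_id: str, linkers: LinkerSet) -> Tag:
    if not seq:
        return Tag(read_id, "", mate, False, False)
    best: Optional[LinkerHit] = None
    for pid, pat in linkers.search_patterns:
        h = bitap_search(seq, pat, linkers.max_mismatch)
        if h is not None and (best is None or h.position < best.position):
            best = LinkerHit(pid, h.position, h.mismatches)
    if best is None:
        # junction may sit at the read end: check read-end overlap with each
        # pattern's prefix (>= 8 bases, <= 1 mismatch)
        for pid, pat in linkers.search_patterns:
            res = _suffix_overlap(seq, pat)
            if res is not None and (best is None or res[0] < best.position):
                best = LinkerHit(pid, res[0], res[1])
    if best is None:
        return Tag(read_id, seq, mate, False, len(seq) >= linkers.min_tag_len)
    tag_seq = seq[: best.position]
    return Tag(
        read_id, tag_seq, mate, True,
        len(tag_seq) >= linkers.min_tag_len, best,
    )


def detect_and_trim(pair: ReadPair, linkers: LinkerSet) -> tuple[Tag, Tag, dict]:
    """Trim the bridge linker from both mates of a read pair.

    Each mate keeps the bases upstream of the leftmost linker hit (whole read
    if none); tags shorter than ``min_tag_len`` are marked unusable. Returns
    the two tags plus a per-pair summary.
    """
    t1 = _trim_one(pair.seq1, 1, pair.read_id, linkers)
    t2 = _trim_one(pair.seq2, 2, pair.read_id, linkers)
    summary = {
        "read_id": pair.read_id,
        "linker_found": t1.linker_found or t2.linker_found,
        "hits": {1: t1.hit, 2: t2.hit},
    }
    return t1, t2, summary


_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


class GenomeIndex:
    """Exact-match index over named sequences.

    A sorted array of k-mer codes (k = 16 by default) seeds lookups; each
    candidate is verified by full-length string comparison, so results are
    exact full-length matches. Queries shorter than k fall back to a direct
    substring scan.
    """

    def __init__(self, genome: dict[str, str], k: int = 16):
        if k < 4 or k > 31:
            raise ValueError("k must be in [4, 31]")
        self.k = k
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._kmers: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        for chrom, seq in self.genome.items():
            n = len(seq)
            if n < k:
                self._kmers[chrom] = np.empty(0, dtype=np.int64)
                self._order[chrom] = np.empty(0, dtype=np.int64)
                continue
            codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            m = n - k + 1
            vals = np.zeros(m, dtype=np.int64)
            for j in range(k):
                vals = vals * 4 + codes[j : j + m]
            bad = np.cumsum(np.concatenate(([0], (codes >= 4).astype(np.int64))))
            valid = (bad[k:] - bad[:-k]) == 0
            pos = np.flatnonzero(valid)
            vals = vals[pos]
            order = np.argsort(vals, kind="stable")
            self._kmers[chrom] = vals[order]
            self._order[chrom] = pos[order]

    def _encode(self, s: str) -> Optional[int]:
        v = 0
        for ch in s:
            c = _CODE[ord(ch)]
            if c >= 4:
                return None
            v = v * 4 + int(c)
        return v

    def _find_forward(self, query: str, limit: int) -> list[tuple[str, int]]:
        hits: list[tuple[str, int]] = []
        if len(query) < self.k:
            for chrom, seq in self.genome.items():
                i = seq.find(query)
                while i != -1:
                    hits.append((chrom, i))
                    if len(hits) >= limit:
                        return hits
                    i = seq.find(query, i + 1)
            return hits
        key = self._encode(query[: self.k])
        if key is None:
            return hits
        for chrom, seq in self.genome.items():
            kmers = self._kmers[chrom]
            lo = int(np.searchsorted(kmers, key, side="left"))
            hi = int(np.searchsorted(kmers, key, side="right"))
            for p in self._order[chrom][lo:hi]:
                p = int(p)
                if seq[p : p + len(query)] == query:
                    hits.append((chrom, p))
                    if len(hits) >= limit:
                        return hits
        return hits

    def find(self, query: str, limit: int = 2) -> list[tuple[str, int, str]]:
        """Up to ``limit`` exact occurrences of ``query`` on either strand,
        as (chrom, start_of_match, strand)."""
        query = query.upper()
        out = [(c, p, "+") for c, p in self._find_forward(query, limit)]
        rc = revcomp(query)
        if rc != query and len(out) < limit:
            out += [(c, p, "-") for c, p in self._find_forward(rc, limit - len(out))]
        return out


def align_tag(tag: Tag, index: GenomeIndex) -> Alignment:
    """Exact-match alignment of a tag against both strands.

    A single full-length exact locus is ``unique``; its position is the
    5'-most genomic coordinate of the tag (leftmost base for +, rightmost
    for -). Multiple loci give ``multi``; none, ``unmapped``.
    """
    if not tag.usable:
        return Alignment(None, None, None, "unmapped", "tag unusable")
    hits = index.find(tag.sequence, limit=2)
    if not hits:
        return Alignment(None, None, None, "unmapped", "no exact match")
    if len(hits) > 1:
        return Alignment(None, None, None, "multi")
    chrom, start, strand = hits[0]
    pos = start if strand == "+" else start + len(tag.sequence) - 1
    return Alignment(chrom, pos, strand, "unique")


@dataclass(frozen=True)
class AlignedPair:
    """Both mates of one read pair after trimming and alignment."""

    read_id: str
    tag1: Tag
    aln1: Alignment
    tag2: Tag
    aln2: Alignment


def form_pets(
    pairs: Sequence[AlignedPair],
    dedup: bool = True,
    self_ligation_cutoff: int = 1000,
) -> tuple[list[PET], LibraryStats]:
    """Join uniquely aligned mate pairs into canonical PETs with stats.

    Pair fates form an exact partition (recorded in ``stats.partition``):
    ``unusable`` (a tag below min length), ``nonunique`` (a mate unmapped or
    multi-mapping), ``self_ligation`` (cis anchors closer than the cutoff),
    ``duplicate`` (identical coordinates+strands of both ends; first
    occurrence kept), and ``unique_pet``.
    """
    pets: list[PET] = []
    seen: set[tuple] = set()
    part = {"unusable": 0, "nonunique": 0, "self_ligation": 0, "duplicate": 0,
            "unique_pet": 0}
    n_linker = 0
    cis = trans = 0
    for pr in pairs:
        if pr.tag1.linker_found or pr.tag2.linker_found:
            n_linker += 1
        if not (pr.tag1.usable and pr.tag2.usable):
            part["unusable"] += 1
            continue
        if pr.aln1.status != "unique" or pr.aln2.status != "unique":
            part["nonunique"] += 1
            continue
        pet = PET(
            pr.aln1.chrom, pr.aln1.pos, pr.aln1.strand,
            pr.aln2.chrom, pr.aln2.pos, pr.aln2.strand, pr.read_id,
        ).canonical()
        if pet.cis and abs(pet.pos2 - pet.pos1) < self_ligation_cutoff:
            part["self_ligation"] += 1
            continue
        if dedup:
            if pet.coords in seen:
                part["duplicate"] += 1
                continue
            seen.add(pet.coords)
        part["unique_pet"] += 1
        if pet.cis:
            cis += 1
        else:
            trans += 1
        pets.append(pet)
    total = len(pairs)
    n_unique = len(pets)
    n_dup = part["duplicate"]
    stats = LibraryStats(
        total_read_pairs=total,
        pairs_with_linker=n_linker,
        unique_pets=n_unique,
        duplicate_rate=n_dup / (n_dup + n_unique) if (n_dup + n_unique) else 0.0,
        cis_unique=cis,
        trans_unique=trans,
        cis_trans_ratio=cis / trans if trans else float("inf"),
        unique_pet_fraction=n_unique / total if total else 0.0,
        partition=part,
    )
    return pets, stats


def process_library(
    read_pairs: Sequence[ReadPair],
    linkers: LinkerSet,
    genome: dict[str, str] | GenomeIndex,
    dedup: bool = True,
    self_ligation_cutoff: int = 1000,
) -> tuple[list[PET], LibraryStats, list[AlignedPair]]:
    """Full trim -> align -> PET pipeline over an in-memory library."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    aligned: list[AlignedPair] = []
    for pair in read_pairs:
        t1, t2, _ = detect_and_trim(pair, linkers)
        aligned.append(
            AlignedPair(pair.read_id, t1, align_tag(t1, index), t2, align_tag(t2, index))
        )
    pets, stats = form_pets(aligned, dedup=dedup, self_ligation_cutoff=self_ligation_cutoff)
    return pets, stats, aligned


def call_peaks_simple(
    tags: Sequence[tuple[str, int, str]],
    chrom_sizes: dict[str, int],
    extension: int = 250,
    threshold: int = 5,
) -> list[Peak]:
    """Depth-threshold peak calling over tag 5' positions.

    Each tag is extended ``extension`` bp in its strand direction; maximal
    runs of per-base depth >= ``threshold`` become peaks, with the summit at
    the leftmost maximum. Peaks carry their max depth as score (a q-value
    surrogate when ranked).
    """
    if extension <= 0:
        raise ValueError("extension must be > 0")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, strand in tags:
        by_chrom.setdefault(chrom, []).append((pos, strand))
    peaks: list[Peak] = []
    for chrom in sorted(by_chrom):
        size = chrom_sizes[chrom]
        delta = np.zeros(size + 1, dtype=np.int64)
        for pos, strand in by_chrom[chrom]:
            if strand == "-":
                s, e = max(0, pos - extension + 1), min(size, pos + 1)
            else:
                s, e = max(0, pos), min(size, pos + extension)
            if s < e:
                delta[s] += 1
                delta[e] -= 1
        depth = np.cumsum(delta[:-1])
        above = depth >= threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
        for s, e in zip(edges[::2], edges[1::2]):
            seg = depth[s:e]
            summit = int(s + np.argmax(seg))
            peaks.append(
                Peak(chrom, int(s), int(e), score=float(seg.max()), summit=summit)
            )
    return peaks
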