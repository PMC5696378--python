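"""Ground-truth synthetic data: genomes, planted sites and loops, two-step
ligation junction molecules, and paired-end reads with known provenance.

The generator emulates a bridge-linker proximity-ligation library on a small
random genome so the whole pipeline is testable without downloads:

* an i.i.d. random genome at a chosen GC content, optionally with extra
  enzyme recognition sites planted near protein-binding sites (the premise
  that a GC-rich cutter lands close to active regions),
* planted stranded binding sites and loops pairing sites on the same
  chromosome (log-uniform anchor distances, configurable convergent-motif
  fraction),
* ligation events: signal events join restriction-fragment ends adjacent to
  the two anchors of a planted loop; noise events join two uniformly chosen
  cut sites (cross-chromosome with probability ``trans_fraction``),
* junction molecules ``arm + bridge + arm`` with each arm's cut end at the
  junction, random left/right arm placement and bridge insertion
  orientation (exercising all four linker search patterns), and sonication
  arm lengths uniform in [min_arm, max_arm] (arms are not truncated at
  fragment boundaries, emulating partial digestion and keeping arm lengths
  independent of event type),
* paired reads from the two molecule ends with i.i.d. substitution errors,
  optional duplicate molecules, and a full per-read provenance record.

Everything derives deterministically from a single master seed via labeled
sub-streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import kinetics
from .digestion import ENZYMES, digest
from .intervals import Interval
from .linker import (
    FULL_LINKER_ONE_STEP,
    HALF_LINKER_A,
    HALF_LINKER_B,
    ReadPair,
    revcomp,
)

SITE_CLASSES = ("CTCF-like", "RNAPII-like")


@dataclass
class SimConfig:
    """Study conditions of the synthetic library (defaults are the desk-scale
    reference conditions: 1 Mb genome, 200 sites, 50 loops, 50 000 read
    pairs at 1% substitution error with 10% noise events)."""

    genome_length: int = 1_000_000
    n_chroms: int = 2
    gc_content: float = 0.5
    n_sites: int = 200
    site_width: int = 20
    site_min_gap: int = 3000
    site_cut_bias: float = 1.0
    site_bias_window: int = 200
    n_loops: int = 50
    loop_dist_min: int = 10_000
    loop_dist_max: int = 200_000
    convergent_fraction: float = 0.7
    pairs_signal: int = 45_000
    pairs_noise: int = 5_000
    trans_fraction: float = 0.5
    read_length: int = 100
    error_rate: float = 0.01
    linker_mode: str = "two-step"
    duplicate_rate: float = 0.0
    min_arm: int = 50
    max_arm: int = 500
    enzyme: str = "HaeIII"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "convergent_fraction", "trans_fraction",
                     "error_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        if self.n_sites < 2 * self.n_loops:
            raise ValueError("need n_sites >= 2 * n_loops")
        if self.site_cut_bias < 1:
            raise ValueError("site_cut_bias must be >= 1")
        if not (0 < self.min_arm <= self.max_arm):
            raise ValueError("need 0 < min_arm <= max_arm")
        if self.linker_mode not in ("two-step", "one-step"):
            raise ValueError("linker_mode must be 'two-step' or 'one-step'")
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.n_chroms < 1:
            raise ValueError("n_chroms must be >= 1")
        if self.n_chroms == 1 and self.trans_fraction > 0:
            raise ValueError("trans_fraction > 0 requires n_chroms >= 2")

    @property
    def bridge(self) -> str:
        """The junction insert: mate 1 reads into half-linker A, mate 2 into
        half-linker B (one-step: the palindromic full linker)."""
        if self.linker_mode == "two-step":
            return HALF_LINKER_A + revcomp(HALF_LINKER_B)
        return FULL_LINKER_ONE_STEP

    def chrom_sizes(self) -> dict[str, int]:
        base = self.genome_length // self.n_chroms
        sizes = {f"chr{i + 1}": base for i in range(self.n_chroms)}
        sizes[f"chr{self.n_chroms}"] += self.genome_length - base * self.n_chroms
        return sizes


@dataclass
class TruthLoop:
    loop_id: int
    anchor1: Interval
    anchor2: Interval


@dataclass
class MateTruth:
    chrom: str
    pos: int           # 5'-most coordinate of the genomic tag
    strand: str
    arm_len: int
    linker_offset: Optional[int]            # bridge start within the read
    pattern_offsets: list = field(default_factory=list)  # (pattern_id, offset)
    errors: list = field(default_factory=list)           # error positions in read

    @property
    def tag_len(self) -> int:
        return self.linker_offset if self.linker_offset is not None else self.arm_len

    @property
    def errors_in_tag(self) -> int:
        return sum(1 for e in self.errors if e < self.tag_len)


@dataclass
class ReadProvenance:
    event_id: int
    event_type: str            # signal | noise
    loop_id: Optional[int]
    category: str              # cis | trans
    duplicate_of: Optional[str]
    mate1: MateTruth
    mate2: MateTruth


@dataclass
class GroundTruth:
    sites: list[Interval]
    loops: list[TruthLoop]
    loop_counts: dict = field(default_factory=dict)   # loop_id -> event count
    provenance: dict = field(default_factory=dict)    # read_id -> ReadProvenance
    redraws: int = 0


@dataclass
class Junction:
    event_id: int
    event_type: str
    loop_id: Optional[int]
    category: str
    molecule: str
    mate1: MateTruth
    mate2: MateTruth


@dataclass
class SimResult:
    config: SimConfig
    genome: dict
    chrom_sizes: dict
    truth: GroundTruth
    read_pairs: list


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("layout", "genome", "events", "reads")
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


# ---------------------------------------------------------------------------
# Genome and truth layout


def _recognition_prob(recognition: str, gc: float) -> float:
    p = 1.0
    for ch in recognition:
        p *= gc / 2 if ch in "GC" else (1 - gc) / 2
    return p


def layout_sites_and_loops(
    chrom_sizes: dict[str, int], config: SimConfig, rng: np.random.Generator
) -> GroundTruth:
    """Place non-overlapping stranded sites and pair them into loops.

    Sites keep a minimum gap; loop anchor distances are drawn log-uniformly
    from [loop_dist_min, loop_dist_max] and matched to the nearest free site.
    Loop anchor strand pairs are convergent (+,-) with probability
    ``convergent_fraction``; the remainder splits evenly between divergent
    and identical.
    """
    chroms = list(chrom_sizes)
    n_per = {c: config.n_sites // len(chroms) for c in chroms}
    n_per[chroms[0]] += config.n_sites - sum(n_per.values())
    margin = config.max_arm + config.read_length
    sites: list[Interval] = []
    site_idx_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for chrom in chroms:
        k = n_per[chrom]
        if k == 0:
            continue
        length = chrom_sizes[chrom]
        slot = config.site_width + config.site_min_gap
        free = length - 2 * margin - k * slot
        if free <= 0:
            raise ValueError(f"genome too small to place {k} sites on {chrom}")
        offs = np.sort(rng.uniform(0, free, size=k))
        for i in range(k):
            start = int(margin + offs[i] + i * slot)
            site_idx_by_chrom[chrom].append(len(sites))
            cls = SITE_CLASSES[int(rng.integers(len(SITE_CLASSES)))]
            sites.append(Interval(chrom, start, start + config.site_width, name=cls))
    # pair disjoint sites into loops, chrom by chrom proportional to sites
    loops: list[TruthLoop] = []
    strands: dict[int, str] = {}
    n_left = config.n_loops
    order = sorted(chroms, key=lambda c: -len(site_idx_by_chrom[c]))
    for ci, chrom in enumerate(order):
        avail = list(site_idx_by_chrom[chrom])
        quota = min(n_left, len(avail) // 2) if ci == len(order) - 1 else min(
            round(config.n_loops * len(avail) / max(config.n_sites, 1)),
            n_left, len(avail) // 2,
        )
        for _ in range(quota):
            if len(avail) < 2:
                break
            i1 = avail[int(rng.integers(len(avail)))]
            d = math.exp(rng.uniform(math.log(config.loop_dist_min),
                                     math.log(config.loop_dist_max)))
            target = sites[i1].center + (d if rng.random() < 0.5 else -d)
            others = [i for i in avail if i != i1]
            i2 = min(others, key=lambda i: abs(sites[i].center - target))
            avail.remove(i1)
            avail.remove(i2)
            a, b = (i1, i2) if sites[i1].start <= sites[i2].start else (i2, i1)
            u = rng.random()
            if u < config.convergent_fraction:
                strands[a], strands[b] = "+", "-"
            elif u < config.convergent_fraction + (1 - config.convergent_fraction) / 2:
                strands[a], strands[b] = "-", "+"
            else:
                s = "+" if rng.random() < 0.5 else "-"
                strands[a] = strands[b] = s
            loops.append(TruthLoop(len(loops), sites[a], sites[b]))
            n_left -= 1
        if n_left == 0:
            break
    if n_left > 0:
        raise ValueError("could not place all loops; loosen distance range")
    final_sites = []
    for i, s in enumerate(sites):
        strand = strands.get(i) or ("+" if rng.random() < 0.5 else "-")
        final_sites.append(Interval(s.chrom, s.start, s.end, s.name, None, strand))
    # re-point loop anchors at the stranded site objects
    loops = [
        TruthLoop(lp.loop_id,
                  final_sites[sites.index(lp.anchor1)],
                  final_sites[sites.index(lp.anchor2)])
        for lp in loops
    ]
    return GroundTruth(sites=final_sites, loops=loops)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_genome(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    sites: Optional[list[Interval]] = None,
) -> tuple[dict[str, str], dict[str, int]]:
    """Generate an i.i.d. random genome at the configured GC content.

    With ``site_cut_bias > 1`` and ``sites`` given, extra enzyme recognition
    occurrences are planted within +/- ``site_bias_window`` of each site so
    that local site density is about ``site_cut_bias`` times background.
    Byte-identical across runs for the same seed.
    """
    rng = rng if rng is not None else _rngs(config.seed)["genome"]
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    sizes = config.chrom_sizes()
    raw: dict[str, bytearray] = {}
    for chrom, size in sizes.items():
        idx = rng.choice(4, size=size, p=probs)
        raw[chrom] = bytearray(_BASES[idx].tobytes())
    if config.site_cut_bias > 1 and sites:
        rec = ENZYMES[config.enzyme].recognition.encode()
        w = config.site_bias_window
        p_hit = _recognition_prob(ENZYMES[config.enzyme].recognition, gc)
        lam = (config.site_cut_bias - 1) * 2 * w * p_hit
        for site in sites:
            buf = raw[site.chrom]
            for _ in range(int(rng.poisson(lam))):
                lo = max(site.center - w, 0)
                hi = min(site.center + w, len(buf)) - len(rec)
                if hi <= lo:
                    continue
                at = int(rng.integers(lo, hi))
                buf[at : at + len(rec)] = rec
    genome = {c: b.decode() for c, b in raw.items()}
    return genome, sizes


def plant_sites_and_loops(
    chrom_sizes: dict[str, int], config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Public wrapper: lay out ground-truth sites and loops for a genome."""
    rng = rng if rng is not None else _rngs(config.seed)["layout"]
    return layout_sites_and_loops(chrom_sizes, config, rng)


# ---------------------------------------------------------------------------
# Ligation events


def _nearest_cut(cuts: np.ndarray, pos: int) -> Optional[int]:
    if cuts.size == 0:
        return None
    i = int(np.searchsorted(cuts, pos))
    cands = [c for c in (i - 1, i) if 0 <= c < cuts.size]
    return int(min((abs(cuts[c] - pos), cuts[c]) for c in cands)[1])


def _make_arm(
    genome: dict[str, str], chrom: str, cut: int, side: str, length: int
) -> tuple[str, int, int]:
    """Arm sequence extending from ``cut`` leftward or rightward, clipped at
    the chromosome ends. Returns (seq, start, end)."""
    seq = genome[chrom]
    if side == "left":
        s, e = max(0, cut - length), cut
    else:
        s, e = cut, min(len(seq), cut + length)
    return seq[s:e], s, e


def _mate_truth_from_arm(
    chrom: str, start: int, end: int, side: str, read_length: int,
    bridge_len: int, first_pattern: str, second_pattern: str,
) -> MateTruth:
    """Truth for the mate reading this arm from its sonication end.

    Each mate reads from the molecule's outer (sonication) end toward the
    ligation junction, so the tag's 5' coordinate is the arm end away from
    the cut: a 'left' arm (cut at its right edge) reads + strand from
    ``start``; a 'right' arm (cut at its left edge) reads - strand from
    ``end - 1``.
    """
    arm_len = end - start
    if side == "left":
        strand, pos5 = "+", start
    else:
        strand, pos5 = "-", end - 1
    linker_offset = arm_len if arm_len < read_length else None
    patterns: list[tuple[str, int]] = []
    if arm_len < read_length:
        if first_pattern == "full":
            if arm_len + bridge_len <= read_length:
                patterns.append(("full", arm_len))
        else:
            half = bridge_len // 2
            if arm_len + half <= read_length:
                patterns.append((first_pattern, arm_len))
            if arm_len + bridge_len <= read_length:
                patterns.append((second_pattern, arm_len + half))
    return MateTruth(chrom, pos5, strand, arm_len, linker_offset, patterns)


def simulate_ligation_events(
    genome: dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[Junction]:
    """Draw signal and noise ligation events and build junction molecules.

    Signal events join arms at the cut sites nearest the two anchors of a
    uniformly chosen planted loop; noise events join arms at two uniformly
    chosen cut sites (different chromosomes with probability
    ``trans_fraction``). Arm placement around the bridge and the bridge's
    insertion orientation are randomized independently, exercising all
    linker search orientations.
    """
    rng = rng if rng is not None else _rngs(config.seed)["events"]
    enzyme = ENZYMES[config.enzyme]
    fragments, _ = digest(genome, enzyme)
    cuts: dict[str, np.ndarray] = {}
    for chrom in genome:
        bounds = sorted({f.end for f in fragments if f.chrom == chrom} - {len(genome[chrom])})
        cuts[chrom] = np.array(bounds, dtype=np.int64)
    chroms = [c for c in genome if cuts[c].size > 0]
    if not chroms:
        raise ValueError("no cut sites anywhere in the genome")
    weights = np.array([cuts[c].size for c in chroms], dtype=float)
    weights /= weights.sum()
    bridge = config.bridge
    junctions: list[Junction] = []
    redraws = 0
    loop_counts: dict[int, int] = {lp.loop_id: 0 for lp in truth.loops}

    def build(eid, etype, loop_id, catg, armspec1, armspec2) -> Junction:
        # The cut end of each arm always abuts the bridge; two independent
        # coin flips randomize which arm sits left of the bridge and the
        # bridge's own insertion orientation, exercising all four linker
        # search patterns across the two mates.
        (c1, cut1, side1), (c2, cut2, side2) = armspec1, armspec2
        l1 = int(rng.integers(config.min_arm, config.max_arm + 1))
        l2 = int(rng.integers(config.min_arm, config.max_arm + 1))
        seq1, s1, e1 = _make_arm(genome, c1, cut1, side1, l1)
        seq2, s2, e2 = _make_arm(genome, c2, cut2, side2, l2)
        arm1 = (c1, seq1, s1, e1, side1)
        arm2 = (c2, seq2, s2, e2, side2)
        if rng.random() < 0.5:
            left, right = arm1, arm2
        else:
            left, right = arm2, arm1
        bridge_flipped = bool(rng.random() < 0.5)
        ins = revcomp(bridge) if bridge_flipped else bridge
        # orient each arm so its cut end faces the bridge
        lseq = left[1] if left[4] == "left" else revcomp(left[1])
        rseq = right[1] if right[4] == "right" else revcomp(right[1])
        molecule = lseq + ins + rseq
        if config.linker_mode == "one-step":
            pats1 = pats2 = ("full", "full")
        elif bridge_flipped:  # insert reads B + rcA; its revcomp A + rcB
            pats1, pats2 = ("B", "rcA"), ("A", "rcB")
        else:
            pats1, pats2 = ("A", "rcB"), ("B", "rcA")
        m_left = _mate_truth_from_arm(left[0], left[2], left[3], left[4],
                                      config.read_length, len(bridge), *pats1)
        m_right = _mate_truth_from_arm(right[0], right[2], right[3], right[4],
                                       config.read_length, len(bridge), *pats2)
        return Junction(eid, etype, loop_id, catg, molecule, m_left, m_right)

    eid = 0
    for _ in range(config.pairs_signal):
        while True:
            lp = truth.loops[int(rng.integers(len(truth.loops)))]
            cut_a = _nearest_cut(cuts[lp.anchor1.chrom], lp.anchor1.center)
            cut_b = _nearest_cut(cuts[lp.anchor2.chrom], lp.anchor2.center)
            if cut_a is None or cut_b is None:
                redraws += 1
                continue
            side_a = "left" if lp.anchor1.center < cut_a else "right"
            side_b = "left" if lp.anchor2.center < cut_b else "right"
            j = build(eid, "signal", lp.loop_id, "cis",
                      (lp.anchor1.chrom, cut_a, side_a),
                      (lp.anchor2.chrom, cut_b, side_b))
            if min(j.mate1.arm_len, j.mate2.arm_len) < config.min_arm // 2:
                redraws += 1
                continue
            loop_counts[lp.loop_id] += 1
            junctions.append(j)
            eid += 1
            break
    for _ in range(config.pairs_noise):
        while True:
            trans = len(chroms) > 1 and rng.random() < config.trans_fraction
            i1 = int(rng.choice(len(chroms), p=weights))
            if trans:
                others = [i for i in range(len(chroms)) if i != i1]
                w = weights[others] / weights[others].sum()
                i2 = others[int(rng.choice(len(others), p=w))]
            else:
                i2 = i1
            c1, c2 = chroms[i1], chroms[i2]
            cut1 = int(cuts[c1][int(rng.integers(cuts[c1].size))])
            cut2 = int(cuts[c2][int(rng.integers(cuts[c2].size))])
            j = build(eid, "noise", None, "trans" if trans else "cis",
                      (c1, cut1, "left" if rng.random() < 0.5 else "right"),
                      (c2, cut2, "left" if rng.random() < 0.5 else "right"))
            if min(j.mate1.arm_len, j.mate2.arm_len) < config.min_arm // 2:
                redraws += 1
                continue
            junctions.append(j)
            eid += 1
            break
    truth.loop_counts = loop_counts
    truth.redraws = redraws
    return junctions


# ---------------------------------------------------------------------------
# Read emission


def _apply_errors(seq: str, rate: float, rng: np.random.Generator
                  ) -> tuple[str, list[int]]:
    if rate <= 0 or not seq:
        return seq, []
    mask = rng.random(len(seq)) < rate
    pos = np.flatnonzero(mask)
    if pos.size == 0:
        return seq, []
    buf = bytearray(seq.encode())
    for p in pos:
        cur = buf[p]
        choices = [b for b in b"ACGT" if b != cur]
        buf[p] = choices[int(rng.integers(3))]
    return buf.decode(), [int(p) for p in pos]


def emit_reads(
    junctions: list[Junction],
    truth: GroundTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[ReadPair]:
    """Emit paired reads from junction molecules and record provenance.

    Read 1 is the molecule's left end; read 2 the reverse complement read
    from the right end. With probability ``duplicate_rate`` a molecule emits
    one extra (independently erroneous) copy. Deterministic under the seed.
    """
    rng = rng if rng is not None else _rngs(config.seed)["reads"]
    rl = config.read_length
    pairs: list[ReadPair] = []
    for j in junctions:
        base_id = f"sim{j.event_id}"
        n_copies = 1 + int(rng.random() < config.duplicate_rate)
        rc_mol = revcomp(j.molecule)
        for copy in range(n_copies):
            rid = base_id if copy == 0 else f"{base_id}d{copy}"
            s1, err1 = _apply_errors(j.molecule[:rl], config.error_rate, rng)
            s2, err2 = _apply_errors(rc_mol[:rl], config.error_rate, rng)
            m1 = MateTruth(j.mate1.chrom, j.mate1.pos, j.mate1.strand,
                           j.mate1.arm_len, j.mate1.linker_offset,
                           list(j.mate1.pattern_offsets), err1)
            m2 = MateTruth(j.mate2.chrom, j.mate2.pos, j.mate2.strand,
                           j.mate2.arm_len, j.mate2.linker_offset,
                           list(j.mate2.pattern_offsets), err2)
            truth.provenance[rid] = ReadProvenance(
                j.event_id, j.event_type, j.loop_id, j.category,
                None if copy == 0 else base_id, m1, m2,
            )
            pairs.append(ReadPair(rid, s1, s2))
    return pairs


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: layout -> genome -> events -> reads."""
    rngs = _rngs(config.seed)
    truth = layout_sites_and_loops(config.chrom_sizes(), config, rngs["layout"])
    genome, sizes = make_genome(config, rngs["genome"], truth.sites)
    junctions = simulate_ligation_events(genome, truth, config, rngs["events"])
    read_pairs = emit_reads(junctions, truth, config, rngs["reads"])
    return SimResult(config, genome, sizes, truth, read_pairs)


def event_mix_from_kinetics(
    total_pairs: int,
    params: Optional[kinetics.KineticsParams] = None,
    model: str = "two-step",
    t_star: float = 1.0,
) -> tuple[int, int]:
    """Split a pair budget into (signal, noise) proportional to the kinetics
    closed-form y(t*)/z(t*)."""
    params = params if params is not None else kinetics.KineticsParams()
    if model == "one-step":
        st = kinetics.one_step_closed_form(params, t_star)
    else:
        st = kinetics.two_step_closed_form(params, t_star)
    if st.y + st.z <= 0:
        raise ValueError("no products at t_star; cannot derive a mix")
    n_signal = round(total_pairs * st.y / (st.y + st.z))
    return n_signal, total_pairs - n_signal


def config_to_json(config: SimConfig) -> dict:
    return asdict(config)
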