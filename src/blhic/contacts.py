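"""Downstream PET analytics: enrichment, contact matrices, loop calling,
loop classification, CTCF motif orientation, and visual 4C.

A PET (paired-end tag) reduces one sequenced contact to two mapped anchor
positions. This module provides the analyses run on PET collections:

* overlap of PET tags with reference peak sets (ChIP-seq-style enrichment),
* depth-normalized per-peak fold-change grouping (high / normal / low),
* genomic-feature annotation of grouped peaks with enrichment vs background,
* binned, depth-normalized contact matrices and differential matrices,
* transitive single-linkage PET clustering into loops (PET clusters),
* common/specific loop classification by mutual paired-anchor overlap
  (the ``pairtopair -type both`` contract),
* convergent/divergent/identical CTCF motif orientation proportions,
* viewpoint ("visual 4C") profiles of distal partners of a bait interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .intervals import Interval, Peak, RegionIndex, find_overlaps
from .linker import PET


# ---------------------------------------------------------------------------
# PET / region overlap


def _pet_tags(pets: Sequence[PET]) -> list[tuple[str, int]]:
    out = []
    for p in pets:
        out.append((p.chrom1, p.pos1))
        out.append((p.chrom2, p.pos2))
    return out


def pet_overlap_fraction(
    pets: Sequence[PET],
    regions: Sequence[Interval],
    mode: str = "tag",
) -> float:
    """Fraction of PET tags (default) or PETs overlapping any region.

    ``mode='tag'``: each PET end counts as one 1-bp tag (matching per-tag
    files used for enrichment). ``mode='either'``: a PET counts once if
    either end overlaps.
    """
    if not pets:
        raise ValueError("empty PET list")
    idx = RegionIndex(regions)
    if mode == "tag":
        tags = _pet_tags(pets)
        n_in = sum(idx.contains_point(c, p) for c, p in tags)
        return n_in / len(tags)
    if mode == "either":
        n_in = sum(
            idx.contains_point(p.chrom1, p.pos1) or idx.contains_point(p.chrom2, p.pos2)
            for p in pets
        )
        return n_in / len(pets)
    raise ValueError(f"unknown mode {mode!r}")


def tf_enrichment_table(
    pets_a: Sequence[PET],
    pets_b: Sequence[PET],
    site_sets: dict[str, Sequence[Interval]],
    total_a: Optional[int] = None,
    total_b: Optional[int] = None,
) -> pd.DataFrame:
    """Per site set: percentage of library A tags overlapping, and the
    depth-normalized A/B tag-count ratio.

    The ratio is (count_A/total_A) / (count_B/total_B); missing (NaN) when
    count_B is zero. Totals default to the libraries' tag counts, which makes
    the ratio invariant to uniform depth scaling.
    """
    tags_a = _pet_tags(pets_a)
    tags_b = _pet_tags(pets_b)
    ta = total_a if total_a is not None else len(tags_a)
    tb = total_b if total_b is not None else len(tags_b)
    if ta <= 0 or tb <= 0:
        raise ValueError("totals must be > 0")
    rows = []
    for name, sites in site_sets.items():
        idx = RegionIndex(sites)
        ca = sum(idx.contains_point(c, p) for c, p in tags_a)
        cb = sum(idx.contains_point(c, p) for c, p in tags_b)
        ratio = (ca / ta) / (cb / tb) if cb > 0 else float("nan")
        rows.append({"site_set": name, "count_A": ca, "pct_A": 100.0 * ca / ta,
                     "count_B": cb, "ratio_A_over_B": ratio})
    return pd.DataFrame(rows).set_index("site_set")


# ---------------------------------------------------------------------------
# Peak fold-change grouping and feature annotation


def group_peaks_by_fc(
    peaks: Sequence[Peak],
    depth_a: Sequence[float],
    depth_b: Sequence[float],
    total_a: float,
    total_b: float,
    pseudocount: float = 1.0,
) -> list[str]:
    """Label peaks high / normal / low by depth-normalized log2 fold change.

    log2 FC = log2((dA + c)/total_A) - log2((dB + c)/total_B), pseudocount
    c = 1 tag. Labels: > 1 -> high, < -1 -> low, otherwise (closed interval
    [-1, 1], including the boundaries) -> normal.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be > 0")
    da = np.asarray(depth_a, dtype=float)
    db = np.asarray(depth_b, dtype=float)
    if len(da) != len(peaks) or len(db) != len(peaks):
        raise ValueError("depth vectors must match peak count")
    if (da < 0).any() or (db < 0).any():
        raise ValueError("depths must be non-negative")
    fc = np.log2((da + pseudocount) / total_a) - np.log2((db + pseudocount) / total_b)
    return ["high" if f > 1 else ("low" if f < -1 else "normal") for f in fc]


def annotate_peak_groups(
    peaks: Sequence[Peak],
    labels: Sequence[str],
    features: dict[str, Sequence[Interval]],
    genome_size: int,
    precedence: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Feature distribution and fold enrichment per peak group.

    Each peak is assigned to the first feature class (by precedence, default
    promoter > exon > intron > intergenic insofar as present) whose regions
    contain its center; unassigned peaks fall in ``intergenic``. Enrichment
    is observed group fraction over the feature's genomic length share
    (intergenic background = remaining length).
    """
    if not features:
        raise ValueError("features is empty")
    if len(labels) != len(peaks):
        raise ValueError("labels must match peak count")
    default_order = ["promoter", "exon", "intron", "intergenic"]
    order = list(precedence) if precedence is not None else (
        [f for f in default_order if f in features]
        + [f for f in features if f not in default_order]
    )
    idxs = {name: RegionIndex(features[name]) for name in order if name in features}
    feat_len = {name: idxs[name].total_length() for name in idxs}
    bg = {name: feat_len[name] / genome_size for name in idxs}
    bg["intergenic"] = max(genome_size - sum(feat_len.values()), 0) / genome_size
    classes = list(idxs) + (["intergenic"] if "intergenic" not in idxs else [])

    assigned: dict[str, dict[str, int]] = {}
    for peak, lab in zip(peaks, labels):
        cls = "intergenic"
        for name in idxs:
            if idxs[name].contains_point(peak.chrom, peak.center):
                cls = name
                break
        assigned.setdefault(lab, {}).setdefault(cls, 0)
        assigned[lab][cls] += 1
    rows = []
    for lab, counts in sorted(assigned.items()):
        n = sum(counts.values())
        for cls in classes:
            obs = counts.get(cls, 0) / n
            b = bg.get(cls, 0.0)
            rows.append({
                "group": lab, "feature": cls, "n_peaks": counts.get(cls, 0),
                "observed_fraction": obs, "background_fraction": b,
                "enrichment": obs / b if b > 0 else float("nan"),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contact matrices


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal binned contact counts."""

    chrom: str
    resolution: int
    n_bins: int
    counts: sp.csr_matrix
    normalized: bool = False
    scale: float = 1.0  # counts multiplier applied (per-million when normalized)

    def dense(self) -> np.ndarray:
        return self.counts.toarray()


def bin_contacts(
    pets: Sequence[PET], resolution: int, chrom: str, chrom_size: Optional[int] = None
) -> ContactMatrix:
    """Bin cis PETs of one chromosome into a symmetric count matrix."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    sel = [p for p in pets if p.cis and p.chrom1 == chrom]
    if chrom_size is None:
        chrom_size = max((max(p.pos1, p.pos2) for p in sel), default=0) + 1
    n_bins = (chrom_size + resolution - 1) // resolution
    rows, cols = [], []
    for p in sel:
        i, j = p.pos1 // resolution, p.pos2 // resolution
        rows.append(i)
        cols.append(j)
        if i != j:  # symmetrize off-diagonal
            rows.append(j)
            cols.append(i)
    data = np.ones(len(rows))
    counts = sp.coo_matrix((data, (rows, cols)), shape=(n_bins, n_bins)).tocsr()
    return ContactMatrix(chrom, resolution, n_bins, counts)


def normalize_per_million(m: ContactMatrix, total_pets: int) -> ContactMatrix:
    """Scale counts to contacts per million PETs (sequencing-depth norm)."""
    if total_pets <= 0:
        raise ValueError("total_pets must be > 0")
    scale = 1e6 / total_pets
    return ContactMatrix(
        m.chrom, m.resolution, m.n_bins, m.counts * scale, normalized=True, scale=scale
    )


def diff_matrix(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Signed difference A - B of two matrices on the same grid."""
    if (a.resolution, a.chrom, a.n_bins) != (b.resolution, b.chrom, b.n_bins):
        raise ValueError("matrices must share chrom, resolution and bin count")
    return ContactMatrix(
        a.chrom, a.resolution, a.n_bins, (a.counts - b.counts).tocsr(),
        normalized=a.normalized and b.normalized,
    )


# ---------------------------------------------------------------------------
# Loops (PET clusters)


@dataclass(frozen=True)
class Loop:
    """A PET cluster: two anchor intervals with a supporting PET count."""

    anchor1: Interval
    anchor2: Interval
    pet_count: int
    name: Optional[str] = None


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_pets(
    pets: Sequence[PET], anchor_extension: int = 2500, min_count: int = 5
) -> list[Loop]:
    """Transitive single-linkage clustering of PETs into loops.

    Each PET end is extended to ``[pos - e, pos + e]``; two PETs are linked
    when *both* extended ends mutually overlap (equivalently both anchor
    positions are within 2e of each other), and linked components become
    loops. Anchors are the union spans of member extended ends; loops with
    fewer than ``min_count`` PETs are dropped. Deterministic given the input
    multiset (PETs are processed in sorted order).
    """
    if not pets:
        return []
    e = anchor_extension
    d = 2 * e  # linkage distance on both axes
    by_pair: dict[tuple[str, str], list[PET]] = {}
    for p in pets:
        by_pair.setdefault((p.chrom1, p.chrom2), []).append(p)
    loops: list[Loop] = []
    for (c1, c2), group in sorted(by_pair.items()):
        group.sort(key=lambda p: (p.pos1, p.pos2, p.strand1, p.strand2))
        n = len(group)
        p1 = np.array([p.pos1 for p in group])
        p2 = np.array([p.pos2 for p in group])
        dsu = _DSU(n)
        # grid-bucket the (pos1, pos2) points at cell size d: all points in
        # one cell are pairwise within d in both coordinates
        cells: dict[tuple[int, int], list[int]] = {}
        for i in range(n):
            cells.setdefault((p1[i] // d, p2[i] // d), []).append(i)
        for members in cells.values():
            first = members[0]
            for m in members[1:]:
                dsu.union(first, m)
        # neighbor cells: link if any cross pair is within d in both coords
        for (cx, cy), members in sorted(cells.items()):
            for dx, dy in ((0, 1), (1, -1), (1, 0), (1, 1)):
                other = cells.get((cx + dx, cy + dy))
                if not other:
                    continue
                if dsu.find(members[0]) == dsu.find(other[0]):
                    continue
                linked = False
                for i in members:
                    for j in other:
                        if abs(int(p1[i]) - int(p1[j])) <= d and \
                           abs(int(p2[i]) - int(p2[j])) <= d:
                            dsu.union(i, j)
                            linked = True
                            break
                    if linked:
                        break
        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(dsu.find(i), []).append(i)
        for root in sorted(comps):
            members = comps[root]
            if len(members) < min_count:
                continue
            a1s = int(min(p1[m] for m in members) - e)
            a1e = int(max(p1[m] for m in members) + e + 1)
            a2s = int(min(p2[m] for m in members) - e)
            a2e = int(max(p2[m] for m in members) + e + 1)
            loops.append(
                Loop(
                    Interval(c1, max(a1s, 0), a1e),
                    Interval(c2, max(a2s, 0), a2e),
                    pet_count=len(members),
                )
            )
    return loops


def classify_loops(
    loops_a: Sequence[Loop], loops_b: Sequence[Loop], slack: int = 0
) -> tuple[list[str], list[str]]:
    """Label loops in A and B as ``common`` or ``specific``.

    A pair is common iff anchor1 overlaps anchor1' AND anchor2 overlaps
    anchor2' (each within ``slack``), testing both the direct and the
    swapped anchor pairing — the ``pairtopair -type both`` contract. Returns
    (labels_a, labels_b); each list partitions its input set.
    """
    labels_a = ["specific"] * len(loops_a)
    labels_b = ["specific"] * len(loops_b)
    for i, la in enumerate(loops_a):
        for j, lb in enumerate(loops_b):
            direct = la.anchor1.overlaps(lb.anchor1, slack) and \
                la.anchor2.overlaps(lb.anchor2, slack)
            swapped = la.anchor1.overlaps(lb.anchor2, slack) and \
                la.anchor2.overlaps(lb.anchor1, slack)
            if direct or swapped:
                labels_a[i] = "common"
                labels_b[j] = "common"
    return labels_a, labels_b


def loop_reference_overlap(
    loops: Sequence[Loop], reference_loops: Sequence[Loop], slack: int = 0
) -> float:
    """Fraction of ``loops`` common with a reference loop set."""
    if not loops:
        raise ValueError("empty loop list")
    labels, _ = classify_loops(loops, reference_loops, slack=slack)
    return labels.count("common") / len(loops)


def motif_orientation(
    loops: Sequence[Loop], motif_hits: Sequence[Interval]
) -> dict:
    """Convergent / divergent / identical proportions over loops whose two
    anchors each contain exactly one stranded motif hit.

    With anchors in genomic order: (+,-) convergent, (-,+) divergent,
    (+,+) or (-,-) identical. Returns counts, proportions (summing to 1 over
    classified loops) and the classified-loop count.
    """
    counts = {"convergent": 0, "divergent": 0, "identical": 0}
    n_classified = 0
    for loop in loops:
        hits1 = find_overlaps(list(motif_hits), loop.anchor1.chrom,
                              loop.anchor1.start, loop.anchor1.end)
        hits2 = find_overlaps(list(motif_hits), loop.anchor2.chrom,
                              loop.anchor2.start, loop.anchor2.end)
        if len(hits1) != 1 or len(hits2) != 1:
            continue
        s1, s2 = hits1[0].strand, hits2[0].strand
        if s1 not in "+-" or s2 not in "+-":
            continue
        n_classified += 1
        if (s1, s2) == ("+", "-"):
            counts["convergent"] += 1
        elif (s1, s2) == ("-", "+"):
            counts["divergent"] += 1
        else:
            counts["identical"] += 1
    props = {
        k: (v / n_classified if n_classified else 0.0) for k, v in counts.items()
    }
    return {"counts": counts, "proportions": props, "n_classified": n_classified}


# ---------------------------------------------------------------------------
# Visual 4C


@dataclass
class ViewpointProfile:
    """Distal interaction clusters of a viewpoint (bait) interval."""

    viewpoint: Interval
    clusters: list[tuple[Interval, int]] = field(default_factory=list)

    @property
    def arcs(self) -> list[tuple[Interval, Interval, int]]:
        return [(self.viewpoint, iv, n) for iv, n in self.clusters]


def visual_4c(
    pets: Sequence[PET],
    viewpoint: Interval,
    merge_gap: int = 2500,
    min_count: int = 5,
) -> ViewpointProfile:
    """Profile the distal partners of a viewpoint interval.

    PETs with at least one end inside the viewpoint are selected; PETs with
    *both* ends inside are self-interactions and excluded. The distal ends
    are merged into clusters when consecutive ends lie within ``merge_gap``;
    clusters with fewer than ``min_count`` PETs are dropped.
    """
    vp = viewpoint
    def inside(chrom: str, pos: int) -> bool:
        return chrom == vp.chrom and vp.start <= pos < vp.end

    distal: list[tuple[str, int]] = []
    for p in pets:
        in1, in2 = inside(p.chrom1, p.pos1), inside(p.chrom2, p.pos2)
        if in1 and in2:
            continue  # self interaction
        if in1:
            distal.append((p.chrom2, p.pos2))
        elif in2:
            distal.append((p.chrom1, p.pos1))
    profile = ViewpointProfile(viewpoint=vp)
    if not distal:
        return profile
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in distal:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        start = positions[0]
        prev = positions[0]
        n = 1
        segments = []
        for pos in positions[1:]:
            if pos - prev <= merge_gap:
                n += 1
            else:
                segments.append((start, prev, n))
                start, n = pos, 1
            prev = pos
        segments.append((start, prev, n))
        for s, e, cnt in segments:
            if cnt >= min_count:
                profile.clusters.append((Interval(chrom, s, e + 1), cnt))
    return profile
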