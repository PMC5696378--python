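# blhic

A toolkit for **bridge-linker Hi-C** (BL-Hi-C) style proximity-ligation
data: the ligation-kinetics models behind two-step ligation, in-silico
restriction-enzyme targeting analysis, bridge-linker read processing into
paired-end tags (PETs), and the downstream contact analytics (enrichment,
loop calling, motif orientation, visual 4C) — together with a synthetic-data
generator that plants a known genome, binding sites, loops, and ligation
junctions so the whole pipeline can be validated against ground truth
without any external downloads.

It is aimed at people developing or teaching 3D-genomics processing
pipelines: every step is a plain Python function with a tested contract,
and every downstream claim can be exercised on a library whose truth is
known by construction.

## The models and algorithms at the core

**Ligation kinetics.** Free proximal fragment ends `ω` (with `ω(0) = 2N`)
turn into signal products `y` (protein-mediated contacts) and noise
products `z` (random collisions with isolated fragments of abundance `β`).
One-step ligation joins ends directly:

    dω/dt = −(p₁+p₂)ω,   dy/dt = p₁ω²,   dz/dt = p₂βω

Two-step ligation first caps ends with a bridge linker at rate `p₀`,
making intermediates `x` that then resolve:

    dω/dt = −2p₀ω,  dx/dt = 2p₀ω − (p₁+p₂)x,  dy/dt = p₁xω,  dz/dt = p₂xβ

Both systems are solved in closed form (the two-step solution carries the
coefficient `α = 2p₀ / (2p₀ − (p₁+p₂))`, with the analytic limit on the
singular line `2p₀ = p₁+p₂`) and independently by a fixed-step RK4
integrator; the two agree to 1e−6 relative error. Both models share the
asymptotic noise level `z(∞) = p₂β·2N/(p₁+p₂)` and the short-time
signal-to-noise limit `y/z → (p₁/p₂)(2N/β)`.

**Enzyme targeting.** HaeIII (`GGCC`), MboI (`GATC`) and HindIII
(`AAGCTT`) are scanned over any FASTA; fragments, cutting frequencies, and
signed-distance depth profiles around reference peaks quantify how closely
a cutter lands to protein-bound regions (on uniform sequence all 4-cutters
average one site per 256 bp, 6-cutters one per 4096 bp).

**Read processing.** The 15-bp half-linkers (`ACGCGATATCTTATC` /
`AGTCAGATAAGATAT`, or the 20-bp one-step linker) are located by a
bit-parallel **bitap** fuzzy search under a substitution-only Hamming
distance (default tolerance 1 mismatch), verified against a brute-force
oracle. Trimmed tags are exact-matched against the genome (k-mer-seeded),
and unique mate pairs become canonical PETs with duplicate and
self-ligation accounting.

**Contact analytics.** PET–peak overlap fractions, depth-normalized
fold-change peak grouping (log₂FC > 1 / [−1, 1] / < −1), feature
annotation with background-corrected enrichment, binned per-million
contact and differential matrices, transitive single-linkage PET
clustering into loops (minimum 5 PETs by default), common/specific loop
classification by mutual paired-anchor overlap, convergent / divergent /
identical CTCF-motif orientation proportions, and viewpoint ("visual 4C")
profiles.

## Worked example

```python
from blhic import SimConfig, LinkerSet, simulate_library, process_library
from blhic.contacts import cluster_pets, pet_overlap_fraction
from blhic.intervals import Interval

cfg = SimConfig(genome_length=200_000, n_chroms=2, n_sites=40, n_loops=8,
                loop_dist_min=5_000, loop_dist_max=30_000,
                pairs_signal=2_700, pairs_noise=300, seed=1)
res = simulate_library(cfg)                     # genome + reads + truth
pets, stats, _ = process_library(res.read_pairs, LinkerSet(), res.genome)
print(f"read pairs:        {stats.total_read_pairs}")
print(f"pairs with linker: {stats.pairs_with_linker}")
print(f"unique PETs:       {stats.unique_pets} "
      f"({100 * stats.unique_pet_fraction:.1f}% of pairs)")
print(f"cis/trans ratio:   {stats.cis_trans_ratio:.2f}")
loops = cluster_pets(pets, anchor_extension=2500, min_count=5)
print(f"loops (>=5 PETs):  {len(loops)} of {len(res.truth.loops)} planted")
sites = [Interval(s.chrom, s.start - 500, s.end + 500) for s in res.truth.sites]
print(f"PET tags at sites: {100 * pet_overlap_fraction(pets, sites):.1f}%")
```

prints

```
read pairs:        3000
pairs with linker: 563
unique PETs:       435 (14.5% of pairs)
cis/trans ratio:   18.77
loops (>=5 PETs):  8 of 8 planted
PET tags at sites: 92.3%
```

All 3000 read pairs are simulated; 563 carry a detectable bridge linker
(most sonication arms are longer than the 100-bp reads, so the junction
usually lies outside the sequenced window). 435 pairs survive exact-match
alignment of both mates into unique PETs — the 14.5% rate is dominated by
the 1% per-base error model meeting an exact-match aligner, not by linker
losses. The cis/trans ratio reflects the designed 10% noise with half of
noise pairs inter-chromosomal, clustering recovers all 8 planted loops
with no false loops, and 92.3% of PET tag ends fall within 500 bp of a
planted binding site.

The same workflow is available from the shell:

```bash
blhic simulate --out-dir sim/ --seed 1
blhic pets --fastq1 sim/reads_1.fastq --fastq2 sim/reads_2.fastq \
      --fasta sim/genome.fa --out-prefix lib
blhic loops --pets lib.pets.bedpe --min-count 5 --out loops.bedpe
blhic v4c   --pets lib.pets.bedpe --viewpoint chr1:0-50000 --out v4c.bedgraph
```

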