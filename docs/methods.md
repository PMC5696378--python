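# Methods

This note records the models, numerical choices, and deliberate design
decisions behind `blhic`, and what the synthetic-data validation does and
does not demonstrate.

## Ligation kinetics

Two mass-action ODE systems describe proximity ligation in dimensionless
model units (no unit-conversion layer is provided). State variables:
`ω` — fragment ends held in proximity by protein complexes, `ω(0) = 2N`;
`x` — linker-capped intermediates (two-step only); `y` — accumulated
signal products; `z` — accumulated noise products formed against isolated
fragments of abundance `β`. Rates: `p₀` linker capping, `p₁` signal
ligation, `p₂` noise ligation. Defaults `p₀ = 0.05`, `p₁ = 1`,
`p₂ = 0.025` encode that random collision ligation is intrinsically fast
relative to the slow linker-capping step, and `N = β = 1` so that ratios
reduce to pure rate functions (the model itself fixes neither population
size).

Both systems are integrated in closed form. The two-step solution uses
`α = 2p₀/(2p₀ − (p₁+p₂))`, which diverges on the line `2p₀ = p₁+p₂`; when
`|2p₀ − (p₁+p₂)| < 1e−9 · (2p₀+p₁+p₂)` the analytic limit (L'Hôpital) is
evaluated instead and the returned state is flagged `singular_branch`.
Unit tests check that the general form converges to the limit form from
both sides. Two algebraic identities are verified numerically as
properties: both models share `z(∞) = p₂β·2N/(p₁+p₂)` (the α cancels
exactly), and both share the short-time ratio limit
`y/z → (p₁/p₂)(2N/β)`.

The independent numerical route is a fixed-step classical RK4 integrator —
chosen over an adaptive library solver because determinism and a trivial
error model matter more here than efficiency. With 20 000 steps over
`t ∈ [0, 50]` and rates up to 2, the per-step relative error
`(λh)⁵/120` accumulates to ≲ 1e−7, comfortably inside the 1e−6
closed-form agreement asserted in tests. Note one modelling asymmetry
taken as given: the one-step `dy/dt = p₁ω²` is quadratic while
`dω/dt = −(p₁+p₂)ω` is linear, so the system conserves nothing — it is a
rate sketch, not a population balance.

With the default parameters the *asymptotic* `y/z` of the two-step model
is smaller than the one-step value (`y∞` gains a `+2p₀` in its
denominator while `z∞` is identical). The package therefore computes and
reports both ratio curves without asserting an ordering between the
models; any claimed two-step enrichment advantage depends on the time
point and normalization chosen, which is outside what these equations
alone determine.

## In-silico digestion

Coordinates are 0-based half-open throughout; a cut position is a
between-base coordinate. Recognition scanning counts overlapping
occurrences (a sequence statistic, not a claim that a real enzyme cleaves
both of two overlapping sites), never matches through `N`, and — since all
built-in enzymes are palindromic — scans one strand only; non-palindromic
specs are rejected rather than silently half-handled. Mean cutting
frequency is reported as non-N length over site count, matching the
genome-average interpretation. Proximity profiles bin *signal-interval
centers* by signed distance from *reference-peak centers* (summit if
present, else midpoint), average per reference peak, and scale per
million sequenced reads; total profile mass is invariant to bin
refinement, which the tests assert.

## Linker detection and PET formation

Linker matching is substitution-only (Hamming) bitap with bit-parallel
mismatch rows, default tolerance 1 mismatch and minimum tag length 15 —
the tolerances the upstream tools expose. Indel-tolerant matching is
deliberately out of scope: it would complicate the oracle (a naive
sliding Hamming scan, asserted equal on randomized inputs) without
changing what the tolerance models. The two-step search set is both
half-linkers and their reverse complements in the fixed order A, B, rcA,
rcB; the leftmost hit wins, ties by that order. A junction that reaches
the read's final bases is caught by a read-end overlap check against each
pattern's prefix (≥ 8 bases, ≤ 1 mismatch); shorter overlaps are
undetectable in principle and those reads keep 1–7 linker bases, which
then fail exact alignment — an accepted, accounted loss of roughly 3% of
pairs at 100-bp reads.

Alignment of tags is exact full-length matching against both strands,
seeded by a sorted 16-mer code array and verified by string comparison.
This is intentionally strict: it is meant for synthetic genomes where the
truth is exact, and it doubles as a conservative survival model (any
substitution in a tag unmaps it). Real libraries enter through the
aligned-tag TSV import path after an external aligner. The seed array is
only a lookup accelerator — queries shorter than 16 bases fall back to a
direct scan, so the 15-bp minimum tag length remains alignable.

PETs are canonically ordered on (chrom, pos); duplicates are exact
coordinate+strand equality of both ends after ordering, first occurrence
kept; cis PETs closer than 1000 bp (configurable) are flagged
self-ligation and excluded. The library statistics form an exact
partition of input pairs (unusable / non-unique / self-ligation /
duplicate / unique PET), asserted as an invariant.

The simple peak caller extends each tag 5' position by a fixed width in
its strand direction, thresholds per-base depth, and takes the leftmost
maximum as summit. It exists to make depth/peak analyses self-contained;
it is not a model-based caller and peak scores are max depth, usable only
as a rank surrogate.

## Contact analytics

Loop calling is transitive single-linkage clustering of PETs whose
extended ends (± 2500 bp default) mutually overlap — equivalently, whose
anchor positions differ by ≤ 2× the extension in both coordinates. The
implementation grid-buckets PET position pairs at the linkage distance so
whole cells union in one pass and neighbor cells union on the first
qualifying pair; tests assert exact equality with an O(n²) transitive
closure. The minimum cluster size defaults to 5 PETs, the one printed
count threshold in this assay family; statistical confidence modelling of
clusters is out of scope. Loop anchors are reported as the union span of
member extended ends, so anchor width reflects both the extension and the
sonication spread.

Common/specific loop classification implements the `pairtopair -type
both` contract: common iff anchor1 overlaps anchor1′ and anchor2 overlaps
anchor2′, testing the direct and swapped pairings because file
conventions differ; slack defaults to 0 (pure overlap). One test runs
bedtools itself as an independent oracle.

Fold-change grouping uses log₂ of depth ratios normalized by library
totals with a pseudocount of 1 tag (zero-depth peaks are otherwise
undefined); the boundary values ±1 classify as "normal" since the printed
rule gives "high"/"low" strict inequalities. Enrichment tables report
tag-level overlap by default (each PET end counted once), with either-end
counting as an option, because the underlying per-tag files are
ambiguous on this point. Matrix normalization is counts per million PETs;
no ICE/KR balancing is applied — depth is the only correction used in the
analyses this package supports. Visual-4C excludes PETs with both ends in
the viewpoint as self-interactions and merges distal ends within a gap
(default 2500 bp), keeping clusters of ≥ 5 PETs.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the reference
study conditions used by the acceptance checks: 1 Mb genome over 2
chromosomes at GC 0.5, 200 non-overlapping stranded binding sites (min
gap 3 kb), 50 loops pairing disjoint sites at log-uniform distances of
10–200 kb with a 0.7 convergent-motif fraction, 45 000 signal + 5 000
noise ligation events (10% noise, half of noise trans), 100-bp reads at
1% substitution error, HaeIII digestion, and no injected duplicates
(duplicate injection is exercised separately at rate 0.2).

Event model: a signal event picks a planted loop uniformly and ligates at
the cut site nearest each anchor; a noise event picks two cut sites
uniformly (cross-chromosome with the configured probability). Junction
molecules are `arm + bridge + arm` where each arm's **cut end abuts the
bridge** and the outer end is the sonication breakpoint; which arm sits
left of the bridge and the bridge's insertion orientation are two
independent fair coin flips, which exercises all four linker search
orientations across the two mates. (An earlier variant that
reverse-complemented arms in place put cut ends at the molecule surface
and collapsed half of all tag 5' coordinates onto the cut coordinate —
physically wrong and a source of spurious duplicates.) The synthetic
two-step bridge is `half_A + revcomp(half_B)` (30 bp), so each mate reads
into "its" half-linker; the real bridge is a 20-bp duplex, but what the
pipeline observes is exactly the two 15-bp search sequences, which is the
property that matters here.

Sonication arm lengths are uniform in [50, 500] bp and are *not*
truncated at restriction-fragment boundaries, emulating partial
digestion. This keeps the tag-length distribution — and hence the
probability a pair survives the exact-match aligner under substitution
errors — identical between signal and noise events, making the designed
cis/trans split a genuine prediction for the measured one (a fragment-
truncated variant couples survival to local cut density and biases the
measured ratio away from design). For the same reason the default
`site_cut_bias` is 1; planting extra recognition sites near binding sites
(bias > 1) remains available and is what the enzyme-targeting contrast
tests use. Event proportions can alternatively be derived from the
kinetics closed forms via `event_mix_from_kinetics`.

All randomness derives from one master seed through labeled
`SeedSequence` sub-streams (layout / genome / events / reads); FASTQ
output is byte-identical across runs. Every read resolves to a provenance
record carrying event type, loop id, per-mate true tag coordinates,
linker and pattern offsets, and realized error positions.

**What passing does and does not show.** The generator has i.i.d. bases,
no contact-distance decay, no chromatin structure beyond planted loops,
constant base qualities, substitution-only errors, and an exact-match
survival model. Recovery of ~100% of planted loops with zero false calls
therefore validates the *pipeline logic* — linker localization, tag
coordinates, canonicalization, clustering, accounting — not performance
on real genomes with repeats, mappability structure, polymer background
contacts, or indel/quality error profiles. Real-data figures (unique-PET
rates above 60%, cis/trans ≈ 5.8, loop counts at hundreds of millions of
reads) require real sequencing data through the external-aligner import
path and are not claimed by the synthetic results.

## Problem sizes

Validation runs are sized for a desk machine: kinetics fidelity uses 100
random parameter draws at 20 000 RK4 steps over `t ∈ [0, 50]`; the
spacing law uses a 10 Mb random genome (2 Mb in the unit test); the bitap
oracle uses 10 000 randomized cases; the end-to-end check uses the full
default 50 000-pair library; shared test fixtures use a 200 kb / 3 000-
pair scale of the same design.
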