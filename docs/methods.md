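# Methods

## The assembly simulation

asmsim computes, for a set of read mappings against a known reference, the
best de novo assembly theoretically obtainable. The procedure per reference
sequence is:

1. **Sort and containment-filter.** Fragments are sorted by start (ties:
   longer first, then id); any fragment whose end does not exceed the running
   maximum end is a subsequence of an earlier one and contributes nothing, so
   it is dropped. Starts and ends of the survivors strictly increase.
2. **Junction tests.** Consecutive survivors `a`, `b` connect unless
   (i) they do not overlap (`b.start >= a.end`), (ii) the overlap is shorter
   than `min_overlap`, or (iii) the reference substring `[b.start, a.end)`
   occurs at least twice in the multiplicity scope on either strand. Contigs
   are maximal connected runs; isolated fragments are single-fragment contigs.
3. **Certification.** Every breakpoint is emitted with its cause (gap,
   short_overlap, repeat, or unknown_base for imported mappings whose overlap
   crosses an N run), so any reported break can be checked independently.

Assumptions inherited from this design: reads are placed at their *true*
origin (truth mapping), so read errors never displace a fragment; the
simulator never reconstructs sequence from read overlaps and never outputs a
collapsed copy of a long repeat — a region is assembled only if it can be
tiled unambiguously. Contig and scaffold are deliberately conflated: a mate
pair with uniquely mapped ends becomes a single long fragment whose
unsequenced interior is carried along as a scaffold gap (masked as N in FASTA
output) but counts as covered in the metrics.

A consequence of rule (iii) worth noting: when a repeat copy is much longer
than the read length, *every* interior junction of the copy is repeated, so
the copy interior shatters into single-read contigs. These slivers are kept
and counted (they are legitimate contigs of the optimal assembly); only reads
containing unique flanking sequence in their overlaps extend contigs across a
copy boundary.

## Repeat oracle

Multiplicity queries are exact. A query of length `m >= k` (anchor `k = 12`)
is located via binary search in a sorted array of 2-bit-packed k-mer codes of
the forward strand; every anchor hit is verified by a full string comparison,
and the reverse complement of the query is looked up the same way. Queries
shorter than `k` fall back to a naive scan. Occurrences are counted at every
start position (overlapping occurrences of periodic strings count multiply);
a query equal to its own reverse complement has each locus counted once.
Windows overlapping N never match, and queries containing N are rejected —
an undetermined overlap can never be certified unique.

The scope of the index is a parameter: the whole genome (shotgun), one
chromosome (chromosome sorting), one clone or one pool of clones (BAC
strategies), or the two homologs of a diploid (phase determination). For deep
simulations a batch query path reads anchor codes off precomputed
per-position arrays and resolves an overlap without verification when its
anchor occurs exactly once forward with no reverse-complement anchor hit;
everything else goes through the exact string query. A vectorized assembly
path (`assemble_read_starts`) handles equal-length unpaired reads as numpy
arrays; its equivalence with the general fragment path is asserted by a test.

## Read simulator

Reads are drawn uniformly over start positions admitting an N-free window,
on both strands; windows containing N are rejected and redrawn, so unknown
regions behave as forced coverage gaps. Counts may be given directly or as
fold-coverage, `round(c * L / r)` reads (pairs use `2r` — coverage counts
sequenced bases, not pair interiors). Error models: per-base substitution,
insertion and deletion probabilities, applied to the observed sequence only
(the truth interval is never shifted); SOLiD color space, where each color
encodes a base transition (`color_i = code(base_i) XOR code(base_{i+1})`,
A/C/G/T = 0/1/2/3) and each color is independently miscalled with the given
rate — a single miscall corrupts every naively decoded downstream base. In
color-space mode indel rates are ignored (SOLiD miscalls are
substitution-like in color space). Pair inner distances are drawn from a
normal distribution whose central 95% interval equals the configured
`[min, max]` range (SD = range / (2 x 1.959964)), rounded and clamped at 0;
a flag reinterprets the range as the outer fragment span instead. Truth
mappings are emitted as SAM so that simulated and externally mapped reads
flow through one import path.

## Strategies

* **shotgun** — multiplicity scope = whole genome.
* **chromosome_sorting** — each sequence assembled with scope restricted to
  itself; this is the *only* difference from shotgun.
* **bac** — a clone library is sampled (clone count
  `round(bac_coverage * L / clone_length)`, uniform independent starts, so
  clones may overlap), partitioned into pools of `pool_size`; per-clone reads
  are assembled at stage 1 with scope = the clone (barcoded) or its pool
  (pooled), and the stage-1 contigs, placed at their true coordinates, are
  assembled at stage 2 against the whole genome. Both scope modes are
  provided because published descriptions of pooling are ambiguous about
  whether clone identity is known within a pool.
* **phase** — the reference is diploidized (substitution heterozygosity at a
  per-site rate, alternate base uniform over the other three, N sites never
  mutated) and both homologs form the scope. Any fragment or overlap not
  covering a heterozygous site occurs in both copies and is treated exactly
  like a repeat; fragments whose substring is non-unique are discarded
  entirely, since they map to either homolog. Contigs are therefore the
  phaseable haplotype blocks, and the covered fraction of the combined
  homologs is reported as the *sequenced fraction*. The configured coverage
  for this strategy is total depth over both homologs (half per homolog).

A master seed spawns per-stage child generators (`numpy.random.SeedSequence`),
so reference generation, read sampling and clone sampling are independently
reproducible and whole runs are bit-stable.

## Metrics

Per-site N50: each reference site scores the length of the longest contig
covering it, uncovered sites score 0, and N50 is the largest value `v` with
at least half of all sites scoring `>= v`. The "at least half" threshold
resolves the even-count median ambiguity so that N50 is always an attained
contig length (or 0); it follows that N50 = 0 exactly when the covered
fraction is below one half, and for non-overlapping contigs tiling the whole
reference it reduces to the classical length-weighted median contig length.
Because neighbouring contigs may share short overlaps, the per-site value can
be slightly larger than a contig-only statistic. The computation sweeps
contigs longest-first, crediting newly covered sites per contig-length class
(an interval union, never a per-site array); a brute-force per-site
implementation backs it in the tests. N sites are included in the default
denominator; a variant with the N-excluded denominator (`n50_known`) is
reported alongside, since either convention is defensible. Coverage
fractions are reported against all sites and against non-N sites.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_overlap` (bases) | 1 | minimal connecting overlap; models De Bruijn word size `w` as `w - 1` |
| anchor `k` (bases) | 12 | repeat-index granularity only; answers are exact for any query length |
| pair distance range (bases) | — | inner distance between facing mate ends; 95% of draws fall inside |
| `het_rate` (per site) | — | heterozygosity of the simulated diploid; 1e-3 approximates a human genome |
| `clone_length` (bases) | — | BAC insert length; 150–250 kbp is typical of real libraries |
| `bac_coverage` (fold) | — | clone coverage of the genome; with read coverage per clone it sets total depth |
| error rates (per base/color) | 0 | substitution / insertion / deletion / color miscall probabilities |

## What the synthetic generators emulate — and what they do not

Random references with i.i.d. bases, planted exact repeats (direct or
inverted), substitution-only heterozygosity and uniform BAC sampling
reproduce the *mechanisms* being studied: repeat-induced ambiguity, coverage
gaps, pairing, scope reduction. They do not emulate the repeat-family
structure, GC-dependent sampling bias, cloning chimeras, indel
heterozygosity, or the N-run landscape of a real mammalian genome, and no
real read mapper is involved (truth positions replace mapping, so
mapper-specific losses are outside the model). Passing tests therefore
demonstrate the correctness of the simulation machinery and the direction
and rough magnitude of the strategy effects, not genome-accurate N50 values.
The `distinct_copy_flanks` option of the planted-repeat generator pins the
single base on each side of every copy to differ across copies, so fixtures
that assert exact contig counts are immune to the ~4^-f chance that two
copies share an f-base flank and create an unplanned repeated junction.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; SAM conversion happens only
  at the I/O boundary. Sort ties break deterministically (longer fragment
  first, then fragment id).
* Pair discard drops both mates (a flag can demote them to unpaired reads
  for sensitivity analysis); unpaired reads lying wholly inside repeats are
  kept.
* BAC clone counts use `round()`, not Poisson sampling; clone placement is
  uniform and independent.
* Distances are clamped at zero after rounding; the zero-width range is the
  deterministic limit.
* Stage-2 BAC assembly places stage-1 contigs at their true coordinates
  rather than re-mapping them, consistent with the reference-guided design.
* Imported SAM records contribute their CIGAR reference span (M/=/X/D/N);
  clipped bases are excluded, and secondary/supplementary/unmapped records
  are skipped and counted.

## Problem sizes used in tests and the acceptance script

Desk-scale stand-ins are used throughout: megabase random and planted
references for the shotgun/phase experiments (20–40x, read lengths
50–2000 bases, 10 sampling seeds for the coverage-saturation check),
kilobase-scale fixtures for exact contig-count and brute-force-equivalence
checks (200 randomized references for the latter), and a 2 Mbp combined
diploid for phase determination. These sizes keep every experiment exact and
fully reproducible while exhibiting the same mechanisms as genome-scale runs.

## Known limitations

* The error-truncation effect of De Bruijn words on *real* assemblers (a
  miscall invalidating all words crossing it) is not simulated; `min_overlap`
  captures only the minimal-overlap consequence of word size, so word-size
  sweeps of the simulator are flat where a real assembler's curve falls off.
* Multiplicity is exact-match only; diverged repeat copies below 100%
  identity are not detected as repeats.
* Optimal contig lengths can be slightly optimistic where neighbouring
  contigs overlap, and the scaffold interiors counted as covered inflate
  coverage relative to sequenced bases.
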