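# Methods

This note documents the models and procedures `mitopop` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show about
real data.

## Study system and scope

The toolkit models a two-germplasm plant population of the kind found in
*Tylosema esculentum*: a type 1 reference mitogenome (two autonomous rings)
and a structurally diverged type 2 genome (three rings plus one linear
chromosome, 436,568 bp in total), differing at a few hundred SNP/indel
loci, sharing long repeats and a 9,798 bp chloroplast-derived insertion,
and distinguished by a 2,108 bp type-2-exclusive marker fragment. The
pipeline consumes per-sample, per-position, strand-split allele counts
(a pileup TSV derivable from `samtools mpileup`); read mapping itself,
de-novo assembly and gene annotation are out of scope.

All interface coordinates are 1-based inclusive; any half-open
representation is internal only.

## Repeat detection and recombination conformations

Repeats are **exact** maximal repeated pairs, found by hashing k-mers
(k = 31, lowered to `min_len` when `min_len` < 31) and merging seed hits
along alignment diagonals; because matching is exact, every maximal match
of length ≥ k is fully tiled by seeds and needs no extension step. Both
orientations are searched, within and between molecules. Repeats spanning
a circular origin are not reported. Mismatch-tolerant repeat families are
a documented non-goal: the recombination-active repeats in the study
system are identical copies.

Recombination is enumerated at depth 1 (one event per conformation),
mirroring how structural differences are reasoned about one event at a
time; composite structures are reachable by iterating on a product
genome. The three geometries:

- direct pair on one circle → two circles; with copies starting at a1 and
  a2, the products are the arcs [a1, a2) and [a2, a1) (circularly), each
  retaining exactly one repeat copy, lengths summing to the parent;
- direct pair across two circles → one fused circle of summed length
  retaining both copies;
- inverted pair on one circle → the segment strictly between the copies
  is reverse-complemented in place (an involution; length preserved).

**Junction signatures.** A 2×anchor window at the novel seam is *not*
diagnostic: for direct events it is identical to the parent's sequence
context at the other repeat copy, and for inversions it equals the
reverse complement of a parent junction, so strand-agnostic read matching
cannot distinguish them. Signatures therefore span one full retained
repeat copy plus `anchor` (default 30) flanking bases on each side. The
practical consequence is faithful to the underlying biology: short reads
can attest events on short repeats (e.g. a 35 bp direct repeat) but carry
no information about events on multi-kilobase repeats, and
`junction_support` then reports zero support rather than guessing — for
long-repeat events the package abstains, never asserts. Signatures
occurring more than once in the supplied genome sequences are flagged and
excluded from frequency denominators. Frequencies are support counts
normalized over the competing signature sets at a locus; zero spanning
reads is a no-call.

## Coverage: copy number and linear-end taper

Copy-number segmentation smooths per-position depth with a running median
(window 501 bp), divides by a baseline (default: global median depth),
rounds to the nearest positive integer — half-integers round away from
zero so a 1.5× ratio flags as multicopy for review — and merges constant
runs, discarding segments shorter than 1,000 bp. The window and minimum
segment length are chosen to sit safely below the ~4 kb scale of the
shortest multicopy region in the study system.

Linear molecules degrade from their unprotected ends, producing a
progressive coverage decline. The taper detector smooths the profile,
takes the interior median m, and for each end estimates the taper extent
T as the first position where depth recovers to 0.95 m. The end is called
tapered when T ≥ 2,000 bp, the terminal depth is below 0.5 m, and a
non-decreasing (isotonic, pool-adjacent-violators) fit over [0, T] leaves
a relative RMS residual under 0.1 — i.e. the decline is monotone rather
than noise. Under the forge's uniform-truncation model the expected depth
at distance x from an end is coverage·x/taper_max, so the 0.95 m crossing
sits at 0.95·taper_max and the estimator lands within ~5% of the true
extent at coverage ≥ 50×. The default ceiling under test (`max_taper`)
is 20 kb, consistent with a ~18 kb signal on a ~97 kb molecule and the
precondition that molecules be longer than four times the ceiling.

## Variant and heteroplasmy calling

Counts are assumed to have passed a per-base quality floor (Phred > 20)
upstream, at count time. A variant is called where the sample's majority
allele differs from the reference base; loci below `min_depth` (default
10) are no-calls, recorded separately from reference matches. Allele
strings follow pileup conventions (`T`, `+AT`, `-GCA`); deletions are
anchored at the first deleted base, insertions after the anchor base.
Count ties for the majority allele are broken by the lexicographically
smallest allele string (deterministic, and exercised by the property
tests).

A heteroplasmic minor allele is recorded iff its frequency is
≥ `min_minor_freq` (default 0.02) of the locus's quality-passing depth
AND it is seen on ≥ 1 read in each orientation AND the locus is outside
the homology mask. The denominator choice (full quality-passing depth,
before strand considerations) and the presence — not proportion — reading
of the both-strands rule are deliberate and documented here because both
are open choices; the filters are ANDed, so their order does not affect
the result. Raising the frequency threshold can only remove records
(monotonicity, property-tested against a row-wise oracle).

The homology mask is the union of mitogenome intervals with a ≥ 500 bp
k-mer-chained match (k = 31, gap-merge 200 bp) in the plastome or nuclear
decoys, minus the registered chloroplast-insertion interval, which is
analysed rather than masked. Because seeds chain along exact diagonals,
homologies diverged by substitutions are found directly while indel-bearing
homologies fragment into separate segments; at the ~1% substitution
divergence the pipeline targets this is adequate, and it is the stated
limitation of the scanner.

Typing assigns each sample the germplasm whose alleles win the majority
vote over covered differential loci, and independently flags whether mean
depth over the marker fragment reaches 0.5× the sample's genome-median
depth; a vote/marker discordance is reported, never silently resolved.
Aggregation counts, per chromosome and variant class, the loci variant in
each type versus the reference, with a variant deemed type-exclusive when
its alternate allele is the majority allele in ≥ 1 sample of exactly one
type. Per-class totals count distinct loci (a locus can be variant in
both types), so totals are not column sums. The variant matrix keeps one
alternate allele per locus (the first caller's); truly multi-allelic loci
would be aggregated under that allele — a documented simplification.

## Chloroplast-insertion origin assignment

A single ancestral insertion predating the germplasm split implies the
fixed unrooted quartet ((chloro_t1, chloro_t2), (mito_t1, mito_t2)) for
the four present-day copies of each insertion locus. The topology is an
assumption flag, not an inference. Each locus's Ref/Alt quad pattern
(Ref = identical to the type-1 chloroplast reference) is scored by Fitch
parsimony — implemented by enumerating the four internal-node labelings —
and checked in tests against an exhaustive enumeration of change
placements on all five branches:

- score 0 → NoVariant;
- score 1 on a unique terminal branch → Mito or Chloro, with the branch
  named;
- score 1 forced onto the internal branch → Ambiguous (the change
  predates the split; it cannot be attributed to either organelle);
- score ≥ 2 → Conflict.

Indel loci are treated as binary presence/absence characters. A state
polymorphic within a type is encoded Alt and the call flagged
polymorphic. The parsimony score is reported with every call so users can
judge the strength of the inference. Loci identical in both types but
differing between organelles are by construction Ambiguous and are never
resolved.

## Marker chromosomes, distances, trees

For each sample, a 40 bp reference window centered on each differential
locus (positions anchor−19 … anchor+20; centering is a documented choice —
only the window width is fixed by convention) is emitted with the
sample's allele substituted; insertions lengthen and deletions shorten
the yield, a no-call contributes an N at the anchor, windows are clipped
at molecule ends, and overlapping windows are merged once with a warning.
For cross-sample comparability the per-locus windows are right-padded
with gaps to the maximum length (`pad=True`), which preserves per-locus
alignment without a multiple-alignment dependency; columns with a gap or
N in either sequence are excluded pairwise from distances.

Jukes–Cantor: d = −(3/4) ln(1 − (4/3) p) with p the mismatch proportion
over retained sites; p ≥ 3/4 and empty site sets are errors. Neighbor
joining is the canonical Saitou–Nei agglomeration on the Q-criterion with
a deterministic tie-break (lowest node-index pair) and the final edge
split evenly to place the arbitrary root; negative branch lengths on
non-additive inputs are kept, as in the classical algorithm. On additive
matrices the tree's leaf-to-leaf path lengths reproduce the input exactly
(property-tested at 4–8 taxa against independently generated random
trees).

## SSR scanning

Perfect tandem runs of primitive motifs (not themselves a repeat of a
shorter motif) are reported with their count of complete repetitions when
that count meets the per-length minimum (10, 6, 5, 5, 5, 5 for 1–6 bp).
When two qualifying runs overlap, the longer is kept (tie: earlier
start). Motif groups merge a motif with its rotations and its reverse
complement's rotations, displayed A/T, C/G, AT, AG/CT… Scanning is
linear; circular wrap-around runs are not counted (documented, since the
convention of the original scanner on circular replicons is unknown).
Compound and interrupted SSRs are out of scope.

## The synthetic forge

The forge's defaults are the study conditions: molecule sizes
169,406 / 56,355 / 97,120 (linear) / 113,687 bp; a 9,798 bp insertion from a
160 kb plastome, carried by both organelle genomes, with 20 post-split
variants on randomly chosen terminal branches and 72 pre-split
organelle-divergence variants (substitutions only); a 2,108 bp
type-2-exclusive marker; 254 differential loci split 143/52/59
(SNP/INS/DEL by largest-remainder apportionment), placed ≥ 25 bp from
repeat copies, the insertion and the marker, and ≥ 12 bp apart so indel
edits never interact; 45 + 39 samples with one type 1 individual carrying
4% heteroplasmy; coverage 100×, read length 150, substitution error rate
10⁻³; linear ends truncated Uniform(0, 18 kb) per end per molecule copy;
one nuclear decoy carrying a 5 kb mitogenome segment at 1% divergence.
Indel sequencing errors are not simulated — indel alleles exist only as
planted variants, matching the filters under test. The empirical
distribution of linear-end truncation is unknown in vivo; uniform is a
stand-in chosen for its closed-form depth ramp, not a biological claim.

Randomness: genome construction uses one generator seeded from the forge
seed; each sample's counts use a sub-stream derived from (seed, sample
index), so adding samples never shifts earlier samples' draws. Truth
tables record every planted feature in reference (type 1) coordinates.

What the forge does **not** emulate — and hence what green tests do not
certify on real data: mapping artifacts and mapping-quality effects,
base-quality miscalibration, indel sequencing errors, repeat families
below 100% identity, GC-dependent coverage bias, and chimeric reads. The
pileup converter and the quality floor are the interface where those
enter a real analysis.

## Problem sizes in the test suite

Unit tests run on scaled-down genomes (tens of kb, 8 samples, 30 loci);
the end-result suite additionally forges one population at the full study
conditions (84 samples, 254 loci, coverage 100×) for typing,
heteroplasmy-recovery, clustering, copy-number and taper checks, with
counts simulated at the differential loci (the quantities under test are
locus-level). The whole suite completes in well under a minute on one
CPU.

## Known limitations

- Exact-match repeats and substitution-only homology chaining (above).
- Depth-1 conformation enumeration; no probabilistic structural-variant
  genotyping.
- One alternate allele per locus in the population matrix.
- Junction support requires exact containment of the full
  flank+repeat+flank signature; a mismatch parameter would be needed for
  error-prone real reads and is deliberately not defaulted on.
- Whether a linear molecule recombines with other chromosomes cannot be
  decided when no read spans its terminal repeats; the package reports
  junction evidence and abstains.
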