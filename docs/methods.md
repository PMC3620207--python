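# Methods

This note documents the models, parameter choices and numerical
conventions behind each pipeline stage, what the synthetic generator does
and does not emulate, and the design decisions taken where the underlying
workflow left the choice open.

## Read cleaning

Reads are single-end, fixed machine length (default 36 nt). Because small
RNA inserts (12–30 nt) are shorter than the read, every real read runs
through into the 3′ adapter; trimming is therefore the defining step. The
adapter is located by first exact occurrence of the full adapter, falling
back to the longest read-end suffix equal to an adapter prefix of at
least `min_overlap` = 7 nt — the convention of common trimmers. Reads are
discarded, with per-reason tallies, when mean Phred < 20, when they
contain an N, when no adapter is found, or when the trimmed insert falls
outside the clean-length window [12, 30] nt. The window follows the
clean-read definition of the source workflow even though the gel excision
there was 18–30 nt; both bounds are configuration keys
(`preprocess.min_len/max_len`). The accounting identity (input = clean +
Σ discards) is asserted on every run, and collapsing to unique tags
conserves the clean-read count per library.

## Annotation

Tags are matched exactly against the toy genome on both strands (no
mismatches); tags with zero loci or more than `max_hits` = 1 loci are
excluded from category assignment but kept in the report, mirroring the
keep-unique-matches convention of short-read small-RNA pipelines. Each
retained tag receives exactly one category by a fixed priority walk —
miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > exon > intron >
unannotated — the order used by sequencing-provider pipelines; it is
fully configurable, and swapping it demonstrably flips calls for tags
matching two classes. The miRNA category is a sequence predicate (exact
mature match, or a 3′ length variant up to ±2 nt sharing the 5′ end, the
dominant isomiR mode); all other categories are interval overlaps.
Antisense hits to exonic features are classified as that feature with the
strand recorded. Coordinates are 0-based half-open internally; GFF3 I/O
converts to 1-based inclusive at the boundary.

## Folding model

The folder minimises a deliberately transparent stack-additive energy: a
base pair contributes −3.0 (GC), −2.0 (AU) or −1.0 (GU) kcal/mol only
when it is directly enclosed by another pair, so terminal (unstacked)
pairs score 0 and a k-pair helix scores the sum over its k−1 stacked
pairs. Hairpin loops need ≥ 3 unpaired bases; structures are nested
(pseudoknot-free). The dynamic programme tracks three quantities per span
— best energy overall, best with the endpoints not mutually paired, and
best given the endpoints paired with the pair's own energy deferred to
its encloser — which makes the "terminal pairs score 0" convention exact;
the DP equals an exhaustive enumeration oracle for sequences up to 18 nt
in the test-suite. All energies are sums of the three integer-valued pair
terms, so float equality in the traceback is exact. This is an
approximation, not nearest-neighbour thermodynamics: absolute energies
are not comparable to a thermodynamic folder, though helix-rich hairpins
score far below unstructured sequence, which is all the candidate filter
needs. The `FoldBackend` callable contract allows an external
thermodynamic folder to substitute.

## Novel hairpin candidates

Unannotated, uniquely mapped tags (excluding loci inside known precursor
intervals) are clustered with a 30 nt gap; a cluster's most abundant tag
(support ≥ `min_tag_count` = 5 reads, length 18–26 nt) seeds a window of
100 nt flanks on each side, evaluated on both strands. Acceptance
requires Dicer-consistent geometry in the folded window: the tag fully on
one arm (no self-pairing), ≥ 16 of its bases paired with all partners on
the opposite arm, and a 4–30 nt loop between the arms; the precursor is
then trimmed to the mature–star duplex span (+3 nt so a Dicer-offset star
read fits), refolded, re-checked, and must reach the energy threshold
(default −18 kcal/mol, following the published defaults of hairpin-based
discovery tools; all thresholds are configuration keys). Overlapping
candidates keep the lowest energy, and relaxing the energy threshold can
only add candidates. Star support is declared when another cluster tag on
the opposite arm ends exactly 2 nt past the partner of the mature's first
paired base — the 2-nt 3′ overhang signature of Dicer processing,
measured from the first *paired* mature base so a frayed terminal pair
does not void the check. Candidates are named `novel_mir_<k>` after
sorting by genomic position, and every emitted candidate is structurally
re-validated (balanced brackets, mature-in-arm, energy bound) rather than
trusted.

## Differential expression

Normalisation is reads-per-million of clean reads. The low-expression
rule removes a miRNA only when **both** libraries are below 1 RPM
(`--filter-mode both`): an "either" reading would delete miRNAs expressed
in a single condition, which are precisely the strongly differential
ones; the switch `either` is provided. Surviving zeros are floored to
0.01 so the fold change is defined; thresholds are on the log2 scale with
strict inequalities (a fold change of exactly −2.0 is not called).

The exact test is the Audic–Claverie conditional probability (the
standard two-pooled-library test of this pipeline family; the source
workflow printed its formula only as an image, so this form is adopted
and flagged here). The implementation works in log space via `gammaln`,
sums the lower tail with compensated summation, obtains the upper tail as
its complement plus the observed term — ties therefore count in both
tails, which is conservative — doubles the smaller tail and caps at 1.
One subtlety worth recording: the per-point probability p(y|x) is
exchange-symmetric under (x, y, N₁, N₂) → (y, x, N₂, N₁), but the doubled
tail p-value is not exactly so (the two orientations' tails differ by the
observed term); the tests pin the pmf-level symmetry and the tail
definition separately. Calibration, measured in the acceptance suite:
agreement with an arbitrary-precision summation oracle to < 1e−10 over a
51×51 grid of counts at library ratios {0.5, 1, 2}; empirical type-I rate
0.03–0.07 at α = 0.05 under an equal-Poisson null (mean 100, 2,000
replicates); planted ±3 log2 effects at mean count 100 recovered with the
correct sign in ≥ 95% of 500 replicates.

## Targets, network, enrichment

Seed sites are the canonical taxonomy: a position is an 8mer when the UTR
matches the reverse complement of miRNA nt 2–8 followed by an A opposite
nt 1, a 7mer-m8 with the nt 2–8 match alone, a 7mer-A1 with the nt 2–7
match plus the t1 A; at a given start position only the highest tier is
reported, and overlapping sites at different starts are all reported. U/T
are equivalent on input. No context scoring, conservation or 3′
supplementary pairing is attempted; an externally predicted site table
can be merged as a union with a provenance column, mirroring
multi-predictor workflows. Edges of the bipartite network are unique
(miRNA, gene) pairs with at least `min_sites_per_edge` sites; "hub" genes
have degree ≥ 5, reading "more than four connectivities" literally (the
source workflow's own hub counts are internally inconsistent, so the
cutoff is exposed as a parameter).

Enrichment is the upper-tail hypergeometric probability P(X ≥ k) for a
query of n genes against a set of K in a universe of N, with
Benjamini–Hochberg adjustment across tested sets (Bonferroni by flag).
The universe defaults to all genes carrying at least one gene-set
annotation — the least arbitrary choice when the original background is
unstated — and is overridable. Every emitted row carries its overlap IDs
so k can be re-counted from the row itself.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies
on: two libraries (default 200,000 reads each, chosen so planted effects
sit at count depths where the exact test has power while a full run stays
in tens of seconds on one CPU); an insert-length distribution peaked at
22 nt; a category mixture in the spirit of the source study (miRNA a few
percent, unannotated the majority — no attempt to match its exact
percentages); 50 known miRNAs with log-normal abundances; 10 planted
log2 effects of magnitude 3 (half up, half down), assigned to miRNAs at
or above the median abundance so the planted signal is at detectable
depth — the detectability regime the recovery claims refer to; 5 planted
novel hairpins (24 nt arms, 4–15 nt loops, 2 interior mutations on the
star arm so loci map uniquely, 0.8 probability of a 5′ U, and star reads
carrying the 2-nt Dicer offset); ncRNA degradation fragments drawn from
typed feature intervals (400 species) and random genomic fragments (250
species); adapter read-through; uniform per-base substitution errors
(0.001); and a 2% low-quality contaminant fraction. Everything is
deterministic in one root seed via named substreams, so reruns are
byte-identical and an independent sampling seed can redraw the noise
around a fixed truth.

It does **not** emulate: realistic position- or cycle-dependent error
profiles, quality-score distributions (qualities are constant high except
the contaminant knob), ligation or PCR bias, isomiR spectra beyond 3′
trimming variants, multi-mapping repeat structure at genome scale, or
biologically coupled UTR/target structure (UTRs are random sequence, so
network edges arise from chance seed matches). Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
signal under idealised noise — not performance on real libraries.

## Numerical and degenerate-input conventions

Zero-read libraries produce valid empty FASTQ with a warning; empty tag
collections give all-zero (never NaN) distributions; empty candidate sets
give zeroed summaries. Hypergeometric inputs are bounds-checked and fail
loudly. Malformed FASTQ fails naming the record index. Infeasible feature
placement in the generator fails after 500 bounded retries naming the
constraint. Tables are sorted with stable keys (fold change ascending;
adjusted p then set name; genomic position) so outputs are reproducible
regardless of iteration order.

## Problem sizes used in tests

The shared integration fixture runs 2 × 30,000 reads on a 60 kb contig
with 20 miRNAs and 3 planted hairpins; the acceptance suite runs the full
default scale above. These sizes were chosen as the smallest at which
every statistical claim is comfortably inside its tolerance.

## Known limitations

Two pooled libraries only — no replicate-aware dispersion modelling (a
negative-binomial framework would be the upgrade path); the folding model
is not thermodynamic; enrichment p-values on random gene sets are only as
meaningful as the synthetic universe; and the published per-miRNA
p-values cannot be recomputed without the original deposited libraries,
so the printed summary tables are used as classification inputs, not as
regression targets.
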