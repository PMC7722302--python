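# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic generator does and does
not emulate, and the numerical choices made where the design was open.

## Read QC and collapsing

Five filter rules are applied per raw read, in a fixed order so every
rejection is attributed to exactly one rule:

1. quality — more than 4 bases with Phred < 10, else more than 6 bases
   with Phred < 13 (evaluated on the full raw read, adapters included);
2. homopolymer — one nucleotide makes up ≥ 90% of the insert;
3. adapter — a 5' adapter contaminant (read begins with ≥ 8 bases of
   the 5' adapter), else a missing 3' adapter (no ≥ 8-base prefix of
   the 3' adapter anywhere in the read; the leftmost match wins and
   defines the insert);
4. no insert — trimmed insert of length 0;
5. length — trimmed insert < 18 nt.

The ordering, the 90% homopolymer definition and the 8-base adapter
match are implementation choices; the rules themselves and the 18 nt
floor are the analysis's stated filter criteria. Whether the original
filtering trimmed adapters before or after the quality rules is
unknowable from the description; quality here sees the full read.
Survivors are collapsed to unique insert sequences with counts
(`seq{i}_x{count}`); counts, not unique sequences, weight every
downstream statistic (a `--unique` switch inverts this in the CLI).

## Mapping and best-hit filtering

Reads are placed ungapped on both strands with ≤ 3 substitutions; `N`
counts as a mismatch wherever it sits. The mapper splits each read
into `max_mismatch + 1` disjoint chunks; by pigeonhole any qualifying
placement contains at least one exact chunk, so exact k-mer lookups
plus vectorised verification enumerate every placement. Any algorithm
with this contract is conforming; the test suite pins the behaviour to
an exhaustive sliding-window Hamming oracle on small genomes.

Mismatches in the last two read positions (read orientation) are
treated as putative non-template 3' additions ("tail"); all others are
internal. Best-hit filtering keeps, per read, only hits with minimal
total mismatches (tail included in the total), then discards hits with
> 1 internal or > 2 tail mismatches. Multi-mapping reads keep all
surviving best hits; downstream stages decide the weighting (piRNA
statistics use 1/hit-count, annotation counts each read once).

## Annotation cascade

Precedence miRNA > tRNA > rRNA > mRNA > repeat > none, with a ≥ 50%
read-overlap requirement; both the order and the overlap rule are
package choices, fashioned after the common annotation cascade of
small-RNA classifiers. Ties at equal precedence resolve to the larger
overlap, then the lexicographically first feature id, making labels
order-independent. tRF sub-typing: a read is a 5'-tRF (3'-tRF) when
its 5' (3') end lies within ±1 nt of the mature tRNA terminus. Repeat
reads are sense/antisense by hit strand versus the annotated repeat
orientation; repeats of unknown orientation count separately. Class
fractions use reads successfully mapped to the genome as denominator.

## miRNA locus discovery

Hits pooled across libraries (mapped at ≤ 2 mismatches for this stage)
are clustered with a 200 nt gap. A locus is accepted when

* read support ≥ 10 (weighted by collapsed counts),
* ≥ 80% of read mass on one strand,
* dominant read length within 20–24 nt,
* a star partner exists: a disjoint 5'-position group on the same
  strand, within 150 nt, supported by ≥ 2 reads, whose sequence pairs
  with the mature arm at ≥ 60% of positions (Watson–Crick plus G:U)
  under the canonical duplex geometry with a 2-nt 3' overhang.

The pairing check is a maximal-complementarity heuristic, not
thermodynamic folding — deliberately: it is deterministic, fast, and
testable against planted hairpins, at the cost of accepting a small
rate (≈ 0.3% per candidate pair) of spurious duplexes on random
sequence. The star-support and arm-distance floors suppress exactly
that failure mode on dense single-strand read fields.

Naming: best local alignment (match +2, mismatch −3, gap −5/−2)
against known hairpins, converted to a Karlin–Altschul E-value
E = K·m·n·e^(−λS) with λ solved numerically for the +2/−3 ungapped
score system (λ ≈ 0.634) and K ≈ 0.41 (standard ungapped
approximation). A locus is named after its best hit when E < 1e-6 and
is otherwise `novel-k`. The E-value model is ungapped while the
alignment allows gaps; for the decision threshold involved (19+ nt of
exact identity needed on this problem size) the approximation is
immaterial.

## piRNA diagnostics

**Candidates** are mapped reads of 24–35 nt labelled `none` or
`repeat`. The lower bound is 24 nt rather than 30 nt so the
`[24, pimax]` window criterion of the cluster caller is meaningful; the
size window is configurable because descriptions of this population
vary between 30–34 and 30–35 nt. 1U statistics are reported on the
`none` (intergenic) fraction, which is where the 5'-uridine bias of
primary piRNAs is diagnostic.

**Ping-pong profile.** For overlap o ∈ 1..30, the pair mass n_o sums,
over opposite-strand 5'-position pairs at exactly o nt 5' overlap, the
product of the read counts at the two positions (unique-sequence
weighting is available). Z(o) = (n_o − mean of the other 29 masses) /
their sample standard deviation; with fewer than two overlaps carrying
mass the background is undefined and Z is reported as 0 with a flag.
Note the calibration: under a null of unstructured positions Z(10)
behaves like √(1+1/29)·t(28), so |Z| < 2 holds in ≈ 94–95% of null
data sets, slightly less than the normal-theory 95.4%. The ping-pong
length matrix accumulates mass for exact 10-nt-overlap pairs into both
(len_a, len_b) and (len_b, len_a), so it is symmetric and a row
marginal is the pair mass in which that read length participates.

**Clusters.** 1 kb windows, 100 nt step, over candidate read mass
weighted 1/(genomic hit count). A window qualifies at mass ≥ 10 when
its 1U fraction is ≥ 0.5 or ≥ 75% of its mass has lengths in
[24, pimax] (pimax 35 accommodates piRNAs > 32 nt). Qualifying windows
merge; the merged interval is trimmed to the span of its supporting
reads (without trimming, 1 kb windows overhang a locus by up to
~900 nt per side and interval accuracy degrades); loci < 1 kb are
dropped. Cross-library merging is a plain interval union — idempotent,
commutative, oracle-tested against a sweep-line. The caller is a
simplified re-implementation of the sliding-window cluster-prediction
idea; exact concordance with any particular external caller is not
promised. On libraries containing repeat-derived reads, repeat copies
with piRNA-like lengths can legitimately qualify and merge into called
loci — real piRNA clusters are transposon-rich, and this caller makes
no attempt to exclude them.

## Differential expression

Counts are normalised per library to reads per million *of the same
class* (miRNA genes against total miRNA reads, tRFs against total tRF
reads, piRNA clusters against clustered piRNA reads), so composition
shifts within a class are separated from shifts of the class as a
whole. Entities below 100 RPM in every timepoint are dropped; the
mean-RPM ≥ 100 filter applies only at candidate selection. Rows and
columns are clustered by average linkage on Pearson distance
d = 1 − r, computed on raw RPM rows; row Z-scores (sample sd; constant
rows flagged and zeroed) are display values. Clustering runs through
scipy's agglomerative linkage and is pinned to an O(n³) reference
implementation in the tests. The two clusters of the final row merge
are group-a/group-b, group-a being the one with the higher mean row-Z
at 24 h (the amputation-induced group). "Upregulated upon amputation"
compares the maximum post-amputation RPM against 0 h (≥ 2-fold; a zero
baseline with later expression counts as upregulated) with mean RPM
≥ 100.

## Downstream statistics

**Target scanning** is a documented seed-plus-score approximation of
energy-model target predictors: a site requires a perfect
Watson–Crick match of miRNA positions 2–8 (one G:U tolerable), scored
ungapped over the whole duplex at +5/WC, +2/G:U, −3/mismatch with the
seed region weighted 4-fold, threshold 140 (a perfect unsupplemented
seed). Absolute site counts from energy-model predictors are therefore
not comparable; planted-site recall and seed-match statistics are.

**GO enrichment**: per term, a 2×2 chi-square without continuity
correction (targets with/without term versus non-target background
with/without); terms with any expected cell < 5 are excluded from
testing; significance is Bonferroni-strict at 0.05/n_tested. The
background defaults to all genes with annotation, minus the target
set.

**Phenotype scoring**: lesion/lysis dominates; 0 photoreceptors is
no-PR, 1 is cyclopia; paired photoreceptors are irregular when the two
surface areas differ by more than 33% (difference relative to the
smaller area — the reading under which "140 versus 100" is a 40%
difference), when the eye distance relative to head diameter deviates
more than 33% from the control mean, or when the surrounding white
region is absent. Eye-size comparisons use the pooled-variance
two-sample t-test, two-tailed, on per-animal mean photoreceptor area
(Welch behind a flag); the variance ratio of relative eye distances is
reported descriptively, as no test is specified for it.

## The synthetic generator

`build_genome` plants non-overlapping features on uniform-random
contigs (default 2 × 100 kb): hairpins as 21 nt arm + 12 nt loop + a
3' arm complementary to the 5' arm with 2-nt 3' overhangs; 72 nt
tRNAs; 150 nt rRNAs; 800 nt mRNAs with 200 nt 3' UTRs; repeat
families as exact multi-copy consensus insertions with recorded
orientation (unknown for ~20% of families); 5 kb piRNA clusters placed
with a 2 kb margin so kb-window density scans can resolve adjacent
loci. Exact repeat copies make sense/antisense classification
consistent across every placement of a multi-mapping read.

`simulate_library` allocates reads multinomially over QC-artifact
rules and classes, so class counts are binomial around their planted
shares. Defaults are the study conditions the analysis expects:
mixture 12% miRNA, 13% tRF, 4% rRF, 6% mRNA, 21% repeat, 44%
intergenic piRNA; 1U fraction 0.775; ping-pong pair fraction 0.3;
antisense:sense repeat ratio 2.4; 80% of tRFs 5'-anchored; miRNA
lengths peaked at 22 nt; piRNA lengths uniform on 30–34 nt; per-rule
artifact rates 0.4%. Ping-pong pairs are emitted as exact
opposite-strand pairs with 10 nt 5' overlap, both members subject to
the 1U rate (a 10A bias on the partner read is settable but off by
default, as no such bias is asserted for this system). Reads are exact
genome substrings with Q30 qualities and an appended 3' adapter;
artifact reads violate exactly one targeted QC rule. Inserts are
re-drawn if they would spuriously trigger a QC rule (chance adapter
prefixes, homopolymers), so planted QC counts are exact.

What the generator does **not** emulate: sequencing errors, ligation
and PCR biases, isomiR 5' heterogeneity, genuine RNA secondary
structure, divergent repeat copies, and genome-scale realism (contigs
are ~three orders of magnitude smaller than a real assembly).
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of planted structure, not robustness to
real-data noise sources outside this list.

## Problem sizes and determinism

Test and acceptance runs use 6 000–50 000 reads against 40–200 kb of
genome, sized so planted parameters are recoverable within 3 binomial
standard deviations while the whole suite stays desk-scale. All
randomness flows through `numpy.random.default_rng` seeds carried in
the spec objects; identical specs produce byte-identical FASTQ and
truth tables. Agglomeration ties follow scipy's deterministic merge
order; annotation ties are broken as described above; cluster calling
and locus discovery are invariant to read input order.
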