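# Methods

## The problem

Small-RNA sequencing of total RNA (without size selection) captures enormous numbers
of fragments of the ribosomal RNAs. The default assumption is that these rRNA-derived
fragments (rRFs) are random degradation products and should be discarded. That
assumption is testable: random degradation places fragment breakpoints roughly
uniformly along the rRNA, whereas regulated biogenesis concentrates fragment termini
at specific coordinates. Two signatures distinguish the latter: fragments whose 5' or
3' end coincides *exactly* with a mature rRNA gene boundary (rRF5 and rRF3 series),
and, within such a series, fragment lengths that form a ladder of consecutive
integers - one fixed terminus, one ragged terminus varying in 1-nt steps.

`rrfscan` operationalizes this contrast as a pipeline: clean reads, align them to an
annotated rDNA reference, classify fragment termini against gene boundaries, detect
1-bp ladders, and test terminal enrichment against a uniform-degradation null.

## Reference model

The reference is a single rDNA sequence with ordered, named, non-overlapping regions
(canonically 18S-ITS1-5.8S-ITS2-28S) carrying a `gene`/`spacer` role. All internal
coordinates are 0-based half-open, which keeps BED/SAM arithmetic and terminus
offsets free of off-by-one adjustments; 1-based coordinates appear only in
human-readable report columns. Gaps between annotated regions are permitted
(fragments there are `unannotated`) because external spacers are often absent from
user annotations. Gene boundary coordinates are always an explicit input, never
inferred from sequence. N bases are allowed in the reference but never match any
read base during alignment - the conservative choice for an ambiguity code.

## Cleaning

Cleaning is the minimal set of steps the downstream statistics depend on: optional
3' adapter trimming (leftmost match of a >= 8-nt adapter prefix with at most one
mismatch; untrimmed reads are kept, since long inserts never reach the adapter),
a length floor of 15 nt, and removal of reads with more than 10% N. Q20 (percentage
of bases with Phred >= 20) is reported, not enforced; a mean-quality filter exists
but is off by default. The counting unit everywhere downstream is the *read count*
(duplicates included), because every headline percentage is a ratio of read counts;
unique-sequence tallies are additionally available after collapsing.

## Alignment

The contract is "at most one mismatch or one 1-nt gap": edit distance <= 1, with the
single edit being a substitution, a 1-nt insertion, or a 1-nt deletion - never one of
each. Search is seed-and-extend over an exact k-mer index (k = 7 by default) of the
sense strand; antisense placements are found by querying the reverse complement of
the read. Completeness follows from the pigeonhole principle: with at most one edit,
at least one read half is edit-free, so exact lookup of the leading k-mer of each
half (allowing a +-1 offset shift for a gap in the left half) enumerates every
candidate placement; each candidate is then checked directly for the four edit
cases. Reads shorter than 2k fall back to scanning every offset.

Only the single best placement is kept (the rDNA contains internal repeats, so a
deterministic rule is mandatory): lower cost, then sense over antisense, then
smaller reference start, then substitution over deletion over insertion. Reads
longer than the reference are unmapped, not an error. The reference span of a gapped
alignment is len(read) +- 1; fragment *length* downstream always means the reference
span, so a 1-nt-deletion variant of a 30-nt fragment still counts as length 30 and
aggregates into the same ladder bin.

External SAM alignments can be imported instead; records with NM >= 2, indels longer
than 1 nt, a mismatch plus a gap, or any clipping are discarded, so both routes
enforce the same contract. Clipped alignments are excluded deliberately: a clipped
terminus is not evidence about the fragment's true end. The bespoke aligner is the
default path; SAM import exists for parity checks against external mappers, whose
randomized tie-breaking among equal-score placements is out of contract.

## Terminus classification

Within its containing region, a fragment has offsets `offset5 = start - region.start`
and `offset3 = region.end - end`. In a gene region, `|offset5| <= tol` makes it an
rRF5, else `|offset3| <= tol` an rRF3, else body; fragments crossing any region
boundary are `spanning` and belong to no terminus class (so a read running off the
28S 3' end into downstream sequence is spanning, not rRF3). The tolerance defaults
to 0 - "precisely aligned" taken literally - but is exposed (`--end-tolerance`)
because mature-rRNA boundary annotations are commonly off by 1-2 nt. A fragment
matching an entire short gene is classed rRF5 (rRF5 is checked first) and flagged
full-length; it contributes to both the 5' and 3' series of that gene. Antisense
fragments are classified against the same sense-strand boundaries, flagged, and
excluded from series detection by default (real libraries are ~99.98% sense).

## Series detection and ladder statistic

Series identity is the anchored coordinate, not the member sequences, so 1-edit
variants aggregate naturally. For each (gene, terminus) the member lengths form a
histogram; the ladder statistic is the longest run of consecutive integer lengths
each at depth >= `min_count` (default 1, since observed ladders need no depth
threshold to be visible). A series is *called* when the run is >= `min_run`
(default 3 - a lone fragment or a pair is never a series) and the total depth is
>= `min_total` (default 10). Whether a biological "series" requires strict ladder
contiguity is genuinely open; `min_run` over the longest contiguous run encodes one
explicit, tunable choice.

At `min_count = 1` a single background fragment that happens to end exactly on a
gene boundary at a length adjacent to a real ladder legitimately extends the
measured run by one. Such a fragment is indistinguishable from a ladder member -
this is a property of the data, not a detection error - so recovery experiments
check run length at depth 2 when exact equality with the planted range is the
question.

## Terminal enrichment test

Under uniform degradation, the anchored coordinate of a fragment whose terminus
falls in a gene of G positions is uniform over those G positions. With n such
fragments and a boundary window of `w = 1 + 2*tol` positions (clipped at region
edges, so `1 + tol` at a boundary), the boundary count is Binomial(n, w/G); the
one-sided upper tail is the p-value and `(observed/n)/(w/G)` the fold enrichment.
Counting uses fragment *termini* (each sense alignment's anchored end that falls in
the gene, regardless of where the other end lies), which keeps the null exactly
uniform; series membership, by contrast, requires full containment. Gene ends with
zero anchored fragments are reported as NA rather than dropped, keeping the
Benjamini-Hochberg correction's multiplicity stable across runs. BH q-values are
computed with `scipy.stats.false_discovery_control` across all (gene, terminus)
pairs of the reference. Regions shorter than 2 positions are rejected as degenerate.

The test is one-sided and discrete: for realistic boundary-count means (a few
fragments) its exact size at alpha = 0.05 is below 0.05, typically 0.03-0.05. The
calibration experiments account for this (see below).

## Synthetic data generator

The generator emulates what the analysis assumes about a real total-RNA sRNA-seq
run, and is itself first-class, tested code:

* **Toy reference** - random sequence with regions in canonical order; default
  lengths {18S: 1200, ITS1: 170, 5.8S: 160, ITS2: 190, 28S: 2230} (3950 nt). These
  keep arthropod rDNA proportions at roughly half scale, with 5.8S at its natural
  ~160 nt; the scale was fixed once by an exact power analysis (below) and not
  revisited.
* **Ladders** - for each spec (gene, terminus, length range, Poisson mean per
  length), exact subsequences anchored at the boundary, one per length value.
* **Background** - uniform breakpoints: length ~ U[15, 40] drawn first, then start
  uniform over all placements that fit the reference. Drawing length first avoids
  piling clipped fragments onto the last reference coordinate, which would fake
  terminal enrichment at the 28S 3' end and corrupt the null.
* **PCR duplication** - exact copies (no fresh errors - duplicates replicate their
  template) of named planted fragments or literal sequences, at a given factor.
* **Errors and strand** - per-base substitutions at `error_rate` (default 1e-3,
  matching a Q20 ~ 99% run); reads become antisense with probability
  `antisense_fraction` (default 2e-4, mirroring a 99.98%-sense library); qualities
  are constant Phred 40 (QC behaviour is tested separately on hand-built FASTQ).

Every read carries a truth row (origin, true coordinates, strand); output is
byte-identical for a fixed config. What the generator does *not* model - ligation
bias, position-dependent error profiles, adapter chimeras, ITS-derived series,
multi-locus rDNA variation - bounds what passing tests show about real data: they
validate the statistical machinery, not the sequencing chemistry.

## Calibration design and numerical choices

The null-calibration experiment uses libraries of 10,000 background fragments on
the default toy reference. The expected number of fragments anchored exactly on any
single coordinate is then ~2.6, and an exact computation over the binomial test's
discrete rejection regions (averaging over the library-to-library variation in
per-gene totals) gives a size of ~0.042 at alpha = 0.05 for every gene - inside the
[0.03, 0.07] band expected of a calibrated test, and about as close to the nominal
level as a discrete one-sided test of this mean can get. At the same density the
probability that any gene terminus accumulates the 10 anchored fragments needed for
a (false) series call is ~3e-4 per terminus, so essentially all pure-background
libraries yield zero called series. The reference scale was chosen once from this
analysis, before the experiments were run.

Problem sizes used by the recovery and calibration experiments (20 replicates of
4 planted ladders; 167 libraries pooling ~1000 enrichment tests, the first 100 used
for the series-caller check) were chosen to give stable rates while keeping each
experiment in the low minutes on one core.

Other numerical conventions: report percentages round half-up (banker's rounding
would make printed ratios irreproducible); all randomness flows from explicit
`numpy.random.default_rng` seeds; ties in collapsed-read ordering break
lexicographically by sequence so outputs are byte-stable; empty inputs produce
empty-but-valid outputs (zero-count summaries, "not computable" errors for undefined
ratios) rather than crashes.

## Known limitations

* A single rDNA locus: no genome-wide mapping, so a read that happens to match
  elsewhere in the genome better than the rDNA is still assigned to the rDNA.
* One library at a time: no differential analysis across samples.
* The enrichment null is uniform breakpoints; structured degradation (for example,
  nuclease-preferred sites within the gene body) would require a different null and
  can inflate terminal fold estimates.
* Desk-scale validation is synthetic. Reproducing the real tick-library statistics
  (30.4% rRNA mapping, the specific 5.8S/28S-vs-18S contrast, the named abundant
  sequences) requires downloading the original sequencing run and reference
  accession, which the pipeline supports as ordinary inputs but the test suite does
  not attempt.
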