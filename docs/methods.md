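# Methods

This note records the models, conventions and design choices behind
`lg4scape`, in the package's own words: what each stage computes, which
parameters matter and why their defaults are what they are, what the
synthetic worlds do and do not emulate, and where the numerics make
choices that a user should know about.

## Coordinates and upstream windows

All user-facing coordinates are 1-based and inclusive on both ends
(`Chr5:551935:556936` denotes 5002 bp), matching Ensembl and the curated
enhancer tables this package consumes.  BED files are converted to and from
their native 0-based half-open convention only inside `io.py`.

Promoter upstream windows are given as offset pairs `(far, near)` in bp
upstream of a TSS and denote the half-open span `[-far, -near)`, of length
`far - near`.  This is the only convention simultaneously consistent with all
three reference deletion-construct lengths the package verifies (2108/1126 →
982 bp, 1592/1444 → 148 bp, 1592/1557 → 35 bp), which is why those three
checks are part of the acceptance surface: they pin the convention.

For a minus-strand gene the upstream window is mirrored downstream of the TSS
in genome coordinates.  Whether real-world "5 kb upstream" tabulations were
strand-resolved is rarely stated; strand resolution is the default here and
`strand_resolved=False` reproduces the always-leftward alternative.

## G-triplet counting and LG4 calling

A **G-run** is a maximal stretch of ≥ 3 consecutive Gs on one strand; minus
strand content is read as C-runs on the plus-strand text so coordinates stay
in one frame.  N never matches G or C, and a run interrupted by N is two runs.

**GGG repeats** are counted by non-overlapping tiling: each maximal run
contributes `floor(run_length / 3)` (so `GGGGG` → 1, `GGGGGG` → 2).  "Repeats"
implies tiling; the alternative reading (one count per run) is available as
`counting_mode="runs"`.  The synthetic generator plants only isolated
exact-GGG tracts in promoter windows, so planted counts are identical under
both modes.

**Minimal G4 motifs** are four consecutive maximal G-runs whose three loops
all lie in `[loop_min, loop_max]` (default 1–7 — the conventional
quadruplex-prediction loop bound; the motif definition itself says only
"short spacer").  Scanning is greedy left-to-right and non-overlapping.

**LG4 calling** uses a two-scale scan, because the published density
criterion (≥ 80 GGG repeats / 1000 bp) specifies the *what* but not the scan
mechanics:

1. sliding windows (default 1000 bp, step 100 bp) are marked when either
   strand's tiled repeat density reaches the threshold; overlapping marked
   windows are merged into candidate regions;
2. each candidate is refined to the span from its first to last qualifying
   *step-bin* (a 100 bp bin qualifies when its own density reaches the
   threshold), which anchors boundaries near the dense sequence instead of
   the coarse window grid — a window that only grazes a dense block still
   marks, but its background-only bins do not.  If no single bin qualifies
   (diffuse signal near threshold) the full candidate is kept;
3. the refined span is trimmed to the outermost contributing G- or C-run,
   so call edges always land on sequence, and calls shorter than
   `min_length` (default 1000 bp) are discarded.

Window/step/min-length defaults are chosen so that the multi-kilobase
reference loci are comfortably callable; all four values are configuration
parameters.  Lowering the density threshold can only grow calls (monotonicity
is property-tested), and every call re-attains threshold density when its own
sequence is rescanned in isolation.

The **composite availability ratio** of an LG4 against a promoter set is its
both-strand tiled repeat count divided by the mean both-strand count of the
promoters — a dimensionless measure of how many promoter-equivalents of
G-tract material one LG4 carries.  A zero promoter mean yields NaN with a
warning rather than an exception.

## Enrichment statistics

**Matched controls.**  Control loci are drawn uniformly at random
(chromosome-length weighted), each matched to its source locus in exact
length and in GC fraction within ±0.02 (configurable), rejected if it
overlaps any source locus or a control already placed in the same set, with
1000 placement attempts before a named error.  In a homogeneous background
genome a GC-rich query locus has no matched territory; the demo world
therefore plants a ladder of GC-shifted background blocks spanning the
mosaic generator's own composition range (~0.60–0.64).

**Overlap enrichment.**  Comparing one real overlap count against a handful
of control-set counts with a t-test is ill-posed (one observation has no
variance), so the default contract compares per-locus overlap indicators
(real loci vs pooled control loci) with an unpaired one-tailed
pooled-variance t, direction real > control.  The per-set construction is
retained behind `mode="per_set"` for fidelity with how such comparisons are
sometimes reported.  Zero-variance degenerate inputs return t = 0 with the
boundary p (0.5 one-tailed / 1.0 two-tailed) and an explicit flag.

**Chi-square on promoter G-triplets.**  Triplets are enumerated over both
strands of each promoter's upstream window and pooled per group; the 2×2
table is `[triplet slots, non-triplet slots]` per group, where one slot is
3 bp (`[count, floor(total_bp / 3) − count]`).  Slot units keep groups with
unequal window totals comparable *and* keep the statistic calibrated: the
superficially natural base-pair occupancy table (3 bp per motif) multiplies
every cell — and hence the statistic — by three for identical proportions,
which would triple the type-I error.  The bp table remains available as
`table_units="bp"`; no continuity correction is applied by default (a Yates
flag exists).  Null calibration (5 % ± 2 % rejections at α = 0.05 over 1000
same-distribution replicates) is asserted in the acceptance suite.

**Fusion neighborhoods.**  Intra-neighborhood fusion counts (both partners
of a fusion pair inside one gene neighborhood) are compared real-vs-control
with an unpaired two-tailed t; an empty fusion list short-circuits to a
flagged degenerate result.  No multiple-testing correction is applied by
default anywhere in the package.

## Pore-C contact mining

**Masking.**  Promoter stretches longer than 100 bp that occur perfectly at
two or more genomic locations (either strand) are replaced by N before any
alignment; a duplicated stretch of exactly 100 bp stays (the rule is
strictly "greater than").  Implementation: the union of duplicated
101-mers equals the union of maximal duplicated substrings longer than
100 bp.  The k-mer occurrence dictionary makes this practical for the
megabase-scale synthetic genomes this package targets, not for a full
mammalian genome.

**Alignment.**  Fragments are placed by exact k-mer seeding (word size 15)
grouped per (chromosome, strand, diagonal), chains split at seed gaps over
150 bp, and gapless extension at match +2 / mismatch −3 to the
maximal-scoring segment containing the seed chain.  The package's error
model is substitution-only, for which gapless extension at these scores is
exactly optimal; the affine gap parameters (open 5, extend 2) are accepted
for interface compatibility and a fragment spanning a true indel is
reported as two segments.  Low-complexity sequence is deliberately not
filtered.

Read segments are selected greedily by descending score.  A selected
segment's neighbours are *clipped*, not discarded, where they overlap it on
the read: extension can bleed a short distance across a ligation junction
(the first bases of the adjacent fragment match by chance with probability
¼ per base), and discarding the overlapped true fragment would silently
drop real contacts.  Clipped segments are rescored over their remaining
span and dropped below `min_score` (default 100, i.e. 50 perfectly matched
bases — a stand-in for the stringent e-value thresholds used with BLAST at
genome scale, where e-value is monotone decreasing in score at fixed
parameters; that monotonicity is why "lowest e-value" is implemented as
"highest score").  Consequence: a recovered fragment's boundaries can
jitter by a few bases relative to its true restriction fragment, and two
genomically adjacent fragments sampled consecutively into a read merge
into one segment; contact calls, which depend only on interval overlap,
are unaffected, and the test suite asserts exact contact-set recovery but
only coverage-level (≥ 90 %) fragment-boundary recovery.

Tied best placements (a fragment from duplicated sequence) are counted,
resolved to the smallest genomic coordinate (chromosome name, then start),
flagged ambiguous, and excluded from contact calling unless
`include_ambiguous=True` — conservative, since a multi-mapping fragment's
locus identity is unknown.

**Contact calling.**  For each read, every pair of distinct resolved
fragments with non-overlapping read spans where one fragment's target
overlaps an LG4 interval and the other overlaps a promoter window yields
one contact record; distinct supporting reads are tallied per
LG4:promoter pair.  One alignment pass (read fragments → genome, then
interval intersection) replaces the two-pass promoters→reads→genome
procedure used with BLAST at archive scale; at the scale this package
operates the two are equivalent for contact calling, and the top-N
highest-scoring-read pre-filter used there is likewise a scale-management
step that is unnecessary here.

## The synthetic world

`make_genome` draws i.i.d. background at a configurable GC fraction
(default 0.5, giving ~24 tiled GGG repeats/kb summed over both strands —
well under the 80/kb calling threshold).  Planted elements are validated
for fit and mutual non-overlap before any base is drawn:

* **LG4 blocks** — either exact unit repeats (`GGGT` × 500 → 2000 bp at
  exactly 250 repeats/kb; tiling closure is exact by construction) or
  aperiodic *mosaic* blocks of GGG tracts with random 1–7 bp non-G spacers
  (~140 repeats/kb).  Unit repeats are ideal for density arithmetic but
  multi-map internally; mosaic blocks have effectively unique k-mers, so
  concatemer fragments drawn from them align unambiguously — contact
  simulations use mosaics.
* **Promoter windows** — the window background is scrubbed of incidental
  plus-strand GGG runs, then the requested number of isolated `GGG` tracts
  is planted on a 5-bp grid with non-G guard bases, making the plus-strand
  count exact under either counting mode.
* **Duplications** — verbatim copies at seeded random non-overlapping
  positions, for masking and ambiguity tests.
* **GC blocks** — composition-shifted background with plus-strand GGG
  scrubbed, providing matched-control territory.

`digest_genome` cuts immediately 5′ of each GATC (DpnII); fragments tile
each chromosome exactly.  `simulate_porec` builds each read from 3–12
digest fragments (uniform; the real fragment-number distribution is
dataset-dependent and this default is a modelling choice): with the
configured per-pair probability the read carries one fragment overlapping
the LG4 and one overlapping the promoter window, plus fillers from within
±250 kb of an anchor (mimicking insulated-neighborhood locality without a
polymer model; the demo uses ±25 kb so background reads cannot span an
LG4–promoter gap); otherwise all fragments come from one random
neighborhood.  Fragments are independently strand-flipped, substituted at
the configured rate (substitution-only — no indels, so alignment score
arithmetic stays exact; an indel model is deliberately absent), shuffled
and concatenated.  Fragments shorter than 150 bp are not sampled, so every
simulated fragment is alignable above the default score threshold.

Each read's truth records every fragment's source interval and the read's
*realized* contact pairs (computed from the assembled fragments, not from
the Bernoulli intent), so truth-closure tests are exact even when filler
fragments incidentally create a contact.

What a green test does **not** establish: the generator has no realistic
nanopore error profile, no indels, no crosslinking or ligation-efficiency
chemistry, no chromatin polymer model, and its genomes are orders of
magnitude smaller than a mammalian genome.  Genome-scale published
quantities (the 301-locus catalogue, genome-wide promoter triplet means,
the 74-fold availability ratio) depend on the full human genome plus
external databases and are *not* reproduced here; the test surface instead
verifies the operations that would produce them, on worlds where the truth
is known exactly.

## Numerical and degenerate-input conventions

* Chi-square identical-proportion tables return exactly 0 with p = 1.
* Zero-variance t inputs return t = 0, boundary p, and a flag; expected
  chi-square cells below 5 flag `low_expected_count`.
* All randomness flows from a single integer seed per operation
  (numpy `default_rng`); identical inputs and seed give byte-identical
  outputs, including the whole demo bundle.
* Upstream windows clipped at a chromosome edge are returned truncated
  with a flag rather than erroring.
* Alignment ties break toward the smallest (chromosome, start); greedy
  segment selection breaks score ties the same way, making the aligner
  fully deterministic.

## Known limitations

* The k-mer index and the 101-mer masking dictionary hold Python
  dictionaries over the whole genome: fine to tens of megabases, not for
  hg38.  A full-genome scan would need an on-disk index; the CLI supports
  the mode but it is outside the tested surface.
* The aligner reports no e-values or bit scores; score is the ranking key.
* Mosaic LG4 blocks approximate G4-dense sequence statistically; they are
  not drawn from real LG4 sequence models.
* The per-set overlap-enrichment construction is retained only for
  fidelity; with few control sets it is underpowered and flagged.
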