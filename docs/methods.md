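# Methods

sharpmir implements a small-RNA miRNA discovery pipeline for desk-scale
transcriptome datasets, modelled on the workflow used to annotate novel
miRNAs in the glassy-winged sharpshooter (*Homalodisca vitripennis*): raw
adapter-ligated reads are cleaned and collapsed, mapped onto an assembled
transcriptome, screened against a mature-miRNA reference set, folded into
candidate hairpin precursors, quantified per strand, and scanned against
mRNAs for target sites.  This note records the models, the parameters
that matter, and the design choices made where the procedure was open.

## Curated reference set

The package ships five cross-keyed tables describing 14 novel
*H. vitripennis* miRNAs: mature sequences (all 22 nt), precursor
sequences (52–90 nt), host-transcript origin descriptions with printed
coordinates, precursor secondary structures in dot-bracket notation, and
per-strand read counts (totals 12–1,860, cutoff 10).  These tables are
used both as ground truth for the synthetic-data generator and as direct
inputs for the fixture-level analyses (5' nucleotide bias, origin
rollup, hairpin screening).

Two caveats are stored with the data rather than silently fixed.  The
printed origin coordinates are kept verbatim because their 0/1-based and
open/closed convention is not stated (for one miRNA the printed span is
53 positions but the precursor is 52 nt); the pipeline's own coordinates
are 1-based fully closed, and the generator embeds each precursor at the
printed *start* coordinate only.  The printed structure strings use
typographic ellipsis glyphs for runs of three unpaired positions;
`normalize_structure` expands them and validates balance, and is
idempotent.

## Read processing

**Adapter trimming.** The 3' adapter (default: the Illumina TruSeq
small-RNA 3' adapter, `TGGAATTCTCGGGTGCCAAGG`; the protocol names the
kit, so the kit's published sequence is the default and it is
configurable) is removed by finding the earliest position at which a
prefix of the adapter matches the read with overlap ≥ `min_overlap`
(default 6) and mismatch rate ≤ `max_mismatch_rate` (default 0.1);
everything from that position on is removed.  When the adapter runs off
the 3' end this is exactly the classic read-suffix/adapter-prefix
overlap rule; when the read sequences through the whole adapter into
downstream bases, those bases are removed with it, as real trimmers do.
Reads with no qualifying overlap, or with an empty insert, are rejected.
Qualities are carried but never used: every filter in this pipeline is
sequence-based.

**Length filter.** Default window 18–26 nt for general use.  The strict
reproduction preset filters exactly 22-nt inserts, matching the original
study's filter and the uniform 22-nt mature length.  The
abundance-recovery analysis instead uses 12–30 nt: star strands are not
length-22 in general — under the 2-nt-overhang duplex rule their length
shifts by the net bulge asymmetry, and the inferred stars of the curated
set span 13–27 nt — so a window that keeps every planned star read must
cover at least that range.

**Collapsing** merges identical sequences into one record carrying the
summed count (representative id: lexicographically smallest member);
output is sorted by descending count so the collapsed set is independent
of input order.

**Contaminant filter.** A read is removed iff it occurs as a substring
of any rRNA/tRNA sequence or its reverse complement with ≤
`max_mismatch` mismatches (default 0).

**Mapping** is a direct scan reporting every sense and antisense
placement with ≤ `max_mismatch` mismatches (default 0: discovery
requires exact precursor residency; the only mismatch allowance in the
reproduced protocol — two mismatches — belongs to the reference
comparison, not to mapping).  Antisense hits are recorded but excluded
from precursor discovery and quantification, since precursors live on
sense transcripts.  At desk scale (hundreds of transcripts ≤ a few kb)
the naive scan is fast and serves as its own specification; no index is
built.

## Hairpin model

**Energy model.** A single embedded nearest-neighbor parameter file
(`data/nn_params.json`) backs every energy computation: Watson-Crick and
G:U stack energies (kcal/mol at 37 °C, standard published magnitudes),
hairpin/bulge/internal loop length penalties with Jacobson-Stockmayer
extrapolation beyond the tables, an internal-loop asymmetry penalty
(0.5/nt, capped at 3.0), an affine multiloop term (3.4 init + 0.4 per
branch, no per-nucleotide term), a terminal AU/GU helix-end penalty
(0.5), and a bimolecular duplex initiation penalty (4.1).
Single-nucleotide bulges preserve the flanking stack.  Dangling ends and
coaxial stacking are excluded for simplicity; all screening thresholds
are calibrated to this model (below).  Because the folder and the
evaluator share one parameter source and one loop-decomposition routine,
the reported MFE always equals independent re-evaluation of the returned
structure.

**Folding.** Two folders are provided.  `fold_maxpair` is a
base-pair-maximisation (Nussinov) DP with a minimum hairpin loop of 3,
reporting −1 per pair in surrogate units; it is the simple structural
oracle.  `fold_mfe` is a Zuker-style MFE DP over the nearest-neighbor
model: hairpin/stack/interior terms (interior loops capped at 30 nt
total), multiloop closure requiring ≥ 2 internal branches, free exterior
bases, no pseudoknots.  Both are verified against exhaustive structure
enumeration on short sequences.

**Hairpin screening.** A candidate precursor passes iff
(a) matched base pairs ≥ `min_matched_pairs`,
(b) the mature-bearing stem leads to at most one terminal loop, and
(c) structure energy ≤ `max_energy`.
Every violated criterion is reported.  Two calibration notes:

* `min_matched_pairs` defaults to 15, because the curated published
  structures contain as few as 15 pairs and the default screen must
  accept the reference set it ships; the stricter preset uses the
  stated 18.
* `max_energy` defaults to −5.0 kcal/mol under the embedded model.  The
  stated criterion ("folding energy lower than 18 kCal/mol") is read as
  ΔG ≤ −18 and kept in the strict preset; under this package's
  simplified tables (no dangling ends, conservative internal-loop
  penalties) the curated structures evaluate between −5.97 and −22.1
  kcal/mol, so the default ceiling is set just above the weakest curated
  precursor.  Energy thresholds are meaningful only relative to the
  model that computes them.

The loop criterion is applied to the *mature-bearing stem*, not the
whole window: the pairs touching the mature arm must form a single
nested chain, and the helix path is followed inward, at a multiloop
taking the branch adjacent to the mature arm.  Side branches hanging off
a multiloop are not charged against the mature stem — two of the curated
published structures have a second terminal loop on a side branch and
are nonetheless bona fide precursors.  A mature arm that is entirely
unpaired, spans branching structure, or contains its own terminal loop
fails the screen.

**Star inference.** The star (passenger) span is the segment pairing
with the mature arm, restricted to the mature-bearing stem, with bulged
mature positions bridged through the nearest flanking stem pairs and
each strand's 3' end extended 2 nt past the last base paired with the
other strand (the Dicer 2-nt 3'-overhang geometry).  The span is clipped
to the precursor and trimmed so it never overlaps the mature span.  On a
perfect duplex this yields a star of exactly the mature's length;
composing the rule twice returns to the mature arm within the 2+2-nt
overhang bookkeeping per end.

## Conservation, origins, abundance

**Conservation.** A query is conserved iff some reference mature lies
within `max_mismatch` (default 2) under the minimum-mismatch ungapped
placement of the shorter sequence against the longer with end offsets up
to 2 nt; overhanging bases count as mismatches.  Ties keep the first
reference in input order; an empty reference set yields "novel".
Gapped comparison is deliberately out of scope.

**Origins** are called by a fixed, case-insensitive keyword cascade on
the host-transcript description: "tc3" → TC3 transposable element,
"retro" → retrotransposon, "transposable" → transposable element, any
other informative text → named gene, "uncharacterized"/empty →
uncharacterized.  The first three categories roll up as
transposable-element derived.

**Quantification.** A read's count accrues to a miRNA's mature (or
star) tally iff one of its sense mapping intervals lies within the
mature (or star) arm interval on the host transcript, extended by
`arm_tolerance` nt at each end (default 2 for isomiR slack; 0 in
exact-arm mode, which the recovery analyses use).  Each read is assigned
at most once; mature wins overlap ties.  Records with total below
`cutoff` (default 10) are dropped.  Assigned plus unassigned counts
equal the mapped total, and raising the cutoff can only shrink the
output.

## Target scan

The scanner re-implements a miRanda-style duplex alignment: global in
the miRNA, local in the target, affine gaps, scored match +5, G:U +1,
mismatch −3, gap −9 open / −4 extend, with a 4× scale on miRNA positions
1–8.  These per-position weights are the canonical target-scanner
defaults; the score threshold (≥ 145) is only meaningful relative to
them (a perfect 22-mer duplex scores 8·5·4 + 14·5 = 230).  Candidate
windows of width miRNA length + 8 slide with step 1; each alignment is
screened by the seed rules — no mismatch or gap at miRNA positions 2–7,
at most one G:U there, at most one gap in the whole duplex — and by the
hybridisation energy, a nearest-neighbor stack sum over consecutive
paired columns (G:U included) plus the initiation penalty, with no
intramolecular terms.  A site is accepted iff it passes the seed rules
with score ≥ 145 and energy ≤ −10 kcal/mol.  Overlapping accepted sites
collapse to the single best-scoring one (ties: smallest start, fewest
gaps), and output order is deterministic.  Note the scaled region (1–8)
and the filtered seed (2–7) are independent settings: the filter
implements the stated screening rule, the scale shapes the score.

## Synthetic data

The generator produces exactly the structure the analysis assumes:

* a transcriptome with one host transcript per curated precursor,
  embedded at its annotated start coordinate with seeded random padding
  and the origin text as description, plus random decoys re-drawn until
  they contain no precursor;
* a miRBase-like reference set of random 21–23-nt matures, each verified
  ≥ 3 mismatches from every curated mature (so novelty calls are forced
  by construction), optionally including the curated matures verbatim;
* rRNA/tRNA-like contaminants (random 60–120-mers free of any curated
  mature);
* an adapter-ligated read pool emitting exactly the planned number of
  mature- and star-insert reads per miRNA (stars from the inferred
  spans), plus random background inserts (18–28 nt) and
  contaminant-derived inserts, every read suffixed with the adapter and
  truncated/padded to a fixed 36-nt read length, shuffled
  deterministically.  Ground truth travels in read ids (`name|arm|serial`).

Everything is byte-deterministic under a fixed seed.  The generator does
*not* emulate sequencing error, ligation bias, isomiR end heterogeneity,
or expression noise: a passing recovery test shows the pipeline's
bookkeeping is exact under clean reads, not that it is robust to
platform artifacts.  The default analysis scale (≈ 2,870 planned reads
+ 1,000 background + 500 contaminant reads over 34 transcripts) keeps
every stage inspectable and the whole suite fast; it stands in for the
original 22-million-read library, which is deliberately not required.

## Numerical choices

* Energies are floats in kcal/mol rounded to 10 decimals at module
  boundaries; DP tracebacks compare against recomputed terms with an
  absolute tolerance of 1e-9.
* Folding tie-breaks are fixed by traceback order (pairing preferred,
  outermost first; interior candidates scanned nearest-first), making
  structures deterministic.
* Duplex alignment tie-breaks: smallest target start, then fewest gaps.
* Degenerate inputs: empty FASTA is an empty collection, not an error;
  the open chain has energy exactly 0; a window shorter than the miRNA
  is skipped; an all-unpaired mature arm makes the star uninferable and
  is reported as such.

## Limitations

* The energy model is deliberately small: no dangling ends, coaxial
  stacking, special tetraloop bonuses, or temperature dependence.
  Absolute energies are therefore not comparable to mfold/ViennaRNA
  outputs; only the relative screening behaviour is.
* Published precursor structures are evaluated as printed, not
  re-derived; the MFE folder will generally find slightly lower-energy
  structures than the printed ones.
* Conservation is ungapped; deletions/insertions between query and
  reference are scored as end offsets at best.
* The target scan's sliding window with per-window alignment is
  quadratic per transcript and meant for desk-scale transcriptomes, not
  for genome-wide scans of tens of thousands of mRNAs.
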