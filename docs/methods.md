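# Methods

## Data model and geometry

An annotation is a circular genome length plus features with 1-based,
inclusive coordinates on the heavy (H) strand (GenBank convention); a
feature with `end < start` wraps the origin and has length
`genome_length − start + 1 + end`. Strand is a label (H/L); coordinates
never refer to the L strand, which only matters when sequence is extracted
(reverse complement) or codons are read.

The gap at the junction between consecutive features is
`start_next − end_prev − 1`: positive values are intergenic spacers,
negative values overlaps, zero abutting. For circular annotations the
junction from the last feature back to the first is included, so on a fully
tiled circle feature lengths plus all gaps telescope exactly to the genome
length (a property the test suite checks on random layouts).

### The packaged reference tables

The published coordinate table of the rearranged eel mitogenome
(MT571331, 17,673 bp, 40 features) ships with the package together with its
intergenic and composition columns. Geometry is always recomputed from the
From/To coordinates; the published intergenic column is kept as data and
cross-checked. Exactly two junctions — both flanking O<sub>L</sub> —
disagree (published −7 and 7 vs coordinate-derived 0 and 11), which is why
the published positive gaps total 89 bp over 12 spacers while the
coordinate-derived ones total 93 bp over the same 12 junctions. Both totals
are reported; neither side is silently corrected. Likewise the published
COI row (1,603 bp with a complete TAA stop) is out of frame by one
nucleotide; the validator warns and codon counting skips the gene rather
than truncating it.

## Composition and skew

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C) are computed from
counts or percentages interchangeably (the formulas are scale-free) and
reported at full precision, rounded to 3 d.p. only in rendered reports.
Ambiguity codes are excluded from the four base counts and tallied
separately. Per-feature composition is reported on the H strand for all
features regardless of coding strand — the convention under which the
published L-strand ND6 row reproduces — with a `strand_mode="coding"`
switch for coding-strand slices. Skews recomputed from the published
percentages match the published values to 3 d.p. for most rows; rows whose
printed skew is inconsistent with their own rounded percentages at the
third decimal (whole-genome AT-skew 0.076 vs 0.0754, ND2 GC-skew −0.321 vs
−0.3187) are asserted only to ~3e-3.

## Codon usage

The genetic code is the vertebrate mitochondrial table (NCBI table 2).
Each PCG is extracted on its coding strand, trailing incomplete-stop
nucleotides (`T-`, `TA-`) are dropped, and codons are read in frame from
the annotated start; a gene whose trimmed length is not a multiple of 3 is
skipped with a recorded warning. Counts include the start and any complete
stop codon. For amino-acid frequencies, start codons (including COI's GTG)
are re-assigned to Met — the convention of standard codon-usage software —
and stop codons are excluded from the denominator. RSCU is count ×
degeneracy / family total, with Ser and Leu as single six-fold families and
the stop family excluded unless requested.

## Gene orders and comparison

A gene order is a tuple of signed tokens (sign = strand), circular by
default, compared up to rotation; duplicated elements carry numeric
suffixes (CR1/CR2) that are stripped to a base label for comparisons. The
canonical vertebrate order is the fixed 39-token arrangement anchored at
trnF with −ND6, −E between ND5 and Cytb and a single CR at the end.

`compare_orders` proceeds: (1) surplus duplicate copies in the observed
order are matched to their reference copy by neighbourhood similarity and
set aside; (2) both orders are rotated to the trnF anchor (falling back to
the best common-prefix rotation, ties broken by smallest offset so the
choice is independent of label spelling); (3) maximal sign-flipped runs
that read as consecutive descending reference positions are reported as
inversions and restored; (4) a weighted longest common subsequence finds
the minimal set of moved tokens. When two interpretations are equally
parsimonious (moving block X is indistinguishable from moving the
complementary block Y, as for (−ND6,−E) vs (Cytb,T) in the eel), a tiny
exact power-of-two weight increasing with reference index makes the LCS
retain downstream tokens, i.e. the upstream reference block is reported as
the moved one. This is a declared tie-break, chosen because it reproduces
the field's reading of the eel rearrangement; the alternative reading is
recoverable from the alignment itself. Kinds are classified as
translocation (block moved ≥2 positions), shuffling (adjacent swap),
inversion, duplication, or complex (losses, multiple moved blocks, or
mixtures).

## TDRL inference

A TDRL event is a contiguous reference window plus per-copy kept-sets;
applying it yields prefix + copy-1 survivors (window order) + copy-2
survivors (window order) + suffix, with labels kept in both copies
suffixed 1/2. Events never flip strand signs. Both-copy retention is
restricted to control-region tokens by default (`dup_bases`), matching the
biology of retained duplicate CRs while keeping the search small.

Because an event's output is a *concatenation* of two increasing runs of
window positions, single-event feasibility of an observed segment is
equivalent to the segment having at most one descent of window indices;
every cut position splitting it into two increasing runs yields one loss
bipartition. The search therefore checks, for every window up to the cap
(12 by default), whether the rest of the reference survives intact in the
observed order (rotation-aware) and enumerates the valid cuts exactly —
this is exhaustive over single events and is verified in the test suite
against an independent brute-force enumerator of all windows × all loss
assignments. Infeasibility (e.g. any sign flip, deletion, or duplicate
outside the allowed classes) is returned as a result, not an exception.
Scenarios are ordered by event count, then total window length, then
window position, so the first scenario is the most parsimonious with the
tightest window; for the eel order the unique minimal single event has the
six-token window (−ND6, −E, Cytb, T, −P, CR), copy 1 keeping {Cytb, T, CR}
and copy 2 keeping {ND6, E, P, CR}.

Multi-event search (capped at 3 events) recurses through intermediate
events. On small orders the intermediate enumeration is complete; on
orders longer than 15 tokens it is restricted to windows intersecting the
region where the current and target orders disagree — a parsimony-guided
narrowing, since full enumeration of two-event compositions over a 39-gene
circle is combinatorially out of reach. Search depth 1 results are always
exact.

## Model adjudication

The four-mechanism verdict is rule-based, operating on the *rearranged
region*: the minimal circular span of the observed order covering every
token whose neighbourhood differs from the reference.

- **Recombination** — plausible iff an inverted (sign-flipped, reversed)
  fragment exists; it is the only mechanism that can invert.
- **TDNL** — plausible iff the region is polarity-clustered (each strand's
  tokens form one contiguous run) with relative order preserved within each
  strand class, there are no sign flips, and no retained duplicate lies in
  the region: polarity-determined loss is complete, so a surviving
  duplicate CR (as in the eel) rules TDNL out.
- **DRRL** — plausible iff two control regions exist, every changed token
  lies between them (tokens flanking an inserted CR copy whose other side
  is intact are treated as the insertion scar, not as independently
  rearranged), and the strictly-between segment is polarity-clustered with
  order preserved. For the eel, Cytb and trnT changed context *upstream*
  of CR1, which is what excludes DRRL.
- **TDRL** — plausible iff a scenario exists and, when a spacer report is
  supplied, at least two positive intergenic spacers fall in or adjacent
  to the region (duplication remnants). On the eel tables this finds the
  four spacers at ND5–Cytb (35 bp), Cytb–trnT (4 bp), ND6–trnE (1 bp) and
  trnE–trnP (23 bp).

Each verdict carries a one-line reason; "none fits" is an explicit note.

## Synthetic mitogenomes

The generator lays a gene order (template + applied TDRL events) on a
circle using per-label lengths and a junction-gap plan, fills PCGs with
start codon + i.i.d. codon-bias-drawn sense codons + (possibly incomplete)
stop, fills everything else i.i.d. from the base-probability vector, and
plants one TACAT and one ATGTA palindrome at fixed offsets in each control
region. A single seeded generator drives all draws, so emissions are
byte-reproducible. Ground truth (order, events, planted codon counts,
base probabilities, motif positions, realized gaps) is recorded before
emission.

Defaults are the published eel values: gene lengths and coordinate-derived
junction gaps from the packaged table, base probabilities
(A, C, G, T) = (0.321, 0.238, 0.166, 0.275) — the published whole-genome
percentages with T adjusted by 0.001 so the vector sums to 1, since the
printed row sums to 100.1 — uniform codon bias, published start/stop
codons. `muraenesox_like_config` is the structural twin: exactly 17,673 bp
with the published layout, including the out-of-frame COI (emitted with one
trailing pad nucleotide so the length is exact, and flagged by the
validator just as the published table is). `frame_clean_config` instead
plants all 13 PCGs in frame with complete stops, with per-gene codon counts
following the published amino-acid column scaled to total exactly 3,818
codons (11,454 coding nt; the published per-gene lengths sum to 11,487 and
are mutually inconsistent with that text total, so the text total — the
self-consistent pair — is the one reproduced).

What the twin emulates: the statistical layout of the real genome
(lengths, gaps, overlaps, order, composition, motifs). What it does not:
real codon bias (uniform by default), tRNA/rRNA secondary structure,
overlap-aware dual-coding (features written later overwrite overlapped
nucleotides of earlier ones, so planted codon counts are only guaranteed
for non-overlapped genes — exact codon-recovery tests use the overlap-free
clean configuration). Passing tests on synthetic data therefore validate
the geometry, counting and inference machinery, not annotation quality on
real sequencing data.

## Numerical and interface choices

- Skews raise an explicit error when their denominator is zero.
- Composition percentage checks allow for published rows whose four
  percentages do not sum exactly to 100 (rounding).
- The LCS tie-break weight is 2⁻²⁰, a power of two so dynamic-programming
  sums stay exact and backtracking is deterministic.
- `infer_tdrl` anchors the reference at trnF when present (otherwise the
  given rotation), making results invariant under rotation of either
  input; window indices in reported events refer to that anchored
  reference, which is returned alongside the scenarios.
- Exit codes of the CLI: 0 success, 1 analysis infeasibility, 2 input
  error.
- Problem sizes in the test suite and acceptance script: single-event
  searches on 39–40-token orders, 100-case seeded round-trip batches,
  full-genome (17.7 kb) syntheses — all chosen to run the entire suite in
  a few seconds.

## Known limitations

- Multi-event inference beyond one event on full-size genomes is
  parsimony-guided rather than exhaustive (see above).
- The adjudication rules are qualitative reconstructions of verbal
  criteria from the rearrangement literature; they adjudicate plausibility,
  not probability, and several mechanisms can be simultaneously plausible
  on order evidence alone.
- Duplicate-copy matching by neighbourhood similarity reports ambiguity
  but resolves ties deterministically; pathological orders with many
  repeated labels are classified `complex` rather than analysed in depth.
- GenBank parsing maps the five standard feature types only and takes
  gene/product qualifiers as names; exotic annotations may need the TSV
  route.
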