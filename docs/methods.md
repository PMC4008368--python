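# Methods

This note documents the detectors, the scoring model, the arbiter, the
synthetic-data generator and the design choices behind them.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Structural feature detection

**Terminal repeats.** The 5′ window (first `min(L/2, max_length + 200)` bp
of a length-L consensus) is locally aligned against the 3′ window — as-is
for direct (LTR-like) repeats, against its reverse complement for inverted
(TIR-like) repeats — with blastn-like affine scores (match +2, mismatch −3,
gap open −5, gap extend −2; all configurable).  A candidate is reported
when the aligned copies are 10–7000 bp long at ≥80% identity (identity is
computed over aligned residue pairs, gap columns excluded) and are
*anchored*: the left copy must start, and the right copy end, within
`max_offset` (default 25 bp) of the termini.  Anchoring is our addition: on
multi-kilobase windows a spurious internal 10–12 bp exact match is
expected by chance, and a terminal-repeat detector should not report it.
With `best_only` (default) at most one best candidate per orientation is
returned, ranked by identity × length.  The alignment engine is
Bio.Align.PairwiseAligner in local mode; the test suite checks its optimal
scores and accept/reject decisions against an independent affine-gap
Smith–Waterman dynamic program with exhaustive enumeration of minimal
co-optimal alignments, on seeded sequences up to 200 bp.

**Simple sequence repeats.** Periods 1–6 are scanned.  A stretch is a
period-p run when it spans at least 5 motif copies (periods 1–2) or 3
copies (periods 3–6), at least 90% of its positions match the base p
positions upstream, and both boundary comparisons match.  The boundary
condition is deliberate: purity alone would let a run absorb up to ~10%
mismatching bases at its edges, making planted-run coverage fuzzy.  The
90% bound is evaluated in exact rational arithmetic.  The detector finds,
for every start, the longest valid run via a suffix-maximum structure on
the purity prefix sums (O(n log n) per period); reported coverage is the
union of all valid runs as a percentage of sequence length, which the
tests verify against an exhaustive O(n²) scan.  A TRF `.dat` file, when
supplied, overrides the internal detector so TRF-based preprocessing can
be reproduced exactly.

**polyA tails.** Within the terminal 30 bp window, the best
terminus-anchored run of A (3′) or T (5′, the minus-strand convention) is
selected by score = matches − 3 × mismatches (ties to the longer run) and
reported when it is ≥10 bp with ≥80% purity.  All four numbers are
invented defaults exposed in the configuration; the tail definition in the
underlying feature set is qualitative only.

**ORFs.** All six frames are walked codon by codon.  An ORF runs from the
previous stop codon (or the frame start) through the end of the next stop
codon, stop included, with no start-codon requirement — consensus
sequences are routinely 5′-truncated, so demanding ATG would discard real
coding evidence.  Spans that never reach a stop are not reported; this
makes the minimal example (a 9 bp sequence whose frame +1 ends in TAA)
yield exactly one ORF and keeps strand symmetry exact.  Default minimum
length 300 bp.  Coordinates everywhere are 1-based inclusive on the
forward strand.

## Evidence intake

BLAST tabular input must carry subject lengths (13th `slen` column or a
sidecar index) because all filtering is subject-side: subject coverage =
|s_end − s_start| + 1 over the subject length.  TE-bank hits are retained
only when coverage strictly exceeds 5%; profile hits (HMMER3
`--domtblout`, query names suffixed `_fr{+1..-3}` by the six-frame
translation) only when profile coverage strictly exceeds 20%.  Both
thresholds are strict by design ("exceeds"), and both filters are
idempotent.  Hits against the rDNA / host-gene / helitron-end banks are
kept regardless, because the filter agents reason about sub-threshold
matches (a 16.55% gene match on a genuine TE must survive into the
evidence summary without triggering a host-gene verdict).  Subject
categories are parsed from Repbase-style `name#Order/Superfamily` headers,
with a TSV override map for other banks; profile names map to domain roles
(RT, INT, GAG, AP, RH, ENV, EN, Tase, YR, HEL, RPA, PolB, ATPase) through
an ordered, configurable substring table.  The evidence store is a plain
in-memory map keyed by consensus id — the contract of a database-backed
store without the database.

## Scoring

Each category is scored by additive rules over a closed condition
vocabulary (profile-role presence, co-framed roles within one ORF,
terminal-repeat kind, per-program blast matches to a given order, polyA,
SSR tail/coverage, ORF counts, total and repeat-free length windows,
helitron-end matches, boolean combinators).  Confidence is the raw sum
normalized to 100 by the category's maximum attainable score and clamped
at 0 — normalization to a 0–100 index implies a non-negative scale.
`max_raw` is validated at load time against the sum of positive
increments, which is adopted when `max_raw: auto`.

The LTR ruleset is fixed (see README); the category's declared maximum of
17 equals its sum of positive increments.  "Co-framed" means: at least two
distinct roles share the same frame and the same containing ORF; a lone
ENV inside an ORF is sufficient evidence (+2) but earns no co-framing
point.  The rules for the other eleven categories are this package's
defaults, chosen from each order's canonical domain inventory and
structure: YR for DIRS and Crypton, EN+RT for PLE, RT/EN plus a 3′ tail
and no terminal repeat for LINE, short tailed non-coding elements for
SINE, inverted repeats plus transposase for TIR, short non-coding inverted
repeats for MITE, helitron-end matches plus HEL/RPA for Helitron,
PolB/INT/ATPase and length >9 kb for Maverick, long/short non-coding
direct-repeat elements for LARD/TRIM.  Matches to a same-order bank
subject add +3 per blast program for these categories (the LTR category
keeps its fixed +2): with +2, a structure-only LARD/TRIM/MITE bundle would
sit at exactly half of its maximum and a terminal-repeat-bearing element
would be callable as LARD from structure alone, which contradicts the
intended behaviour that similarity-free calls stay below the decision
threshold.  All increments are expected tuning surfaces and live in the
shipped YAML.

Because several default rules reward the *absence* of evidence (no
profiles for LARD/TRIM, no terminal repeat for LINE/Crypton, no long ORF
for SINE/MITE), adding a profile hit can lower those scores; score
monotonicity under added evidence is therefore guaranteed — and tested —
for added blast hits on every category and for added profile/blast hits
on the LTR rules.

## Arbitration

Filter verdicts win outright: ≥75% SSR coverage with no retained TE
evidence, ≥80% rDNA subject coverage, or ≥75% host-gene coverage that
dominates the TE evidence, produce a non-TE record with status OK.
Otherwise the cards with confidence ≥50 (`chimera_conf_min`) compete.
None: order Unknown, with a class-level call when every positive card
agrees on one class.  One: that order, status OK.  Two or more: status
"potential chimeric"; the top card wins when it leads the runner-up by at
least 10 points (`decision_margin`), otherwise the candidate orders are
emitted pipe-joined (classes likewise) with the best candidate's
confidence.  Both knobs are invented defaults, chosen so that a lone
strong card is never chimeric and near-ties are never silently decided.

Completeness is the conjunction: (blast coverage >30% OR profile coverage
>75%) AND order-expected termini (direct repeats for LTR/LARD/TRIM/DIRS,
inverted for TIR/MITE, polyA or SSR tail for LINE/SINE) AND length inside
the order's expected window (curated per-order defaults in the YAML, e.g.
MITE 50–800 bp, Maverick 9–25 kb).  Orientation — reported but nowhere
given a published rule — is our coverage-weighted majority strand over all
stranded evidence (blast hit orientation, profile frame sign), with "."
for no evidence or a tie.

## Synthetic fixtures

`tewick.synthetic` emulates every input so the full pipeline is testable
offline.  Backgrounds are uniform i.i.d. ACGT; each category plants its
hallmarks: e.g. the LTR element carries 433 bp exact terminal direct
repeats around a 4500 bp interior containing a 3000 bp stop-free frame +1
ORF with co-framed ENV/AP/RT/RH/GAG (+INT) profile hits; TIR/MITE carry
inverted termini; LINE/SINE carry 20 bp polyA tails; the SSR fixture is a
pure dinucleotide tandem; a substitution rate μ can be applied to one
repeat copy.  Fabricated evidence uses Repbase-style subject headers and
role-bearing profile names, at 90%/60% coverages (the "boundary" dialect
adds hits at exactly 20%/5% coverage, which the parsers must drop).
Categories whose rules reward structural absences are rejection-sampled so
the absences hold by construction.  Everything is deterministic under the
seed and byte-stable.

These fixtures validate the machinery, not biology: uniform backgrounds
have no GC structure, no nested or decayed elements, no genuinely coding
domains, and evidence coverages are noiseless.  Passing the recovery tests
shows the rules and plumbing behave as specified, not that real repeat
libraries will be classified with any particular accuracy.

## Numerical and degenerate-input choices

Strict inequalities at every published threshold; exact rational
arithmetic for SSR purity; confidence rounding is half-up.  Sequences
shorter than twice the minimum repeat length return no terminal repeats
(not an error); non-ACGTN residues are errors in detectors but are
N-masked on FASTA intake.  Ties in the polyA scorer go to the longer run;
ties in orientation return ".".  Problem sizes in the test suite are kept
small by design — oracle comparisons on ≤200 bp sequences, 1000 fuzzed
bundles for scorer equivalence, one 15-element panel per pipeline test.

## Known limitations

No superfamily-level calls; no target-site-duplication search (requires
genomic copies); no tRNA promoter model for SINEs; helitron hairpin motifs
are not searched, so helitron calls lean on end-bank matches; the
confidence index is a rule tally, not a probability; default rules beyond
LTR are heuristics meant to be tuned against a curated library.
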