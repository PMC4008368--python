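# tewick

Rule-based classification of transposable-element (TE) consensus sequences
to the order level of the Wicker hierarchy.

De novo repeat-finding pipelines emit consensus sequences that must then be
identified: is this an LTR retrotransposon, a LINE, a DNA transposon with
terminal inverted repeats, a Helitron — or not a TE at all, but a
microsatellite stretch, rDNA or a repeated host gene?  `tewick` answers
this for curators of repeat libraries.  It detects structural hallmarks
directly on the sequence (terminal direct/inverted repeats, SSR content,
polyA tails, long ORFs from six-frame translation), combines them with
pre-computed similarity evidence (blastx/tblastx hits against a TE bank,
HMM-profile hits for TE protein domains, blastn hits against rDNA /
host-gene / helitron-end banks), and scores every category of the taxonomy
with editable additive decision rules.  Every consensus receives a class,
an order, a completeness call, a 0–100 confidence index and a full
evidence trail for manual curation; ambiguous elements are flagged
"potential chimeric" with their candidate orders pipe-joined.

## The model

The taxonomy covers twelve order-level TE categories — class I
retrotransposons LTR, DIRS, PLE, LINE, SINE plus the non-autonomous LARD
and TRIM; class II DNA transposons TIR, Crypton, Helitron, Maverick plus
the non-autonomous MITE — and three non-TE filter categories (SSR, rDNA,
HostGene).  Each category *c* has a set of decision rules; rule *r* fires
on an evidence bundle *B* and contributes an increment *w_r*:

    raw(c, B)   = Σ_{r fired} w_r
    conf(c, B)  = round(100 · max(raw, 0) / max_raw(c)) ∈ [0, 100]

For the LTR category the shipped rules are: +2 for an ENV (envelope)
profile, sufficient on its own; +1 for each of INT/GAG/RT/RH/AP present
together with a detected terminal direct repeat; +1 for each of
ENV/AP/RT/RH/GAG found in the same frame in the same ORF; +2 per blast
program (blastx, tblastx) matching a known LTR retrotransposon; +1 when
the length without the terminal repeats is 4000–15000 bp and −1 when it is
below 1000 bp or above 15000 bp.  Evidence intake is thresholded: a
TE-bank blast hit counts only if its subject coverage exceeds 5%, a
profile hit only if its profile coverage exceeds 20%.  Terminal repeats
are reported between 10 and 7000 bp at ≥80% identity, in both reciprocal
orientations.

An arbiter compares the normalized confidences: a filter verdict (e.g. a
consensus that is ≥75% SSR with no TE evidence) wins outright; otherwise
categories at ≥50 confidence compete, a lone survivor is reported as OK,
and several survivors make the element "potential chimeric" — decided for
the best card when it leads by ≥10 points, otherwise left as a pipe-joined
candidate list.  Completeness requires blast coverage >30% or profile
coverage >75%, the order's expected termini (direct repeats for
LTR/LARD/TRIM/DIRS, inverted for TIR/MITE, a polyA/SSR tail for
LINE/SINE), and a plausible length.  All thresholds and increments live in
an editable YAML rules file (`src/tewick/data/decision_rules.yaml`).

## Worked example

No external data is needed: the fixture generator emulates every input.

```sh
tewick fixtures --category panel --seed 1 --out-dir demo
tewick classify --fasta demo/panel.fasta \
    --blastx demo/te_blastx.tsv --tblastx demo/te_tblastx.tsv \
    --domtbl demo/profiles.domtbl \
    --blastn-rdna demo/rdna_blastn.tsv \
    --blastn-hostgene demo/hostgene_blastn.tsv \
    --blastn-helitron demo/helitron_end_blastn.tsv \
    --out demo/classified.tsv
```

`demo/classified.tsv` then contains one row per consensus (first eight
columns shown):

```
#te_id	length	orientation	status	class	order	completeness	confidence
LTR_1	5366	+	OK	I	LTR	complete	100
DIRS_2	5000	+	OK	I	DIRS	incomplete	100
PLE_3	4000	+	OK	I	PLE	complete	100
LARD_4	5800	+	OK	I	LARD	complete	100
TRIM_5	1500	+	OK	I	TRIM	complete	100
LINE_6	5000	+	OK	I	LINE	complete	100
SINE_7	400	+	OK	I	SINE	complete	100
TIR_8	3000	+	OK	II	TIR	complete	100
MITE_9	350	+	OK	II	MITE	complete	100
Crypton_10	2500	+	OK	II	Crypton	complete	100
Helitron_11	4000	+	OK	II	Helitron	complete	100
Maverick_12	10000	+	OK	II	Maverick	complete	100
SSR_13	500	.	OK	nonTE	SSR	incomplete	100
rDNA_14	2000	+	OK	nonTE	rDNA	incomplete	95
HostGene_15	1500	+	OK	nonTE	HostGene	incomplete	85
```

Every planted category is recovered with status OK.  The ninth column
holds the evidence trail; for `LTR_1` it reads

```
coding(TE_BLRtx: LTR_cons1#LTR/Gypsy 60.00%; TE_BLRx: LTR_cons1#LTR/Gypsy 60.00%;
  profiles: ENV_1 (ENV) 90.00%; profiles: GAG_1 (GAG) 90.00%; ...);
struct(>4000bps; TermLTR: 433bp 100.0%; ORFs: 4 (longest 3000bp));
other(SSRs 1.5%; HostGene: At1g01010#Gene 16.55%)
```

i.e. tblastx/blastx matches at 60% subject coverage, six retained domain
profiles at 90% coverage, a 433 bp terminal direct repeat at 100%
identity, a 3000 bp ORF, and a sub-threshold host-gene match (16.55%
coverage) kept as an annotation rather than a verdict.  Library use
without the CLI goes through `tewick.run_pipeline(...)` or, per consensus,
`tewick.classify_bundle(...)`.

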