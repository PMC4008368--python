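"""Structural feature detection on TE consensus sequences.

Four detectors produce the structural half of the evidence used for
classification:

* terminal repeats — direct (LTR-like) and inverted (TIR-like) repeats found
  by local alignment of the two sequence termini, with the published bounds
  (length 10–7000 bp, identity >= 80%) enforced on every reported candidate;
* simple sequence repeats (microsatellites), period 1–6, with an exact
  integer-arithmetic purity criterion;
* polyA tails at either terminus (polyT at the 5' end on the minus-strand
  convention);
* open reading frames from six-frame translation, stop-to-stop with no
  start-codon requirement (consensus sequences are frequently truncated).

Coordinates in all reported annotations are 1-based inclusive on the forward
strand.
"""
from __future__ import annotations

import itertools
from bisect import bisect_left
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
from Bio.Align import PairwiseAligner

from .errors import InputError

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _check_dna(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise InputError(f"non-ACGTN characters in sequence: {sorted(bad)}")


# ---------------------------------------------------------------------------
# terminal repeats
# ---------------------------------------------------------------------------

@dataclass
class TerminalRepeatParams:
    """Detector settings for terminal direct/inverted repeats.

    The length and identity bounds are the published detector constants; the
    alignment scores (blastn-like), the search-window padding and the
    terminal anchoring distance are implementation choices exposed here so
    they can be tuned from the configuration file.
    """

    min_length: int = 10
    min_identity: float = 80.0
    max_length: int = 7000
    max_offset: int = 25       # bp: copies must start/end within this distance of the termini
    window_pad: int = 200      # extra window beyond max_length
    best_only: bool = True
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    max_candidates: int = 64   # co-optimal alignments examined per kind


@dataclass
class TerminalRepeat:
    kind: str                  # "direct" | "inverted"
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    repeat_length: int
    identity: float            # percent over aligned (non-gap) columns
    score: float = 0.0


def _aligner(p: TerminalRepeatParams) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = p.match
    a.mismatch_score = p.mismatch
    a.open_gap_score = p.gap_open
    a.extend_gap_score = p.gap_extend
    return a


def _alignment_stats(aln, a: str, b: str):
    """(matches, aligned_cols, a_span, b_span) for one local alignment."""
    blocks_a, blocks_b = aln.aligned
    matches = 0
    cols = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        cols += a1 - a0
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    a_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))   # half-open on a
    b_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return matches, cols, a_span, b_span


def find_terminal_repeats(seq: str, params: Optional[TerminalRepeatParams] = None) -> list[TerminalRepeat]:
    """Detect the best terminal direct and/or inverted repeat of a sequence.

    The first and last windows of the sequence are locally aligned against
    each other (direct kind) and against the reverse complement of the 3'
    window (inverted kind).  A candidate is reported when the aligned copies
    satisfy the length and identity bounds and are anchored near the termini
    (``max_offset``).  With ``best_only`` (default) at most one repeat per
    kind is returned; candidates are ordered best-first by
    identity x repeat_length.

    Sequences shorter than twice the minimum repeat length yield an empty
    list.
    """
    p = params or TerminalRepeatParams()
    _check_dna(seq)
    n = len(seq)
    if n < 2 * p.min_length:
        return []
    window = min(n // 2, p.max_length + p.window_pad)
    left = seq[:window]
    right = seq[-window:]
    offset = n - window
    aligner = _aligner(p)

    out: list[TerminalRepeat] = []
    for kind in ("direct", "inverted"):
        b = right if kind == "direct" else revcomp(right)
        try:
            alns = aligner.align(left, b)
        except Exception:
            continue
        if len(left) == 0 or alns.score <= 0:
            continue
        found: list[TerminalRepeat] = []
        for aln in itertools.islice(alns, p.max_candidates):
            matches, cols, (a0, a1), (b0, b1) = _alignment_stats(aln, left, b)
            if cols == 0:
                continue
            rep_len = a1 - a0
            identity = float(100.0 * matches / cols)
            if kind == "direct":
                r_start, r_end = offset + b0 + 1, offset + b1
            else:
                # map coordinates back from the reverse complement of `right`
                r_start, r_end = offset + window - b1 + 1, offset + window - b0
            anchored = a0 <= p.max_offset and r_end >= n - p.max_offset
            if not anchored:
                continue
            if rep_len < p.min_length or rep_len > p.max_length:
                continue
            if identity < p.min_identity:
                continue
            found.append(
                TerminalRepeat(kind, a0 + 1, a1, r_start, r_end, rep_len,
                               round(identity, 2), float(alns.score))
            )
            if p.best_only:
                break
        found.sort(key=lambda t: (-t.identity * t.repeat_length, t.left_start))
        if found:
            out.extend(found[:1] if p.best_only else found)
    out.sort(key=lambda t: -t.identity * t.repeat_length)
    return out


# ---------------------------------------------------------------------------
# simple sequence repeats
# ---------------------------------------------------------------------------

@dataclass
class SSRParams:
    max_period: int = 6
    min_copies_short: int = 5   # periods 1-2
    min_copies_long: int = 3    # periods 3-6
    min_purity: float = 0.9

    def min_copies(self, period: int) -> int:
        return self.min_copies_short if period <= 2 else self.min_copies_long


@dataclass
class SSRAnnotation:
    motif: str
    period: int
    start: int      # 1-based inclusive
    end: int
    copy_number: float


def find_ssrs(seq: str, params: Optional[SSRParams] = None) -> tuple[list[SSRAnnotation], float]:
    """Detect simple sequence repeats and their total sequence coverage.

    A stretch [i, j] is a period-p run when it spans at least
    ``min_copies(p)`` motif copies, the fraction of positions matching the
    base p positions upstream is at least ``min_purity`` (exact rational
    arithmetic, so the 90% boundary is sharp), and both boundary positions
    of the compared region match — so a run cannot absorb mismatching bases
    at its edges.  For every start the longest valid run is kept; coverage
    is the union of all valid runs over all periods, as a percentage of
    sequence length.
    """
    p = params or SSRParams()
    _check_dna(seq)
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    frac = Fraction(str(p.min_purity))
    num, den = frac.numerator, frac.denominator

    mask = np.zeros(n, dtype=bool)
    annos: list[SSRAnnotation] = []
    for period in range(1, p.max_period + 1):
        min_run = period * p.min_copies(period)
        if n < min_run:
            continue
        m = np.zeros(n, dtype=np.int64)
        m[period:] = (s[period:] == s[:-period]).astype(np.int64)
        M = np.cumsum(m)
        f = den * M - num * np.arange(n, dtype=np.int64)
        # strict suffix maxima of f over match positions only:
        # stack_j descending, stack_f ascending
        stack_j: list[int] = []
        stack_f: list[int] = []
        best = None
        for j in range(n - 1, -1, -1):
            if not m[j]:
                continue
            fj = int(f[j])
            if best is None or fj > best:
                best = fj
                stack_j.append(j)
                stack_f.append(fj)
        kept_end = -1
        for i in range(0, n - min_run + 1):
            if not m[i + period]:
                continue
            t = int(f[i + period - 1])
            idx = bisect_left(stack_f, t)
            if idx == len(stack_f):
                continue
            j = stack_j[idx]    # largest match position j with f[j] >= t
            if j < i + min_run - 1:
                continue
            mask[i:j + 1] = True
            if j > kept_end:
                annos.append(
                    SSRAnnotation(
                        motif=seq[i:i + period],
                        period=period,
                        start=i + 1,
                        end=j + 1,
                        copy_number=round((j - i + 1) / period, 2),
                    )
                )
                kept_end = j
    annos.sort(key=lambda a: (a.start, a.period))
    coverage = 100.0 * int(mask.sum()) / n if n else 0.0
    return annos, coverage


def ssr_coverage_of(annos: list[SSRAnnotation], length: int) -> float:
    """Union coverage (%) of a set of SSR annotations, e.g. parsed from TRF."""
    if length <= 0:
        return 0.0
    mask = np.zeros(length, dtype=bool)
    for a in annos:
        mask[max(a.start - 1, 0):min(a.end, length)] = True
    return 100.0 * int(mask.sum()) / length


def parse_trf_dat(path) -> dict[str, list[SSRAnnotation]]:
    """Parse a Tandem Repeats Finder ``.dat`` table.

    When supplied to the pipeline, these annotations override the internal
    SSR detector, preserving fidelity to TRF-based preprocessing.
    """
    out: dict[str, list[SSRAnnotation]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                current = line.split(None, 1)[1].split()[0]
                out.setdefault(current, [])
                continue
            fields = line.split()
            if len(fields) >= 14 and fields[0].isdigit() and fields[1].isdigit():
                if current is None:
                    raise InputError(f"{path}: repeat row before any 'Sequence:' header")
                start, end = int(fields[0]), int(fields[1])
                period = int(fields[2])
                copies = float(fields[3])
                motif = fields[13]
                out[current].append(SSRAnnotation(motif, period, start, end, copies))
    return out


# ---------------------------------------------------------------------------
# polyA tails
# ---------------------------------------------------------------------------

@dataclass
class PolyAParams:
    min_length: int = 10
    min_purity: float = 0.8
    window: int = 30
    mismatch_penalty: int = 3


@dataclass
class PolyATail:
    side: str       # "5prime" | "3prime"
    length: int
    purity: float


def _best_terminal_run(region: str, base: str, anchored_at_end: bool, penalty: int):
    """Best-scoring terminus-anchored run; score = matches - penalty*mismatches.

    Ties go to the longer run.  Returns (score, length, purity) or None.
    """
    best = None
    for run_len in range(1, len(region) + 1):
        run = region[-run_len:] if anchored_at_end else region[:run_len]
        matches = run.count(base)
        score = matches - penalty * (run_len - matches)
        if best is None or score > best[0] or (score == best[0] and run_len > best[1]):
            best = (score, run_len, matches / run_len)
    return best


def find_polya(seq: str, params: Optional[PolyAParams] = None) -> Optional[PolyATail]:
    """Detect a polyA tail at the 3' end (or polyT at the 5' end, the
    minus-strand convention), looking within the terminal ``window`` bp."""
    p = params or PolyAParams()
    _check_dna(seq)
    candidates = []
    for side, base, at_end in (("3prime", "A", True), ("5prime", "T", False)):
        region = seq[-p.window:] if at_end else seq[:p.window]
        if not region:
            continue
        best = _best_terminal_run(region, base, at_end, p.mismatch_penalty)
        if best is None:
            continue
        score, run_len, purity = best
        if run_len >= p.min_length and purity >= p.min_purity:
            candidates.append((score, side == "3prime", PolyATail(side, run_len, round(purity, 4))))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], not c[1]))
    return candidates[0][2]


# ---------------------------------------------------------------------------
# open reading frames
# ---------------------------------------------------------------------------

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class ORFAnnotation:
    frame: int      # +1..+3, -1..-3
    start: int      # 1-based inclusive, forward strand, start < end
    end: int
    length: int     # bp, multiple of 3, includes the terminating stop codon


def _orfs_forward(seq: str, min_len: int):
    """Stop-terminated spans per forward frame, as 0-based half-open (frame, start, end)."""
    n = len(seq)
    for off in range(3):
        seg_start = off
        c = off
        while c + 3 <= n:
            if seq[c:c + 3] in STOP_CODONS:
                end = c + 3
                if end - seg_start >= min_len:
                    yield off + 1, seg_start, end
                seg_start = end
            c += 3


def find_orfs(seq: str, min_len: int = 300) -> list[ORFAnnotation]:
    """Open reading frames in all six frames.

    An ORF is a span running from the previous stop codon (or the frame
    start) through the end of the next stop codon, with no internal stop; no
    start codon is required.  Spans that never reach a stop are not
    reported.  Minus-frame ORFs are mapped back to forward-strand
    coordinates.
    """
    if min_len % 3 != 0:
        raise ValueError(f"min_len must be a multiple of 3, got {min_len}")
    _check_dna(seq)
    n = len(seq)
    out: list[ORFAnnotation] = []
    for frame, s0, e0 in _orfs_forward(seq, min_len):
        out.append(ORFAnnotation(frame, s0 + 1, e0, e0 - s0))
    rc = revcomp(seq)
    for frame, s0, e0 in _orfs_forward(rc, min_len):
        # rc interval [s0, e0) maps to forward [n - e0, n - s0)
        out.append(ORFAnnotation(-frame, n - e0 + 1, n - s0, e0 - s0))
    out.sort(key=lambda o: (o.start, o.frame))
    return out


# ---------------------------------------------------------------------------
# feature set
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """All structural findings for one consensus."""

    length: int
    terminal_repeats: list[TerminalRepeat] = field(default_factory=list)
    ssrs: list[SSRAnnotation] = field(default_factory=list)
    total_ssr_coverage: float = 0.0
    polya: Optional[PolyATail] = None
    orfs: list[ORFAnnotation] = field(default_factory=list)

    @property
    def internal_length(self) -> int:
        """Length excluding the terminal repeats when one is retained."""
        if self.terminal_repeats:
            return self.length - 2 * self.terminal_repeats[0].repeat_length
        return self.length


@dataclass
class DetectorParams:
    terminal_repeat: TerminalRepeatParams = field(default_factory=TerminalRepeatParams)
    ssr: SSRParams = field(default_factory=SSRParams)
    polya: PolyAParams = field(default_factory=PolyAParams)
    orf_min_length: int = 300


def compute_features(
    sequence: str,
    params: Optional[DetectorParams] = None,
    ssr_override: Optional[list[SSRAnnotation]] = None,
) -> FeatureSet:
    """Run all structural detectors on one sequence.

    ``ssr_override`` (e.g. parsed TRF annotations) replaces the internal SSR
    detector when given.
    """
    p = params or DetectorParams()
    trs = find_terminal_repeats(sequence, p.terminal_repeat)
    if ssr_override is not None:
        ssrs = ssr_override
        cov = ssr_coverage_of(ssrs, len(sequence))
    else:
        ssrs, cov = find_ssrs(sequence, p.ssr)
    return FeatureSet(
        length=len(sequence),
        terminal_repeats=trs,
        ssrs=ssrs,
        total_ssr_coverage=cov,
        polya=find_polya(sequence, p.polya),
        orfs=find_orfs(sequence, p.orf_min_length),
    )
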