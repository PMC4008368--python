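"""Independent brute-force oracles used to check the detectors and parsers.

Everything here is deliberately slow, simple and separate from the package
implementation: exhaustive scans, naive dynamic programming and
codon-by-codon walks at tiny problem sizes.
"""
from __future__ import annotations

from fractions import Fraction

from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# affine-gap Smith-Waterman (naive DP + co-optimal path enumeration)
# ---------------------------------------------------------------------------

NEG = float("-inf")


def sw_score(a: str, b: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2) -> float:
    """Optimal local alignment score, affine gaps (first gap base costs
    ``gap_open``, each extra base ``gap_extend``)."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def sw_optimal_alignments(a: str, b: str, match=2, mismatch=-3,
                          gap_open=-5, gap_extend=-2, cap=500):
    """All minimal co-optimal local alignments as (a0, a1, b0, b1, matches, cols).

    Coordinates are 0-based half-open spans on ``a`` and ``b``; ``cols``
    counts aligned residue pairs (gap columns excluded).  Enumeration stops
    at ``cap`` paths.  Alignments that merely pad another optimal alignment
    with net-zero-scoring columns (their path passes through an intermediate
    cell that already achieves the optimal score) are excluded, matching the
    usual traceback convention.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    if best <= 0:
        return []

    results = []

    def walk(state, i, j, matches, cols, end_i, end_j):
        if len(results) >= cap:
            return
        if state == "H":
            if H[i][j] == 0:
                results.append((i, end_i, j, end_j, matches, cols))
                return
            if (i, j) != (end_i, end_j) and H[i][j] == best:
                return  # net-zero extension of another optimal alignment
            s = match if a[i - 1] == b[j - 1] else mismatch
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + s:
                walk("H", i - 1, j - 1, matches + (a[i - 1] == b[j - 1]), cols + 1, end_i, end_j)
            if H[i][j] == E[i][j]:
                walk("E", i, j, matches, cols, end_i, end_j)
            if H[i][j] == F[i][j]:
                walk("F", i, j, matches, cols, end_i, end_j)
        elif state == "E":
            if H[i - 1][j] + gap_open == E[i][j]:
                walk("H", i - 1, j, matches, cols, end_i, end_j)
            if i > 1 and E[i - 1][j] + gap_extend == E[i][j]:
                walk("E", i - 1, j, matches, cols, end_i, end_j)
        else:
            if H[i][j - 1] + gap_open == F[i][j]:
                walk("H", i, j - 1, matches, cols, end_i, end_j)
            if j > 1 and F[i][j - 1] + gap_extend == F[i][j]:
                walk("F", i, j - 1, matches, cols, end_i, end_j)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i][j] == best:
                walk("H", i, j, 0, 0, i, j)
    return results


def terminal_repeat_decision(seq: str, kind: str, *, min_length=10, min_identity=80.0,
                             max_length=7000, max_offset=25, window_pad=200) -> bool:
    """Would an exhaustive search accept a terminal repeat of this kind?"""
    from tewick.features import revcomp

    n = len(seq)
    if n < 2 * min_length:
        return False
    window = min(n // 2, max_length + window_pad)
    left = seq[:window]
    right = seq[-window:]
    b = right if kind == "direct" else revcomp(right)
    offset = n - window
    for a0, a1, b0, b1, matches, cols in sw_optimal_alignments(left, b):
        if cols == 0:
            continue
        rep_len = a1 - a0
        identity = 100.0 * matches / cols
        if kind == "direct":
            r_end = offset + b1
        else:
            r_end = offset + window - b0
        if a0 <= max_offset and r_end >= n - max_offset \
                and min_length <= rep_len <= max_length and identity >= min_identity:
            return True
    return False


# ---------------------------------------------------------------------------
# exhaustive SSR scan
# ---------------------------------------------------------------------------

def ssr_union_mask(seq: str, max_period=6, min_copies=(5, 5, 3, 3, 3, 3),
                   min_purity="0.9") -> list[bool]:
    """Per-position union of all valid SSR runs, by exhaustive (p, i, j) scan.

    A run [i, j] of period p is valid when it is at least min_copies[p-1]*p
    long, the compared positions i+p..j match their period-p predecessor at
    a rate >= min_purity, and positions i+p and j themselves match.
    """
    n = len(seq)
    q = Fraction(min_purity)
    mask = [False] * n
    for p in range(1, max_period + 1):
        min_run = p * min_copies[p - 1]
        match = [False] * n
        for k in range(p, n):
            match[k] = seq[k] == seq[k - p]
        prefix = [0] * (n + 1)
        for k in range(n):
            prefix[k + 1] = prefix[k] + (1 if match[k] else 0)
        for i in range(0, n - min_run + 1):
            if not match[i + p]:
                continue
            for j in range(i + min_run - 1, n):
                if not match[j]:
                    continue
                good = prefix[j + 1] - prefix[i + p]
                total = j - i + 1 - p
                if Fraction(good, total) >= q:
                    for k in range(i, j + 1):
                        mask[k] = True
    return mask


# ---------------------------------------------------------------------------
# ORF walk via Biopython translation
# ---------------------------------------------------------------------------

def orf_spans(seq: str, min_len: int) -> set[tuple[int, int, int]]:
    """(frame, start, end) of all stop-terminated ORFs, via Bio.Seq.translate."""
    out: set[tuple[int, int, int]] = set()
    n = len(seq)
    for strand, s in ((1, seq), (-1, str(Seq(seq).reverse_complement()))):
        for off in range(3):
            usable = (len(s) - off) // 3 * 3
            if usable == 0:
                continue
            prot = str(Seq(s[off:off + usable]).translate())
            seg_start = 0  # codon index within the frame
            for idx, aa in enumerate(prot):
                if aa != "*":
                    continue
                length = (idx - seg_start + 1) * 3
                if length >= min_len:
                    s0 = off + seg_start * 3      # 0-based on s
                    e0 = off + (idx + 1) * 3
                    if strand == 1:
                        out.add((off + 1, s0 + 1, e0))
                    else:
                        out.add((-(off + 1), n - e0 + 1, n - s0))
                seg_start = idx + 1
    return out


# ---------------------------------------------------------------------------
# polyA best-window scan
# ---------------------------------------------------------------------------

def best_tail(seq: str, *, window=30, penalty=3):
    """Best terminus-anchored A/T run by brute force.

    Returns (side, length, purity) of the best-scoring candidate passing no
    thresholds (thresholding is the caller's concern), or None.
    """
    candidates = []
    for side, base in (("3prime", "A"), ("5prime", "T")):
        region = seq[-window:] if side == "3prime" else seq[:window]
        best = None
        for length in range(1, len(region) + 1):
            run = region[-length:] if side == "3prime" else region[:length]
            matches = run.count(base)
            score = matches - penalty * (length - matches)
            if best is None or score > best[0] or (score == best[0] and length > best[1]):
                best = (score, length, matches / length)
        if best:
            candidates.append((best[0], side == "3prime", side, best[1], best[2]))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], not c[1]))
    _, _, side, length, purity = candidates[0]
    return side, length, purity
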