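import numpy as np
import pytest

from conftest import random_dna
from oracles import best_tail, orf_spans, ssr_union_mask, sw_score, terminal_repeat_decision
from tewick.errors import InputError
from tewick.features import (
    PolyAParams,
    SSRParams,
    TerminalRepeatParams,
    compute_features,
    find_orfs,
    find_polya,
    find_ssrs,
    find_terminal_repeats,
    revcomp,
)


class TestTerminalRepeats:
    def test_planted_exact_direct_repeat(self):
        rng = np.random.default_rng(11)
        r = random_dna(rng, 50)
        seq = r + random_dna(rng, 500) + r
        reps = [t for t in find_terminal_repeats(seq) if t.kind == "direct"]
        assert len(reps) == 1
        t = reps[0]
        assert (t.repeat_length, t.identity) == (50, 100.0)
        assert (t.left_start, t.left_end) == (1, 50)
        assert (t.right_start, t.right_end) == (551, 600)

    def test_planted_inverted_repeat_with_mismatches(self):
        # two interior substitutions in the right copy: 28/30 matched columns
        rng = np.random.default_rng(5)
        r = random_dna(rng, 30)
        mutated = list(r)
        for pos in (10, 20):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        seq = r + random_dna(rng, 500) + revcomp("".join(mutated))
        reps = [t for t in find_terminal_repeats(seq) if t.kind == "inverted"]
        assert len(reps) == 1
        t = reps[0]
        assert t.repeat_length == 30
        assert t.identity == pytest.approx(100 * 28 / 30, abs=0.01)
        # the oracle agrees the termini align at this score
        window = min(len(seq) // 2, 7200)
        assert t.score == sw_score(seq[:window], revcomp(seq[-window:]))

    def test_low_identity_termini_rejected(self):
        # substitutions every third position: no >=10 bp window reaches 80%
        rng = np.random.default_rng(3)
        r = random_dna(rng, 21)
        noisy = list(r)
        for pos in range(2, 21, 3):
            noisy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[pos]]
        seq = r + random_dna(rng, 400) + "".join(noisy)
        assert [t for t in find_terminal_repeats(seq) if t.kind == "direct"] == []
        assert not terminal_repeat_decision(seq, "direct")

    def test_repeat_in_the_middle_is_not_terminal(self):
        rng = np.random.default_rng(9)
        r = random_dna(rng, 40)
        seq = random_dna(rng, 100) + r + random_dna(rng, 300) + r + random_dna(rng, 100)
        assert [t for t in find_terminal_repeats(seq) if t.kind == "direct"] == []

    def test_too_short_sequence_yields_empty(self):
        assert find_terminal_repeats("ACGTACGTACGTACG") == []

    def test_non_dna_raises(self):
        with pytest.raises(InputError):
            find_terminal_repeats("ACGU" * 20)

    def test_reported_repeats_respect_published_bounds(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            r = random_dna(rng, int(rng.integers(10, 120)))
            seq = r + random_dna(rng, int(rng.integers(100, 800))) + r
            for t in find_terminal_repeats(seq):
                assert 10 <= t.repeat_length <= 7000
                assert t.identity >= 80.0
                assert t.left_end < t.right_start

    def test_revcomp_symmetry(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            r = random_dna(rng, 40)
            seq = r + random_dna(rng, 300) + r
            fwd = find_terminal_repeats(seq)
            rev = find_terminal_repeats(revcomp(seq))
            assert [(t.kind, t.repeat_length, t.identity) for t in fwd] == \
                   [(t.kind, t.repeat_length, t.identity) for t in rev]
            n = len(seq)
            for tf, tr in zip(fwd, rev):
                assert tr.left_start == n - tf.right_end + 1
                assert tr.right_end == n - tf.left_start + 1

    def test_oracle_equivalence_on_random_suite(self):
        """Detector score and accept/reject match exhaustive search, <=200 bp."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(40, 201))
            seq = random_dna(rng, n)
            if trial % 3 == 0:  # plant a weak terminal repeat in some
                k = int(rng.integers(10, 25))
                seq = seq[:k] + seq[:k][::-1].translate(str.maketrans("ACGT", "TGCA"))[::-1] + seq[2 * k:]
            window = n // 2
            for kind in ("direct", "inverted"):
                b = seq[-window:] if kind == "direct" else revcomp(seq[-window:])
                expected = sw_score(seq[:window], b)
                got = [t for t in find_terminal_repeats(seq) if t.kind == kind]
                if got:
                    assert got[0].score == expected
                assert bool(got) == terminal_repeat_decision(seq, kind), \
                    f"trial {trial} kind {kind}"


class TestSSRs:
    def test_pure_dinucleotide_run_covers_everything(self):
        annos, cov = find_ssrs("AT" * 50)
        assert cov == 100.0
        assert any(a.period == 2 and a.start == 1 and a.end == 100 for a in annos)

    def test_planted_trinucleotide_run_coverage(self):
        # CAG x10 at positions 31-60 of a 100 bp sequence -> 30% coverage
        rng = np.random.default_rng(8)
        for _ in range(20):
            seq = random_dna(rng, 30) + "CAG" * 10 + random_dna(rng, 40)
            _, cov = find_ssrs(seq)
            oracle_cov = 100.0 * sum(ssr_union_mask(seq)) / len(seq)
            assert cov == oracle_cov
        # with an SSR-free background the planted run is the whole signal
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 30) + "CAG" * 10 + random_dna(rng, 40)
        _, cov = find_ssrs(seq)
        assert cov == pytest.approx(30.0)

    def test_exhaustive_oracle_equivalence(self):
        rng = np.random.default_rng(33)
        for _ in range(15):
            n = int(rng.integers(30, 201))
            seq = random_dna(rng, n)
            if rng.random() < 0.6:  # plant a noisy run
                motif = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 5))))
                copies = int(rng.integers(4, 12))
                run = list(motif * copies)
                if rng.random() < 0.5 and len(run) > 4:
                    run[len(run) // 2] = "ACGT"[int(rng.integers(4))]
                pos = int(rng.integers(0, n - len(run))) if n > len(run) else 0
                seq = seq[:pos] + "".join(run) + seq[pos + len(run):]
            _, cov = find_ssrs(seq)
            oracle = ssr_union_mask(seq)
            assert cov == pytest.approx(100.0 * sum(oracle) / len(seq))

    def test_annotation_union_matches_reported_coverage(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 80) + "TTTTTTTT" + random_dna(rng, 40) + "ACACACACACAC"
        annos, cov = find_ssrs(seq)
        mask = np.zeros(len(seq), dtype=bool)
        for a in annos:
            mask[a.start - 1:a.end] = True
        assert cov == pytest.approx(100.0 * mask.sum() / len(seq))


class TestPolyA:
    def test_planted_pure_tail(self):
        rng = np.random.default_rng(13)
        seq = random_dna(rng, 500)
        assert seq[-1] != "A"  # tail must not merge with background
        tail = find_polya(seq + "A" * 20)
        assert tail is not None
        assert (tail.side, tail.length, tail.purity) == ("3prime", 20, 1.0)

    def test_no_tail_in_random_sequence(self):
        seq = random_dna(np.random.default_rng(14), 500)
        assert find_polya(seq) is None

    def test_impure_tail_matches_window_oracle(self):
        tail_seq = "AAAAAGAAAAAGAAAAA"  # 17 bp, two G
        rng = np.random.default_rng(15)
        seq = random_dna(rng, 500) + tail_seq
        tail = find_polya(seq)
        assert tail is not None
        side, length, purity = best_tail(seq)
        assert (tail.side, tail.length) == (side, length)
        assert tail.purity == pytest.approx(purity, abs=1e-4)
        assert tail.purity == pytest.approx(15 / 17, abs=1e-4)

    def test_five_prime_polyt_detected(self):
        rng = np.random.default_rng(16)
        seq = "T" * 18 + random_dna(rng, 400)
        tail = find_polya(seq)
        assert tail is not None
        assert tail.side == "5prime"

    def test_short_run_below_minimum_absent(self):
        rng = np.random.default_rng(19)
        seq = random_dna(rng, 300)
        assert seq[-1] != "A"
        assert find_polya(seq + "A" * 8) is None


class TestORFs:
    def test_minimal_stop_terminated_orf(self):
        orfs = find_orfs("ATGAAATAA", min_len=9)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.frame, o.start, o.end, o.length) == (1, 1, 9, 9)

    def test_strand_symmetry_mirrors_coordinates(self):
        orfs = find_orfs(revcomp("ATGAAATAA"), min_len=9)
        assert len(orfs) == 1
        o = orfs[0]
        assert o.frame == -1
        assert (o.start, o.end) == (1, 9)

    def test_min_len_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            find_orfs("ATGAAATAA", min_len=10)

    def test_oracle_equivalence_on_random_sequences(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            n = int(rng.integers(60, 201))
            seq = random_dna(rng, n)
            got = {(o.frame, o.start, o.end) for o in find_orfs(seq, min_len=30)}
            assert got == orf_spans(seq, 30)

    def test_all_orfs_are_stop_terminated_codon_multiples(self):
        seq = random_dna(np.random.default_rng(56), 2000)
        for o in find_orfs(seq, min_len=300):
            assert o.length % 3 == 0
            assert o.length >= 300


class TestFeatureSet:
    def test_internal_length_subtracts_terminal_repeats(self):
        rng = np.random.default_rng(60)
        r = random_dna(rng, 60)
        seq = r + random_dna(rng, 700) + r
        fs = compute_features(seq)
        assert fs.terminal_repeats
        assert fs.internal_length == fs.length - 2 * fs.terminal_repeats[0].repeat_length

    def test_internal_length_defaults_to_length(self):
        fs = compute_features(random_dna(np.random.default_rng(61), 400))
        if not fs.terminal_repeats:
            assert fs.internal_length == fs.length

    def test_determinism(self):
        seq = random_dna(np.random.default_rng(62), 1500)
        assert compute_features(seq) == compute_features(seq)
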