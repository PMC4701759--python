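import itertools

import numpy as np
import pytest

from wophage.align import (NUCLEOTIDE_SCORING, PROTEIN_SCORING, GeneArray, Orf,
                           RepeatPair, Scoring, align_identity, concat_identity,
                           find_direct_repeats, intergenic_layout)

# ---------------------------------------------------------------------------
# exhaustive alignment enumeration oracle (affine gaps, BLAST convention:
# a length-k gap run costs open + k*extend)


def _enumerate_global(a, b, sc):
    """Yield (score, cols) over every global alignment of a and b."""
    def score_cols(cols):
        total = 0.0
        for side in (0, 1):
            run = 0
            for col in cols:
                if col[side] == "-":
                    run += 1
                else:
                    if run:
                        total -= sc.gap_open + run * sc.gap_extend
                    run = 0
            if run:
                total -= sc.gap_open + run * sc.gap_extend
        for x, y in cols:
            if x != "-" and y != "-":
                total += sc.match if x == y else sc.mismatch
        return total

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            yield score_cols(cols), list(cols)
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            yield from rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            yield from rec(i, j + 1, cols + [("-", b[j])])

    yield from rec(0, 0, [])


def _best_global(a, b, sc):
    return max(s for s, _ in _enumerate_global(a, b, sc))


def _best_local(a, b, sc):
    """Best score over all non-empty substring pairs; 0 if nothing positive."""
    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, _best_global(a[i1:i2], b[j1:j2], sc))
    return best


def _alignment_score(res, sc):
    """Recompute the score of a returned alignment from its gapped strings."""
    cols = list(zip(res.aligned_a, res.aligned_b))
    total = 0.0
    for side in (0, 1):
        run = 0
        for col in cols:
            if col[side] == "-":
                run += 1
            else:
                if run:
                    total -= sc.gap_open + run * sc.gap_extend
                run = 0
        if run:
            total -= sc.gap_open + run * sc.gap_extend
    for x, y in cols:
        if x != "-" and y != "-":
            total += sc.match if x == y else sc.mismatch
    return total


class TestAlignIdentity:
    def test_identical_sequences_are_100_pct(self):
        r = align_identity("ACGTACGT", "ACGTACGT", mode="global")
        assert r.identity_pct == 100.0

    def test_single_substitution_linear_gap(self):
        sc = Scoring(match=1, mismatch=-1, gap_open=0, gap_extend=2)
        r = align_identity("ACGT", "ACGA", mode="global", scoring=sc)
        assert r.identity_pct == pytest.approx(75.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_identity("", "ACGT")

    def test_identity_counts_internal_gap_columns(self):
        # forced internal gap: identity denominator includes the gap column
        r = align_identity("ACGTTT", "ACTTT", mode="global",
                           scoring=Scoring(match=2, mismatch=-3, gap_open=1,
                                           gap_extend=1))
        assert r.alignment_length == 6
        assert r.identities == 5
        assert r.identity_pct == pytest.approx(100 * 5 / 6)

    def test_global_equals_exhaustive_enumeration(self, rng):
        sc = Scoring(match=2, mismatch=-3, gap_open=2, gap_extend=1)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            res = align_identity(a, b, mode="global", scoring=sc)
            assert res.score == pytest.approx(_best_global(a, b, sc))
            # the returned alignment itself achieves the optimal score
            assert _alignment_score(res, sc) == pytest.approx(res.score)

    def test_local_equals_exhaustive_enumeration(self, rng):
        sc = Scoring(match=2, mismatch=-3, gap_open=2, gap_extend=1)
        for _ in range(12):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 6)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 6)))
            res = align_identity(a, b, mode="local", scoring=sc)
            assert res.score == pytest.approx(_best_local(a, b, sc))

    def test_identity_pct_symmetric(self, rng):
        for mode in ("global", "local"):
            for _ in range(10):
                a = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 20)))
                b = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 20)))
                assert align_identity(a, b, mode=mode).identity_pct == \
                    pytest.approx(align_identity(b, a, mode=mode).identity_pct)

    def test_protein_local_matches_blastp_convention(self):
        # diverged protein pair: nident / alignment length incl. gaps
        rng = np.random.default_rng(3)
        alpha = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(alpha, 120))
        b = "".join(c if rng.random() > 0.4 else str(rng.choice(alpha))
                    for c in a)
        r = align_identity(a, b, mode="local", scoring=PROTEIN_SCORING)
        assert r.identity_pct == pytest.approx(
            100.0 * r.identities / r.alignment_length)
        assert 30.0 < r.identity_pct < 100.0


class TestConcatIdentity:
    def test_single_pair_equals_align_identity(self):
        a, b = "ACGTACGTAA", "ACGTCCGTAA"
        single = align_identity(a, b, scoring=NUCLEOTIDE_SCORING)
        concat = concat_identity([(a, b)], scoring=NUCLEOTIDE_SCORING)
        assert concat.identity_pct == pytest.approx(single.identity_pct)

    def test_identical_pairs_are_100_pct(self):
        r = concat_identity([("ACGT", "ACGT"), ("GGCC", "GGCC")])
        assert r.identity_pct == 100.0

    def test_equals_alignment_of_explicit_concatenation(self, rng):
        pairs = []
        for _ in range(3):
            x = "".join(rng.choice(list("ACGT"), size=12))
            y = "".join(c if rng.random() > 0.1 else "A" for c in x)
            pairs.append((x, y))
        direct = align_identity("".join(p[0] for p in pairs),
                                "".join(p[1] for p in pairs))
        assert concat_identity(pairs).identity_pct == \
            pytest.approx(direct.identity_pct)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            concat_identity([])


class TestGeneArray:
    def test_adjacent_orfs_have_zero_gap(self):
        arr = GeneArray([Orf("g1", 1, 10), Orf("g2", 11, 20)])
        layout = intergenic_layout(arr)
        assert list(layout["gap_bp"]) == [0]

    def test_overlap_is_negative(self):
        arr = GeneArray([Orf("g1", 1, 10), Orf("g2", 8, 20)])
        assert list(intergenic_layout(arr)["gap_bp"]) == [-3]

    def test_published_flank_gaps_reproduced(self):
        # layout mirroring the syntenic ten-gene array: a 125-bp gap upstream
        # of the second gene and a 95-bp gap before the ninth
        orfs = [Orf("WD0611", 1, 900), Orf("WD0612", 1026, 2000),
                Orf("WD0618", 2001, 2900), Orf("WD0619", 2996, 4000),
                Orf("WD0620", 4005, 4900, "-")]
        layout = intergenic_layout(GeneArray(orfs))
        gaps = dict(zip(layout["upstream_locus"], layout["gap_bp"]))
        assert gaps["WD0611"] == 125
        assert gaps["WD0618"] == 95

    def test_lengths_plus_gaps_telescope(self, rng):
        # sum of ORF lengths and intergenic gaps spans first start..last end
        starts = np.cumsum(rng.integers(1, 50, size=6))
        orfs = [Orf(f"g{i}", int(s), int(s + rng.integers(5, 40)))
                for i, s in enumerate(starts)]
        orfs.sort(key=lambda o: o.start)
        arr = GeneArray(orfs)
        total = sum(len(o) for o in orfs) + intergenic_layout(arr)["gap_bp"].sum()
        assert total == orfs[-1].end - orfs[0].start + 1

    def test_minus_strand_orf_reverse_complemented(self):
        seq = "ATGAAATTTCCC"
        arr = GeneArray([Orf("g1", 1, 6), Orf("g2", 7, 12, "-")], sequence=seq)
        assert arr.orf_sequence("g1") == "ATGAAA"
        assert arr.orf_sequence("g2") == "GGGAAA"  # revcomp of TTTCCC


# ---------------------------------------------------------------------------
# direct repeats


def _brute_force_repeats(seq, min_len, max_mismatch):
    """Direct re-statement of the repeat-pair definition."""
    n = len(seq)

    def mism(i, j, L):
        return sum(1 for k in range(L) if seq[i + k] != seq[j + k])

    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            d = j - i
            for L in range(min_len, min(d, n - j) + 1):
                if mism(i, j, L) > max_mismatch:
                    continue
                right_ok = (L + 1 > min(d, n - j)) or \
                    mism(i, j, L + 1) > max_mismatch
                left_ok = (i == 0) or (L + 1 > d) or \
                    mism(i - 1, j - 1, L + 1) > max_mismatch
                if right_ok and left_ok:
                    candidates.append((i, j, L))
    kept = []
    for (i, j, L) in candidates:
        contained = any(
            (i2, j2, L2) != (i, j, L) and j2 - i2 == j - i
            and i2 <= i and i2 + L2 >= i + L
            for (i2, j2, L2) in candidates
        )
        if not contained:
            kept.append(RepeatPair(i + 1, j + 1, L, mism(i, j, L)))
    return sorted(kept, key=lambda r: (r.pos1, r.pos2))


class TestDirectRepeats:
    def test_hand_enumerated_example(self):
        assert find_direct_repeats("ACGTACGT", 4) == [RepeatPair(1, 5, 4)]

    def test_homopolymer_collapses_to_nonoverlapping_pair(self):
        assert find_direct_repeats("AAAAAA", 3) == [RepeatPair(1, 4, 3)]

    def test_no_repeats_is_empty(self):
        assert find_direct_repeats("ACGT", 3) == []

    def test_shuffled_sequence_usually_empty(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            seq = "".join(rng.permutation(list("ACGT" * 31) + ["A"]))
            hits += bool(find_direct_repeats(seq, 8))
        assert hits <= 2  # 8-mer repeats are rare in shuffled 125-mers

    def test_min_len_below_three_rejected(self):
        with pytest.raises(ValueError):
            find_direct_repeats("ACGTACGT", 2)

    @pytest.mark.parametrize("max_mismatch", [0, 1])
    def test_matches_brute_force(self, rng, max_mismatch):
        for _ in range(15):
            n = int(rng.integers(10, 60))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert find_direct_repeats(seq, 4, max_mismatch) == \
                _brute_force_repeats(seq, 4, max_mismatch)

    def test_matches_brute_force_on_repeat_rich_sequence(self, rng):
        for _ in range(5):
            unit = "".join(rng.choice(list("ACGT"), size=7))
            seq = unit + "".join(rng.choice(list("ACGT"), size=9)) + unit
            assert find_direct_repeats(seq, 5, 0) == \
                _brute_force_repeats(seq, 5, 0)
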