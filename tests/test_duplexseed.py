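"""Duplex DP, seed typing and negative generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirtransfer import duplexseed as dx
from mirtransfer.duplexseed import (
    DuplexStructure, NegativeGenerationError, best_window, classify_seed,
    generate_negative, predict_duplex, seed_kmers, window_scores,
)
from mirtransfer.records import InteractionRecord

BASES = "ACGU"


# ------------------------------------------------------------------ oracle

def brute_force_score(mirna: str, site: str) -> int:
    """Exhaustive enumeration of all non-crossing antiparallel matchings
    under the same scoring scheme; independent of the DP."""
    rev = site[::-1]
    n, m = len(mirna), len(rev)
    best = 0

    def rec(i, j, last, total):
        nonlocal best
        best = max(best, total)
        for i2 in range(i, n):
            for j2 in range(j, m):
                p = dx._PAIR_SCORE[dx._BASE_INDEX[mirna[i2]],
                                   dx._BASE_INDEX[rev[j2]]]
                if p == 0:
                    continue
                add = p
                if last is not None:
                    add -= dx._gap_cost(i2 - last[0] - 1)
                    add -= dx._gap_cost(j2 - last[1] - 1)
                rec(i2 + 1, j2 + 1, (i2, j2), total + add)

    rec(0, 0, None, 0)
    return best


def random_seq(r, lo, hi):
    return "".join(r.choice(list(BASES), r.integers(lo, hi + 1)))


class TestPredictDuplex:
    def test_perfect_gc_complement(self):
        d = predict_duplex("GGGG", "CCCC")
        assert d.score == 12
        assert len(d.pairs) == 4
        assert set(d.pair_types) == {"WC"}

    def test_unpairable_bases_give_empty_duplex(self):
        d = predict_duplex("AAAA", "GGGG")
        assert d.score == 0
        assert d.pairs == ()

    def test_matches_brute_force_on_random_short_pairs(self):
        r = np.random.default_rng(42)
        for _ in range(60):
            a, b = random_seq(r, 1, 8), random_seq(r, 1, 8)
            assert predict_duplex(a, b).score == brute_force_score(a, b), (a, b)

    def test_antiparallel_monotone_pairs(self):
        r = np.random.default_rng(3)
        for _ in range(20):
            d = predict_duplex(random_seq(r, 8, 15), random_seq(r, 8, 20))
            mpos = [i for i, _ in d.pairs]
            spos = [j for _, j in d.pairs]
            assert mpos == sorted(mpos)
            assert spos == sorted(spos, reverse=True)

    def test_t_converted_to_u_with_warning(self):
        with pytest.warns(UserWarning):
            d = predict_duplex("GGTT", "AACC")
        assert d.score > 0

    def test_invalid_characters_rejected(self):
        with pytest.raises(dx.DuplexError, match="N"):
            predict_duplex("GGNN", "CCCC")

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_deterministic(self, seed):
        r = np.random.default_rng(seed)
        a, b = random_seq(r, 5, 12), random_seq(r, 5, 15)
        assert predict_duplex(a, b) == predict_duplex(a, b)

    def test_perfect_duplex_symmetric_under_role_swap(self):
        # swapping strand roles on a perfect duplex keeps the score
        r = np.random.default_rng(9)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(10):
            a = random_seq(r, 6, 12)
            b = "".join(comp[c] for c in reversed(a))
            assert predict_duplex(a, b).score == predict_duplex(b, a).score


class TestWindowScan:
    def test_window_scores_match_scalar_dp(self):
        r = np.random.default_rng(7)
        mir = random_seq(r, 10, 12)
        utr = random_seq(r, 50, 60)
        w = 15
        ws = window_scores(mir, utr, w)
        for k in range(len(ws)):
            assert ws[k] == predict_duplex(mir, utr[k:k + w]).score

    def test_best_window_is_leftmost_argmax(self):
        r = np.random.default_rng(8)
        mir = random_seq(r, 8, 8)
        utr = random_seq(r, 60, 60)
        off, site, score = best_window(mir, utr, 13)
        ws = window_scores(mir, utr, 13)
        assert score == ws.max()
        assert off == int(np.argmax(ws))
        assert site == utr[off:off + 13]


def _duplex(pairs, types, mlen=22, slen=30):
    return DuplexStructure(tuple(pairs), tuple(types), 0, mlen, slen)


def _consecutive(positions, start_site=20, types=None):
    """Helper: pairs at given miRNA positions to consecutive site bases."""
    pairs = []
    for k, p in enumerate(positions):
        pairs.append((p, start_site - (p - positions[0])))
    return pairs


class TestClassifySeed:
    def test_exact_wc_2_7_is_canonical(self):
        pairs = _consecutive(list(range(2, 8)))
        d = _duplex(pairs, ["WC"] * 6)
        assert classify_seed(d) == dx.CANONICAL

    def test_exact_wc_3_8_is_canonical(self):
        pairs = _consecutive(list(range(3, 9)))
        d = _duplex(pairs, ["WC"] * 6)
        assert classify_seed(d) == dx.CANONICAL

    def test_single_gu_demotes_to_noncanonical(self):
        pairs = _consecutive(list(range(2, 8)))
        types = ["WC"] * 6
        types[3] = "GU"  # position 5
        d = _duplex(pairs, types)
        assert classify_seed(d) == dx.NON_CANONICAL

    def test_single_unpaired_position_is_noncanonical(self):
        positions = [2, 3, 4, 6, 7]  # 5 unpaired (mismatch vs site gap)
        pairs = [(2, 20), (3, 19), (4, 18), (6, 16), (7, 15)]
        d = _duplex(pairs, ["WC"] * 5)
        assert classify_seed(d) == dx.NON_CANONICAL

    def test_site_bulge_within_window_is_noncanonical(self):
        # site skips one base between miRNA 4 and 5
        pairs = [(2, 20), (3, 19), (4, 18), (5, 16), (6, 15), (7, 14)]
        d = _duplex(pairs, ["WC"] * 6)
        assert classify_seed(d) == dx.NON_CANONICAL

    def test_two_defects_fall_to_other(self):
        # positions 2 and 6 unpaired, rest WC
        pairs = [(3, 19), (4, 18), (5, 17), (7, 15), (8, 14)]
        d = _duplex(pairs, ["WC"] * 5)
        # window 2-7: unpaired 2 and 6 -> 2 defects; window 3-8: 6 unpaired
        # (1 defect) ... the 3-8 window rescues this to non-canonical
        assert classify_seed(d) == dx.NON_CANONICAL

    def test_two_defects_in_both_windows_is_other(self):
        # positions 2, 5 and 8 unpaired: every window has >= 2 defects
        pairs = [(3, 19), (4, 18), (6, 16), (7, 15)]
        d = _duplex(pairs, ["WC"] * 4)
        assert classify_seed(d) == dx.OTHER

    def test_window_3_8_rescues_canonical(self):
        # 2 unpaired but 3-8 perfectly paired: canonical via 3-8
        pairs = _consecutive(list(range(3, 9)))
        d = _duplex(pairs, ["WC"] * 6)
        assert classify_seed(d) == dx.CANONICAL

    def test_empty_duplex_is_other(self):
        assert classify_seed(_duplex([], [])) == dx.OTHER

    @pytest.mark.parametrize("n_gu", [2, 3])
    def test_multiple_gu_without_bulge_is_noncanonical(self, n_gu):
        pairs = _consecutive(list(range(2, 8)))
        types = ["GU"] * n_gu + ["WC"] * (6 - n_gu)
        d = _duplex(pairs, types)
        assert classify_seed(d) == dx.NON_CANONICAL


class TestGenerateNegative:
    def _positive(self, mirna, seed=0):
        return InteractionRecord(
            interaction_id="p1", mirna_id="mir1", mirna_seq=mirna,
            site_seq=mirna[:8], label=1)

    def test_homopolymer_mirna_fails(self, rng):
        mir = "A" * 22
        pos = self._positive(mir)
        with pytest.raises(NegativeGenerationError, match="mir1"):
            generate_negative(pos, [mir], "ACGU" * 20, rng, max_attempts=50)

    def test_negative_avoids_all_catalog_seed_kmers(self, rng):
        r = np.random.default_rng(5)
        catalog = [random_seq(r, 20, 24) for _ in range(20)]
        utr = random_seq(r, 120, 150)
        pos = self._positive(catalog[0])
        neg = generate_negative(pos, catalog, utr, rng)
        k27, k38 = seed_kmers(neg.mirna_seq)
        assert k27 not in {m[1:7] for m in catalog}
        assert k38 not in {m[2:8] for m in catalog}
        assert sorted(neg.mirna_seq) == sorted(catalog[0])
        assert neg.label == 0

    def test_site_is_best_window_by_independent_scan(self, rng):
        r = np.random.default_rng(6)
        catalog = [random_seq(r, 20, 22) for _ in range(5)]
        utr = random_seq(r, 60, 60)
        pos = self._positive(catalog[0])
        neg = generate_negative(pos, catalog, utr, rng)
        w = len(neg.mirna_seq) + 5
        scores = [predict_duplex(neg.mirna_seq, utr[k:k + w]).score
                  for k in range(len(utr) - w + 1)]
        got = predict_duplex(neg.mirna_seq, neg.site_seq).score
        assert got == max(scores)
        assert neg.site_offset == int(np.argmax(scores))
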