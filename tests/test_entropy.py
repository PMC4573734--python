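import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afdetect import EntropyState, build_pimap, entropy_direct
from conftest import sliding_direct_entropy

N = 127
CONS = 10**6


class TestPiMap:
    def test_golden_entries(self, pimap):
        assert pimap.values[1] == 7874
        assert pimap.values[63] == 71790
        assert pimap.values[64] == 71291
        assert pimap.values[0] == 0
        assert pimap.values[127] == 0

    def test_invariants_other_sizes(self):
        for n in (2, 17, 127, 256):
            t = build_pimap(n, CONS)
            assert t.values[0] == 0 and t.values[n] == 0
            assert (t.values >= 0).all()
            scale = CONS / math.log2(n)
            for i in (1, n // 2, n - 1):
                p = i / n
                assert t.values[i] == math.floor(scale * (-p * math.log2(p)))

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            build_pimap(1)
        with pytest.raises(ValueError):
            build_pimap(127, 0)

    def test_text_roundtrip(self, pimap, tmp_path):
        p = tmp_path / "pimap.txt"
        pimap.save_text(p)
        assert np.array_equal(np.loadtxt(p, dtype=np.int64), pimap.values)


class TestDirect:
    def test_single_repeated_word_is_zero(self):
        assert entropy_direct([5] * 127) == 0.0

    def test_all_distinct_is_one(self):
        assert entropy_direct(range(127)) == pytest.approx(1.0)

    def test_two_block_window(self):
        # 64 copies of one word + 63 of another, probabilities over N=127
        expected = (
            2
            / (127 * math.log2(127))
            * (-(64 / 127) * math.log2(64 / 127) - (63 / 127) * math.log2(63 / 127))
        )
        h = entropy_direct([0] * 64 + [1] * 63)
        assert h == pytest.approx(expected)
        assert h == pytest.approx(0.0022533, abs=1e-6)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            entropy_direct([])


class TestRecursion:
    def test_first_push(self, pimap):
        state = EntropyState(pimap)
        h = state.push(42)
        assert state.k == 1
        assert state.acc == 7874
        assert h == pytest.approx(7874 / 127e6)

    def test_saturated_single_word(self, pimap):
        state = EntropyState(pimap)
        for _ in range(127):
            h = state.push(9)
        assert state.counts == {9: 127}
        assert h == 0.0

    def test_reset_equals_fresh(self, pimap):
        a = EntropyState(pimap)
        for w in [3, 1, 4, 1, 5]:
            a.push(w)
        a.reset()
        b = EntropyState(pimap)
        ws = [2, 7, 1, 8, 2, 8]
        ha = [a.push(w) for w in ws]
        hb = [b.push(w) for w in ws]
        assert ha == hb
        assert a.occupancy == len(ws)

    @pytest.mark.parametrize("alphabet", [1, 5, 50, 300])
    def test_matches_direct_oracle(self, pimap, alphabet):
        """Recursive integer entropy tracks the defining formula to within
        the lookup-table quantisation error at every saturated position."""
        rng = np.random.default_rng(alphabet)
        words = rng.integers(0, alphabet, 500)
        state = EntropyState(pimap)
        h_rec = np.array([state.push(int(w)) for w in words])
        h_dir = sliding_direct_entropy(words, N)
        assert np.max(np.abs(h_rec[N - 1 :] - h_dir)) <= 2e-4

    def test_direct_oracle_helpers_agree(self):
        """The vectorised sliding oracle equals entropy_direct per window."""
        rng = np.random.default_rng(3)
        words = rng.integers(0, 40, 300)
        vec = sliding_direct_entropy(words, N)
        for j in (0, 57, len(vec) - 1):
            assert vec[j] == pytest.approx(entropy_direct(words[j : j + N], N))

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=400),
    )
    def test_state_bookkeeping(self, pimap, words):
        """Counts, k and the accumulator always match a brute-force recount
        of the trailing window."""
        state = EntropyState(pimap)
        for w in words:
            state.push(w)
        trailing = Counter(words[-N:])
        assert state.counts == dict(trailing)
        assert state.k == len(trailing)
        assert sum(state.counts.values()) == min(len(words), N)
        assert state.acc == sum(int(pimap.values[c]) for c in trailing.values())

    def test_permutation_invariance(self, pimap):
        rng = np.random.default_rng(11)
        window = rng.integers(0, 30, N)
        h1 = EntropyState(pimap)
        for w in window:
            last1 = h1.push(int(w))
        rng.shuffle(window)
        h2 = EntropyState(pimap)
        for w in window:
            last2 = h2.push(int(w))
        assert last1 == last2

    def test_range_bounds(self, pimap):
        rng = np.random.default_rng(5)
        state = EntropyState(pimap)
        for w in rng.integers(0, 1000, 2000):
            h = state.push(int(w))
            assert 0.0 <= h <= 1.0 + 1e-12
            if h == 0.0:
                # zero entropy only for a saturated single-word window
                assert state.k == 1 and state.counts == {state.window[0]: N}
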