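"""Coarse Shannon entropy of the word-window, direct and recursive.

The detector scores each beat with a normalised ("coarse") Shannon
entropy of the last N = 127 words,

    H'' = -(k / (N log2 N)) * sum_i p_i log2 p_i,   p_i = N_i / N,

where N_i is the count of the i-th distinct word in the window and k the
number of distinct words.  H'' lies in [0, 1]: 0 for a single repeated
word, 1 when all window words differ.

Two evaluation routes are provided:

* :func:`entropy_direct` — the floating-point formula above, used as the
  reference oracle in tests;
* :class:`EntropyState` — the O(1)-per-beat streaming recursion built on
  a precomputed integer lookup table (:func:`build_pimap`), which is what
  the real-time detector runs.

Note the probability denominator is the *nominal* window size N even
while the window is still filling; the recursion indexes the lookup table
by raw count, and the direct oracle mirrors that so the two routes agree
from the very first word.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass
from typing import Iterable

import numpy as np

DEFAULT_N = 127
DEFAULT_CONS = 1_000_000

__all__ = [
    "DEFAULT_N",
    "DEFAULT_CONS",
    "PiMapTable",
    "build_pimap",
    "entropy_direct",
    "EntropyState",
]


@dataclass(frozen=True)
class PiMapTable:
    """Integer lookup table of scaled per-count entropy terms.

    ``values[i]`` holds ``floor((cons / log2 N) * (-(i/N) log2(i/N)))``
    for ``1 <= i <= N``; ``values[0] = 0`` by convention.  The table lets
    the streaming update replace all logarithms with array lookups.
    """

    N: int
    cons: int
    values: np.ndarray

    def save_text(self, path) -> None:
        """Write the table as one integer per line (for inspection)."""
        np.savetxt(path, self.values, fmt="%d")


def build_pimap(N: int = DEFAULT_N, cons: int = DEFAULT_CONS) -> PiMapTable:
    """Precompute the integer entropy lookup table for window size *N*.

    With the defaults (N=127, cons=10**6) the table starts
    ``[0, 7874, ...]`` and ends in ``0`` (a certain event carries no
    surprise).
    """
    if not (isinstance(N, (int, np.integer)) and N >= 2):
        raise ValueError(f"window size N must be an integer >= 2, got {N!r}")
    if not (isinstance(cons, (int, np.integer)) and cons >= 1):
        raise ValueError(f"scale constant must be an integer >= 1, got {cons!r}")
    scale = cons / math.log2(N)
    values = np.zeros(N + 1, dtype=np.int64)
    for i in range(1, N + 1):
        p = i / N
        values[i] = math.floor(scale * (-p * math.log2(p)))
    return PiMapTable(N=int(N), cons=int(cons), values=values)


def entropy_direct(window: Iterable[int], N: int = DEFAULT_N) -> float:
    """Coarse Shannon entropy of a word multiset, by the defining formula.

    ``window`` is the (at most N) words currently in scope; probabilities
    use the fixed denominator N.  This is the floating-point oracle — no
    integer quantisation.
    """
    counts = Counter(window)
    if not counts:
        raise ValueError("empty window: entropy undefined")
    if sum(counts.values()) > N:
        raise ValueError(f"window holds more than N={N} words")
    k = len(counts)
    s = 0.0
    for c in counts.values():
        p = c / N
        s += p * math.log2(p)
    return -(k / (N * math.log2(N))) * s


class EntropyState:
    """Rolling detector state: sliding word window with O(1) entropy updates.

    Maintains the circular window of the last N words, per-word counts,
    the distinct-word count ``k`` and an exact integer accumulator
    ``acc = sum PiMap[count(w)]`` over live words.  Each :meth:`push`
    performs a constant number of integer operations plus one multiply
    and one divide to produce H''.
    """

    def __init__(self, table: PiMapTable | None = None):
        self.table = table if table is not None else build_pimap()
        self._pimap = [int(v) for v in self.table.values]
        self.reset()

    def reset(self) -> None:
        """Zero all state, as at the start of a record."""
        self.window: deque[int] = deque()
        self.counts: dict[int, int] = {}
        self.k = 0
        self.acc = 0
        self.n_seen = 0

    @property
    def occupancy(self) -> int:
        return len(self.window)

    def push(self, w: int) -> float:
        """Slide word *w* into the window; return the updated H''.

        When the window is full the oldest word slides out first: its
        lookup term at the old count is removed, the count decremented,
        the term at the new count added, and ``k`` decremented if the
        count reached zero.  The mirror-image then admits *w*.
        """
        w = int(w)
        if w < 0:
            raise ValueError(f"negative word value {w}")
        N = self.table.N
        pimap = self._pimap
        if len(self.window) == N:
            old = self.window.popleft()
            c = self.counts[old]
            self.acc -= pimap[c]
            c -= 1
            self.acc += pimap[c]
            if c == 0:
                del self.counts[old]
                self.k -= 1
            else:
                self.counts[old] = c
        c = self.counts.get(w, 0)
        if c == 0:
            self.k += 1
        self.acc -= pimap[c]
        c += 1
        self.acc += pimap[c]
        self.counts[w] = c
        self.window.append(w)
        self.n_seen += 1
        return self.k * self.acc / (N * self.table.cons)

    @property
    def h(self) -> float:
        """Current H'' without pushing (0.0 for an empty window)."""
        return self.k * self.acc / (self.table.N * self.table.cons)
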