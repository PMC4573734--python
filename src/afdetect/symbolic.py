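"""Symbolic dynamics of heart-rate sequences.

An RR-interval stream is mapped to instantaneous heart rates (bpm), each
heart rate to one of 64 discrete state symbols (5-bpm bins, capped at
315 bpm), and each run of three consecutive symbols to a single integer
"word" by bit-shifting.  The occupancy statistics of these words inside a
sliding window are what the entropy detector operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AF = "AF"
NONAF = "NONAF"
WARMUP = "WARMUP"

#: number of symbols in the alphabet: heart rates are quantised into
#: 5-bpm bins from 0 up to the 315-bpm cap, symbol 63 absorbing the tail.
N_SYMBOLS = 64
HR_CAP = 315.0
BIN_WIDTH = 5.0
MAX_WORD = N_SYMBOLS**3 - 1  # 262143

__all__ = [
    "AF",
    "NONAF",
    "WARMUP",
    "N_SYMBOLS",
    "HR_CAP",
    "BIN_WIDTH",
    "MAX_WORD",
    "BeatStream",
    "rr_to_hr",
    "symbolize",
    "encode_word",
    "decode_word",
    "symbolize_stream",
]


@dataclass
class BeatStream:
    """An ordered sequence of beats for one record.

    Parameters
    ----------
    record_id
        Identifier of the record the beats belong to.
    rr
        RR intervals in milliseconds, all strictly positive.
    labels
        Optional per-beat ground-truth rhythm labels, ``"AF"`` or
        ``"NONAF"``, same length as ``rr``.
    """

    record_id: str
    rr: np.ndarray
    labels: np.ndarray | None = None
    time_s: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1:
            raise ValueError("rr must be one-dimensional")
        bad = ~np.isfinite(self.rr) | (self.rr <= 0)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"record {self.record_id!r}: invalid RR interval "
                f"{self.rr[idx]!r} at beat {idx} (must be finite and > 0)"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.rr):
                raise ValueError(
                    f"record {self.record_id!r}: {len(self.labels)} labels "
                    f"for {len(self.rr)} beats"
                )
            unknown = set(self.labels) - {AF, NONAF}
            if unknown:
                raise ValueError(f"unknown rhythm labels: {sorted(unknown)}")
        if self.time_s is not None:
            self.time_s = np.asarray(self.time_s, dtype=float)
            if len(self.time_s) != len(self.rr):
                raise ValueError("time_s and rr must have equal length")

    def __len__(self) -> int:
        return len(self.rr)

    @property
    def hr(self) -> np.ndarray:
        """Instantaneous heart rate in bpm, ``60000 / rr_ms``."""
        return 60000.0 / self.rr


def rr_to_hr(rr_ms: float) -> float:
    """Convert one RR interval (ms) to instantaneous heart rate (bpm).

    The heart rate is kept real-valued; quantisation happens only in
    :func:`symbolize`.
    """
    if not np.isfinite(rr_ms) or rr_ms <= 0:
        raise ValueError(f"invalid RR interval {rr_ms!r}: must be finite and > 0")
    return 60000.0 / rr_ms


def symbolize(hr: float, *, hr_cap: float = HR_CAP, bin_width: float = BIN_WIDTH) -> int:
    """Map a heart rate to its instantaneous-state symbol.

    Rates at or above ``hr_cap`` map to the top symbol; below it the rate
    is floored into ``bin_width``-bpm bins, giving 64 attainable symbols
    at the defaults (0..63).
    """
    if not np.isfinite(hr) or hr < 0:
        raise ValueError(f"invalid heart rate {hr!r}: must be finite and >= 0")
    top = int(hr_cap // bin_width)
    if hr >= hr_cap:
        return top
    return int(hr // bin_width)


def encode_word(s2: int, s1: int, s0: int) -> int:
    """Pack three consecutive symbols (oldest first) into one word.

    Implemented as ``(s2 << 12) | (s1 << 6) | s0``, e.g. symbols
    ``0, 1, 3`` encode to ``67``.
    """
    for s in (s2, s1, s0):
        if not 0 <= int(s) < N_SYMBOLS:
            raise ValueError(f"symbol {s!r} outside [0, {N_SYMBOLS - 1}]")
    return (int(s2) << 12) | (int(s1) << 6) | int(s0)


def decode_word(w: int) -> tuple[int, int, int]:
    """Invert :func:`encode_word`: recover the (oldest, middle, newest) triple."""
    if not 0 <= int(w) <= MAX_WORD:
        raise ValueError(f"word {w!r} outside [0, {MAX_WORD}]")
    w = int(w)
    return (w >> 12) & 63, (w >> 6) & 63, w & 63


def symbolize_stream(
    stream: BeatStream,
    *,
    hr_cap: float = HR_CAP,
    bin_width: float = BIN_WIDTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised symbol and word sequences for a beat stream.

    Returns ``(symbols, words)`` where ``symbols[n]`` is the state of beat
    ``n`` and ``words[j]`` encodes beats ``j, j+1, j+2``; the word stream
    is therefore two elements shorter than the beat stream (empty for
    fewer than three beats).  Identical to applying the per-beat
    operations sequentially.
    """
    if len(stream) == 0:
        raise ValueError(f"record {stream.record_id!r}: empty beat stream")
    hr = stream.hr
    top = int(hr_cap // bin_width)
    symbols = np.where(hr >= hr_cap, top, np.floor(hr / bin_width)).astype(np.int64)
    if len(symbols) < 3:
        return symbols, np.empty(0, dtype=np.int64)
    words = (symbols[:-2] << 12) | (symbols[1:-1] << 6) | symbols[2:]
    return symbols, words
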