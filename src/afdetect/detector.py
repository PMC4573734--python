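"""Beat-by-beat streaming AF classifier.

For each incoming beat the detector updates the symbol and word state,
slides the new word into the entropy window, and labels the beat AF when
the coarse Shannon entropy meets or exceeds the decision threshold.  The
first N+1 beats (2 to form the first word, N-1 more to fill the window;
128 beats at the default N=127) are the warm-up during which the window
is under-filled; how they are reported is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .entropy import DEFAULT_CONS, DEFAULT_N, EntropyState, build_pimap
from .symbolic import AF, BIN_WIDTH, HR_CAP, NONAF, WARMUP, BeatStream, symbolize_stream

__all__ = ["DetectorConfig", "BeatDecision", "decide", "detect_stream"]

WARMUP_POLICIES = ("mark", "nonaf", "drop")

#: entropy threshold separating AF from non-AF rhythm, as selected on a
#: long-term training database by ROC analysis.
DEFAULT_THRESHOLD = 0.639


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the streaming detector.

    ``warmup_policy`` controls the first N+1 beats: ``"mark"`` labels
    them WARMUP (excluded from evaluation), ``"nonaf"`` forces NONAF,
    ``"drop"`` omits them from the output.
    """

    threshold: float = DEFAULT_THRESHOLD
    N: int = DEFAULT_N
    cons: int = DEFAULT_CONS
    hr_cap: float = HR_CAP
    bin_width: float = BIN_WIDTH
    warmup_policy: str = "mark"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold {self.threshold} outside [0, 1]")
        if self.N < 2:
            raise ValueError("window size N must be >= 2")
        if self.hr_cap <= 0 or self.bin_width <= 0:
            raise ValueError("hr_cap and bin_width must be positive")
        if self.warmup_policy not in WARMUP_POLICIES:
            raise ValueError(
                f"warmup_policy {self.warmup_policy!r} not in {WARMUP_POLICIES}"
            )


@dataclass(frozen=True)
class BeatDecision:
    """Per-beat detector output.

    ``h`` is the entropy after the word ending at this beat was pushed
    (None for the first two beats, which complete no word); ``label`` is
    AF, NONAF or WARMUP.
    """

    beat_index: int
    h: float | None
    label: str


def decide(h: float, threshold: float) -> str:
    """AF iff the entropy meets or exceeds the threshold (ties are AF)."""
    return AF if h >= threshold else NONAF


def detect_stream(stream: BeatStream, config: DetectorConfig | None = None) -> list[BeatDecision]:
    """Classify every beat of one record, causally.

    The decision for beat n uses only beats <= n: the word ending at beat
    n enters the window before n is scored.  Detector state is fresh for
    every call, so records never leak into each other.
    """
    if config is None:
        config = DetectorConfig()
    _, words = symbolize_stream(stream, hr_cap=config.hr_cap, bin_width=config.bin_width)
    state = EntropyState(build_pimap(config.N, config.cons))
    first_defined = config.N + 1  # beat index of the first full-window decision
    decisions: list[BeatDecision] = []

    def emit(i: int, h: float | None) -> None:
        if i < first_defined:
            if config.warmup_policy == "drop":
                return
            label = NONAF if config.warmup_policy == "nonaf" else WARMUP
        else:
            label = decide(h, config.threshold)
        decisions.append(BeatDecision(beat_index=i, h=h, label=label))

    for i in range(min(2, len(stream))):
        emit(i, None)
    for j, w in enumerate(words):
        emit(j + 2, state.push(int(w)))
    return decisions
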