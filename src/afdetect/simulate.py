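"""Synthetic RR-interval streams with ground-truth rhythm labels.

Two rhythm models capture the statistical contrast the detector
exploits:

* **Sinus rhythm (NSR)** — heart rate drifts slowly (sinusoidal
  modulation) around a mean with small beat-to-beat Gaussian
  variability, so the symbol sequence occupies only a handful of 5-bpm
  states and the word window is dominated by a few repeated words (low
  entropy).
* **Atrial fibrillation (AF)** — RR intervals are drawn i.i.d. uniform
  over a wide physiological range (default 300-1000 ms, i.e. 60-200
  bpm), mimicking the near-memoryless ventricular response: the window
  fills with mostly distinct words (entropy near 1).

Paroxysmal records concatenate labelled NSR/AF episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .symbolic import AF, NONAF, BeatStream

__all__ = ["SimConfig", "gen_nsr", "gen_af", "gen_paroxysmal"]

DEFAULT_EPISODES: tuple[tuple[str, int], ...] = (("NSR", 500), ("AF", 500), ("NSR", 500))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters (units in field names; defaults are the
    simulated study conditions)."""

    seed: int = 0
    n_beats: int = 2000
    nsr_hr_mean: float = 70.0  # bpm
    nsr_hr_sd: float = 2.0  # bpm, beat-to-beat Gaussian jitter
    nsr_drift_amp: float = 3.0  # bpm, slow respiratory-like modulation
    nsr_drift_period: float = 60.0  # beats per modulation cycle
    af_rr_min: float = 300.0  # ms
    af_rr_max: float = 1000.0  # ms
    episode_spec: tuple[tuple[str, int], ...] = DEFAULT_EPISODES

    def __post_init__(self) -> None:
        if self.n_beats <= 0:
            raise ValueError("n_beats must be positive")
        if self.af_rr_min >= self.af_rr_max:
            raise ValueError("af_rr_min must be < af_rr_max")
        if self.nsr_hr_sd < 0:
            raise ValueError("nsr_hr_sd must be >= 0")


def _nsr_rr(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    i = np.arange(n)
    hr = (
        config.nsr_hr_mean
        + config.nsr_drift_amp * np.sin(2.0 * np.pi * i / config.nsr_drift_period)
        + rng.normal(0.0, config.nsr_hr_sd, n)
    )
    hr = np.clip(hr, 20.0, None)  # guard against pathological jitter draws
    return 60000.0 / hr


def _af_rr(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(config.af_rr_min, config.af_rr_max, n)


def gen_nsr(
    config: SimConfig, n: int | None = None, rng: np.random.Generator | None = None
) -> BeatStream:
    """Generate *n* beats of sinus rhythm (all labelled NONAF)."""
    n = config.n_beats if n is None else n
    if n <= 0:
        raise ValueError("number of beats must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rr = _nsr_rr(config, n, rng)
    return BeatStream("sim-nsr", rr, labels=np.array([NONAF] * n, dtype=object))


def gen_af(
    config: SimConfig, n: int | None = None, rng: np.random.Generator | None = None
) -> BeatStream:
    """Generate *n* beats of simulated AF (all labelled AF)."""
    n = config.n_beats if n is None else n
    if n <= 0:
        raise ValueError("number of beats must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rr = _af_rr(config, n, rng)
    return BeatStream("sim-af", rr, labels=np.array([AF] * n, dtype=object))


def gen_paroxysmal(config: SimConfig) -> BeatStream:
    """Concatenate NSR/AF episodes per ``config.episode_spec``.

    A single seeded RNG drives all segments, so the whole record is
    reproducible from the config alone.  Episode boundaries in the
    emitted labels fall exactly at the cumulative segment lengths.
    """
    if not config.episode_spec:
        raise ValueError("episode_spec must be nonempty")
    rng = np.random.default_rng(config.seed)
    rr_parts: list[np.ndarray] = []
    labels: list[str] = []
    for rhythm, length in config.episode_spec:
        length = int(length)
        if length <= 0:
            raise ValueError(f"zero- or negative-length episode {(rhythm, length)!r}")
        if rhythm.upper() in ("NSR", "N", NONAF):
            rr_parts.append(_nsr_rr(config, length, rng))
            labels.extend([NONAF] * length)
        elif rhythm.upper() == AF:
            rr_parts.append(_af_rr(config, length, rng))
            labels.extend([AF] * length)
        else:
            raise ValueError(f"unknown rhythm {rhythm!r} (expected NSR or AF)")
    return BeatStream(
        "sim-paroxysmal",
        np.concatenate(rr_parts),
        labels=np.array(labels, dtype=object),
    )
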