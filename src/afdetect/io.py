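"""Reading and writing beat streams, annotations, decisions and ROC tables.

Conventions used at every interface: beat indices are 0-based, times are
seconds, RR intervals are milliseconds.

Supported formats
-----------------
beat CSV
    Headered, UTF-8, columns ``rr_ms`` (required), ``label`` (optional,
    ``AF``/``NONAF``) and ``time_s`` (optional).
rdann-style text
    Whitespace-delimited annotation exports: ``time code`` or
    ``time sample code`` per line, where ``time`` is seconds or
    ``[HH:]MM:SS[.sss]`` elapsed time.  Lines whose code starts with
    ``(`` are rhythm annotations (``(AFIB``, ``(N`` ...); all other
    lines are beats.  RR intervals are successive beat-time differences,
    so the first beat carries no RR and is dropped (a notice is logged).
decisions CSV
    ``record_id, beat_index, h, label`` with h to 6 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detector import BeatDecision
from .evaluate import RocCurve
from .symbolic import AF, NONAF, BeatStream

logger = logging.getLogger(__name__)

__all__ = [
    "RhythmAnnotation",
    "read_beats",
    "write_beats",
    "read_rhythm_annotations",
    "expand_rhythm_labels",
    "write_decisions",
    "read_decisions",
    "write_roc",
    "DEFAULT_AF_CODES",
]

#: rhythm codes counted as the AF class; atrial flutter "(AFL" is not
#: included by default but may be added by the caller.
DEFAULT_AF_CODES = frozenset({"(AFIB"})


@dataclass(frozen=True)
class RhythmAnnotation:
    """A rhythm-change marker: the rhythm *code* governs from *onset*
    (beat index or time in seconds) until the next annotation."""

    onset: float
    rhythm: str


def _parse_time(token: str, lineno: int) -> float:
    """Seconds from a float literal or an ``[HH:]MM:SS[.sss]`` stamp."""
    try:
        return float(token)
    except ValueError:
        pass
    parts = token.split(":")
    if len(parts) in (2, 3):
        try:
            fields = [float(p) for p in parts]
        except ValueError:
            fields = None
        if fields is not None:
            t = 0.0
            for f in fields:
                t = t * 60.0 + f
            return t
    raise ValueError(f"line {lineno}: cannot parse time {token!r}")


def read_beats(path, format: str = "csv") -> BeatStream:
    """Load a beat stream from ``csv`` or ``rdann_text``."""
    path = Path(path)
    if format == "csv":
        return _read_beats_csv(path)
    if format == "rdann_text":
        return _read_beats_rdann(path)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'rdann_text')")


def _read_beats_csv(path: Path) -> BeatStream:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if "rr_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column 'rr_ms'")
    if len(df) == 0:
        raise ValueError(f"{path}: no beats")
    labels = None
    if "label" in df.columns:
        labels = df["label"].astype(str).to_numpy(dtype=object)
    time_s = df["time_s"].to_numpy(dtype=float) if "time_s" in df.columns else None
    return BeatStream(path.stem, df["rr_ms"].to_numpy(dtype=float), labels=labels, time_s=time_s)


def _read_beats_rdann(path: Path) -> BeatStream:
    beat_times: list[float] = []
    rhythms: list[RhythmAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'time [sample] code'")
            t = _parse_time(tokens[0], lineno)
            code = tokens[2] if len(tokens) >= 3 else tokens[1]
            if code.startswith("("):
                rhythms.append(RhythmAnnotation(onset=t, rhythm=code))
            else:
                beat_times.append(t)
    if len(beat_times) < 2:
        raise ValueError(f"{path}: fewer than 2 beat annotations; no RR intervals")
    times = np.asarray(beat_times)
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise ValueError(f"{path}: beat times not strictly increasing at beat {bad}")
    rr = np.diff(times) * 1000.0
    logger.info("%s: first beat (t=%.3f s) dropped — no preceding RR interval", path, times[0])
    labels = None
    if rhythms:
        labels = expand_rhythm_labels(rhythms, len(rr), beat_times=times[1:])
    return BeatStream(path.stem, rr, labels=labels, time_s=times[1:])


def read_rhythm_annotations(path) -> list[RhythmAnnotation]:
    """Rhythm annotations only (lines whose code starts with ``(``)."""
    path = Path(path)
    out: list[RhythmAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            code = tokens[2] if len(tokens) >= 3 else tokens[1]
            if code.startswith("("):
                out.append(RhythmAnnotation(onset=_parse_time(tokens[0], lineno), rhythm=code))
    return out


def expand_rhythm_labels(
    annotations: Sequence[RhythmAnnotation | tuple],
    n_beats: int,
    beat_times: Sequence[float] | None = None,
    af_codes: frozenset[str] | set[str] = DEFAULT_AF_CODES,
) -> np.ndarray:
    """Expand interval rhythm annotations to one label per beat.

    Half-open semantics: annotation j governs beats in
    ``[onset_j, onset_{j+1})``.  Onsets are beat indices when
    ``beat_times`` is None, otherwise times in seconds matched against
    ``beat_times``.  A code in ``af_codes`` maps to AF, anything else to
    NONAF.  A beat before the first annotation has no rhythm and is an
    error.
    """
    anns = [a if isinstance(a, RhythmAnnotation) else RhythmAnnotation(*a) for a in annotations]
    if not anns:
        raise ValueError("no rhythm annotations to expand")
    onsets = np.asarray([a.onset for a in anns], dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("rhythm annotation onsets must be strictly increasing")
    positions = np.arange(n_beats, dtype=float) if beat_times is None else np.asarray(beat_times, dtype=float)
    if len(positions) != n_beats:
        raise ValueError("beat_times length must equal n_beats")
    if n_beats and positions[0] < onsets[0]:
        raise ValueError(
            f"beat 0 (at {positions[0]:g}) precedes the first rhythm annotation "
            f"(onset {onsets[0]:g})"
        )
    idx = np.searchsorted(onsets, positions, side="right") - 1
    is_af = np.asarray([a.rhythm in af_codes for a in anns])
    return np.where(is_af[idx], AF, NONAF).astype(object)


def write_beats(stream: BeatStream, path) -> None:
    """Write a beat stream as the standard headered CSV."""
    cols: dict[str, object] = {"rr_ms": stream.rr}
    if stream.labels is not None:
        cols["label"] = stream.labels
    if stream.time_s is not None:
        cols["time_s"] = stream.time_s
    pd.DataFrame(cols).to_csv(path, index=False)


def write_decisions(decisions: Sequence[BeatDecision], path, record_id: str = "") -> None:
    """Write per-beat decisions (h rounded to 6 decimals, empty if undefined)."""
    pd.DataFrame(
        {
            "record_id": [record_id] * len(decisions),
            "beat_index": [d.beat_index for d in decisions],
            "h": [None if d.h is None else round(d.h, 6) for d in decisions],
            "label": [d.label for d in decisions],
        }
    ).to_csv(path, index=False)


def read_decisions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"record_id", "beat_index", "h", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing decision columns {sorted(missing)}")
    return df


def write_roc(curve: RocCurve, path) -> None:
    """Per-threshold table; AUC and the best operating point ride along
    as comment header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# auc={curve.auc:.6f}\n")
        fh.write(
            f"# best_threshold={curve.best_threshold:.3f} best_distance={curve.best_distance:.6f}\n"
        )
        curve.points.to_csv(fh, index=False)
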