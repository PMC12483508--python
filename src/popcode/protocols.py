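"""Stimulus protocols: trial structure for gray-screen, drifting-grating and
natural-movie sessions.

A protocol is an ordered list of labeled presentations (condition label, onset
frame, duration in frames) plus the bookkeeping needed to cut traces into
trials.  The three session kinds mirror a standard awake two-photon protocol:

* ``gray``     — 640 s of static gray screen (spontaneous activity), no labels.
* ``gratings`` — 16 trials; each trial is a fixed sequence of 8 drifting-grating
  directions (45° apart), each direction 2 s ON preceded by a 3 s OFF period.
* ``movies``   — 32 trials; each trial is a 3 s OFF period followed by 7
  consecutive 2 s natural-movie clips in fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Presentation", "StimulusProtocol", "make_protocol", "GRATING_DIRECTIONS_DEG"]

#: The 8 drifting-grating directions, degrees, in condition-label order.
GRATING_DIRECTIONS_DEG = np.arange(8) * 45.0

_GRAY_DURATION_S = 640.0
_GRATING_TRIALS = 16
_GRATING_DIRECTIONS = 8
_GRATING_ON_S = 2.0
_GRATING_OFF_S = 3.0
_MOVIE_TRIALS = 32
_MOVIE_CLIPS = 7
_MOVIE_CLIP_S = 2.0
_MOVIE_OFF_S = 3.0


@dataclass(frozen=True)
class Presentation:
    """A single labeled stimulus presentation."""

    label: int
    onset_frame: int
    duration_frames: int

    @property
    def offset_frame(self) -> int:
        return self.onset_frame + self.duration_frames


@dataclass
class StimulusProtocol:
    """Trial structure of one imaging session.

    Attributes
    ----------
    kind:
        ``"gray"``, ``"gratings"`` or ``"movies"``.
    presentations:
        Ordered, non-overlapping labeled presentations.
    n_trials, n_conditions:
        Trial repetitions and number of distinct condition labels
        (8 directions for gratings, 7 clips for movies, 0 for gray).
    frame_rate_hz:
        Acquisition frame rate the onsets were computed at.
    total_frames:
        Session length in frames.
    """

    kind: str
    presentations: list[Presentation]
    n_trials: int
    n_conditions: int
    frame_rate_hz: float
    total_frames: int

    def __post_init__(self) -> None:
        last_end = -1
        for p in self.presentations:
            if p.onset_frame <= last_end:
                raise ValueError("presentations must be non-overlapping and increasing")
            if not (0 <= p.label < max(self.n_conditions, 1)):
                raise ValueError(f"label {p.label} outside [0, {self.n_conditions})")
            last_end = p.offset_frame - 1

    @property
    def duration_s(self) -> float:
        return self.total_frames / self.frame_rate_hz

    def frame_labels(self) -> np.ndarray:
        """Condition label per frame; -1 during OFF/blank frames."""
        labels = np.full(self.total_frames, -1, dtype=np.int64)
        for p in self.presentations:
            labels[p.onset_frame : p.offset_frame] = p.label
        return labels

    def onsets_of(self, label: int) -> np.ndarray:
        return np.array(
            [p.onset_frame for p in self.presentations if p.label == label], dtype=np.int64
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [p.label for p in self.presentations],
                "onset_frame": [p.onset_frame for p in self.presentations],
                "duration_frames": [p.duration_frames for p in self.presentations],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame_labels(
        cls, labels: np.ndarray, kind: str, n_trials: int, n_conditions: int,
        frame_rate_hz: float,
    ) -> "StimulusProtocol":
        """Reconstruct the presentation list from a per-frame label vector."""
        labels = np.asarray(labels)
        pres: list[Presentation] = []
        boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [labels.size]])
        for s, e in zip(starts, ends):
            if labels[s] >= 0:
                pres.append(Presentation(int(labels[s]), int(s), int(e - s)))
        return cls(kind, pres, n_trials, n_conditions, frame_rate_hz, int(labels.size))


def _frames(seconds: float, frame_rate_hz: float) -> int:
    return int(round(seconds * frame_rate_hz))


def make_protocol(kind: str, frame_rate_hz: float = 16.0) -> StimulusProtocol:
    """Build the presentation schedule for one session of the given kind.

    Parameters
    ----------
    kind:
        ``"gray"`` (640 s blank), ``"gratings"`` (16 trials x 8 directions,
        2 s ON after 3 s OFF each) or ``"movies"`` (32 trials, 3 s OFF then
        7 consecutive 2 s clips).
    frame_rate_hz:
        Acquisition rate used to convert the printed second-scale protocol to
        frame indices.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    if kind == "gray":
        return StimulusProtocol(
            "gray", [], n_trials=1, n_conditions=0, frame_rate_hz=frame_rate_hz,
            total_frames=_frames(_GRAY_DURATION_S, frame_rate_hz),
        )
    pres: list[Presentation] = []
    t = 0
    if kind == "gratings":
        on = _frames(_GRATING_ON_S, frame_rate_hz)
        off = _frames(_GRATING_OFF_S, frame_rate_hz)
        for _ in range(_GRATING_TRIALS):
            for direction in range(_GRATING_DIRECTIONS):
                t += off
                pres.append(Presentation(direction, t, on))
                t += on
        return StimulusProtocol(
            "gratings", pres, _GRATING_TRIALS, _GRATING_DIRECTIONS, frame_rate_hz, t
        )
    if kind == "movies":
        clip = _frames(_MOVIE_CLIP_S, frame_rate_hz)
        off = _frames(_MOVIE_OFF_S, frame_rate_hz)
        for _ in range(_MOVIE_TRIALS):
            t += off
            for clip_id in range(_MOVIE_CLIPS):
                pres.append(Presentation(clip_id, t, clip))
                t += clip
        return StimulusProtocol("movies", pres, _MOVIE_TRIALS, _MOVIE_CLIPS, frame_rate_hz, t)
    raise ValueError(f"unknown protocol kind {kind!r}; expected gray, gratings or movies")
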