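"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Behavior", "PopulationRecording"]


@dataclass
class Behavior:
    """Behavioral covariates sampled at the imaging frame rate.

    running:  running speed (cm/s), one value per frame.
    pupil:    pupil diameter (arbitrary units), one value per frame.
    """

    running: np.ndarray
    pupil: np.ndarray

    def __post_init__(self) -> None:
        self.running = np.asarray(self.running, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.running.shape != self.pupil.shape or self.running.ndim != 1:
            raise ValueError("running and pupil must be 1-D arrays of equal length")

    @property
    def n_frames(self) -> int:
        return self.running.size


@dataclass
class PopulationRecording:
    """Raw two-photon fluorescence of one imaged population.

    F_raw, F_neuropil:
        neurons x frames fluorescence matrices; the neuropil trace is the
        contaminating surround signal matched to each ROI.
    frame_rate_hz:
        acquisition rate.
    behavior:
        simultaneously recorded running/pupil series, one sample per frame.
    """

    F_raw: np.ndarray
    F_neuropil: np.ndarray
    frame_rate_hz: float
    behavior: Behavior | None = None

    def __post_init__(self) -> None:
        self.F_raw = np.asarray(self.F_raw, dtype=float)
        self.F_neuropil = np.asarray(self.F_neuropil, dtype=float)
        if self.F_raw.shape != self.F_neuropil.shape:
            raise ValueError("F_raw and F_neuropil must have identical shapes")
        if self.F_raw.ndim != 2:
            raise ValueError("fluorescence matrices must be neurons x frames")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.behavior is not None and self.behavior.n_frames != self.n_frames:
            raise ValueError("behavior length must equal the number of frames")

    @property
    def n_neurons(self) -> int:
        return self.F_raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F_raw.shape[1]
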