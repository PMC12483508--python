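"""HDF5 + CSV + JSON persistence of synthetic sessions and derived traces.

Layout of the HDF5 container:

* ``F_raw``, ``F_neuropil``           — neurons x frames fluorescence
* ``behavior/running``, ``behavior/pupil``
* ``truth/*``                         — ground-truth arrays (synthetic sessions)
* ``dff``, ``events``                 — written back by preprocessing
* root attribute ``frame_rate_hz``

The protocol travels as a CSV table (label, onset_frame, duration_frames)
and the simulation config as JSON.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Behavior, PopulationRecording
from .preprocessing import DffTraces, EventTraces
from .protocols import Presentation, StimulusProtocol
from .synthetic import GroundTruth, SimulationConfig, SyntheticSession

__all__ = [
    "save_session",
    "load_recording",
    "load_session",
    "write_traces",
    "read_traces",
    "protocol_to_csv",
    "protocol_from_csv",
]

_TRUTH_FIELDS = (
    "preferred_direction", "tuning_gain", "behavior_weights",
    "is_tuned", "is_behavior_coupled", "latent_loadings",
)


def save_session(session: SyntheticSession, path: str | Path) -> None:
    """Write a synthetic session container (HDF5 + sidecar protocol CSV/config JSON)."""
    path = Path(path)
    rec = session.recording
    with h5py.File(path, "w") as fh:
        fh.attrs["frame_rate_hz"] = rec.frame_rate_hz
        fh.attrs["kind"] = session.protocol.kind
        fh.attrs["n_trials"] = session.protocol.n_trials
        fh.attrs["n_conditions"] = session.protocol.n_conditions
        fh.create_dataset("F_raw", data=rec.F_raw)
        fh.create_dataset("F_neuropil", data=rec.F_neuropil)
        if rec.behavior is not None:
            fh.create_dataset("behavior/running", data=rec.behavior.running)
            fh.create_dataset("behavior/pupil", data=rec.behavior.pupil)
        grp = fh.create_group("truth")
        for name in _TRUTH_FIELDS:
            grp.create_dataset(name, data=getattr(session.truth, name))
    protocol_to_csv(session.protocol, path.with_suffix(".protocol.csv"))
    session.config.to_json(path.with_suffix(".config.json"))


def load_recording(path: str | Path) -> PopulationRecording:
    with h5py.File(path, "r") as fh:
        behavior = None
        if "behavior" in fh:
            behavior = Behavior(fh["behavior/running"][:], fh["behavior/pupil"][:])
        return PopulationRecording(
            fh["F_raw"][:], fh["F_neuropil"][:], float(fh.attrs["frame_rate_hz"]),
            behavior,
        )


def load_session(path: str | Path) -> SyntheticSession:
    path = Path(path)
    rec = load_recording(path)
    with h5py.File(path, "r") as fh:
        truth = GroundTruth(
            **{name: fh["truth"][name][:].astype(
                bool if name.startswith("is_") else float)
               for name in _TRUTH_FIELDS}
        )
        kind = str(fh.attrs["kind"])
        n_trials = int(fh.attrs["n_trials"])
        n_conditions = int(fh.attrs["n_conditions"])
    protocol = protocol_from_csv(
        path.with_suffix(".protocol.csv"), kind, n_trials, n_conditions,
        rec.frame_rate_hz, rec.n_frames,
    )
    config = SimulationConfig.from_json(path.with_suffix(".config.json"))
    return SyntheticSession(rec, protocol, truth, config)


def write_traces(path: str | Path, dff: DffTraces, events: EventTraces | None = None) -> None:
    """Write derived dF/F (and optionally events) back into the container."""
    with h5py.File(path, "a") as fh:
        for name in ("dff", "f0", "events"):
            if name in fh:
                del fh[name]
        fh.create_dataset("dff", data=dff.dff)
        fh.create_dataset("f0", data=dff.f0)
        if events is not None:
            ds = fh.create_dataset("events", data=events.events)
            ds.attrs["tau_s"] = events.tau_s


def read_traces(path: str | Path) -> tuple[DffTraces, EventTraces | None]:
    with h5py.File(path, "r") as fh:
        fr = float(fh.attrs["frame_rate_hz"])
        dff = DffTraces(
            fh["dff"][:], fh["f0"][:], fr, valid=np.isfinite(fh["dff"][:, 0])
        )
        events = None
        if "events" in fh:
            events = EventTraces(fh["events"][:], float(fh["events"].attrs["tau_s"]), fr)
    return dff, events


def protocol_to_csv(protocol: StimulusProtocol, path: str | Path) -> None:
    protocol.to_csv(path)


def protocol_from_csv(
    path: str | Path, kind: str, n_trials: int, n_conditions: int,
    frame_rate_hz: float, total_frames: int,
) -> StimulusProtocol:
    df = pd.read_csv(path)
    pres = [
        Presentation(int(r.label), int(r.onset_frame), int(r.duration_frames))
        for r in df.itertuples()
    ]
    return StimulusProtocol(kind, pres, n_trials, n_conditions, frame_rate_hz, total_frames)
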