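"""Single-neuron and pairwise response statistics.

Everything here operates on a :class:`TrialTensor` — evoked responses cut
into neuron x condition x trial — built from either dF/F or deconvolved
events.  The statistics are the standard visual-physiology set: visual
responsiveness, direction tuning curves, orientation selectivity (OSI),
maximum response, trial-to-trial reliability, and spontaneous / signal /
noise pairwise correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .protocols import StimulusProtocol

__all__ = [
    "TrialTensor",
    "TuningResult",
    "CorrelationSet",
    "build_trial_tensor",
    "blank_responses",
    "classify_visually_responsive",
    "compute_tuning",
    "compute_osi",
    "reliability_index",
    "neuron_reliability",
    "pairwise_correlation",
    "signal_correlation",
    "noise_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class TrialTensor:
    """Evoked responses arranged neuron x condition x trial.

    ``values`` holds the window-mean response per presentation; if the tensor
    was built with ``keep_time`` the per-frame time courses are retained in
    ``timecourses`` (neuron x condition x trial x frame) for reliability
    analysis.
    """

    values: np.ndarray
    window_s: float
    source: str
    frame_rate_hz: float
    timecourses: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]


@dataclass
class TuningResult:
    """Per-neuron direction tuning summary (arrays over neurons).

    ``tuning_curve`` rows are trial-mean responses per direction;
    ``centered_curve`` is the same curve rolled so the preferred direction
    sits at index 0 (for population averaging).  ``osi_defined`` is False
    where the OSI denominator vanished and the index was set to 0.
    """

    tuning_curve: np.ndarray
    tuning_sem: np.ndarray
    preferred_direction: np.ndarray
    preferred_orientation: np.ndarray
    osi: np.ndarray
    max_response: np.ndarray
    centered_curve: np.ndarray
    osi_defined: np.ndarray


@dataclass
class CorrelationSet:
    """Upper-triangle pairwise correlations with their neuron-index pairs."""

    values: np.ndarray
    pairs: np.ndarray  # n_pairs x 2 neuron indices
    kind: str  # spontaneous | signal | noise

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    def to_frame(self):
        """Long-format pair table (i, j, kind, r); NaN rows are excluded pairs."""
        import pandas as pd

        return pd.DataFrame(
            {"i": self.pairs[:, 0], "j": self.pairs[:, 1],
             "kind": self.kind, "r": self.values}
        )


def build_trial_tensor(
    traces: np.ndarray,
    protocol: StimulusProtocol,
    window_s: float,
    source: str = "dff",
    keep_time: bool = False,
) -> TrialTensor:
    """Cut traces into per-presentation responses.

    For every presentation the response is the mean trace value over
    ``window_s`` seconds from onset (truncated to the presentation duration
    with a warning if longer); presentations of each condition are stacked in
    session order along the trial axis.
    """
    traces = np.asarray(traces, dtype=float)
    C = protocol.n_conditions
    if C == 0:
        raise ValueError("protocol has no labeled conditions")
    counts = np.bincount([p.label for p in protocol.presentations], minlength=C)
    if np.any(counts == 0):
        raise ValueError("every condition must appear at least once")
    if counts.min() != counts.max():
        raise ValueError("unequal trial counts across conditions")
    R = int(counts[0])
    W = int(round(window_s * protocol.frame_rate_hz))
    dur = min(p.duration_frames for p in protocol.presentations)
    if W > dur:
        logger.warning(
            "window %.3gs (%d frames) exceeds presentation duration %d; truncated",
            window_s, W, dur,
        )
        W = dur
    n = traces.shape[0]
    values = np.empty((n, C, R))
    tcs = np.empty((n, C, R, W)) if keep_time else None
    trial_idx = np.zeros(C, dtype=int)
    for p in protocol.presentations:
        r = trial_idx[p.label]
        seg = traces[:, p.onset_frame : p.onset_frame + W]
        values[:, p.label, r] = seg.mean(axis=1)
        if tcs is not None:
            tcs[:, p.label, r] = seg
        trial_idx[p.label] += 1
    return TrialTensor(values, window_s, source, protocol.frame_rate_hz, tcs)


def blank_responses(
    traces: np.ndarray, protocol: StimulusProtocol, window_s: float
) -> np.ndarray:
    """Mean trace value in the OFF window immediately preceding each onset.

    Returns neurons x presentations; the window length matches the evoked
    analysis window so blank and evoked responses are directly comparable.
    """
    traces = np.asarray(traces, dtype=float)
    W = int(round(window_s * protocol.frame_rate_hz))
    out = np.empty((traces.shape[0], len(protocol.presentations)))
    for k, p in enumerate(protocol.presentations):
        lo = max(p.onset_frame - W, 0)
        out[:, k] = traces[:, lo : p.onset_frame].mean(axis=1)
    return out


def classify_visually_responsive(
    tensor: TrialTensor, blanks: np.ndarray, alpha: float = 0.01
) -> np.ndarray:
    """Flag neurons whose responses discriminate stimulus conditions.

    A neuron is visually responsive iff a one-way ANOVA across the stimulus
    conditions plus the blank group rejects at ``alpha`` AND the best
    condition's mean exceeds the blank mean (so pure suppression or blank-only
    structure does not qualify).
    """
    if tensor.n_trials < 2:
        raise ValueError("need at least 2 trials per condition")
    n = tensor.n_neurons
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        groups = [tensor.values[i, c] for c in range(tensor.n_conditions)]
        groups.append(blanks[i])
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            continue  # identical everywhere: not responsive
        _, p = stats.f_oneway(*groups)
        peak = tensor.values[i].mean(axis=1).max()
        flags[i] = bool(np.isfinite(p) and p < alpha and peak > blanks[i].mean())
    return flags


def compute_osi(tuning_curve: np.ndarray) -> tuple[float, bool]:
    """Orientation selectivity index of one 8-direction tuning curve.

    Opposite directions are averaged into 4 orientations (after flooring the
    curve at 0); OSI = (R_pref - R_orth) / (R_pref + R_orth), where R_orth is
    the orientation 90 deg from preferred, clipped to [0, 1].  Returns
    (osi, defined); a vanishing denominator yields (0.0, False).
    """
    curve = np.clip(np.asarray(tuning_curve, dtype=float), 0.0, None)
    if curve.size != 8:
        raise ValueError("expected an 8-direction tuning curve")
    orient = 0.5 * (curve[:4] + curve[4:])
    pref = int(np.argmax(orient))
    r_pref = orient[pref]
    r_orth = orient[(pref + 2) % 4]
    denom = r_pref + r_orth
    if denom == 0:
        return 0.0, False
    return float(np.clip((r_pref - r_orth) / denom, 0.0, 1.0)), True


def compute_tuning(tensor: TrialTensor, baseline: np.ndarray | None = None) -> TuningResult:
    """Direction tuning curve, preferred direction, OSI and max response.

    Preference is the argmax of the trial-mean curve (ties broken toward the
    lowest condition index); the curve is also returned re-centered on the
    preferred direction for population averaging.  If a per-neuron
    ``baseline`` (e.g. mean blank-period response) is given it is subtracted
    from the curve first, so the statistics describe the evoked response:
    without it, an additive offset shared by all directions dilutes the OSI
    and breaks its invariance to evoked-gain scaling.
    """
    if tensor.n_conditions != 8:
        raise ValueError("tuning analysis expects 8 directions")
    mean = tensor.values.mean(axis=2)
    if baseline is not None:
        mean = mean - np.asarray(baseline, dtype=float)[:, None]
    sem = tensor.values.std(axis=2, ddof=1) / np.sqrt(tensor.n_trials)
    pref = mean.argmax(axis=1)
    max_resp = mean[np.arange(tensor.n_neurons), pref]
    osi = np.empty(tensor.n_neurons)
    defined = np.empty(tensor.n_neurons, dtype=bool)
    centered = np.empty_like(mean)
    for i in range(tensor.n_neurons):
        osi[i], defined[i] = compute_osi(mean[i])
        centered[i] = np.roll(mean[i], -pref[i])
    return TuningResult(
        tuning_curve=mean,
        tuning_sem=sem,
        preferred_direction=pref,
        preferred_orientation=pref % 4,
        osi=osi,
        max_response=max_resp,
        centered_curve=centered,
        osi_defined=defined,
    )


def reliability_index(trial_timecourses: np.ndarray) -> float:
    """Mean Pearson correlation over all trial pairs of one neuron/stimulus.

    ``trial_timecourses`` is trials x frames.  Pairs involving a
    zero-variance trial have no defined correlation and are skipped (logged);
    if no pair is defined the index is NaN.
    """
    x = np.asarray(trial_timecourses, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 trials and >= 2 frames")
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore"):
        cc = np.corrcoef(x)
    vals, skipped = [], 0
    for a, b in combinations(range(x.shape[0]), 2):
        if sd[a] == 0 or sd[b] == 0:
            skipped += 1
            continue
        vals.append(cc[a, b])
    if skipped:
        logger.info("reliability: skipped %d undefined trial pairs", skipped)
    return float(np.mean(vals)) if vals else float("nan")


def neuron_reliability(tensor: TrialTensor) -> np.ndarray:
    """Per-neuron reliability at the preferred stimulus.

    The preferred stimulus is the condition with the highest trial-mean
    response (lowest index on ties); the value is the mean pairwise trial
    correlation of that condition's time courses.
    """
    if tensor.timecourses is None:
        raise ValueError("tensor must be built with keep_time=True")
    mean = tensor.values.mean(axis=2)
    pref = mean.argmax(axis=1)
    return np.array(
        [reliability_index(tensor.timecourses[i, pref[i]]) for i in range(tensor.n_neurons)]
    )


def neuron_metrics_frame(
    responsive: np.ndarray,
    tuning: TuningResult,
    reliability: np.ndarray | None = None,
    firing_rate: np.ndarray | None = None,
):
    """Per-neuron metrics table (one row per neuron), ready for CSV export
    or for stacking into the group-comparison table."""
    import pandas as pd

    n = tuning.osi.size
    data = {
        "neuron_id": np.arange(n),
        "responsive": np.asarray(responsive, dtype=bool),
        "preferred_direction": tuning.preferred_direction,
        "osi": tuning.osi,
        "max_response": tuning.max_response,
    }
    if reliability is not None:
        data["reliability"] = reliability
    if firing_rate is not None:
        data["firing_rate"] = firing_rate
    return pd.DataFrame(data)


def _upper_triangle(mat: np.ndarray, keep: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.flatnonzero(keep)
    pairs = np.array(list(combinations(idx, 2)), dtype=np.int64).reshape(-1, 2)
    vals = np.array([mat[a, b] for a, b in pairs])
    return vals, pairs


def pairwise_correlation(
    activity: np.ndarray, protocol: StimulusProtocol | None = None,
    kind: str = "spontaneous",
) -> CorrelationSet:
    """Pearson correlation between neurons' concatenated activity vectors.

    If a labeled protocol is given, only stimulus-ON frames (all trials
    concatenated in session order) enter the vectors; otherwise the full
    trace is used (spontaneous sessions).  Constant neurons are excluded and
    logged.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    if protocol is not None and protocol.presentations:
        on = protocol.frame_labels() >= 0
        activity = activity[:, on]
    keep = activity.std(axis=1) > 0
    if not keep.all():
        logger.warning("excluded %d constant neurons from correlations", (~keep).sum())
    cc = np.corrcoef(activity[keep])
    full = np.full((activity.shape[0],) * 2, np.nan)
    full[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))] = cc
    vals, pairs = _upper_triangle(full, keep)
    return CorrelationSet(vals, pairs, kind)


def signal_correlation(tensor: TrialTensor) -> CorrelationSet:
    """Tuning similarity: Pearson between trial-averaged condition responses."""
    if tensor.n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    mean = tensor.values.mean(axis=2)
    keep = mean.std(axis=1) > 0
    if not keep.all():
        logger.warning("excluded %d flat-tuning neurons from signal correlation",
                       (~keep).sum())
    full = np.full((tensor.n_neurons,) * 2, np.nan)
    cc = np.corrcoef(mean[keep])
    full[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))] = cc
    vals, pairs = _upper_triangle(full, keep)
    return CorrelationSet(vals, pairs, "signal")


def noise_correlation(tensor: TrialTensor) -> CorrelationSet:
    """Shared trial-to-trial variability after removing condition means.

    Each neuron's trial responses are z-scored within condition (mean 0,
    sd 1 across trials), concatenated across conditions, and correlated
    between neurons.  Conditions where either neuron of a pair has zero
    trial variance are dropped for that pair (logged).
    """
    if tensor.n_trials < 2:
        raise ValueError("need at least 2 trials per condition")
    v = tensor.values
    sd = v.std(axis=2, ddof=1)
    with np.errstate(invalid="ignore"):
        z = (v - v.mean(axis=2, keepdims=True)) / sd[:, :, None]
    n = tensor.n_neurons
    degenerate = sd == 0
    pairs = np.array(list(combinations(range(n), 2)), dtype=np.int64).reshape(-1, 2)
    if not degenerate.any():
        flat = z.reshape(n, -1)
        cc = np.corrcoef(flat)
        vals = np.array([cc[a, b] for a, b in pairs])
        return CorrelationSet(vals, pairs, "noise")
    n_dropped = 0
    vals = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        ok = ~(degenerate[a] | degenerate[b])
        n_dropped += int((~ok).sum())
        if ok.sum() < 1 or ok.sum() * tensor.n_trials < 3:
            vals[k] = np.nan
            continue
        za, zb = z[a, ok].ravel(), z[b, ok].ravel()
        vals[k] = np.corrcoef(za, zb)[0, 1]
    if n_dropped:
        logger.info("noise correlation: dropped %d degenerate pair-conditions", n_dropped)
    return CorrelationSet(vals, pairs, "noise")
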