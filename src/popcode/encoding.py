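"""Lasso GLM encoding models of single-neuron activity.

Two models, both linear (identity link) with an L1 penalty:

1. Stimulus/behavior encoding — r_n(t) is a linear sum of 0/1 stimulus-onset
   lag indicators (one column per direction x frame lag over a [0, 2] s
   window) plus z-scored pupil and running regressors.  Performance is
   held-out explained variance (R^2) under 10-fold cross-validation on
   contiguous temporal blocks; each predictor group's contribution is tested
   by refitting with that group's columns zeroed (partial model) and
   comparing fold-wise R^2 with a paired t-test under Holm correction.

2. Population-activity encoding — the target neuron's trace regressed on k
   randomly sampled other neurons' traces; reported with the signed maximum
   predictor weight binned at 0.05 / 0.1.

The lasso objective is (1/2n)||y - X b - e||^2 + lambda ||b||_1 with
lambda = 1e-3 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.metrics import r2_score
from statsmodels.stats.multitest import multipletests

from .containers import Behavior
from .protocols import StimulusProtocol

__all__ = [
    "DesignMatrix",
    "EncodingResult",
    "PopulationEncodingResult",
    "build_design_matrix",
    "contiguous_folds",
    "fit_lasso_glm",
    "partial_model_test",
    "encoder_proportions",
    "population_glm",
]

PREDICTOR_GROUPS = ("stimulus", "pupil", "running")


@dataclass
class DesignMatrix:
    """Frames x predictors design with column-group bookkeeping.

    ``groups`` maps each column to ``direction_<c>``, ``pupil`` or
    ``running``; the umbrella name ``stimulus`` resolves to all direction
    columns.
    """

    X: np.ndarray
    groups: list[str]
    window_s: tuple[float, float]
    frame_rate_hz: float

    def group_columns(self, name: str) -> np.ndarray:
        if name == "stimulus":
            return np.array(
                [i for i, g in enumerate(self.groups) if g.startswith("direction_")],
                dtype=np.int64,
            )
        return np.array(
            [i for i, g in enumerate(self.groups) if g == name], dtype=np.int64
        )


@dataclass
class EncodingResult:
    """Cross-validated encoding model of one neuron."""

    weights: np.ndarray
    intercept: float
    r2_full: float
    r2_folds: np.ndarray
    lam: float
    degenerate: bool = False
    r2_partial: dict = field(default_factory=dict)
    significant: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)


@dataclass
class PopulationEncodingResult:
    """Population-activity GLM summary for one target neuron and size k."""

    target: int
    population_size: int
    r2: float
    max_weight: float
    weight_bin: str
    predictor_ids: np.ndarray
    n_samples: int


def build_design_matrix(
    protocol: StimulusProtocol,
    behavior: Behavior,
    window_s: tuple[float, float] = (0.0, 2.0),
) -> DesignMatrix:
    """Stimulus-lag indicators plus z-scored behavioral regressors.

    For each direction c and each frame lag in the window, the column is 1 at
    frames (onset + lag) over all presentations of c.  Overlapping lag
    windows (not possible in the standard protocols) would sum.  A constant
    behavior series cannot be z-scored; its column is dropped with a warning.
    """
    import logging

    if behavior.n_frames != protocol.total_frames:
        raise ValueError("behavior length must match protocol span")
    fr = protocol.frame_rate_hz
    lag0 = int(round(window_s[0] * fr))
    n_lags = int(round((window_s[1] - window_s[0]) * fr))
    T = protocol.total_frames
    C = protocol.n_conditions
    X = np.zeros((T, C * n_lags + 2))
    groups: list[str] = []
    for c in range(C):
        for lag in range(n_lags):
            groups.append(f"direction_{c}")
    for p in protocol.presentations:
        base = p.label * n_lags
        for lag in range(n_lags):
            t = p.onset_frame + lag0 + lag
            if t < T:
                X[t, base + lag] += 1.0
    col = C * n_lags
    for name, series in (("pupil", behavior.pupil), ("running", behavior.running)):
        sd = series.std()
        if sd == 0:
            logging.getLogger(__name__).warning(
                "constant %s series: behavior column dropped", name
            )
            continue
        X[:, col] = (series - series.mean()) / sd
        groups.append(name)
        col += 1
    return DesignMatrix(X[:, :col], groups, window_s, fr)


def contiguous_folds(n_frames: int, n_folds: int = 10) -> list[np.ndarray]:
    """Contiguous temporal blocks, so held-out frames are not interleaved
    with (autocorrelated) training frames."""
    return [np.asarray(f) for f in np.array_split(np.arange(n_frames), n_folds)]


class _LassoCV:
    """Per-fold centered copies of the design, reusable across many targets.

    Centering X and y on the training block and fitting without an intercept
    is exactly the intercept-bearing lasso; caching the centered training
    blocks makes refitting many targets (and column-zeroed partial models) on
    the same design cheap.
    """

    def __init__(self, X: np.ndarray, folds: list[np.ndarray], lam: float):
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        self.X = X
        self.folds = folds
        self.lam = lam
        T = X.shape[0]
        self._prep = []
        for test_idx in folds:
            mask = np.ones(T, dtype=bool)
            mask[test_idx] = False
            Xtr = X[mask]
            mu = Xtr.mean(axis=0)
            Xc = np.ascontiguousarray(Xtr - mu)
            self._prep.append(dict(mask=mask, test=test_idx, mu=mu, Xc=Xc))

    def fold_r2(self, y: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
        """Held-out R^2 per fold, optionally restricted to a column subset."""
        r2 = np.empty(len(self._prep))
        for k, prep in enumerate(self._prep):
            ytr = y[prep["mask"]]
            my = ytr.mean()
            Xc = prep["Xc"] if cols is None else prep["Xc"][:, cols]
            if self.lam == 0:
                model = LinearRegression(fit_intercept=False)
                model.fit(Xc, ytr - my)
            else:
                model = Lasso(alpha=self.lam, fit_intercept=False, max_iter=5000)
                model.fit(Xc, ytr - my)
            Xte = self.X[prep["test"]]
            Xte = Xte if cols is None else Xte[:, cols]
            mu = prep["mu"] if cols is None else prep["mu"][cols]
            pred = (Xte - mu) @ model.coef_ + my
            r2[k] = r2_score(y[prep["test"]], pred)
        return r2


def _full_fit(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    mu, my = X.mean(axis=0), y.mean()
    if lam == 0:
        model = LinearRegression(fit_intercept=False).fit(X - mu, y - my)
    else:
        model = Lasso(alpha=lam, fit_intercept=False, max_iter=5000).fit(X - mu, y - my)
    return model.coef_, float(my - mu @ model.coef_)


def fit_lasso_glm(
    design: DesignMatrix | np.ndarray,
    y: np.ndarray,
    lam: float = 1e-3,
    n_folds: int = 10,
    _cv: "_LassoCV | None" = None,
) -> EncodingResult:
    """Cross-validated lasso encoding model of one neuron's trace.

    r2_full is the mean held-out R^2 over contiguous-block folds; reported
    weights come from a fit on the full session.  A constant trace cannot be
    scored (R^2 set to 0, flagged degenerate).
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    weights, intercept = _full_fit(X, y, lam)
    if y.std() == 0:
        return EncodingResult(weights, intercept, 0.0, np.zeros(n_folds), lam,
                              degenerate=True)
    cv = _cv if _cv is not None else _LassoCV(X, contiguous_folds(len(y), n_folds), lam)
    r2_folds = cv.fold_r2(y)
    return EncodingResult(weights, intercept, float(r2_folds.mean()), r2_folds, lam)


def partial_model_test(
    design: DesignMatrix,
    y: np.ndarray,
    result: EncodingResult,
    alpha: float = 0.05,
    groups: tuple[str, ...] = PREDICTOR_GROUPS,
    _cv: "_LassoCV | None" = None,
) -> EncodingResult:
    """Test each predictor group by full-vs-partial fold-wise R^2 comparison.

    The partial model refits with the group's columns zeroed (removed);
    fold-wise R^2 of full and partial models are compared with a two-sided
    paired t-test across folds, Holm-corrected over the groups.  A group is
    significant iff corrected p < alpha and the full model explains more
    variance on average.  Results are written back onto ``result``.
    """
    if len(result.r2_folds) < 3:
        raise ValueError("need at least 3 folds for the paired test")
    y = np.asarray(y, dtype=float)
    cv = _cv if _cv is not None else _LassoCV(
        design.X, contiguous_folds(len(y), len(result.r2_folds)), result.lam
    )
    groups = tuple(g for g in groups if design.group_columns(g).size)
    raw_p = []
    for g in groups:
        drop = design.group_columns(g)
        keep = np.setdiff1d(np.arange(design.X.shape[1]), drop)
        r2_partial = cv.fold_r2(y, cols=keep)
        result.r2_partial[g] = r2_partial
        diff = result.r2_folds - r2_partial
        if np.allclose(diff, 0):
            raw_p.append(1.0)
        else:
            raw_p.append(float(stats.ttest_rel(result.r2_folds, r2_partial).pvalue))
    rejected, p_corr, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
    for g, rej, p in zip(groups, rejected, p_corr):
        better = result.r2_folds.mean() > result.r2_partial[g].mean()
        result.p_values[g] = float(p)
        result.significant[g] = bool(rej and better)
    return result


def fit_session_encoders(
    design: DesignMatrix,
    traces: np.ndarray,
    lam: float = 1e-3,
    n_folds: int = 10,
    alpha: float = 0.05,
    groups: tuple[str, ...] = PREDICTOR_GROUPS,
) -> list[EncodingResult]:
    """Fit and partial-test the encoding model for every row of ``traces``.

    The per-fold centered design blocks are built once and shared across
    neurons, which makes whole-session encoding runs roughly an order of
    magnitude cheaper than fitting each neuron in isolation.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    cv = _LassoCV(design.X, contiguous_folds(traces.shape[1], n_folds), lam)
    results = []
    for y in traces:
        res = fit_lasso_glm(design, y, lam=lam, n_folds=n_folds, _cv=cv)
        if not res.degenerate:
            res = partial_model_test(design, y, res, alpha=alpha, groups=groups, _cv=cv)
        results.append(res)
    return results


def encoder_proportions(results: list[EncodingResult]) -> dict[str, float]:
    """Fraction of neurons significantly encoding each predictor group."""
    if not results:
        raise ValueError("need at least one neuron")
    groups = sorted({g for r in results for g in r.significant})
    return {
        g: float(np.mean([bool(r.significant.get(g)) for r in results])) for g in groups
    }


def _bin_weight(w: float) -> str:
    if w < 0.05:
        return "below 0.05"
    if w <= 0.1:
        return "0.05-0.1"
    return "above 0.1"


def population_glm(
    traces: np.ndarray,
    target: int,
    k: int,
    seed: int = 0,
    lam: float = 1e-3,
    n_folds: int = 10,
    n_samples: int = 10,
) -> PopulationEncodingResult:
    """Predict one neuron's trace from k randomly sampled other neurons.

    Predictor traces are z-scored on the training block only (statistics
    reused on the test block); held-out R^2 uses the same contiguous 10-fold
    scheme as the stimulus model.  ``n_samples`` random predictor draws are
    averaged; ``max_weight`` is the signed maximum lasso weight from a
    full-session fit, binned at 0.05 / 0.1.
    """
    traces = np.asarray(traces, dtype=float)
    n, T = traces.shape
    if k >= n:
        raise ValueError(f"population size {k} must be below n_neurons={n}")
    rng = np.random.default_rng(seed)
    others = np.setdiff1d(np.arange(n), [target])
    y = traces[target]
    folds = contiguous_folds(T, n_folds)
    r2s, maxw = [], []
    last_ids = None
    for _ in range(n_samples):
        ids = rng.choice(others, size=k, replace=False)
        last_ids = ids
        Xp = traces[ids].T
        r2_folds = np.empty(len(folds))
        for f, test_idx in enumerate(folds):
            mask = np.ones(T, dtype=bool)
            mask[test_idx] = False
            mu, sd = Xp[mask].mean(axis=0), Xp[mask].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xp[mask] - mu) / sd
            ytr = y[mask]
            my = ytr.mean()
            model = Lasso(alpha=lam, fit_intercept=False, max_iter=5000)
            model.fit(Xtr, ytr - my)
            pred = ((Xp[test_idx] - mu) / sd) @ model.coef_ + my
            r2_folds[f] = r2_score(y[test_idx], pred)
        r2s.append(r2_folds.mean())
        mu, sd = Xp.mean(axis=0), Xp.std(axis=0)
        sd[sd == 0] = 1.0
        full = Lasso(alpha=lam, fit_intercept=False, max_iter=5000)
        full.fit((Xp - mu) / sd, y - y.mean())
        maxw.append(full.coef_.max())
    mean_w = float(np.mean(maxw))
    return PopulationEncodingResult(
        target=target,
        population_size=k,
        r2=float(np.mean(r2s)),
        max_weight=mean_w,
        weight_bin=_bin_weight(mean_w),
        predictor_ids=last_ids,
        n_samples=n_samples,
    )
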