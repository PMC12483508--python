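"""Population decoding of stimulus identity from trial responses.

A linear support-vector classifier is trained on class-balanced trial
splits (33% held out), its regularization strength grid-searched over
10^-3..10^3 by inner cross-validated accuracy, and performance is summarized
as one-vs-rest macro-averaged AUROC of the held-out decision scores.  A
shuffle control re-runs the identical pipeline on permuted labels, and a
population-size sweep (5..25 neurons in steps of 5, random subsets per
iteration) yields the size-resolved decoding curves compared across groups
with a two-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .protocols import StimulusProtocol

__all__ = [
    "DecodingConfig",
    "DecodingResult",
    "build_feature_matrix",
    "balanced_split",
    "fit_decoder",
    "decode_auroc",
    "decode_once",
    "shuffle_control",
    "population_sweep",
    "compare_sweeps",
]

logger = logging.getLogger(__name__)


@dataclass
class DecodingConfig:
    """Decoding pipeline settings."""

    test_fraction: float = 0.33
    grid: np.ndarray = field(default_factory=lambda: np.logspace(-3, 3, 7))
    population_sizes: tuple[int, ...] = (5, 10, 15, 20, 25)
    n_iterations: int = 50
    window_s: float = 2.0
    seed: int = 0
    inner_cv: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if len(np.atleast_1d(self.grid)) == 0:
            raise ValueError("hyperparameter grid must be nonempty")


@dataclass
class DecodingResult:
    """AUROC per (population size, iteration) with matched shuffle nulls."""

    sizes: np.ndarray
    auroc: np.ndarray          # sizes x iterations
    auroc_shuffled: np.ndarray
    n_classes: int

    @property
    def mean_auroc(self) -> np.ndarray:
        return self.auroc.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sizes):
            for j in range(self.auroc.shape[1]):
                rows.append(
                    dict(size=int(s), iteration=j, auroc=self.auroc[i, j],
                         auroc_shuffled=self.auroc_shuffled[i, j])
                )
        return pd.DataFrame(rows)


def build_feature_matrix(
    dff: np.ndarray, protocol: StimulusProtocol, window_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """One row per presentation: per-neuron mean response over the window.

    The window runs [onset, onset + window_s); presentations whose window
    extends past the recording end are dropped with a warning.  Returns
    (trials x neurons features, labels).
    """
    dff = np.asarray(dff, dtype=float)
    W = int(round(window_s * protocol.frame_rate_hz))
    rows, labels = [], []
    dropped = 0
    for p in protocol.presentations:
        if p.onset_frame + W > dff.shape[1]:
            dropped += 1
            continue
        rows.append(dff[:, p.onset_frame : p.onset_frame + W].mean(axis=1))
        labels.append(p.label)
    if dropped:
        logger.warning("dropped %d presentations extending past recording end", dropped)
    return np.asarray(rows), np.asarray(labels, dtype=np.int64)


def balanced_split(
    labels: np.ndarray, test_fraction: float = 0.33, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced disjoint train/test trial indices.

    Per-class trial counts are first equalized by downsampling to the minimum
    count (first-k of a seeded permutation); within each class
    ceil(test_fraction * n) trials go to test and the rest to train, so class
    priors are identical on both sides.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        raise ValueError("every class needs at least 3 trials")
    n_min = int(counts.min())
    n_test = int(np.ceil(test_fraction * n_min))
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        kept = idx[rng.permutation(idx.size)[:n_min]]
        test.append(kept[:n_test])
        train.append(kept[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def fit_decoder(
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: np.ndarray | None = None,
    inner_cv: int = 3,
    seed: int = 0,
) -> tuple[Pipeline, float]:
    """Linear SVM with per-neuron train-statistics standardization.

    The regularization strength C is chosen by inner cross-validated accuracy
    over the grid (default 10^-3..10^3, log-spaced).  Returns the fitted
    pipeline and the chosen C.
    """
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    grid = np.logspace(-3, 3, 7) if grid is None else np.atleast_1d(grid)
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear"))]
    )
    if grid.size == 1:
        pipe.set_params(svm__C=float(grid[0]))
        pipe.fit(X_train, y_train)
        return pipe, float(grid[0])
    cv = StratifiedKFold(inner_cv, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, {"svm__C": grid}, cv=cv, scoring="accuracy")
    search.fit(X_train, y_train)
    return search.best_estimator_, float(search.best_params_["svm__C"])


def decode_auroc(clf, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """One-vs-rest macro-averaged AUROC of the decision scores.

    Each class's continuous decision score is scored against the binary
    class-membership labels; the per-class AUROCs are averaged.  Requires all
    classes present in the test set.
    """
    classes = np.unique(y_test)
    scores = clf.decision_function(X_test)
    if scores.ndim == 1:  # binary SVC: one margin column
        scores = np.column_stack([-scores, scores])
    clf_classes = clf.classes_ if hasattr(clf, "classes_") else clf[-1].classes_
    if not np.all(np.isin(classes, clf_classes)):
        raise ValueError("test set contains classes unseen in training")
    per_class = []
    for c in classes:
        col = int(np.flatnonzero(clf_classes == c)[0])
        per_class.append(roc_auc_score((y_test == c).astype(int), scores[:, col]))
    return float(np.mean(per_class))


def decode_once(
    features: np.ndarray,
    labels: np.ndarray,
    config: DecodingConfig,
    seed: int,
) -> tuple[float, float]:
    """Run one balanced split -> grid-searched SVM -> AUROC. Returns
    (auroc, chosen_C)."""
    train, test = balanced_split(labels, config.test_fraction, seed)
    clf, c = fit_decoder(
        features[train], labels[train], config.grid, config.inner_cv, seed
    )
    return decode_auroc(clf, features[test], labels[test]), c


def shuffle_control(
    features: np.ndarray,
    labels: np.ndarray,
    config: DecodingConfig,
    seed: int,
) -> float:
    """Chance-level AUROC: permute the labels, then rerun the full pipeline."""
    rng = np.random.default_rng(seed)
    shuffled = np.asarray(labels)[rng.permutation(len(labels))]
    auroc, _ = decode_once(features, shuffled, config, seed)
    return auroc


def population_sweep(
    dff: np.ndarray,
    protocol: StimulusProtocol,
    config: DecodingConfig | None = None,
) -> DecodingResult:
    """Decoding accuracy as a function of population size.

    For each size, ``n_iterations`` random neuron subsets are decoded through
    the full balanced pipeline, each paired with a shuffle-null run on the
    same subset.  Sizes exceeding the available population are skipped with a
    warning.
    """
    config = config or DecodingConfig()
    features, labels = build_feature_matrix(dff, protocol, config.window_s)
    n_neurons = features.shape[1]
    sizes = [s for s in config.population_sizes if s <= n_neurons]
    for s in config.population_sizes:
        if s > n_neurons:
            logger.warning("population size %d > %d neurons: skipped", s, n_neurons)
    rng = np.random.default_rng(config.seed)
    auroc = np.empty((len(sizes), config.n_iterations))
    null = np.empty_like(auroc)
    for i, size in enumerate(sizes):
        for j in range(config.n_iterations):
            subset = rng.choice(n_neurons, size=size, replace=False)
            it_seed = int(rng.integers(2**31))
            auroc[i, j], _ = decode_once(features[:, subset], labels, config, it_seed)
            null[i, j] = shuffle_control(
                features[:, subset], labels, config, it_seed + 1
            )
    return DecodingResult(np.asarray(sizes), auroc, null, protocol.n_conditions)


def compare_sweeps(group_a: pd.DataFrame, group_b: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of AUROC on group x population size.

    Inputs are long tables with columns ``session``, ``size``, ``auroc`` (one
    row per session x size, e.g. session-mean AUROC).  Returns the ANOVA
    table with F and p for both main effects and the interaction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for name, df in (("A", group_a), ("B", group_b)):
        missing = {"session", "size", "auroc"} - set(df.columns)
        if missing:
            raise ValueError(f"group {name} table missing columns {missing}")
        if df.groupby("size")["session"].nunique().min() < 2:
            raise ValueError(f"group {name} needs >= 2 sessions per population size")
    data = pd.concat(
        [group_a.assign(group="A"), group_b.assign(group="B")], ignore_index=True
    )
    model = smf.ols("auroc ~ C(group) * C(size)", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)
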