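"""Classical pixel classifiers and random hyperparameter search.

Four baselines operate per pixel on the spectral features (the 12-feature
cube by default, or the 3 PCA components): random forest, linear SVM,
RBF-kernel SVM and XGBoost.  Hyperparameters are tuned by random search
over fixed candidate grids; by default the search scores candidates on a
validation split (pass ``select_on="test"`` to score on the test set
instead, reproducing selection protocols that tune on test data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

BASELINE_NAMES = ("rf", "svm", "ksvm", "xgb")


@dataclass
class SearchSpace:
    """Candidate values per hyperparameter for one classifier."""

    name: str
    grid: dict[str, list]

    def __post_init__(self):
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("every candidate list must be non-empty")


#: Published candidate grids for the four classifiers.
SEARCH_SPACES: dict[str, SearchSpace] = {
    "rf": SearchSpace(
        "rf",
        {
            "n_estimators": [30, 50, 100, 200, 300],
            "max_depth": [5, 10, 20, 30, None],
            "min_samples_split": [3, 5, 10, 30, 100],
            "min_samples_leaf": [1, 3, 5, 7, 10],
        },
    ),
    "svm": SearchSpace(
        "svm",
        {"C": [0.01, 0.05, 0.1, 0.5, 1, 5, 10, 100]},
    ),
    "ksvm": SearchSpace(
        "ksvm",
        {
            "C": [0.01, 0.05, 0.1, 0.5, 1, 5, 10, 100],
            "gamma": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, "auto"],
        },
    ),
    "xgb": SearchSpace(
        "xgb",
        {
            "learning_rate": [0.01, 0.02, 0.05, 0.1, 0.2],
            "gamma": [0.05, 0.1, 0.2, 0.5, 0.7, 1],
            "max_depth": [5, 7, 9, 15, 17, 21, 25],
            "min_child_weight": [1, 5, 7, 9, 11],
            "subsample": [0.5, 0.6, 0.8, 1],
            "colsample_bytree": [0.5, 0.6, 0.8, 1],
            "reg_lambda": [0.01, 0.1, 1],
            "reg_alpha": [0, 0.1, 0.3, 0.5, 1],
        },
    ),
}


def _make_estimator(name: str, params: dict, seed: int):
    params = dict(params)
    if name == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "svm":
        return SVC(kernel="linear", random_state=seed, **params)
    if name == "ksvm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if name == "xgb":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="mlogloss",
            **params,
        )
    raise ValueError(f"unknown baseline {name!r}; choose from {BASELINE_NAMES}")


def train_baseline(
    name: str,
    pixels: np.ndarray,
    labels: np.ndarray,
    params: dict | None = None,
    seed: int = 0,
):
    """Fit one pixel classifier on N×F features and N integer labels."""
    pixels = np.asarray(pixels)
    labels = np.asarray(labels)
    if pixels.ndim != 2 or len(pixels) != len(labels):
        raise ValueError("pixels must be N×F aligned with N labels")
    est = _make_estimator(name, params or {}, seed)
    est.fit(pixels, labels)
    return est


def random_search(
    name: str,
    space: SearchSpace,
    data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    n_iter: int = 10,
    seed: int = 0,
    select_on: str = "val",
) -> tuple[dict, list[dict]]:
    """Uniform random search over the candidate grids.

    ``data`` is (X_train, y_train, X_held, y_held); each trial samples one
    value per hyperparameter, fits, and scores overall accuracy on the
    held-out block.  Returns (best_params, trial_table).  For a fixed seed
    the trial stream is a prefix-stable sequence, so the best score is
    non-decreasing in ``n_iter``.  ``select_on`` is recorded in the trial
    table to document whether the held-out block is a validation or a test
    set.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if select_on not in ("val", "test"):
        raise ValueError("select_on must be 'val' or 'test'")
    x_tr, y_tr, x_he, y_he = data
    rng = np.random.default_rng(seed)
    keys = sorted(space.grid)
    trials = []
    best: dict | None = None
    best_oa = -1.0
    for i in range(n_iter):
        params = {k: space.grid[k][int(rng.integers(len(space.grid[k])))] for k in keys}
        est = _make_estimator(name, params, seed)
        est.fit(x_tr, y_tr)
        oa = float((est.predict(x_he) == y_he).mean())
        trials.append({"trial": i, "params": params, "oa": oa, "select_on": select_on})
        if oa > best_oa:
            best_oa, best = oa, params
    assert best is not None
    return best, trials


def scene_pixels(scene, feature_values: np.ndarray, max_pixels: int | None = None,
                 seed: int = 0):
    """Flatten labeled pixels of a scene into (X, y) for the baselines."""
    labels = scene.labels
    valid = labels >= 0
    x = feature_values[valid]
    y = labels[valid]
    if max_pixels is not None and len(y) > max_pixels:
        idx = np.random.default_rng(seed).choice(len(y), max_pixels, replace=False)
        x, y = x[idx], y[idx]
    return x, y
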