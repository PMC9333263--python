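"""Multichannel vocal/nonvocal decoding with L1 logistic regression.

Features are mean HGA in 100 ms windows sliding by 50 ms (window centers
−50…1,500 ms for VL, −50…2,450 ms for NatS), channel-major column order.
Full models use all channels and windows at once; sliding models fit one
window at a time; cross-task models train on one stimulus set and test on the
other, restricted to the window grid common to both (centers ≤ 550 ms).

The cross-validation protocol: 5 stratified outer folds; within each outer
training+validation set, features are z-scored and observations are weighted
by inverse class prevalence (so chance balanced accuracy stays at 0.5 under
the 37/128 NatS class imbalance); a 20-value L1 path from λ_max (smallest
penalty zeroing every coefficient of the weighted problem) down to
λ_max·10⁻³ is searched by 10-fold inner cross-validation, choosing the
penalty with minimum mean weighted binomial deviance.  Reported accuracy is
balanced (mean of class-conditional accuracies), pooled over outer folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cluster_stats import ClusterResult, TimeStatSeries, permutation_cluster_test
from .config import AnalysisConfig
from .data_model import ConsistencyError
from .preprocessing import EpochedHGA, StimulusResponse

#: last sliding-window center per task (ms); the first is always −50
DECODE_GRID_MAX_MS = {"VL": 1500.0, "NatS": 2450.0}


@dataclass
class FeatureMatrix:
    """Rows = stimuli (or single trials), columns = channel × window mean HGA."""

    X: np.ndarray
    labels: np.ndarray
    window_centers_ms: np.ndarray
    channel_ids: list[str]
    row_ids: list[str]
    task: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return len(self.window_centers_ms)

    def window_slice(self, w: int) -> np.ndarray:
        """Columns of window ``w`` across all channels (channel-major layout)."""
        return self.X[:, w :: self.n_windows] if self.n_windows > 1 else self.X


@dataclass
class DecodingResult:
    balanced_accuracy: float
    per_fold_accuracy: list[float] = field(default_factory=list)
    chosen_C: list[float] = field(default_factory=list)
    permutation_p: float | None = None
    series: TimeStatSeries | None = None
    clusters: ClusterResult | None = None


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of within-class accuracies; 0.5 is chance at any class imbalance."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.all() or not y_true.any():
        raise ValueError("both classes must be present in y_true")
    acc_pos = float(np.mean(y_pred[y_true]))
    acc_neg = float(np.mean(~y_pred[~y_true]))
    return 0.5 * (acc_pos + acc_neg)


def decode_window_centers(task: str, cfg: AnalysisConfig,
                          max_center_ms: float | None = None) -> np.ndarray:
    if max_center_ms is None:
        if task not in DECODE_GRID_MAX_MS:
            raise ValueError(f"unknown task {task!r}")
        max_center_ms = DECODE_GRID_MAX_MS[task]
    step = cfg.decode_window_step_ms
    start = -step
    n = int(round((max_center_ms - start) / step)) + 1
    return start + step * np.arange(n)


def build_features(
    source: StimulusResponse | EpochedHGA,
    stimuli: pd.DataFrame,
    channels: Sequence[str] | None = None,
    cfg: AnalysisConfig | None = None,
    windows: Literal["all"] | Sequence[float] = "all",
) -> FeatureMatrix:
    """Window-mean HGA features, channel-major / window-minor column order.

    ``source`` may be a :class:`StimulusResponse` (rows = stimuli, the
    default analysis) or an :class:`EpochedHGA` (rows = single trials, used
    for the nonspeech analysis where stimulus exemplars are scarce).
    """
    cfg = cfg or AnalysisConfig()
    all_ids = [c.channel_id for c in source.channels]
    if channels is None:
        channels = all_ids
    channels = list(channels)
    if not channels:
        raise ValueError("empty channel set")
    ch_idx = [all_ids.index(c) for c in channels]

    centers = (
        decode_window_centers(source.task, cfg)
        if isinstance(windows, str) and windows == "all"
        else np.asarray(windows, dtype=float)
    )
    half = cfg.decode_window_width_ms / 2.0
    masks = []
    for c in centers:
        m = (source.times_ms >= c - half - 1e-9) & (source.times_ms < c + half - 1e-9)
        if not m.any():
            raise ValueError(f"window centered at {c} ms contains no samples")
        masks.append(m)

    if isinstance(source, StimulusResponse):
        row_ids = list(source.stimulus_ids)
    else:
        row_ids = list(source.trial_stimulus_ids)
    vocal = stimuli.set_index("stimulus_id")["vocal"]
    labels = np.array([bool(vocal.loc[sid]) for sid in row_ids])

    n_rows = source.data.shape[0]
    X = np.empty((n_rows, len(ch_idx) * len(centers)))
    col = 0
    for ci in ch_idx:
        for m in masks:
            X[:, col] = source.data[:, ci, m].mean(axis=1)
            col += 1
    return FeatureMatrix(
        X=X, labels=labels, window_centers_ms=centers,
        channel_ids=channels, row_ids=row_ids, task=source.task,
    )


# ---------------------------------------------------------------------------
# the weighted L1 path
# ---------------------------------------------------------------------------

def _class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse class prevalence, normalized so weights sum to n."""
    y = np.asarray(y, dtype=bool)
    n = y.size
    w = np.where(y, n / (2.0 * y.sum()), n / (2.0 * (~y).sum()))
    return w


def _lambda_path(Xz: np.ndarray, y: np.ndarray, w: np.ndarray, cfg: AnalysisConfig
                 ) -> np.ndarray:
    """C values (inverse penalty) from the all-zero point down the path.

    λ_max is the smallest L1 penalty at which every coefficient of the
    weighted problem is zero; under inverse-prevalence weights the weighted
    label mean is 1/2, so λ_max = max_j |Σ_i w_i x_ij (y_i − 1/2)|.
    """
    grad = Xz.T @ (w * (y - 0.5))
    lam_max = float(np.max(np.abs(grad)))
    if lam_max == 0.0:
        lam_max = 1.0
    lams = np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)
    return 1.0 / lams


def _weighted_deviance(y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = w * (y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(-2.0 * ll.sum() / w.sum())


def _fit_l1(Xz, y, w, C) -> LogisticRegression:
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-6,
        random_state=0,
    )
    model.fit(Xz, y, sample_weight=w)
    return model


def _zscore_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _select_C(X: np.ndarray, y: np.ndarray, cfg: AnalysisConfig, seed: int) -> float:
    """Inner cross-validation over the L1 path; returns the chosen C."""
    mu, sd = _zscore_stats(X)
    Xz = (X - mu) / sd
    w = _class_weights(y)
    Cs = _lambda_path(Xz, y, w, cfg)
    inner = StratifiedKFold(
        n_splits=min(cfg.n_inner_folds, int(min(y.sum(), (~y).sum()))),
        shuffle=True, random_state=seed,
    )
    deviance = np.zeros(len(Cs))
    for tr, va in inner.split(Xz, y):
        for k, C in enumerate(Cs):
            model = _fit_l1(Xz[tr], y[tr], w[tr], C)
            p = model.predict_proba(Xz[va])[:, 1]
            deviance[k] += _weighted_deviance(y[va], p, w[va])
    return float(Cs[int(np.argmin(deviance))])


def fit_l1_logistic_cv(
    X: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
) -> DecodingResult:
    """Nested-CV L1 logistic decoder; see the module docstring for the protocol."""
    cfg = cfg or AnalysisConfig()
    if isinstance(X, FeatureMatrix):
        labels = X.labels
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_min = int(min(y.sum(), (~y).sum()))
    if n_min < cfg.n_outer_folds:
        raise ValueError(
            f"minority class has {n_min} members; cannot stratify {cfg.n_outer_folds} folds"
        )

    outer = StratifiedKFold(n_splits=cfg.n_outer_folds, shuffle=True, random_state=seed)
    pooled_true, pooled_pred = [], []
    per_fold, chosen = [], []
    for f, (tr, te) in enumerate(outer.split(X, y)):
        C = _select_C(X[tr], y[tr], cfg, seed=seed + 1000 + f)
        mu, sd = _zscore_stats(X[tr])
        model = _fit_l1((X[tr] - mu) / sd, y[tr], _class_weights(y[tr]), C)
        pred = model.predict((X[te] - mu) / sd).astype(bool)
        pooled_true.append(y[te])
        pooled_pred.append(pred)
        chosen.append(C)
        if y[te].any() and not y[te].all():
            per_fold.append(balanced_accuracy(y[te], pred))
    acc = balanced_accuracy(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return DecodingResult(balanced_accuracy=acc, per_fold_accuracy=per_fold, chosen_C=chosen)


def decode_sliding(
    features: FeatureMatrix,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
    n_perm: int | None = None,
) -> DecodingResult:
    """One decoder per sliding window; optional cluster permutation inference.

    When ``n_perm`` is given, significance is assessed with the one-sided
    (upper tail) cluster permutation test over window accuracies, refitting
    the entire sliding analysis for every label shuffle.
    """
    cfg = cfg or AnalysisConfig()

    def accuracy_series(X: FeatureMatrix, lab: np.ndarray) -> np.ndarray:
        out = np.empty(X.n_windows)
        for w in range(X.n_windows):
            out[w] = fit_l1_logistic_cv(X.window_slice(w), lab, cfg, seed=seed).balanced_accuracy
        return out

    observed = accuracy_series(features, features.labels)
    series = TimeStatSeries(observed, features.window_centers_ms, kind="accuracy")
    clusters = None
    if n_perm is not None:
        clusters = permutation_cluster_test(
            accuracy_series,
            features,
            features.labels,
            n_perm=n_perm,
            window_alpha=cfg.cluster_window_alpha,
            seed=seed,
            tail="greater",
            window_centers_ms=features.window_centers_ms,
        )
    return DecodingResult(
        balanced_accuracy=float(observed.max()),
        series=series,
        clusters=clusters,
    )


def decode_cross_task(
    train: FeatureMatrix,
    test: FeatureMatrix,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
) -> DecodingResult:
    """Train on all data of one task, test on all data of the other.

    Both matrices must already be restricted to the shared window grid
    (centers up to 550 ms, the shorter stimulus duration); the training-set
    z-scoring statistics are applied to the test matrix.
    """
    cfg = cfg or AnalysisConfig()
    if (
        train.n_windows != test.n_windows
        or not np.allclose(train.window_centers_ms, test.window_centers_ms)
    ):
        raise ConsistencyError("train and test window grids differ")
    if np.max(train.window_centers_ms) > cfg.cross_task_max_center_ms + 1e-9:
        raise ConsistencyError(
            f"cross-task features must stop at {cfg.cross_task_max_center_ms} ms centers"
        )
    C = _select_C(train.X, train.labels, cfg, seed=seed)
    mu, sd = _zscore_stats(train.X)
    model = _fit_l1((train.X - mu) / sd, train.labels, _class_weights(train.labels), C)
    pred = model.predict((test.X - mu) / sd).astype(bool)
    return DecodingResult(
        balanced_accuracy=balanced_accuracy(test.labels, pred), chosen_C=[C]
    )


def permutation_significance_full(
    X: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    cfg: AnalysisConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    n_models: int = 1,
) -> tuple[float, float, float]:
    """Label-shuffle significance of a full decoding model.

    Refits the complete nested-CV pipeline per permutation;
    p = (1 + #{null ≥ observed}) / (1 + n_perm), then Bonferroni-multiplied by
    the number of simultaneous models (capped at 1).  Returns
    ``(observed_accuracy, p, p_bonferroni)``.
    """
    cfg = cfg or AnalysisConfig()
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if isinstance(X, FeatureMatrix):
        labels = X.labels
        X = X.X
    y = np.asarray(labels, dtype=bool)
    observed = fit_l1_logistic_cv(X, y, cfg, seed=seed).balanced_accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = fit_l1_logistic_cv(X, rng.permutation(y), cfg, seed=seed).balanced_accuracy
    p = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    return observed, p, min(1.0, p * n_models)
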