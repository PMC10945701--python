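"""Awareness-state decoding with shrinkage LDA, sub-averaged pseudo-trials,
temporal generalization, and cross-condition generalization.

The cross-validation layout: trials are class-balanced by undersampling,
randomly assigned to 10 folds per class, sub-averaged in disjoint groups of
4 within each fold (pseudo-trials), and scored leave-one-fold-out; the fold
assignment is redrawn 5 times, giving 50 scored fold tests per time point.
Features at each time point are the instantaneous channel vectors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DecodingConfig

__all__ = ["ShrinkageLDA", "balance_classes", "make_pseudotrials",
           "decode_timecourse", "temporal_generalization",
           "cross_condition_generalization", "DecodingResult"]


class ShrinkageLDA:
    """Two-class linear discriminant with Ledoit-Wolf covariance shrinkage.

    The pooled within-class covariance is shrunk toward a scaled identity,
    S_gamma = (1 - gamma) S + gamma * (tr S / p) I, with gamma chosen by the
    Ledoit-Wolf formula when not given.  The decision is the sign of
    ``w . x - b`` with ``w = S_gamma^{-1} (m1 - m0)`` and the threshold at
    the midpoint of the projected class means.
    """

    def __init__(self, gamma: float | None = None):
        self.gamma = gamma

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("ShrinkageLDA is strictly two-class")
        self.classes_ = classes
        X0, X1 = X[y == classes[0]], X[y == classes[1]]
        if len(X0) < 2 or len(X1) < 2:
            raise ValueError("need >= 2 samples per class")
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        Xc = np.concatenate([X0 - m0, X1 - m1])
        n, p = Xc.shape
        S = Xc.T @ Xc / n
        if self.gamma is None:
            from sklearn.covariance import ledoit_wolf
            S_lw, gamma = ledoit_wolf(Xc, assume_centered=True)
        else:
            gamma = self.gamma
            mu = np.trace(S) / p
            S_lw = (1 - gamma) * S + gamma * mu * np.eye(p)
        self.gamma_ = float(gamma)
        if gamma == 0:
            # plain LDA: fail loudly on a singular pooled covariance
            if np.linalg.matrix_rank(S) < p:
                raise np.linalg.LinAlgError(
                    "singular pooled covariance with gamma=0; use shrinkage")
            S_lw = S
        self.w_ = np.linalg.solve(S_lw, m1 - m0)
        self.b_ = float(self.w_ @ (m0 + m1) / 2.0)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w_ - self.b_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes_[1],
                        self.classes_[0])

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def balance_classes(y: np.ndarray, rng: np.random.Generator,
                    min_per_class: int | None = None) -> np.ndarray:
    """Undersample the majority class: random selection without replacement
    down to the minority count.  Returns the retained trial indices."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() == 0:
        raise ValueError("need two non-empty classes")
    if min_per_class is not None and counts.min() < min_per_class:
        raise ValueError(
            f"minority class has {counts.min()} trials, fewer than the "
            f"required {min_per_class}")
    n_keep = counts.min()
    keep = []
    for c in classes:
        idx = np.where(y == c)[0]
        keep.append(rng.choice(idx, size=n_keep, replace=False))
    return np.sort(np.concatenate(keep))


def make_pseudotrials(X: np.ndarray, y: np.ndarray, cfg: DecodingConfig,
                      rng: np.random.Generator):
    """One random fold assignment with within-fold sub-averaging.

    Per class, trials are randomly split across ``cfg.n_folds`` folds; within
    each fold, disjoint groups of ``cfg.subaverage_k`` trials are averaged
    into pseudo-trials and remainder trials are dropped.  Returns a list of
    ``(X_fold, y_fold)`` pseudo-trial sets, one per fold (either array may be
    empty when a fold ends up with fewer than ``subaverage_k`` trials of a
    class).
    """
    y = np.asarray(y)
    folds_X = [[] for _ in range(cfg.n_folds)]
    folds_y = [[] for _ in range(cfg.n_folds)]
    for c in np.unique(y):
        idx = rng.permutation(np.where(y == c)[0])
        for f, chunk in enumerate(np.array_split(idx, cfg.n_folds)):
            n_groups = len(chunk) // cfg.subaverage_k
            for g in range(n_groups):
                grp = chunk[g * cfg.subaverage_k:(g + 1) * cfg.subaverage_k]
                folds_X[f].append(X[grp].mean(axis=0))
                folds_y[f].append(c)
    out = []
    for f in range(cfg.n_folds):
        if folds_X[f]:
            out.append((np.stack(folds_X[f]), np.array(folds_y[f])))
        else:
            out.append((np.empty((0,) + X.shape[1:]), np.array([])))
    return out


@dataclass
class DecodingResult:
    """Decoding accuracies; ``times`` gives the decoded time points (ms)."""

    accuracy: np.ndarray                 # (n_times,), mean over iterations
    times: np.ndarray
    per_iteration: np.ndarray | None = None   # (n_iter, n_times)
    matrix: np.ndarray | None = None          # (n_train_times, n_test_times)
    n_iterations: int = 0


def _zscore_params(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _fit_fold(Xtr, ytr, t, zscore):
    F = Xtr[:, :, t]
    if zscore:
        mu, sd = _zscore_params(F)
        F = (F - mu) / sd
    else:
        mu = sd = None
    clf = ShrinkageLDA().fit(F, ytr)
    return clf, mu, sd


def decode_timecourse(X: np.ndarray, y: np.ndarray, cfg: DecodingConfig,
                      times: np.ndarray,
                      time_indices: np.ndarray | None = None) -> DecodingResult:
    """Leave-one-fold-out decoding accuracy at each time point.

    ``X`` is (trials, channels, times); classes are balanced, pseudo-trials
    formed, and each of ``cfg.n_assignment_repeats`` fold assignments scored
    leave-one-fold-out, for ``n_folds * n_assignment_repeats`` (by default
    50) fold tests per time point.  ``time_indices`` restricts the decoded
    samples (defaults to all).
    """
    rng = np.random.default_rng(cfg.seed)
    y = np.asarray(y)
    keep = balance_classes(y, rng, min_per_class=cfg.n_folds)
    Xb, yb = X[keep], y[keep]
    ti = np.arange(X.shape[2]) if time_indices is None else np.asarray(time_indices)
    accs = []
    for _ in range(cfg.n_assignment_repeats):
        folds = make_pseudotrials(Xb, yb, cfg, rng)
        for f in range(cfg.n_folds):
            Xte, yte = folds[f]
            train = [folds[g] for g in range(cfg.n_folds) if g != f]
            Xtr = np.concatenate([fx for fx, _ in train])
            ytr = np.concatenate([fy for _, fy in train])
            row = np.full(ti.size, np.nan)
            if len(yte) and len(np.unique(ytr)) == 2:
                for k, t in enumerate(ti):
                    clf, mu, sd = _fit_fold(Xtr, ytr, t, cfg.zscore)
                    F = Xte[:, :, t]
                    if cfg.zscore:
                        F = (F - mu) / sd
                    row[k] = clf.score(F, yte)
            accs.append(row)
    per_iter = np.stack(accs)
    return DecodingResult(np.nanmean(per_iter, axis=0), times[ti],
                          per_iteration=per_iter,
                          n_iterations=per_iter.shape[0])


def temporal_generalization(X: np.ndarray, y: np.ndarray, cfg: DecodingConfig,
                            times: np.ndarray,
                            time_indices: np.ndarray | None = None) -> DecodingResult:
    """Train-at-t / test-at-t' accuracy matrix with the same fold structure
    as :func:`decode_timecourse`; the matrix diagonal equals the time-course
    accuracy when seeds are shared."""
    rng = np.random.default_rng(cfg.seed)
    y = np.asarray(y)
    keep = balance_classes(y, rng, min_per_class=cfg.n_folds)
    Xb, yb = X[keep], y[keep]
    ti = np.arange(X.shape[2]) if time_indices is None else np.asarray(time_indices)
    mats = []
    for _ in range(cfg.n_assignment_repeats):
        folds = make_pseudotrials(Xb, yb, cfg, rng)
        for f in range(cfg.n_folds):
            Xte, yte = folds[f]
            train = [folds[g] for g in range(cfg.n_folds) if g != f]
            Xtr = np.concatenate([fx for fx, _ in train])
            ytr = np.concatenate([fy for _, fy in train])
            mat = np.full((ti.size, ti.size), np.nan)
            if len(yte) and len(np.unique(ytr)) == 2:
                for s, t_train in enumerate(ti):
                    clf, mu, sd = _fit_fold(Xtr, ytr, t_train, cfg.zscore)
                    for k, t_test in enumerate(ti):
                        F = Xte[:, :, t_test]
                        if cfg.zscore:
                            F = (F - mu) / sd
                        mat[s, k] = clf.score(F, yte)
            mats.append(mat)
    stack = np.stack(mats)
    matrix = np.nanmean(stack, axis=0)
    diag = np.diagonal(matrix).copy()
    return DecodingResult(diag, times[ti], matrix=matrix,
                          n_iterations=stack.shape[0])


def cross_condition_generalization(X_train: np.ndarray, y_train: np.ndarray,
                                   X_test: np.ndarray, y_test: np.ndarray,
                                   cfg: DecodingConfig, times: np.ndarray,
                                   time_indices: np.ndarray | None = None) -> DecodingResult:
    """Train on one condition pair, test on another (e.g. train NA/NU, test
    HA/LU with HA = aware, LU = unaware).

    Classifiers are fit at each training time on all training pseudo-trials
    (no fold withholding is needed since the test conditions are disjoint
    trials) and evaluated at every test time on the test-condition
    pseudo-trials; the pseudo-trial assignment is redrawn
    ``cfg.n_assignment_repeats`` times and accuracies averaged.
    """
    for arr, lab in ((y_train, "train"), (y_test, "test")):
        if np.unique(arr).size != 2:
            raise ValueError(f"{lab} labels must contain exactly two classes")
    rng = np.random.default_rng(cfg.seed)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    ti = np.arange(X_train.shape[2]) if time_indices is None else np.asarray(time_indices)
    mats = []
    for _ in range(cfg.n_assignment_repeats):
        keep_tr = balance_classes(y_train, rng, min_per_class=cfg.n_folds)
        keep_te = balance_classes(y_test, rng)
        ftr = make_pseudotrials(X_train[keep_tr], y_train[keep_tr], cfg, rng)
        fte = make_pseudotrials(X_test[keep_te], y_test[keep_te], cfg, rng)
        Xtr = np.concatenate([fx for fx, _ in ftr if len(fx)])
        ytr = np.concatenate([fy for _, fy in ftr if len(fy)])
        Xte = np.concatenate([fx for fx, _ in fte if len(fx)])
        yte = np.concatenate([fy for _, fy in fte if len(fy)])
        mat = np.full((ti.size, ti.size), np.nan)
        for s, t_train in enumerate(ti):
            clf, mu, sd = _fit_fold(Xtr, ytr, t_train, cfg.zscore)
            for k, t_test in enumerate(ti):
                F = Xte[:, :, t_test]
                if cfg.zscore:
                    F = (F - mu) / sd
                mat[s, k] = clf.score(F, yte)
        mats.append(mat)
    stack = np.stack(mats)
    matrix = stack.mean(axis=0)
    return DecodingResult(np.diagonal(matrix).copy(), times[ti], matrix=matrix,
                          n_iterations=stack.shape[0])
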