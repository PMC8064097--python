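"""Multilevel multivariate statistics for repeated-measures breath data.

The repeated-measures structure (every participant sampled at every
timepoint, in duplicate) is handled by splitting the preprocessed matrix
into between-subject variation (subject means, expanded back to sample
rows) and within-subject variation (deviations from the subject mean)::

    X = X_between + X_within          (exact, by construction)

Exploratory analysis (M-PCA) and discriminant modelling (M-PLS-DA) then
operate on ``X_within``, so each participant's baseline acts as their own
control.  PLS-DA is PLS2 regression of the within matrix on a one-hot
class membership matrix, fitted by the iterative NIPALS sequence with
X-only deflation; variable selection uses the Variable Importance in
Projection (VIP) score, whose squares average to 1 by construction so
that VIP > 1 marks influential ions.  Model validation is subject-level
stratified k-fold cross-validation: all samples of a subject share a
fold, so no subject leaks between training and test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PreprocessedMatrix:
    """Log-transformed, column-centred samples x ions matrix."""

    x: pd.DataFrame          # samples x ions
    subjects: pd.Series      # sample -> participant id
    labels: pd.Series        # sample -> class label (timepoint or group)

    def subset(self, mask) -> "PreprocessedMatrix":
        return PreprocessedMatrix(self.x.loc[mask], self.subjects.loc[mask],
                                  self.labels.loc[mask])


def preprocess(values: pd.DataFrame, subjects: pd.Series, labels: pd.Series,
               drop_ions: list[str] | None = None,
               center: bool = True) -> PreprocessedMatrix:
    """Natural-log transform and column mean-centre a concentration matrix.

    All values must be strictly positive (guaranteed downstream of LoD
    replacement); a non-positive entry aborts naming the sample and ion.
    ``drop_ions`` removes e.g. exogenous-flagged channels from the model.
    """
    x = values.drop(columns=drop_ions or [], errors="ignore")
    bad = np.argwhere(~(x.to_numpy() > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive concentration for sample {x.index[i]} ion "
            f"{x.columns[j]}; was the LoD replacement step skipped?")
    logged = np.log(x)
    if center:
        logged = logged - logged.mean(axis=0)
    return PreprocessedMatrix(x=logged, subjects=subjects.reindex(x.index),
                              labels=labels.reindex(x.index))


def multilevel_split(x: pd.DataFrame, subjects: pd.Series
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between/within decomposition: X = X_between + X_within, exactly.

    ``X_between`` row i is the mean of all rows belonging to subject(i).
    Subjects contributing a single sample are excluded with a warning
    (their within-row would be identically zero).
    """
    subjects = subjects.reindex(x.index)
    counts = subjects.value_counts()
    singles = counts[counts < 2].index
    if len(singles):
        logger.warning("excluding %d single-sample subjects from the "
                       "multilevel split: %s", len(singles), list(singles))
        keep = ~subjects.isin(singles)
        x, subjects = x.loc[keep], subjects.loc[keep]
    if x.empty:
        raise ValueError("no subjects with repeated measures")
    between = x.groupby(subjects).transform("mean")
    within = x - between
    return between, within


@dataclass
class MPCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def mpca(pm: PreprocessedMatrix, n_components: int = 2) -> MPCAResult:
    """Multilevel PCA: singular decomposition of the within-subject matrix."""
    _, within = multilevel_split(pm.x, pm.subjects)
    arr = within.to_numpy()
    if not np.any(arr):
        raise ValueError("within-subject matrix has zero variance")
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    ratio = (s ** 2 / np.sum(s ** 2))[:n_components]
    scores = pd.DataFrame(u[:, :n_components] * s[:n_components],
                          index=within.index,
                          columns=[f"PC{a+1}" for a in range(n_components)])
    loadings = pd.DataFrame(vt[:n_components].T, index=within.columns,
                            columns=scores.columns)
    return MPCAResult(scores, loadings, ratio)


@dataclass
class MultilevelModel:
    """Fitted M-PLS-DA model (NIPALS PLS2 on the within-subject matrix)."""

    classes: list[str]
    ions: list[str]
    weights: np.ndarray        # p x A, unit columns
    loadings: np.ndarray       # p x A
    scores: np.ndarray         # n x A
    y_loadings: np.ndarray     # g x A (regression of centred Y on scores)
    ss_y: np.ndarray           # A, Y-variance explained per component
    y_mean: np.ndarray         # g, class proportions
    x_between: pd.DataFrame
    x_within: pd.DataFrame
    sample_index: pd.Index = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.sample_index,
                            columns=[f"LV{a+1}" for a in
                                     range(self.n_components)])

    def rotations(self) -> np.ndarray:
        """W* = W (P'W)^-1, mapping raw within-rows to scores."""
        return self.weights @ np.linalg.inv(self.loadings.T @ self.weights)

    def predict(self, x_within: pd.DataFrame) -> pd.Series:
        """Classify within-decomposed rows by maximal predicted dummy column."""
        t_new = x_within[self.ions].to_numpy() @ self.rotations()
        y_hat = t_new @ self.y_loadings.T + self.y_mean
        idx = np.argmax(y_hat, axis=1)
        return pd.Series([self.classes[i] for i in idx], index=x_within.index)


def _dummy_y(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    classes = sorted(labels.unique())
    y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        y[np.asarray(labels == c), j] = 1.0
    return y, classes


def mplsda(pm: PreprocessedMatrix, n_components: int = 2,
           tol: float = 1e-12, max_iter: int = 1000) -> MultilevelModel:
    """Multilevel PLS-DA via NIPALS with X-only deflation.

    Deterministic: the score iteration for every component starts from
    the centred dummy-Y column with maximal variance.  Successive score
    vectors are mutually orthogonal (a consequence of X deflation).
    """
    labels = pm.labels
    if labels.nunique() < 2:
        raise ValueError("discrimination needs at least two classes")
    y_raw, classes = _dummy_y(labels)
    between, within = multilevel_split(pm.x, pm.subjects)
    x = within.to_numpy().copy()
    y_mean = y_raw.mean(axis=0)
    y = y_raw - y_mean
    n, p = x.shape
    a_max = min(n_components, p, n - 1)
    if a_max < n_components:
        raise ValueError(f"cannot extract {n_components} components from a "
                         f"{n} x {p} matrix")
    start_col = int(np.argmax(y.var(axis=0)))

    ws, ps, ts, cs, ss = [], [], [], [], []
    for _ in range(n_components):
        u = y[:, start_col]
        w_old = np.zeros(p)
        for _ in range(max_iter):
            w = x.T @ u / (u @ u)
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("degenerate component: zero weight vector")
            w /= norm
            t = x @ w
            c = y.T @ t / (t @ t)
            u = y @ c / (c @ c)
            if np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        p_load = x.T @ t / (t @ t)
        x = x - np.outer(t, p_load)
        ws.append(w); ps.append(p_load); ts.append(t); cs.append(c)
        ss.append(float((c @ c) * (t @ t)))

    model = MultilevelModel(
        classes=classes, ions=list(within.columns),
        weights=np.column_stack(ws), loadings=np.column_stack(ps),
        scores=np.column_stack(ts), y_loadings=np.column_stack(cs),
        ss_y=np.asarray(ss), y_mean=y_mean,
        x_between=between, x_within=within, sample_index=within.index)
    return model


def vip_scores(model: MultilevelModel) -> pd.Series:
    """Variable Importance in Projection per ion.

    VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ) with unit weight
    vectors, so that sum_j VIP_j^2 = p exactly.  SS_a is the Y-variance
    explained by component a.
    """
    total = model.ss_y.sum()
    if total <= 0:
        raise ValueError("no Y variance explained; VIP undefined")
    w2 = model.weights ** 2                     # columns already unit norm
    p = len(model.ions)
    vip = np.sqrt(p * (w2 @ model.ss_y) / total)
    return pd.Series(vip, index=model.ions, name="VIP")


@dataclass
class CVResult:
    mean_error: float
    sd_error: float
    per_repetition: list[float]
    n_components: int


def _subject_folds(subjects: np.ndarray, subject_class: dict, folds: int,
                   rng: np.random.Generator) -> dict:
    """Stratified assignment of whole subjects to folds."""
    assignment: dict = {}
    by_class: dict = {}
    for s in subjects:
        by_class.setdefault(subject_class[s], []).append(s)
    offset = 0
    for cls in sorted(by_class):
        members = sorted(by_class[cls])
        rng.shuffle(members)
        for i, s in enumerate(members):
            assignment[s] = (offset + i) % folds
        offset += len(members)
    return assignment


def cross_validate(pm: PreprocessedMatrix, n_components: int = 2,
                   folds: int = 5, repetitions: int = 10,
                   seed: int = 0) -> CVResult:
    """Repeated subject-level k-fold cross-validation of M-PLS-DA.

    Folds partition subjects (never splitting a subject's samples) with
    class stratification by each subject's most frequent label.  Held-out
    samples are within-decomposed using their own subject means and
    classified by maximal predicted dummy column.  The error metric is
    the balanced error rate (mean over classes of 1 - recall), reported
    as mean +/- sd over repetitions.
    """
    subjects = pm.subjects.to_numpy()
    uniq = np.unique(subjects)
    if folds > len(uniq):
        raise ValueError("more folds than subjects")
    subject_class = {
        s: pm.labels[pm.subjects == s].mode().iloc[0] for s in uniq}
    classes = sorted(pm.labels.unique())
    errors = []
    for rep in range(repetitions):
        for attempt in range(10):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, rep, attempt)))
            assignment = _subject_folds(uniq, subject_class, folds, rng)
            fold_of = np.array([assignment[s] for s in subjects])
            ok = all(
                set(pm.labels[fold_of != f]) == set(classes)
                for f in range(folds))
            if ok:
                break
            logger.info("repartitioning repetition %d: a class was absent "
                        "from a training split", rep)
        else:
            raise RuntimeError("could not build folds covering all classes")
        y_true, y_pred = [], []
        for f in range(folds):
            train = pm.subset(fold_of != f)
            test = pm.subset(fold_of == f)
            if test.x.empty:
                continue
            model = mplsda(train, n_components=n_components)
            # leakage guard: no test subject may appear in training
            assert not set(test.subjects) & set(train.subjects)
            _, test_within = multilevel_split(test.x, test.subjects)
            pred = model.predict(test_within)
            y_true.extend(test.labels.reindex(test_within.index))
            y_pred.extend(pred)
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        per_class = [np.mean(y_pred[y_true == c] != c)
                     for c in classes if np.any(y_true == c)]
        errors.append(float(np.mean(per_class)))
    return CVResult(mean_error=float(np.mean(errors)),
                    sd_error=float(np.std(errors, ddof=1)) if len(errors) > 1
                    else 0.0,
                    per_repetition=errors, n_components=n_components)


def select_n_components(pm: PreprocessedMatrix, max_components: int = 5,
                        folds: int = 5, repetitions: int = 3,
                        seed: int = 0) -> int:
    """Pick the component count minimising mean CV error (capped)."""
    p = pm.x.shape[1]
    best_a, best_err = 1, np.inf
    for a in range(1, min(max_components, p) + 1):
        err = cross_validate(pm, n_components=a, folds=folds,
                             repetitions=repetitions, seed=seed).mean_error
        if err < best_err - 1e-12:
            best_a, best_err = a, err
    return best_a
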