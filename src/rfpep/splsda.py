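"""PCA and sparse PLS discriminant analysis with stability selection.

The sPLS-DA follows the soft-thresholded singular-vector formulation with
regression-mode deflation: per component the dominant left singular vector of
the X'Y cross-covariance is soft-thresholded so that exactly ``keepX``
variables keep non-zero weight, samples are scored along the resulting
direction, and both blocks are deflated by regression on the score. Class
membership enters as a centred one-hot indicator matrix; prediction uses the
maximum-distance rule (the class with the largest predicted indicator wins)
and model quality is the balanced error rate (BER, the unweighted mean of
per-class error rates).

Model selection mirrors the three-step protocol of the analysis: tune the
number of components H (2..5) and the per-component number of retained
peptides by stratified three-fold cross-validation with 50 repeats, then
count for every peptide the fraction of CV repeats whose models select it
(its *occurrence*). Discriminative peptides are the variable-region peptides
with adjusted p < 0.05, fold change > 5, occurrence > 50%, and the lowest
median Z-score in the disease-control group.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

H_GRID = (2, 3, 4, 5)
KEEPX_GRID = (1, 2, 3, 5, 10, 20, 50)
FOLDS = 3
REPEATS = 50
OCCURRENCE_MIN = 0.5


def mean_impute(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean imputation (multivariate analysis only; the rank
    statistics stay imputation-free)."""
    means = matrix.mean(axis=1, skipna=True)
    return matrix.T.fillna(means).T


def pca(X: np.ndarray, n_components: int | None = None, center: bool = True,
        scale: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD principal components: (scores, loadings, explained-variance ratio)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples and features")
    Xc = X - X.mean(axis=0) if center else X.copy()
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd == 0, 1.0, sd)
    if not np.any(Xc):
        raise ValueError("rank-0 matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if n_components is not None:
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    total = np.sum(np.linalg.svd(Xc, compute_uv=False) ** 2)
    return U * s, Vt.T, (s ** 2) / total


def _one_hot(y: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    idx = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(y), len(classes)))
    for i, label in enumerate(y):
        Y[i, idx[label]] = 1.0
    return Y


def _soft_threshold(u: np.ndarray, keepx: int) -> np.ndarray:
    p = len(u)
    if keepx > p:
        raise ValueError(f"keepX={keepx} exceeds {p} variables")
    if keepx < p:
        lam = np.sort(np.abs(u))[::-1][keepx]
        u = np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("all weights thresholded to zero")
    return u / norm


@dataclass
class SplsdaModel:
    classes: tuple[str, ...]
    keepx: tuple[int, ...]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray       # p x H soft-thresholded X-weights
    x_loadings: np.ndarray    # p x H regression loadings
    y_loadings: np.ndarray    # k x H
    scores: np.ndarray        # n x H training-sample scores
    feature_names: tuple[str, ...] | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def selected(self, component: int | None = None) -> np.ndarray:
        """Indices of variables with non-zero weight (one component or any)."""
        if component is not None:
            return np.flatnonzero(self.weights[:, component])
        return np.flatnonzero(np.any(self.weights != 0, axis=1))


def splsda_fit(X: np.ndarray, y: Sequence[str], keepx: Sequence[int],
               scale: bool = True,
               feature_names: Sequence[str] | None = None) -> SplsdaModel:
    """Fit an sPLS-DA with ``len(keepx)`` components."""
    X = np.asarray(X, dtype=float)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        logger.warning("single-class y: trivial discriminant model")
    Y = _one_hot(y, classes)
    x_mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
    x_scale = np.where(sd == 0, 1.0, sd)
    Xh = (X - x_mean) / x_scale
    y_mean = Y.mean(axis=0)
    Yh = Y - y_mean

    p, k = X.shape[1], len(classes)
    H = len(keepx)
    W = np.zeros((p, H))
    P = np.zeros((p, H))
    C = np.zeros((k, H))
    T = np.zeros((X.shape[0], H))
    for h, kx in enumerate(keepx):
        M = Xh.T @ Yh
        U, _, _ = np.linalg.svd(M, full_matrices=False)
        u = U[:, 0]
        # sign convention: the largest-magnitude loading is positive
        u = u * np.sign(u[np.argmax(np.abs(u))] or 1.0)
        u = _soft_threshold(u, kx)
        t = Xh @ u
        tt = t @ t
        if tt == 0:
            logger.warning("degenerate component %d (zero score variance)", h + 1)
            tt = 1.0
        p_load = Xh.T @ t / tt
        c_load = Yh.T @ t / tt
        Xh = Xh - np.outer(t, p_load)
        Yh = Yh - np.outer(t, c_load)
        W[:, h], P[:, h], C[:, h], T[:, h] = u, p_load, c_load, t
    return SplsdaModel(classes, tuple(keepx), x_mean, x_scale, y_mean,
                       W, P, C, T,
                       tuple(feature_names) if feature_names is not None else None)


def splsda_predict(model: SplsdaModel, X_new: np.ndarray,
                   return_scores: bool = False):
    """Maximum-distance prediction: class with the largest predicted
    indicator value; ties go to the first class in sorted order."""
    Xc = (np.asarray(X_new, dtype=float) - model.x_mean) / model.x_scale
    # B = W (P'W)^-1 C'
    PW = model.x_loadings.T @ model.weights
    B = model.weights @ np.linalg.solve(PW, model.y_loadings.T)
    Yhat = Xc @ B + model.y_mean
    labels = np.array(model.classes)[np.argmax(Yhat, axis=1)]
    if return_scores:
        return labels, Yhat
    return labels


def balanced_error_rate(y_true: Sequence[str], y_pred: Sequence[str],
                        classes: Sequence[str] | None = None) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = classes if classes is not None else sorted(set(y_true))
    errs = []
    for c in classes:
        mask = y_true == c
        if mask.any():
            errs.append(float(np.mean(y_pred[mask] != c)))
    return float(np.mean(errs))


def _stratified_folds(y: Sequence[str], folds: int,
                      rng: np.random.Generator,
                      allow_small: bool = True) -> np.ndarray:
    y = np.asarray(y)
    assignment = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < folds:
            if not allow_small:
                raise ValueError(f"class {c!r} has {len(idx)} < {folds} members")
            logger.warning("class %s has %d < %d members; stratified fallback",
                           c, len(idx), folds)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


@dataclass
class CvResult:
    ber_per_repeat: np.ndarray
    occurrence: pd.Series         # per-feature selection fraction
    mean_ber: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_ber = float(np.mean(self.ber_per_repeat))


def cross_validate(X: np.ndarray, y: Sequence[str], keepx: Sequence[int],
                   folds: int = FOLDS, repeats: int = REPEATS,
                   seed: int = 0, scale: bool = True,
                   feature_names: Sequence[str] | None = None,
                   occurrence_denominator: str = "repeats") -> CvResult:
    """Stratified repeated CV: per-repeat pooled BER and per-feature
    occurrence (fraction of repeats — or of fold-models — selecting it)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    names = (list(feature_names) if feature_names is not None
             else list(range(X.shape[1])))
    rng = np.random.default_rng(seed)
    bers = np.zeros(repeats)
    counts = np.zeros(X.shape[1])
    n_models = 0
    for rep in range(repeats):
        assignment = _stratified_folds(y, folds, rng)
        y_pred = np.empty(len(y), dtype=object)
        rep_selected = np.zeros(X.shape[1], dtype=bool)
        for f in range(folds):
            test = assignment == f
            model = splsda_fit(X[~test], y[~test], keepx, scale=scale)
            y_pred[test] = splsda_predict(model, X[test])
            sel = model.selected()
            n_models += 1
            if occurrence_denominator == "models":
                counts[sel] += 1
            else:
                rep_selected[sel] = True
        if occurrence_denominator == "repeats":
            counts += rep_selected
        bers[rep] = balanced_error_rate(y, y_pred)
    denom = n_models if occurrence_denominator == "models" else repeats
    occurrence = pd.Series(counts / denom, index=names, name="occurrence")
    return CvResult(bers, occurrence)


@dataclass
class TuneResult:
    n_components: int
    keepx: tuple[int, ...]
    ber_by_depth: dict[int, float]
    keepx_table: pd.DataFrame


def splsda_tune(X: np.ndarray, y: Sequence[str],
                h_grid: Sequence[int] = H_GRID,
                keepx_grid: Sequence[int] = KEEPX_GRID,
                folds: int = FOLDS, repeats: int = REPEATS,
                seed: int = 0, scale: bool = True) -> TuneResult:
    """Sequential per-component keepX tuning followed by depth selection.

    Component h's keepX is chosen (previous components fixed) to minimize
    mean CV BER, smallest keepX on ties; H* is the depth in ``h_grid`` with
    minimal BER, smallest H on ties.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    grid = sorted({min(k, p) for k in keepx_grid})
    h_max = max(h_grid)
    chosen: list[int] = []
    ber_by_depth: dict[int, float] = {}
    rows = []
    for h in range(1, h_max + 1):
        best_kx, best_ber = None, np.inf
        for kx in grid:
            cv = cross_validate(X, y, chosen + [kx], folds=folds,
                                repeats=repeats, seed=seed, scale=scale)
            rows.append(dict(component=h, keepx=kx, mean_ber=cv.mean_ber))
            if cv.mean_ber < best_ber - 1e-12:
                best_kx, best_ber = kx, cv.mean_ber
        chosen.append(best_kx)
        ber_by_depth[h] = best_ber
    candidates = [h for h in h_grid if h in ber_by_depth]
    best_h = min(candidates, key=lambda h: (ber_by_depth[h], h))
    return TuneResult(best_h, tuple(chosen[:best_h]), ber_by_depth,
                      pd.DataFrame(rows))


def select_discriminative(occurrence: pd.Series, diff: pd.DataFrame,
                          z_scores: pd.DataFrame,
                          sample_groups: Mapping[str, str],
                          assignments: Mapping[str, str],
                          control_group: str = "RFneg_control",
                          adj_p_max: float = 0.05, fc_min: float = 5.0,
                          occurrence_min: float = OCCURRENCE_MIN) -> pd.DataFrame:
    """Flag peptides satisfying the discriminative-peptide conjunction.

    ``assignments`` maps feature_id -> annotation category; a peptide is
    variable-region related when its category is ``"variable"``. The median-Z
    criterion requires the declared control group to attain the minimum of
    the per-group median Z-scores.
    """
    groups = sorted(set(sample_groups.values()))
    med = pd.DataFrame({
        g: z_scores[[s for s in z_scores.columns
                     if sample_groups[s] == g]].median(axis=1, skipna=True)
        for g in groups})
    rows = []
    for fid in diff.index:
        occ = float(occurrence.get(fid, 0.0))
        medians = med.loc[fid]
        control_lowest = (medians.notna().any()
                          and medians.idxmin() == control_group)
        v_region = assignments.get(fid) == "variable"
        flag = (bool(diff.loc[fid, "adj_p"] < adj_p_max)
                and bool(diff.loc[fid, "fc"] > fc_min)
                and occ > occurrence_min and control_lowest and v_region)
        rows.append(dict(feature_id=fid, occurrence=occ,
                         adj_p=diff.loc[fid, "adj_p"], fc=diff.loc[fid, "fc"],
                         control_lowest_median_z=control_lowest,
                         v_region=v_region, discriminative=flag,
                         **{f"median_z_{g}": medians[g] for g in groups}))
    return pd.DataFrame(rows).set_index("feature_id")
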