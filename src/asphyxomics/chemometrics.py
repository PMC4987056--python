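"""Multivariate layer: unit-variance scaling, PCA, PLS/PLS-DA with
segment-wise cross-validation, repeated-CV misclassification counts and a
permuted-label null, and backscaled loading weights.

Cross-validation is segment-wise: the samples are split into ``k``
contiguous segments of a (repetition-specific) random ordering; scaling is
refit inside every training fold to avoid leakage.  Q2 = 1 - PRESS/TSS
with TSS computed against training-fold means.  For discriminant analysis
the classes are dummy-coded and centered; a held-out sample is assigned to
the nearest class target, which for two classes is the midpoint threshold.

The number of misclassifications (NMC) is summarized over repeated
cross-validation (default 500 repetitions, re-randomized segment
assignment) and compared with the NMC distribution obtained under random
label permutations.  Two p-values are reported, labeled distinctly: an
empirical exceedance p (resolution-limited at 1/(nperm+1)) and a rank-sum
comparison p between the observed-repetition and null NMC distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "ScaledMatrix",
    "PLSModel",
    "CVResult",
    "NMCPermutationResult",
    "BackscaledLoading",
    "uv_scale",
    "pca",
    "pls_fit",
    "pls_predict",
    "cross_validate",
    "select_ncomp",
    "nmc_repetitions",
    "nmc_permutation_null",
    "backscale_loadings",
    "dummy_code",
    "assemble_matrix",
]


# --------------------------------------------------------------------------
# scaling

@dataclass
class ScaledMatrix:
    """Unit-variance-scaled data with the statistics needed to back-scale."""

    X: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    columns: list
    dropped: list = field(default_factory=list)

    def backtransform(self) -> np.ndarray:
        return self.X * self.sds + self.means


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[1]))


def uv_scale(X) -> ScaledMatrix:
    """Mean-center and scale each column to unit (sample) variance.

    Zero-variance columns are dropped with a warning; an all-constant
    matrix is an error.
    """
    M, columns = _as_matrix(X)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 samples to scale")
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all columns are constant; nothing to scale")
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance column(s): {dropped[:5]}")
    Xs = (M[:, keep] - means[keep]) / sds[keep]
    return ScaledMatrix(X=Xs, means=means[keep], sds=sds[keep],
                        columns=[c for c, k in zip(columns, keep) if k],
                        dropped=dropped)


# --------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray   # p x k
    explained_variance_ratio: np.ndarray


def pca(X, k: int) -> PCAResult:
    """PCA of a (scaled) matrix via singular value decomposition.

    Deterministic sign convention: the largest-magnitude loading of each
    component is positive.
    """
    M = X.X if isinstance(X, ScaledMatrix) else np.asarray(X, dtype=float)
    M = M - M.mean(axis=0)
    n, p = M.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    for a in range(k):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] = -Vt[a]
            U[:, a] = -U[:, a]
    scores = U[:, :k] * s[:k]
    var = s ** 2
    return PCAResult(scores=scores, loadings=Vt[:k].T,
                     explained_variance_ratio=var[:k] / var.sum())


# --------------------------------------------------------------------------
# PLS

@dataclass
class PLSModel:
    """NIPALS partial least squares model on centered (scaled) data."""

    ncomp: int
    weights: np.ndarray      # p x a   (loading weights W, unit norm)
    scores: np.ndarray       # n x a   (T)
    x_loadings: np.ndarray   # p x a   (P)
    y_loadings: np.ndarray   # q x a   (Q)
    coef: np.ndarray         # p x q   (B, for centered X and Y)
    r2: np.ndarray           # cumulative R2 per component


def dummy_code(labels) -> tuple[np.ndarray, list]:
    """Class labels -> centered dummy matrix and the class order."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    Y = np.zeros((labels.size, len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y - Y.mean(axis=0), classes


def pls_fit(X, Y, ncomp: int, tol: float = 1e-12, max_iter: int = 500) -> PLSModel:
    """Sequential NIPALS extraction with deflation of X and Y.

    ``X`` and ``Y`` must be centered (``Y`` dummy-coded then centered for
    discriminant analysis).  The first weight vector is the dominant
    direction of the X'Y covariance.
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    if np.allclose(Y, 0):
        raise ValueError("degenerate response: Y has no variation (single class?)")
    n, p = X.shape
    ssy0 = float((Y ** 2).sum())
    W = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    P = np.zeros((p, ncomp))
    Q = np.zeros((Y.shape[1], ncomp))
    r2 = np.zeros(ncomp)
    Xd, Yd = X.copy(), Y.copy()
    for a in range(ncomp):
        u = Yd[:, int(np.argmax((Yd ** 2).sum(axis=0)))]
        if not np.any(u):
            break
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                break
            w_new /= nrm
            t = Xd @ w_new
            tt = float(t @ t)
            if tt == 0:
                break
            q = Yd.T @ t / tt
            u_next = Yd @ q / float(q @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_next
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            break
        q = Yd.T @ t / tt
        pvec = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pvec, q
        r2[a] = 1.0 - float((Yd ** 2).sum()) / ssy0
    # regression coefficients reproducing the fitted values
    PtW = P.T @ W
    R = W @ np.linalg.pinv(PtW)
    coef = R @ Q.T
    return PLSModel(ncomp=ncomp, weights=W, scores=T, x_loadings=P,
                    y_loadings=Q, coef=coef, r2=r2)


def pls_predict(model: PLSModel, X, ncomp: int | None = None) -> np.ndarray:
    """Predict (centered) responses for centered ``X``."""
    X = np.asarray(X, dtype=float)
    a = model.ncomp if ncomp is None else ncomp
    W, P, Q = model.weights[:, :a], model.x_loadings[:, :a], model.y_loadings[:, :a]
    R = W @ np.linalg.pinv(P.T @ W)
    return X @ (R @ Q.T)


# --------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    folds: int
    ncomp: int
    order: np.ndarray
    predictions: np.ndarray   # n x q x ncomp cross-validated predictions
    q2: np.ndarray            # Q2 per cumulative component
    y_centered: np.ndarray


def _segments(order: np.ndarray, folds: int):
    return np.array_split(order, folds)


def cross_validate(X, Y, folds: int = 7, ncomp: int = 2,
                   order: np.ndarray | None = None,
                   labels=None) -> CVResult:
    """Segment-wise cross-validation with scaling refit per training fold.

    ``X`` is the raw (unscaled) matrix; ``Y`` either a continuous response
    or a centered dummy matrix (pass ``labels`` for logging of degenerate
    fold compositions).  Every sample is predicted exactly once.
    """
    M, _cols = _as_matrix(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = M.shape[0]
    if n < folds:
        raise ValueError(f"need at least folds={folds} samples, got {n}")
    if order is None:
        order = np.arange(n)
    preds = np.zeros((n, Y.shape[1], ncomp))
    press = np.zeros(ncomp)
    tss = 0.0
    for seg in _segments(order, folds):
        train = np.setdiff1d(np.arange(n), seg)
        if labels is not None and len(set(np.asarray(labels)[train].tolist())) < 2:
            warnings.warn(
                f"training fold contains a single class (held-out {seg.tolist()})")
        m = M[train].mean(axis=0)
        sd = M[train].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        ym = Y[train].mean(axis=0)
        Xtr = (M[train] - m) / sd
        Ytr = Y[train] - ym
        Xte = (M[seg] - m) / sd
        model = pls_fit(Xtr, Ytr, ncomp=ncomp)
        for a in range(1, ncomp + 1):
            yhat = pls_predict(model, Xte, ncomp=a) + ym
            preds[seg, :, a - 1] = yhat
            press[a - 1] += float(((Y[seg] - yhat) ** 2).sum())
        tss += float(((Y[seg] - ym) ** 2).sum())
    q2 = 1.0 - press / tss
    return CVResult(folds=folds, ncomp=ncomp, order=order, predictions=preds,
                    q2=q2, y_centered=Y - Y.mean(axis=0))


def select_ncomp(q2: np.ndarray, tol: float = 1e-9) -> int:
    """Smallest component count achieving the maximal cross-validated Q2."""
    q2 = np.asarray(q2)
    best = q2.max()
    return int(np.flatnonzero(q2 >= best - tol)[0]) + 1


# --------------------------------------------------------------------------
# NMC with permutation null

@dataclass
class NMCPermutationResult:
    observed: np.ndarray
    null: np.ndarray | None
    median: float
    ci: tuple[float, float]
    null_median: float | None = None
    null_ci: tuple[float, float] | None = None
    p_empirical: float | None = None
    p_ranksum: float | None = None


def _nmc_once(M, Y, labels_idx, folds, ncomp, order):
    """One cross-validation repetition -> number of misclassifications."""
    n = M.shape[0]
    nmc = 0
    for seg in _segments(order, folds):
        train = np.setdiff1d(np.arange(n), seg)
        m = M[train].mean(axis=0)
        sd = M[train].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        ym = Y[train].mean(axis=0)
        model = pls_fit((M[train] - m) / sd, Y[train] - ym, ncomp=ncomp)
        yhat = pls_predict(model, (M[seg] - m) / sd, ncomp=ncomp) + ym
        # nearest dummy target (midpoint threshold for two classes)
        assigned = np.argmax(yhat, axis=1)
        nmc += int((assigned != labels_idx[seg]).sum())
    return nmc


def nmc_repetitions(X, labels, folds: int = 7, ncomp: int = 1,
                    reps: int = 500, seed: int = 0) -> NMCPermutationResult:
    """Observed NMC distribution over repeated segment-wise CV.

    Each repetition re-randomizes the sample ordering before contiguous
    segment assignment.  Reports the median and the 2.5-97.5 percentile
    interval.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    M, _ = _as_matrix(X)
    Y, classes = dummy_code(labels)
    labels_idx = np.array([classes.index(v) for v in np.asarray(labels)])
    rng = np.random.default_rng(seed)
    obs = np.array([
        _nmc_once(M, Y, labels_idx, folds, ncomp, rng.permutation(M.shape[0]))
        for _ in range(reps)
    ])
    lo, hi = np.percentile(obs, [2.5, 97.5])
    return NMCPermutationResult(observed=obs, null=None,
                                median=float(np.median(obs)), ci=(float(lo), float(hi)))


def nmc_permutation_null(X, labels, folds: int = 7, ncomp: int = 1,
                         reps: int = 500, nperm: int = 500,
                         seed: int = 0) -> NMCPermutationResult:
    """Observed repeated-CV NMC compared with a permuted-label null.

    The null draws ``nperm`` random label permutations, one CV repetition
    each.  ``p_empirical`` is the exceedance probability
    ``(1 + #{null <= observed median}) / (nperm + 1)``; ``p_ranksum`` is a
    Wilcoxon rank-sum comparison of the observed and null NMC
    distributions (alternative: observed smaller).
    """
    if nperm < 20:
        raise ValueError("nperm < 20 gives no useful p-value resolution")
    res = nmc_repetitions(X, labels, folds=folds, ncomp=ncomp, reps=reps,
                          seed=seed)
    M, _ = _as_matrix(X)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    labels = np.asarray(labels)
    null = np.empty(nperm, dtype=int)
    for b in range(nperm):
        perm = rng.permutation(labels)
        Yp, classes = dummy_code(perm)
        idx = np.array([classes.index(v) for v in perm])
        null[b] = _nmc_once(M, Yp, idx, folds, ncomp,
                            rng.permutation(M.shape[0]))
    p_emp = (1.0 + int((null <= res.median).sum())) / (nperm + 1.0)
    p_rank = float(mannwhitneyu(res.observed, null, alternative="less").pvalue)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return NMCPermutationResult(
        observed=res.observed, null=null, median=res.median, ci=res.ci,
        null_median=float(np.median(null)), null_ci=(float(lo), float(hi)),
        p_empirical=float(p_emp), p_ranksum=p_rank)


# --------------------------------------------------------------------------
# backscaled loadings

@dataclass
class BackscaledLoading:
    columns: list
    amplitude: np.ndarray
    color: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"amplitude": self.amplitude, "color": self.color},
                            index=self.columns)


def backscale_loadings(model: PLSModel, sds, X, y,
                       columns=None) -> BackscaledLoading:
    """Loading weights reverted to natural scaling, color-coded by the
    Pearson correlation of each variable with the response.

    Amplitude_j = w1_j * sd_j (zero where sd_j = 0); color_j in [-1, 1].
    """
    sds = np.asarray(sds, dtype=float)
    if sds.size != model.weights.shape[0]:
        raise ValueError("sds length does not match the number of variables")
    M, cols = _as_matrix(X)
    if columns is None:
        columns = cols
    y = np.asarray(y, dtype=float)
    if y.ndim > 1:
        y = y[:, 0]
    amplitude = model.weights[:, 0] * sds
    yc = y - y.mean()
    Xc = M - M.mean(axis=0)
    denom = np.sqrt((Xc ** 2).sum(axis=0) * float((yc ** 2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        color = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    color = np.clip(color, -1.0, 1.0)
    amplitude = np.where(sds > 0, amplitude, 0.0)
    return BackscaledLoading(columns=list(columns), amplitude=amplitude,
                             color=color)


# --------------------------------------------------------------------------
# spectra -> data matrix

def assemble_matrix(spectra, decimals: int = 4) -> pd.DataFrame:
    """Stack preprocessed spectra into a samples x ppm data matrix.

    Spectra are linearly interpolated onto the retained ppm grid of the
    first spectrum (excised gaps stay absent).
    """
    if not spectra:
        raise ValueError("no spectra to assemble")
    ref = spectra[0].ppm
    rows = {}
    for s in spectra:
        rows[s.sample_id or f"s{len(rows)}"] = np.interp(ref, s.ppm, s.real)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=np.round(ref, decimals))
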