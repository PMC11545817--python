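"""PLS2 discriminant analysis: the modelling engine of the pipeline.

Class membership is dummy-coded (one 0/1 column per class), predictors are
autoscaled (mean-centred, unit variance with the n-1 SD), and a PLS2 model
is fitted by NIPALS with X-deflation only.  Internal validation is a seeded
stratified leave-10%-out cross-validation; the retained number of latent
variables minimises RMSEcv.  Overfitting diagnostics are the label
permutation test (original Q2 must beat every permuted Q2) and an F-test on
the cross-validated predictive residuals against the class-mean-only null
model (CV-ANOVA).

Predicted values (PVs) are unconstrained reals: rows are not clipped to
[0, 1] and do not sum to 1.  Classification from PVs lives in
:mod:`isonut.decision`.

All preprocessing is re-estimated inside each cross-validation fold, so a
held-out sample never influences its own scaling constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data import MARKER_NAMES


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge within the iteration budget."""


NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def dummy_encode(labels: Sequence[str], class_labels: Sequence[str]) -> np.ndarray:
    """n x k membership matrix: exactly one 1 per row, column order fixed."""
    index = {c: j for j, c in enumerate(class_labels)}
    Y = np.zeros((len(labels), len(class_labels)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"unknown class label {lab!r}")
        Y[i, index[lab]] = 1.0
    return Y


def autoscale_fit(
    X: np.ndarray, marker_names: Sequence[str] = MARKER_NAMES
) -> tuple[np.ndarray, np.ndarray]:
    """Column means and sample SDs (n-1) for mean-centring + unit variance."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0.0:
            name = marker_names[j] if j < len(marker_names) else f"column {j}"
            raise ValueError(f"zero-variance column: {name}")
    return mean, sd


def autoscale_apply(
    constants: tuple[np.ndarray, np.ndarray], X: np.ndarray
) -> np.ndarray:
    mean, sd = constants
    return (np.asarray(X, dtype=float) - mean) / sd


# ---------------------------------------------------------------------------
# NIPALS PLS2
# ---------------------------------------------------------------------------

@dataclass
class PLSFit:
    """Raw NIPALS decomposition at ``A`` components (scaled/centred space)."""

    W: np.ndarray  # p x A X-weights, unit norm
    P: np.ndarray  # p x A X-loadings
    Q: np.ndarray  # k x A Y-loadings
    T: np.ndarray  # n x A scores

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def coefficients(self, A: int | None = None) -> np.ndarray:
        """Regression coefficients B = W (P'W)^-1 Q' using the first A LVs."""
        A = self.n_components if A is None else A
        W, P, Q = self.W[:, :A], self.P[:, :A], self.Q[:, :A]
        return W @ np.linalg.solve(P.T @ W, Q.T)


def fit_pls2(
    Xs: np.ndarray,
    Yc: np.ndarray,
    A: int,
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
) -> PLSFit:
    """NIPALS PLS2 on a scaled X and centred dummy Y.

    Per component: iterate u -> w = X'u/|X'u| -> t = Xw -> q = Y't/t't ->
    u = Yq/q'q to a relative score tolerance, then deflate X by t p' with
    p = X't/t't.  Y is not deflated (predictions are unaffected by Y
    deflation in PLS2).  Sign convention: the largest-magnitude element of
    each weight vector is made positive.
    """
    X = np.array(Xs, dtype=float)
    Y = np.array(Yc, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if not 1 <= A <= rank:
        raise ValueError(f"A = {A} outside [1, rank(X) = {rank}]")
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((Y.shape[1], A))
    T = np.zeros((n, A))
    for a in range(A):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if not np.any(u):
            u = Y[:, 0].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = X.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0.0:
                raise ConvergenceError(f"component {a + 1}: X'u vanished")
            w /= norm_w
            t = X @ w
            tt = t @ t
            q = Y.T @ t / tt
            qq = q @ q
            if qq == 0.0:
                break  # Y residual orthogonal to t; accept current component
            u = Y @ q / qq
            if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        else:
            raise ConvergenceError(f"component {a + 1} did not converge")
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, q = -w, -t, -q
        pvec = X.T @ t / (t @ t)
        X -= np.outer(t, pvec)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t
    return PLSFit(W=W, P=P, Q=Q, T=T)


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    """A fitted PLS-DA model with its preprocessing constants and diagnostics.

    ``thresholds`` (per-class PV decision thresholds) are attached by the
    ROC stage; they are ``None`` until then.
    """

    class_labels: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    A: int
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    B: np.ndarray
    T: np.ndarray
    rmsecv_curve: np.ndarray | None = None
    q2_curve: np.ndarray | None = None
    q2: float | None = None
    cv_pv: np.ndarray | None = None
    thresholds: np.ndarray | None = None

    def to_json(self, path) -> None:
        doc = {
            "class_labels": list(self.class_labels),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean.tolist(),
            "A": int(self.A),
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "Q": self.Q.tolist(),
            "B": self.B.tolist(),
            "T": self.T.tolist(),
            "rmsecv_curve": None
            if self.rmsecv_curve is None
            else self.rmsecv_curve.tolist(),
            "q2_curve": None if self.q2_curve is None else self.q2_curve.tolist(),
            "q2": self.q2,
            "cv_pv": None if self.cv_pv is None else self.cv_pv.tolist(),
            "thresholds": None
            if self.thresholds is None
            else self.thresholds.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "PLSDAModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        arr = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(
            class_labels=tuple(doc["class_labels"]),
            x_mean=arr(doc["x_mean"]),
            x_sd=arr(doc["x_sd"]),
            y_mean=arr(doc["y_mean"]),
            A=int(doc["A"]),
            W=arr(doc["W"]),
            P=arr(doc["P"]),
            Q=arr(doc["Q"]),
            B=arr(doc["B"]),
            T=arr(doc["T"]),
            rmsecv_curve=arr(doc["rmsecv_curve"]),
            q2_curve=arr(doc["q2_curve"]),
            q2=doc["q2"],
            cv_pv=arr(doc["cv_pv"]),
            thresholds=arr(doc["thresholds"]),
        )


def predict_pv(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted values for new samples: autoscale with the stored training
    constants, apply B, add back the dummy-column means.  Unconstrained."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != len(model.x_mean):
        raise ValueError(
            f"expected (n, {len(model.x_mean)}) matrix, got {X_new.shape}"
        )
    Xs = autoscale_apply((model.x_mean, model.x_sd), X_new)
    return Xs @ model.B + model.y_mean


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVDiagnostics:
    """Leave-10%-out cross-validation results across candidate LV counts."""

    class_labels: tuple[str, ...]
    rmsecv: np.ndarray  # (A_max,)
    q2: np.ndarray  # (A_max,)
    cv_pv: np.ndarray  # (A_max, n, k) cross-validated predicted values
    Y: np.ndarray  # (n, k) true dummy matrix
    ss_total: float  # total SS of the centred dummy matrix
    fold_of: np.ndarray  # (n,) fold index per sample

    @property
    def a_max(self) -> int:
        return len(self.rmsecv)

    def cv_residuals(self, A: int) -> np.ndarray:
        return self.Y - self.cv_pv[A - 1]


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each sample to a fold, dealing shuffled class members round-
    robin from a random starting fold so folds are class-balanced."""
    fold_of = np.empty(len(labels), dtype=int)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        start = int(rng.integers(n_folds))
        for pos, i in enumerate(idx):
            fold_of[i] = (start + pos) % n_folds
    return fold_of


def cross_validate(
    X: np.ndarray,
    labels: Sequence[str],
    class_labels: Sequence[str] | None = None,
    a_max: int = 8,
    fold_fraction: float = 0.10,
    seed: int = 0,
) -> CVDiagnostics:
    """Seeded stratified leave-``fold_fraction``-out cross-validation.

    For each fold the retained samples are autoscaled and dummy-centred from
    scratch, a NIPALS model is fitted at ``a_max`` components, and the
    held-out samples are predicted at every A in 1..a_max.  Returns RMSEcv(A)
    = sqrt(PRESS(A)/(n k)) and Q2(A) = 1 - PRESS(A)/SS with SS the total sum
    of squares of the centred dummy matrix.

    A fold assignment that would strip an entire class from some training
    set is re-drawn (up to 100 attempts).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if n < 10:
        raise ValueError("cross-validation needs n >= 10")
    if class_labels is None:
        class_labels = tuple(sorted(set(labels)))
    class_labels = tuple(class_labels)
    k = len(class_labels)
    if k < 2:
        raise ValueError("classification needs at least 2 distinct classes")
    Y = dummy_encode(labels, class_labels)
    n_folds = math.ceil(1.0 / fold_fraction)
    rng = np.random.default_rng(seed)

    for _ in range(100):
        fold_of = _stratified_folds(labels, n_folds, rng)
        ok = True
        for f in range(n_folds):
            train_labels = set(labels[fold_of != f])
            if train_labels != set(class_labels):
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not build folds covering every class")

    cv_pv = np.zeros((a_max, n, k))
    for f in range(n_folds):
        test = np.flatnonzero(fold_of == f)
        if len(test) == 0:
            continue
        train = np.flatnonzero(fold_of != f)
        const = autoscale_fit(X[train])
        Xtr = autoscale_apply(const, X[train])
        ym = Y[train].mean(axis=0)
        fit = fit_pls2(Xtr, Y[train] - ym, a_max)
        Xte = autoscale_apply(const, X[test])
        for A in range(1, a_max + 1):
            cv_pv[A - 1, test] = Xte @ fit.coefficients(A) + ym

    ss_total = float(((Y - Y.mean(axis=0)) ** 2).sum())
    press = ((cv_pv - Y) ** 2).sum(axis=(1, 2))
    rmsecv = np.sqrt(press / (n * k))
    q2 = 1.0 - press / ss_total
    return CVDiagnostics(
        class_labels=class_labels,
        rmsecv=rmsecv,
        q2=q2,
        cv_pv=cv_pv,
        Y=Y,
        ss_total=ss_total,
        fold_of=fold_of,
    )


def select_components(diag: CVDiagnostics) -> int:
    """Smallest A attaining the minimum RMSEcv (ties break to fewer LVs)."""
    if diag.a_max == 0:
        raise ValueError("empty RMSEcv curve")
    return int(np.argmin(diag.rmsecv)) + 1


def fit_plsda(
    X: np.ndarray,
    labels: Sequence[str],
    class_labels: Sequence[str] | None = None,
    a_max: int = 8,
    fold_fraction: float = 0.10,
    seed: int = 0,
) -> PLSDAModel:
    """Cross-validate, pick A* by lowest RMSEcv, refit on all samples."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if class_labels is None:
        class_labels = tuple(sorted(set(labels)))
    class_labels = tuple(class_labels)
    diag = cross_validate(X, labels, class_labels, a_max, fold_fraction, seed)
    A = select_components(diag)
    const = autoscale_fit(X)
    Y = dummy_encode(labels, class_labels)
    ym = Y.mean(axis=0)
    fit = fit_pls2(autoscale_apply(const, X), Y - ym, A)
    return PLSDAModel(
        class_labels=class_labels,
        x_mean=const[0],
        x_sd=const[1],
        y_mean=ym,
        A=A,
        W=fit.W,
        P=fit.P,
        Q=fit.Q,
        B=fit.coefficients(),
        T=fit.T,
        rmsecv_curve=diag.rmsecv,
        q2_curve=diag.q2,
        q2=float(diag.q2[A - 1]),
        cv_pv=diag.cv_pv[A - 1],
    )


# ---------------------------------------------------------------------------
# overfitting diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    q2_original: float
    q2_permuted: list[float]
    overfit_suspect: bool = field(init=False)

    def __post_init__(self) -> None:
        self.overfit_suspect = not all(
            self.q2_original > q for q in self.q2_permuted
        )


def permutation_test(
    X: np.ndarray,
    labels: Sequence[str],
    A: int,
    n_perm: int = 20,
    seed: int = 0,
    class_labels: Sequence[str] | None = None,
    permutations: Sequence[np.ndarray] | None = None,
) -> PermutationResult:
    """Label-permutation overfitting check at a fixed A.

    Class labels are shuffled ``n_perm`` times and Q2 recomputed by the same
    cross-validation procedure.  The model is "not overfit" iff the original
    Q2 strictly exceeds every permuted Q2.  Explicit ``permutations`` may be
    supplied (e.g. to include the identity for testing).
    """
    labels = np.asarray(labels, dtype=object)
    if class_labels is None:
        class_labels = tuple(sorted(set(labels)))
    ss = np.random.SeedSequence(seed)
    cv_seed, perm_seed = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(2))
    q2_orig = float(
        cross_validate(X, labels, class_labels, a_max=A, seed=cv_seed).q2[A - 1]
    )
    rng = np.random.default_rng(perm_seed)
    if permutations is None:
        permutations = [rng.permutation(len(labels)) for _ in range(n_perm)]
    q2_perm = []
    for perm in permutations:
        q2_perm.append(
            float(
                cross_validate(
                    X, labels[np.asarray(perm)], class_labels, a_max=A, seed=cv_seed
                ).q2[A - 1]
            )
        )
    return PermutationResult(q2_original=q2_orig, q2_permuted=q2_perm)


def cv_anova(diag: CVDiagnostics, A: int) -> float:
    """F-test of cross-validated predictive residuals against the
    class-mean-only null model.

    SS_model is the PRESS of the PLS model at A; SS_null is the PRESS of
    predicting every dummy column by its mean.  Degrees of freedom: nk - k
    for the null (k column means) and nk - k(A + 1) for the model (the A
    latent variables add one fitted direction per dummy column each).
    Returns the upper-tail p of F = ((SS_null - SS_model)/(k A)) /
    (SS_model/df_model); a perfect model (SS_model = 0) returns p = 0.
    """
    n, k = diag.Y.shape
    ss_model = float(((diag.Y - diag.cv_pv[A - 1]) ** 2).sum())
    ss_null = diag.ss_total
    if ss_model == 0.0:
        return 0.0
    df_model = n * k - k * (A + 1)
    df_diff = k * A
    if df_model <= 0:
        raise ValueError("not enough residual degrees of freedom")
    f_stat = ((ss_null - ss_model) / df_diff) / (ss_model / df_model)
    return float(stats.f.sf(f_stat, df_diff, df_model))
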