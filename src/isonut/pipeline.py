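"""End-to-end validation pipeline for the multi-isotopic origin classifier.

The study design: optionally merge origin classes, split the dataset into
80% training / 20% validation per class (stratified down to the
(origin, harvest-year) cell so every populated cell is represented in both
sets), fit a PLS-DA model on the training set with leave-10%-out
cross-validation, calibrate per-class ROC thresholds on the cross-validated
predicted values, predict the held-out validation samples, and tabulate a
confusion table including the NO_CLASS rejection column.  The whole cycle
runs for a configurable number of iterations (seven by default) with
iteration seeds derived from a single root seed, and the report carries
mean +/- SD correct-classification rates over iterations.

Rate conventions: the per-class rate of one iteration is (diagonal count /
class n) * 100; the global rate is (sum of diagonal / total n) * 100.
Summary rates are means over per-iteration rates, not rates of mean counts
(the two differ and the former is what the summary table reports).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import NO_CLASS, IsotopeDataset
from .decision import DecisionRule, classify_matrix, fit_thresholds
from .plsda import (
    CVDiagnostics,
    PLSDAModel,
    autoscale_apply,
    autoscale_fit,
    cross_validate,
    dummy_encode,
    fit_pls2,
    predict_pv,
    select_components,
)

logger = logging.getLogger(__name__)

TRAIN_FRACTION = 0.8
N_ITERATIONS = 7
# fixed offsets for deriving per-iteration and per-stage seeds from the root
_SEED_STRIDE = 7919
_CV_OFFSET = 104_729
_MOD = 2**31


def merge_classes(dataset: IsotopeDataset, mapping: dict[str, str]) -> IsotopeDataset:
    """Relabel origins through *mapping* (e.g. ESP and ITA into one class).

    Marker values, sample ids and years are untouched; the mapping must
    cover every origin present."""
    missing = set(map(str, dataset.origins)) - set(mapping)
    if missing:
        raise ValueError(f"mapping does not cover origins: {sorted(missing)}")
    new_origins = np.array([mapping[str(o)] for o in dataset.origins], dtype=object)
    return IsotopeDataset(
        dataset.sample_ids.copy(),
        new_origins,
        dataset.harvest_years.copy(),
        dataset.X.copy(),
        dataset.marker_names,
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class SplitPlan:
    """One train/validation partition of a dataset."""

    iteration: int
    seed: int
    train_idx: np.ndarray
    val_idx: np.ndarray


def stratified_split(
    dataset: IsotopeDataset,
    train_fraction: float = TRAIN_FRACTION,
    seed: int = 0,
    iteration: int = 0,
) -> SplitPlan:
    """Per-class stratified split honouring (origin, year) cells.

    Each class contributes round(train_fraction * n_class) training samples
    (round half away from zero).  Within a class the training quota is
    apportioned over its (origin, year) cells by largest remainder, clamped
    so every cell with >= 2 samples appears in both sets; singleton cells go
    to training with a logged warning.  Deterministic in *seed*.
    """
    rng = np.random.default_rng(seed)
    train_parts: list[np.ndarray] = []
    val_parts: list[np.ndarray] = []
    for cls in dataset.class_labels:
        cls_mask = dataset.origins == cls
        n_cls = int(cls_mask.sum())
        if n_cls < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        target = _round_half_away(train_fraction * n_cls)
        years = sorted({int(y) for y in dataset.harvest_years[cls_mask]})
        cells = [
            np.flatnonzero(cls_mask & (dataset.harvest_years == y)) for y in years
        ]
        sizes = [len(c) for c in cells]
        quota = []
        for ci, sz in enumerate(sizes):
            t = _round_half_away(train_fraction * sz)
            if sz == 1:
                logger.warning(
                    "singleton cell (%s, %s): sample assigned to training",
                    cls, years[ci],
                )
                t = 1
            else:
                t = min(max(t, 1), sz - 1)
            quota.append(t)
        # largest-remainder adjustment to hit the class target exactly
        remainders = [train_fraction * sz - q for sz, q in zip(sizes, quota)]
        order_up = sorted(range(len(cells)), key=lambda i: (-remainders[i], i))
        order_dn = sorted(range(len(cells)), key=lambda i: (remainders[i], i))
        diff = target - sum(quota)
        pos = 0
        while diff > 0:
            i = order_up[pos % len(cells)]
            cap = sizes[i] - 1 if sizes[i] >= 2 else sizes[i]
            if quota[i] < cap:
                quota[i] += 1
                diff -= 1
            pos += 1
            if pos > 10 * len(cells) * max(sizes):
                raise RuntimeError("cell constraints unsatisfiable")
        pos = 0
        while diff < 0:
            i = order_dn[pos % len(cells)]
            if quota[i] > (1 if sizes[i] >= 2 else sizes[i]):
                quota[i] -= 1
                diff += 1
            pos += 1
            if pos > 10 * len(cells) * max(sizes):
                raise RuntimeError("cell constraints unsatisfiable")
        for cell, q in zip(cells, quota):
            perm = rng.permutation(cell)
            train_parts.append(perm[:q])
            val_parts.append(perm[q:])
    train_idx = np.sort(np.concatenate(train_parts))
    val_idx = np.sort(np.concatenate(val_parts)) if any(
        len(v) for v in val_parts
    ) else np.array([], dtype=int)
    return SplitPlan(iteration=iteration, seed=seed, train_idx=train_idx,
                     val_idx=val_idx)


# ---------------------------------------------------------------------------
# confusion bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ConfusionTable:
    """True classes x (predicted classes + NO_CLASS) counts."""

    class_labels: tuple[str, ...]
    counts: np.ndarray  # (k, k + 1); last column = NO_CLASS

    @classmethod
    def from_predictions(
        cls, true: np.ndarray, predicted: np.ndarray, class_labels
    ) -> "ConfusionTable":
        class_labels = tuple(class_labels)
        index = {c: j for j, c in enumerate(class_labels)}
        counts = np.zeros((len(class_labels), len(class_labels) + 1), dtype=int)
        for t, p in zip(true, predicted):
            row = index[str(t)]
            col = index.get(str(p), len(class_labels))
            counts[row, col] += 1
        return cls(class_labels, counts)

    @property
    def class_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def per_class_rates(self) -> np.ndarray:
        """Correct-classification % per true class."""
        return 100.0 * np.diag(self.counts[:, : len(self.class_labels)]) / self.class_sizes

    def global_rate(self) -> float:
        """Overall correct-classification %."""
        return 100.0 * float(
            np.trace(self.counts[:, : len(self.class_labels)])
        ) / float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.class_labels, name="true"),
            columns=list(self.class_labels) + [NO_CLASS],
        )


@dataclass
class IterationResult:
    """One train -> threshold -> predict cycle."""

    plan: SplitPlan
    model: PLSDAModel
    rule: DecisionRule
    confusion: ConfusionTable  # external validation
    internal_confusion: ConfusionTable  # CV predictions of the training set
    diagnostics: CVDiagnostics


def run_iteration(
    train: IsotopeDataset,
    val: IsotopeDataset,
    a_max: int = 8,
    seed: int = 0,
    plan: SplitPlan | None = None,
) -> IterationResult:
    """Fit on *train* (CV -> A* -> refit -> ROC thresholds), predict *val*."""
    class_labels = train.class_labels
    if set(val.class_labels) - set(class_labels):
        raise ValueError("validation set contains unseen classes")
    labels = train.origins.astype(object)
    diag = cross_validate(train.X, labels, class_labels, a_max=a_max, seed=seed)
    A = select_components(diag)
    const = autoscale_fit(train.X)
    Y = dummy_encode(labels, class_labels)
    ym = Y.mean(axis=0)
    fit = fit_pls2(autoscale_apply(const, train.X), Y - ym, A)
    model = PLSDAModel(
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
    rule = fit_thresholds(diag.cv_pv[A - 1], labels, class_labels)
    model.thresholds = rule.thresholds

    internal_pred = classify_matrix(diag.cv_pv[A - 1], rule)
    internal = ConfusionTable.from_predictions(labels, internal_pred, class_labels)
    val_pred = classify_matrix(predict_pv(model, val.X), rule)
    confusion = ConfusionTable.from_predictions(
        val.origins.astype(object), val_pred, class_labels
    )
    if plan is None:
        plan = SplitPlan(0, seed, np.arange(len(train)), np.array([], dtype=int))
    return IterationResult(plan, model, rule, confusion, internal, diag)


@dataclass
class ValidationReport:
    """Per-iteration confusions plus summary rates over iterations."""

    class_labels: tuple[str, ...]
    iterations: list[IterationResult]

    def _rates(self, which: str) -> np.ndarray:
        tables = [
            it.confusion if which == "external" else it.internal_confusion
            for it in self.iterations
        ]
        return np.vstack([t.per_class_rates() for t in tables])

    def per_class_mean_sd(self, which: str = "external") -> pd.DataFrame:
        r = self._rates(which)
        sd = r.std(axis=0, ddof=1) if len(r) > 1 else np.zeros(r.shape[1])
        return pd.DataFrame(
            {"class": self.class_labels, "mean_rate": r.mean(axis=0), "sd_rate": sd}
        )

    def global_rates(self, which: str = "external") -> np.ndarray:
        tables = [
            it.confusion if which == "external" else it.internal_confusion
            for it in self.iterations
        ]
        return np.array([t.global_rate() for t in tables])

    def global_mean_sd(self, which: str = "external") -> tuple[float, float]:
        g = self.global_rates(which)
        sd = float(g.std(ddof=1)) if len(g) > 1 else 0.0
        return float(g.mean()), sd

    def mean_diagnostics(self) -> dict[str, float]:
        return {
            "A": float(np.mean([it.model.A for it in self.iterations])),
            "q2": float(np.mean([it.model.q2 for it in self.iterations])),
            "rmsecv": float(
                np.mean(
                    [it.model.rmsecv_curve[it.model.A - 1] for it in self.iterations]
                )
            ),
        }


def run_study(
    dataset: IsotopeDataset,
    n_iterations: int = N_ITERATIONS,
    root_seed: int = 0,
    a_max: int = 8,
    train_fraction: float = TRAIN_FRACTION,
) -> ValidationReport:
    """The full repeated external validation.

    Iteration seeds are derived from *root_seed* by fixed offsets, so one
    number reproduces the whole report."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    iterations = []
    for i in range(n_iterations):
        split_seed = (root_seed + _SEED_STRIDE * (i + 1)) % _MOD
        cv_seed = (split_seed + _CV_OFFSET) % _MOD
        plan = stratified_split(dataset, train_fraction, seed=split_seed,
                                iteration=i + 1)
        train = dataset.subset(plan.train_idx)
        val = dataset.subset(plan.val_idx)
        iterations.append(run_iteration(train, val, a_max=a_max, seed=cv_seed,
                                        plan=plan))
        logger.info(
            "iteration %d: A*=%d, Q2=%.3f", i + 1,
            iterations[-1].model.A, iterations[-1].model.q2,
        )
    return ValidationReport(dataset.class_labels, iterations)


def report(vr: ValidationReport) -> tuple[str, pd.DataFrame]:
    """Summary-table layout: mean +/- SD counts per confusion cell and the
    per-class / global correct-classification rates.

    Per-class percentages are means of per-iteration rates; they are not
    recomputed from the mean counts (the two orderings differ)."""
    if not vr.iterations:
        raise ValueError("empty report")
    k = len(vr.class_labels)
    stack = np.stack([it.confusion.counts for it in vr.iterations])  # (iters,k,k+1)
    mean_counts = stack.mean(axis=0)
    sd_counts = stack.std(axis=0, ddof=1) if len(vr.iterations) > 1 else np.zeros_like(
        mean_counts, dtype=float
    )
    per_class = vr.per_class_mean_sd()
    g_mean, g_sd = vr.global_mean_sd()
    cols = list(vr.class_labels) + [NO_CLASS]
    rows = []
    for i, cls in enumerate(vr.class_labels):
        row = {"true": cls, "n": int(vr.iterations[0].confusion.class_sizes[i])}
        for j, col in enumerate(cols):
            row[f"{col}_mean"] = mean_counts[i, j]
            row[f"{col}_sd"] = sd_counts[i, j]
        row["correct_pct_mean"] = per_class["mean_rate"].iloc[i]
        row["correct_pct_sd"] = per_class["sd_rate"].iloc[i]
        rows.append(row)
    df = pd.DataFrame(rows)

    lines = ["External validation (mean ± SD over "
             f"{len(vr.iterations)} iterations)", ""]
    header = f"{'True':>10} {'n':>4}" + "".join(f"{c:>16}" for c in cols) + \
        f"{'Correct %':>16}"
    lines.append(header)
    for i, cls in enumerate(vr.class_labels):
        cells = "".join(
            f"{mean_counts[i, j]:>8.1f} ±{sd_counts[i, j]:>5.1f}"
            for j in range(k + 1)
        )
        lines.append(
            f"{cls:>10} {int(vr.iterations[0].confusion.class_sizes[i]):>4}"
            + cells
            + f"{per_class['mean_rate'].iloc[i]:>9.1f} ±{per_class['sd_rate'].iloc[i]:>5.1f}"
        )
    diag = vr.mean_diagnostics()
    lines.append(f"{'Total':>10} {int(stack[0].sum()):>4}" + " " * 16 * (k + 1)
                 + f"{g_mean:>9.1f} ±{g_sd:>5.1f}")
    lines.append("")
    lines.append(
        f"Mean training diagnostics: {diag['A']:.1f} LVs, "
        f"Q2 = {diag['q2']:.3f}, RMSEcv = {diag['rmsecv']:.3f}"
    )
    return "\n".join(lines), df


# ---------------------------------------------------------------------------
# exploratory PCA with outlier diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PCAExploration:
    scores: np.ndarray  # (n, A)
    explained_variance_fraction: np.ndarray  # (A,)
    t2: np.ndarray  # (n,) Hotelling T2
    t2_limit: float
    residual_ss: np.ndarray  # (n,) raw residual sum of squares
    residual_distance: np.ndarray  # (n,) normalised residual SD
    residual_limit: float
    outlier: np.ndarray = field(init=False)  # (n,) bool

    def __post_init__(self) -> None:
        self.outlier = (self.t2 > self.t2_limit) | (
            self.residual_distance > self.residual_limit
        )


def explore_pca(
    dataset: IsotopeDataset, n_components: int = 2, conf: float = 0.95
) -> PCAExploration:
    """PCA on autoscaled markers with Hotelling T2 and residual-distance
    outlier flags.

    T2 uses the F-distribution limit A(n^2-1)/(n(n-A)) F(conf; A, n-A).
    The residual distance is each sample's residual SD normalised by the
    pooled residual SD, with an approximate F-based limit.
    """
    n, p = dataset.X.shape
    A = int(n_components)
    if not 1 <= A < min(n, p + 1):
        raise ValueError("n_components must satisfy 1 <= A < n")
    const = autoscale_fit(dataset.X, dataset.marker_names)
    Xs = autoscale_apply(const, dataset.X)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :A] * s[:A]
    ev = s**2
    frac = ev[:A] / ev.sum()
    lam = s[:A] ** 2 / (n - 1)
    t2 = ((scores**2) / lam).sum(axis=1)
    t2_limit = (
        A * (n**2 - 1) / (n * (n - A)) * stats.f.ppf(conf, A, n - A)
    )
    E = Xs - scores @ Vt[:A]
    rss = (E**2).sum(axis=1)
    dof = p - A
    s_i = np.sqrt(rss / dof)
    pooled_dof = (n - A - 1) * dof
    s0 = np.sqrt(rss.sum() / pooled_dof)
    resid = s_i / s0 if s0 > 0 else np.zeros(n)
    resid_limit = (
        float(np.sqrt(stats.f.ppf(conf, dof, pooled_dof))) if s0 > 0 else np.inf
    )
    return PCAExploration(
        scores=scores,
        explained_variance_fraction=frac,
        t2=t2,
        t2_limit=float(t2_limit),
        residual_ss=rss,
        residual_distance=resid,
        residual_limit=resid_limit,
    )
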