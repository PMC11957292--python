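"""Correlation analysis and Mahalanobis-distance LDA/QDA discrimination.

Two cell populations (positive = the cancer-like class 1, negative = the
fibroblast-like class 2) are compared on motility-parameter tables:
Pearson correlations within each population, Welch two-sample tests per
parameter, and two-class discrimination.

The discriminant rule is nearest-class Mahalanobis distance:

    d_i^2(x) = (x - mean_i)^T  S_i^{-1}  (x - mean_i)

with a pooled covariance S = ((n1-1) S1 + (n2-1) S2) / (n1 + n2 - 2)
shared by both classes in LDA and class-specific S1, S2 in QDA. A point is
assigned to the class with the smaller squared distance; an exact tie goes
to the positive class. Equal priors, equal misclassification costs, no
log-determinant term (the rule is purely distance-based, so LDA and QDA
agree exactly whenever S1 = S2).

Performance is summarized by sensitivity tp/(tp+fn), specificity
tn/(tn+fp) and accuracy (tp+tn)/n, estimated by stratified 10-fold
cross-validation; an exhaustive search over the 45 unordered parameter
pairs ranks pairings by accuracy.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motility import PARAMETER_NAMES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- statistics


def pearson_corr(x, y) -> float:
    """Pearson correlation r = s_xy / (s_x s_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 2:
        raise ValueError("need >= 2 observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("undefined correlation: zero variance")
    sxy = np.cov(x, y, ddof=1)[0, 1]
    return float(sxy / (sx * sy))


def correlation_matrix(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-cell parameter values.

    Constant columns yield NaN entries (flagged with a log warning);
    the diagonal is 1 wherever the column is non-constant.
    """
    cols = columns if columns is not None else [c for c in PARAMETER_NAMES if c in table.columns]
    sub = table[cols].astype(float)
    constant = [c for c in cols if sub[c].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("constant columns flagged in correlation matrix: %s", constant)
    corr = sub.corr(method="pearson")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("degenerate: zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ------------------------------------------------------------- model objects


@dataclass
class DiscriminantModel:
    """Fitted class means and covariance structure for LDA or QDA."""

    kind: str  # "lda" | "qda"
    mean1: np.ndarray
    mean2: np.ndarray
    cov1: np.ndarray
    cov2: np.ndarray
    pooled_cov: np.ndarray | None
    n1: int
    n2: int
    parameter_names: list[str] = field(default_factory=list)

    def _covs(self) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "lda":
            return self.pooled_cov, self.pooled_cov
        return self.cov1, self.cov2

    def mahalanobis_sq(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Squared Mahalanobis distances (d1^2, d2^2) of points x to each class."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        c1, c2 = self._covs()
        d1 = _maha_sq(x, self.mean1, c1)
        d2 = _maha_sq(x, self.mean2, c2)
        return d1, d2

    def decision_values(self, x) -> np.ndarray:
        """d2^2 - d1^2: positive where x is nearer the positive class."""
        d1, d2 = self.mahalanobis_sq(x)
        return d2 - d1


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    accuracy: float


def _maha_sq(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    dev = x - mean
    sol = np.linalg.solve(cov, dev.T)
    return np.einsum("ij,ji->i", dev, sol)


def _check_classes(X1: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("classes must share the feature dimension")
    if X1.shape[0] < 3 or X2.shape[0] < 3:
        raise ValueError("need >= 3 observations per class")
    if np.isnan(X1).any() or np.isnan(X2).any():
        raise ValueError("missing values in fit data; drop incomplete rows first")
    return X1, X2


def _spd_check(cov: np.ndarray, what: str) -> None:
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"{what} covariance is singular or not positive definite; "
            "try a different parameter pair"
        ) from None


def fit_lda(
    X1, X2, parameter_names: list[str] | None = None
) -> DiscriminantModel:
    """Linear discriminant model: class means + pooled covariance.

    S = ((n1-1) S1 + (n2-1) S2) / (n1 + n2 - 2), with S_i the sample
    covariance (ddof=1) of class i.
    """
    X1, X2 = _check_classes(X1, X2)
    n1, n2 = X1.shape[0], X2.shape[0]
    S1 = np.cov(X1, rowvar=False, ddof=1)
    S2 = np.cov(X2, rowvar=False, ddof=1)
    S1, S2 = np.atleast_2d(S1), np.atleast_2d(S2)
    pooled = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    _spd_check(pooled, "pooled")
    return DiscriminantModel(
        kind="lda",
        mean1=X1.mean(axis=0),
        mean2=X2.mean(axis=0),
        cov1=S1,
        cov2=S2,
        pooled_cov=pooled,
        n1=n1,
        n2=n2,
        parameter_names=list(parameter_names or []),
    )


def fit_qda(
    X1, X2, parameter_names: list[str] | None = None
) -> DiscriminantModel:
    """Quadratic discriminant model: class means + class-specific covariances."""
    X1, X2 = _check_classes(X1, X2)
    n1, n2 = X1.shape[0], X2.shape[0]
    S1 = np.atleast_2d(np.cov(X1, rowvar=False, ddof=1))
    S2 = np.atleast_2d(np.cov(X2, rowvar=False, ddof=1))
    _spd_check(S1, "class-1")
    _spd_check(S2, "class-2")
    pooled = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    return DiscriminantModel(
        kind="qda",
        mean1=X1.mean(axis=0),
        mean2=X2.mean(axis=0),
        cov1=S1,
        cov2=S2,
        pooled_cov=pooled,
        n1=n1,
        n2=n2,
        parameter_names=list(parameter_names or []),
    )


def classify(model: DiscriminantModel, x) -> np.ndarray:
    """Assign each point to the nearest class (1 = positive, 2 = negative).

    An exact tie d1^2 = d2^2 is assigned positive.
    """
    d1, d2 = model.mahalanobis_sq(x)
    return np.where(d1 <= d2, 1, 2)


def confusion_metrics(predicted, actual) -> ConfusionMetrics:
    """Confusion counts and rates; labels are 1 (positive) / 2 (negative)."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    tp = int(np.sum((predicted == 1) & (actual == 1)))
    fp = int(np.sum((predicted == 1) & (actual == 2)))
    fn = int(np.sum((predicted == 2) & (actual == 1)))
    tn = int(np.sum((predicted == 2) & (actual == 2)))
    pos, neg = tp + fn, tn + fp
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=tp / pos if pos else float("nan"),
        specificity=tn / neg if neg else float("nan"),
        accuracy=(tp + tn) / predicted.size,
    )


# ------------------------------------------------------------ table handling


def _split_table(
    table: pd.DataFrame,
    columns: list[str],
    label_col: str = "label",
    positive: object = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix + 1/2 labels, dropping rows with missing chosen columns."""
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    sub = table[columns + [label_col]]
    complete = sub[columns].notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("dropped %d rows with missing values in %s", dropped, columns)
    sub = sub[complete]
    y = np.where(sub[label_col] == positive, 1, 2)
    X = sub[columns].to_numpy(dtype=float)
    return X[y == 1], X[y == 2], X, y


def kfold_cv(
    table: pd.DataFrame,
    columns: list[str],
    kind: str = "qda",
    k: int = 10,
    seed: int = 0,
    label_col: str = "label",
    positive: object = 1,
) -> ConfusionMetrics:
    """Stratified k-fold cross-validated confusion metrics.

    Folds come from a seeded stratified shuffle; each fold is evaluated on a
    model fitted to the other k-1 folds and the per-fold rates are averaged.
    Confusion counts are summed over folds for reference.
    """
    from sklearn.model_selection import StratifiedKFold

    X1, X2, X, y = _split_table(table, columns, label_col, positive)
    if min(len(X1), len(X2)) < k:
        raise ValueError(f"each class needs >= k={k} rows for {k}-fold CV")
    fitter = fit_lda if kind == "lda" else fit_qda
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    sens, spec, acc = [], [], []
    tp = fp = fn = tn = 0
    for train_idx, test_idx in skf.split(X, y):
        Xtr, ytr = X[train_idx], y[train_idx]
        model = fitter(Xtr[ytr == 1], Xtr[ytr == 2], columns)
        pred = classify(model, X[test_idx])
        m = confusion_metrics(pred, y[test_idx])
        sens.append(m.sensitivity)
        spec.append(m.specificity)
        acc.append(m.accuracy)
        tp += m.tp
        fp += m.fp
        fn += m.fn
        tn += m.tn
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=float(np.nanmean(sens)),
        specificity=float(np.nanmean(spec)),
        accuracy=float(np.mean(acc)),
    )


def pair_search(
    table: pd.DataFrame,
    kinds: tuple[str, ...] = ("lda", "qda"),
    columns: list[str] | None = None,
    include_singles: bool = False,
    k: int = 10,
    seed: int = 0,
    label_col: str = "label",
    positive: object = 1,
) -> pd.DataFrame:
    """Exhaustive parameter-pair ranking by cross-validated accuracy.

    Evaluates every unordered pair of the ten parameters (45 pairs) for
    each discriminant kind, ranked by accuracy, ties broken by sensitivity
    then the lexical pair name. Pairs whose fit fails (singular covariance)
    are skipped with a log message.
    """
    cols = columns if columns is not None else [c for c in PARAMETER_NAMES if c in table.columns]
    combos: list[tuple[str, ...]] = list(itertools.combinations(cols, 2))
    if include_singles:
        combos = [(c,) for c in cols] + combos
    rows = []
    for kind in kinds:
        for combo in combos:
            try:
                m = kfold_cv(table, list(combo), kind, k, seed, label_col, positive)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.info("skipping %s %s: %s", kind, combo, exc)
                continue
            rows.append(
                {
                    "kind": kind,
                    "parameters": " + ".join(combo),
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            by=["accuracy", "sensitivity", "parameters"],
            ascending=[False, False, True],
        ).reset_index(drop=True)
    return out


# ----------------------------------------------------- model/results facade


class DiscriminantAnalysis:
    """Two-class motility discriminant model on a labelled feature table.

    statsmodels-style facade: construct from data, call ``fit()``, inspect
    the returned :class:`DiscriminantResults`.

    Parameters
    ----------
    table : DataFrame with one row per cell, the motility parameters as
        columns, and a label column.
    columns : the parameters to use (a pair, typically).
    kind : "lda" or "qda".
    label_col, positive : how rows are labelled and which label is the
        positive (cancer-like) class.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        columns: list[str],
        kind: str = "qda",
        label_col: str = "label",
        positive: object = 1,
    ) -> None:
        if kind not in ("lda", "qda"):
            raise ValueError("kind must be 'lda' or 'qda'")
        self.table = table
        self.columns = list(columns)
        self.kind = kind
        self.label_col = label_col
        self.positive = positive

    @classmethod
    def from_profiles(
        cls, profiles_by_class: dict[object, list], columns: list[str], **kw
    ) -> "DiscriminantAnalysis":
        """Build from {label: [MotilityProfile, ...]} dictionaries."""
        frames = []
        for label, profs in profiles_by_class.items():
            df = pd.DataFrame([p.as_dict() for p in profs])
            df["label"] = label
            frames.append(df)
        return cls(pd.concat(frames, ignore_index=True), columns, **kw)

    def fit(self, cv_k: int = 10, cv_seed: int = 0) -> "DiscriminantResults":
        X1, X2, X, y = _split_table(
            self.table, self.columns, self.label_col, self.positive
        )
        fitter = fit_lda if self.kind == "lda" else fit_qda
        model = fitter(X1, X2, self.columns)
        resub = confusion_metrics(classify(model, X), y)
        cv = None
        if min(len(X1), len(X2)) >= cv_k:
            cv = kfold_cv(
                self.table, self.columns, self.kind, cv_k, cv_seed,
                self.label_col, self.positive,
            )
        return DiscriminantResults(self, model, resub, cv)


class DiscriminantResults:
    """Estimates and diagnostics of a fitted discriminant model."""

    def __init__(
        self,
        analysis: DiscriminantAnalysis,
        model: DiscriminantModel,
        resubstitution: ConfusionMetrics,
        cv: ConfusionMetrics | None,
    ) -> None:
        self.analysis = analysis
        self.model = model
        self.resubstitution = resubstitution
        self.cv = cv

    def predict(self, x) -> np.ndarray:
        return classify(self.model, x)

    def decision_boundary(
        self, x_range: tuple[float, float], n: int = 200, grid_n: int = 400
    ) -> np.ndarray:
        """Sample the d1^2 = d2^2 curve for a two-parameter model.

        Returns an (m, 2) polyline sampled on a grid over x_range x the
        observed range of the second parameter (for plotting the
        discrimination curve).
        """
        if len(self.analysis.columns) != 2:
            raise ValueError("boundary sampling needs a two-parameter model")
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        tab = self.analysis.table
        ycol = self.analysis.columns[1]
        yvals = tab[ycol].dropna()
        y_range = (float(yvals.min()), float(yvals.max()))
        xs = np.linspace(*x_range, grid_n)
        ys = np.linspace(*y_range, grid_n)
        XX, YY = np.meshgrid(xs, ys)
        ZZ = self.model.decision_values(
            np.column_stack([XX.ravel(), YY.ravel()])
        ).reshape(XX.shape)
        fig, ax = plt.subplots()
        cs = ax.contour(XX, YY, ZZ, levels=[0.0])
        segs = [s for p in cs.get_paths() for s in [p.vertices] if len(s)]
        plt.close(fig)
        if not segs:
            return np.empty((0, 2))
        poly = max(segs, key=len)
        if len(poly) > n:
            idx = np.linspace(0, len(poly) - 1, n).astype(int)
            poly = poly[idx]
        return poly

    def summary(self) -> str:
        a, m = self.analysis, self.model
        lines = [
            f"{m.kind.upper()} discriminant analysis",
            "=" * 46,
            f"parameters : {', '.join(a.columns)}",
            f"n positive : {m.n1}    n negative : {m.n2}",
            f"mean (pos) : {np.array2string(m.mean1, precision=4)}",
            f"mean (neg) : {np.array2string(m.mean2, precision=4)}",
        ]
        if m.kind == "lda":
            lines.append(
                f"pooled cov : {np.array2string(m.pooled_cov, precision=4)}"
            )
        else:
            lines.append(f"cov (pos)  : {np.array2string(m.cov1, precision=4)}")
            lines.append(f"cov (neg)  : {np.array2string(m.cov2, precision=4)}")
        r = self.resubstitution
        lines.append(
            "resubstitution  sens {:.1f}%  spec {:.1f}%  acc {:.1f}%".format(
                100 * r.sensitivity, 100 * r.specificity, 100 * r.accuracy
            )
        )
        if self.cv is not None:
            c = self.cv
            lines.append(
                "10-fold CV      sens {:.1f}%  spec {:.1f}%  acc {:.1f}%".format(
                    100 * c.sensitivity, 100 * c.specificity, 100 * c.accuracy
                )
            )
        return "\n".join(lines)
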