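"""Low/high-arousal classification benchmark.

SAM arousal scores are binarised at the scale midpoint (score >= 5 is
"high" on the 1–9 scale) and a fixed catalogue of 20 classifier
configurations — logistic regression, linear discriminant, two naive
Bayes variants, three decision trees, four ensembles, five KNNs and four
SVMs — is benchmarked per musical genre over repeated stratified
70/15/15 train/test/validation splits.  Reported accuracy comes from the
test partition; the validation partition is carved out to honour the
protocol but unused by default (no tuning is performed).

Feature standardisation and NaN-sentinel imputation use training-fold
statistics only, so no information leaks from test rows into the fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES
from .io import GENRE_STYLES, SAMResponse

logger = logging.getLogger(__name__)

SAM_SCALE = (1, 9)
DEFAULT_THRESHOLD = 5
SVM_MAX_ITER = 100_000  # the benchmark protocol's iteration cap (10^5)
SVM_TOL = 1e-3  # convergence ("MSE") criterion
N_ENSEMBLE_LEARNERS = 30
SUBSPACE_DIM = int(np.ceil(np.sqrt(len(FEATURE_NAMES))))  # 5 of 23


def binarize_sam(arousal: int, threshold: int = DEFAULT_THRESHOLD, scale=SAM_SCALE) -> int:
    """1 ("high") iff the SAM score is at or above the threshold."""
    lo, hi = scale
    if not lo <= arousal <= hi:
        raise ValueError(f"SAM score {arousal} outside scale [{lo}, {hi}]")
    return int(arousal >= threshold)


@dataclass(frozen=True)
class ClassifierSpec:
    """One catalogue entry: family, display name and hyperparameters."""

    family: str
    variant: str
    hyperparameters: dict = field(default_factory=dict, hash=False)

    @property
    def name(self) -> str:
        return f"{self.family}/{self.variant}"


class KernelNB(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel-density likelihoods.

    The non-Gaussian ("kernel distribution") naive Bayes variant: class-
    conditional densities are estimated per feature by a Gaussian KDE
    with Silverman bandwidth, and combined under the independence
    assumption.
    """

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.priors_ = {}
        self.kdes_ = {}
        for c in self.classes_:
            Xc = X[y == c]
            self.priors_[c] = Xc.shape[0] / X.shape[0]
            kdes = []
            for j in range(X.shape[1]):
                col = Xc[:, j]
                if np.ptp(col) == 0:  # degenerate: fall back to a tight Gaussian
                    kdes.append(("gauss", col.mean(), max(col.std(), 1e-6)))
                else:
                    kdes.append(("kde", gaussian_kde(col, bw_method="silverman"), None))
            self.kdes_[c] = kdes
        return self

    def _log_likelihood(self, X):
        X = np.asarray(X, float)
        ll = np.zeros((X.shape[0], self.classes_.size))
        for i, c in enumerate(self.classes_):
            ll[:, i] = np.log(self.priors_[c])
            for j, spec in enumerate(self.kdes_[c]):
                kind, a, b = spec
                if kind == "kde":
                    dens = a(X[:, j])
                else:
                    dens = np.exp(-0.5 * ((X[:, j] - a) / b) ** 2) / (b * np.sqrt(2 * np.pi))
                ll[:, i] += np.log(np.maximum(dens, 1e-300))
        return ll

    def predict(self, X):
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost with per-round random undersampling of the majority class.

    Each boosting round fits a shallow tree on a class-balanced random
    subsample drawn with the current boosting weights; weight updates
    follow discrete AdaBoost (SAMME) on the full training set.
    """

    def __init__(self, n_estimators: int = N_ENSEMBLE_LEARNERS, learning_rate: float = 0.1,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.unique(y)
        n = y.size
        w = np.full(n, 1.0 / n)
        self.estimators_: list = []
        self.alphas_: list[float] = []
        counts = {c: int((y == c).sum()) for c in self.classes_}
        n_min = min(counts.values())
        for _ in range(self.n_estimators):
            idx_parts = []
            for c in self.classes_:
                members = np.flatnonzero(y == c)
                p = w[members] / w[members].sum()
                take = min(n_min, members.size)
                idx_parts.append(rng.choice(members, size=take, replace=True, p=p))
            idx = np.concatenate(idx_parts)
            tree = DecisionTreeClassifier(
                max_depth=2, random_state=int(rng.integers(2**31 - 1))
            ).fit(X[idx], y[idx])
            pred = tree.predict(X)
            err = float(np.sum(w * (pred != y)))
            err = min(max(err, 1e-10), 1 - 1e-10)
            alpha = self.learning_rate * np.log((1 - err) / err)
            if alpha <= 0:  # worse than chance: skip round
                continue
            w *= np.exp(alpha * (pred != y))
            w /= w.sum()
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
        if not self.estimators_:  # degenerate: keep one stump
            self.estimators_ = [DecisionTreeClassifier(max_depth=1).fit(X, y)]
            self.alphas_ = [1.0]
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        votes = np.zeros((X.shape[0], self.classes_.size))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            pred = tree.predict(X)
            for i, c in enumerate(self.classes_):
                votes[:, i] += alpha * (pred == c)
        return self.classes_[np.argmax(votes, axis=1)]


def classifier_catalogue() -> list[ClassifierSpec]:
    """The fixed 20-entry classifier configuration catalogue."""
    specs = [
        ClassifierSpec("logistic", "logistic", {"max_iter": 1000, "penalty": None}),
        ClassifierSpec("linear_discriminant", "lda", {}),
        ClassifierSpec("naive_bayes", "gaussian", {}),
        ClassifierSpec("naive_bayes", "kernel", {}),
    ]
    for variant, splits in (("fine", 4), ("medium", 20), ("coarse", 100)):
        specs.append(ClassifierSpec("tree", variant, {"criterion": "gini", "max_splits": splits}))
    specs += [
        ClassifierSpec("ensemble", "boosted_trees",
                       {"n_estimators": N_ENSEMBLE_LEARNERS, "learning_rate": 0.1}),
        ClassifierSpec("ensemble", "bagged_trees", {"n_estimators": N_ENSEMBLE_LEARNERS}),
        ClassifierSpec("ensemble", "rus_boosted",
                       {"n_estimators": N_ENSEMBLE_LEARNERS, "learning_rate": 0.1}),
        ClassifierSpec("ensemble", "subspace_knn",
                       {"n_estimators": N_ENSEMBLE_LEARNERS, "max_features": SUBSPACE_DIM}),
    ]
    for variant, k, metric, weights in (
        ("fine", 2, "euclidean", "uniform"),
        ("medium", 10, "euclidean", "uniform"),
        ("coarse", 100, "euclidean", "uniform"),
        ("cosine", 10, "cosine", "uniform"),
        ("weighted", 10, "manhattan", "distance"),
    ):
        specs.append(ClassifierSpec(
            "knn", variant, {"n_neighbors": k, "metric": metric, "weights": weights}
        ))
    for variant, kernel, degree in (
        ("linear", "poly", 1), ("quadratic", "poly", 2), ("cubic", "poly", 3),
        ("rbf", "rbf", None),
    ):
        hp = {"kernel": kernel, "max_iterations": SVM_MAX_ITER, "tol": SVM_TOL}
        if degree is not None:
            hp["degree"] = degree
        specs.append(ClassifierSpec("svm", variant, hp))
    assert len(specs) == 20
    return specs


def instantiate(spec: ClassifierSpec, seed: int, n_train: int):
    """Build the sklearn (or in-package) estimator for a catalogue spec."""
    hp = spec.hyperparameters
    if spec.family == "logistic":
        # plain maximum-likelihood fit: the enumerated configuration has no
        # shrinkage penalty
        return LogisticRegression(
            penalty=hp.get("penalty"), max_iter=hp["max_iter"], random_state=seed
        )
    if spec.family == "linear_discriminant":
        return LinearDiscriminantAnalysis()
    if spec.family == "naive_bayes":
        return GaussianNB() if spec.variant == "gaussian" else KernelNB()
    if spec.family == "tree":
        # "max splits" (internal nodes) maps to max_leaf_nodes = splits + 1
        return DecisionTreeClassifier(
            criterion=hp["criterion"], max_leaf_nodes=hp["max_splits"] + 1,
            random_state=seed,
        )
    if spec.family == "ensemble":
        if spec.variant == "boosted_trees":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=2),
                n_estimators=hp["n_estimators"], learning_rate=hp["learning_rate"],
                random_state=seed,
            )
        if spec.variant == "bagged_trees":
            return BaggingClassifier(
                estimator=DecisionTreeClassifier(),
                n_estimators=hp["n_estimators"], random_state=seed,
            )
        if spec.variant == "rus_boosted":
            return RUSBoostClassifier(
                n_estimators=hp["n_estimators"], learning_rate=hp["learning_rate"],
                random_state=seed,
            )
        if spec.variant == "subspace_knn":
            return BaggingClassifier(
                estimator=KNeighborsClassifier(n_neighbors=min(10, max(1, n_train - 1))),
                n_estimators=hp["n_estimators"], max_features=hp["max_features"],
                bootstrap=False, random_state=seed,
            )
    if spec.family == "knn":
        k = hp["n_neighbors"]
        if k > n_train:
            logger.warning("knn/%s: n_neighbors %d > training fold %d; clamped",
                           spec.variant, k, n_train)
            k = n_train
        return KNeighborsClassifier(n_neighbors=k, metric=hp["metric"], weights=hp["weights"])
    if spec.family == "svm":
        kw = dict(kernel=hp["kernel"], max_iter=hp["max_iterations"], tol=hp["tol"],
                  random_state=seed)
        if "degree" in hp:
            # inhomogeneous polynomial kernel (1 + <x, x'>)^d; a pure even
            # kernel could not represent a linear boundary at degree 2
            kw.update(degree=hp["degree"], coef0=1.0)
        return SVC(**kw)
    raise ValueError(f"unknown spec {spec}")


def build_dataset(
    sheet: pd.DataFrame,
    sam: list[SAMResponse] | pd.DataFrame,
    genre: str,
    threshold: int = DEFAULT_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (X, y) for one genre: one row per participant x style segment.

    X holds the raw 23 features (standardisation happens inside the
    benchmark loop, per training fold); y is the binarised SAM label.
    """
    if isinstance(sam, list):
        sam = pd.DataFrame(
            [(r.participant_id, r.segment_label, r.arousal) for r in sam],
            columns=["participant_id", "segment_label", "arousal"],
        )
    sam = sam.assign(participant_id=sam.participant_id.astype(str))
    styles = GENRE_STYLES[genre]
    rows = sheet[sheet.segment_label.isin(styles)]
    merged = rows.merge(sam, on=["participant_id", "segment_label"], how="left")
    missing = merged[merged.arousal.isna()]
    if not missing.empty:
        pairs = [f"{r.participant_id}/{r.segment_label}" for r in missing.itertuples()]
        raise ValueError(f"missing SAM response for segment(s): {pairs}")
    X = merged[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = np.array([binarize_sam(int(a), threshold) for a in merged.arousal])
    if len(np.unique(y)) < 2:
        warnings.warn(f"genre {genre}: all labels identical after binarisation", stacklevel=2)
    return X, y


def _standardize_impute(X_train: np.ndarray, *others: np.ndarray):
    """Median-impute NaNs and z-score all matrices with train-fold statistics."""
    med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)

    def fill(A):
        A = A.copy()
        nan = ~np.isfinite(A)
        if nan.any():
            A[nan] = np.broadcast_to(med, A.shape)[nan]
        return A

    Xt = fill(X_train)
    mu = Xt.mean(axis=0)
    sd = Xt.std(axis=0)
    sd[sd == 0] = 1.0
    out = [(Xt - mu) / sd]
    for A in others:
        out.append((fill(A) - mu) / sd)
    return out


@dataclass
class BenchmarkResult:
    """Accuracy mean (SD) in percent per classifier for one dataset."""

    rows: pd.DataFrame  # family, variant, accuracy_mean, accuracy_sd
    n_iterations: int
    split: tuple[float, float, float]
    seed: int

    def accuracy(self, family: str, variant: str) -> float:
        m = self.rows[(self.rows.family == family) & (self.rows.variant == variant)]
        return float(m.accuracy_mean.iloc[0])


def run_benchmark(
    X: np.ndarray,
    y: np.ndarray,
    catalogue: list[ClassifierSpec] | None = None,
    n_iterations: int = 30,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> BenchmarkResult:
    """Repeated stratified-split benchmark of the catalogue on one dataset.

    Per iteration the data are split 70/15/15 (train/test/validation,
    stratified); each classifier is fit on the standardized training fold
    and scored on the test fold.  Accuracies are summarised as mean and
    SD over iterations, in percent.
    """
    if catalogue is None:
        catalogue = classifier_catalogue()
    if not np.isclose(sum(split), 1.0):
        raise ValueError(f"split {split} does not sum to 1")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    rng = np.random.default_rng(seed)
    acc = {spec.name: [] for spec in catalogue}
    for _ in range(n_iterations):
        for _attempt in range(10):
            s = int(rng.integers(2**31 - 1))
            # stratified when feasible; plain random otherwise (rare,
            # extremely imbalanced datasets)
            try:
                X_tr, X_rest, y_tr, y_rest = train_test_split(
                    X, y, train_size=split[0], stratify=y, random_state=s
                )
                X_te, X_va, y_te, y_va = train_test_split(
                    X_rest, y_rest, train_size=split[1] / (split[1] + split[2]),
                    stratify=y_rest, random_state=s,
                )
            except ValueError:
                X_tr, X_rest, y_tr, y_rest = train_test_split(
                    X, y, train_size=split[0], random_state=s
                )
                X_te, X_va, y_te, y_va = train_test_split(
                    X_rest, y_rest, train_size=split[1] / (split[1] + split[2]),
                    random_state=s,
                )
            if len(np.unique(y_tr)) == 2 and len(y_te) > 0:
                break
        else:
            raise RuntimeError("could not draw a split with both classes in training")
        X_tr_s, X_te_s = _standardize_impute(X_tr, X_te)
        for spec in catalogue:
            clf = instantiate(spec, seed=s, n_train=len(y_tr))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X_tr_s, y_tr)
                pred = clf.predict(X_te_s)
            acc[spec.name].append(float(np.mean(pred == y_te)))
    rows = []
    for spec in catalogue:
        a = 100.0 * np.asarray(acc[spec.name])
        rows.append(dict(
            family=spec.family, variant=spec.variant,
            accuracy_mean=a.mean(), accuracy_sd=a.std(ddof=1) if a.size > 1 else 0.0,
        ))
    return BenchmarkResult(
        rows=pd.DataFrame(rows), n_iterations=n_iterations, split=split, seed=seed
    )


def report_benchmark(results: dict[str, BenchmarkResult]) -> pd.DataFrame:
    """Combine per-genre results into one table (genre x classifier rows).

    The best variant within each family for each genre is marked; ties
    break to the first variant in catalogue order.
    """
    frames = []
    for genre, res in results.items():
        t = res.rows.copy()
        t.insert(0, "genre", genre)
        t["best_in_family"] = False
        for fam in t.family.unique():
            sub = t[t.family == fam]
            t.loc[sub.accuracy_mean.idxmax(), "best_in_family"] = True
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def format_benchmark(table: pd.DataFrame) -> str:
    """Human-readable rendering of the combined benchmark table."""
    lines = []
    for genre in table.genre.unique():
        lines.append(f"=== {genre} ===")
        sub = table[table.genre == genre]
        for r in sub.itertuples():
            star = " *" if r.best_in_family else ""
            lines.append(
                f"  {r.family:>20s}/{r.variant:<14s} {r.accuracy_mean:5.1f} ({r.accuracy_sd:4.1f}){star}"
            )
    return "\n".join(lines)
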