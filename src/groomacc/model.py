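"""Random-forest behaviour classification.

The model follows the standard supervised workflow for collar-mounted
accelerometry: the labelled per-second feature table is divided into a 70%
training and 30% validation set, stratified so that every (individual,
behaviour) cell keeps the same proportion (within 1%); a 500-tree random
forest (canonical defaults: bootstrap resampling per tree, sqrt(p) = 4
features per split, unlimited depth) is fitted on the training epochs; the
final label of an epoch is the majority vote across trees, ties broken by the
fixed alphabetical class order; performance is summarised by the 6x6
predicted-by-observed confusion matrix with per-class precision
TP/(TP+FP) and recall TP/(TP+FN).

Tree construction is delegated to scikit-learn; voting, splitting and the
evaluation statistics are implemented here so each step can be checked
against brute-force oracles.

The public surface is the pair :class:`BehaviourClassifier` (model, built
from a labelled feature table) and :class:`ClassifierResults` (estimates,
diagnostics and ``summary()``); the underlying operations are module-level
functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .types import BEHAVIOURS, FEATURE_COLUMNS, UNCLASSIFIED

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stratified split


@dataclass
class SplitResult:
    """A stratified train/validation division of a labelled feature table."""

    train: pd.DataFrame
    validation: pd.DataFrame
    cell_fractions: pd.DataFrame  # (individual, behaviour, n, train_fraction)

    @property
    def achieved_fraction(self) -> float:
        n = len(self.train) + len(self.validation)
        return len(self.train) / n if n else float("nan")


def stratified_split(
    labelled: pd.DataFrame,
    fraction: float = 0.7,
    seed: int = 0,
    label_col: str = "label",
    individual_col: str = "individual_id",
) -> SplitResult:
    """Divide epochs at random within every (individual, behaviour) cell.

    Largest-remainder rounding across cells makes the overall training size
    exactly round(N * fraction) while keeping every cell's achieved
    proportion as close to ``fraction`` as integer counts allow.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    is_state = labelled[label_col].astype(str).isin(BEHAVIOURS)
    if (~is_state).any():
        logger.warning("%d epochs with non-state labels excluded from the split",
                       int((~is_state).sum()))
    df = labelled.loc[is_state].reset_index(drop=True)

    cells = [((str(ind), str(beh)), idx.to_numpy())
             for (ind, beh), idx in df.groupby(
                 [individual_col, label_col], sort=True).groups.items()]
    total_target = int(round(len(df) * fraction))
    quotas = [(key, idx, len(idx) * fraction) for key, idx in cells]
    base = {key: int(np.floor(q)) for key, _, q in quotas}
    extras = total_target - sum(base.values())
    by_remainder = sorted(quotas, key=lambda t: (-(t[2] - np.floor(t[2])), t[0]))
    for key, _, _ in by_remainder[:max(extras, 0)]:
        base[key] += 1

    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    rows = []
    for key, idx, _ in quotas:
        k = min(base[key], len(idx))
        perm = rng.permutation(len(idx))
        train_idx.append(idx[perm[:k]])
        val_idx.append(idx[perm[k:]])
        rows.append({"individual_id": key[0], "behaviour": key[1],
                     "n": len(idx), "train_fraction": k / len(idx)})
    train = df.loc[np.sort(np.concatenate(train_idx))] if train_idx else df.iloc[:0]
    val = df.loc[np.sort(np.concatenate(val_idx))] if val_idx else df.iloc[:0]
    return SplitResult(train, val, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# forest training and prediction


@dataclass
class TrainedClassifier:
    """A fitted forest plus the metadata needed for reproducible prediction."""

    forest: RandomForestClassifier
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    n_trees: int
    seed: int
    n_train: int
    n_invalid_dropped: int = 0

    @property
    def importances(self) -> pd.Series:
        """Mean decrease in Gini impurity per feature, averaged over trees."""
        return pd.Series(self.forest.feature_importances_,
                         index=list(self.feature_names), name="gini_importance")


def train_forest(
    train: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    label_col: str = "label",
) -> TrainedClassifier:
    """Fit a random forest on the valid epochs of a labelled feature table."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    usable = train["valid"].to_numpy(bool) if "valid" in train else np.ones(len(train), bool)
    dropped = int((~usable).sum())
    if dropped:
        logger.warning("%d invalid epochs excluded from training", dropped)
    sub = train.loc[usable]
    X = sub[list(FEATURE_COLUMNS)].to_numpy(float)
    y = sub[label_col].astype(str).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two behaviours")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    return TrainedClassifier(forest, tuple(forest.classes_), FEATURE_COLUMNS,
                             n_trees, seed, len(sub), dropped)


def _check_schema(clf: TrainedClassifier, features: pd.DataFrame) -> None:
    missing = [c for c in clf.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")


def tree_votes(clf: TrainedClassifier, features: pd.DataFrame) -> np.ndarray:
    """Per-epoch vote counts over classes, shape (n_epochs, n_classes).

    Each of the forest's trees casts one hard vote per epoch.  Invalid
    epochs receive zero votes.
    """
    _check_schema(clf, features)
    X = features[list(clf.feature_names)].to_numpy(float)
    ok = ~np.isnan(X).any(axis=1)
    counts = np.zeros((len(X), len(clf.classes)), dtype=np.int32)
    if ok.any():
        per_tree = _tree_predictions(clf, X[ok])
        for c in range(len(clf.classes)):
            counts[ok, c] = (per_tree == c).sum(axis=0)
    return counts


def _tree_predictions(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Class-index predictions per tree, shape (n_trees, n_rows)."""
    return np.stack([est.predict(X).astype(np.intp) for est in clf.forest.estimators_])


def predict(clf: TrainedClassifier, features: pd.DataFrame) -> np.ndarray:
    """Majority-vote label per epoch; invalid epochs are unclassified.

    Vote ties are broken by the fixed alphabetical class order.
    """
    counts = tree_votes(clf, features)
    out = np.array([clf.classes[i] for i in counts.argmax(axis=1)], dtype=object)
    out[counts.sum(axis=1) == 0] = UNCLASSIFIED
    return out


# ---------------------------------------------------------------------------
# evaluation


def confusion(predicted: np.ndarray, observed: np.ndarray) -> pd.DataFrame:
    """6x6 predicted (rows) by observed (columns) epoch counts.

    Epochs predicted unclassified or observed outside the six states are
    excluded and counted in ``df.attrs["n_excluded"]``.
    """
    predicted = np.asarray(predicted, dtype=object)
    observed = np.asarray(observed, dtype=object)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed differ in length")
    keep = np.isin(predicted.astype(str), BEHAVIOURS) & np.isin(
        observed.astype(str), BEHAVIOURS)
    cm = pd.DataFrame(0, index=list(BEHAVIOURS), columns=list(BEHAVIOURS), dtype=int)
    pair_counts = pd.crosstab(pd.Series(predicted[keep], name="predicted"),
                              pd.Series(observed[keep], name="observed"))
    cm.loc[pair_counts.index, pair_counts.columns] += pair_counts
    cm.attrs["n_excluded"] = int((~keep).sum())
    return cm


def precision_recall(cm: pd.DataFrame) -> pd.DataFrame:
    """Per-class precision TP/(TP+FP) and recall TP/(TP+FN).

    Classes with a zero denominator are reported as NaN.
    """
    tp = np.diag(cm.to_numpy()).astype(float)
    row = cm.sum(axis=1).to_numpy(float)  # TP + FP (predicted totals)
    col = cm.sum(axis=0).to_numpy(float)  # TP + FN (observed totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(row > 0, tp / row, np.nan)
        rec = np.where(col > 0, tp / col, np.nan)
    return pd.DataFrame({"precision": prec, "recall": rec}, index=cm.index)


def importance_ranking(clf: TrainedClassifier) -> pd.Series:
    """Features by descending mean Gini decrease; ties broken by name."""
    imp = clf.importances
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return imp.loc[order]


def stability_curve(
    clf: TrainedClassifier,
    validation: pd.DataFrame,
    step: int = 25,
    label_col: str = "label",
) -> pd.DataFrame:
    """Validation error rate using only the first k trees, for growing k.

    Checkpoints at multiples of ``step`` plus the full forest; the error at
    k = n_trees equals the full-forest validation error exactly.
    """
    _check_schema(clf, validation)
    usable = validation["valid"].to_numpy(bool) if "valid" in validation \
        else np.ones(len(validation), bool)
    sub = validation.loc[usable]
    X = sub[list(clf.feature_names)].to_numpy(float)
    y = sub[label_col].astype(str).to_numpy()
    per_tree = _tree_predictions(clf, X)
    y_idx = np.array([clf.classes.index(b) if b in clf.classes else -1 for b in y])
    checkpoints = sorted(set(range(step, clf.n_trees + 1, step)) | {clf.n_trees})
    counts = np.zeros((len(X), len(clf.classes)), dtype=np.int32)
    rows, done = [], 0
    for k in checkpoints:
        for t in range(done, k):
            counts[np.arange(len(X)), per_tree[t]] += 1
        done = k
        err = float((counts.argmax(axis=1) != y_idx).mean())
        rows.append({"n_trees": k, "error_rate": err})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results objects


class BehaviourClassifier:
    """Random-forest behaviour model over a labelled per-second feature table.

    Parameters
    ----------
    labelled
        Feature table with the 16 feature columns, a ``label`` column of
        state behaviours, a boolean ``valid`` column and ``individual_id``.

    Examples
    --------
    >>> model = BehaviourClassifier.from_dataframe(table)   # doctest: +SKIP
    >>> res = model.fit(n_trees=500, seed=1)                # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
    """

    def __init__(self, labelled: pd.DataFrame, label_col: str = "label",
                 individual_col: str = "individual_id") -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in labelled.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        if label_col not in labelled.columns:
            raise ValueError(f"no label column {label_col!r}")
        self.data = labelled
        self.label_col = label_col
        self.individual_col = individual_col

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BehaviourClassifier":
        return cls(df, **kwargs)

    def fit(self, n_trees: int = 500, train_fraction: float = 0.7,
            seed: int = 0) -> "ClassifierResults":
        """Split, train and validate; returns the fitted results object."""
        split = stratified_split(self.data, train_fraction, seed,
                                 self.label_col, self.individual_col)
        clf = train_forest(split.train, n_trees, seed, self.label_col)
        pred = predict(clf, split.validation)
        obs = split.validation[self.label_col].astype(str).to_numpy()
        cm = confusion(pred, obs)
        return ClassifierResults(self, clf, split, cm)


@dataclass
class ClassifierResults:
    """Fitted forest, validation confusion matrix and derived diagnostics."""

    model: BehaviourClassifier
    classifier: TrainedClassifier
    split: SplitResult
    confusion_matrix: pd.DataFrame
    _pr: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def precision_recall(self) -> pd.DataFrame:
        if self._pr is None:
            self._pr = precision_recall(self.confusion_matrix)
        return self._pr

    @property
    def macro_precision(self) -> float:
        return float(self.precision_recall["precision"].mean())

    @property
    def macro_recall(self) -> float:
        return float(self.precision_recall["recall"].mean())

    @property
    def importances(self) -> pd.Series:
        return importance_ranking(self.classifier)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict(self.classifier, features)

    def stability_curve(self, step: int = 25) -> pd.DataFrame:
        return stability_curve(self.classifier, self.split.validation, step,
                               self.model.label_col)

    def summary(self) -> str:
        """Plain-text summary: fit metadata, per-class precision/recall,
        top feature importances."""
        from statsmodels.iolib.table import SimpleTable

        pr = self.precision_recall
        head = SimpleTable(
            [["trees", self.classifier.n_trees],
             ["training epochs", self.classifier.n_train],
             ["validation epochs", len(self.split.validation)],
             ["achieved train fraction", f"{self.split.achieved_fraction:.4f}"],
             ["macro precision", f"{self.macro_precision:.3f}"],
             ["macro recall", f"{self.macro_recall:.3f}"]],
            headers=["", ""], title="Behaviour classifier (random forest)")
        body = SimpleTable(
            [[b, f"{pr.loc[b, 'precision']:.3f}", f"{pr.loc[b, 'recall']:.3f}"]
             for b in pr.index],
            headers=["behaviour", "precision", "recall"])
        imp = self.importances.head(5)
        tail = SimpleTable([[f, f"{v:.4f}"] for f, v in imp.items()],
                           headers=["top features", "Gini importance"])
        return "\n".join([str(head), str(body), str(tail)])

    def plot_confusion(self, ax=None):
        """Heat map of the validation confusion matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cm = self.confusion_matrix
        ax.imshow(cm.to_numpy(), cmap="Blues")
        ax.set_xticks(range(len(cm.columns)), cm.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(cm.index)), cm.index)
        ax.set_xlabel("observed")
        ax.set_ylabel("predicted")
        return ax

    def plot_importances(self, ax=None):
        """Bar chart of features ranked by mean Gini decrease."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        imp = self.importances[::-1]
        ax.barh(range(len(imp)), imp.to_numpy())
        ax.set_yticks(range(len(imp)), imp.index)
        ax.set_xlabel("mean Gini decrease")
        return ax
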