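"""Grey/white-matter discrimination from polarimetric features.

Pipeline: balance the pixel table so every (specimen, class) cell has the
same count, run K-nearest-neighbors under leave-one-specimen-out
cross-validation (one fold per specimen, so the training fraction is
(k-1)/k), and report accuracy, true-GM rate, and true-WM rate per fold and
averaged.  Feature relevance is assessed two ways: permutation importance
(mean accuracy decrease over s random shuffles of one feature) and
sequential floating feature selection (forward or backward) with the
cross-validated KNN accuracy as objective.  Features are z-scored with a
scaler fitted on each fold's training split; without it the depolarization
(unitless, [0,1]) and retardance (radians, [0, pi]) scales would be
incommensurate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.stats import mannwhitneyu
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

#: Class labels; GM is the "positive" class of the confusion matrix.
CLASSES = ("GM", "WM")

#: Default neighbor counts per model family (single-wavelength, all-features,
#: selected-features), from the accuracy-vs-Kn sweep of the study protocol.
DEFAULT_KN = {"single": 50, "all": 8, "sf": 48}


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def balance(
    table: pd.DataFrame, seed: int | np.random.Generator = 0, max_per_cell: int | None = None
) -> pd.DataFrame:
    """Equalize (specimen x class) cell counts by uniform random removal.

    Every cell is downsampled to the global minimum cell count (optionally
    capped at ``max_per_cell`` to bound problem size).  Specimens missing a
    class are dropped with a warning-free removal (none occur in complete
    studies).  Deterministic under ``seed``; already-balanced input is
    returned unchanged up to row order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = table.groupby(["specimen", "class"], observed=True).size()
    complete = [
        s for s in table["specimen"].unique()
        if all((s, c) in counts.index for c in CLASSES)
    ]
    table = table[table["specimen"].isin(complete)]
    n = int(counts[counts.index.get_level_values("specimen").isin(complete)].min())
    if max_per_cell is not None:
        n = min(n, max_per_cell)
    parts = []
    for (_, _), grp in table.groupby(["specimen", "class"], observed=True):
        idx = rng.choice(len(grp), size=n, replace=False)
        parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_metrics(confusion: NDArray) -> dict[str, float]:
    """Accuracy and per-class true rates (percent) from a 2x2 confusion matrix.

    Layout: rows = predicted (GM, WM), columns = expected (GM, WM).
    true_gm_rate = TG / (TG + FW) (expected-GM column), true_wm_rate
    symmetric; zero denominators yield NaN.
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ValueError("confusion matrix must be 2x2 with nonnegative counts")
    tg, fg, fw, tw = c[0, 0], c[0, 1], c[1, 0], c[1, 1]
    total = c.sum()

    def _ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "accuracy": _ratio(tg + tw, total),
        "true_gm_rate": _ratio(tg, tg + fw),
        "true_wm_rate": _ratio(tw, tw + fg),
    }


def _confusion(y_true: NDArray, y_pred: NDArray) -> NDArray:
    """Confusion counts with rows = predicted, columns = expected."""
    c = np.zeros((2, 2))
    for i, pred in enumerate(CLASSES):
        for j, true in enumerate(CLASSES):
            c[i, j] = np.sum((y_pred == pred) & (y_true == true))
    return c


# ---------------------------------------------------------------------------
# leave-one-specimen-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class Fold:
    """One cross-validation fold (test set = all pixels of one specimen)."""

    specimen: object
    train_metrics: dict[str, float]
    test_metrics: dict[str, float]
    train_confusion: NDArray
    test_confusion: NDArray


@dataclass
class CVReport:
    """Per-fold and averaged leave-one-specimen-out results."""

    model: str
    kn: int
    features: list[str]
    folds: list[Fold] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD over folds, one row per (split, metric)."""
        rows = []
        for split in ("train", "test"):
            vals = {
                k: [getattr(f, f"{split}_metrics")[k] for f in self.folds]
                for k in ("accuracy", "true_gm_rate", "true_wm_rate")
            }
            for k, v in vals.items():
                rows.append(
                    {"model": self.model, "split": split, "metric": k,
                     "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
                )
        return pd.DataFrame(rows)

    def mean_test_accuracy(self) -> float:
        return float(np.mean([f.test_metrics["accuracy"] for f in self.folds]))

    @property
    def train_fraction(self) -> float:
        k = len(self.folds)
        return (k - 1) / k


def _fit_fold(
    train: pd.DataFrame, test: pd.DataFrame, features: list[str], kn: int, scale: bool
) -> tuple[KNeighborsClassifier, StandardScaler | None, NDArray, NDArray]:
    Xtr = train[features].to_numpy()
    Xte = test[features].to_numpy()
    scaler = None
    if scale:
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
    model = KNeighborsClassifier(n_neighbors=kn).fit(Xtr, train["class"].to_numpy())
    return model, scaler, Xtr, Xte


def losocv_knn(
    table: pd.DataFrame,
    features: list[str],
    kn: int,
    model_tag: str = "knn",
    scale: bool = True,
) -> CVReport:
    """Leave-one-specimen-out KNN cross-validation.

    One fold per specimen: the model is fitted on the remaining specimens
    and evaluated on the held-out one, preventing specimen leakage.
    """
    specimens = sorted(table["specimen"].unique())
    if len(specimens) < 2:
        raise ValueError("need at least two specimens for leave-one-out folds")
    report = CVReport(model_tag, kn, list(features))
    for sp in specimens:
        train = table[table["specimen"] != sp]
        test = table[table["specimen"] == sp]
        if kn > len(train):
            raise ValueError("Kn exceeds the training-set size")
        model, _, Xtr, Xte = _fit_fold(train, test, features, kn, scale)
        ctr = _confusion(train["class"].to_numpy(), model.predict(Xtr))
        cte = _confusion(test["class"].to_numpy(), model.predict(Xte))
        report.folds.append(
            Fold(sp, confusion_metrics(ctr), confusion_metrics(cte), ctr, cte)
        )
    return report


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(
    table: pd.DataFrame,
    features: list[str],
    kn: int,
    s: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> pd.DataFrame:
    """Mean test-accuracy decrease when one feature is shuffled.

    For every feature, fold, and one of ``s`` seeded shuffles, the feature
    column of the held-out specimen is permuted and the accuracy drop
    relative to the unshuffled baseline recorded; the table reports the mean
    and SD over folds x shuffles per feature.
    """
    if s < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    drops: dict[str, list[float]] = {f: [] for f in features}
    for sp in sorted(table["specimen"].unique()):
        train = table[table["specimen"] != sp]
        test = table[table["specimen"] == sp]
        model, scaler, _, Xte = _fit_fold(train, test, features, kn, scale)
        y_te = test["class"].to_numpy()
        base = confusion_metrics(_confusion(y_te, model.predict(Xte)))["accuracy"]
        for fi, feat in enumerate(features):
            for _ in range(s):
                Xs = Xte.copy()
                Xs[:, fi] = rng.permutation(Xs[:, fi])
                acc = confusion_metrics(_confusion(y_te, model.predict(Xs)))["accuracy"]
                drops[feat].append(base - acc)
    return pd.DataFrame(
        {
            "feature": features,
            "importance": [float(np.mean(drops[f])) for f in features],
            "sd": [float(np.std(drops[f], ddof=1)) for f in features],
        }
    ).sort_values("importance", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# sequential floating feature selection
# ---------------------------------------------------------------------------

def _train_accuracy(
    table: pd.DataFrame, features: list[str], kn: int, scale: bool
) -> float:
    """KNN accuracy on the data it was fitted on (default selection objective).

    For KNN this measures how pure the neighborhoods of the induced distance
    metric are, so it rewards subsets whose every dimension discriminates.
    """
    model, _, Xtr, _ = _fit_fold(table, table, features, min(kn, len(table)), scale)
    return confusion_metrics(
        _confusion(table["class"].to_numpy(), model.predict(Xtr))
    )["accuracy"]


def _inner_cv_accuracy(
    table: pd.DataFrame, features: list[str], kn: int, scale: bool
) -> float:
    """Leave-one-specimen-out accuracy (alternative selection objective)."""
    accs = []
    for sp in sorted(table["specimen"].unique()):
        train = table[table["specimen"] != sp]
        test = table[table["specimen"] == sp]
        k = min(kn, len(train))
        model, _, _, Xte = _fit_fold(train, test, features, k, scale)
        acc = confusion_metrics(
            _confusion(test["class"].to_numpy(), model.predict(Xte))
        )["accuracy"]
        accs.append(acc)
    return float(np.mean(accs))


def sequential_feature_selection(
    table: pd.DataFrame,
    features: list[str],
    n_select: int = 3,
    direction: str = "forward",
    kn: int = 8,
    scale: bool = True,
    objective: str = "train",
    max_rows_per_cell: int | None = 1000,
    seed: int = 0,
) -> list[str]:
    """Floating sequential feature selection (SFFS / SBFS).

    Forward: grow the subset to ``n_select``, after each inclusion trying a
    conditional exclusion that improves the objective.  Backward: shrink
    from the full set, after each exclusion trying a conditional
    re-inclusion.  Once a feature is removed it is never revisited.

    ``objective='train'`` (default) scores a subset by the KNN accuracy on
    the table it was fitted on, run fold-wise on each fold's training
    specimens; ``objective='cv'`` uses a nested leave-one-specimen-out
    accuracy instead.  For tractability the table may be subsampled per
    (specimen, class) cell.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if n_select > len(features):
        raise ValueError("cannot select more features than available")
    if objective not in ("train", "cv"):
        raise ValueError("objective must be 'train' or 'cv'")
    if max_rows_per_cell is not None:
        table = balance(table, seed=seed, max_per_cell=max_rows_per_cell)
    scorer = _train_accuracy if objective == "train" else _inner_cv_accuracy

    def score(subset: list[str]) -> float:
        return scorer(table, subset, kn, scale)

    removed: set[str] = set()
    if direction == "forward":
        selected: list[str] = []
        while len(selected) < n_select:
            pool = [f for f in features if f not in selected and f not in removed]
            gains = [(score(selected + [f]), f) for f in pool]
            best_score, best_f = max(gains)
            selected.append(best_f)
            # floating step: try dropping one previously selected feature
            if len(selected) > 2:
                drops = [
                    (score([g for g in selected if g != f]), f)
                    for f in selected[:-1]
                ]
                drop_score, drop_f = max(drops)
                if drop_score > best_score:
                    selected.remove(drop_f)
                    removed.add(drop_f)
        return selected

    selected = list(features)
    while len(selected) > n_select:
        drops = [(score([g for g in selected if g != f]), f) for f in selected]
        best_score, best_f = max(drops)
        selected.remove(best_f)
        removed.add(best_f)
        # floating step: try re-adding one feature never removed by choice
        if len(selected) < len(features) - 1:
            pool = [f for f in features if f not in selected and f not in removed]
            if pool:
                adds = [(score(selected + [f]), f) for f in pool]
                add_score, add_f = max(adds)
                if add_score > best_score and len(selected) + 1 <= len(features):
                    selected.append(add_f)
    return selected


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

def compare_distributions(gm_values, wm_values) -> dict[str, float]:
    """Two-sided Mann-Whitney U test of GM vs WM value distributions."""
    gm = np.asarray(gm_values, dtype=float)
    wm = np.asarray(wm_values, dtype=float)
    if gm.size == 0 or wm.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.all(gm == gm[0]) and np.all(wm == gm[0]):
        return {"U": float(gm.size * wm.size / 2.0), "p_value": 1.0}
    res = mannwhitneyu(gm, wm, alternative="two-sided")
    return {"U": float(res.statistic), "p_value": float(res.pvalue)}
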