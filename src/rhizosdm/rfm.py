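"""Per-genus random forests and Gini-gap predictor selection.

Presence/absence labels follow the co-report pseudo-absence rule: a row
of the curated frame (an occupied cell-month) is a presence for every
genus reported there and an absence for all other genera — if an
observer photographs one jellyfish they would have reported any other.
A shared 80/20 split feeds per-genus Gini forests; "relative importance"
is the mean decrease in Gini impurity, and the predictor subset is cut
at the largest importance gap (extended to the second-largest gap when
the largest would keep only one predictor).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .envpair import CuratedFrame, impute_for_model
from .fields import PREDICTORS

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class LabeledTable:
    """Feature matrix plus per-genus binary presence labels."""

    features: pd.DataFrame          # rows x 28 predictors (imputed)
    labels: pd.DataFrame            # rows x genera, values in {0, 1}
    imputed: pd.DataFrame           # audit: True where a feature was imputed

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")


@dataclasses.dataclass
class EvalResult:
    accuracy_pct: float
    specificity_pct: Optional[float]
    confusion: dict[str, int]


@dataclasses.dataclass
class RFResult:
    genus: str
    importance: pd.Series           # predictor -> mean decrease Gini
    test_accuracy: float            # percent
    test_specificity: Optional[float]
    selected: tuple[str, ...]
    split_seed: int
    n_trees: int
    confusion: dict[str, int] = dataclasses.field(default_factory=dict)


def build_labels(frame: CuratedFrame) -> LabeledTable:
    """Derive presence/absence labels from the curated frame's counts.

    Label 1 wherever a genus has a positive count, 0 otherwise; rows with
    no positive genus cannot exist by the frame's construction.
    """
    if len(frame.df) == 0:
        raise ValueError("empty curated frame")
    X, audit = impute_for_model(frame)
    labels = (frame.counts() > 0).astype(int)
    return LabeledTable(features=X.reset_index(drop=True),
                        labels=labels.reset_index(drop=True),
                        imputed=audit.reset_index(drop=True))


def split_80_20(
    table: LabeledTable, seed: int, test_fraction: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """One shared uniform train/test row split reused for every genus.

    Returns (train_idx, test_idx): a random permutation cut at
    ``1 - test_fraction``.  Sharing the partition across genera keeps the
    per-genus test folds comparable.
    """
    n = len(table.features)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_test = int(round(n * test_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError("split would leave an empty fold")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def train_rf(
    features: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    class_weight: Optional[str] = None,
) -> tuple[RandomForestClassifier, pd.Series]:
    """Fit a Gini-impurity classification forest; return it with importances.

    Importance is sklearn's impurity-based feature importance — the Gini
    impurity decrease attributable to each feature averaged over trees
    (normalized to sum to 1; a per-model constant scale that leaves gap
    ordering unchanged).
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: single class in training fold")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        random_state=seed,
        class_weight=class_weight,
        n_jobs=1,
    )
    model.fit(features.to_numpy(), y)
    importance = pd.Series(model.feature_importances_, index=features.columns)
    return model, importance


def evaluate_rf(
    model: RandomForestClassifier,
    features: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
) -> EvalResult:
    """Accuracy and specificity (percent) on a held-out fold.

    Specificity = TN / (TN + FP); with zero actual negatives it is
    undefined and reported as missing.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise ValueError("test fold is empty")
    pred = model.predict(features.to_numpy())
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    accuracy = 100.0 * (tp + tn) / len(y)
    negatives = tn + fp
    specificity = 100.0 * tn / negatives if negatives > 0 else None
    return EvalResult(accuracy_pct=accuracy, specificity_pct=specificity,
                      confusion={"TP": tp, "TN": tn, "FP": fp, "FN": fn})


def select_predictors(
    importance: Mapping[str, float] | pd.Series,
    canonical_order: Sequence[str] = PREDICTORS,
) -> tuple[str, ...]:
    """Cut the importance ranking at the largest gap between ordered values.

    Predictors are sorted by decreasing importance (ties broken by the
    canonical predictor order); consecutive gaps are computed and the cut
    is placed at the largest gap, keeping everything above it.  If that
    keeps exactly one predictor the rule is extended to the
    second-largest gap.  Gap ties break toward the earlier
    (larger-importance) position.  When no extension is possible (only
    two predictors, or all gaps tied at the top) the single top predictor
    is kept.
    """
    items = dict(importance)
    if len(items) < 2:
        raise ValueError("need at least 2 predictors with importance values")
    canon = {p: i for i, p in enumerate(canonical_order)}
    ordered = sorted(items, key=lambda p: (-items[p], canon.get(p, len(canon)), p))
    vals = np.array([items[p] for p in ordered], dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("importance values must be finite")
    gaps = vals[:-1] - vals[1:]
    best = int(np.argmax(gaps))            # argmax takes the earliest tie
    keep = best + 1
    if keep == 1 and len(gaps) > 1:
        rest = gaps[1:]
        second = 1 + int(np.argmax(rest))
        keep = second + 1
    return tuple(ordered[:keep])


def fit_genus_forests(
    table: LabeledTable,
    genera: Sequence[str],
    split_seed: int = 0,
    rf_seed: int = 0,
    n_trees: int = 500,
    test_fraction: float = 0.2,
    class_weight: Optional[str] = None,
) -> list[RFResult]:
    """Train/evaluate one forest per genus on the shared split.

    Genera whose training fold is single-class (too rare to model) are
    skipped with a warning.
    """
    train_idx, test_idx = split_80_20(table, split_seed, test_fraction)
    Xtr = table.features.iloc[train_idx]
    Xte = table.features.iloc[test_idx]
    results: list[RFResult] = []
    for gi, g in enumerate(genera):
        ytr = table.labels[g].to_numpy()[train_idx]
        yte = table.labels[g].to_numpy()[test_idx]
        if len(np.unique(ytr)) < 2:
            logger.warning("genus %s: single-class training labels, skipped", g)
            continue
        model, imp = train_rf(Xtr, ytr, n_trees=n_trees,
                              seed=rf_seed + gi, class_weight=class_weight)
        ev = evaluate_rf(model, Xte, yte)
        results.append(
            RFResult(
                genus=g,
                importance=imp,
                test_accuracy=ev.accuracy_pct,
                test_specificity=ev.specificity_pct,
                selected=select_predictors(imp),
                split_seed=split_seed,
                n_trees=n_trees,
                confusion=ev.confusion,
            )
        )
    return results
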