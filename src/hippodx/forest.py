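"""Supervised validation with a random-forest classifier.

The validation pipeline mirrors a standard morphometry workflow: regional
volumes are normalized to percent of intracranial volume (thickness passes
through unscaled, whole-brain "global" summaries and any asymmetry-derived
columns are excluded), then a random forest is assessed under Monte-Carlo
cross-validation (repeated stratified 80/20 shuffle-splits).  Progressive
feature elimination (PFE) repeatedly drops the feature with the lowest mean
Gini importance across the splits, tracing validation accuracy as a function
of feature count; the working feature count is the smallest one whose mean
accuracy is within one standard error of the best point (a deterministic
surrogate for picking the visual plateau).  A final, larger set of
shuffle-splits yields the mean accuracy, accumulated confusion matrix,
per-subject class probabilities, one-vs-rest ROC curves, and fold-wise Gini
importances normalized to the trivial level 1/N.

Forests grow fully (nodes split while they hold at least two samples and are
impure) with mtry = sqrt(current feature count), matching common practice
for small-sample morphometric cohorts.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedShuffleSplit

from . import roc as roc_mod
from .io import FeatureTable

TASKS = ("HC_vs_HS", "LHS_vs_RHS", "three_class")


@dataclass
class PFEConfig:
    """Sizes and seeds of the PFE + Monte-Carlo-cross-validation pipeline.

    ``n_trees`` is used for the final evaluation forests; ``n_trees_pfe``
    (defaulting to ``n_trees``) for the many forests inside the elimination
    loop, which is commonly run at a reduced tree count.  ``min_samples_split=2``
    encodes the grow-until-pure-or-<2-samples rule.
    """

    n_splits_pfe: int = 30
    train_fraction: float = 0.8
    n_trees: int = 2000
    n_trees_pfe: int | None = None
    n_splits_eval: int = 200
    seed: int = 0
    min_samples_split: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        for name in ("n_splits_pfe", "n_trees", "n_splits_eval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def pfe_trees(self) -> int:
        return self.n_trees if self.n_trees_pfe is None else self.n_trees_pfe


def _derive_seeds(master: int, salt: str, n: int) -> np.ndarray:
    """Deterministic per-fold seeds (< 2**31) from a master seed."""
    salt_int = int.from_bytes(hashlib.sha256(salt.encode()).digest()[:4], "big") % (2**31)
    ss = np.random.SeedSequence([master & 0x7FFFFFFF, salt_int])
    return ss.generate_state(n) % (2**31)


def _forest(n_trees: int, seed: int, min_samples_split: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        min_samples_split=min_samples_split,
        random_state=int(seed),
        n_jobs=1,
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_features(table: FeatureTable) -> tuple[pd.DataFrame, pd.Series]:
    """Model matrix for classification.

    Volume features become percent of TIV; thickness features pass through;
    whole-brain globals and asymmetry-derived columns are dropped (the
    forest sees both hemispheres, so laterality is represented implicitly).
    """
    if (table.tiv <= 0).any():
        raise ValueError("non-positive TIV")
    cols = {}
    for f in table.feature_names:
        kind, side = table.registry[f]
        if side == "global" or f.endswith("_asym") or f.endswith("_pct"):
            continue
        if kind == "volume":
            cols[f + "_pct"] = table.data[f].to_numpy() * 100.0 / table.tiv.to_numpy()
        else:
            cols[f] = table.data[f].to_numpy()
    X = pd.DataFrame(cols, index=table.data.index)
    return X, table.groups.copy()


# ---------------------------------------------------------------------------
# Progressive feature elimination
# ---------------------------------------------------------------------------

@dataclass
class PFECurve:
    """Accuracy-vs-feature-count curve and the elimination order."""

    n_features: np.ndarray          # ascending 1..P
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    elimination_order: list[str]    # worst-first; last entry survives longest
    n_splits: int
    selected_n: int | None = None

    def feature_ranking(self) -> list[str]:
        """Features best-first (reverse elimination order)."""
        return list(reversed(self.elimination_order))

    def selected_features(self, n: int | None = None) -> list[str]:
        n = self.selected_n if n is None else n
        if n is None:
            raise ValueError("no selected_n recorded; pass n explicitly")
        return self.feature_ranking()[:n]


def _splits(y: pd.Series, n_splits: int, train_fraction: float, seed: int):
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_fraction, random_state=int(seed)
    )
    return list(splitter.split(np.zeros((len(y), 1)), y))


def run_pfe(X: pd.DataFrame, y: pd.Series, config: PFEConfig) -> PFECurve:
    """Progressive feature elimination under Monte-Carlo cross-validation.

    The same stratified shuffle-splits are reused at every feature count.
    At each count, forests are fitted per split; validation accuracies are
    recorded and Gini importances are averaged across splits *before* the
    single least-important feature is dropped (ties go to the
    lexicographically first name).
    """
    y = pd.Series(y)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 members, got {counts.to_dict()}")

    splits = _splits(y, config.n_splits_pfe, config.train_fraction, config.seed)
    seeds = _derive_seeds(config.seed, "pfe", config.n_splits_pfe)
    yv = y.to_numpy()

    features = list(X.columns)
    ns, means, sds, order = [], [], [], []
    while features:
        Xv = X[features].to_numpy()
        accs = np.empty(len(splits))
        imps = np.zeros(len(features))
        for k, (tr, te) in enumerate(splits):
            rf = _forest(config.pfe_trees, seeds[k], config.min_samples_split)
            rf.fit(Xv[tr], yv[tr])
            accs[k] = rf.score(Xv[te], yv[te])
            imps += rf.feature_importances_
        imps /= len(splits)
        ns.append(len(features))
        means.append(accs.mean())
        sds.append(accs.std(ddof=1) if len(splits) > 1 else 0.0)
        if len(features) == 1:
            order.append(features[0])
            break
        # drop the lowest-mean-importance feature; ties lexicographic
        worst = min(zip(imps, features), key=lambda t: (t[0], t[1]))[1]
        order.append(worst)
        features.remove(worst)

    # recorded from P down to 1; store ascending
    return PFECurve(
        n_features=np.asarray(ns[::-1]),
        mean_accuracy=np.asarray(means[::-1]),
        sd_accuracy=np.asarray(sds[::-1]),
        elimination_order=order,
        n_splits=config.n_splits_pfe,
    )


def select_optimal_n(curve: PFECurve) -> int:
    """Smallest feature count within one SE of the best mean accuracy.

    The standard error is that of the best point over the Monte-Carlo
    splits.  A flat curve therefore selects a single feature; a strictly
    rising curve selects all of them.
    """
    if curve.n_features.size == 0:
        raise ValueError("empty curve")
    best = int(np.argmax(curve.mean_accuracy))
    se = curve.sd_accuracy[best] / np.sqrt(curve.n_splits)
    ok = curve.mean_accuracy >= curve.mean_accuracy[best] - se
    return int(curve.n_features[np.nonzero(ok)[0][0]])


# ---------------------------------------------------------------------------
# Final evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Accumulated Monte-Carlo evaluation of a fixed feature set."""

    task: str
    classes: list
    features: list[str]
    accuracies: np.ndarray
    confusion: pd.DataFrame                 # rows true, cols predicted; counts
    per_subject_prob: pd.DataFrame          # subjects x classes, NaN if never held out
    roc: dict                               # class -> ROCResult (one-vs-rest)
    importances: pd.DataFrame               # folds x features, normalized by 1/N

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def macro_auc(self) -> float:
        return float(np.mean([r.auc for r in self.roc.values()]))


def evaluate(
    X: pd.DataFrame,
    y: pd.Series,
    selected_features: list[str],
    config: PFEConfig,
    task: str = "",
) -> EvalReport:
    """Evaluate a feature subset over ``n_splits_eval`` shuffle-splits.

    Per split a fresh forest is fitted; accuracy is averaged, the confusion
    matrix accumulated over test folds, and each subject's class-probability
    vector is the mean of the forests' vote fractions over the folds where
    that subject was held out.  One-vs-rest ROC curves are computed on those
    averaged probabilities, and fold-wise Gini importances are reported
    relative to the trivial level 1/N (values > 1 mean more important than
    an average feature).
    """
    missing = set(selected_features) - set(X.columns)
    if missing:
        raise KeyError(f"unknown features: {sorted(missing)}")
    y = pd.Series(y)
    classes = sorted(y.unique())
    Xv = X[selected_features].to_numpy()
    yv = y.to_numpy()

    splits = _splits(y, config.n_splits_eval, config.train_fraction, config.seed)
    seeds = _derive_seeds(config.seed, "eval", config.n_splits_eval)

    n = len(y)
    accs = np.empty(len(splits))
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    prob_sum = np.zeros((n, len(classes)))
    prob_cnt = np.zeros(n, dtype=int)
    imps = np.empty((len(splits), len(selected_features)))

    for k, (tr, te) in enumerate(splits):
        rf = _forest(config.n_trees, seeds[k], config.min_samples_split)
        rf.fit(Xv[tr], yv[tr])
        pred = rf.predict(Xv[te])
        accs[k] = float((pred == yv[te]).mean())
        conf += confusion_matrix(yv[te], pred, labels=classes)
        proba = rf.predict_proba(Xv[te])
        col = [classes.index(c) for c in rf.classes_]
        prob_sum[np.ix_(te, col)] += proba
        prob_cnt[te] += 1
        imps[k] = rf.feature_importances_ * len(selected_features)

    never = prob_cnt == 0
    if never.any():
        warnings.warn(
            f"{int(never.sum())} subject(s) never held out across folds; "
            "their class probabilities are missing",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        probs = prob_sum / prob_cnt[:, None]

    prob_df = pd.DataFrame(probs, index=X.index, columns=classes)
    held = ~never
    rocs = {
        c: roc_mod.roc_points(
            prob_df.loc[held, c], (y[held] == c).astype(int), "higher_is_positive"
        )
        for c in classes
    }
    return EvalReport(
        task=task,
        classes=classes,
        features=list(selected_features),
        accuracies=accs,
        confusion=pd.DataFrame(conf, index=classes, columns=classes),
        per_subject_prob=prob_df,
        roc=rocs,
        importances=pd.DataFrame(imps, columns=selected_features),
    )


# ---------------------------------------------------------------------------
# Model / Results interface and the three standard tasks
# ---------------------------------------------------------------------------

@dataclass
class ForestValidationResults:
    """Fitted PFE + evaluation bundle for one classification task."""

    task: str
    pfe_curve: PFECurve
    selected_n: int
    selected_features: list[str]
    report: EvalReport

    @property
    def mean_accuracy(self) -> float:
        return self.report.mean_accuracy

    @property
    def macro_auc(self) -> float:
        return self.report.macro_auc

    def summary(self) -> str:
        lines = [
            f"Random-forest validation ({self.task})",
            f"  features in:      {int(self.pfe_curve.n_features.max())}",
            f"  selected N:       {self.selected_n}",
            f"  selected features: {', '.join(self.selected_features[:6])}"
            + (" ..." if len(self.selected_features) > 6 else ""),
            f"  mean accuracy:    {self.mean_accuracy:.3f}",
            f"  macro AUC (OvR):  {self.macro_auc:.3f}",
            "  confusion (rows true / cols predicted):",
        ]
        lines += ["    " + l for l in self.report.confusion.to_string().splitlines()]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "selected_n": self.selected_n,
            "selected_features": self.selected_features,
            "mean_accuracy": self.mean_accuracy,
            "macro_auc": self.macro_auc,
            "pfe_curve": {
                "n_features": self.pfe_curve.n_features.tolist(),
                "mean_accuracy": self.pfe_curve.mean_accuracy.tolist(),
                "sd_accuracy": self.pfe_curve.sd_accuracy.tolist(),
                "elimination_order": self.pfe_curve.elimination_order,
            },
            "confusion": {
                "classes": [str(c) for c in self.report.classes],
                "counts": self.report.confusion.to_numpy().tolist(),
            },
            "auc_per_class": {str(c): r.auc for c, r in self.report.roc.items()},
            "per_subject_prob": {
                str(s): [None if np.isnan(v) else float(v) for v in row]
                for s, row in self.report.per_subject_prob.iterrows()
            },
            "median_normalized_importance": self.report.importances.median().to_dict(),
        }


class ForestValidation:
    """Model object: PFE + selection + Monte-Carlo evaluation on (X, y).

    Construct from a raw feature matrix and labels, or from a
    :class:`FeatureTable` and a named task via :meth:`from_table`.
    ``fit()`` runs the whole pipeline and returns
    :class:`ForestValidationResults`.
    """

    def __init__(self, X: pd.DataFrame, y: pd.Series, config: PFEConfig | None = None,
                 task: str = "custom"):
        self.X = X
        self.y = pd.Series(y)
        self.config = config or PFEConfig()
        self.task = task

    @classmethod
    def from_table(cls, table: FeatureTable, task: str,
                   config: PFEConfig | None = None) -> "ForestValidation":
        if task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        for g in ("HC", "RHS", "LHS"):
            if not (table.groups == g).any():
                raise ValueError(f"group {g!r} absent from table")
        X, y = preprocess_features(table)
        if task == "HC_vs_HS":
            y = y.replace({"RHS": "HS", "LHS": "HS"})
        elif task == "LHS_vs_RHS":
            mask = y.isin(["LHS", "RHS"])
            X, y = X.loc[mask], y.loc[mask]
        return cls(X, y, config, task)

    def fit(self) -> ForestValidationResults:
        curve = run_pfe(self.X, self.y, self.config)
        n = select_optimal_n(curve)
        curve.selected_n = n
        feats = curve.selected_features(n)
        report = evaluate(self.X, self.y, feats, self.config, task=self.task)
        return ForestValidationResults(self.task, curve, n, feats, report)


def run_tasks(table: FeatureTable, config: PFEConfig | None = None) -> dict[str, ForestValidationResults]:
    """Run the three standard tasks: HC vs patients, left vs right HS, 3-class."""
    config = config or PFEConfig()
    out = {}
    for i, task in enumerate(TASKS):
        task_cfg = PFEConfig(**{**config.__dict__, "seed": int(_derive_seeds(config.seed, task, 1)[0])})
        out[task] = ForestValidation.from_table(table, task, task_cfg).fit()
    return out
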