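"""MLP classification of statistical cycles under patient-grouped evaluation.

The core object is :class:`CycleClassifier`, a model built from a feature
table (one row per statistical cycle: variance, skewness, kurtosis and
optionally the center statistic, plus subject and class label).  Its
``fit`` method runs either a subject-stratified 70/30 holdout or grouped
k-fold cross-validation (all cycles of one subject stay on one side of
every split, so no identity leakage) and returns a
:class:`ClassificationResults` carrying per-fold accuracy, sensitivity
and specificity, confusion totals, their mean ± standard deviation, and a
``summary()`` table.

The classifier is a small multi-layer perceptron (one hidden layer of 5,
10 or 100 neurons; two output classes) trained with log-loss.  The
default configuration is ReLU activation with the Adam optimizer,
learning rate 0.01, at most 1000 epochs and gradient tolerance 1e-4; a
sigmoid (logistic) + SGD variant is available through
:class:`MLPConfig`.  Features are standardized to zero mean and unit
variance using training-fold statistics only.

The epilepsy class is the positive class throughout: sensitivity is the
true-positive rate on epileptic cycles, specificity the true-negative
rate on healthy cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "MLPConfig",
    "SplitPlan",
    "FoldMetrics",
    "EvalReport",
    "make_patient_split",
    "grouped_kfold",
    "train_mlp",
    "evaluate",
    "CycleClassifier",
    "ClassificationResults",
    "run_experiment",
]

POSITIVE_CLASS = "epilepsy"
NEGATIVE_CLASS = "healthy"
FEATURES_3 = ["variance", "skewness", "kurtosis"]
FEATURES_4 = ["center", "variance", "skewness", "kurtosis"]


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the single-hidden-layer perceptron."""

    hidden_neurons: int = 5
    learning_rate: float = 0.01
    max_epochs: int = 1000
    tolerance: float = 1e-4
    activation: str = "relu"        # "relu" or "sigmoid"
    optimizer: str = "adam"         # "adam" or "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1:
            raise ValueError("hidden_neurons must be >= 1")
        if self.learning_rate <= 0 or self.max_epochs < 1 or self.tolerance <= 0:
            raise ValueError("invalid training hyperparameters")
        if self.activation not in ("relu", "sigmoid"):
            raise ValueError("activation must be 'relu' or 'sigmoid'")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level assignment to train/test or to folds.

    ``assignment`` maps subject_id to "train"/"test" (holdout) or to a
    fold index (k-fold, the fold in which the subject is *tested*).
    """

    assignment: dict
    k: int = 1

    def test_subjects(self, fold: int | str = "test") -> list:
        return sorted(s for s, v in self.assignment.items() if v == fold)


def _subject_table(subjects) -> pd.DataFrame:
    """Normalize to a DataFrame with subject_id, label[, sex]."""
    if isinstance(subjects, pd.DataFrame):
        df = subjects.copy()
    else:
        rows = []
        for item in subjects:
            if isinstance(item, (tuple, list)):
                row = {"subject_id": item[0], "label": item[1]}
                if len(item) > 2:
                    row["sex"] = item[2]
            else:
                row = {"subject_id": item, "label": "unknown"}
            rows.append(row)
        df = pd.DataFrame(rows)
    if df["subject_id"].duplicated().any():
        df = df.drop_duplicates("subject_id")
    return df.reset_index(drop=True)


def make_patient_split(subjects, train_fraction: float = 0.7, seed: int = 0) -> SplitPlan:
    """Subject-level holdout split, stratified by class (and sex if given).

    Within every stratum, ``floor(n * train_fraction)`` subjects go to the
    training side (e.g. 5 males at 0.7 -> 3 train + 2 test; 13 females ->
    9 train + 4 test).  Deterministic for a given seed.  A class with a
    single subject cannot be held out and raises.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    df = _subject_table(subjects)
    for label, grp in df.groupby("label"):
        if len(grp) < 2:
            raise ValueError(f"class {label!r} has a single subject; cannot hold out")
    rng = np.random.default_rng(seed)
    strata_cols = ["label"] + (["sex"] if "sex" in df.columns else [])
    assignment: dict = {}
    for _, grp in df.groupby(strata_cols, sort=True):
        ids = sorted(grp["subject_id"])
        rng.shuffle(ids)
        n_train = int(math.floor(len(ids) * train_fraction))
        n_train = min(max(n_train, 1), len(ids) - 1) if len(ids) > 1 else n_train
        for s in ids[:n_train]:
            assignment[s] = "train"
        for s in ids[n_train:]:
            assignment[s] = "test"
    return SplitPlan(assignment=assignment, k=1)


def grouped_kfold(subjects, k: int = 10, seed: int = 0) -> SplitPlan:
    """Subject-grouped k-fold plan, class-stratified, deterministic by seed.

    Subjects are shuffled within each class and dealt round-robin across
    folds, so every subject's cycles are tested in exactly one fold and
    trained on in the rest.  When there are fewer subjects than folds the
    effective number of folds is reduced to the subject count (a fold
    needs at least one whole test subject — subjects never straddle a
    split).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = _subject_table(subjects)
    k_eff = min(k, len(df))
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    offset = 0
    for _, grp in df.groupby("label", sort=True):
        ids = sorted(grp["subject_id"])
        rng.shuffle(ids)
        for i, s in enumerate(ids):
            assignment[s] = (i + offset) % k_eff
        offset += len(ids)
    return SplitPlan(assignment=assignment, k=k_eff)


def _build_mlp(cfg: MLPConfig) -> Pipeline:
    activation = "logistic" if cfg.activation == "sigmoid" else "relu"
    clf = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_neurons,),
        activation=activation,
        solver=cfg.optimizer,
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.max_epochs,
        tol=cfg.tolerance,
        random_state=cfg.seed,
        n_iter_no_change=10,
    )
    return Pipeline([("scale", StandardScaler()), ("mlp", clf)])


def _design(features: pd.DataFrame, columns: Sequence[str]):
    X = features[list(columns)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    y = features["label"].to_numpy()
    return X, y


def train_mlp(features: pd.DataFrame, cfg: MLPConfig | None = None,
              feature_columns: Sequence[str] = tuple(FEATURES_3)) -> Pipeline:
    """Fit the scaler+MLP pipeline on a feature table.

    Requires both classes present; reproducible for a fixed config seed.
    """
    cfg = cfg or MLPConfig()
    X, y = _design(features, feature_columns)
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = _build_mlp(cfg)
    import warnings
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    model.feature_columns_ = list(feature_columns)
    return model


@dataclass(frozen=True)
class FoldMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    tn: int
    fp: int
    fn: int


def _metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> FoldMetrics:
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return FoldMetrics(acc, sens, spec, tp, tn, fp, fn)


def evaluate(model: Pipeline, features: pd.DataFrame,
             positive_class: str = POSITIVE_CLASS) -> FoldMetrics:
    """Score a fitted model on a labelled feature table.

    Sensitivity = TP/(TP+FN) with the epilepsy class positive;
    specificity = TN/(TN+FP); an undefined metric (no positive or no
    negative instances) is reported as NaN, never as 0.
    """
    columns = getattr(model, "feature_columns_", FEATURES_3)
    X, y = _design(features, columns)
    pred = model.predict(X)
    tp = int(np.sum((y == positive_class) & (pred == positive_class)))
    fn = int(np.sum((y == positive_class) & (pred != positive_class)))
    fp = int(np.sum((y != positive_class) & (pred == positive_class)))
    tn = int(np.sum((y != positive_class) & (pred != positive_class)))
    return _metrics_from_confusion(tp, tn, fp, fn)


@dataclass(frozen=True)
class EvalReport:
    """Per-fold and aggregate accuracy/sensitivity/specificity."""

    per_fold: list
    mode: str
    center_kind: str
    hidden_neurons: int

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.per_fold], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(np.mean(vals)), float(np.std(vals))

    @property
    def accuracy(self) -> tuple[float, float]:
        return self._agg("accuracy")

    @property
    def sensitivity(self) -> tuple[float, float]:
        return self._agg("sensitivity")

    @property
    def specificity(self) -> tuple[float, float]:
        return self._agg("specificity")

    @property
    def confusion(self) -> dict:
        return {
            key: int(sum(getattr(f, key) for f in self.per_fold))
            for key in ("tp", "tn", "fp", "fn")
        }

    def format_metric(self, attr: str) -> str:
        m, s = self._agg(attr)
        return f"{m:.2f} ± {s:.2f}"

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "center_kind": self.center_kind,
            "hidden_neurons": self.hidden_neurons,
            "per_fold": [asdict(f) for f in self.per_fold],
            "aggregate": {
                "accuracy": dict(zip(("mean", "std"), self.accuracy)),
                "sensitivity": dict(zip(("mean", "std"), self.sensitivity)),
                "specificity": dict(zip(("mean", "std"), self.specificity)),
                "confusion": self.confusion,
            },
        }


class ClassificationResults:
    """Fit results: per-fold metrics, aggregates and a summary table."""

    def __init__(self, model: "CycleClassifier", report: EvalReport,
                 plan: SplitPlan, fitted_models: list):
        self.model = model
        self.report = report
        self.plan = plan
        self.fitted_models = fitted_models

    @property
    def per_fold(self) -> list:
        return self.report.per_fold

    @property
    def accuracy(self):
        return self.report.accuracy

    @property
    def sensitivity(self):
        return self.report.sensitivity

    @property
    def specificity(self):
        return self.report.specificity

    def summary(self) -> str:
        r = self.report
        lines = [
            "Statistical-cycle classification (MLP)",
            "=" * 54,
            f"center statistic:   {r.center_kind}",
            f"hidden neurons:     {r.hidden_neurons}",
            f"evaluation:         {r.mode} ({len(r.per_fold)} fold(s), subject-grouped)",
            f"cycles evaluated:   {sum(f.tp + f.tn + f.fp + f.fn for f in r.per_fold)}",
            "-" * 54,
            f"accuracy:           {r.format_metric('accuracy')}",
            f"sensitivity:        {r.format_metric('sensitivity')}",
            f"specificity:        {r.format_metric('specificity')}",
            "-" * 54,
            "confusion totals:   "
            + ", ".join(f"{k.upper()}={v}" for k, v in r.confusion.items()),
        ]
        return "\n".join(lines)

    def plot_metrics(self, ax=None):
        """Bar chart of mean metrics with per-fold standard deviation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3))
        names = ["accuracy", "sensitivity", "specificity"]
        means = [self.report._agg(n)[0] for n in names]
        stds = [self.report._agg(n)[1] for n in names]
        ax.bar(names, means, yerr=stds, capsize=4, color="#4878a8")
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("metric")
        ax.set_title(
            f"{self.report.center_kind}-centered features, "
            f"h={self.report.hidden_neurons}"
        )
        return ax


class CycleClassifier:
    """Model object: an MLP over a per-cycle feature table.

    Parameters
    ----------
    features : DataFrame
        One row per statistical cycle with columns ``subject_id``,
        ``label``, ``variance``, ``skewness``, ``kurtosis`` (and
        ``center`` when a 4-input network is requested).
    config : MLPConfig
    n_inputs : {3, 4}
        3 uses variance/skewness/kurtosis; 4 adds the center statistic.
    """

    def __init__(self, features: pd.DataFrame, config: MLPConfig | None = None,
                 n_inputs: int = 3):
        required = {"subject_id", "label"} | set(FEATURES_3)
        missing = required - set(features.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        if n_inputs not in (3, 4):
            raise ValueError("n_inputs must be 3 or 4")
        if n_inputs == 4 and "center" not in features.columns:
            raise ValueError("4-input network requires a 'center' column")
        labels = set(features["label"])
        if not labels <= {POSITIVE_CLASS, NEGATIVE_CLASS}:
            raise ValueError(f"unexpected labels {labels}")
        self.features = features.reset_index(drop=True)
        self.config = config or MLPConfig()
        self.columns = FEATURES_4 if n_inputs == 4 else FEATURES_3
        self.center_kind = (
            features["center_kind"].iloc[0] if "center_kind" in features.columns else "unknown"
        )

    @classmethod
    def from_cycle_features(cls, feature_sets: Iterable, config: MLPConfig | None = None,
                            n_inputs: int = 3) -> "CycleClassifier":
        """Build from :class:`~cardiocycle.features.CycleFeatures` objects."""
        df = pd.concat([f.to_dataframe() for f in feature_sets], ignore_index=True)
        return cls(df, config=config, n_inputs=n_inputs)

    def _subjects(self) -> pd.DataFrame:
        return (
            self.features[["subject_id", "label"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def fit(self, mode: str = "cv", k: int = 10, seed: int = 0,
            train_fraction: float = 0.7,
            plan: Optional[SplitPlan] = None) -> ClassificationResults:
        """Run grouped cross-validation ("cv") or a 70/30 holdout ("holdout").

        A precomputed ``plan`` may be supplied to evaluate different
        feature sets on identical folds (paired comparison).
        """
        if mode not in ("cv", "holdout"):
            raise ValueError("mode must be 'cv' or 'holdout'")
        if set(self.features["label"]) != {POSITIVE_CLASS, NEGATIVE_CLASS}:
            raise ValueError("both classes must be present to fit")
        subjects = self._subjects()
        if plan is None:
            if mode == "cv":
                plan = grouped_kfold(subjects, k=k, seed=seed)
            else:
                plan = make_patient_split(subjects, train_fraction=train_fraction, seed=seed)
        folds = range(plan.k) if mode == "cv" else ["test"]
        per_fold = []
        fitted = []
        subj = self.features["subject_id"]
        for fold in folds:
            if mode == "cv":
                test_ids = {s for s, v in plan.assignment.items() if v == fold}
            else:
                test_ids = {s for s, v in plan.assignment.items() if v == "test"}
            test_mask = subj.isin(test_ids).to_numpy()
            train_df = self.features[~test_mask]
            test_df = self.features[test_mask]
            assert not (set(train_df["subject_id"]) & set(test_df["subject_id"])), \
                "subject leakage across a train/test split"
            model = train_mlp(train_df, self.config, feature_columns=self.columns)
            per_fold.append(evaluate(model, test_df))
            fitted.append(model)
        report = EvalReport(
            per_fold=per_fold,
            mode=mode,
            center_kind=self.center_kind,
            hidden_neurons=self.config.hidden_neurons,
        )
        return ClassificationResults(self, report, plan, fitted)


def run_experiment(feature_sets: Iterable, config: MLPConfig | None = None,
                   mode: str = "cv", k: int = 10, seed: int = 0,
                   n_inputs: int = 3,
                   plan: Optional[SplitPlan] = None) -> ClassificationResults:
    """Functional wrapper: build a :class:`CycleClassifier` and fit it."""
    model = CycleClassifier.from_cycle_features(feature_sets, config=config, n_inputs=n_inputs)
    return model.fit(mode=mode, k=k, seed=seed, plan=plan)
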