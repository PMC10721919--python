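"""Feature-table assembly, correlation pruning, the four classification
tasks, and permutation feature importance.

The classification study asks four questions of each papilla segment: its
type (fungiform / filiform / none), and the gender, age group and identity
of the participant it came from.  Models are deliberately simple (RBF-kernel
SVM and logistic regression at library default hyperparameters) evaluated
by balanced accuracy over repeated stratified 80/20 splits, or leave-one-
group-out folds where each fold's test set is one whole participant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.exceptions import UndefinedMetricWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import LeaveOneGroupOut, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .geometry import (BASELINE_FEATURE_NAMES, CURVATURE_FEATURE_NAMES,
                       geometric_feature_vector)
from .meshes import DegenerateInputError
from .synthesis import rng_stream
from .topology import TOPO_FEATURE_NAMES, TopoConfig, topo_feature_vector

log = logging.getLogger("tonguetopo")

CORRELATION_THRESHOLD = 0.65
N_RANDOM_SPLITS = 50
TEST_FRACTION = 0.2
N_PERMUTATIONS = 30

FAMILIES = {
    "baseline": list(BASELINE_FEATURE_NAMES),
    "curvature": list(CURVATURE_FEATURE_NAMES),
    "topological": list(TOPO_FEATURE_NAMES),
}
LABEL_COLUMNS = ["type", "participant", "gender", "age", "age_group"]
TASK_LABELS = {"type": "type", "gender": "gender", "age": "age_group",
               "participant": "participant"}


@dataclass
class FeatureTable:
    """One row per segment: feature columns + label columns, with a
    family tag per feature column."""

    df: pd.DataFrame
    families: dict          # feature column -> family name
    #: positions of the source segments that survived assembly (row-aligned)
    segment_indices: list = field(default_factory=list)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.df.columns if c in self.families]

    def family_columns(self, family: str) -> list[str]:
        if family == "all":
            return self.feature_columns
        cols = [c for c in self.feature_columns if self.families[c] == family]
        if not cols:
            raise ValueError(f"no columns for family {family!r}")
        return cols

    def to_csv(self, path) -> None:
        header = self.df.copy()
        header.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        fams = {c: f for f, cols in FAMILIES.items() for c in cols if c in df.columns}
        return cls(df, fams)


def assemble_features(segments, topo_config: TopoConfig | None = None,
                      seed: int = 0,
                      ransac_inlier_threshold: float | None = None) -> FeatureTable:
    """Run the geometric and topological feature extractors on every
    labelled segment and return the joined table in fixed column order.
    Segments where extraction fails are dropped with a warning."""
    rows = []
    kept = []
    for i, seg in enumerate(segments):
        try:
            geo = geometric_feature_vector(
                seg.patch, seg.m_point,
                inlier_threshold=ransac_inlier_threshold,
                rng=rng_stream(seed, "features", f"geo{i}"))
            topo = topo_feature_vector(
                seg.points(), topo_config,
                rng=rng_stream(seed, "features", f"topo{i}"))
        except (DegenerateInputError, ValueError) as exc:
            log.warning("segment %d dropped: %s", i, exc)
            continue
        row = {**geo.as_dict(), **topo,
               "type": seg.label,
               "participant": seg.metadata.get("participant", "unknown"),
               "gender": seg.metadata.get("gender", "unknown"),
               "age": seg.metadata.get("age", np.nan),
               "age_group": seg.metadata.get("age_group", "unknown")}
        rows.append(row)
        kept.append(i)
    order = (BASELINE_FEATURE_NAMES + CURVATURE_FEATURE_NAMES
             + TOPO_FEATURE_NAMES + LABEL_COLUMNS)
    df = pd.DataFrame(rows, columns=order)
    fams = {c: f for f, cols in FAMILIES.items() for c in cols}
    return FeatureTable(df, fams, kept)


def prune_correlated(table: FeatureTable,
                     threshold: float = CORRELATION_THRESHOLD):
    """Greedy correlation pruning: walk feature pairs in canonical column
    order and drop the later column of any pair with |Pearson r| above the
    threshold.  Returns (pruned table, removal log)."""
    cols = table.feature_columns
    if len(cols) < 2:
        raise ValueError("pruning needs at least 2 feature columns")
    corr = table.df[cols].corr().abs().to_numpy()
    keep = np.ones(len(cols), dtype=bool)
    removals = []
    for i in range(len(cols)):
        if not keep[i]:
            continue
        for j in range(i + 1, len(cols)):
            if keep[j] and corr[i, j] > threshold:
                keep[j] = False
                removals.append((cols[j], cols[i], float(corr[i, j])))
    kept_cols = [c for c, k in zip(cols, keep) if k]
    df = table.df[kept_cols + [c for c in LABEL_COLUMNS if c in table.df.columns]]
    fams = {c: table.families[c] for c in kept_cols}
    for removed, because_of, r in removals:
        log.info("pruned %s (|r|=%.3f with %s)", removed, r, because_of)
    return FeatureTable(df.copy(), fams), removals


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def make_model(model: str) -> Pipeline:
    """SVM-RBF or logistic regression at default hyperparameters, behind a
    train-split-fit z-score standardizer."""
    if model == "svm":
        clf = SVC(kernel="rbf", C=1.0, gamma="scale")
    elif model == "lr":
        clf = LogisticRegression(C=1.0, max_iter=5000)
    else:
        raise ValueError(f"unknown model {model!r} (use 'svm' or 'lr')")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class ClassificationReport:
    task: str
    family: str
    model: str
    scheme: str
    scores: np.ndarray
    confusion: np.ndarray
    classes: list
    best_split: tuple | None = None     # (train_idx, test_idx) of best split

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1)) if len(self.scores) > 1 else 0.0

    def summary(self) -> dict:
        return {"task": self.task, "family": self.family, "model": self.model,
                "scheme": self.scheme, "balanced_accuracy_mean": self.mean,
                "balanced_accuracy_sd": self.sd, "n_splits": len(self.scores)}


def evaluate_task(table: FeatureTable, task: str, family: str = "all",
                  model: str = "svm", scheme: str = "random", seed: int = 0,
                  n_splits: int = N_RANDOM_SPLITS,
                  test_size: float = TEST_FRACTION) -> ClassificationReport:
    """Balanced accuracy of one (task, feature family, model) combination.

    ``scheme='random'``: ``n_splits`` stratified 80/20 splits.
    ``scheme='logo'``: leave-one-participant-out folds (test = one whole
    participant); unavailable for the participant task itself.
    """
    label = TASK_LABELS[task]
    y = table.df[label].to_numpy()
    X = table.df[table.family_columns(family)].to_numpy(dtype=np.float64)
    classes = sorted(pd.unique(y))
    pipe = make_model(model)
    scores = []
    conf = np.zeros((len(classes), len(classes)), dtype=np.int64)
    best = (-np.inf, None)

    if scheme == "random":
        splitter = StratifiedShuffleSplit(
            n_splits=n_splits, test_size=test_size,
            random_state=int(rng_stream(seed, "splits", task, family, model)
                             .integers(2 ** 31)))
        folds = splitter.split(X, y)
    elif scheme == "logo":
        if task == "participant":
            raise ValueError("LOGO is degenerate for the participant task")
        groups = table.df["participant"].to_numpy()
        if len(pd.unique(groups)) < 2:
            raise ValueError("LOGO needs at least 2 participants")
        folds = LeaveOneGroupOut().split(X, y, groups)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedMetricWarning)
        for train, test in folds:
            if len(pd.unique(y[train])) < 2:
                # a LOGO fold of a tiny cohort can leave one class in
                # training; the fold carries no information either way
                log.warning("fold skipped: single-class training set")
                continue
            fit = clone(pipe).fit(X[train], y[train])
            pred = fit.predict(X[test])
            missing = set(y[test]) ^ set(classes)
            if scheme == "logo" and missing:
                log.info("LOGO fold: classes %s absent from test set; "
                         "skipped in macro mean", sorted(missing))
            score = balanced_accuracy_score(y[test], pred)
            scores.append(score)
            conf += confusion_matrix(y[test], pred, labels=classes)
            if score > best[0]:
                best = (score, (train.copy(), test.copy()))
    if not scores:
        raise ValueError("every fold had a single-class training set")
    return ClassificationReport(task, family, model, scheme,
                                np.asarray(scores), conf, classes, best[1])


# ---------------------------------------------------------------------------
# Permutation feature importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    features: list
    mean_drop: np.ndarray          # balanced-accuracy drop per feature
    sd_drop: np.ndarray
    family_importance: dict        # normalized aggregate by family

    def ranking(self) -> list:
        order = np.argsort(-self.mean_drop)
        return [(self.features[i], float(self.mean_drop[i]),
                 float(self.sd_drop[i])) for i in order]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.features,
                             "mean_drop": self.mean_drop,
                             "sd_drop": self.sd_drop})


def permutation_importance_report(model, X_test: np.ndarray, y_test: np.ndarray,
                                  feature_names: list, families: dict,
                                  n_permutations: int = N_PERMUTATIONS,
                                  seed: int = 0) -> ImportanceReport:
    """Per-feature balanced-accuracy drop over independent test-column
    shuffles of a fitted model's held-out data, with a normalized
    per-family aggregate."""
    rng = rng_stream(seed, "permutation_importance")
    base = balanced_accuracy_score(y_test, model.predict(X_test))
    n_feat = X_test.shape[1]
    drops = np.empty((n_feat, n_permutations))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedMetricWarning)
        for f in range(n_feat):
            Xp = X_test.copy()
            for k in range(n_permutations):
                Xp[:, f] = rng.permutation(X_test[:, f])
                drops[f, k] = base - balanced_accuracy_score(
                    y_test, model.predict(Xp))
    mean_drop = drops.mean(axis=1)
    sd_drop = drops.std(axis=1, ddof=1)
    fam_tot = {}
    for name, d in zip(feature_names, mean_drop):
        fam = families.get(name, "other")
        fam_tot[fam] = fam_tot.get(fam, 0.0) + max(d, 0.0)
    total = sum(fam_tot.values())
    fam_norm = {k: (v / total if total > 0 else 0.0) for k, v in fam_tot.items()}
    return ImportanceReport(list(feature_names), mean_drop, sd_drop, fam_norm)


def importance_for_task(table: FeatureTable, task: str, family: str = "all",
                        model: str = "svm", seed: int = 0,
                        n_permutations: int = N_PERMUTATIONS,
                        n_splits: int = N_RANDOM_SPLITS) -> ImportanceReport:
    """Permutation importance on the best-balanced-accuracy random split
    (first split attaining the max under the seed order), refitting the
    model on that split's training rows."""
    report = evaluate_task(table, task, family, model, "random", seed,
                           n_splits=n_splits)
    train, test = report.best_split
    cols = table.family_columns(family)
    X = table.df[cols].to_numpy(dtype=np.float64)
    y = table.df[TASK_LABELS[task]].to_numpy()
    fit = make_model(model).fit(X[train], y[train])
    return permutation_importance_report(
        fit, X[test], y[test], cols, table.families,
        n_permutations=n_permutations, seed=seed)
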