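"""Cross-validation benchmarking, metrics, and classifier comparison.

Implements the study-style harness: stratified (optionally participant-
grouped) k-fold cross-validation repeated over many runs of the
non-deterministic tree inducer, the ACC / AUC / F1 / WF1 metric set with
confusion matrices, protein-selection frequency aggregation, and the
Friedman + Dunn multiple-comparison procedure for ranking algorithms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .io_model import ExpressionMatrix, SampleLabels, ValidationError


@dataclass
class MetricSet:
    """ACC / AUC / F1(macro) / WF1 plus the confusion matrix (rows = truth)."""

    acc: float
    auc: float | None
    f1: float
    wf1: float
    confusion: np.ndarray

    def as_row(self) -> dict:
        return {
            "acc": self.acc,
            "auc": np.nan if self.auc is None else self.auc,
            "f1": self.f1,
            "wf1": self.wf1,
        }


@dataclass
class CVReport:
    """Per-fold metrics with aggregates over runs x folds."""

    folds: int
    runs: int
    base_seed: int
    classes: tuple[str, ...]
    fold_metrics: list[MetricSet] = field(default_factory=list)
    selection_frequency: dict[str, int] = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        rows = pd.DataFrame([m.as_row() for m in self.fold_metrics])
        return pd.DataFrame({"mean": rows.mean(), "stdev": rows.std(ddof=1)})

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.fold_metrics):
            run, fold = divmod(i, self.folds)
            rows.append({"run": run, "fold": fold, **m.as_row()})
        return pd.DataFrame(rows)

    def metrics_csv(self) -> str:
        """Deterministic CSV (per-fold rows + aggregate block)."""
        buf = io.StringIO()
        self.metrics_frame().to_csv(buf, index=False, float_format="%.10g")
        buf.write("# aggregate\n")
        self.summary.to_csv(buf, float_format="%.10g")
        return buf.getvalue()

    def total_confusion(self) -> np.ndarray:
        return sum(m.confusion for m in self.fold_metrics)


def stratified_folds(
    y: SampleLabels,
    k: int,
    seed: int,
    groups: dict[str, str] | None = None,
) -> list[tuple[list[str], list[str]]]:
    """Stratified k-fold split of labelled samples.

    When ``groups`` maps samples to participants, all biopsies of one
    participant land in the same fold (leakage control for repeated-measures
    designs); otherwise plain stratification balances class counts per fold
    to within one sample.
    """
    sample_ids = list(y.labels)
    labels = [y.labels[s] for s in sample_ids]
    counts = y.class_counts()
    for cls, n in counts.items():
        if 0 < n < k:
            raise ValidationError(f"class {cls!r} has {n} samples, fewer than k={k}")
    X = np.zeros((len(sample_ids), 1))
    if groups is not None:
        g = [groups[s] for s in sample_ids]
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
        split = splitter.split(X, labels, groups=g)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
        split = splitter.split(X, labels)
    out = []
    for train_idx, test_idx in split:
        out.append(([sample_ids[i] for i in train_idx], [sample_ids[i] for i in test_idx]))
    return out


def compute_metrics(y_true, y_pred, y_score, classes: tuple[str, ...]) -> MetricSet:
    """Metric set for one evaluation; ``y_score`` is the probability of the
    positive class (``classes[1]``).  AUC uses the rank (Mann-Whitney)
    statistic with half credit for score ties; with a single-class truth
    vector it is undefined and reported as None.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    labels = list(classes)
    acc = float(accuracy_score(y_true, y_pred))
    if len(set(y_true)) < 2:
        auc = None
    else:
        auc = float(roc_auc_score([labels.index(t) for t in y_true], np.asarray(y_score)))
    f1 = float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0))
    wf1 = float(f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return MetricSet(acc=acc, auc=auc, f1=f1, wf1=wf1, confusion=cm)


def cross_validate(
    m: ExpressionMatrix,
    y: SampleLabels,
    model_factory,
    k: int = 10,
    runs: int = 1,
    base_seed: int = 0,
    groups: dict[str, str] | None = None,
) -> CVReport:
    """Repeated stratified k-fold cross-validation.

    ``model_factory(seed)`` must return an object with
    ``fit(matrix, labels)``, ``predict(matrix) -> labels`` and
    ``predict_proba(matrix) -> (n, 2) array``; if it also exposes
    ``selected_proteins()`` the protein-selection frequency across all fitted
    models is accumulated.  Seeding is fully deterministic:
    run r, fold f -> seed = base_seed + r * 10**4 + f.
    """
    report = CVReport(folds=k, runs=runs, base_seed=base_seed, classes=y.classes)
    for r in range(runs):
        folds = stratified_folds(y, k, seed=base_seed + r * 10**4, groups=groups)
        for f, (train_ids, test_ids) in enumerate(folds):
            seed = base_seed + r * 10**4 + f
            model = model_factory(seed)
            m_train = m.subset_samples(train_ids)
            m_test = m.subset_samples(test_ids)
            model.fit(m_train, y.restrict(train_ids))
            y_pred = model.predict(m_test)
            proba = np.asarray(model.predict_proba(m_test))
            y_true = [y.labels[s] for s in test_ids]
            report.fold_metrics.append(
                compute_metrics(y_true, y_pred, proba[:, 1], y.classes)
            )
            if hasattr(model, "selected_proteins"):
                for p in model.selected_proteins():
                    report.selection_frequency[p] = report.selection_frequency.get(p, 0) + 1
    return report


# ---------------------------------------------------------------------------
# selection-frequency overlaps


@dataclass
class SelectionOverlap:
    task_names: list[str]
    counts: pd.DataFrame          # protein x task selection counts
    regions: dict[tuple[str, ...], set[str]]  # task combination -> proteins

    def to_tsv(self) -> str:
        buf = io.StringIO()
        df = self.counts.copy()
        df.index.name = "protein_id"
        df["tasks"] = [
            ",".join(t for t in self.task_names if df.loc[p, t] > 0) for p in df.index
        ]
        df.to_csv(buf, sep="\t")
        return buf.getvalue()


def selection_frequency_report(reports: list[CVReport], task_names: list[str]) -> SelectionOverlap:
    """Cross-task protein-selection table with Venn-style regions."""
    if len(reports) < 2:
        raise ValidationError("need at least 2 tasks to compare selections")
    proteins = sorted(set().union(*(r.selection_frequency for r in reports)))
    counts = pd.DataFrame(0, index=proteins, columns=task_names, dtype=int)
    for rep, name in zip(reports, task_names):
        for p, c in rep.selection_frequency.items():
            counts.loc[p, name] = c
    membership = {name: set(rep.selection_frequency) for rep, name in zip(reports, task_names)}
    regions: dict[tuple[str, ...], set[str]] = {}
    from itertools import combinations

    for r in range(1, len(task_names) + 1):
        for combo in combinations(task_names, r):
            inside = set.intersection(*(membership[t] for t in combo)) if combo else set()
            outside = set().union(*(membership[t] for t in task_names if t not in combo), set())
            regions[combo] = inside - outside
    return SelectionOverlap(task_names=list(task_names), counts=counts, regions=regions)


# ---------------------------------------------------------------------------
# Friedman + Dunn comparison


@dataclass
class FriedmanDunnReport:
    statistic: float
    p_value: float
    mean_ranks: dict[str, float]
    posthoc: pd.DataFrame | None   # pairwise Dunn z and Bonferroni-adjusted p
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def friedman_dunn(metric_table: pd.DataFrame, alpha: float = 0.05) -> FriedmanDunnReport:
    """Friedman rank test across algorithms (rows) over blocks (columns),
    followed — when significant at ``alpha`` — by all pairwise Dunn z tests
    with Bonferroni family-wise adjustment.

    Ties within a block receive midranks and the Friedman statistic carries
    the standard tie correction.
    """
    table = pd.DataFrame(metric_table)
    k, n = table.shape
    if k < 3:
        raise ValidationError("Friedman test needs at least 3 algorithms")
    if n < 2:
        raise ValidationError("Friedman test needs at least 2 blocks")
    ranks = np.apply_along_axis(stats.rankdata, 0, table.to_numpy())  # rank within block
    R = ranks.sum(axis=1)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)
    # tie correction
    T = 0.0
    for j in range(n):
        _, t = np.unique(ranks[:, j], return_counts=True)
        T += np.sum(t**3 - t)
    denom = 1.0 - T / (n * k * (k**2 - 1))
    if denom > 0:
        stat = stat / denom
        p = float(stats.chi2.sf(stat, df=k - 1))
    else:  # all columns fully tied: no evidence of any difference
        stat = 0.0
        p = 1.0
    mean_ranks = {alg: float(r) for alg, r in zip(table.index, ranks.mean(axis=1))}
    posthoc = None
    if p < alpha and alpha > 0:
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        rows = []
        algos = list(table.index)
        n_pairs = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                z = (mean_ranks[algos[i]] - mean_ranks[algos[j]]) / se
                p_raw = 2 * stats.norm.sf(abs(z))
                p_adj = min(1.0, p_raw * n_pairs)
                rows.append({
                    "algo_a": algos[i], "algo_b": algos[j],
                    "z": z, "p_raw": p_raw, "p_adj": p_adj,
                    "significant": p_adj < alpha,
                })
        posthoc = pd.DataFrame(rows)
    return FriedmanDunnReport(statistic=float(stat), p_value=p,
                              mean_ranks=mean_ranks, posthoc=posthoc, alpha=alpha)
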