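"""Proteomics differential-expression filter cascade and baseline tests.

The cascade mirrors standard practice for DIA protein matrices: a presence
gate (measured in at least half the samples), an identification-confidence
gate (at least two unique peptides), a per-protein two-group test on log2
intensities, Benjamini-Hochberg FDR control over the tested set, and a
fold-change band of |log2FC| >= 0.585 (a 1.5-fold difference).  A protein is
called significant only if it passes all gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import ExpressionMatrix, ProteinMeta, SampleLabels, ValidationError

#: log2 fold-change magnitude corresponding to a 1.5-fold (50%) difference.
LOG2_FC_CUTOFF = round(float(np.log2(1.5)), 3)  # 0.585


@dataclass
class DEFilterConfig:
    presence_fraction: float = 0.5
    min_unique_peptides: int = 2
    log2fc_threshold: float = LOG2_FC_CUTOFF
    q_threshold: float = 0.05
    test: str = "welch"  # or "wilcoxon" (unpaired rank-sum)

    def __post_init__(self):
        if not (0.0 < self.presence_fraction <= 1.0):
            raise ValidationError("presence_fraction must lie in (0, 1]")
        if self.min_unique_peptides < 0 or self.q_threshold < 0 or self.log2fc_threshold < 0:
            raise ValidationError("thresholds must be >= 0")
        if self.test not in ("welch", "wilcoxon"):
            raise ValidationError("test must be 'welch' or 'wilcoxon'")


def _group_columns(m: ExpressionMatrix, y: SampleLabels, group: str) -> np.ndarray:
    if group not in y.classes:
        raise ValidationError(f"group {group!r} not in class set {y.classes}")
    cols = [j for j, s in enumerate(m.sample_ids) if y.labels.get(s) == group]
    if not cols:
        raise ValidationError(f"no samples labelled {group!r} in the matrix")
    return np.array(cols)


def compute_log2fc(m: ExpressionMatrix, y: SampleLabels, group_a: str, group_b: str) -> pd.Series:
    """Per-protein log2 fold change: mean log2 intensity in ``group_a`` minus
    ``group_b`` (values are log2 by convention, so this is the log ratio of
    geometric means).  Proteins with fewer than 2 non-missing values in either
    group get NaN.
    """
    ca = _group_columns(m, y, group_a)
    cb = _group_columns(m, y, group_b)
    out = np.full(m.n_proteins, np.nan)
    va, vb = m.values[:, ca], m.values[:, cb]
    na = (~np.isnan(va)).sum(axis=1)
    nb = (~np.isnan(vb)).sum(axis=1)
    ok = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore"):
        out[ok] = np.nanmean(va[ok], axis=1) - np.nanmean(vb[ok], axis=1)
    return pd.Series(out, index=m.protein_ids, name="log2fc")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _protein_test(va: np.ndarray, vb: np.ndarray, test: str) -> float:
    a = va[~np.isnan(va)]
    b = vb[~np.isnan(vb)]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue)


def de_filter_pipeline(
    m: ExpressionMatrix,
    y: SampleLabels,
    meta: ProteinMeta,
    cfg: DEFilterConfig = DEFilterConfig(),
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Run the full filter cascade for a binary comparison.

    Stage order: presence gate over all samples of the task, unique-peptide
    gate, per-protein two-group test on proteins passing both gates, BH over
    exactly that tested set, then the effect-size and FDR gates.  The emitted
    table covers every protein (including failures) with columns log2fc, p,
    q, neg_log10_p and the individual pass flags.
    """
    if group_a is None or group_b is None:
        if len(y.classes) != 2:
            raise ValidationError("specify group_a/group_b for non-binary label sets")
        group_b, group_a = y.classes  # a = positive/second class vs b = reference
    ca = _group_columns(m, y, group_a)
    cb = _group_columns(m, y, group_b)
    cols = np.concatenate([ca, cb])
    present = (~m.missing_mask[:, cols]).mean(axis=1)
    presence_pass = present >= cfg.presence_fraction
    peptide_pass = np.array([
        meta.unique_peptides.get(p, 0) >= cfg.min_unique_peptides for p in m.protein_ids
    ])
    tested = presence_pass & peptide_pass
    p_values = np.full(m.n_proteins, np.nan)
    for i in np.flatnonzero(tested):
        p_values[i] = _protein_test(m.values[i, ca], m.values[i, cb], cfg.test)
    computable = tested & ~np.isnan(p_values)
    q_values = np.full(m.n_proteins, np.nan)
    if computable.any():
        q_values[computable] = bh_adjust(p_values[computable])
    log2fc = compute_log2fc(m, y, group_a, group_b).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log10_p = -np.log10(p_values)
    effect_pass = np.abs(log2fc) >= cfg.log2fc_threshold
    effect_pass &= ~np.isnan(log2fc)
    fdr_pass = np.where(np.isnan(q_values), False, q_values < cfg.q_threshold)
    significant = presence_pass & peptide_pass & effect_pass & fdr_pass
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p_values,
            "q_value": q_values,
            "neg_log10_p": neg_log10_p,
            "presence_pass": presence_pass,
            "peptide_pass": peptide_pass,
            "effect_pass": effect_pass,
            "fdr_pass": fdr_pass,
            "significant": significant,
        },
        index=pd.Index(m.protein_ids, name="protein_id"),
    )


def bonferroni_baseline(
    m: ExpressionMatrix,
    y: SampleLabels,
    test: str = "t",
    group_a: str | None = None,
    group_b: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Foundational baseline: per-protein t-test or rank-sum with Bonferroni.

    The rank test is the unpaired rank-sum (the groups are independent
    subjects, so a paired signed-rank test does not apply).  Adjusted
    p = min(1, p * m_tested); the significant set at ``alpha`` is flagged.
    """
    if test not in ("t", "wilcoxon"):
        raise ValidationError("test must be 't' or 'wilcoxon'")
    if group_a is None or group_b is None:
        if len(y.classes) != 2:
            raise ValidationError("specify group_a/group_b for non-binary label sets")
        group_b, group_a = y.classes
    ca = _group_columns(m, y, group_a)
    cb = _group_columns(m, y, group_b)
    stat_test = "welch" if test == "t" else "wilcoxon"
    p_values = np.array([
        _protein_test(m.values[i, ca], m.values[i, cb], stat_test)
        for i in range(m.n_proteins)
    ])
    m_tested = int((~np.isnan(p_values)).sum())
    adj = np.minimum(1.0, p_values * max(m_tested, 1))
    return pd.DataFrame(
        {
            "p_value": p_values,
            "p_bonferroni": adj,
            "significant": np.where(np.isnan(adj), False, adj < alpha),
        },
        index=pd.Index(m.protein_ids, name="protein_id"),
    )


def overlap_sets(stat_significant, ml_selected):
    """Three-region comparison of statistics-significant vs ML-selected
    proteins: (stat-only, both, ml-only) membership sets.
    """
    stat = set(stat_significant)
    ml = set(ml_selected)
    return stat - ml, stat & ml, ml - stat


def overlap_table(stat_significant, ml_selected) -> pd.DataFrame:
    stat_only, both, ml_only = overlap_sets(stat_significant, ml_selected)
    rows = [("stat_only", sorted(stat_only)), ("both", sorted(both)), ("ml_only", sorted(ml_only))]
    return pd.DataFrame(
        [{"region": name, "size": len(members), "proteins": ",".join(members)}
         for name, members in rows]
    )
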