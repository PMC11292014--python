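"""Synthetic DIA-proteomics cohort generator.

Emulates the study design that the rest of the package is exercised on:
three glycemic groups (normoglycemia, prediabetes, type 2 diabetes) of
13 / 11 / 8 participants with two biopsies each (64 samples), around a
thousand proteins on a log2-intensity scale, participant-correlated
replicates, planted group fold-change effects, planted order-reversal
protein pairs, intensity-dependent (missing-not-at-random) dropout,
per-protein unique-peptide counts, and a batch-shifted external replica
sharing a protein subset for merge scenarios.

The generative model per cell is

    x[p, s] = mu_p + b[participant(s)] + delta_p * 1[class(s) != reference]
              + offset_p(class(s)) + eps[p, s]

with mu_p ~ N(mu, protein_spread^2), b ~ N(0, tau^2), eps ~ N(0, sigma^2);
reversal-pair proteins share a base mean and receive class-dependent offsets
of +/- reversal_gap / 2 with opposite signs, so the within-sample order of
the pair flips between the reference and non-reference classes.  A cell is
then dropped with probability logistic((mnar_threshold - x) / mnar_scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import ExpressionMatrix, ProteinMeta, SampleLabels, ValidationError

DEFAULT_CLASSES = ("NG", "PD", "T2D")


@dataclass
class CohortConfig:
    group_sizes: tuple[int, ...] = (13, 11, 8)
    class_names: tuple[str, ...] = DEFAULT_CLASSES
    biopsies_per_participant: int = 2
    n_proteins: int = 1139
    baseline_mean: float = 20.0       # log2 intensity
    protein_spread: float = 2.0
    participant_sd: float = 0.5       # tau: within-person correlation source
    residual_sd: float = 0.7          # sigma
    n_de_proteins: int = 100
    de_log2fc_range: tuple[float, float] = (0.585, 2.0)
    n_reversal_pairs: int = 2
    reversal_gap: float = 1.0
    mnar_threshold: float = 16.0
    mnar_scale: float = 1.5
    peptide_rate: float = 3.0         # lambda of 1 + Poisson(lambda)
    seed: int = 0

    def __post_init__(self):
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        self.class_names = tuple(self.class_names)[: len(self.group_sizes)]
        if len(self.class_names) != len(self.group_sizes):
            raise ValidationError("one class name per group required")
        if any(g < 1 for g in self.group_sizes) or self.biopsies_per_participant < 1:
            raise ValidationError("group sizes and biopsies must be positive")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        if self.residual_sd < 0 or self.participant_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.n_de_proteins + 2 * self.n_reversal_pairs > self.n_proteins:
            raise ValidationError(
                "n_de_proteins + 2 * n_reversal_pairs exceeds n_proteins"
            )

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes) * self.biopsies_per_participant


@dataclass
class GroundTruth:
    """Planted-signal record enabling parameter-recovery checks."""

    de_proteins: dict[str, float]                 # protein id -> planted log2fc
    reversal_pairs: list[tuple[str, str]]
    reversal_orders: dict[tuple[str, str], dict[str, str]]  # pair -> class -> 'a<b'/'a>b'
    participants: dict[str, str]                  # sample id -> participant id
    protein_means: dict[str, float] = field(default_factory=dict)
    reference_class: str = "NG"


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_cohort(cfg: CohortConfig):
    """Draw one cohort; returns (matrix, labels, meta, ground_truth).

    Fully reproducible from ``cfg.seed``: all randomness flows through one
    generator in a fixed order.
    """
    rng = np.random.default_rng(cfg.seed)
    protein_ids = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]

    # planted-signal protein assignment: reversal pairs first, DE from the rest
    order = rng.permutation(cfg.n_proteins)
    rev_idx = order[: 2 * cfg.n_reversal_pairs]
    de_idx = order[2 * cfg.n_reversal_pairs: 2 * cfg.n_reversal_pairs + cfg.n_de_proteins]

    mu_p = rng.normal(cfg.baseline_mean, cfg.protein_spread, size=cfg.n_proteins)
    reversal_pairs = []
    for k in range(cfg.n_reversal_pairs):
        ia, ib = int(rev_idx[2 * k]), int(rev_idx[2 * k + 1])
        mu_p[ib] = mu_p[ia]  # shared base mean so offsets control the order
        reversal_pairs.append((protein_ids[ia], protein_ids[ib]))

    lo, hi = cfg.de_log2fc_range
    de_mag = rng.uniform(lo, hi, size=len(de_idx))
    de_sign = rng.choice([-1.0, 1.0], size=len(de_idx))
    delta = np.zeros(cfg.n_proteins)
    delta[de_idx] = de_mag * de_sign

    # samples / participants
    sample_ids, participants, labels = [], {}, {}
    subj = 0
    for cls, size in zip(cfg.class_names, cfg.group_sizes):
        for _ in range(size):
            subj += 1
            pid = f"subj{subj:03d}"
            for b in range(cfg.biopsies_per_participant):
                sid = f"{cls}_{pid}_b{b + 1}"
                sample_ids.append(sid)
                participants[sid] = pid
                labels[sid] = cls
    n = len(sample_ids)
    y_cls = np.array([labels[s] for s in sample_ids])
    nonref = (y_cls != cfg.class_names[0]).astype(float)

    b_subj = {p: rng.normal(0.0, cfg.participant_sd) for p in dict.fromkeys(participants.values())}
    b_vec = np.array([b_subj[participants[s]] for s in sample_ids])

    X = mu_p[:, None] + b_vec[None, :] + delta[:, None] * nonref[None, :]
    reversal_orders = {}
    for k, (pa, pb) in enumerate(reversal_pairs):
        ia, ib = int(rev_idx[2 * k]), int(rev_idx[2 * k + 1])
        # reference class: a below b; non-reference classes: a above b
        X[ia] += np.where(nonref > 0, cfg.reversal_gap / 2, -cfg.reversal_gap / 2)
        X[ib] += np.where(nonref > 0, -cfg.reversal_gap / 2, cfg.reversal_gap / 2)
        reversal_orders[(pa, pb)] = {
            cls: ("a<b" if cls == cfg.class_names[0] else "a>b") for cls in cfg.class_names
        }
    X = X + rng.normal(0.0, cfg.residual_sd, size=X.shape)

    if cfg.mnar_scale > 0:
        p_missing = _logistic((cfg.mnar_threshold - X) / cfg.mnar_scale)
    else:
        p_missing = (X < cfg.mnar_threshold).astype(float)
    mask = rng.random(X.shape) < p_missing
    values = X.copy()
    values[mask] = np.nan

    peptides = 1 + rng.poisson(cfg.peptide_rate, size=cfg.n_proteins)
    meta = ProteinMeta(unique_peptides={p: int(c) for p, c in zip(protein_ids, peptides)})
    matrix = ExpressionMatrix(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        values=values,
        missing_mask=mask,
        source_tags=["cohort"] * n,
    )
    y = SampleLabels(labels=labels, classes=cfg.class_names)
    truth = GroundTruth(
        de_proteins={protein_ids[i]: float(delta[i]) for i in de_idx},
        reversal_pairs=reversal_pairs,
        reversal_orders=reversal_orders,
        participants=participants,
        protein_means={p: float(m) for p, m in zip(protein_ids, mu_p)},
        reference_class=cfg.class_names[0],
    )
    return matrix, y, meta, truth


def generate_external_replica(
    base,
    shared_protein_count: int = 645,
    batch_sd: float = 0.5,
    cfg: CohortConfig | None = None,
    group_sizes: tuple[int, ...] = (11, 10),
    class_names: tuple[str, ...] = ("NG", "PD"),
    seed: int | None = None,
):
    """Batch-shifted external cohort sharing a protein subset with ``base``.

    ``base`` is the tuple returned by :func:`generate_cohort` together with
    the config it was drawn from: ``(matrix, labels, meta, truth, cfg)`` or
    ``(matrix, labels, meta, truth)`` plus an explicit ``cfg``.  New
    participants are drawn under the same generative law, restricted to a
    random subset of ``shared_protein_count`` proteins, with a per-protein
    batch offset ~ N(0, batch_sd^2) and fresh sample ids; planted signals are
    preserved on the shared proteins.  The default external design is two
    groups of 11 and 10 participants with two biopsies (42 samples).
    """
    if len(base) == 5:
        matrix, _, _, truth, base_cfg = base
    else:
        matrix, _, _, truth = base
        base_cfg = cfg
    if base_cfg is None:
        raise ValidationError("the base cohort's CohortConfig is required")
    if shared_protein_count < 2:
        raise ValidationError("shared_protein_count must be >= 2")
    if shared_protein_count > matrix.n_proteins:
        raise ValidationError("shared_protein_count exceeds base protein count")
    seed = base_cfg.seed + 10_007 if seed is None else seed
    rng = np.random.default_rng(seed)

    shared = sorted(rng.choice(matrix.protein_ids, size=shared_protein_count, replace=False))
    mu_p = np.array([truth.protein_means[p] for p in shared])
    delta = np.array([truth.de_proteins.get(p, 0.0) for p in shared])
    pos = {p: i for i, p in enumerate(shared)}

    sample_ids, participants, labels = [], {}, {}
    subj = 0
    for cls, size in zip(class_names, group_sizes):
        if cls not in base_cfg.class_names:
            raise ValidationError(f"replica class {cls!r} unknown to the base cohort")
        for _ in range(size):
            subj += 1
            pid = f"ext{subj:03d}"
            for b in range(base_cfg.biopsies_per_participant):
                sid = f"EXT_{cls}_{pid}_b{b + 1}"
                sample_ids.append(sid)
                participants[sid] = pid
                labels[sid] = cls
    y_cls = np.array([labels[s] for s in sample_ids])
    nonref = (y_cls != truth.reference_class).astype(float)
    b_subj = {p: rng.normal(0.0, base_cfg.participant_sd)
              for p in dict.fromkeys(participants.values())}
    b_vec = np.array([b_subj[participants[s]] for s in sample_ids])

    X = mu_p[:, None] + b_vec[None, :] + delta[:, None] * nonref[None, :]
    for pa, pb in truth.reversal_pairs:
        if pa in pos and pb in pos:
            X[pos[pa]] += np.where(nonref > 0, base_cfg.reversal_gap / 2,
                                   -base_cfg.reversal_gap / 2)
            X[pos[pb]] += np.where(nonref > 0, -base_cfg.reversal_gap / 2,
                                   base_cfg.reversal_gap / 2)
    X = X + rng.normal(0.0, base_cfg.residual_sd, size=X.shape)
    X = X + rng.normal(0.0, batch_sd, size=(len(shared), 1))  # per-protein batch offset

    if base_cfg.mnar_scale > 0:
        p_missing = _logistic((base_cfg.mnar_threshold - X) / base_cfg.mnar_scale)
    else:
        p_missing = (X < base_cfg.mnar_threshold).astype(float)
    mask = rng.random(X.shape) < p_missing
    values = X.copy()
    values[mask] = np.nan
    matrix_ext = ExpressionMatrix(
        protein_ids=list(shared),
        sample_ids=sample_ids,
        values=values,
        missing_mask=mask,
        source_tags=["external"] * len(sample_ids),
    )
    labels_ext = SampleLabels(labels=labels, classes=tuple(class_names))
    return matrix_ext, labels_ext


# ---------------------------------------------------------------------------
# hand-checkable fixture

_TOY_SAMPLES = ["NG1", "NG2", "NG3", "NG4", "PD1", "PD2", "PD3", "PD4"]
NA = np.nan
_TOY_TABLE = {
    # planted 2-fold protein: PD mean 11.0 vs NG mean 10.0 (log2fc = 1.0)
    "PROT_FC":   [10.0, 10.2,  9.8, 10.0, 11.0, 11.2, 10.8, 11.0],
    # no group effect
    "PROT_NULL": [12.0, 12.1, 11.9, 12.0, 12.0, 12.2, 11.8, 12.0],
    # strong effect but only 1 unique peptide (blocked by the peptide gate)
    "PROT_1PEP": [ 8.0,  8.1,  7.9,  8.0,  9.5,  9.6,  9.4,  9.5],
    # mostly missing: present in 3 of 8 samples (blocked by the presence gate)
    "PROT_MISS": [  NA,   NA,   NA, 14.0,   NA,   NA, 13.5, 13.8],
    # reversal pair: A < B in every NG sample, A > B in every PD sample,
    # with |log2fc(A)| = 0.4 below the fold-change band
    "PROT_RVA":  [15.0, 15.1, 14.9, 15.0, 15.4, 15.5, 15.3, 15.4],
    "PROT_RVB":  [15.25, 15.35, 15.15, 15.25, 15.25, 15.35, 15.15, 15.25],
}
_TOY_PEPTIDES = {"PROT_FC": 4, "PROT_NULL": 3, "PROT_1PEP": 1,
                 "PROT_MISS": 3, "PROT_RVA": 3, "PROT_RVB": 3}


def toy_fixture():
    """Hard-coded 6-protein x 8-sample table used across module examples.

    Contains one planted 2-fold protein, one single-peptide protein, one
    mostly-missing protein and one planted order-reversal pair; identical on
    every call.
    """
    protein_ids = list(_TOY_TABLE)
    values = np.array([_TOY_TABLE[p] for p in protein_ids], dtype=float)
    mask = np.isnan(values)
    matrix = ExpressionMatrix(
        protein_ids=protein_ids,
        sample_ids=list(_TOY_SAMPLES),
        values=values,
        missing_mask=mask,
        source_tags=["toy"] * len(_TOY_SAMPLES),
    )
    labels = SampleLabels(
        labels={s: ("NG" if s.startswith("NG") else "PD") for s in _TOY_SAMPLES},
        classes=("NG", "PD"),
    )
    meta = ProteinMeta(unique_peptides=dict(_TOY_PEPTIDES))
    return matrix, labels, meta
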