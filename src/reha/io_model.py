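"""Data model and I/O for protein expression matrices and sample labels.

The canonical in-memory container is :class:`ExpressionMatrix`: a proteins x
samples table of log2 intensities with an explicit missing-value mask and a
per-sample dataset-of-origin tag.  Readers accept plain TSV exports (header row
of sample ids, first column protein accession), the common interchange format
for DIA proteomics intensity matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents treated as missing values in TSV input.
MISSING_SENTINELS = frozenset({"", "NA", "NaN", "nan"})


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ParseError(ValueError):
    """Input file is malformed."""


@dataclass
class ExpressionMatrix:
    """Protein x sample intensity matrix on a log2 scale.

    Parameters
    ----------
    protein_ids : list of str
        Unique row identifiers (accessions or gene symbols).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_proteins, n_samples)
        Log2 intensities; entries under ``missing_mask`` are NaN.
    missing_mask : ndarray of bool, same shape
        True where the measurement is missing.
    source_tags : list of str
        Dataset of origin, one tag per sample (all equal for a single-source
        matrix; preserved through merging).
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    source_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not self.source_tags:
            self.source_tags = ["default"] * len(self.sample_ids)
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError("duplicate protein ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        shape = (len(self.protein_ids), len(self.sample_ids))
        if self.values.shape != shape or self.missing_mask.shape != shape:
            raise ValidationError(
                f"values/mask shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if len(self.source_tags) != len(self.sample_ids):
            raise ValidationError("one source tag per sample required")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValidationError("non-missing values must be finite")
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def protein_index(self, protein_id: str) -> int:
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise ValidationError(f"unknown protein id {protein_id!r}") from None

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Column subset (and reorder) by sample id."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            protein_ids=list(self.protein_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            missing_mask=self.missing_mask[:, idx],
            source_tags=[self.source_tags[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)


@dataclass
class SampleLabels:
    """Sample id -> class label mapping for a classification task.

    ``classes`` is an ordered tuple; the first class is the reference /
    "negative" class and the second the positive class for scoring purposes.
    """

    labels: dict[str, str]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        if len(self.classes) < 2:
            raise ValidationError("a task needs at least 2 classes")
        bad = {c for c in self.labels.values() if c not in self.classes}
        if bad:
            raise ValidationError(f"labels outside declared class set: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def y(self, sample_ids: list[str]) -> np.ndarray:
        """Integer-coded labels (index into ``classes``) for the given samples."""
        code = {c: i for i, c in enumerate(self.classes)}
        return np.array([code[self.labels[s]] for s in sample_ids], dtype=int)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for lab in self.labels.values():
            counts[lab] += 1
        return counts

    def restrict(self, sample_ids: list[str]) -> "SampleLabels":
        return SampleLabels(
            labels={s: self.labels[s] for s in sample_ids if s in self.labels},
            classes=self.classes,
        )


@dataclass
class ProteinMeta:
    """Per-protein metadata: unique-peptide counts and optional descriptions."""

    unique_peptides: dict[str, int]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, c in self.unique_peptides.items():
            if int(c) != c or c < 0:
                raise ValidationError(f"peptide count for {pid!r} must be an integer >= 0")
        self.unique_peptides = {p: int(c) for p, c in self.unique_peptides.items()}


# ---------------------------------------------------------------------------
# readers / writers


def _parse_cell(text: str, row: str, col: str) -> float:
    text = text.strip()
    if text in MISSING_SENTINELS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"non-numeric cell {text!r} at protein {row!r} / sample {col!r} "
            f"(missing sentinels: empty, NA, NaN, nan)"
        ) from None


def read_expression_matrix(
    path, orientation: str = "proteins-in-rows", source_tag: str | None = None
) -> ExpressionMatrix:
    """Read a TSV intensity matrix into canonical proteins x samples form.

    The first header row carries ids for the columns, the first column ids for
    the rows.  Empty cells and the sentinels NA/NaN/nan denote missing values;
    any other non-numeric content is a :class:`ParseError`.
    """
    if orientation not in ("proteins-in-rows", "samples-in-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.index.isnull().any() or df.columns.isnull().any():
        raise ParseError(f"malformed header in {path}")
    if orientation == "samples-in-rows":
        df = df.T
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    if len(set(row_ids)) != len(row_ids):
        raise ValidationError(f"duplicate protein ids in {path}")
    if len(set(col_ids)) != len(col_ids):
        raise ValidationError(f"duplicate sample ids in {path}")
    values = np.empty((len(row_ids), len(col_ids)), dtype=float)
    raw = df.to_numpy(dtype=object)
    for i, rid in enumerate(row_ids):
        for j, cid in enumerate(col_ids):
            cell = raw[i, j]
            values[i, j] = _parse_cell("" if cell is None or cell != cell else str(cell), rid, cid)
    mask = np.isnan(values)
    tag = source_tag if source_tag is not None else str(path)
    return ExpressionMatrix(row_ids, col_ids, values, mask, [tag] * len(col_ids))


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write TSV (proteins in rows, NA for missing); round-trips exactly."""
    df = m.to_frame()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_labels(path, class_set: set[str] | list[str]) -> SampleLabels:
    """Read a two-column sample_id<TAB>class table restricted to ``class_set``.

    Samples labelled outside the class set are dropped (with a logged count) so
    that one three-class label file serves every binary task.
    """
    classes = list(dict.fromkeys(class_set))
    if len(classes) < 2:
        raise ValidationError("class_set must contain at least 2 classes")
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise ParseError(f"label file {path} must have exactly 2 columns, got {df.shape[1]}")
    # tolerate an optional header line
    first = tuple(df.iloc[0])
    if first[1] not in set(df.iloc[1:, 1]) and str(first[0]).lower() in ("sample_id", "sample"):
        df = df.iloc[1:]
    if df.isnull().any().any():
        raise ParseError(f"label file {path} has empty fields")
    seen: dict[str, str] = {}
    dropped = 0
    for sid, cls in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sid, cls = str(sid), str(cls)
        if sid in seen:
            raise ValidationError(f"sample {sid!r} labelled more than once")
        seen[sid] = cls
        if cls not in classes:
            dropped += 1
    if dropped:
        logger.info("read_labels: dropped %d samples outside class set %s", dropped, classes)
    labels = {s: c for s, c in seen.items() if c in classes}
    return SampleLabels(labels=labels, classes=tuple(classes))


def write_labels(labels: SampleLabels, path) -> None:
    with open(path, "w") as fh:
        for sid, cls in labels.labels.items():
            fh.write(f"{sid}\t{cls}\n")


def read_peptide_counts(path) -> ProteinMeta:
    """Read a protein_id<TAB>unique_peptides table."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"peptide-count file {path} must have 2 columns")
    if str(df.iloc[0, 0]).lower() in ("protein_id", "protein"):
        df = df.iloc[1:]
    counts: dict[str, int] = {}
    for pid, c in zip(df.iloc[:, 0], df.iloc[:, 1]):
        try:
            counts[str(pid)] = int(c)
        except ValueError:
            raise ParseError(f"non-integer peptide count {c!r} for {pid!r}") from None
    return ProteinMeta(unique_peptides=counts)


def write_peptide_counts(meta: ProteinMeta, path) -> None:
    with open(path, "w") as fh:
        for pid, c in meta.unique_peptides.items():
            fh.write(f"{pid}\t{c}\n")


# ---------------------------------------------------------------------------
# merging and standardization


def merge_by_shared_proteins(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Merge two cohorts on their shared proteins.

    The result keeps exactly the protein intersection (in ``a``'s row order),
    all samples of both inputs, and each sample's source tag, enabling the
    external-validation scenario where two studies overlap on a protein subset.
    """
    overlap_samples = set(a.sample_ids) & set(b.sample_ids)
    if overlap_samples:
        raise ValidationError(f"sample ids overlap between datasets: {sorted(overlap_samples)[:5]}")
    shared = [p for p in a.protein_ids if p in set(b.protein_ids)]
    if not shared:
        raise ValidationError("no shared proteins between datasets")
    ia = [a.protein_ids.index(p) for p in shared]
    b_pos = {p: i for i, p in enumerate(b.protein_ids)}
    ib = [b_pos[p] for p in shared]
    values = np.hstack([a.values[ia, :], b.values[ib, :]])
    mask = np.hstack([a.missing_mask[ia, :], b.missing_mask[ib, :]])
    return ExpressionMatrix(
        protein_ids=shared,
        sample_ids=list(a.sample_ids) + list(b.sample_ids),
        values=values,
        missing_mask=mask,
        source_tags=list(a.source_tags) + list(b.source_tags),
    )


def per_dataset_standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each protein within each source dataset (population SD).

    This is a preprocessing step for baselines that use absolute intensities;
    the relative-expression classifier does not need it because its node tests
    depend only on within-sample order relations.  Zero-variance rows are set
    to 0 with a warning rather than raising, so merged runs stay alive.
    """
    values = m.values.copy()
    tags = np.asarray(m.source_tags)
    for tag in dict.fromkeys(m.source_tags):
        cols = np.flatnonzero(tags == tag)
        block = values[:, cols]
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(block, axis=1, keepdims=True)
            sd = np.nanstd(block, axis=1, keepdims=True)  # population (n) denominator
        zero_var = (sd == 0) | np.isnan(sd)
        if np.any(zero_var & ~np.all(np.isnan(block), axis=1, keepdims=True)):
            logger.warning(
                "per_dataset_standardize: %d zero-variance protein rows in dataset %r set to 0",
                int(np.sum(zero_var)), tag,
            )
        sd_safe = np.where(zero_var, 1.0, sd)
        z = (block - mean) / sd_safe
        z = np.where(zero_var, 0.0, z)
        values[:, cols] = z
    values[m.missing_mask] = np.nan
    return replace(m, values=values, missing_mask=m.missing_mask.copy(),
                   protein_ids=list(m.protein_ids), sample_ids=list(m.sample_ids),
                   source_tags=list(m.source_tags))
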