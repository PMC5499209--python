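"""Domain types, file formats and shared statistics.

The pipeline's universal currency is a genes x samples matrix of log2-scale
expression values (:class:`ExpressionMatrix`), moved around as GCT 1.2 files.
Per-class marker lists (the NTP classifier artifact) are
:class:`GeneSignatureSet` objects stored as GMT. Everything downstream —
subtype discovery, template classification, k-TSP, enrichment — builds on the
normalization primitives and generic statistics defined here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

#: Reserved label for samples that no classifier could confidently assign.
UNASSIGNED = "UNASSIGNED"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with unique identifiers.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique, opaque, case-sensitive identifiers. No symbol-alias
        resolution is attempted (probe -> gene collapse happens upstream).
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``.
    platform_label
        Optional tag for the measurement platform the matrix came from.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform_label: str | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValidationError(f"duplicate {name} identifier: {dup!r}")
        if self.values.size and not np.isfinite(self.values).any(axis=1).all():
            bad = self.gene_ids[
                int(np.flatnonzero(~np.isfinite(self.values).any(axis=1))[0])
            ]
            raise ValidationError(f"gene {bad!r} has no finite value")

    # convenience -----------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, platform_label: str | None = None
    ) -> "ExpressionMatrix":
        return cls(
            list(map(str, frame.index)),
            list(map(str, frame.columns)),
            frame.to_numpy(dtype=float),
            platform_label=platform_label,
        )

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :],
            platform_label=self.platform_label,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.sample_ids[j] for j in idx],
            self.values[:, idx],
            platform_label=self.platform_label,
        )


@dataclass
class GeneSignatureSet:
    """Disjoint per-class marker gene lists (an NTP-compatible classifier)."""

    classes: list[str]
    genes_by_class: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.classes = [str(c) for c in self.classes]
        if set(self.classes) != set(self.genes_by_class):
            raise ValidationError("classes and genes_by_class keys differ")
        seen: dict[str, str] = {}
        for cls in self.classes:
            genes = self.genes_by_class[cls]
            if not genes:
                raise ValidationError(f"class {cls!r} has an empty gene list")
            for g in genes:
                if g in seen:
                    raise ValidationError(
                        f"gene {g!r} appears in classes {seen[g]!r} and {cls!r}; "
                        "per-class signatures must be disjoint"
                    )
                seen[g] = cls

    @property
    def all_genes(self) -> list[str]:
        return [g for c in self.classes for g in self.genes_by_class[c]]

    def sizes(self) -> dict[str, int]:
        return {c: len(self.genes_by_class[c]) for c in self.classes}


@dataclass
class ClassAssignment:
    """Per-sample classification outcome.

    ``predicted_class`` is :data:`UNASSIGNED` exactly when ``fdr`` reaches the
    run's assignment threshold; ``distance`` keeps the full per-class profile.
    """

    sample_id: str
    predicted_class: str
    distance: dict[str, float]
    p_value: float
    fdr: float


@dataclass
class ScoreTable:
    """One scalar score per sample (signature, receptor activity, load...)."""

    sample_ids: list[str]
    score_name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids),):
            raise ValidationError("one score per sample required")
        if self.scores.size and not np.isfinite(self.scores).all():
            raise ValidationError(f"non-finite score in {self.score_name!r}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.score_name)


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# GCT 1.2 / GMT
# ---------------------------------------------------------------------------


def read_gct(path) -> ExpressionMatrix:
    """Read a GCT 1.2 expression file.

    Errors name the offending line (1-based) so malformed exports are easy
    to trace.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: line 1: expected '#1.2' version header")
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GCT (needs >= 3 lines)")
    dims = lines[1].split("\t")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: line 2: malformed dimensions line") from exc
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
        raise FormatError(f"{path}: line 3: expected 'Name\\tDescription\\t...' header")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: line 3: header declares {len(sample_ids)} samples, "
            f"dimensions line says {n_samples}"
        )
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_genes:
        raise FormatError(
            f"{path}: line 2: declares {n_genes} genes but file contains "
            f"{len(body)} data rows"
        )
    gene_ids: list[str] = []
    values = np.empty((n_genes, n_samples), dtype=float)
    for i, ln in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != n_samples + 2:
            raise FormatError(
                f"{path}: line {i + 4}: expected {n_samples + 2} fields, "
                f"got {len(parts)}"
            )
        gene_ids.append(parts[0])
        try:
            values[i, :] = [float(x) for x in parts[2:]]
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 4}: non-numeric value") from exc
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate gene identifier {dup!r}")
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample identifier {dup!r}")
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_gct(matrix: ExpressionMatrix, path, descriptions: Mapping[str, str] | None = None) -> None:
    """Write GCT 1.2; the Description column is 'na' when absent."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, g in enumerate(matrix.gene_ids):
            row = "\t".join(format(v, ".6f") for v in matrix.values[i, :])
            fh.write(f"{g}\t{descriptions.get(g, 'na')}\t{row}\n")


def read_gmt(path) -> GeneSignatureSet:
    """Read GMT: one class per line, ``name<TAB>description<TAB>genes...``."""
    classes: list[str] = []
    genes_by_class: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT needs name, description and "
                    "at least one gene"
                )
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: class {name!r} has no genes")
            if name in genes_by_class:
                raise FormatError(f"{path}: line {lineno}: duplicate class {name!r}")
            classes.append(name)
            genes_by_class[name] = genes
    return GeneSignatureSet(classes, genes_by_class)


def write_gmt(sets: GeneSignatureSet, path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for cls in sets.classes:
            desc = descriptions.get(cls, "na")
            fh.write("\t".join([cls, desc, *sets.genes_by_class[cls]]) + "\n")


def read_score_table(path, score_name: str | None = None) -> ScoreTable:
    df = pd.read_csv(path, sep="\t")
    name = score_name or df.columns[1]
    return ScoreTable(list(df.iloc[:, 0].astype(str)), name, df[name].to_numpy())


def write_score_table(table: ScoreTable, path) -> None:
    pd.DataFrame(
        {"sample_id": table.sample_ids, table.score_name: table.scores}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization primitives
# ---------------------------------------------------------------------------


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene row at median 0 across samples."""
    med = np.nanmedian(matrix.values, axis=1, keepdims=True)
    return dataclasses.replace(matrix, values=matrix.values - med)


def zscore_samples(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize every sample column to mean 0, sd 1 (n-1 denominator)."""
    mean = matrix.values.mean(axis=0, keepdims=True)
    sd = matrix.values.std(axis=0, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd[0] == 0)
    if zero.size:
        raise ValidationError(
            f"sample {matrix.sample_ids[int(zero[0])]!r} has zero variance; "
            "cannot standardize"
        )
    return dataclasses.replace(matrix, values=(matrix.values - mean) / sd)


# ---------------------------------------------------------------------------
# Generic statistics
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohen_kappa(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    *,
    include_unassigned: bool = False,
) -> float:
    """Cohen's kappa, kappa = (p_o - p_e) / (1 - p_e).

    By default pairs where either labeling is :data:`UNASSIGNED` are dropped
    before computing agreement; pass ``include_unassigned=True`` to score
    UNASSIGNED as a class of its own.
    """
    if len(labels_a) != len(labels_b):
        raise ValidationError("label vectors must have equal length")
    a = np.asarray([str(x) for x in labels_a], dtype=object)
    b = np.asarray([str(x) for x in labels_b], dtype=object)
    if not include_unassigned:
        keep = (a != UNASSIGNED) & (b != UNASSIGNED)
        a, b = a[keep], b[keep]
    n = a.size
    if n == 0:
        raise ValidationError("no label pairs to compare")
    alphabet = sorted(set(a) | set(b))
    index = {c: i for i, c in enumerate(alphabet)}
    p_o = float(np.mean(a == b))
    pa = np.bincount([index[x] for x in a], minlength=len(alphabet)) / n
    pb = np.bincount([index[x] for x in b], minlength=len(alphabet)) / n
    p_e = float(pa @ pb)
    if p_e == 1.0:
        raise ValidationError(
            "chance agreement p_e == 1 (single shared class); kappa undefined"
        )
    return (p_o - p_e) / (1.0 - p_e)


def matched_correlation_test(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    pairing: Mapping[str, str],
    sd_threshold: float = 0.8,
):
    """Compare matched vs unmatched cross-dataset sample correlations.

    Genes exceeding ``sd_threshold`` (across samples) in ``matrix_a`` define
    the correlation space; Pearson correlation is computed for every A x B
    sample pair and the matched pairs (per ``pairing``) are compared to the
    unmatched ones by a Wilcoxon rank-sum test.

    Returns
    -------
    (matched, unmatched, result)
        Two 1-D arrays of correlations and the scipy rank-sum test result.
    """
    shared = [g for g in matrix_a.gene_ids if g in set(matrix_b.gene_ids)]
    a = matrix_a.subset_genes(shared)
    b = matrix_b.subset_genes(shared)
    sds = a.values.std(axis=1, ddof=1)
    keep = sds > sd_threshold
    if keep.sum() < 3:
        raise ValidationError(
            f"only {int(keep.sum())} genes exceed sd {sd_threshold}; need >= 3"
        )
    av = a.values[keep, :]
    bv = b.values[keep, :]
    # corr of every A column with every B column, over the high-variance genes
    az = (av - av.mean(axis=0)) / av.std(axis=0, ddof=1)
    bz = (bv - bv.mean(axis=0)) / bv.std(axis=0, ddof=1)
    corr = az.T @ bz / (az.shape[0] - 1)
    b_index = {s: j for j, s in enumerate(b.sample_ids)}
    matched_mask = np.zeros(corr.shape, dtype=bool)
    for i, s in enumerate(a.sample_ids):
        if s in pairing:
            matched_mask[i, b_index[pairing[s]]] = True
    matched = corr[matched_mask]
    unmatched = corr[~matched_mask]
    if matched.size == 0:
        raise ValidationError("pairing matches no sample of matrix_a")
    result = sp_stats.mannwhitneyu(matched, unmatched, alternative="two-sided")
    return matched, unmatched, result
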