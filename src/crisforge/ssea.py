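"""Scores and enrichment: signature scores, receptor activity, preranked
enrichment, sample set enrichment analysis (SSEA) and stromal C/L/E scores.

SSEA turns the preranked enrichment machinery on its head: the ranked list
holds *samples* ordered by a per-sample score, and the "sets" are the sample
memberships of each class, so a positive normalized enrichment score means a
class is concentrated among the high-scoring samples. All scores are computed
on per-gene median-centered log2 values of the analyzed cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    UNASSIGNED,
    ExpressionMatrix,
    ScoreTable,
    ValidationError,
    bh_fdr,
    median_center,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Per-sample scores
# ---------------------------------------------------------------------------


def _mean_over_genes(matrix: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    idx = matrix.gene_index(genes)
    return matrix.values[idx, :].mean(axis=0)


def signature_score(
    matrix: ExpressionMatrix,
    up_genes: list[str],
    down_genes: list[str] | None = None,
    score_name: str = "signature_score",
) -> ScoreTable:
    """Score_j = mean(up genes, j) - mean(down genes, j), median-centered.

    With an empty down set the score is simply the mean of the up genes.
    """
    centered = median_center(matrix)
    present = set(matrix.gene_ids)
    up = [g for g in up_genes if g in present]
    if not up:
        raise ValidationError("no up gene present in the matrix")
    down = [g for g in (down_genes or []) if g in present]
    scores = _mean_over_genes(centered, up)
    if down:
        scores = scores - _mean_over_genes(centered, down)
    return ScoreTable(list(matrix.sample_ids), score_name, scores)


def receptor_activity_score(
    matrix: ExpressionMatrix,
    receptor_gene: str,
    ligand_genes: list[str],
    score_name: str | None = None,
) -> ScoreTable:
    """Score_j = (Receptor_j + mean(Ligands_j)) / 2 on median-centered values."""
    present = set(matrix.gene_ids)
    if receptor_gene not in present:
        raise ValidationError(f"receptor {receptor_gene!r} not in matrix")
    ligands = [g for g in ligand_genes if g in present]
    if not ligands:
        raise ValidationError(f"no ligand of {receptor_gene!r} in matrix")
    centered = median_center(matrix)
    receptor = centered.values[centered.gene_index([receptor_gene])[0], :]
    scores = (receptor + _mean_over_genes(centered, ligands)) / 2.0
    return ScoreTable(
        list(matrix.sample_ids),
        score_name or f"{receptor_gene}_activity",
        scores,
    )


def stromal_scores(
    matrix: ExpressionMatrix,
    caf_genes: list[str],
    endo_genes: list[str],
    leuko_genes: list[str],
) -> dict[str, ScoreTable]:
    """C / E / L stromal infiltration scores: per-sample mean expression of
    fibroblast, endothelial and leukocyte signatures."""
    centered = median_center(matrix)
    present = set(matrix.gene_ids)
    out = {}
    for name, genes in (("C", caf_genes), ("E", endo_genes), ("L", leuko_genes)):
        overlap = [g for g in genes if g in present]
        if not overlap:
            raise ValidationError(f"stromal signature {name} has no gene in matrix")
        out[name] = ScoreTable(
            list(matrix.sample_ids), f"stromal_{name}", _mean_over_genes(centered, overlap)
        )
    return out


# ---------------------------------------------------------------------------
# Preranked enrichment
# ---------------------------------------------------------------------------


@dataclass
class RankedEnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    n_permutations: int
    size: int


def _running_es(order_weights: np.ndarray, hits: np.ndarray, weight_p: float) -> float:
    """Weighted Kolmogorov-Smirnov max-deviation statistic.

    ``order_weights`` are the ranking values in ranked order; ``hits`` marks
    set members along that order.
    """
    n = hits.size
    n_h = int(hits.sum())
    w = np.abs(order_weights) ** weight_p
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit weights zero: fall back to unweighted steps
        hit_w = hits.astype(float)
        total = hit_w.sum()
    inc = hit_w / total
    dec = np.where(~hits, 1.0 / (n - n_h), 0.0)
    running = np.cumsum(inc - dec)
    return float(running[np.argmax(np.abs(running))])


def _null_es_matrix(
    order_weights: np.ndarray, size: int, weight_p: float, n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES of random same-size sets (set-membership permutation null)."""
    n = order_weights.size
    out = np.empty(n_permutations)
    w = np.abs(order_weights) ** weight_p
    for b in range(n_permutations):
        hits = np.zeros(n, dtype=bool)
        hits[rng.choice(n, size=size, replace=False)] = True
        hit_w = np.where(hits, w, 0.0)
        total = hit_w.sum()
        if total == 0:
            hit_w = hits.astype(float)
            total = hit_w.sum()
        running = np.cumsum(hit_w / total - np.where(~hits, 1.0 / (n - size), 0.0))
        out[b] = running[np.argmax(np.abs(running))]
    return out


def preranked_enrichment(
    ranked_ids: list[str],
    ranking_values,
    item_sets: dict[str, list[str]],
    weight_p: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    fdr_method: str = "nes",
) -> list[RankedEnrichmentResult]:
    """Weighted-KS enrichment of item sets along a ranked list.

    The null permutes set membership (random same-size sets); NES divides ES
    by the mean |null ES| of matching sign; FDR follows the standard pooled
    NES procedure (``fdr_method="nes"``) or Benjamini-Hochberg on nominal
    p-values (``fdr_method="bh"``). Sets smaller than 2 or larger than N - 2
    are skipped with a warning.
    """
    ids = list(ranked_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("ranked_ids must be unique")
    values = np.asarray(ranking_values, dtype=float)
    if values.shape != (len(ids),):
        raise ValidationError("one ranking value per id required")
    order = np.argsort(-values, kind="stable")
    ordered_ids = [ids[i] for i in order]
    ordered_values = values[order]
    pos = {x: i for i, x in enumerate(ordered_ids)}
    n = len(ids)
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, np.ndarray, int]] = []
    for name, members in item_sets.items():
        unknown = [m for m in members if m not in pos]
        if unknown:
            raise ValidationError(f"set {name!r}: items {unknown[:3]} not in ranking")
        size = len(set(members))
        if size < 2 or size > n - 2:
            warnings.warn(f"set {name!r} of size {size} skipped (degenerate)",
                          stacklevel=2)
            continue
        hits = np.zeros(n, dtype=bool)
        hits[[pos[m] for m in set(members)]] = True
        kept.append((name, hits, size))

    results = []
    null_by_size: dict[int, np.ndarray] = {}
    all_nes: list[float] = []
    all_null_nes: list[np.ndarray] = []
    for name, hits, size in kept:
        es = _running_es(ordered_values, hits, weight_p)
        if size not in null_by_size:
            null_by_size[size] = _null_es_matrix(
                ordered_values, size, weight_p, n_permutations, rng
            )
        null = null_by_size[size]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            nominal_p = 1.0 / (n_permutations + 1)
            nes = 0.0
            null_nes = np.zeros(0)
        else:
            nominal_p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
            denom = float(np.mean(np.abs(same_sign)))
            nes = es / denom if denom > 0 else 0.0
            pos_mean = float(np.mean(null[null >= 0])) if np.any(null >= 0) else np.nan
            neg_mean = float(np.mean(np.abs(null[null < 0]))) if np.any(null < 0) else np.nan
            with np.errstate(invalid="ignore", divide="ignore"):
                null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
            null_nes = null_nes[np.isfinite(null_nes)]
        all_nes.append(nes)
        all_null_nes.append(null_nes)
        results.append(
            RankedEnrichmentResult(
                set_name=name, es=es, nes=float(nes),
                nominal_p=float(nominal_p), fdr_q=np.nan,
                n_permutations=n_permutations, size=size,
            )
        )

    if not results:
        return results
    if fdr_method == "bh":
        qs = bh_fdr([r.nominal_p for r in results])
        for r, q in zip(results, qs):
            r.fdr_q = float(q)
    else:
        pooled_null = np.concatenate(all_null_nes) if all_null_nes else np.zeros(0)
        obs = np.asarray(all_nes)
        for r, nes in zip(results, obs):
            if pooled_null.size == 0:
                r.fdr_q = 1.0
                continue
            if nes >= 0:
                num = np.mean(pooled_null[pooled_null >= 0] >= nes) if np.any(pooled_null >= 0) else 0.0
                den = np.mean(obs[obs >= 0] >= nes) if np.any(obs >= 0) else 1.0
            else:
                num = np.mean(pooled_null[pooled_null < 0] <= nes) if np.any(pooled_null < 0) else 0.0
                den = np.mean(obs[obs < 0] <= nes) if np.any(obs < 0) else 1.0
            r.fdr_q = float(min(1.0, num / den)) if den > 0 else 1.0
    return results


# ---------------------------------------------------------------------------
# SSEA
# ---------------------------------------------------------------------------


def ssea(
    score: ScoreTable,
    class_assignments: pd.Series,
    weight_p: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    fdr_method: str = "nes",
) -> list[RankedEnrichmentResult]:
    """Enrichment of each class along the sample ranking of a score.

    UNASSIGNED samples are excluded; classes with fewer than 2 assigned
    samples are skipped (with a warning from the enrichment engine).
    """
    assignments = class_assignments.reindex(score.sample_ids)
    keep = assignments.notna() & (assignments != UNASSIGNED)
    if keep.sum() < 4:
        raise ValidationError("too few assigned samples for SSEA")
    samples = [s for s, ok in zip(score.sample_ids, keep) if ok]
    values = score.to_series().loc[samples].to_numpy()
    sets = {
        str(cls): list(assignments.index[assignments == cls])
        for cls in assignments[keep].unique()
    }
    return preranked_enrichment(
        samples, values, sets, weight_p=weight_p,
        n_permutations=n_permutations, seed=seed, fdr_method=fdr_method,
    )
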