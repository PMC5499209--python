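"""Stage 1: from an expression matrix to a validated per-class signature.

The discovery cascade mirrors how intrinsic subtypes are derived from
stroma-depleted profiles: restrict to high-variance genes, standardize each
sample N(0,1), run consensus NMF over a range of cluster numbers and pick K
by the cophenetic coefficient, keep core samples by silhouette width, call
class-discriminant genes by a permutation (SAM-style) multiclass statistic,
prioritize them with nearest shrunken centroids (PAM) under LOOCV, drop genes
whose signal is mostly stromal, and assign the survivors non-redundantly to
single classes — yielding an NTP-compatible :class:`GeneSignatureSet`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_samples

from .core_io import ExpressionMatrix, GeneSignatureSet, ValidationError, zscore_samples

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Variable genes
# ---------------------------------------------------------------------------


def select_variable_genes(matrix: ExpressionMatrix, sd_threshold: float = 0.8) -> list[str]:
    """Genes with across-sample sd above ``sd_threshold``, order preserved."""
    sds = matrix.values.std(axis=1, ddof=1)
    kept = [g for g, s in zip(matrix.gene_ids, sds) if s > sd_threshold]
    if not kept:
        raise ValidationError(
            f"no gene exceeds sd {sd_threshold}; lower the threshold"
        )
    return kept


# ---------------------------------------------------------------------------
# Consensus NMF
# ---------------------------------------------------------------------------


@dataclass
class ConsensusResult:
    """Consensus clustering outcome for one value of K."""

    K: int
    consensus: np.ndarray  # samples x samples, in [0, 1]
    cophenetic: float
    hard_labels: np.ndarray  # per-sample cluster id, 1..K
    sample_ids: list[str]
    #: dispersion coefficient rho = mean(4 * (c - 1/2)^2); 1 for a crisp 0/1
    #: consensus, smaller when co-clustering is ambiguous
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.dispersion is None:
            self.dispersion = float(np.mean(4.0 * (self.consensus - 0.5) ** 2))


def _split_nonnegative(values: np.ndarray) -> np.ndarray:
    """Row-split a centered matrix into positive and negated-negative parts.

    The standard device for factorizing z-scored data with NMF: each gene
    contributes one row holding max(x, 0) and one holding max(-x, 0).
    """
    return np.vstack([np.clip(values, 0, None), np.clip(-values, 0, None)])


def _consensus_tree(consensus: np.ndarray):
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.average(condensed)
    return link, condensed


def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    link, condensed = _consensus_tree(consensus)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        return 1.0  # degenerate: all pairs equidistant, tree is exact
    coeff, _ = hierarchy.cophenet(link, condensed)
    return float(np.clip(coeff, 0.0, 1.0))


def nmf_consensus(
    matrix: ExpressionMatrix,
    K_range=range(2, 7),
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
) -> list[ConsensusResult]:
    """Consensus NMF over a range of cluster numbers.

    The input is expected to be variable-gene-filtered and sample-normalized;
    it is made non-negative by row-splitting. For each K, ``n_runs``
    random-restart KL-divergence factorizations (multiplicative updates)
    assign each sample to its dominant metagene; the consensus matrix is the
    average co-clustering indicator. Hard labels come from average-linkage
    clustering of 1 - consensus, and the cophenetic coefficient measures how
    ultrametric-consistent the consensus is.
    """
    X = _split_nonnegative(matrix.values)
    n_samples = matrix.n_samples
    rng = np.random.default_rng(seed)
    results = []
    for K in K_range:
        if K >= n_samples:
            raise ValidationError(f"K={K} must be smaller than n_samples={n_samples}")
        consensus = np.zeros((n_samples, n_samples))
        for _ in range(n_runs):
            run_seed = int(rng.integers(0, 2**31 - 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = NMF(
                    n_components=K,
                    init="random",
                    solver="mu",
                    beta_loss="kullback-leibler",
                    max_iter=max_iter,
                    tol=1e-4,
                    random_state=run_seed,
                )
                H = model.fit_transform(X.T)  # samples x K
            labels = H.argmax(axis=1)
            consensus += labels[:, None] == labels[None, :]
        consensus /= n_runs
        np.fill_diagonal(consensus, 1.0)
        link, _ = _consensus_tree(consensus)
        hard = hierarchy.fcluster(link, t=K, criterion="maxclust")
        results.append(
            ConsensusResult(
                K=K,
                consensus=consensus,
                cophenetic=_cophenetic_coefficient(consensus),
                hard_labels=hard,
                sample_ids=list(matrix.sample_ids),
            )
        )
    return results


def best_k(results: list[ConsensusResult]) -> ConsensusResult:
    """The K whose consensus is most cophenetic-stable.

    On well-separated data the cophenetic coefficient can saturate at 1 for
    several K at once (consistently merging true clusters, or consistently
    splitting one, both yield an ultrametric-consistent consensus). Exact
    ties are therefore broken by the dispersion coefficient — how close the
    consensus is to a crisp 0/1 matrix — and finally toward the smaller K.
    """
    return max(results, key=lambda r: (r.cophenetic, r.dispersion, -r.K))


# ---------------------------------------------------------------------------
# Silhouette core-sample filter
# ---------------------------------------------------------------------------


def silhouette_filter(result: ConsensusResult) -> tuple[list[str], list[str]]:
    """Drop samples with negative silhouette width on 1 - consensus."""
    dist = 1.0 - result.consensus
    np.fill_diagonal(dist, 0.0)
    widths = silhouette_samples(dist, result.hard_labels, metric="precomputed")
    keep = widths >= 0
    for k in np.unique(result.hard_labels):
        if not np.any(keep & (result.hard_labels == k)):
            raise ValidationError(f"cluster {k} would lose all members")
    core = [s for s, ok in zip(result.sample_ids, keep) if ok]
    dropped = [s for s, ok in zip(result.sample_ids, keep) if not ok]
    return core, dropped


# ---------------------------------------------------------------------------
# SAM-style multiclass differential expression
# ---------------------------------------------------------------------------


def _multiclass_stat(values: np.ndarray, labels: np.ndarray, s0: float | None = None):
    """Between-class contrast over (pooled sd + fudge), per gene."""
    classes = np.unique(labels)
    n = values.shape[1]
    K = classes.size
    overall = values.mean(axis=1)
    between = np.zeros(values.shape[0])
    within_ss = np.zeros(values.shape[0])
    for cls in classes:
        cols = labels == cls
        nk = int(cols.sum())
        mk = values[:, cols].mean(axis=1)
        between += nk * (mk - overall) ** 2
        within_ss += ((values[:, cols] - mk[:, None]) ** 2).sum(axis=1)
    s = np.sqrt(within_ss / max(n - K, 1))
    if s0 is None:
        s0 = float(np.median(s))
    contrast = np.sqrt(between / max(K - 1, 1))
    return contrast / (s + s0), s0


def sam_multiclass(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    fdr_threshold: float = 0.005,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-FDR multiclass differential expression (SAM-style).

    Returns a gene-indexed frame with columns ``statistic``, ``q_value`` and
    ``selected``; the null distribution comes from label permutations, and
    gene-level FDR at each observed statistic is the median permuted count of
    exceedances over the observed count, made monotone.
    """
    if n_permutations < 25:
        raise ValidationError("n_permutations < 25 gives an unstable FDR")
    lab = labels.reindex(matrix.sample_ids)
    if lab.isna().any():
        raise ValidationError("every sample needs a label")
    lab = lab.to_numpy()
    classes, counts = np.unique(lab, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValidationError("need >= 2 classes with >= 2 samples each")
    values = matrix.values
    stat, s0 = _multiclass_stat(values, lab)
    rng = np.random.default_rng(seed)
    order = np.argsort(stat)[::-1]
    sorted_stat = stat[order]
    exceed = np.zeros((n_permutations, values.shape[0]))
    for b in range(n_permutations):
        perm = rng.permutation(lab)
        null_stat, _ = _multiclass_stat(values, perm, s0=s0)
        # for each observed cutoff, how many null stats reach it
        null_sorted = np.sort(null_stat)
        exceed[b, :] = null_stat.size - np.searchsorted(
            null_sorted, sorted_stat, side="left"
        )
    observed_count = np.arange(1, values.shape[0] + 1)
    fdr_sorted = np.median(exceed, axis=0) / observed_count
    fdr_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]  # monotone in stat
    q = np.empty_like(fdr_sorted)
    q[order] = np.clip(fdr_sorted, 0, 1)
    out = pd.DataFrame(
        {"statistic": stat, "q_value": q, "selected": q <= fdr_threshold},
        index=matrix.gene_ids,
    )
    return out


# ---------------------------------------------------------------------------
# PAM / nearest shrunken centroids
# ---------------------------------------------------------------------------


@dataclass
class PamModel:
    """Nearest-shrunken-centroid model at the LOOCV-selected threshold."""

    gene_ids: list[str]
    classes: list[str]
    shrunken_scores: np.ndarray  # genes x classes, d'_ik
    centroids: np.ndarray  # genes x classes, unshrunken class means
    overall_centroid: np.ndarray
    pooled_sd: np.ndarray
    s0: float
    threshold: float
    cv_error: float

    @property
    def active_genes(self) -> np.ndarray:
        """Mask of genes with at least one surviving (non-zero) score."""
        return np.any(self.shrunken_scores != 0, axis=1)

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.shrunken_scores, index=self.gene_ids, columns=self.classes)


def _pam_fit(values, lab, classes, delta, s0=None):
    n = values.shape[1]
    K = len(classes)
    overall = values.mean(axis=1)
    centroids = np.column_stack([values[:, lab == c].mean(axis=1) for c in classes])
    within_ss = np.zeros(values.shape[0])
    mks = np.empty(K)
    for k, c in enumerate(classes):
        cols = lab == c
        nk = int(cols.sum())
        mks[k] = np.sqrt(1.0 / nk - 1.0 / n)
        within_ss += ((values[:, cols] - centroids[:, [k]]) ** 2).sum(axis=1)
    s = np.sqrt(within_ss / max(n - K, 1))
    if s0 is None:
        s0 = float(np.median(s))
    denom = (s + s0)[:, None] * mks[None, :]
    d = (centroids - overall[:, None]) / denom
    d_shrunk = np.sign(d) * np.clip(np.abs(d) - delta, 0, None)
    shrunk_centroids = overall[:, None] + denom * d_shrunk
    return d_shrunk, shrunk_centroids, overall, s, s0


def _pam_predict(values, shrunk_centroids, s, s0):
    # discriminant: squared standardized distance to each shrunken centroid
    w2 = ((s + s0) ** 2)[:, None]
    scores = np.empty((values.shape[1], shrunk_centroids.shape[1]))
    for k in range(shrunk_centroids.shape[1]):
        diff = values - shrunk_centroids[:, [k]]
        scores[:, k] = (diff**2 / w2).sum(axis=0)
    return scores.argmin(axis=1)


def pam_train(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    delta_grid=None,
) -> PamModel:
    """Fit shrunken centroids, choosing the threshold by LOOCV error.

    Ties between thresholds are broken toward the smallest (retaining the
    most genes, since the selected genes feed the downstream signature);
    the class prior is uniform.
    """
    lab = labels.reindex(matrix.sample_ids)
    if lab.isna().any():
        raise ValidationError("every sample needs a label")
    lab = lab.to_numpy()
    classes = sorted(np.unique(lab))
    counts = {c: int((lab == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        small = min(counts, key=counts.get)
        raise ValidationError(f"class {small!r} has one sample; LOOCV degenerate")
    values = matrix.values
    if delta_grid is None:
        d0, _, _, _, _ = _pam_fit(values, lab, classes, delta=0.0)
        delta_grid = np.linspace(0.0, float(np.abs(d0).max()), 30)
    delta_grid = np.asarray(delta_grid, dtype=float)

    n = values.shape[1]
    errors = np.zeros(delta_grid.size)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub, sub_lab = values[:, keep], lab[keep]
        # unshrunk fold statistics computed once; only shrinkage varies
        d, _, overall, s, s0 = _pam_fit(sub, sub_lab, classes, delta=0.0)
        mks = np.array(
            [np.sqrt(1.0 / (sub_lab == c).sum() - 1.0 / sub.shape[1]) for c in classes]
        )
        denom = (s + s0)[:, None] * mks[None, :]
        for di, delta in enumerate(delta_grid):
            d_shrunk = np.sign(d) * np.clip(np.abs(d) - delta, 0, None)
            cent = overall[:, None] + denom * d_shrunk
            pred = _pam_predict(values[:, [i]], cent, s, s0)[0]
            if classes[pred] != lab[i]:
                errors[di] += 1
    errors /= n
    best = np.flatnonzero(errors == errors.min()).min()  # keep the most genes
    delta = float(delta_grid[best])
    d_shrunk, _, overall, s, s0 = _pam_fit(values, lab, classes, delta)
    centroids = np.column_stack([values[:, lab == c].mean(axis=1) for c in classes])
    return PamModel(
        gene_ids=list(matrix.gene_ids),
        classes=list(classes),
        shrunken_scores=d_shrunk,
        centroids=centroids,
        overall_centroid=overall,
        pooled_sd=s,
        s0=s0,
        threshold=delta,
        cv_error=float(errors[best]),
    )


# ---------------------------------------------------------------------------
# Stromal filter and non-redundant class assignment
# ---------------------------------------------------------------------------


def stromal_filter(
    gene_list: list[str],
    stromal_fraction_table: pd.DataFrame | pd.Series,
    threshold: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Remove genes whose stromal signal fraction is strictly above threshold.

    Genes missing from the table are kept with a logged warning (a
    xenograft-derived stromal table need not cover every gene).
    """
    if isinstance(stromal_fraction_table, pd.DataFrame):
        fractions = stromal_fraction_table.iloc[:, 0]
    else:
        fractions = stromal_fraction_table
    known = fractions.dropna()
    if len(known) and (known.min() < 0 or known.max() > 1):
        raise ValidationError("stromal fractions must lie in [0, 1]")
    kept, removed = [], []
    missing = 0
    for g in gene_list:
        if g not in fractions.index or pd.isna(fractions.get(g)):
            missing += 1
            kept.append(g)
        elif float(fractions[g]) > threshold:
            removed.append(g)
        else:
            kept.append(g)
    if missing:
        logger.warning(
            "%d gene(s) missing from the stromal table were kept", missing
        )
    return kept, removed


def assign_nonredundant(pam_model: PamModel, gap: float = 0.2) -> GeneSignatureSet:
    """Assign genes with positive shrunken scores to single classes.

    A gene positive for exactly one class goes to that class; a gene positive
    for several goes to its best class only when best - second >= gap, and is
    excluded otherwise. Genes with no positive score are excluded.
    """
    scores = pam_model.scores_frame()
    genes_by_class: dict[str, list[str]] = {c: [] for c in pam_model.classes}
    for g, row in scores.iterrows():
        positive = row[row > 0]
        if positive.empty:
            continue
        ranked = positive.sort_values(ascending=False)
        if len(ranked) == 1 or ranked.iloc[0] - ranked.iloc[1] >= gap:
            genes_by_class[ranked.index[0]].append(g)
    empty = [c for c, gs in genes_by_class.items() if not gs]
    if empty:
        raise ValidationError(f"class(es) {empty} end with 0 genes")
    return GeneSignatureSet(list(pam_model.classes), genes_by_class)


# ---------------------------------------------------------------------------
# Cascade bookkeeping
# ---------------------------------------------------------------------------


def filter_cascade_report(
    candidates: int,
    no_positive_score: int = 0,
    stromal_removed: int = 0,
    redundancy_excluded: int = 0,
) -> dict[str, int]:
    """Arithmetic ledger of the signature-building cascade.

    candidates - no_positive_score - stromal_removed = pre-redundancy pool;
    pool - redundancy_excluded = final classifier size. Raises on any
    negative intermediate.
    """
    pool = candidates - no_positive_score - stromal_removed
    final = pool - redundancy_excluded
    report = {
        "candidates": candidates,
        "no_positive_score": no_positive_score,
        "stromal_removed": stromal_removed,
        "pre_redundancy_pool": pool,
        "redundancy_excluded": redundancy_excluded,
        "final_classifier_size": final,
    }
    if pool < 0 or final < 0:
        raise ValidationError(f"negative intermediate in cascade: {report}")
    return report


# ---------------------------------------------------------------------------
# End-to-end discovery pipeline
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryResult:
    consensus_results: list[ConsensusResult]
    selected: ConsensusResult
    core_samples: list[str]
    dropped_samples: list[str]
    sam_table: pd.DataFrame
    pam_model: PamModel
    signatures: GeneSignatureSet
    cascade: dict[str, int]
    cluster_labels: pd.Series  # core samples -> cluster class label


def discover_signatures(
    matrix: ExpressionMatrix,
    stromal_fraction_table: pd.DataFrame | pd.Series | None = None,
    sd_threshold: float = 0.8,
    K_range=range(2, 7),
    n_runs: int = 50,
    sam_fdr: float = 0.005,
    sam_permutations: int = 100,
    stromal_threshold: float = 0.5,
    gap: float = 0.2,
    seed: int = 0,
) -> DiscoveryResult:
    """Run the full discovery cascade and return the signature set.

    Cluster classes are named ``CLS1..CLSK`` in hard-label order.
    """
    variable = select_variable_genes(matrix, sd_threshold)
    normalized = zscore_samples(matrix.subset_genes(variable))
    consensus_results = nmf_consensus(
        normalized, K_range=K_range, n_runs=n_runs, seed=seed
    )
    selected = best_k(consensus_results)
    core, dropped = silhouette_filter(selected)
    label_map = dict(zip(selected.sample_ids, selected.hard_labels))
    cluster_labels = pd.Series(
        {s: f"CLS{label_map[s]}" for s in core}, name="cluster"
    )
    core_matrix = normalized.subset_samples(core)
    sam_table = sam_multiclass(
        core_matrix, cluster_labels, fdr_threshold=sam_fdr,
        n_permutations=sam_permutations, seed=seed,
    )
    sam_genes = list(sam_table.index[sam_table["selected"]])
    if len(sam_genes) < 2:
        raise ValidationError("fewer than 2 genes pass the SAM FDR threshold")
    pam_model = pam_train(core_matrix.subset_genes(sam_genes), cluster_labels)
    scores = pam_model.scores_frame()
    has_positive = (scores > 0).any(axis=1)
    candidates = list(scores.index)
    positives = list(scores.index[has_positive])
    if stromal_fraction_table is not None:
        kept, removed = stromal_filter(positives, stromal_fraction_table, stromal_threshold)
    else:
        kept, removed = positives, []
    kept_set = set(kept)
    pruned = PamModel(
        gene_ids=pam_model.gene_ids,
        classes=pam_model.classes,
        shrunken_scores=np.where(
            np.array([g in kept_set for g in pam_model.gene_ids])[:, None],
            pam_model.shrunken_scores,
            0.0,
        ),
        centroids=pam_model.centroids,
        overall_centroid=pam_model.overall_centroid,
        pooled_sd=pam_model.pooled_sd,
        s0=pam_model.s0,
        threshold=pam_model.threshold,
        cv_error=pam_model.cv_error,
    )
    signatures = assign_nonredundant(pruned, gap=gap)
    cascade = filter_cascade_report(
        candidates=len(candidates),
        no_positive_score=len(candidates) - len(positives),
        stromal_removed=len(removed),
        redundancy_excluded=len(kept) - len(signatures.all_genes),
    )
    return DiscoveryResult(
        consensus_results=consensus_results,
        selected=selected,
        core_samples=core,
        dropped_samples=dropped,
        sam_table=sam_table,
        pam_model=pam_model,
        signatures=signatures,
        cascade=cascade,
        cluster_labels=cluster_labels,
    )
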