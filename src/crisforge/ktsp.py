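"""Single-sample multiclass top-scoring-pairs (k-TSP) classification.

A TSP votes for one of two classes according to whether gene A exceeds gene B
within a sample, so the classifier depends only on within-sample gene ranks
and is invariant to any strictly monotone per-sample transform — the property
that makes it portable across platforms. Cross-platform gene reproducibility
is screened first with the integrative correlation (ICOR) index, dichotomized
by a two-component Gaussian mixture; candidate genes per class come from a
Wilcoxon rank-sum screen; pairs are then picked greedily per pairwise class
comparison in a caller-specified order, consuming genes so that all pairs are
disjoint. Votes are aggregated by per-class vote proportions with explicit
tie rules.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.mixture import GaussianMixture

from .core_io import (
    UNASSIGNED,
    ExpressionMatrix,
    GeneSignatureSet,
    ValidationError,
)


# ---------------------------------------------------------------------------
# Integrative correlation
# ---------------------------------------------------------------------------


def integrative_correlation(datasets: list[ExpressionMatrix]) -> pd.DataFrame:
    """Per-gene cross-dataset reproducibility of co-expression profiles.

    Within each dataset, expression is rank-transformed across samples and a
    gene x gene correlation matrix computed. For each gene and each pair of
    datasets, the pairwise ICOR is the Pearson correlation between the gene's
    two co-expression profiles (self excluded); the ``icor`` column is the
    mean over dataset pairs.
    """
    if len(datasets) < 2:
        raise ValidationError("need >= 2 datasets")
    shared = [g for g in datasets[0].gene_ids
              if all(g in set(d.gene_ids) for d in datasets[1:])]
    if len(shared) < 10:
        raise ValidationError(f"only {len(shared)} shared genes; need >= 10")
    corrs = []
    for d in datasets:
        sub = d.subset_genes(shared)
        ranks = sp_stats.rankdata(sub.values, axis=1)
        c = np.corrcoef(ranks)
        corrs.append(np.nan_to_num(c, nan=0.0))
    G = len(shared)
    off_diag = ~np.eye(G, dtype=bool)
    pair_cols = {}
    total = np.zeros(G)
    n_pairs = 0
    for (ia, ca), (ib, cb) in itertools.combinations(enumerate(corrs), 2):
        vals = np.empty(G)
        for g in range(G):
            pa = ca[g, off_diag[g]]
            pb = cb[g, off_diag[g]]
            sa, sb = pa.std(), pb.std()
            vals[g] = 0.0 if sa == 0 or sb == 0 else float(np.corrcoef(pa, pb)[0, 1])
        pair_cols[f"icor_{ia + 1}_{ib + 1}"] = vals
        total += vals
        n_pairs += 1
    out = pd.DataFrame(pair_cols, index=shared)
    out["icor"] = total / n_pairs
    return out


def em_dichotomize(icor_values, seed: int = 0, max_iter: int = 500):
    """Split ICOR values into reproducible / irreproducible groups by EM.

    Fits a two-component univariate Gaussian mixture; the threshold is the
    equal-posterior crossing between the component means, and genes in the
    upper component are kept.

    Returns
    -------
    (threshold, kept_index)
    """
    if isinstance(icor_values, pd.DataFrame):
        series = icor_values["icor"]
    elif isinstance(icor_values, pd.Series):
        series = icor_values
    else:
        series = pd.Series(np.asarray(icor_values, dtype=float))
    x = series.to_numpy(dtype=float)
    if x.size < 20:
        raise ValidationError("need >= 20 values for EM dichotomization")
    if np.ptp(x) == 0:
        raise ValidationError("all values identical; mixture is degenerate")
    gm = GaussianMixture(
        n_components=2, covariance_type="full", max_iter=max_iter,
        n_init=5, random_state=seed, reg_covar=1e-6,
    ).fit(x[:, None])
    if not gm.converged_:
        raise ValidationError(
            f"EM did not converge in {max_iter} iterations "
            f"(lower bound {gm.lower_bound_:.4g})"
        )
    means = gm.means_.ravel()
    lo_c, hi_c = np.argsort(means)
    lo, hi = means[lo_c], means[hi_c]
    grid = np.linspace(lo, hi, 2001)
    post = gm.predict_proba(grid[:, None])
    diff = post[:, hi_c] - post[:, lo_c]
    cross = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    threshold = float(grid[cross[0]]) if cross.size else float((lo + hi) / 2)
    kept = series.index[x > threshold]
    return threshold, list(kept)


# ---------------------------------------------------------------------------
# Candidate markers and pair scoring
# ---------------------------------------------------------------------------


def select_class_markers(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    class_label: str,
    n_top: int = 50,
) -> list[str]:
    """Top differentially expressed genes for one class vs the rest.

    Genes are ranked by the two-sided Wilcoxon rank-sum p-value of the class
    samples against all others (ties broken by absolute standardized
    statistic).
    """
    lab = labels.reindex(matrix.sample_ids)
    in_class = (lab == class_label).to_numpy()
    if not in_class.any():
        raise ValidationError(f"class {class_label!r} absent from labels")
    x = matrix.values[:, in_class]
    y = matrix.values[:, ~in_class]
    stat, p = sp_stats.ranksums(x, y, axis=1)
    order = np.lexsort((-np.abs(stat), p))
    return [matrix.gene_ids[i] for i in order[:n_top]]


def tsp_delta(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    gene_i: str,
    gene_j: str,
    comparison: tuple[str, str],
):
    """Score one gene pair for one pairwise class comparison.

    delta = |P(X_i < X_j | classX) - P(X_i < X_j | classY)| with within-sample
    ties counting 0.5; gamma is the absolute difference of the mean
    within-sample rank difference between the two classes (the secondary
    score). The orientation records which class a ``gene_i > gene_j``
    observation votes for.

    Returns
    -------
    (delta, gamma, vote_if_high_gt_low)
    """
    class_x, class_y = comparison
    lab = labels.reindex(matrix.sample_ids)
    for c in comparison:
        if not (lab == c).any():
            raise ValidationError(f"class {c!r} has 0 samples")
    xi = matrix.values[matrix.gene_index([gene_i])[0], :]
    xj = matrix.values[matrix.gene_index([gene_j])[0], :]
    less = (xi < xj) + 0.5 * (xi == xj)
    mask_x = (lab == class_x).to_numpy()
    mask_y = (lab == class_y).to_numpy()
    p_x = float(less[mask_x].mean())
    p_y = float(less[mask_y].mean())
    delta = abs(p_x - p_y)
    ranks = sp_stats.rankdata(matrix.values, axis=0)
    rd = ranks[matrix.gene_index([gene_i])[0], :] - ranks[matrix.gene_index([gene_j])[0], :]
    gamma = abs(float(rd[mask_x].mean()) - float(rd[mask_y].mean()))
    # if gene_i > gene_j is more typical of class_x, that ordering votes X
    vote = class_x if p_x < p_y else class_y
    return delta, gamma, vote


# ---------------------------------------------------------------------------
# Classifier construction
# ---------------------------------------------------------------------------


@dataclass
class TspPair:
    gene_high: str
    gene_low: str
    comparison: tuple[str, str]
    vote_if_high_gt_low: str
    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gene_high == self.gene_low:
            raise ValidationError("a pair needs two distinct genes")
        if self.vote_if_high_gt_low not in self.comparison:
            raise ValidationError("vote class must belong to the comparison")

    @property
    def vote_if_low_gt_high(self) -> str:
        a, b = self.comparison
        return b if self.vote_if_high_gt_low == a else a


@dataclass
class KTSPClassifier:
    pairs: list[TspPair]
    k_per_comparison: int
    classes: list[str]

    def __post_init__(self) -> None:
        genes = [g for p in self.pairs for g in (p.gene_high, p.gene_low)]
        if len(genes) != len(set(genes)):
            raise ValidationError("pairs must use disjoint genes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_high": p.gene_high,
                    "gene_low": p.gene_low,
                    "comparison": f"{p.comparison[0]}|{p.comparison[1]}",
                    "vote_class": p.vote_if_high_gt_low,
                    "delta": p.delta,
                    "gamma": p.gamma,
                }
                for p in self.pairs
            ]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, k: int, classes: list[str]) -> "KTSPClassifier":
        pairs = [
            TspPair(
                gene_high=row.gene_high,
                gene_low=row.gene_low,
                comparison=tuple(row.comparison.split("|")),
                vote_if_high_gt_low=row.vote_class,
                delta=float(row.delta),
                gamma=float(row.gamma),
            )
            for row in frame.itertuples()
        ]
        return cls(pairs, k, classes)


def default_comparison_order(
    classes: list[str],
    candidates_by_class: dict[str, list[str]] | None = None,
    priority: list[str] | None = None,
) -> list[tuple[str, str]]:
    """Reproduce the search-order heuristic: priority classes first (each
    compared against the others, smallest candidate pool first), then the
    remaining comparisons by ascending combined pool size."""
    pool = {c: len(candidates_by_class[c]) if candidates_by_class else 0 for c in classes}
    priority = priority or []
    order: list[tuple[str, str]] = []
    seen: set[frozenset] = set()

    def add(a: str, b: str) -> None:
        key = frozenset((a, b))
        if key not in seen:
            seen.add(key)
            order.append((a, b))

    for p in priority:
        others = sorted(
            (c for c in classes if c != p and frozenset((p, c)) not in seen),
            key=lambda c: (pool[c], c),
        )
        for c in others:
            add(p, c)
    rest = sorted(
        (
            (a, b)
            for a, b in itertools.combinations(classes, 2)
            if frozenset((a, b)) not in seen
        ),
        key=lambda ab: (pool[ab[0]] + pool[ab[1]], ab),
    )
    for a, b in rest:
        add(a, b)
    return order


def _pairwise_deltas(values_x, values_y, genes_a_idx, genes_b_idx):
    """delta and orientation for all (a, b) candidate pairs, vectorized."""
    # P(less) per pair within each class
    ax, bx = values_x[genes_a_idx, :], values_x[genes_b_idx, :]
    ay, by = values_y[genes_a_idx, :], values_y[genes_b_idx, :]
    px = ((ax[:, None, :] < bx[None, :, :]) + 0.5 * (ax[:, None, :] == bx[None, :, :])).mean(axis=2)
    py = ((ay[:, None, :] < by[None, :, :]) + 0.5 * (ay[:, None, :] == by[None, :, :])).mean(axis=2)
    return np.abs(px - py), px, py


def build_ktsp(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    candidates_by_class: dict[str, list[str]],
    k: int = 4,
    comparison_order: list[tuple[str, str]] | None = None,
) -> KTSPClassifier:
    """Greedy ordered disjoint pair search.

    Comparisons are processed in the given order; within each, the k
    highest-delta pairs among cross-class candidate pairs whose genes are
    still unused are taken (gamma, then lexicographic gene ids, break ties),
    and their genes are removed from all subsequent searches.
    """
    classes = sorted(candidates_by_class)
    if comparison_order is None:
        comparison_order = default_comparison_order(classes, candidates_by_class)
    needed = set(map(frozenset, itertools.combinations(classes, 2)))
    got = set(map(frozenset, comparison_order))
    if needed - got:
        raise ValidationError(f"comparison_order misses {sorted(map(sorted, needed - got))}")

    lab = labels.reindex(matrix.sample_ids)
    ranks = sp_stats.rankdata(matrix.values, axis=0)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    used: set[str] = set()
    pairs: list[TspPair] = []
    for class_x, class_y in comparison_order:
        cand_a = [g for g in candidates_by_class[class_x] if g not in used]
        cand_b = [g for g in candidates_by_class[class_y] if g not in used and g not in cand_a]
        mask_x = (lab == class_x).to_numpy()
        mask_y = (lab == class_y).to_numpy()
        if not mask_x.any() or not mask_y.any():
            raise ValidationError(f"comparison {class_x} vs {class_y}: empty class")
        if len(cand_a) < k or len(cand_b) < k:
            raise ValidationError(
                f"comparison {class_x} vs {class_y}: candidate pool exhausted "
                f"({len(cand_a)} x {len(cand_b)} genes left, need k={k})"
            )
        ia = np.array([gene_pos[g] for g in cand_a])
        ib = np.array([gene_pos[g] for g in cand_b])
        deltas, px, py = _pairwise_deltas(
            matrix.values[:, mask_x], matrix.values[:, mask_y], ia, ib
        )
        rd_x = ranks[:, mask_x]
        rd_y = ranks[:, mask_y]
        mean_rd_x = rd_x[ia, :].mean(axis=1)[:, None] - rd_x[ib, :].mean(axis=1)[None, :]
        mean_rd_y = rd_y[ia, :].mean(axis=1)[:, None] - rd_y[ib, :].mean(axis=1)[None, :]
        gammas = np.abs(mean_rd_x - mean_rd_y)
        entries = sorted(
            (
                (-deltas[a, b], -gammas[a, b], cand_a[a], cand_b[b], a, b)
                for a in range(len(cand_a))
                for b in range(len(cand_b))
            ),
        )
        taken = 0
        local_used: set[str] = set()
        for negd, negg, ga, gb, a, b in entries:
            if taken == k:
                break
            if ga in local_used or gb in local_used:
                continue
            vote = class_x if px[a, b] < py[a, b] else class_y
            # store pair oriented so gene_high > gene_low is typical of `vote`
            pairs.append(
                TspPair(
                    gene_high=ga,
                    gene_low=gb,
                    comparison=(class_x, class_y),
                    vote_if_high_gt_low=vote,
                    delta=float(-negd),
                    gamma=float(-negg),
                )
            )
            local_used.update((ga, gb))
            taken += 1
        if taken < k:
            raise ValidationError(
                f"comparison {class_x} vs {class_y}: only {taken} disjoint "
                f"pairs available, need k={k}"
            )
        used.update(local_used)
    return KTSPClassifier(pairs=pairs, k_per_comparison=k, classes=classes)


# ---------------------------------------------------------------------------
# Classification rule
# ---------------------------------------------------------------------------


def ktsp_classify(sample_expression: pd.Series, classifier: KTSPClassifier) -> str:
    """Apply the voting rule to a single sample.

    (i) TSPs whose genes are not measured are discarded; (ii) per-class vote
    proportion = votes for the class / comparisons involving the class with
    at least one evaluable pair; (iii) unique maximum wins; (iv) a tie among
    three or more classes leaves the sample UNASSIGNED; (v) a two-way tie is
    resolved by the head-to-head comparison's vote proportions, UNASSIGNED if
    still tied.
    """
    votes: dict[tuple[str, str], dict[str, float]] = {}
    for pair in classifier.pairs:
        if pair.gene_high not in sample_expression.index or pair.gene_low not in sample_expression.index:
            continue
        hi = sample_expression[pair.gene_high]
        lo = sample_expression[pair.gene_low]
        if not (np.isfinite(hi) and np.isfinite(lo)):
            continue
        comp = pair.comparison
        votes.setdefault(comp, {comp[0]: 0.0, comp[1]: 0.0})
        if hi > lo:
            votes[comp][pair.vote_if_high_gt_low] += 1
        elif lo > hi:
            votes[comp][pair.vote_if_low_gt_high] += 1
        else:  # exact tie within the sample: split the vote
            votes[comp][pair.vote_if_high_gt_low] += 0.5
            votes[comp][pair.vote_if_low_gt_high] += 0.5
    if not votes:
        raise ValidationError("no evaluable pair for this sample")

    win_counts: dict[str, float] = {c: 0.0 for c in classifier.classes}
    comp_counts: dict[str, int] = {c: 0 for c in classifier.classes}
    for comp, tally in votes.items():
        total = sum(tally.values())
        for c in comp:
            comp_counts[c] += 1
            win_counts[c] += tally[c] / total if total else 0.5
    proportions = {
        c: (win_counts[c] / comp_counts[c]) for c in classifier.classes if comp_counts[c]
    }
    best = max(proportions.values())
    leaders = sorted(c for c, v in proportions.items() if v == best)
    if len(leaders) == 1:
        return leaders[0]
    if len(leaders) > 2:
        return UNASSIGNED
    a, b = leaders
    head = votes.get((a, b)) or votes.get((b, a))
    if head is None:
        return UNASSIGNED
    if head[a] > head[b]:
        return a
    if head[b] > head[a]:
        return b
    return UNASSIGNED


def ktsp_classify_matrix(matrix: ExpressionMatrix, classifier: KTSPClassifier) -> pd.Series:
    """Vectorized convenience: classify every column of a matrix."""
    frame = matrix.to_frame()
    return pd.Series(
        {s: ktsp_classify(frame[s], classifier) for s in matrix.sample_ids},
        name="predicted_class",
    )


def tsp_to_ntp_signatures(classifier: KTSPClassifier) -> GeneSignatureSet:
    """Reduce the pair classifier to per-class marker lists for NTP.

    Each gene is assigned to the class its ordering votes for; with k pairs
    per comparison and n classes every class receives k*(n-1) genes.
    """
    genes_by_class: dict[str, list[str]] = {c: [] for c in classifier.classes}
    for pair in classifier.pairs:
        genes_by_class[pair.vote_if_high_gt_low].append(pair.gene_high)
        genes_by_class[pair.vote_if_low_gt_high].append(pair.gene_low)
    return GeneSignatureSet(list(classifier.classes), genes_by_class)


def count_candidate_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs, C(n, 2)."""
    if n_genes < 2:
        raise ValidationError("need >= 2 genes to form a pair")
    return math.comb(n_genes, 2)


def stratified_split(
    labels: pd.Series,
    platforms: pd.Series | None = None,
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Train/test split stratified on the (platform x class) grid."""
    rng = np.random.default_rng(seed)
    strata = labels.astype(str)
    if platforms is not None:
        strata = strata + "||" + platforms.reindex(labels.index).astype(str)
    train: list[str] = []
    test: list[str] = []
    for _, group in strata.groupby(strata):
        ids = list(group.index)
        rng.shuffle(ids)
        n_train = int(round(train_fraction * len(ids)))
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return train, test
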