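"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates what human-specific profiling of xenografts provides:
a latent K-subtype cancer signal, contaminated per sample by a convex mixture
with a stromal expression program, observed through Gaussian noise — plus
multi-platform replicates (monotone distortions of the same latent signal),
segmented copy-number profiles and per-sample mutation counts. Marker-block
truth is carried along so discovery and classification can be scored against
the planted structure.

The stromal mixture is applied directly on the log2 scale (a linear, pre-log
residual approximation); real contamination mixes on the intensity scale.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneSignatureSet, ValidationError


@dataclass
class SubtypeModel:
    """Parameters of the latent-subtype generative model.

    Defaults are the fixture used throughout the test suite: 5 classes with
    30 markers each over 500 background genes, marker effect 3 log2 units,
    noise sd 0.5 and mild stromal contamination.
    """

    n_classes: int = 5
    markers_per_class: int = 30
    effect_size: float = 3.0
    n_background_genes: int = 500
    noise_sd: float = 0.5
    n_stromal_genes: int = 40
    stromal_amplitude: float = 3.0
    stromal_fraction_range: tuple[float, float] = (0.0, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        lo, hi = self.stromal_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("stromal_fraction_range must be within [0, 1]")

    # --- planted truth ----------------------------------------------------
    @property
    def class_labels(self) -> list[str]:
        return [f"C{k + 1}" for k in range(self.n_classes)]

    @property
    def n_genes(self) -> int:
        return (
            self.n_classes * self.markers_per_class
            + self.n_stromal_genes
            + self.n_background_genes
        )

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def marker_genes(self) -> dict[str, list[str]]:
        """Disjoint marker blocks, laid out first in the gene list."""
        ids = self.gene_ids
        out: dict[str, list[str]] = {}
        for k, cls in enumerate(self.class_labels):
            start = k * self.markers_per_class
            out[cls] = ids[start : start + self.markers_per_class]
        return out

    def stromal_genes(self) -> list[str]:
        start = self.n_classes * self.markers_per_class
        return self.gene_ids[start : start + self.n_stromal_genes]

    def true_signatures(self) -> GeneSignatureSet:
        return GeneSignatureSet(self.class_labels, self.marker_genes())


def simulate_expression(
    model: SubtypeModel, n_samples_per_class: int
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Draw an expression matrix from the subtype model.

    Observed value = (1 - f_s) * cancer + f_s * stromal + N(0, noise_sd),
    with a per-sample stromal mixing fraction f_s drawn uniformly from the
    model's range.

    Returns
    -------
    (matrix, true_labels, stromal_fraction_table)
        ``true_labels`` is a sample-indexed Series of planted class labels;
        the table has one row per gene with column ``stromal_fraction``, the
        expected share of that gene's signal that is of stromal origin.
    """
    if n_samples_per_class < 1:
        raise ValidationError("n_samples_per_class must be >= 1")
    rng = np.random.default_rng(model.seed)
    genes = model.gene_ids
    classes = model.class_labels
    n_samples = model.n_classes * n_samples_per_class
    labels = np.repeat(classes, n_samples_per_class)
    sample_ids = [f"S{j + 1:04d}" for j in range(n_samples)]

    baseline = rng.normal(7.0, 1.0, size=model.n_genes)
    cancer = np.tile(baseline[:, None], (1, n_samples))
    markers = model.marker_genes()
    gene_pos = {g: i for i, g in enumerate(genes)}
    for k, cls in enumerate(classes):
        cols = np.flatnonzero(labels == cls)
        rows = [gene_pos[g] for g in markers[cls]]
        cancer[np.ix_(rows, cols)] += model.effect_size

    stromal_program = np.zeros(model.n_genes)
    stromal_rows = [gene_pos[g] for g in model.stromal_genes()]
    stromal_program[stromal_rows] = model.stromal_amplitude
    stromal = baseline[:, None] + stromal_program[:, None]

    lo, hi = model.stromal_fraction_range
    f_s = rng.uniform(lo, hi, size=n_samples)
    noise = rng.normal(0.0, model.noise_sd, size=(model.n_genes, n_samples))
    observed = (1 - f_s)[None, :] * cancer + f_s[None, :] * stromal + noise

    # expected stromal share of signal: stromal-specific amplitude weighted by
    # the mean mixing fraction, against the gene's cancer-intrinsic amplitude
    f_bar = (lo + hi) / 2
    intrinsic = np.full(model.n_genes, 1.0)
    for cls in classes:
        intrinsic[[gene_pos[g] for g in markers[cls]]] = max(model.effect_size, 1.0)
    intrinsic[stromal_rows] = model.noise_sd
    numer = f_bar * np.abs(stromal_program)
    denom = numer + (1 - f_bar) * intrinsic
    with np.errstate(invalid="ignore"):
        fraction = np.where(denom > 0, numer / denom, 0.0)

    matrix = ExpressionMatrix(genes, sample_ids, observed, platform_label="synthetic")
    table = pd.DataFrame({"stromal_fraction": fraction}, index=genes)
    return matrix, pd.Series(labels, index=sample_ids, name="true_class"), table


@dataclass
class PlatformDistortion:
    """Monotone per-platform transform plus measurement noise.

    Applies ``gain * (x - center) + cubic * (x - center)**3 + offset`` with
    ``gain > 0`` and ``cubic >= 0`` (strictly increasing), then adds Gaussian
    noise of sd ``noise_sd``.
    """

    gain: float = 1.0
    offset: float = 0.0
    cubic: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.cubic < 0:
            raise ValidationError("distortion must be strictly increasing")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        center = values.mean()
        x = values - center
        out = self.gain * x + self.cubic * x**3 + self.offset + center
        if self.noise_sd > 0:
            out = out + rng.normal(0.0, self.noise_sd, size=values.shape)
        return out


def default_distortions(
    n_platforms: int, noise_sd: float = 0.3, seed: int = 0
) -> list[PlatformDistortion]:
    """A spread of mild monotone distortions, platform 0 near-identity."""
    rng = np.random.default_rng(seed)
    out = [PlatformDistortion(noise_sd=noise_sd)]
    for _ in range(n_platforms - 1):
        out.append(
            PlatformDistortion(
                gain=float(rng.uniform(0.6, 1.6)),
                offset=float(rng.uniform(-2.0, 2.0)),
                cubic=float(rng.uniform(0.0, 0.05)),
                noise_sd=noise_sd,
            )
        )
    return out


def simulate_multiplatform(
    matrix: ExpressionMatrix,
    n_platforms: int,
    distortion: Sequence[PlatformDistortion] | None = None,
    seed: int = 0,
) -> list[ExpressionMatrix]:
    """Replicate a matrix across platforms as monotone distortions + noise.

    Each platform preserves within-sample gene ranks in expectation; all
    platforms share the gene space of the input.
    """
    if n_platforms < 2:
        raise ValidationError("need at least 2 platforms")
    if distortion is None:
        distortion = default_distortions(n_platforms, seed=seed)
    if len(distortion) != n_platforms:
        raise ValidationError("one distortion per platform required")
    rng = np.random.default_rng(seed)
    out = []
    for p, dist in enumerate(distortion):
        values = dist.apply(matrix.values, rng)
        out.append(
            ExpressionMatrix(
                list(matrix.gene_ids),
                list(matrix.sample_ids),
                values,
                platform_label=f"platform{p + 1}",
            )
        )
    return out


def simulate_segments(
    n_samples: int,
    genome_length: int = 3_000_000_000,
    altered_fraction: float = 0.3,
    amplitude: float = 0.8,
    seed: int = 0,
    segments_per_sample: int = 40,
) -> pd.DataFrame:
    """Per-sample segment sets tiling a single synthetic chromosome.

    The nucleotide fraction with ``|seg_mean| > 0.3`` approximates
    ``altered_fraction`` up to segment-boundary discretization. Columns follow
    the SEG convention (Sample, Chromosome, Start, End, Num_Probes,
    Segment_Mean; 1-based inclusive coordinates).
    """
    if not 0 <= altered_fraction <= 1:
        raise ValidationError("altered_fraction must be in [0, 1]")
    if altered_fraction > 0 and amplitude <= 0.3:
        warnings.warn(
            "amplitude <= 0.3: no segment will count as altered at the "
            "default calling threshold",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    records = []
    for j in range(n_samples):
        while True:
            cuts = np.unique(
                rng.integers(1, genome_length, size=segments_per_sample - 1)
            )
            if cuts.size == segments_per_sample - 1:
                break
        bounds = np.concatenate([[0], cuts, [genome_length]])
        starts = bounds[:-1] + 1
        ends = bounds[1:]
        lengths = ends - starts + 1
        order = rng.permutation(segments_per_sample)
        altered = np.zeros(segments_per_sample, dtype=bool)
        covered = 0
        for idx in order:
            if covered >= altered_fraction * genome_length:
                break
            altered[idx] = True
            covered += lengths[idx]
        for i in range(segments_per_sample):
            if altered[i]:
                mean = amplitude * rng.choice([-1.0, 1.0])
            else:
                mean = rng.normal(0.0, 0.05)
            records.append(
                {
                    "Sample": f"S{j + 1:04d}",
                    "Chromosome": "1",
                    "Start": int(starts[i]),
                    "End": int(ends[i]),
                    "Num_Probes": max(int(lengths[i] // 10_000), 1),
                    "Segment_Mean": float(mean),
                }
            )
    return pd.DataFrame.from_records(records)


def simulate_mutation_counts(
    n_samples: int, rate_per_mb: float = 2.0, seed: int = 0, exome_mb: float = 30.0
) -> pd.DataFrame:
    """Poisson somatic mutation counts at ``rate_per_mb`` over ``exome_mb``."""
    if rate_per_mb < 0:
        raise ValidationError("rate_per_mb must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate_per_mb * exome_mb, size=n_samples)
    return pd.DataFrame(
        {"sample_id": [f"S{j + 1:04d}" for j in range(n_samples)], "count": counts}
    )
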