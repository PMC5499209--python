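"""Per-sample mutational and copy-number alteration load.

Mutational load is somatic mutation count per megabase of exome (default
30 Mb). Copy-number load is the fraction of segmented nucleotides lying in
altered segments, where a segment is altered when its absolute log2 segment
mean is strictly greater than 0.3 (the single-sample alteration-calling
convention). SEG coordinates are 1-based inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import ScoreTable, ValidationError

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def read_seg(path) -> pd.DataFrame:
    """Read a tab-delimited SEG file (header row, SEG column order)."""
    df = pd.read_csv(path, sep="\t")
    if len(df.columns) < 6:
        raise ValidationError(f"{path}: SEG needs 6 columns, got {len(df.columns)}")
    df = df.iloc[:, :6]
    df.columns = SEG_COLUMNS
    df["Sample"] = df["Sample"].astype(str)
    df["Chromosome"] = df["Chromosome"].astype(str)
    _validate_segments(df)
    return df


def _validate_segments(segments: pd.DataFrame) -> None:
    if (segments["End"] < segments["Start"]).any():
        bad = segments[segments["End"] < segments["Start"]].iloc[0]
        raise ValidationError(
            f"segment with End < Start for sample {bad['Sample']!r}"
        )
    for (sample, chrom), group in segments.groupby(["Sample", "Chromosome"]):
        g = group.sort_values("Start")
        overlap = g["Start"].to_numpy()[1:] <= g["End"].to_numpy()[:-1]
        if overlap.any():
            raise ValidationError(
                f"overlapping segments for sample {sample!r} on chromosome "
                f"{chrom!r}; nucleotide count would be ambiguous"
            )


def mutational_load(mutation_counts: pd.DataFrame, exome_mb: float = 30.0) -> ScoreTable:
    """Somatic mutations per megabase, count / exome_mb.

    ``mutation_counts`` needs columns ``sample_id`` and ``count`` (or the
    first two columns are taken as such). Duplicate sample ids are refused —
    duplicate tumour aliquots must be de-duplicated upstream.
    """
    df = mutation_counts.iloc[:, :2].copy()
    df.columns = ["sample_id", "count"]
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r} in mutation counts")
    counts = df["count"].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative mutation count")
    if exome_mb <= 0:
        raise ValidationError("exome_mb must be positive")
    return ScoreTable(list(df["sample_id"]), "mutational_load", counts / exome_mb)


def copy_number_load(segments: pd.DataFrame, threshold: float = 0.3) -> ScoreTable:
    """Altered-nucleotide fraction per sample.

    load = sum(length of segments with |seg_mean| > threshold)
           / sum(length of all segments), with length = End - Start + 1 and a
    strictly-greater-than alteration call.
    """
    seg = segments.copy()
    seg.columns = SEG_COLUMNS[: len(seg.columns)]
    _validate_segments(seg)
    lengths = seg["End"].to_numpy(dtype=float) - seg["Start"].to_numpy(dtype=float) + 1
    altered = np.abs(seg["Segment_Mean"].to_numpy(dtype=float)) > threshold
    frame = pd.DataFrame(
        {"sample": seg["Sample"].astype(str), "length": lengths,
         "altered_length": lengths * altered}
    )
    agg = frame.groupby("sample", sort=True).sum()
    if (agg["length"] <= 0).any():
        raise ValidationError("a sample has zero segmented length")
    loads = (agg["altered_length"] / agg["length"]).to_numpy()
    return ScoreTable(list(agg.index), "copy_number_load", loads)
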