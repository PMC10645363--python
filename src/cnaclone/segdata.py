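"""Segment-level single-cell count data.

The clone-inference model consumes a cells x segments matrix of
non-negative integer counts per modality (RNA or ATAC), where a segment is
a contiguous genomic interval (typically a chromosome arm) assumed to carry
one copy-number state per clone. This module reads raw 10x-style feature
counts or pre-aggregated tables, maps features onto a segmentation,
computes per-cell library-size factors, filters uninformative segments and
pairs barcodes for multiome assays.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "SegmentRecord",
    "SegmentedCounts",
    "FeatureCounts",
    "read_segments",
    "read_10x_counts",
    "read_cell_table",
    "write_cell_table",
    "aggregate_to_segments",
    "compute_library_factors",
    "filter_segments",
    "pair_multiome",
]

MODALITIES = ("RNA", "ATAC")


@dataclass(frozen=True)
class SegmentRecord:
    """One genomic segment with an optional prior (expected) copy number."""

    chrom: str
    start: int
    end: int
    segment_id: str
    expected_cn: int = 2

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.segment_id!r}: start ({self.start}) must be "
                f"< end ({self.end})"
            )
        if self.expected_cn < 1:
            raise ValueError(
                f"segment {self.segment_id!r}: expected_cn must be >= 1"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class FeatureCounts:
    """Per-feature (gene or peak) counts with genomic coordinates.

    ``counts`` is cells x features; ``features`` is a DataFrame with at
    least columns ``id``, ``chrom``, ``start``, ``end``.
    """

    counts: sparse.spmatrix | np.ndarray
    features: pd.DataFrame
    barcodes: list[str]

    def __post_init__(self) -> None:
        n_cells, n_feat = self.counts.shape
        if len(self.barcodes) != n_cells:
            raise ValueError("barcode count does not match matrix rows")
        if len(self.features) != n_feat:
            raise ValueError("feature table does not match matrix columns")
        for col in ("id", "chrom", "start", "end"):
            if col not in self.features.columns:
                raise ValueError(f"feature table lacks column {col!r}")


@dataclass
class SegmentedCounts:
    """Cells x segments integer counts for one modality.

    ``library_factors`` are the observed per-cell scaling factors rho_n
    (mean 1 across cells) that multiply the expected counts in the
    observation model; left as None they are derived from the count
    totals on first use (see :func:`compute_library_factors`).
    """

    modality: str
    counts: np.ndarray
    barcodes: list[str] = field(repr=False)
    segment_ids: list[str] = field(repr=False)
    library_factors: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x segments matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        n, i = self.counts.shape
        if len(self.barcodes) != n:
            raise ValueError("one barcode per cell required")
        if len(set(self.barcodes)) != n:
            raise ValueError("barcodes must be unique")
        if len(self.segment_ids) != i:
            raise ValueError("one id per segment column required")
        if self.library_factors is not None:
            self.library_factors = np.asarray(self.library_factors, dtype=float)
            if self.library_factors.shape != (n,):
                raise ValueError("one library factor per cell required")
            if np.any(self.library_factors <= 0):
                raise ValueError("library factors must be strictly positive")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_segments(self) -> int:
        return self.counts.shape[1]

    def effective_library_factors(self) -> np.ndarray:
        """Stored factors, or factors derived from the count totals."""
        if self.library_factors is not None:
            return self.library_factors
        return compute_library_factors(self.counts, self.barcodes)

    def subset_cells(self, index: np.ndarray) -> "SegmentedCounts":
        return replace(
            self,
            counts=self.counts[index],
            barcodes=[self.barcodes[j] for j in index],
            library_factors=(
                None
                if self.library_factors is None
                else self.library_factors[index]
            ),
        )

    def subset_segments(self, keep: np.ndarray) -> "SegmentedCounts":
        keep = np.asarray(keep)
        return replace(
            self,
            counts=self.counts[:, keep],
            segment_ids=[self.segment_ids[j] for j in keep],
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_segments(path: str | Path) -> list[SegmentRecord]:
    """Read a BED-like segmentation (3-5 tab-separated columns).

    Columns: chrom, start, end, optional segment_id, optional expected
    copy number. Missing ids become ``chrom:start-end``; missing expected
    copy numbers default to 2 (diploid). Records are returned sorted by
    (chrom, start); overlapping segments on the same chromosome are
    rejected.
    """
    records: list[SegmentRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            seg_id = (
                parts[3]
                if len(parts) > 3 and parts[3] != ""
                else f"{chrom}:{start}-{end}"
            )
            expected_cn = 2
            if len(parts) > 4 and parts[4] != "":
                try:
                    expected_cn = int(parts[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer expected copy number"
                    ) from exc
            try:
                rec = SegmentRecord(chrom, start, end, seg_id, expected_cn)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if not records:
        raise ValueError(f"{path}: no segments found")
    records.sort(key=lambda r: (r.chrom, r.start))
    ids = [r.segment_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate segment ids: {dupes}")
    for prev, cur in zip(records, records[1:]):
        if cur.chrom == prev.chrom and cur.start < prev.end:
            raise ValueError(
                f"overlapping segments on {cur.chrom}: "
                f"{prev.segment_id} and {cur.segment_id}"
            )
    return records


def read_10x_counts(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> FeatureCounts:
    """Read a 10x-style MatrixMarket triplet.

    The matrix is features x cells (10x convention) and is transposed to
    cells x features. ``features_path`` is a headerless TSV with columns
    (id, name, chrom, start, end); ``barcodes_path`` one barcode per line.
    All three accept gzip.
    """
    with _open_text(matrix_path) as fh:
        mat = spio.mmread(fh)
    mat = sparse.csr_matrix(mat).T  # -> cells x features
    feats = pd.read_csv(
        features_path,
        sep="\t",
        header=None,
        names=["id", "name", "chrom", "start", "end"],
        dtype={"chrom": str},
    )
    with _open_text(barcodes_path) as fh:
        barcodes = [ln.strip() for ln in fh if ln.strip()]
    return FeatureCounts(counts=mat, features=feats, barcodes=barcodes)


def read_cell_table(path: str | Path, modality: str) -> SegmentedCounts:
    """Read a pre-aggregated cells x segments delimited table.

    First column holds barcodes, header row the segment ids. Library
    factors are computed from the table totals.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy()
    barcodes = [str(b) for b in df.index]
    return SegmentedCounts(
        modality=modality,
        counts=counts,
        barcodes=barcodes,
        segment_ids=[str(c) for c in df.columns],
    )


def write_cell_table(data: SegmentedCounts, path: str | Path) -> None:
    df = pd.DataFrame(
        data.counts, index=data.barcodes, columns=data.segment_ids
    )
    df.index.name = "barcode"
    df.to_csv(path, sep="\t")


def aggregate_to_segments(
    features: FeatureCounts,
    segments: Sequence[SegmentRecord],
    modality: str,
) -> tuple[SegmentedCounts, pd.Series]:
    """Sum feature counts into segments by midpoint containment.

    A feature is assigned to the segment containing its midpoint, so
    boundary-spanning features are counted exactly once; features whose
    midpoint falls in no segment are dropped. Returns the aggregated
    counts plus the number of features contributing to each segment.
    """
    n_seg = len(segments)
    mids = ((features.features["start"] + features.features["end"]) // 2).to_numpy()
    chroms = features.features["chrom"].to_numpy()
    assign = np.full(len(mids), -1, dtype=int)
    for j, seg in enumerate(segments):
        hit = (chroms == seg.chrom) & (mids >= seg.start) & (mids < seg.end)
        assign[hit] = j
    if not np.any(assign >= 0):
        raise ValueError("segmentation and features do not overlap")
    mat = features.counts
    if sparse.issparse(mat):
        mat = mat.tocsc()
    out = np.zeros((len(features.barcodes), n_seg), dtype=np.int64)
    for j in range(n_seg):
        cols = np.flatnonzero(assign == j)
        if cols.size == 0:
            continue
        block = mat[:, cols]
        summed = np.asarray(block.sum(axis=1)).ravel() if sparse.issparse(
            block
        ) else block.sum(axis=1)
        out[:, j] = np.rint(summed).astype(np.int64)
    seg_ids = [s.segment_id for s in segments]
    n_features = pd.Series(
        [int(np.sum(assign == j)) for j in range(n_seg)],
        index=seg_ids,
        name="n_features",
    )
    data = SegmentedCounts(
        modality=modality,
        counts=out,
        barcodes=list(features.barcodes),
        segment_ids=seg_ids,
    )
    return data, n_features


def compute_library_factors(
    counts: np.ndarray, barcodes: Sequence[str] | None = None
) -> np.ndarray:
    """Per-cell library-size factors rho_n = cell total / mean cell total.

    The returned factors have mean exactly 1, so the per-segment rate
    theta stays interpretable as counts per copy in an average cell.
    Cells with zero total count are rejected (they carry no signal and
    would make the factor degenerate).
    """
    counts = np.asarray(counts)
    totals = counts.sum(axis=1).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = (
            [barcodes[j] for j in zero[:10]]
            if barcodes is not None
            else zero[:10].tolist()
        )
        raise ValueError(
            f"{zero.size} cell(s) with zero total count: {names}"
        )
    return totals / totals.mean()


def filter_segments(
    data: SegmentedCounts | Sequence[SegmentedCounts],
    max_zero_fraction: float = 0.10,
) -> tuple[list[SegmentedCounts], list[str]]:
    """Drop segments whose zero-count cell fraction exceeds the threshold.

    A segment is removed when, in *any* provided modality, more than
    ``max_zero_fraction`` of cells have a zero count there; removal is
    synchronised across modalities so the segment set stays shared.
    Returns the filtered datasets and the removed segment ids.
    """
    single = isinstance(data, SegmentedCounts)
    datasets = [data] if single else list(data)
    if not datasets:
        raise ValueError("no data provided")
    seg_ids = datasets[0].segment_ids
    for d in datasets[1:]:
        if d.segment_ids != seg_ids:
            raise ValueError("modalities must share the segment list")
    keep = np.ones(len(seg_ids), dtype=bool)
    for d in datasets:
        zero_frac = (d.counts == 0).mean(axis=0)
        keep &= zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValueError(
            "all segments removed; consider a looser max_zero_fraction"
        )
    removed = [s for s, k in zip(seg_ids, keep) if not k]
    out = [d.subset_segments(np.flatnonzero(keep)) for d in datasets]
    return out, removed


def pair_multiome(
    rna: SegmentedCounts, atac: SegmentedCounts
) -> tuple[SegmentedCounts, SegmentedCounts, dict[str, int]]:
    """Restrict both modalities to shared barcodes, identically ordered.

    Needed by the multiome model, where each physical cell carries one
    clone-assignment variable driving both its RNA and ATAC counts.
    Returns the paired datasets and the number of barcodes dropped per
    modality.
    """
    if rna.segment_ids != atac.segment_ids:
        raise ValueError("modalities must share the segment list")
    shared = [b for b in rna.barcodes if b in set(atac.barcodes)]
    if not shared:
        raise ValueError("no shared barcodes; use the flat model")
    rna_pos = {b: j for j, b in enumerate(rna.barcodes)}
    atac_pos = {b: j for j, b in enumerate(atac.barcodes)}
    rna_idx = np.array([rna_pos[b] for b in shared])
    atac_idx = np.array([atac_pos[b] for b in shared])
    report = {
        "dropped_rna": rna.n_cells - len(shared),
        "dropped_atac": atac.n_cells - len(shared),
    }
    return rna.subset_cells(rna_idx), atac.subset_cells(atac_idx), report
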