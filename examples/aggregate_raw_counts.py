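"""From raw feature counts to the model's cells x segments input.

Builds a small 10x-style triplet (MatrixMarket matrix + features +
barcodes) and a BED segmentation on disk, then aggregates features into
segments by midpoint containment, computes library factors and applies
the zero-fraction segment filter.
"""

import tempfile
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.io import mmwrite

from cnaclone import (
    aggregate_to_segments,
    compute_library_factors,
    filter_segments,
    read_10x_counts,
    read_segments,
)

tmp = Path(tempfile.mkdtemp())
rng = np.random.default_rng(0)

# 30 genes on two chromosome arms, 50 cells
n_genes, n_cells = 30, 50
starts = np.concatenate([np.sort(rng.integers(0, 9_000, 15)),
                         np.sort(rng.integers(10_000, 19_000, 15))])
with open(tmp / "features.tsv", "w") as fh:
    for g, s in enumerate(starts):
        fh.write(f"g{g}\tGENE{g}\tchr1\t{s}\t{s + 500}\n")
with open(tmp / "barcodes.tsv", "w") as fh:
    fh.writelines(f"CELL{j}\n" for j in range(n_cells))
counts = rng.poisson(4.0, size=(n_genes, n_cells))  # features x cells
mmwrite(tmp / "matrix.mtx", sparse.csr_matrix(counts))
(tmp / "segments.bed").write_text(
    "chr1\t0\t10000\tchr1_p\t2\nchr1\t10000\t20000\tchr1_q\t2\n"
)

features = read_10x_counts(tmp / "matrix.mtx", tmp / "features.tsv",
                           tmp / "barcodes.tsv")
segments = read_segments(tmp / "segments.bed")
data, features_per_segment = aggregate_to_segments(features, segments, "RNA")

print("features per segment:")
print(features_per_segment.to_string())
print("\nfirst cells' segment counts:")
print(data.counts[:5])
rho = compute_library_factors(data.counts, data.barcodes)
print(f"\nlibrary factors: mean={rho.mean():.3f} (normalised to 1), "
      f"range [{rho.min():.2f}, {rho.max():.2f}]")

(kept,), removed = filter_segments(data, max_zero_fraction=0.10)
print(f"segments removed by the 10% zero-cell filter: {removed or 'none'}")
print("\nThe resulting matrix (cells x segments) plus the factors are "
      "exactly what the clone-mixture fit consumes.")
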