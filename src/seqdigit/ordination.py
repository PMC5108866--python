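"""Ordination of strains by alignment-free composition: FCGR + PCA.

Each record is summarised as its normalised k-mer frequency vector (the
flattened FCGR, default k=3, 64 features), and the family is ordinated by
principal component analysis of the column-centred feature matrix.  For a
family of near-identical ingroup strains plus a more divergent outgroup,
the dominant variance axis separates the outgroup — the strain-level
differentiation this toolkit visualises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .cgr import CornerMap, JEFFREY_CORNERS, fcgr_matrix, kmer_cell
from .seqio import SeqRecord

__all__ = ["FeatureMatrix", "PCAResult", "OrdinationError",
           "feature_vectors", "run_pca"]


class OrdinationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows = records, columns = k-mer frequencies in lexicographic order."""

    labels: tuple[str, ...]
    kmers: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.labels), len(self.kmers)):
            raise OrdinationError("feature matrix shape mismatch")
        if np.any(self.matrix < 0):
            raise OrdinationError("k-mer frequencies cannot be negative")

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.kmers)


@dataclass(frozen=True)
class PCAResult:
    """Scores, orthonormal loadings and explained-variance fractions."""

    labels: tuple[str, ...]
    scores: np.ndarray = field(repr=False)       # (n, k)
    loadings: np.ndarray = field(repr=False)     # (k, n_features)
    explained_variance_ratio: np.ndarray = field(repr=False)  # descending


def feature_vectors(records: Sequence[SeqRecord], k: int = 3,
                    corners: CornerMap = JEFFREY_CORNERS) -> FeatureMatrix:
    """Normalised FCGR k-mer frequencies, one row per record.

    Counts are read out of the FCGR grid in fixed lexicographic k-mer order
    and divided by their total, so every row sums to 1.
    """
    if not records:
        raise OrdinationError("no records")
    kmers = tuple("".join(p) for p in product("ACGT", repeat=k))
    cells = [kmer_cell(km, corners) for km in kmers]
    rows = []
    for rec in records:
        if len(rec.residues) < k:
            raise OrdinationError(f"record {rec.id!r} shorter than k={k}")
        f = fcgr_matrix(rec, k=k, corners=corners)
        vec = np.array([f.counts[r, c] for r, c in cells], dtype=float)
        rows.append(vec / vec.sum())
    return FeatureMatrix(labels=tuple(r.id for r in records), kmers=kmers,
                         matrix=np.vstack(rows))


def run_pca(features: FeatureMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the column-centred feature matrix by SVD.

    Components are ordered by explained variance; the sign of each is fixed
    so its largest-magnitude loading is positive, making scores
    reproducible across runs and library versions.
    """
    x = features.matrix
    n = x.shape[0]
    if n < 2:
        raise OrdinationError("PCA needs at least 2 records")
    centred = x - x.mean(axis=0, keepdims=True)
    if np.allclose(centred, 0):
        raise OrdinationError(
            "all records have identical feature vectors; no variance to ordinate")
    n_components = min(n_components, min(centred.shape))
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    total_var = float((s ** 2).sum())
    ratios = (s ** 2) / total_var

    scores = u * s
    for comp in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[comp])))
        if vt[comp, j] < 0:
            vt[comp] *= -1
            scores[:, comp] *= -1
    return PCAResult(labels=features.labels,
                     scores=scores[:, :n_components],
                     loadings=vt[:n_components],
                     explained_variance_ratio=ratios[:n_components])
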