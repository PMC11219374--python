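"""Unsupervised exploration: PCA, low-level fusion and SUM-PCA super scores.

Low-level fusion concatenates the (autoscaled) blocks column-wise; SUM-PCA
is PCA on that concatenation with per-block weights (default 1/sqrt(block
width) so each autoscaled block contributes equal total variance), yielding
shared "super scores" and a per-block decomposition of each component's
explained variance.  The SVD solution is made deterministic by a sign
convention: the largest-|loading| element of every component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import AnalyteBlock, MultiBlockDataset
from .errors import DataError


@dataclass
class PcaModel:
    """SVD-based PCA fit: orthonormal loadings, scores and variance fractions."""

    loadings: pd.DataFrame  # analytes x k
    scores: pd.DataFrame  # samples x k
    explained_variance: np.ndarray  # fractions per component, non-increasing

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = self.loadings.index.difference(X.columns)
        if len(missing):
            raise DataError(f"matrix lacks analyte(s) {list(missing)[:5]} required by the PCA model")
        scores = X[self.loadings.index].to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(scores, index=X.index, columns=self.loadings.columns)


@dataclass
class SumPcaModel:
    """Multi-block PCA on the weighted concatenation of all blocks."""

    super_scores: pd.DataFrame  # samples x k
    block_loadings: dict[str, pd.DataFrame]  # block -> analytes x k (weighted space)
    explained_variance: np.ndarray  # per-component total fractions
    block_explained: pd.DataFrame  # components x blocks, rows sum to explained_variance
    weights: dict[str, float]
    pca: PcaModel  # underlying fit on the fused matrix

    @property
    def n_components(self) -> int:
        return self.super_scores.shape[1]


def resolve_weights(
    dataset: MultiBlockDataset, weights: Mapping[str, float] | str | None
) -> dict[str, float]:
    """Per-block scale factors: ``"none"`` -> 1, ``"equal_block_variance"`` ->
    1/sqrt(block width), or an explicit mapping."""
    if weights is None or weights == "equal_block_variance":
        return {b.block_id: 1.0 / np.sqrt(b.n_analytes) for b in dataset.blocks}
    if weights == "none":
        return {b.block_id: 1.0 for b in dataset.blocks}
    out = {b.block_id: float(weights[b.block_id]) for b in dataset.blocks}
    return out


def low_level_fuse(
    dataset: MultiBlockDataset, weights: Mapping[str, float] | str | None = "none"
) -> tuple[pd.DataFrame, pd.Series]:
    """Column-wise concatenation of blocks in block order.

    Each block is multiplied by its weight; the returned provenance Series
    maps every fused column to its source block.  Fused width equals the sum
    of block widths.
    """
    w = resolve_weights(dataset, weights)
    pieces, provenance = [], {}
    for block in dataset.blocks:
        for col in block.data.columns:
            if col in provenance:
                raise DataError(f"analyte id {col!r} appears in more than one block")
            provenance[col] = block.block_id
        pieces.append(block.data * w[block.block_id])
    fused = pd.concat(pieces, axis=1)
    return fused, pd.Series(provenance, name="block")


def fit_pca(matrix: pd.DataFrame, k: int) -> PcaModel:
    """Deterministic SVD-based PCA of an (already centered) matrix.

    Explained-variance fractions are relative to the matrix's total sum of
    squares.  Sign convention: the largest-|loading| element of each
    component is positive (ties broken by lowest column index).
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(matrix)
    n, p = matrix.shape
    max_k = min(n - 1, p)
    if not 1 <= k <= max_k:
        raise DataError(f"k={k} out of range; need 1 <= k <= min(n-1, p) = {max_k}")
    X = matrix.to_numpy(dtype=float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_ss = float((s**2).sum())
    loadings = Vt[:k].T.copy()  # p x k, orthonormal columns
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for a in range(k):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    comp_names = [f"PC{a + 1}" for a in range(k)]
    ev = (s[:k] ** 2) / total_ss if total_ss > 0 else np.zeros(k)
    return PcaModel(
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        explained_variance=ev,
    )


def fit_sum_pca(
    dataset: MultiBlockDataset,
    k: int = 3,
    weights: Mapping[str, float] | str | None = "equal_block_variance",
) -> SumPcaModel:
    """SUM-PCA: PCA of the weighted concatenation of all (autoscaled) blocks.

    The super scores are the fused-matrix scores; each component's explained
    variance is decomposed into per-block shares via the loading mass that
    falls in each block (shares sum exactly to the component total).
    """
    for block in dataset.blocks:
        if block.stage != "autoscaled":
            raise DataError(
                f"fit_sum_pca expects autoscaled blocks; block {block.block_id!r} "
                f"is at stage {block.stage!r}"
            )
    w = resolve_weights(dataset, weights)
    fused, provenance = low_level_fuse(dataset, weights=w)
    pca = fit_pca(fused, k)
    # per-block explained variance: component a's total share s_a^2/SS splits
    # over blocks proportionally to sum of squared loadings per block
    shares = {}
    load_sq = pca.loadings.to_numpy() ** 2
    block_of = provenance.loc[pca.loadings.index].to_numpy()
    for block in dataset.blocks:
        mask = block_of == block.block_id
        shares[block.block_id] = pca.explained_variance * load_sq[mask].sum(axis=0)
    block_explained = pd.DataFrame(shares, index=pca.loadings.columns)
    block_loadings = {
        b.block_id: pca.loadings.loc[b.data.columns] for b in dataset.blocks
    }
    return SumPcaModel(
        super_scores=pca.scores,
        block_loadings=block_loadings,
        explained_variance=pca.explained_variance,
        block_explained=block_explained,
        weights=w,
        pca=pca,
    )


def plot_scores(
    scores: pd.DataFrame,
    groups: pd.Series,
    components: tuple[str, str] = ("PC1", "PC2"),
    path=None,
):
    """2-D score plot colored by group; saves to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, idx in groups.groupby(groups).groups.items():
        sub = scores.loc[idx]
        ax.scatter(sub[components[0]], sub[components[1]], label=str(name), s=14, alpha=0.7)
    ax.set_xlabel(components[0])
    ax.set_ylabel(components[1])
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
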