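"""Block-wise Pearson correlation, clustergram ordering, TF ranking.

Correlations are computed between two gene blocks of a CLR-transformed
matrix (raw-TPM correlations are not meaningful for compositional
data). Heatmap row/column orders come from agglomerative clustering
with average linkage on Euclidean distances between correlation
profiles, matching the clustergram convention. Transcription factors
are ranked by their summed correlation with the ion channels, from
predominantly positive to predominantly negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist

from .panels import GenePanel
from .preprocess import ClrMatrix

__all__ = [
    "CorrelationBlock",
    "pearson_block",
    "cluster_order",
    "rank_by_cumulative_correlation",
]


@dataclass
class CorrelationBlock:
    """Pearson correlation matrix between two gene blocks.

    ``r`` is a DataFrame (row genes x column genes); ``row_order`` /
    ``col_order`` hold clustering leaf orders once computed.
    """

    r: pd.DataFrame
    row_order: list[int] | None = field(default=None)
    col_order: list[int] | None = field(default=None)

    @property
    def row_genes(self) -> list[str]:
        return list(self.r.index)

    @property
    def col_genes(self) -> list[str]:
        return list(self.r.columns)

    def ordered(self) -> pd.DataFrame:
        """Return r permuted by the stored clustering orders."""
        df = self.r
        if self.row_order is not None:
            df = df.iloc[self.row_order]
        if self.col_order is not None:
            df = df.iloc[:, self.col_order]
        return df


def pearson_block(A: pd.DataFrame, B: pd.DataFrame) -> CorrelationBlock:
    """Pearson correlation of every column of A with every column of B.

    A and B are samples x genes frames over the same samples (typically
    two blocks of a :class:`~cardiopls.preprocess.ClrMatrix`).
    """
    if not A.index.equals(B.index):
        raise ValueError("A and B must be over identical samples")
    n = len(A)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    for df in (A, B):
        sd = df.std(axis=0, ddof=0)
        if (sd == 0).any():
            bad = sd.index[sd == 0].tolist()
            raise ValueError(
                f"constant columns make the correlation undefined: {bad}"
            )
    Ac = A.to_numpy() - A.to_numpy().mean(axis=0)
    Bc = B.to_numpy() - B.to_numpy().mean(axis=0)
    num = Ac.T @ Bc
    den = np.sqrt((Ac ** 2).sum(axis=0))[:, None] \
        * np.sqrt((Bc ** 2).sum(axis=0))[None, :]
    r = pd.DataFrame(num / den, index=A.columns, columns=B.columns)
    return CorrelationBlock(r)


def block_frames(clr: ClrMatrix, panel: GenePanel, row_block: str,
                 col_block: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pull the two named blocks of a CLR matrix ('modifier', 'TF', 'IC')."""
    def genes(block):
        return panel.modifier_genes if block == "modifier" \
            else panel.blocks[block]
    return clr.block(genes(row_block)), clr.block(genes(col_block))


def cluster_order(block: CorrelationBlock, axis: str = "rows") -> list[int]:
    """Dendrogram leaf order for one axis of a correlation block.

    Average-linkage agglomerative clustering on Euclidean distances
    between correlation-profile rows (or columns). The returned
    permutation is also stored on the block.
    """
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    profiles = block.r.to_numpy() if axis == "rows" else block.r.to_numpy().T
    if profiles.shape[0] < 2:
        warnings.warn("single item on axis; identity order", stacklevel=2)
        order = [0]
    else:
        Z = linkage(pdist(profiles, metric="euclidean"), method="average")
        order = dendrogram(Z, no_plot=True)["leaves"]
    if axis == "rows":
        block.row_order = order
    else:
        block.col_order = order
    return order


def rank_by_cumulative_correlation(block: CorrelationBlock) -> pd.Series:
    """Rank row genes (TFs) by their summed correlation over the columns.

    Returns a Series of row sums sorted descending — predominantly
    positive regulators first, predominantly negative last. Ties break
    alphabetically.
    """
    sums = block.r.sum(axis=1)
    order = sorted(sums.index, key=lambda g: (-sums[g], g))
    return sums.loc[order]
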