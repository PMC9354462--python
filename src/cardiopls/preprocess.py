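"""Quality filtering and the compositional log-ratio transform.

TPM rows are compositions (they carry only relative information), so
Euclidean operations — correlations, distances, regression — are not
meaningful on the raw values. The pipeline therefore (1) filters samples
by the reference-gene (GAPDH) level to remove dilution/quality outliers,
(2) maps each sample into Euclidean space with the centred log-ratio
transform, log10 of each gene over the geometric mean of the basis
genes, and (3) drops gross outlier samples flagged by extreme scores of
a preliminary PLS model. The order filter -> transform -> outlier
removal is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix
from .panels import GenePanel

__all__ = [
    "ClrMatrix",
    "FilterReport",
    "filter_by_reference",
    "geometric_mean",
    "clr_transform",
    "remove_score_outliers",
]


@dataclass
class FilterReport:
    """Which samples a filtering step kept or dropped, and why.

    ``reasons`` maps each dropped sample id to one of ``reference_low``,
    ``reference_high`` or ``score_outlier``.
    """

    kept_sample_ids: list[str]
    dropped_sample_ids: list[str]
    reasons: dict[str, str]
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.kept_sample_ids) & set(self.dropped_sample_ids)
        if overlap:
            raise ValueError(f"samples both kept and dropped: {sorted(overlap)}")

    def to_dict(self) -> dict:
        return {
            "kept_sample_ids": self.kept_sample_ids,
            "dropped_sample_ids": self.dropped_sample_ids,
            "reasons": self.reasons,
            "thresholds": self.thresholds,
        }


@dataclass
class ClrMatrix:
    """Samples x genes matrix of centred log-ratio values (log10 units).

    ``basis_gene_ids`` records the gene set whose per-sample geometric
    mean served as the log-ratio denominator; over those columns every
    row sums to zero.
    """

    data: pd.DataFrame
    basis_gene_ids: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("CLR matrix contains non-finite entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def block(self, genes: Iterable[str]) -> pd.DataFrame:
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.columns]
        if missing:
            raise KeyError(f"genes not in CLR matrix: {missing}")
        return self.data.loc[:, genes]

    def subset_samples(self, sample_ids: list[str]) -> "ClrMatrix":
        return ClrMatrix(self.data.loc[list(sample_ids)].copy(),
                         list(self.basis_gene_ids))


def filter_by_reference(
    expr: ExpressionMatrix,
    gene: str = "GAPDH",
    low: float = 500.0,
    high: float = 2500.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep samples whose reference-gene TPM lies in the closed interval
    ``[low, high]``.

    The reference gene (GAPDH by default) indicates sample dilution and
    quality; the default window is 500–2,500 TPM.
    """
    if gene not in expr.data.columns:
        raise KeyError(f"reference gene {gene!r} not in matrix")
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got low={low}, high={high}")
    ref = expr.data[gene]
    kept = expr.data.index[(ref >= low) & (ref <= high)].tolist()
    reasons = {}
    for s in expr.sample_ids:
        if ref[s] < low:
            reasons[s] = "reference_low"
        elif ref[s] > high:
            reasons[s] = "reference_high"
    dropped = [s for s in expr.sample_ids if s in reasons]
    if not kept:
        raise ValueError(
            f"reference filter [{low}, {high}] on {gene!r} dropped every sample"
        )
    report = FilterReport(kept, dropped, reasons,
                          {"low": low, "high": high})
    return expr.subset_samples(kept), report


def geometric_mean(x: np.ndarray) -> float:
    """Geometric mean ``(prod x_i)^(1/n)`` of a strictly positive vector.

    Computed in log space to avoid overflow.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if (x <= 0).any():
        raise ValueError("geometric mean requires strictly positive entries")
    return float(np.exp(np.mean(np.log(x))))


def clr_transform(
    expr: ExpressionMatrix,
    basis: Iterable[str] | None = None,
    zero_policy: str = "pseudocount",
) -> ClrMatrix:
    """Centred log-ratio transform: ``log10(x_g / gmean(basis genes))``
    per sample.

    Parameters
    ----------
    expr
        TPM matrix.
    basis
        Genes over which the per-sample geometric mean (the log-ratio
        denominator) runs; defaults to every gene in the matrix. All
        matrix columns are transformed either way — only the denominator
        changes.
    zero_policy
        ``"pseudocount"`` replaces zeros per gene with half that gene's
        smallest positive value across samples before transforming;
        ``"error"`` raises on any zero among the transformed columns.

    Notes
    -----
    The transform is invariant to per-sample positive rescaling, so
    whether TPM rows were renormalised after subsetting is irrelevant
    downstream. Rows restricted to the basis genes sum to zero.
    """
    basis = list(basis) if basis is not None else list(expr.gene_ids)
    missing = [g for g in basis if g not in expr.data.columns]
    if missing:
        raise KeyError(f"basis genes not in matrix: {missing}")
    values = expr.data.copy()
    zeros = values.to_numpy() == 0
    if zeros.any():
        if zero_policy == "error":
            r, c = np.argwhere(zeros)[0]
            raise ValueError(
                f"zero TPM at sample {values.index[r]!r}, gene "
                f"{values.columns[c]!r} with zero_policy='error'"
            )
        if zero_policy != "pseudocount":
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
        for j, gene in enumerate(values.columns):
            col = values.iloc[:, j].to_numpy()
            if (col == 0).any():
                pos = col[col > 0]
                if pos.size == 0:
                    raise ValueError(
                        f"gene {gene!r} is zero in every sample; cannot "
                        "impute a pseudocount"
                    )
                col = np.where(col == 0, pos.min() / 2.0, col)
                values.iloc[:, j] = col
    logv = np.log10(values.to_numpy())
    log_gmean = logv[:, [values.columns.get_loc(g) for g in basis]].mean(axis=1)
    clr = pd.DataFrame(
        logv - log_gmean[:, None], index=values.index, columns=values.columns
    )
    return ClrMatrix(clr, basis)


def remove_score_outliers(
    clr: ClrMatrix,
    panel: GenePanel,
    n_components: int = 2,
    k: float = 4.0,
) -> tuple[ClrMatrix, FilterReport]:
    """Drop samples with extreme scores in a preliminary PLS model.

    Fits a PLS model of the modifier block (HDAC+SIRT+HAT) onto the IC
    block and removes any sample whose score on one of the first
    ``n_components`` latent variables exceeds ``k`` standard deviations
    of that component's score distribution. Defaults (2 components,
    k = 4 SD) remove only gross outliers.
    """
    from .pls import PLS  # local import; pls does not depend on preprocess

    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if not k > 0:
        raise ValueError("k must be positive")
    n = len(clr.sample_ids)
    if n < n_components + 2:
        raise ValueError(
            f"need at least {n_components + 2} samples for a "
            f"{n_components}-component outlier screen, got {n}"
        )
    X = clr.block(panel.modifier_genes).to_numpy()
    Y = clr.block(panel.ic_genes).to_numpy()
    res = PLS(Y, X, n_components=n_components).fit()
    scores = res.x_scores  # samples x components
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    extreme = (np.abs(scores) > k * sd).any(axis=1)
    kept = [s for s, e in zip(clr.sample_ids, extreme) if not e]
    dropped = [s for s, e in zip(clr.sample_ids, extreme) if e]
    report = FilterReport(
        kept, dropped, {s: "score_outlier" for s in dropped},
        {"k_sd": k, "n_components": float(n_components)},
    )
    return clr.subset_samples(kept), report
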