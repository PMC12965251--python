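"""scRNA-seq count preprocessing: gene filtering and normalization.

The recipe expects a genes x cells count matrix and applies, in order:

1. drop genes whose total count across cells is <= ``min_total`` (10);
2. transform counts as ``log2(y + 1)``;
3. divide each cell's transformed vector by its total transformed
   expression (per-cell library normalization);
4. standardize every gene to mean zero and unit variance across cells.

The order matters and is fixed; the output is a dense feature x
observation matrix ready for the mixture sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numpy.typing import NDArray

from .core_model import DataMatrix

__all__ = ["CountMatrix", "filter_genes", "normalize"]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Nonnegative genes x cells count matrix with identifiers."""

    counts: NDArray[np.float64]
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense(), dtype=float)
        else:
            self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        g, c = self.counts.shape
        if self.gene_ids is None:
            self.gene_ids = [f"gene{j + 1}" for j in range(g)]
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i + 1}" for i in range(c)]
        if len(self.gene_ids) != g or len(self.cell_ids) != c:
            raise ValueError("identifier lengths must match the matrix shape")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


def filter_genes(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Keep genes with total count strictly greater than ``min_total``.

    A gene whose counts over all cells sum to ``min_total`` or less is
    considered lowly expressed and removed; identifiers are preserved.
    """
    totals = counts.counts.sum(axis=1)
    keep = totals > min_total
    return CountMatrix(
        counts.counts[keep],
        [g for g, k in zip(counts.gene_ids, keep) if k],
        list(counts.cell_ids),
    )


def normalize(counts: CountMatrix, variance: str = "population") -> DataMatrix:
    """Log-transform, per-cell normalize, and per-gene standardize counts.

    ``x = log2(y + 1)`` entrywise, each cell divided by its column total,
    then each gene centered and scaled to unit variance (population
    ``1/n`` variance by default, ``"sample"`` for ``1/(n-1)``).  Genes
    whose normalized expression is constant across cells carry no
    clustering signal and are dropped with a warning.  A cell with no
    counts at all has an undefined profile and raises a ValueError.
    """
    if variance not in ("population", "sample"):
        raise ValueError("variance must be 'population' or 'sample'")
    x = np.log2(counts.counts + 1.0)
    cell_totals = x.sum(axis=0)
    if np.any(cell_totals == 0):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(cell_totals == 0)]
        raise ValueError(f"cells with all-zero counts cannot be normalized: {bad}")
    x = x / cell_totals[None, :]
    ddof = 0 if variance == "population" else 1
    means = x.mean(axis=1)
    sds = x.std(axis=1, ddof=ddof)
    keep = sds > 0
    if not np.all(keep):
        dropped = [counts.gene_ids[j] for j in np.flatnonzero(~keep)]
        logger.warning(
            "dropping %d zero-variance gene(s) after normalization: %s",
            len(dropped),
            dropped[:10],
        )
    x = (x[keep] - means[keep][:, None]) / sds[keep][:, None]
    return DataMatrix(
        x,
        feature_names=[g for g, k in zip(counts.gene_ids, keep) if k],
        observation_names=list(counts.cell_ids),
    )
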