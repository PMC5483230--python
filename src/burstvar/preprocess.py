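"""Count-matrix QC, size-factor normalization and fold-change classes.

The pipeline order mirrors standard single-cell practice on read-count
matrices: (1) drop poor or overloaded libraries by total read count,
(2) equalize sequencing depth within each replicate with median-of-
ratios size factors, (3) drop weakly expressed genes (mean normalized
count below a floor), (4) classify genes as up-/down-regulated between
two time points by replicate-averaged fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "filter_cells",
    "size_factors",
    "normalize",
    "filter_genes",
    "classify_fold_change",
]

REQUIRED_META = ("time_point", "replicate")


@dataclass
class CountMatrix:
    """Gene×cell counts with per-cell metadata.

    ``counts`` is a genes×cells DataFrame (gene IDs as index, cell IDs
    as columns); ``cell_meta`` is indexed by cell ID with at least
    ``time_point`` and ``replicate`` columns.  ``total_reads`` is filled
    from the raw column sums if absent and is preserved through
    normalization (it always refers to raw reads).
    """

    counts: pd.DataFrame
    cell_meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene IDs")
        if not self.counts.columns.equals(self.cell_meta.index):
            self.cell_meta = self.cell_meta.loc[self.counts.columns]
        for col in REQUIRED_META:
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta lacks required column {col!r}")
        if "total_reads" not in self.cell_meta.columns:
            self.cell_meta = self.cell_meta.assign(
                total_reads=self.counts.sum(axis=0).astype(np.int64)
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, cell_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[:, cell_ids],
            cell_meta=self.cell_meta.loc[cell_ids],
            normalized=self.normalized,
        )

    def subset_time_point(self, time_point) -> "CountMatrix":
        keep = self.cell_meta.index[self.cell_meta["time_point"] == time_point]
        return self.subset_cells(keep)


def filter_cells(
    m: CountMatrix, min_reads: int = 500_000, max_reads: int = 7_000_000
) -> CountMatrix:
    """Keep cells with ``min_reads <= total raw reads <= max_reads``.

    Bounds are inclusive: libraries at exactly either bound are kept.
    """
    if m.n_cells == 0:
        raise ValueError("empty matrix")
    totals = m.cell_meta["total_reads"]
    keep = totals.index[(totals >= min_reads) & (totals <= max_reads)]
    if keep.empty:
        raise ValueError("all cells removed by the read-depth filter")
    return m.subset_cells(keep)


def _median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors for one replicate's cells.

    Reference = per-gene geometric mean across cells (genes with any
    zero count excluded); each cell's factor is the median over
    reference genes of count/reference, rescaled to geometric mean 1
    across the replicate.
    """
    x = counts.to_numpy(dtype=float)
    nonzero = (x > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every cell; the median-of-ratios "
            "reference is empty (a pseudo-reference fallback is not enabled)"
        )
    logx = np.log(x[nonzero])
    log_ref = logx.mean(axis=1, keepdims=True)
    log_sf = np.median(logx - log_ref, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1 within the replicate
    return pd.Series(np.exp(log_sf), index=counts.columns)


def size_factors(m: CountMatrix) -> pd.Series:
    """Per-cell median-of-ratios size factors, computed within each replicate."""
    parts = []
    for (_, _), idx in m.cell_meta.groupby(
        ["time_point", "replicate"], sort=False
    ).groups.items():
        parts.append(_median_of_ratios(m.counts.loc[:, idx]))
    return pd.concat(parts).loc[m.counts.columns]


def normalize(m: CountMatrix, factors: pd.Series | None = None) -> CountMatrix:
    """Divide each cell's counts by its size factor."""
    if factors is None:
        factors = size_factors(m)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return CountMatrix(
        counts=m.counts / factors.loc[m.counts.columns],
        cell_meta=m.cell_meta,
        normalized=True,
    )


def filter_genes(m: CountMatrix, floor: float = 10.0) -> CountMatrix:
    """Keep genes whose mean (normalized) count is at least ``floor``.

    Genes with mean strictly below the floor are excluded; a gene at
    exactly the floor is kept.
    """
    if not m.normalized and floor > 0:
        logger.warning("filter_genes called on raw counts; floor refers to normalized means")
    means = m.counts.mean(axis=1)
    keep = means.index[means >= floor]
    if keep.empty:
        logger.warning("all genes fall below the expression floor")
    return CountMatrix(
        counts=m.counts.loc[keep], cell_meta=m.cell_meta, normalized=m.normalized
    )


def _replicate_averaged_means(m: CountMatrix) -> pd.Series:
    """Per-gene mean: average of the per-replicate mean profiles."""
    reps = []
    for (_, _), idx in m.cell_meta.groupby(
        ["time_point", "replicate"], sort=False
    ).groups.items():
        reps.append(m.counts.loc[:, idx].mean(axis=1))
    return pd.concat(reps, axis=1).mean(axis=1)


def classify_fold_change(
    m0: CountMatrix,
    m6: CountMatrix,
    threshold: float = 2.0,
    floor: float = 10.0,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Classify genes as up/down/unchanged between two time points.

    Per-gene means are computed per replicate and averaged across
    replicates at each time point; FC = mean(late)/mean(early).  A gene
    is ``up`` if FC ≥ threshold, ``down`` if FC ≤ 1/threshold, else
    ``unchanged``.

    Zero handling (``pseudocount=None``): a gene with zero early mean
    gets FC = +inf and is ``up`` only if its late mean reaches ``floor``
    (symmetrically for ``down``); a gene with both means zero is
    ``unchanged`` with FC = NaN.  With a ``pseudocount``, FC =
    (late+pc)/(early+pc) everywhere instead.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    if not m0.counts.index.equals(m6.counts.index):
        raise ValueError("gene sets of the two time points must match")
    e = _replicate_averaged_means(m0).to_numpy()
    l = _replicate_averaged_means(m6).to_numpy()
    if pseudocount is not None:
        fc = (l + pseudocount) / (e + pseudocount)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(
                e > 0, l / e, np.where(l > 0, np.inf, np.nan)
            )
    cls = np.full(e.shape, "unchanged", dtype=object)
    up = fc >= threshold
    down = fc <= 1.0 / threshold
    if pseudocount is None:
        up &= np.where(np.isinf(fc), l >= floor, True)
        down &= np.where(fc == 0, e >= floor, True)
    cls[up] = "up"
    cls[down] = "down"
    return pd.DataFrame(
        {
            "gene": m0.counts.index,
            "mean_early": e,
            "mean_late": l,
            "fc": fc,
            "class": cls,
            "threshold": threshold,
        }
    ).set_index("gene")
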