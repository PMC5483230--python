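"""Per-gene noise statistics: CV², running-median trend, DM, expression
binning, a recentred bootstrap test and a rank-sum utility.

CV² (variance/mean²) falls roughly as 1/μ with mean expression, so raw
CV² confounds noise with expression level.  DM ("distance to median")
removes the confound: it is the residual of a gene's log10 CV² from the
running median of log10 CV² among genes of similar mean expression.
Genes above the trend (DM > 0) are noisier than typical for their
expression level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cv2",
    "running_median_trend",
    "dm",
    "bin_genes",
    "binned_class_summary",
    "BootstrapResult",
    "bootstrap_dm_test",
    "ranksum_test",
]


def cv2(counts: np.ndarray) -> float:
    """Squared coefficient of variation, ``var/mean²`` (unbiased variance).

    Raises
    ------
    ValueError
        If the mean is not positive.
    """
    x = np.asarray(counts, dtype=float)
    mu = x.mean()
    if mu <= 0:
        raise ValueError("CV^2 undefined for non-positive mean")
    return float(x.var(ddof=1) / mu**2)


def matrix_noise(counts: np.ndarray) -> pd.DataFrame:
    """Per-gene mean and CV² of a gene×cell matrix.

    CV² is NaN for genes with zero mean.
    """
    x = np.asarray(counts, dtype=float)
    mu = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(mu > 0, var / mu**2, np.nan)
    return pd.DataFrame({"mu": mu, "cv2": c})


def running_median_trend(
    mus: np.ndarray, cv2s: np.ndarray, window: int = 500
) -> np.ndarray:
    """Running median of CV² along expression, evaluated per gene.

    Genes are ordered by mean expression; at each gene the trend is the
    median of log10 CV² over a centered window of ``window`` genes
    (truncated at the edges).  Returned in the original gene order, on
    the linear CV² scale.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    mus = np.asarray(mus, dtype=float)
    cv2s = np.asarray(cv2s, dtype=float)
    if mus.shape != cv2s.shape:
        raise ValueError("mus and cv2s must have the same length")
    order = np.argsort(mus, kind="stable")
    logc = np.log10(cv2s[order])
    trend_log = (
        pd.Series(logc).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    trend = np.empty_like(trend_log)
    trend[order] = 10.0**trend_log
    return trend


def dm(mus: np.ndarray, cv2s: np.ndarray, window: int = 500) -> np.ndarray:
    """Distance-to-median noise: ``log10(CV²) − log10(trend)`` per gene.

    Genes with non-positive CV² or mean are excluded from the trend fit
    and get NaN.  Because the trend is a median of log10 CV², a global
    rescaling of all CV² values leaves DM unchanged.
    """
    mus = np.asarray(mus, dtype=float)
    cv2s = np.asarray(cv2s, dtype=float)
    valid = np.isfinite(mus) & np.isfinite(cv2s) & (mus > 0) & (cv2s > 0)
    out = np.full(mus.shape, np.nan)
    if valid.sum() == 0:
        return out
    trend = running_median_trend(mus[valid], cv2s[valid], window=window)
    out[valid] = np.log10(cv2s[valid]) - np.log10(trend)
    return out


def bin_genes(
    mus: np.ndarray, bin_size: int = 500, floor: float = 10.0
) -> np.ndarray:
    """Assign genes to expression bins of ``bin_size`` genes each.

    Bin borders are defined on the FULL gene set: genes with mean below
    ``floor`` are excluded (assignment −1), the rest are sorted by mean
    and cut into consecutive blocks of ``bin_size``; the last partial
    block is retained as its own bin.  Class-wise summaries should reuse
    these borders rather than re-binning per class.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    mus = np.asarray(mus, dtype=float)
    out = np.full(mus.shape, -1, dtype=np.int64)
    keep = np.flatnonzero(mus >= floor)
    if keep.size == 0:
        return out
    order = keep[np.argsort(mus[keep], kind="stable")]
    out[order] = np.arange(order.size) // bin_size
    return out


def binned_class_summary(
    mus: np.ndarray,
    dms: np.ndarray,
    labels: np.ndarray,
    classes: tuple[str, str],
    bin_size: int = 500,
    floor: float = 10.0,
    min_genes: int = 5,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-bin mean DM ± SEM for two gene classes, with a bootstrap p.

    Bin borders come from :func:`bin_genes` on the full gene set; the two
    classes in ``classes`` (e.g. ``("up", "down")``) are then summarized
    within each bin.  Bins where either class has fewer than
    ``min_genes`` members are flagged (``tested = False``) and get a NaN
    p-value rather than an unstable test.
    """
    mus = np.asarray(mus, dtype=float)
    dms = np.asarray(dms, dtype=float)
    labels = np.asarray(labels)
    bins = bin_genes(mus, bin_size=bin_size, floor=floor)
    a, b = classes
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(bins.max() + 1 if bins.size else 0):
        in_bin = bins == k
        da = dms[in_bin & (labels == a)]
        db = dms[in_bin & (labels == b)]
        da = da[np.isfinite(da)]
        db = db[np.isfinite(db)]
        row = {
            "bin": k,
            "mu_lo": mus[in_bin].min(),
            "mu_hi": mus[in_bin].max(),
            f"n_{a}": da.size,
            f"n_{b}": db.size,
            f"mean_dm_{a}": da.mean() if da.size else np.nan,
            f"sem_{a}": stats.sem(da) if da.size > 1 else np.nan,
            f"mean_dm_{b}": db.mean() if db.size else np.nan,
            f"sem_{b}": stats.sem(db) if db.size > 1 else np.nan,
        }
        if da.size >= min_genes and db.size >= min_genes:
            res = bootstrap_dm_test(
                da, db, n_boot=n_boot, rng=rng
            )
            row["p_boot"] = res.p_h0
            row["tested"] = True
        else:
            row["p_boot"] = np.nan
            row["tested"] = False
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    """Observed Welch t, its recentred-null sample, and p(H0)."""

    t_obs: float
    t_null: np.ndarray
    p_h0: float
    n_boot: int
    seed: int | None = None

    @property
    def significant_05(self) -> bool:
        return self.p_h0 < 0.05


def _welch_t(m1, v1, n1, m2, v2, n2):
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    return t, se2


def bootstrap_dm_test(
    group1: np.ndarray,
    group2: np.ndarray,
    n_boot: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Recentred bootstrap test for a difference in mean DM.

    Each replicate resamples both groups with replacement and shifts each
    resample by (pooled mean − original group mean), so both resampled
    groups share the pooled mean in expectation — the null hypothesis of
    equal means.  A Welch t statistic ``t_i`` is computed per replicate
    and compared with the observed ``t``:

    * ``alternative="two-sided"`` (default):
      ``p = (1 + #{|t_i| > |t|}) / (1 + n_boot)``
    * ``alternative="greater"``: the literal one-sided counting rule
      ``p = (1 + #{t_i > t}) / (1 + n_boot)``.

    Replicates with zero variance in both groups contribute ``t_i = 0``
    (with a warning).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    if rng is None:
        rng = np.random.default_rng(seed)

    mx, my = x.mean(), y.mean()
    pooled = np.concatenate([x, y]).mean()
    t_obs, se2 = _welch_t(mx, x.var(ddof=1), x.size, my, y.var(ddof=1), y.size)
    if not np.isfinite(t_obs):
        t_obs = 0.0

    bx = x[rng.integers(0, x.size, size=(n_boot, x.size))]
    by = y[rng.integers(0, y.size, size=(n_boot, y.size))]
    # recentre with the ORIGINAL group means: x~ = x − mean(x_orig) + pooled
    mbx = bx.mean(axis=1) - mx + pooled
    mby = by.mean(axis=1) - my + pooled
    t_null, se2_null = _welch_t(
        mbx, bx.var(axis=1, ddof=1), x.size, mby, by.var(axis=1, ddof=1), y.size
    )
    bad = ~np.isfinite(t_null)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} degenerate zero-variance bootstrap replicates set to t=0",
            stacklevel=2,
        )
        t_null = np.where(bad, 0.0, t_null)

    if alternative == "two-sided":
        exceed = np.abs(t_null) > abs(t_obs)
    else:
        exceed = t_null > t_obs
    p = (1 + int(exceed.sum())) / (1 + n_boot)
    return BootstrapResult(
        t_obs=float(t_obs), t_null=t_null, p_h0=float(p), n_boot=n_boot, seed=seed
    )


def ranksum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact enumeration for small tie-free samples (≤ 10 per group),
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size <= 10 and y.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))
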