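"""Gibbs sampling of gene pairs from a simulated cloud.

A pair models one gene on either side of a developmental transition: a
high-expressed and a low-expressed version of the "same" gene, at least
``fold_threshold``-fold apart in mean expression.  Candidate partners
are weighted by a Gaussian kernel on their displacement in
(log2 λ, log2 k_on) space; making one axis narrow ("limiting",
SD = 0.3) and the other wide ("non-limiting", SD = 5) restricts the
expression change to be carried by burst size (λ) or burst frequency
(k_on).  Comparing the variability (DM) of low vs high partners under
each regime is the model's prediction for how repression vs induction
shapes transcript noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import noise
from .cloud import GeneCloud
from .telegraph import BurstParams

logger = logging.getLogger(__name__)

__all__ = [
    "REGIMES",
    "PairConfig",
    "GenePair",
    "pair_weight",
    "gibbs_sample_pairs",
    "compare_pair_variance",
    "dm_gap",
    "pairs_to_frame",
]

#: (sd_lam, sd_kon) kernel widths per regulation regime, in log2 units.
#: The limiting parameter gets SD 0.3, the non-limiting SD 5; the equal
#: regime uses the 50:50 cloud component SD (1.91) on both axes.
REGIMES: dict[str, tuple[float, float]] = {
    "size": (5.0, 0.3),
    "freq": (0.3, 5.0),
    "equal": (1.91, 1.91),
}


@dataclass(frozen=True)
class PairConfig:
    """Gibbs pair-sampler settings.

    ``n_sweeps`` alternating partner re-draws form one short Gibbs chain
    per accepted pair; the default 1000 matches the canonical run, and
    far fewer suffice in practice (the chain mixes in a handful of
    sweeps).
    """

    n_pairs: int = 2000
    fold_threshold: float = 2.0
    n_sweeps: int = 1000
    sd_lam: float = 1.91
    sd_kon: float = 1.91
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.sd_lam <= 0 or self.sd_kon <= 0:
            raise ValueError("kernel SDs must be positive")

    @classmethod
    def from_regime(cls, regime: str, **kwargs) -> "PairConfig":
        sd_lam, sd_kon = REGIMES[regime]
        return cls(sd_lam=sd_lam, sd_kon=sd_kon, **kwargs)

    def with_(self, **kwargs) -> "PairConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GenePair:
    """A (high-expressed, low-expressed) gene pair from the cloud."""

    idx_high: int
    idx_low: int
    mu_high: float
    mu_low: float
    fold_change: float
    d_log2_lam: float  # log2 lam(high) - log2 lam(low)
    d_log2_kon: float


def pair_weight(
    ref: BurstParams, cand: BurstParams, sd_lam: float, sd_kon: float
) -> float:
    """Gaussian kernel weight on displacement in (log2 λ, log2 k_on).

    ``exp(−Δλ²/(2 sd_lam²) − Δk_on²/(2 sd_kon²))`` with Δ the log2
    differences; symmetric in its two arguments.
    """
    if sd_lam <= 0 or sd_kon <= 0:
        raise ValueError("kernel SDs must be positive")
    dl = math.log2(ref.lam) - math.log2(cand.lam)
    dk = math.log2(ref.k_on) - math.log2(cand.k_on)
    return math.exp(-(dl**2) / (2 * sd_lam**2) - (dk**2) / (2 * sd_kon**2))


def gibbs_sample_pairs(
    cloud: GeneCloud,
    config: PairConfig,
    rng: np.random.Generator | None = None,
) -> list[GenePair]:
    """Sample gene pairs with ≥ ``fold_threshold`` expression difference.

    For each pair: pick a uniformly random anchor gene, then alternate
    ``n_sweeps`` times between holding one member fixed and re-drawing
    the other from all genes whose mean differs ≥ ``fold_threshold``-fold
    from the fixed member (in either direction), with probability
    proportional to the Gaussian kernel weight.  The final two genes are
    labelled high/low by mean expression.  Genes may recur across pairs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu = np.asarray(cloud.mu, dtype=float)
    usable = np.flatnonzero(mu > 0)
    if usable.size < 2:
        raise ValueError("cloud has fewer than two expressed genes")
    l2mu = np.full(mu.shape, -np.inf)
    l2mu[usable] = np.log2(mu[usable])
    l2lam = cloud.log2_lam
    l2kon = cloud.log2_kon
    log2_f = math.log2(config.fold_threshold)

    # feasibility: at least one admissible pair must exist
    span = l2mu[usable].max() - l2mu[usable].min()
    if span < log2_f:
        raise ValueError(
            "no gene pair satisfies the fold-change threshold "
            f"(expression span {2**span:.2f}-fold < {config.fold_threshold}-fold)"
        )

    inv_2sl2 = 1.0 / (2 * config.sd_lam**2)
    inv_2sk2 = 1.0 / (2 * config.sd_kon**2)

    def draw_partner(fixed: int) -> int | None:
        admissible = usable[np.abs(l2mu[usable] - l2mu[fixed]) >= log2_f]
        if admissible.size == 0:
            return None
        w = np.exp(
            -((l2lam[admissible] - l2lam[fixed]) ** 2) * inv_2sl2
            - ((l2kon[admissible] - l2kon[fixed]) ** 2) * inv_2sk2
        )
        tot = w.sum()
        if tot <= 0 or not np.isfinite(tot):
            return None
        return int(rng.choice(admissible, p=w / tot))

    pairs: list[GenePair] = []
    attempts_cap = 100 * config.n_pairs
    attempts = 0
    while len(pairs) < config.n_pairs:
        attempts += 1
        if attempts > attempts_cap:
            raise RuntimeError("pair sampling failed to converge; cloud too degenerate")
        a = int(rng.choice(usable))
        b = draw_partner(a)
        if b is None:
            logger.warning("anchor gene %d has no admissible partner; resampling", a)
            continue
        ok = True
        for sweep in range(config.n_sweeps - 1):
            # alternate which member is re-drawn
            if sweep % 2 == 0:
                new = draw_partner(b)
                if new is None:
                    ok = False
                    break
                a = new
            else:
                new = draw_partner(a)
                if new is None:
                    ok = False
                    break
                b = new
        if not ok:
            logger.warning("chain stalled without admissible partner; restarting pair")
            continue
        hi, lo = (a, b) if mu[a] >= mu[b] else (b, a)
        pairs.append(
            GenePair(
                idx_high=hi,
                idx_low=lo,
                mu_high=float(mu[hi]),
                mu_low=float(mu[lo]),
                fold_change=float(mu[hi] / mu[lo]),
                d_log2_lam=float(l2lam[hi] - l2lam[lo]),
                d_log2_kon=float(l2kon[hi] - l2kon[lo]),
            )
        )
    return pairs


def pairs_to_frame(pairs: list[GenePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": np.arange(len(pairs)),
            "gene_high": [p.idx_high for p in pairs],
            "gene_low": [p.idx_low for p in pairs],
            "mu_high": [p.mu_high for p in pairs],
            "mu_low": [p.mu_low for p in pairs],
            "fold_change": [p.fold_change for p in pairs],
            "d_log2_lam": [p.d_log2_lam for p in pairs],
            "d_log2_kon": [p.d_log2_kon for p in pairs],
        }
    )


def dm_gap(cloud: GeneCloud, pairs: list[GenePair]) -> float:
    """Sign statistic: mean DM of low partners − mean DM of high partners.

    Positive when the low-expressed (repressed) members are the noisier
    ones — the frequency-regulation signature.
    """
    lo = cloud.dm[[p.idx_low for p in pairs]]
    hi = cloud.dm[[p.idx_high for p in pairs]]
    return float(np.nanmean(lo) - np.nanmean(hi))


def compare_pair_variance(
    cloud: GeneCloud,
    pairs: list[GenePair],
    bin_size: int | None = None,
    floor: float = 0.0,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binned mean DM ± SEM of high vs low partners.

    Bin borders are placed on the pooled set of partner genes (high and
    low together) so both classes are summarized within the same
    expression ranges.  ``bin_size`` defaults to one eighth of the
    pooled set.  Bins where a class has fewer than 5 members are flagged
    and not tested.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    idx = np.array([[p.idx_high, p.idx_low] for p in pairs]).ravel()
    labels = np.tile(["high", "low"], len(pairs))
    mus = cloud.mu[idx]
    dms = cloud.dm[idx]
    if bin_size is None:
        bin_size = max(10, idx.size // 8)
    table = noise.binned_class_summary(
        mus,
        dms,
        labels,
        classes=("high", "low"),
        bin_size=bin_size,
        floor=floor,
        n_boot=n_boot,
        seed=seed,
    )
    empty = (table["n_high"] == 0) | (table["n_low"] == 0)
    if empty.any():
        logger.warning("%d bins lack one class entirely", int(empty.sum()))
    return table
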