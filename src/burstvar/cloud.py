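"""Simulated transcriptomes ("gene clouds") from the bursting model.

Per-gene kinetic parameters are drawn from log2-normal distributions of
the initiation rate λ (burst size ∝ λ/k_off) and the ON-switching rate
k_on (burst frequency = k_on·τ), with the total log2 variance of the
system split between the two by user-set fractions c_size and c_freq.
Each gene is then simulated across cells and summarized by mean (μ),
CV² and DM, producing the characteristic mean–variance cloud.

The five canonical variance splits are named scenarios i–v:
i 1:0 (pure burst-size variation) … iii 0.5:0.5 … v 0:1 (pure burst-
frequency variation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import noise
from .telegraph import BurstParams, simulate_gene

__all__ = [
    "SCENARIOS",
    "CloudConfig",
    "GeneCloud",
    "component_variances",
    "sample_parameter_cloud",
    "simulate_cloud",
]

#: (c_size, c_freq) splits of the total log2 variance.
SCENARIOS: dict[str, tuple[float, float]] = {
    "i": (1.0, 0.0),
    "ii": (0.75, 0.25),
    "iii": (0.5, 0.5),
    "iv": (0.25, 0.75),
    "v": (0.0, 1.0),
}


def component_variances(
    sigma2_tot: float, c_size: float, c_freq: float
) -> tuple[float, float]:
    """Split total log2 variance into (σ²(λ), σ²(k_on)).

    ``σ²(λ) = c_size·σ²_tot`` and ``σ²(k_on) = c_freq·σ²_tot`` with
    ``c_size + c_freq = 1``.
    """
    if sigma2_tot < 0 or c_size < 0 or c_freq < 0:
        raise ValueError("variances and fractions must be non-negative")
    if not math.isclose(c_size + c_freq, 1.0, abs_tol=1e-9):
        raise ValueError("c_size + c_freq must equal 1")
    return c_size * sigma2_tot, c_freq * sigma2_tot


@dataclass(frozen=True)
class CloudConfig:
    """Configuration of a simulated transcriptome.

    ``sigma2_tot`` is the total variance of the system in log2 space
    (default 7.3, the estimate from single-cell data), split between λ
    and k_on by ``c_size``/``c_freq``.  ``mean_lam`` and ``mean_kon``
    are, under ``center="median"`` (default), the linear-space medians of
    the log2-normal laws; ``center="mean"`` instead makes them the
    linear-space means.  Samples are clipped at ``clip_sd`` standard
    deviations from the center — genes occupy a bounded region of burst
    parameter space (the machinery has finite physical limits).
    """

    n_genes: int = 12_000
    n_cells: int = 200
    c_size: float = 0.5
    c_freq: float = 0.5
    sigma2_tot: float = 7.3
    mean_lam: float = 0.2
    mean_kon: float = 0.0013
    k_off: float = 0.01
    tau: float = 1800.0
    dwell: float = 120.0
    t_end: float | None = None  # defaults to 5*tau
    clip_sd: float = 4.0
    center: str = "median"
    dm_window: int = 500
    method: str = "interval"
    seed: int | None = None

    @classmethod
    def from_scenario(cls, scenario: str, **kwargs) -> "CloudConfig":
        """Config for one of the canonical splits i–v."""
        c_size, c_freq = SCENARIOS[scenario]
        return cls(c_size=c_size, c_freq=c_freq, **kwargs)

    def with_(self, **kwargs) -> "CloudConfig":
        return replace(self, **kwargs)


@dataclass
class GeneCloud:
    """A simulated transcriptome: parameters, counts and noise summaries."""

    params: list[BurstParams]
    counts: np.ndarray  # n_genes x n_cells
    mu: np.ndarray
    cv2: np.ndarray
    dm: np.ndarray
    config: CloudConfig

    @property
    def n_genes(self) -> int:
        return len(self.params)

    @property
    def log2_lam(self) -> np.ndarray:
        return np.log2([p.lam for p in self.params])

    @property
    def log2_kon(self) -> np.ndarray:
        return np.log2([p.k_on for p in self.params])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [f"g{i:05d}" for i in range(self.n_genes)],
                "k_on": [p.k_on for p in self.params],
                "k_off": [p.k_off for p in self.params],
                "lam": [p.lam for p in self.params],
                "mu": self.mu,
                "cv2": self.cv2,
                "dm": self.dm,
            }
        )


def _sample_log2(
    center_linear: float,
    var_log2: float,
    n: int,
    rng: np.random.Generator,
    clip_sd: float,
    center: str,
) -> np.ndarray:
    """Draw log2-values with the requested linear-space center."""
    sd = math.sqrt(var_log2)
    loc = math.log2(center_linear)
    if center == "mean":
        # E[2^X] = 2^{loc} * e^{(sd ln2)^2/2}  =>  shift loc down accordingly
        loc -= var_log2 * math.log(2.0) / 2.0
    elif center != "median":
        raise ValueError("center must be 'median' or 'mean'")
    x = rng.normal(loc, sd, size=n) if sd > 0 else np.full(n, loc)
    if sd > 0 and clip_sd is not None:
        x = np.clip(x, loc - clip_sd * sd, loc + clip_sd * sd)
    return x


def sample_parameter_cloud(
    config: CloudConfig, rng: np.random.Generator | None = None
) -> list[BurstParams]:
    """Draw per-gene burst parameters.

    log2 λ ~ Normal(log2 mean_lam, σ²(λ)) and log2 k_on ~
    Normal(log2 mean_kon, σ²(k_on)), independent across genes and
    between the two parameters; k_off, τ and dwell are constant.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    var_lam, var_kon = component_variances(
        config.sigma2_tot, config.c_size, config.c_freq
    )
    n = config.n_genes
    l2lam = _sample_log2(config.mean_lam, var_lam, n, rng, config.clip_sd, config.center)
    l2kon = _sample_log2(config.mean_kon, var_kon, n, rng, config.clip_sd, config.center)
    return [
        BurstParams(
            k_on=float(2.0**k),
            k_off=config.k_off,
            lam=float(2.0**l),
            tau=config.tau,
            dwell=config.dwell,
        )
        for l, k in zip(l2lam, l2kon)
    ]


def simulate_cloud(
    config: CloudConfig, rng: np.random.Generator | None = None
) -> GeneCloud:
    """Simulate an entire transcriptome and attach μ, CV² and DM."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = sample_parameter_cloud(config, rng=rng)
    t_end = config.t_end if config.t_end is not None else 5.0 * config.tau
    counts = np.empty((config.n_genes, config.n_cells), dtype=np.int64)
    for i, p in enumerate(params):
        ens = simulate_gene(
            p, config.n_cells, t_end=t_end, method=config.method, rng=rng
        )
        counts[i] = ens.counts
    nt = noise.matrix_noise(counts)
    mu = nt["mu"].to_numpy()
    cv2 = nt["cv2"].to_numpy()
    dms = noise.dm(mu, cv2, window=min(config.dm_window, max(3, config.n_genes)))
    return GeneCloud(params=params, counts=counts, mu=mu, cv2=cv2, dm=dms, config=config)
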