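"""End-to-end runs: simulated clouds + pair comparisons, and the binned
up/down noise analysis on a (synthetic or user) count dataset.

Everything is written as TSV/JSON; plots are an optional convenience
layer on top of the tables.  Every run writes a ``manifest.json`` with
the configuration, seed, package version and SHA-256 checksums of all
outputs, so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from . import noise
from .cloud import SCENARIOS, CloudConfig, GeneCloud, simulate_cloud
from .pairs import REGIMES, PairConfig, compare_pair_variance, dm_gap, gibbs_sample_pairs, pairs_to_frame
from .preprocess import (
    CountMatrix,
    classify_fold_change,
    filter_cells,
    filter_genes,
    normalize,
    size_factors,
)
from .synthetic import SyntheticDataset

logger = logging.getLogger(__name__)

__all__ = ["run_figure_clouds_and_pairs", "run_updown_noise", "preprocess_dataset", "write_manifest"]


def write_manifest(outdir: Path, config: dict, seed) -> Path:
    outdir = Path(outdir)
    checksums = {}
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            checksums[str(f.relative_to(outdir))] = hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
    try:
        ver = _pkg_version("burstvar")
    except Exception:  # not installed (e.g. run from a checkout)
        ver = "unknown"
    return bio.write_json(
        {"config": config, "seed": seed, "version": ver, "checksums": checksums},
        outdir / "manifest.json",
    )


def run_figure_clouds_and_pairs(
    outdir: str | Path,
    n_genes: int = 12_000,
    n_cells: int = 200,
    n_pairs: int = 2000,
    n_sweeps: int = 1000,
    n_boot: int = 10_000,
    seed: int = 0,
    scenarios: tuple[str, ...] = tuple(SCENARIOS),
    regimes: tuple[str, ...] = tuple(REGIMES),
    plot: bool = False,
) -> dict:
    """Simulated clouds for each variance split + pair comparisons.

    Writes one ``cloud_<scenario>.tsv`` per scenario, and for each
    regulation regime (pairs drawn from the 50:50 cloud)
    ``pairs_<regime>.tsv`` and ``pair_bins_<regime>.tsv``.  Returns (and
    writes) a summary with the sign statistic mean DM(low) − mean
    DM(high) and its bootstrap p per regime.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    clouds: dict[str, GeneCloud] = {}
    for sc in scenarios:
        cfg = CloudConfig.from_scenario(sc, n_genes=n_genes, n_cells=n_cells)
        clouds[sc] = simulate_cloud(cfg, rng=rng)
        bio.write_tsv(clouds[sc].to_frame(), outdir / f"cloud_{sc}.tsv")

    base = clouds.get("iii") or simulate_cloud(
        CloudConfig.from_scenario("iii", n_genes=n_genes, n_cells=n_cells), rng=rng
    )
    summary: dict = {"seed": seed, "regimes": {}}
    for regime in regimes:
        pcfg = PairConfig.from_regime(regime, n_pairs=n_pairs, n_sweeps=n_sweeps)
        pairs = gibbs_sample_pairs(base, pcfg, rng=rng)
        bio.write_tsv(pairs_to_frame(pairs), outdir / f"pairs_{regime}.tsv")
        table = compare_pair_variance(base, pairs, n_boot=n_boot, seed=int(rng.integers(2**31)))
        bio.write_tsv(table, outdir / f"pair_bins_{regime}.tsv")
        gap = dm_gap(base, pairs)
        res = noise.bootstrap_dm_test(
            base.dm[[p.idx_low for p in pairs]],
            base.dm[[p.idx_high for p in pairs]],
            n_boot=n_boot,
            rng=rng,
        )
        summary["regimes"][regime] = {
            "dm_gap_low_minus_high": gap,
            "p_boot": res.p_h0,
            "n_pairs": len(pairs),
        }
    bio.write_json(summary, outdir / "summary.json")
    if plot:
        _plot_clouds(clouds, outdir)
    write_manifest(
        outdir,
        {
            "n_genes": n_genes,
            "n_cells": n_cells,
            "n_pairs": n_pairs,
            "n_sweeps": n_sweeps,
            "scenarios": list(scenarios),
            "regimes": list(regimes),
        },
        seed,
    )
    return summary


def preprocess_dataset(
    m: CountMatrix,
    min_reads: int = 500_000,
    max_reads: int = 7_000_000,
    floor: float = 10.0,
) -> tuple[CountMatrix, pd.Series]:
    """Cell QC → per-replicate size factors → normalization → gene floor."""
    m = filter_cells(m, min_reads=min_reads, max_reads=max_reads)
    sf = size_factors(m)
    m = normalize(m, sf)
    m = filter_genes(m, floor=floor)
    return m, sf


def run_updown_noise(
    m: CountMatrix,
    outdir: str | Path,
    thresholds: tuple[float, ...] = (2.0, 3.0),
    time_points: tuple[int, int] = (0, 6),
    bin_size: int = 500,
    floor: float = 10.0,
    window: int = 500,
    n_boot: int = 10_000,
    seed: int = 0,
    min_reads: int = 500_000,
    max_reads: int = 7_000_000,
) -> dict:
    """Binned DM of up- vs downregulated genes at both time points.

    For each fold-change threshold: classify genes between the early and
    late time point, compute per-gene noise (μ, CV², DM) at each time
    point, place bin borders every ``bin_size`` genes above the floor,
    and summarize each class per bin with a recentred-bootstrap p-value.
    Writes one ``dm_bins_t<tp>_fc<threshold>.tsv`` per combination and a
    ``summary.json`` with the overall mean-DM gap per table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    t_early, t_late = time_points
    norm, _ = preprocess_dataset(
        m, min_reads=min_reads, max_reads=max_reads, floor=0.0
    )
    m_early = norm.subset_time_point(t_early)
    m_late = norm.subset_time_point(t_late)

    # per-time-point noise tables: expression floor applied per pooled
    # time-point dataset, then μ/CV²/DM on the retained genes
    tables = {}
    for tp, sub in ((t_early, m_early), (t_late, m_late)):
        sub_f = filter_genes(sub, floor=floor)
        nt = noise.matrix_noise(sub_f.counts.to_numpy())
        nt.index = sub_f.counts.index
        nt["dm"] = noise.dm(
            nt["mu"].to_numpy(), nt["cv2"].to_numpy(), window=window
        )
        tables[tp] = nt
        bio.write_tsv(
            nt.reset_index().rename(columns={"index": "gene"}),
            outdir / f"noise_t{tp}.tsv",
        )

    summary: dict = {"seed": seed, "tables": {}}
    for thr in thresholds:
        labels = classify_fold_change(m_early, m_late, threshold=thr, floor=floor)
        for tp in (t_early, t_late):
            nt = tables[tp]
            tab = noise.binned_class_summary(
                nt["mu"].to_numpy(),
                nt["dm"].to_numpy(),
                labels.loc[nt.index, "class"].to_numpy(),
                classes=("up", "down"),
                bin_size=bin_size,
                floor=floor,
                n_boot=n_boot,
                seed=int(rng.integers(2**31)),
            )
            name = f"dm_bins_t{tp}_fc{thr:g}"
            bio.write_tsv(tab, outdir / f"{name}.tsv")
            tested = tab[tab["tested"]]
            summary["tables"][name] = {
                "n_up": int((labels["class"] == "up").sum()),
                "n_down": int((labels["class"] == "down").sum()),
                "n_bins": int(len(tab)),
                "n_bins_tested": int(len(tested)),
                "n_bins_down_noisier": int(
                    (tested["mean_dm_down"] > tested["mean_dm_up"]).sum()
                ),
                "n_bins_significant": int((tested["p_boot"] < 0.05).sum()),
                "mean_dm_gap_down_minus_up": float(
                    np.nanmean(tab["mean_dm_down"] - tab["mean_dm_up"])
                ),
            }
    bio.write_json(summary, outdir / "summary.json")
    write_manifest(
        outdir,
        {
            "thresholds": list(thresholds),
            "time_points": list(time_points),
            "bin_size": bin_size,
            "floor": floor,
            "window": window,
            "n_boot": n_boot,
        },
        seed,
    )
    return summary


def _plot_clouds(clouds: dict[str, GeneCloud], outdir: Path) -> None:
    """Mean-vs-CV² scatter per scenario (convenience only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(clouds), figsize=(3 * len(clouds), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (sc, cl) in zip(axes, clouds.items()):
        ok = (cl.mu > 0) & (cl.cv2 > 0)
        ax.scatter(cl.mu[ok], cl.cv2[ok], s=2, alpha=0.3)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_title(f"scenario {sc}")
        ax.set_xlabel("mean")
    axes[0].set_ylabel("CV$^2$")
    fig.tight_layout()
    fig.savefig(outdir / "clouds.png", dpi=120)
    plt.close(fig)
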