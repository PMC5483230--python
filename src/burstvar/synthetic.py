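"""Ground-truthed synthetic scRNA-seq datasets from the bursting model.

Each gene gets baseline burst parameters drawn from the 50:50 parameter
cloud.  Regulated genes change expression between 0 hr and 6 hr by a
drawn log2 fold change ``d``, realized SYMMETRICALLY around the baseline
point: the 0-hr parameters sit at −d/2 and the 6-hr parameters at +d/2
(in log2 of the regulated quantity), with the 3-hr time point at the
geometric midpoint (the baseline itself).  Under frequency-mode
regulation the displacement is applied to the ON-state occupancy
``a = k_on/(k_on+k_off)`` (the mean is λ·τ·a, so the fold change on the
mean is exact even where k_on approaches k_off); under size mode it is
applied to λ; under equal mode it is split evenly between the two.

The symmetric placement encodes the bounded-parameter-region logic of
the model: a gene that will be induced must start from the low end of
its regulated axis, and one that will be repressed from the high end.
At 0 hr, up-genes therefore carry a typical burst size at an atypically
low expression level (noisy for their level), and vice versa at 6 hr —
the mechanism by which frequency-dominated regulation makes repressed
genes the more variable ones.

Sequencing is emulated by drawing a per-cell library size from a
log-uniform depth law and distributing it over genes as a multinomial
on the cell's true transcript abundances, so size factors are
recoverable from the counts.  Per-gene transcript counts come either
from the exact telegraph sampler or (default) from a negative binomial
moment-matched to the telegraph stationary mean and variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cloud import CloudConfig, sample_parameter_cloud
from .preprocess import CountMatrix
from .telegraph import BurstParams, simulate_gene, steady_state_fano, steady_state_mean
from . import io as bio

logger = logging.getLogger(__name__)

__all__ = ["SyntheticDesign", "SyntheticDataset", "generate_dataset", "write_fixture", "read_fixture"]

MODES = ("frequency", "size", "equal")
MAX_ACTIVITY = 0.98  # regulated ON-occupancy endpoints must stay below this


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design for a synthetic dataset.

    Defaults emulate a three-time-point (0/3/6 hr), three-replicate
    single-cell experiment of 433 cells and 12 000 genes with library
    sizes spanning 0.5–7 million reads.  ``frac_down > frac_up`` by
    default (differentiation represses more genes than it induces).
    ``log2_fc_range`` is the uniform law of |log2 FC| for regulated
    genes; ``qc_fail_fraction`` of cells get library sizes outside the
    QC window so depth filtering is exercised.
    """

    n_genes: int = 12_000
    cells_per_timepoint: tuple[tuple[int, int], ...] = ((0, 131), (3, 157), (6, 145))
    n_replicates: int = 3
    frac_up: float = 0.08
    frac_down: float = 0.12
    log2_fc_range: tuple[float, float] = (1.0, 4.0)
    regulation_mode: str = "frequency"
    depth_range: tuple[float, float] = (6.0e5, 6.0e6)
    qc_fail_fraction: float = 0.05
    sigma2_tot: float = 7.3
    cloud_scenario: str = "iii"
    exact: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.regulation_mode not in MODES:
            raise ValueError(f"regulation_mode must be one of {MODES}")
        if min(self.depth_range) <= 0:
            raise ValueError("depths must be positive")

    def with_(self, **kwargs) -> "SyntheticDesign":
        return replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """Counts for all cells plus the generating ground truth."""

    matrix: CountMatrix
    truth: pd.DataFrame  # indexed by gene
    design: SyntheticDesign
    params: dict[int, list[BurstParams]] = field(default_factory=dict)

    def matrix_at(self, time_point: int) -> CountMatrix:
        return self.matrix.subset_time_point(time_point)


def _split_cells(n: int, n_replicates: int) -> list[int]:
    base = n // n_replicates
    out = [base + (1 if i < n % n_replicates else 0) for i in range(n_replicates)]
    return out


def _activity(kon: np.ndarray, koff: float) -> np.ndarray:
    return kon / (kon + koff)


def _kon_from_activity(a: np.ndarray, koff: float) -> np.ndarray:
    return koff * a / (1.0 - a)


def _displaced(
    lam: np.ndarray,
    act: np.ndarray,
    d_signed: np.ndarray,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift (λ, activity) by a signed log2 displacement under a mode."""
    if mode == "frequency":
        return lam, act * 2.0**d_signed
    if mode == "size":
        return lam * 2.0**d_signed, act
    # equal: split the displacement between the two axes
    return lam * 2.0 ** (d_signed / 2), act * 2.0 ** (d_signed / 2)


def generate_dataset(design: SyntheticDesign) -> SyntheticDataset:
    """Generate counts for every (time point, replicate) plus ground truth."""
    rng = np.random.default_rng(design.seed)
    cfg = CloudConfig.from_scenario(
        design.cloud_scenario,
        n_genes=design.n_genes,
        sigma2_tot=design.sigma2_tot,
    )
    base = sample_parameter_cloud(cfg, rng=rng)
    lam0 = np.array([p.lam for p in base])
    kon0 = np.array([p.k_on for p in base])
    koff, tau, dwell = cfg.k_off, cfg.tau, cfg.dwell
    act0 = _activity(kon0, koff)
    n = design.n_genes

    n_up = int(round(design.frac_up * n))
    n_down = int(round(design.frac_down * n))
    d_mag = rng.uniform(*design.log2_fc_range, size=n)
    # the high endpoint of a regulated gene sits at +d/2 on the regulated
    # axis; genes where that endpoint is infeasible (ON-occupancy would
    # saturate) are skipped when assigning regulated slots — the bounded
    # region of parameter space in action
    half = d_mag / 2.0
    if design.regulation_mode == "frequency":
        feasible = act0 * 2.0**half < MAX_ACTIVITY
    elif design.regulation_mode == "equal":
        feasible = act0 * 2.0 ** (half / 2) < MAX_ACTIVITY
    else:
        feasible = np.ones(n, dtype=bool)
    order = rng.permutation(n)
    reg_candidates = order[feasible[order]]
    if reg_candidates.size < n_up + n_down:
        raise ValueError("too few genes admit the requested fold changes")
    n_skipped = int((~feasible[order[: n_up + n_down]]).sum())
    if n_skipped:
        logger.warning(
            "%d genes skipped for regulation (fold change infeasible)", n_skipped
        )
    up_idx = reg_candidates[:n_up]
    down_idx = reg_candidates[n_up : n_up + n_down]

    classes = np.full(n, "unchanged", dtype=object)
    classes[up_idx] = "up"
    classes[down_idx] = "down"
    d_signed = np.zeros(n)
    d_signed[up_idx] = d_mag[up_idx]
    d_signed[down_idx] = -d_mag[down_idx]

    # per-time-point parameters: 0 hr at -d/2, 3 hr at baseline, 6 hr at +d/2
    tp_params: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    tps = [tp for tp, _ in design.cells_per_timepoint]
    offsets = {tps[0]: -0.5, tps[-1]: +0.5}
    for tp in tps[1:-1]:
        offsets[tp] = 0.0
    for tp in tps:
        lam_t, act_t = _displaced(
            lam0, act0, offsets[tp] * d_signed, design.regulation_mode
        )
        if (act_t >= 1.0).any():
            raise RuntimeError("ON-occupancy saturated despite feasibility screen")
        tp_params[tp] = (lam_t, _kon_from_activity(act_t, koff))

    # transcript abundances, then multinomial sequencing per cell
    gene_ids = [f"g{i:05d}" for i in range(n)]
    blocks, metas = [], []
    qc_lo, qc_hi = 5.0e5, 7.0e6
    for tp, n_cells_tp in design.cells_per_timepoint:
        lam_t, kon_t = tp_params[tp]
        mean_t = lam_t * tau * _activity(kon_t, koff)
        if design.exact:
            expr = np.empty((n, n_cells_tp), dtype=np.int64)
            for g in range(n):
                p = BurstParams(
                    k_on=float(kon_t[g]), k_off=koff, lam=float(lam_t[g]),
                    tau=tau, dwell=dwell,
                )
                expr[g] = simulate_gene(
                    p, n_cells_tp, method="interval", rng=rng
                ).counts
        else:
            fano_t = np.array(
                [
                    steady_state_fano(
                        BurstParams(
                            k_on=float(kon_t[g]), k_off=koff, lam=float(lam_t[g]),
                            tau=tau, dwell=dwell,
                        )
                    )
                    for g in range(n)
                ]
            )
            var_t = mean_t * fano_t
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(var_t > mean_t, mean_t**2 / (var_t - mean_t), np.nan)
                pnb = np.where(var_t > mean_t, mean_t / var_t, np.nan)
            nb = var_t > mean_t
            expr = np.empty((n, n_cells_tp), dtype=np.int64)
            if nb.any():
                expr[nb] = rng.negative_binomial(
                    r[nb][:, None], pnb[nb][:, None], size=(int(nb.sum()), n_cells_tp)
                )
            if (~nb).any():
                expr[~nb] = rng.poisson(
                    mean_t[~nb][:, None], size=(int((~nb).sum()), n_cells_tp)
                )

        # per-cell library sizes: log-uniform within the QC window, with a
        # fraction of deliberately failing libraries on either side
        fail = rng.random(n_cells_tp) < design.qc_fail_fraction
        lo, hi = design.depth_range
        depths = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n_cells_tp)
        low_fail = rng.random(n_cells_tp) < 0.5
        depths = np.where(
            fail & low_fail, rng.uniform(1.0e5, qc_lo * 0.98, size=n_cells_tp), depths
        )
        depths = np.where(
            fail & ~low_fail, rng.uniform(qc_hi * 1.01, 9.0e6, size=n_cells_tp), depths
        )
        depths = depths.astype(np.int64)

        reads = np.zeros((n, n_cells_tp), dtype=np.int64)
        colsum = expr.sum(axis=0)
        for c in range(n_cells_tp):
            if colsum[c] == 0:
                warnings.warn("cell with zero transcripts; left empty", stacklevel=2)
                continue
            reads[:, c] = rng.multinomial(depths[c], expr[:, c] / colsum[c])
        blocks.append(reads)

        rep_sizes = _split_cells(n_cells_tp, design.n_replicates)
        rep_of = np.repeat(np.arange(1, design.n_replicates + 1), rep_sizes)
        metas.append(
            pd.DataFrame(
                {
                    "cell_id": [
                        f"c{tp}h_r{rep_of[c]}_{c:04d}" for c in range(n_cells_tp)
                    ],
                    "time_point": tp,
                    "replicate": rep_of,
                    "total_reads": depths,
                }
            )
        )

    meta = pd.concat(metas, ignore_index=True).set_index("cell_id")
    counts = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(gene_ids, name="gene"), columns=meta.index
    )
    matrix = CountMatrix(counts=counts, cell_meta=meta)

    t0, t6 = tps[0], tps[-1]
    lam_a, kon_a = tp_params[t0]
    lam_b, kon_b = tp_params[t6]
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "class": classes,
            "mode": np.where(classes == "unchanged", "none", design.regulation_mode),
            "log2_fc": d_signed,
            "fc": 2.0**d_signed,
            "k_on_0": kon_a,
            "lam_0": lam_a,
            "k_on_6": kon_b,
            "lam_6": lam_b,
            "mu_0": lam_a * tau * _activity(kon_a, koff),
            "mu_6": lam_b * tau * _activity(kon_b, koff),
        }
    ).set_index("gene")

    params = {
        tp: [
            BurstParams(
                k_on=float(tp_params[tp][1][g]), k_off=koff,
                lam=float(tp_params[tp][0][g]), tau=tau, dwell=dwell,
            )
            for g in range(n)
        ]
        for tp in tps
    }
    return SyntheticDataset(matrix=matrix, truth=truth, design=design, params=params)


def write_fixture(dataset: SyntheticDataset, outdir) -> None:
    """Write counts (MTX + sidecars), truth.tsv and design.json."""
    bio.write_count_matrix(dataset.matrix, outdir)
    bio.write_tsv(dataset.truth.reset_index(), f"{outdir}/truth.tsv")
    d = dataset.design
    bio.write_json(
        {
            "n_genes": d.n_genes,
            "cells_per_timepoint": list(map(list, d.cells_per_timepoint)),
            "n_replicates": d.n_replicates,
            "frac_up": d.frac_up,
            "frac_down": d.frac_down,
            "log2_fc_range": list(d.log2_fc_range),
            "regulation_mode": d.regulation_mode,
            "depth_range": list(d.depth_range),
            "qc_fail_fraction": d.qc_fail_fraction,
            "sigma2_tot": d.sigma2_tot,
            "cloud_scenario": d.cloud_scenario,
            "exact": d.exact,
            "seed": d.seed,
        },
        f"{outdir}/design.json",
    )


def read_fixture(outdir) -> tuple[CountMatrix, pd.DataFrame]:
    """Read back a written fixture (counts + truth)."""
    m = bio.read_count_matrix(outdir)
    truth = bio.read_tsv(f"{outdir}/truth.tsv").set_index("gene")
    return m, truth
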