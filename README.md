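# burstvar

Simulation and analysis tools for asking how transcriptional bursting
shapes cell-to-cell transcript variability — in particular, whether
genes regulated through the *frequency* of transcriptional bursts
become noisier when repressed, and quieter when induced, across a
single-cell RNA-seq time course.

The package is aimed at computational biologists studying stochastic
gene expression: it provides an exact simulator of the two-state
(telegraph) model, transcriptome-scale "gene cloud" simulations with a
controlled split of expression variance between burst size and burst
frequency, a Gibbs sampler of regulated gene pairs, the standard noise
statistics (CV², distance-to-median), a recentred bootstrap test, and a
ground-truthed synthetic scRNA-seq generator so the whole analysis
chain can be exercised without any external data.

## The model

A gene switches between an inactive and an active promoter state at
rates `k_on` (OFF→ON) and `k_off` (ON→OFF). While active, transcripts
initiate at rate λ; each appears in the mature pool after a fixed dwell
time (elongation + termination) and then decays with lifetime τ. Two
derived quantities summarize the regime:

- burst size `= λ / k_off` — transcripts made per activity pulse,
- burst frequency `= k_on · τ` — pulses per mature-RNA lifetime.

Default kinetics (`k_on = 0.0013 s⁻¹`, `k_off = 0.01 s⁻¹`,
`λ = 0.2 s⁻¹`, `τ = 1800 s`, dwell `= 120 s`) give 2.34 bursts per RNA
lifetime and 20 RNAs per burst, with stationary mean
`λτ·k_on/(k_on+k_off) ≈ 41.4` copies per cell.

To simulate a transcriptome, per-gene `log2 λ` and `log2 k_on` are drawn
from normal distributions whose variances split a total log2-variance of
7.3 in a chosen ratio `c_size : c_freq` (scenarios i–v from pure
burst-size to pure burst-frequency variation). Noise per gene is scored
as CV² `= σ²/μ²` and DM, the residual of `log10 CV²` from its
running-median trend over mean expression — genes with `DM > 0` are
noisier than typical for their expression level.

## Worked example

Simulate the canonical clouds and the three pair-regulation regimes:

```sh
burstvar figures --out demo --n-genes 2000 --n-cells 100 \
    --n-pairs 200 --sweeps 100 --seed 1
```

prints (also written to `demo/summary.json`):

```json
{
  "size":  { "dm_gap_low_minus_high": -0.340, "p_boot": 0.0001, "n_pairs": 200 },
  "freq":  { "dm_gap_low_minus_high":  0.505, "p_boot": 0.0001, "n_pairs": 200 },
  "equal": { "dm_gap_low_minus_high": -0.003, "p_boot": 0.944,  "n_pairs": 200 }
}
```

`dm_gap_low_minus_high` is the mean DM of the low-expressed pair members
minus that of their high-expressed partners. When expression changes are
carried by burst frequency the repressed partner is markedly noisier
(+0.50, significant); under burst-size regulation the sign flips
(−0.34); when both contribute equally there is no significant
difference. This is the model's signature that repression generates
variability when genes are regulated through burst frequency.

The same analysis runs end-to-end on synthetic sequencing data:

```sh
burstvar synth --mode frequency --n-genes 3000 --seed 0 --out ds
burstvar -v run --config run.yaml       # or drive the library directly
```

where the pipeline (cell QC at 0.5–7 M reads, per-replicate
median-of-ratios size factors, gene floor at mean normalized count 10,
2-fold classification between 0 hr and 6 hr, binned DM with a recentred
bootstrap per bin) shows downregulated genes significantly noisier than
upregulated genes at 6 hr in every expression bin, with the ordering
reversed at 0 hr — induced-to-be genes start out the more variable ones.

Other subcommands: `cloud`, `pairs`, `preprocess`, `noise`, `boottest`
(see `burstvar --help`).

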