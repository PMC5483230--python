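# Methods

## The two-state transcription model

`burstvar.telegraph` implements the random telegraph model: a promoter
alternates between OFF and ON states with exponential waiting times
(rates `k_on`, `k_off`); while ON, initiation events occur as a Poisson
process of rate λ. An initiated transcript enters the observed mature
pool only after a fixed dwell time (default 120 s, a physiological
elongation + termination estimate) and is degraded thereafter with
first-order rate 1/τ. The counted species is mature RNA; transcripts
still inside the dwell window can be included with
`count_nascent=True`, since a sequencing experiment would detect
nascent molecules too — the choice is exposed rather than hidden
because the difference (≈ λ·p_on·dwell ≈ 2.8 copies at defaults) is
small but not nil.

Closed forms used throughout (derived for degradation rate `d = 1/τ`,
with the dwell shifting timing but not stationary moments):

- mean `μ = λτ·k_on/(k_on+k_off)`
- Fano factor `F = 1 + λ·k_off/((k_on+k_off)(k_on+k_off+d))`

Both are verified against simulation in the test suite.

### Two exact samplers

`simulate_gene(..., method="gillespie")` is an event-driven exact
simulation. Delayed appearance is handled by a pending-event min-heap
merged into the Gillespie clock: if a scheduled appearance precedes the
next drawn Markov event, the clock jumps to the appearance and the
exponential waiting time is redrawn — exact by memorylessness.
Degradation is a propensity channel `(mature count)/τ`.

`method="interval"` exploits the conditional structure of the model:
given the ON/OFF trajectory, initiations are an inhomogeneous Poisson
process, and each molecule independently survives to the observation
time `T` with probability `exp(−(T − t_init − dwell)/τ)`. The mature
count at `T` is therefore exactly Poisson with rate
`λ ∫ exp(−(T−dwell−t)/τ) dt` over ON time before `T − dwell` (the
immigration–death/M/G/∞ thinning argument). Only the switching
trajectory needs simulating, and since all cells start OFF, a whole
ensemble advances in lockstep with vectorized exponential draws. The
two samplers target the same distribution (asserted by a KS test);
`interval` is used for transcriptome-scale runs, `gillespie` remains the
default for single-gene work and as the structural reference.

Cells start OFF with zero transcripts; stationarity is approached by
simulating to `t_end = 5τ` by default (the residual transient in the
mean is ≈ 0.7%, well inside Monte-Carlo error at the ensemble sizes
used). A warning is emitted below `3τ`.

## Gene clouds

`burstvar.cloud` draws per-gene `log2 λ ~ N(log2 0.2, c_size·σ²_tot)`
and `log2 k_on ~ N(log2 0.0013, c_freq·σ²_tot)` independently, with
`σ²_tot = 7.3` (an estimate of the total log2 expression variance of
single-cell data) and `c_size + c_freq = 1`; `k_off`, τ and dwell are
constant. The stated centers are interpreted as linear-space medians
(the location parameter of the log2-normal); a `center="mean"` switch
shifts the location by `−σ² ln2 / 2` for users who prefer the
linear-space mean. The median reading keeps the derived burst
statistics at their quoted values (median burst frequency 2.34, median
burst size 20) by construction. Samples are clipped at ±4 SD —
transcription operates within finite physical limits, so genes occupy a
bounded region of burst-parameter space; the bound is configurable.

Scenarios i–v split the variance 1:0, 0.75:0.25, 0.5:0.5, 0.25:0.75,
0:1 between size and frequency. Because CV² at a given mean grows with
burst size but shrinks with burst frequency, scenario i piles variance
on top of the shot-noise trend while scenario v rides along it; the
intermediate scenarios produce clouds that straddle the running-median
trend, as real data do.

## Noise statistics

`cv2` uses the unbiased (n−1) variance. The running-median trend sorts
genes by mean, takes a centered rolling median of `log10 CV²`
(default window 500 genes, mirroring the binning granularity; truncated
at the edges), and `dm` is the `log10` residual from it. The median
makes DM invariant to a global rescaling of CV² and robust to
outliers; residuals are centred near zero over a large cloud by
construction. Expression bins place borders every 500 genes of the
full analyzed set (mean ≥ 10), so class summaries within bins share
identical borders.

### Recentred bootstrap

To test whether two gene classes differ in mean DM, each bootstrap
replicate resamples both classes with replacement and shifts each
resample by (pooled mean − original class mean), imposing the null of
equal means while preserving each class's dispersion; a Welch t is
computed per replicate and `p(H0) = (1 + #{exceedances})/(1 + n_boot)`
with 10 000 replicates by default. The counting rule is two-sided
(`|t_i| > |t|`) by default; `alternative="greater"` gives the literal
one-sided count `t_i > t`, which is the variant under which two
identical samples score p ≈ 0.5 (two-sided counting drives degenerate
`t = 0` cases toward 1 instead). Replicates with zero variance in both
groups are set to `t_i = 0` with a warning. The two-sided rule is
calibrated: its type-I error at α = 0.05 matches the nominal rate in
the test suite. A Mann-Whitney utility (`ranksum_test`) is provided for
non-parametric comparisons: exact for tie-free samples of ≤ 10 per
group, normal approximation with tie/continuity corrections otherwise.

## Gibbs pair sampling

To model a gene whose expression changes across a transition,
`burstvar.pairs` samples pairs of cloud genes at least 2-fold apart in
mean. Candidates are weighted by a Gaussian kernel on the displacement
in `(log2 λ, log2 k_on)` with per-axis SDs; the "limiting" axis gets
SD 0.3 and the "non-limiting" axis SD 5, so the expression change is
carried by burst size (`size` regime: λ free), burst frequency (`freq`:
k_on free), or both (`equal`). The kernel form is the natural reading
of "probability based on distance" with the quoted SDs as Gaussian
widths. For the equal regime, where no limiting/non-limiting split is
quoted, both axes use the 50:50 cloud component SD (1.91).

Each accepted pair is the end state of a short Gibbs chain: starting
from a random anchor, the sampler alternates re-drawing one member
conditioned on the other (admissible candidates = genes ≥ 2-fold away
in either direction; high/low roles are assigned afterwards by mean).
The canonical chain length is 1000 sweeps; the chain mixes in a handful
of sweeps, so scaled-down runs use 100. Genes may recur across pairs
(sampling with replacement); duplication is modest in practice
(≈ 5% at 200 pairs from 2000 genes).

The headline statistic is `mean DM(low) − mean DM(high)`. Its sign is
positive under frequency regulation (the repressed partner is noisier),
negative under size regulation, and indistinguishable from zero under
equal regulation — the mechanism is that a gene moved down by frequency
keeps its (typical) burst size and is therefore noisier than cloud
genes of the same mean, which tend to have smaller bursts.

## Synthetic sequencing datasets

`burstvar.synthetic` emulates a 3-time-point (0/3/6 hr), 3-replicate
experiment of 433 cells and 12 000 genes. Baseline parameters come from
the 50:50 cloud. A fraction of genes (defaults 8% up, 12% down — more
repression than induction, as in differentiation) receives a fold
change with `|log2 FC| ~ U(1, 4)`, realized symmetrically: 0-hr
parameters at −d/2 and 6-hr parameters at +d/2 in log2 of the regulated
quantity, with 3 hr at the baseline (geometric midpoint). Under
frequency mode the displacement acts on the ON-occupancy
`a = k_on/(k_on+k_off)` so the fold change on the mean `λτa` is exact
even near saturation; draws whose +d/2 endpoint would saturate
(`a ≥ 0.98`) are skipped when regulated slots are assigned — the
bounded-region constraint again. The symmetric placement is what makes
the 0-hr prediction non-trivial: genes to be induced sit low on their
regulated axis with an otherwise typical burst size, hence are noisier
than their expression peers *before* the transition, and the ordering
flips after it.

Per-gene transcript counts use a negative binomial moment-matched to
the telegraph mean and Fano factor (the `exact` switch substitutes the
interval sampler; the two agree on normalized means with r > 0.98).
Sequencing depth is a per-cell library size drawn log-uniformly on
0.6–6 M reads (within the 0.5–7 M QC window), with a configurable
fraction of deliberately failing libraries outside the window;
reads are distributed over genes as a multinomial on the cell's
transcript abundances, so column sums equal the drawn depths exactly
and median-of-ratios size factors recover them (Spearman ≥ 0.95).

What the generator does *not* emulate: gene-length and GC bias, PCR
duplicates, spike-ins, mitochondrial fractions, dropout beyond
multinomial thinning, cell-cycle or pseudotime structure, and
cell-to-cell variation in τ/k_off/dwell. Passing tests therefore
demonstrate the statistical machinery and the model's qualitative
predictions, not robustness to those technical artifacts in real data.
The DM implementation likewise omits the gene-length correction of the
original distance-to-median method, as simulated genes have no length.

## Preprocessing conventions

Cell QC keeps libraries with 0.5 M ≤ reads ≤ 7 M (bounds inclusive, a
literal reading of "fewer than"/"higher than"). Size factors are
median-of-ratios: reference = per-gene geometric mean over the cells of
one replicate (genes with any zero excluded), factor = median ratio to
the reference, rescaled to geometric mean 1 within each replicate so
normalized scales are comparable; computation is strictly
within-replicate. The implementation matches the DESeq reference
implementation up to that rescaling convention (asserted in tests).
Gene filtering keeps mean normalized count ≥ 10, applied per pooled
time-point dataset. Fold-change classification averages per-replicate
means (replicates weighted equally regardless of cell count), with
FC ≥ t → up and FC ≤ 1/t → down; a gene silent at one time point is
classified only if its expressed mean reaches the floor (a pseudocount
alternative is available). Optional additional QC filters (genes
detected, mitochondrial fraction) exist as hooks but have no default
thresholds.

## Problem sizes and numerical choices

Transcriptome-scale checks run at 2000 genes × 100 cells with 200 pairs
and 100 sweeps (clouds), and 3000 genes × 433 cells (datasets) — sizes
at which every qualitative contrast above is stable across seeds while
a full run stays interactive; the canonical sizes (12 000 × 200, 2000
pairs, 1000 sweeps) remain the defaults. All randomness flows from
per-run `numpy` Generators; ensembles, clouds, pair sets and datasets
are bit-reproducible under a fixed seed, and pipeline manifests record
config, seed and output checksums. Degenerate inputs fail loudly
(empty QC result, empty median-of-ratios reference, clouds with no
admissible pair) rather than silently returning empty results.

## Known limitations

- The telegraph model ignores intra-burst polymerase dynamics and
  mechanistic elongation; dwell is a fixed offset.
- The pair sampler models regulation as a probabilistic constraint on
  endpoints, not a temporal trajectory.
- The bootstrap treats genes as independent units; residual correlation
  from pair-sampling duplication slightly inflates its effective n.
- 3-hr data are interface completeness (parameter midpoint), not an
  independently calibrated intermediate state.
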