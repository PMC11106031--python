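# Methods

## Statistical model

Contacts of RNA *i* are treated as independent draws over genomic bins:
`X_ij ~ Binomial(N_i, p_ij)`, where `N_i` counts the RNA's contacts outside
its own gene body (self-proximity around the transcription site is
uninformative, so the gene-body bin is excluded from `N_i` and never
tested). The only estimated parameter is `p_ij`, assembled from two
empirical components:

1. **Heterogeneity background.** A fine-resolution track of non-specific
   signal: for all-to-all data, pooled trans contacts of mRNAs (each mRNA
   contributes only contacts off its own chromosome, so decay structure
   never leaks in); for one-to-all data, a user-supplied input track. The
   default fine resolution is 1 kb (`--bg-binsize`); the track is
   re-aggregated onto each RNA's grid by exact fractional overlap. Grid
   bins with zero background receive a width-proportional pseudo-count
   equal to the smallest nonzero fine-bin value scaled by bin width over
   fine width — masking them instead would silently drop testable signal,
   and the scaling estimate requires `p_bg > 0` everywhere. Probabilities
   are normalized over testable bins. `--no-background` swaps the track for
   a width-proportional (uniform) one.

2. **Distance decay.** Per RNA, the raw factor `f̂_j = (O_j/N_i)/p̂_bg_j` is
   computed for every non-gene-body cis bin at distance `d_j` (nearer gene
   boundary to bin midpoint, floored at 1 bp). Raw factors are averaged
   within log10-distance windows of 0.05 dex *on the factor scale* and a
   cubic smoothing spline is fitted to `(mean log10 d, log10(mean f̂ + ε))`.
   Averaging before the log matters: at fine bins the expected count per
   bin is small, and the expectation of the log of a noisy count sits below
   the log of the expected count, which systematically bent the fitted
   decay downward when the spline was fitted to per-bin log factors (the
   same reason Hi-C expected-contact curves are aggregated in log-spaced
   distance windows before smoothing). The offset
   `ε = 0.5/(N_i · max_j p̂_bg_j)` (half a count on the factor scale) keeps
   empty windows defined; dropping empty bins instead would bias the distal
   curve upward. Smoothing uses the fitter's generalized cross-validation
   default (`--scaling-smooth` overrides; `lam` of
   `scipy.interpolate.make_smoothing_spline`). Estimation is **two-step**:
   step-1 probabilities `f₁(d)·p̂_bg`, renormalized to the RNA's cis contact
   mass, give right-sided binomial p-values; bins significant at per-RNA
   BH q < 0.05 (`--alpha-refine`) are removed and the spline refitted once.
   This keeps genuine binding sites from inflating the presumed background
   decay. Evaluation is clamped to the fitted log-distance domain (flat
   extrapolation); fewer than 4 usable windows, or no cis contacts, degrade
   to the flat model f ≡ 1, which is also what `--no-scaling` forces.
   Scaling applies to cis bins only; trans bins always get factor 1.

Cis raw values `f(d_j)·p̂_bg_j` are rescaled to sum to `N_cis/N_i`, trans
raw values to `N_trans/N_i`, so `Σ_j p_ij = 1` per RNA and each compartment
carries exactly its observed contact fraction — the decay factor's absolute
level therefore cancels; only its shape affects calling. Right-sided
binomial p-values (`scipy.stats.binom.sf`) are computed for all testable
bins; only non-empty bins enter Benjamini–Hochberg correction, applied
pooled over all RNAs (global q) and within each RNA (RNA q). Peaks are
single significant bins (global q below `--qval`, default 0.05); adjacent
significant bins are merged only on request (`--merge`).

## Binning

Trans chromosomes are tiled uniformly. The trans bin size is selected per
RNA from a candidate grid (`--trans_min`/`--trans_max`/`--trans_step`;
defaults 10 kb / 1 Mb / 1 kb, or 400 nt / 50 nt steps for high-resolution
one-to-all data via `BinningParams.ota()`) by minimizing the
Shimazaki–Shinomoto histogram cost `C(s) = (2m − v)/s²` with `m`, `v` the
mean and biased variance of per-bin counts. Counts are winsorized at their
99th percentile before computing the cost: candidate binding sites are
point contamination for the background density the cost targets, and a
handful of peak bins otherwise dominates `v` at every size, collapsing the
choice to the finest candidate. When the clip falls below one count
(sparse data) winsorization is skipped. Ties break to the smallest size; an
RNA with no trans contacts falls back to the coarsest candidate.

Cis bins grow geometrically outward from both gene boundaries,
`width(i) = min(startsize · factor^i, trans_binsize)`, with the gene body
as its own flagged bin and terminal bins truncated at the chromosome ends,
so every chromosome is tiled exactly. `startsize` defaults to a tenth of
the selected trans size (`--cis_start` overrides; 100 nt for the
one-to-all parameterization). The default growth factor is 1.05: the decay
zone of real RNAs spans tens of bin widths, and a gentle factor keeps bin
width roughly tracking the reciprocal of the decay — approximately even
expected coverage per bin — across that whole zone, where a steep factor
reaches the uniform cap within a couple of bins of the gene. Contacts are
assigned to bins by DNA-fragment midpoint.

## Simulation framework

One RNA on two chromosomes. Per 50 kb window *w*, a heterogeneity weight
`λ_w ~ Poisson(5)` is drawn; the cis sampling density is
`λ_w · f_sig(d_w)` with `f_sig(d) = 1 + A/(1 + exp((log10 d − μ)/s))`
(limit 1 at large distance), the trans density is `λ_w` alone. Non-specific
contact positions, and peak summit positions, are sampled from these
densities (summits landing in the gene body are resampled); each peak
contributes a fixed number of specific contacts placed
`Normal(summit, peak_sd)` and clipped to the chromosome. The λ track is
returned as the input background the pipeline would receive.

Default conditions: 100 Mb cis chromosome with a 10 kb central gene, 200 Mb
trans chromosome, 50 000 background contacts split 85/15 cis/trans, 33 cis
and 50 trans peaks of 23 contacts each with 3.5 kb spread, A = 12,
μ = 6.0 (midpoint ~1 Mb), s = 0.4. These values were calibrated once, as a
set, so that the benchmark reproduces the published behaviour of this class
of caller on simulated data — cis AUPRC ≈ 0.85 with decay correction,
collapsing ≈ 6-fold without it, trans AUPRC ≈ 0.999 in both modes — and
then frozen. The regime is deliberate: peak enrichment is *moderate*,
comparable to the decay excess near the gene, because that is where decay
modelling decides cis accuracy; peaks much stronger than the decay excess
out-rank it in any ordering and the ablation shows nothing. Per-peak
contact counts are fixed rather than Poisson-distributed so that benchmark
variance reflects placement, not depth draws.

What the simulation does **not** emulate: zero inflation (centromeres,
dropout), overdispersed or extreme background counts (the Poisson-λ
background is nearly uniform at coarse scales, so the benchmark cannot
separate background modelling from a uniform assumption — it isolates the
decay correction), restriction-site structure, read-level noise, or
multiple RNAs competing in one library. Passing benchmarks therefore
demonstrate correct decay handling and calibrated testing under idealized
heterogeneity, not performance on any particular real protocol.

## Evaluation

A called peak is a true positive if it overlaps at least one simulated
summit; a summit is covered if any called peak overlaps it. Precision is
TP/(TP+FP) over called peaks; recall is the fraction of summits covered
(the convention a point-summit truth forces on bin-shaped calls; precision
at zero called peaks is defined as 1). Precision–recall curves sweep the
distinct global q-values of the candidate (non-empty, tested) bins in one
compartment; the area is the step-wise sum Σ (R_k − R_{k−1})·P_k with
R₀ = 0. Benchmarks run 20 replicates (seeded independently via
`default_rng([seed, r])`, shared between modes so the ablation is paired)
and report per-mode means with Student-t 95% intervals.

## Numerical choices and edge cases

* Binomial tails via `scipy.stats.binom.sf` (stable for small tails);
  BH via `statsmodels.stats.multitest.multipletests`; both are checked in
  the test suite against explicit pmf summation and an O(n²) textbook BH.
* Geometric bin widths round to integer bp; coordinates stay integral;
  the exponent is capped before exponentiation to avoid float overflow.
* `cis_binsize` ties and caps: any width reaching `trans_binsize` stays
  there; bin-size selection ties break to the smaller candidate.
* Zero q-values export as −log10 = 400 in narrowPeak (score capped at
  1000) rather than infinity.
* Empty compartments: an RNA with no cis (or trans) contacts leaves that
  compartment untested with a warning rather than failing the run.
* Per-RNA stages are independent and deterministic; `fit(n_jobs=k)` is
  byte-identical to the serial run.
* The HDF5 container stores one group per RNA (bin coordinates, counts,
  background, scaling, p/q-values) plus a schema version string; loading
  any other schema fails loudly.

## Limitations

The binomial model ignores overdispersion between replicates and zero
inflation; both are documented extensions (negative-binomial or
zero-inflated variants) that this package deliberately does not implement.
The exact bin-size cost of the original tool in this family is unpublished;
the winsorized Shimazaki–Shinomoto criterion used here matches its stated
goal (balancing resolution against per-bin coverage) but not necessarily
its selected sizes. Fitted decay factors are identified only up to a
multiplicative constant (the compartment renormalization absorbs the
level); diagnostic plots of f(d) should be read for shape, not scale.
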