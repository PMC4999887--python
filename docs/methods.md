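# Methods

## Model and procedure

The pipeline treats a 4-plex iTRAQ experiment as a fixed sequence of
estimators on PSM reporter intensities.

**Filtering.** A PSM is used only if its identification error probability
(FDR/PEP scale) is at most `min_confidence` (default 0.01) and all four
reporter intensities are strictly positive. "High-confidence PSMs" are
operationalised as exactly this post-filter set; no second confidence tier
exists. Zeros that appear later (e.g. after impurity correction) are
treated as missing, never pseudocounted: the complete-reporter rule means a
zero is an absent measurement, not a measured zero.

**Isotope-impurity correction.** The manufacturer's matrix `M` has entry
(i, j) = fraction of tag j's signal observed in channel i (channel order
114, 115, 116, 117; columns are fractions that sum to ≤ 1 because some
signal leaves the ±2 Da window). Correction solves `M·x = observed` by LU
factorisation per PSM. Validation rejects matrices with negative entries,
column sums above 1 + 1e-9, or condition number above 1e8. Negative
solution components — possible when noise exceeds a small satellite — are
clamped to 0 and counted in the log.

**Roll-up.** Peptide intensity per channel is the arithmetic mean of that
peptide's PSM intensities. A peptide's ratio for a comparison is
geomean(numerator channels)/geomean(denominator channels); a protein's
ratio is the geometric mean of its *unique* peptides' ratios. Aggregating
multi-channel ratio sides by geometric mean (the duplicate-labelled GV
sample spans tags 114 and 115) keeps all averaging on the log scale.
Uniqueness is taken from the input flag; no protein inference is performed.
Shared peptides carry composite `;`-joined group ids, so they can never
enter a single group's ratio; they count toward `n_peptides` only.
Quantification requires ≥ 1 usable unique peptide (`min_unique_for_quant`);
the differential-expression call separately requires ≥ 2 — both knobs are
independent because quantification depth and calling stringency are
different decisions.

**Significance B.** Proteins with a defined ratio are sorted by summed
reporter intensity (stable sort, ties broken by protein id) and cut into
consecutive bins of `bin_size` = 300; a trailing bin smaller than
`bin_size`/2 merges into its neighbour, and fewer than 2·`bin_size`
proteins form a single bin. Within a bin, m = median, r₊ = P84.13 − m,
r₋ = m − P15.87 (linear-interpolation percentiles); z uses r₊ above the
median and r₋ below, and p = ½·erfc(z/√2). A bin whose half-width
collapses to zero is merged with a neighbour; if the only bin is
degenerate the input distribution is rejected. One-sided p is the default
(the convention for this statistic); `two_sided=True` doubles and caps at
1. Raw p < α is used for calling, matching practice for this statistic; a
Benjamini–Hochberg option would be a deliberate departure and is not
wired into the default pipeline. The default bin size of 300 is the
standard choice at the ~3,000-protein scale of these experiments.

**Replicate QC.** For a duplicate-labelled channel pair, σ_log2 is the
sample sd (ddof = 1) of log₂(I_A/I_B) over proteins positive in both
channels; Pearson R² and the OLS slope of I_B on I_A summarise the linear
intensity agreement. Percent variation per protein is defined as
|I_A − I_B| / mean(I_A, I_B) × 100 (the alternative |ratio − 1|·100 differs
only in the denominator; the symmetric form is used because it is bounded
and orientation-free), and its empirical CDF is the cumulative
%-variation curve. The equal-mixing check reports per-channel median and
quartile log₂ ratios against a reference channel, flagging |median| >
0.5. Median normalisation (shifting a comparison's log₂ ratios to median
0) exists but is off by default: verified equal mixing replaces
normalisation.

**Differential expression and clustering.** Status is up when ratio ≥ 2,
down when ratio ≤ 0.5 (both inclusive, mirroring each other), given
p < 0.05 and ≥ 2 unique peptides; proteins lacking a ratio or p-value are
`not_tested`. The DE union is clustered on raw log₂-ratio profiles with
Ward/Euclidean agglomerative clustering cut at exactly k = 5. Profiles are
not per-protein standardised — with only two comparison dimensions row
z-scoring degenerates. A missing profile entry is imputed as 0 and
flagged (no signal invented, profile kept complete). Labels are
renumbered 1..k by decreasing size with ties broken by smallest member id,
making the labelling invariant to input row order.

**qPCR.** ΔCt = mean Ct(target) − mean Ct(reference gene) per group;
ΔΔCt = ΔCt(group) − ΔCt(calibrator); RQ = 2^−ΔΔCt with amplification
efficiency fixed at 2 (efficiency-corrected variants are out of scope).
Averaging at the ΔCt level makes the calibrator's RQ exactly 1.
Per-replicate ΔCt values (replicate Ct minus the group's mean reference
Ct) are retained; group comparisons use Welch's t-test on them — a robust
default given only "statistical software" is typically reported. The
reference gene is a required input, never defaulted.

## Synthetic-data generator

The generator emulates the two-biological-replicate 4-plex design: tags
114/115 = one sample labelled twice, 116 and 117 = two further samples.
Per protein: base intensity ~ 2^N(16, 1.5²) (arbitrary units, Orbitrap-like
spread); exactly round(frac_de·n) proteins get a fold change 2^(±magnitude)
(default magnitude 2, i.e. 4-fold; signs 50/50) applied to the sample of
channel 116, so altered proteins are changed in every contrast against
116. Peptide counts follow a categorical {1,…,5,6+} distribution (default
17/11/7/6/5/54 %, the identification-depth shape of a deep 4-plex run;
the 6+ category adds a geometric tail, p = 0.3). Each peptide has a
lognormal ionisation efficiency (sd 0.5 log₂); each PSM multiplies the
true channel vector by i.i.d. 2^N(0, tech_noise_sd²) noise — additive
Gaussian on the log₂ scale, matching the near-normal log-ratio
distributions such experiments show — and is then mixed by the forward
impurity matrix. Shared peptides sum their parents' contributions, the
simplest physically motivated confound for testing the unique-peptide
rule. A single RNG keyed by `seed` drives all draws in documented order,
with technical replicates optionally redrawing only the PSM-noise stream
(modelling re-injection of one labelled pool — whether real technical
replicates share a labelling reaction is usually unstated, so this is a
switch, not an assumption).

What the generator does **not** emulate: real peptide sequences and their
chemistry (missed cleavages, modifications), retention time, spectral
interference/co-isolation, intensity-dependent variance, batch effects
between biological replicates, and missingness that correlates with
abundance. Passing recovery tests therefore demonstrates the estimators
are correct under the stated noise model, not that real data meet that
model.

## Problem sizes and numerical choices

Recovery suites use sizes chosen to make Monte-Carlo error small relative
to the tolerances while keeping the full suite fast: 2,000 proteins × 3
peptides for fold-change recovery, 5,000 proteins for σ recovery, 10,000
null proteins for calibration, 200 profiles for clustering. The
calibration check accepts 3 Monte-Carlo standard errors around the nominal
rate; percentile estimation in bins of 300 adds a small positive bias
(~+0.003 two-sided) that sits within that band. Percentiles use linear
interpolation; impurity solves go through LAPACK with a 1e-8 inverse
tolerance asserted in tests; TSV output uses `%.10g` floats so identical
runs are byte-identical.

## Known limitations

- Significance B assumes a Gaussian core for the null log-ratios; heavy
  tails inflate the robust width and cost power rather than type-I error.
- With two comparison dimensions, k = 5 Ward clusters are descriptive
  groupings, not model-selected structure; k is a user choice.
- Welch's t-test at triplicate scale is conservative (type-I ≈ 3.6 % at
  nominal 5 %); this is a property of the Satterthwaite approximation, not
  of the implementation.
- The DE boundary at exactly 0.5 is implemented as inclusive; sources that
  state "less than 0.5" differ by the measure-zero boundary only, and the
  cutoffs are configurable.
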