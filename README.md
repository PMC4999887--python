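# itraquant

A tested pipeline for 4-plex iTRAQ quantitative proteomics, from
peptide-spectrum-match (PSM) reporter-ion intensities to differentially
expressed protein lists — with replicate QC, expression-profile clustering
and a 2^−ΔΔCt qPCR cross-check. It targets the common oocyte-style study
design in which one biological sample (immature GV oocytes) is labelled in
duplicate with tags 114 and 115, competent matured (MII G) oocytes with tag
116, and incompetent matured (MII B) oocytes with tag 117, but every channel
assignment and comparison is configuration-driven.

Because raw MS data for such studies are rarely released, the package ships
a synthetic-data generator with known ground truth (true abundances, fold
changes, impurity mixing and noise), so that every downstream stage is
testable end to end with no download.

## What it computes

**Quantification.** PSMs are filtered (identification error ≤ 0.01 and a
complete set of four reporter ions), reporter cross-talk is removed by
solving `M·x = observed` with the manufacturer's 4×4 isotope-impurity matrix
`M`, peptide intensities are arithmetic means over PSMs, and a protein's
ratio for a comparison is

&nbsp;&nbsp;&nbsp;&nbsp;ratio(protein) = geomean over unique peptides of
geomean(numerator channels) / geomean(denominator channels).

**Significance B.** Proteins are sorted by total reporter intensity and
split into bins of ~300; within each bin the log₂-ratio distribution gives
a robust asymmetric z-score

&nbsp;&nbsp;&nbsp;&nbsp;z = (x − m)/r₊ if x ≥ m, else (m − x)/r₋,
with m = P50, r₊ = P84.13 − m, r₋ = m − P15.87,

and p = ½·erfc(z/√2), the Gaussian upper tail. Binning lets the null width
shrink with intensity, as reporter noise does.

**Differential expression.** A protein is up/down when ratio ≥ 2 (or
≤ 0.5), p < 0.05, and it has ≥ 2 unique peptides; both fold boundaries are
inclusive. The DE union across comparisons is clustered on its log₂-ratio
profiles (Ward linkage, Euclidean metric) into k = 5 expression groups.

**QC.** σ of the log₂ ratio between duplicate-labelled channels, Pearson R²
and OLS slope of their intensities, an equal-mixing box check of per-channel
median log ratios, and the cumulative %-variation curve
(|I_A − I_B| / mean · 100) used to justify the 2-fold cutoff.

**qPCR.** Livak 2^−ΔΔCt relative quantification with replicates averaged at
the ΔCt level (calibrator RQ ≡ 1) and Welch's t-test on replicate ΔCt.

## Worked example

```sh
cat > demo.yaml <<'EOF'
seed: 42
simulate:
  n_proteins: 1000
  frac_de: 0.1
  tech_noise_sd: 0.2
  peptides_per_protein_dist: [0, 0, 1, 0, 0, 0]   # 3 unique peptides each
  psms_per_peptide_dist: [1.0]
EOF
itraquant run --config demo.yaml --out demo_run
```

simulates 1,000 proteins (100 with a true 4-fold change in the MII G
channel), quantifies, scores and clusters them, and writes
`demo_run/report.md`:

```
| comparison   | up | down | total |
| MIIG_vs_GVO  | 55 |  45  |  100  |
| MIIG_vs_MIIB | 55 |  45  |  100  |

- sigma(log2 ratio) = 0.1654
- Pearson R^2 = 0.9746, slope = 0.9871
- fraction within 30% variation = 0.990

100 proteins clustered (cluster sizes 36, 19, 18, 15, 12)
```

All 100 truly changed proteins are recovered in each comparison with no
false positives: the per-protein log₂ ratio noise here is
0.2·√1.5/√3 ≈ 0.14, so a true |log₂FC| = 2 sits ~14 robust sigmas from the
bin median. The replicate σ = 0.165 is the noise floor implied by
tech_noise_sd = 0.2 per channel averaged over 3 peptides, and 99 % of
proteins fall within 30 % variation between the duplicate-labelled
channels.

Each stage is also a subcommand (`simulate`, `quantify`, `qc`, `stats`,
`diffexp`, `cluster`, `overlap`, `qpcr`, `report`) over the same library
functions (`itraquant <cmd> --help`).

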