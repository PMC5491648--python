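# Methods

This note documents the models and procedures saltphen implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical decisions taken where the published
formulas leave room.

## Assay formulas (`saltphen.assay`)

All calculators operate on single readings in full precision; replicate
aggregation happens in `saltphen.stats`, and rounding only in report writers
(2 decimals for assay tables, 3 for the tolerance index).

- **Total chlorophyll** (mg/g FW): 20.2·A645 + 8.02·A663 (DMSO extract,
  Arnon-type two-wavelength relation).
- **MDA / lipid peroxidation**: (A532 − A600)/coefficient. The printed
  denominator 1.56 × 10⁵ is the default, although the stated extinction
  coefficient of 155 mM⁻¹ cm⁻¹ implies 1.55 × 10⁵; the coefficient is a
  keyword argument so either convention can be used. The output is labelled
  "formula units": with a molar extinction coefficient the quotient is a
  molar concentration (mol/L of extract), not the nM sometimes quoted for
  this assay, and the implementation does not guess which the user wants.
- **Membrane stability index**: 100·(1 − EC1/EC2). EC1 > EC2 is physically
  suspect and flagged (`leakage_exceeds_total`) but not fatal, to let users
  inspect raw data; EC2 = 0 is an error naming the autoclaved set.
- **Proline** (µM/g DW): ((µg/mL × mL toluene)/115.5)/(g sample/5).
- **Standard curves** (soluble sugar via anthrone at A630, total phenolics as
  gallic-acid equivalents at A760): ordinary least squares of absorbance on
  concentration **with an intercept** — the protocol does not state a
  through-origin fit, and a free intercept is the safer general model.
  Interpolation inverts the line; a zero slope is an error. Whether a glucose
  or a starch curve is used per tissue is a user choice; the fit is agnostic.
- **DPPH scavenging**: 100·(A0 − A1)/A0. **IC50** is the linear interpolation
  between the two sampled points bracketing 50 % scavenging; if no sampled
  point brackets 50 % the result is `None` (flagged, never extrapolated).
  No four-parameter logistic is fitted — the assay description only supports
  a determination from the sampled curve.
- **Percent change**: 100·(control − treated)/control, so stress-induced
  *decreases are positive* (matching how the morphology table prints them);
  increases are reported as negative values.

## Tolerance index (`saltphen.tolerance`)

Relative value = 100 · treated mean / control mean, per indicator and
genotype. Each indicator column is min–max standardized across genotypes with
a polarity; the composite score is the unweighted mean over indicators and
ranking is descending (ties share the lower rank number and carry a `tied`
flag).

Design choices:

- **Polarity is configuration, not hard-coded.** The shipped defaults mark
  dry weights, osmolytes, phenolics, antioxidant activity and chlorophyll as
  positive, lipid peroxidation and the Na⁺/K⁺ ratio as negative. Note the
  source material is internally inconsistent here: its prose groups dry
  weight and chlorophyll with the negatively correlated indicators, yet its
  standardized table awards the tolerant genotype (least reduction, highest
  relative value) a standardized value of 1 for those rows — which is only
  consistent with positive polarity. The defaults follow the table; users
  who prefer the prose grouping can override the polarity map.
- A **constant column** (all genotypes equal) leaves (X − Xmin)/(Xmax − Xmin)
  undefined and raises an error naming the indicator rather than imputing an
  arbitrary 0.5.
- The indicator count is not fixed at 15; the mean generalizes to any
  configured set.
- No weighting, PCA or cluster-based indices — only the min–max composite.

## Group statistics (`saltphen.stats`)

- **One-way ANOVA** by the standard between/within decomposition; p from
  F(k−1, N−k).
- **Fisher's LSD**: LSD_ij = t(1 − α/2, df_within)·√(MSE·(1/n_i + 1/n_j)),
  significant iff |mean_i − mean_j| > LSD_ij. Whether the original analyses
  gated LSD on a significant omnibus F is not stated; the default is the
  **protected** test (gate at α) with `protected=False` available. For two
  groups the distinction is moot (F = t²), which is also why the two-group
  LSD decision coincides exactly with a pooled-variance t-test. Unequal n is
  handled by the 1/n_i + 1/n_j form, although the design this supports is
  balanced (3 replicates).
- **Compact letter display** uses the insert-and-absorb algorithm: start from
  one all-inclusive letter column, split it on every significant pair, absorb
  subset columns, and letter the surviving columns in order of their
  highest-ranking (largest-mean) member. The defining property — two levels
  share a letter iff not significantly different — is exhaustively tested.
- **Fisher's exact test** (two-sided) sums hypergeometric probabilities of
  all tables (margins fixed) no more probable than the observed one, with a
  1 + 1e-7 relative guard on pmf ties; a degenerate margin gives p = 1. The
  enumeration uses `scipy.stats.hypergeom` pmf values; tests cross-check it
  against exact rational enumeration and against `scipy.stats.fisher_exact`.

## Bisulfite methylation analysis (`saltphen.methylome`)

Scope: Sanger-scale clonal amplicon data (~10 clones/sample), not short-read
bisulfite mapping.

- **Alignment**: global affine-gap alignment (Gotoh; match +1, mismatch −1,
  gap open −2, gap extend −1, a run of k gaps costing open + (k−1)·extend)
  computed on C→T-collapsed copies of both sequences, so bisulfite conversion
  is never penalized; original bases are restored afterwards. Traceback
  tie-breaking is deterministic: diagonal, then up, then left. Clones whose
  collapsed identity falls below 80 % (configurable) are rejected with a
  warning. Clones whose collapsed sequence equals the collapsed reference
  (the common indel-free case) take a direct gapless path.
- **Strand**: only top-strand reference cytosines are analyzed; clones are
  assumed to read the converted top strand, as in a PCR-clone design.
- **Calls**: at a reference-C column, clone C → methylated, T → unmethylated,
  anything else (gap, A, G, N) → ambiguous and excluded from totals. Context
  (CG / CHG / CHH, H ∈ {A, C, T}) is a pure function of the reference; a
  cytosine with fewer than two downstream bases or an N in the lookahead is
  `unknown`.
- **Summaries**: per-context percent = 100·m/(m+u); a context with zero
  informative calls is reported as missing, not 0 %.
- **DMRs**: windows [k·step, k·step + window) anchored at the region start
  (defaults 100/50), trailing short windows tested when informative; counts
  pooled across clones and contexts (per-context testing available via the
  `contexts` argument); two-sided Fisher exact; flagged iff p ≤ 0.05 (raw
  p-values, matching the windowed-test convention; no FDR by default);
  direction = sign of the methylation-fraction difference A − B. Windows
  without informative calls in either sample are skipped with a log entry.
  Overlapping significant windows are reported individually. Coordinates are
  0-based half-open internally and in the BED-style TSV output.
- **No conversion-efficiency correction** is applied by default; the
  generator can simulate incomplete conversion to study its bias.

Because the exact test is conservative at these call counts (≈250 informative
calls per window per sample with 10 clones), the realized null flagging rate
sits below the nominal 5 % (≈3–4 % in the shipped calibration); the
calibration asserts the rate never exceeds 7 %.

## qPCR and variants (`saltphen.molecular`)

- **ΔΔCt** with amplification efficiency fixed at 2 (no efficiency
  correction, as none is specified for the supported workflow): technical
  replicates averaged per biological replicate; ΔCt = Ct(target) −
  Ct(reference) per biological replicate; ΔΔCt = mean ΔCt(treated) − mean
  ΔCt(control); ratio = 2^(−ΔΔCt). Downregulation is reported as a fold
  *decrease* (reported_fold = 1/ratio ≥ 1, direction "down"); the signed
  ratio is always retained. The SD of per-replicate ΔΔCt (treated replicates
  against the control mean) is propagated as a fold range.
- **Mutation classification** on pre-aligned pairs: transitions are
  purine↔purine or pyrimidine↔pyrimidine substitutions, the rest
  transversions; a maximal contiguous gap run in the second sequence is one
  deletion event (runs in the first are insertion events, so the summary is
  swap-symmetric); N columns are excluded; IUPAC codes other than N are
  rejected (Sanger-cloned CDS should not contain them). Note that
  substitution/indel counts between two real accessions are sensitive to the
  aligner and its gap parameters; this module deliberately takes the
  alignment as input.
- **Translation** uses the standard genetic code (Biopython) with trailing
  partial codons dropped; **motif scanning** reports all exact, possibly
  overlapping occurrences (defaults: the HKT1 selectivity filter SGGG and the
  membrane-anchoring GR dipeptide).

## Synthetic data (`saltphen.simulate`)

Every generator is a deterministic function of (config, seed); the root seed
is split into fixed per-generator child streams so adding a generator never
perturbs existing draws.

- **Assay generator**: 4 genotypes × 2 treatments × 3 replicates per tissue
  indicator; value = control_mean × effect multiplier (1 under control) +
  Gaussian noise. Default effect multipliers encode the reported contrasts
  (56–78 % shoot dry-matter reduction, 20–28 % root; up to 60 % MDA increase
  in the sensitive genotype; 120–166 % shoot proline increase; ~35 % maximum
  phenolics increase; larger Na⁺/K⁺ inflation in sensitive genotypes), with
  tolerance ordering Kharchia-65 > KRL-210 > WH-542 > HD-2329. The default
  noise SD is 5 % of the control mean — typical bench-replicate scatter.
- **Reference generator**: i.i.d. bases at a target GC fraction (default
  0.45, a plant-exon-like value); sequences ≥ 50 bp are redrawn until all
  three cytosine contexts occur.
- **Clone generator**: Bernoulli per-cytosine methylation with per-context
  probabilities; unmethylated cytosines convert C→T with the configured
  conversion efficiency (default 1.0 — no correction is applied downstream,
  so the default keeps generation and analysis consistent); methylated
  cytosines stay C. No sequencing errors or indels are simulated, so the
  aligner's indel path is exercised by dedicated tests rather than by the
  generator.
- **Ct generator**: fixed reference-gene Ct (20) and control target Ct (26);
  the treated target Ct is offset by −log₂(ratio) so the ΔΔCt analysis is the
  generator's exact inverse at zero noise. Default ratios encode the reported
  shoot fold changes of the two HKT2 transporters (down 4.05/3.21 and
  8.05/6.52 in the tolerant genotypes, up 4.52/6.05 and 8.51/10.30 in the
  sensitive ones).

**What passing tests do and do not show.** The generators produce Gaussian
measurement noise, exchangeable replicates, indel-free clones and
context-homogeneous methylation within a sample. Real data add instrument
drift, heteroscedastic and occasionally heavy-tailed noise, clone-to-clone
conversion variability, positional methylation structure, and alignment
artefacts — so green tests validate the *computational* pipeline
(correctness, calibration, invertibility), not robustness to every
real-world failure mode.

## Pipeline (`saltphen.pipeline`, `saltphen.cli`)

Configuration is YAML (JSON accepted); defaults match the supported study
conditions (window 100, step 50, α 0.05, 3 replicates, 10 clones). All input
files are schema-validated up front with all violations collected before any
computation. Stages run in dependency order and are independently skippable,
so a partial config yields a partial report. Reports carry a provenance block
(package version, config hash, seed) and contain no timestamps, making
re-runs byte-identical. Numbers are rounded only at render time (TSVs at 2–3
decimals); `report.json` keeps full precision.

## Problem sizes in the shipped checks

The calibration and recovery checks use: 1000 random 2×2 tables (totals
≤ 30) for the exact-test comparison; 500 Monte-Carlo replicates of 10 + 10
clones on a 200-bp reference for the DMR null rate; 200 clones on a 300-bp
reference for methylation-level recovery (±2 percentage points) and 20 + 20
clones for the contrast-detection check; 200 random two-group instances for
the LSD/t-test equivalence. These sizes give comfortable Monte-Carlo margins
for the asserted tolerances while keeping the default suite quick.

## Known limitations

- No FASTQ/BAM support, no multiple-sequence alignment, no 4PL dose–response
  fits, no qPCR efficiency estimation from dilution series, no homology
  modeling or domain-database scans.
- The MDA unit ambiguity (see above) is surfaced, not resolved.
- LSD is per-comparison; no familywise correction beyond the optional
  ANOVA gate.
- The composite index inherits min–max standardization's sensitivity to the
  genotype panel: adding or removing a genotype rescales every column.
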