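# Methods

`ebcquant` implements the quantitative machinery of a two-condition
(control vs salt-treated) single-cell-type experiment on epidermal
bladder cells of a halophyte: label-free spectral-count proteomics,
2D-DIGE spot statistics with a pooled internal standard, and ICP-MS
ionomics. This note records the models, conventions and numerical
choices, and what the synthetic-data generator does and does not
emulate.

## Spectral-count quantification

A peptide-spectrum-match (PSM) table — one row per identified tandem-MS
spectrum with its peptide sequence and candidate protein accessions —
is summarised into four per-protein abundance indices per sample:

* **TSC** (total spectral count): every candidate protein of a spectrum
  is incremented, so shared peptides are counted multiply.
* **WSC** (weighted spectral count): each spectrum is assigned to
  exactly one candidate — the protein with the most experiment-wide
  spectra from peptides unique to it; ties go to the lexicographically
  smaller accession. WSC therefore conserves the total spectrum count
  of a sample.
* **emPAI** = `10^(N_observed/N_observable) − 1`, where `N_observable`
  is the number of distinct tryptic peptides of the protein whose m/z
  `(M + z·1.007276)/z` falls inside the instrument full-scan window
  (default 300–1800 m/z) for at least one charge in {1, 2, 3}, using
  monoisotopic masses; `N_observed` counts the distinct observable
  peptides identified in that sample (per replicate, not pooled — a
  config flag pools per condition instead).
* **NSAF** `= (SpC_i/L_i) / Σ_j (SpC_j/L_j)` over the proteins of a
  sample, with `SpC` the unweighted count and `L` the sequence length;
  NSAF columns sum to 1 whenever the sample has any spectra.

Tryptic digestion cleaves C-terminal to K/R except before proline, with
0 missed cleavages by default (configurable); a peptide is *unique* when
it is a tryptic fragment of exactly one database protein.

### Filtering and consensus calling

Proteins enter testing only when detected (unweighted counts) in every
replicate of at least one condition and supported by ≥ 2 unique
peptides across the experiment. Each retained protein is tested per
index with a two-sample, two-tailed, equal-variance Student's t-test on
the raw index values (no multiple-testing correction is applied — the
consensus requirement across indices is the only guard against false
positives, and this is deliberate and should be kept in mind when
interpreting single-index calls). Flags are `**` (p ≤ 0.01), `*`
(p ≤ 0.05), `NS`. Fold change is mean(salt)/mean(control) on the
signed scale (decreases as negative reciprocals, so |FC| ≥ 1); a
protein *meets the criteria* on an index when flagged and finite
|FC| > 2. The consensus tier (0–4) counts the indices met; proteins
with tier ≥ 1 form the reported salt-responsive set.

Condition-exclusive proteins (zero counts in every replicate of one
condition, complete presence in the other) bypass the t-test — their
variance structure is undefined — and are reported with the `INF`
(salt-only) or `ZERO` (control-only) token rather than an arbitrary
numeric fold change; they meet the criteria on every index with
nonzero signal in the present condition.

Degenerate t-tests (zero variance in both groups) are resolved by
convention: equal means → p = 1, unequal means → p = 0.

## DIGE spot statistics

Each gel carries three dye channels: the pooled internal standard (Cy2)
plus one control and one salt sample, with the Cy3/Cy5 assignment
swapped between gels so dye bias cancels in the condition means.
The standardised abundance of a spot is its volume divided by the
same-gel standard-channel volume — this cancels gel-to-gel
multiplicative effects exactly — and log10 of it is the tested
quantity. Spots must be present in all 3 × n_gels spot maps (12/12 for
the default 4-gel design) and must not carry an overlap flag (overlap
detection is image-analysis metadata, out of scope here). Retained
spots get a two-sample equal-variance t-test on the log standardised
abundance (significance at p ≤ 0.03) and a signed average ratio of the
unlogged standardised abundances, salt relative to control. No
additional median-centring of the ratio distribution is applied.

## Ionomics

The element table holds 27 major and trace elements (mg/L) for 6
replicates per condition. The workflow:

1. **Outlier screen**: a single pass removes values more than 3 SD from
   the element mean (strict inequality), with mean and SD pooled over
   all 12 samples; per-condition screening is available by config. The
   screen is deliberately not iterated — values that would only exceed
   the threshold after the first removal survive. Note that with 12
   samples the largest attainable z-score is (n−1)/√n ≈ 3.18, so the
   3-SD rule can flag at most one gross outlier per element per pass.
2. **Per-element one-way ANOVA** (control vs salt) with `**`/`*`/`NS`
   flags at 0.01/0.05 and signed fold changes. With two groups F = t²,
   and the implementation asserts agreement with the equal-variance
   t-test to 1e-9 as a self-check. Box summaries (median, mean, IQR,
   5th/95th percentiles, extremes) use linear-interpolation
   percentiles so they are exactly reproducible.
3. **PCA on the correlation matrix**: elements are standardised to zero
   mean and unit variance (SD with ddof = 1) so concentrations spanning
   seven orders of magnitude contribute equally; components are
   eigenvectors of the correlation matrix in decreasing eigenvalue
   order, variance explained is eigenvalue/Σ × 100. Eigenvector signs
   are arbitrary, so each loading vector is flipped to make its
   largest-magnitude entry positive — score plots are then
   bit-reproducible. Elements with zero variance, or left incomplete
   by the outlier screen, are excluded and logged.
4. **Diagnostic ratios** per condition: Na/K, the Na+K total, and
   Cl/(Na+K), the panel used to characterise chloride versus cation
   accumulation.

## Synthetic data

The generator provides ground-truth inputs shaped like the study design:
2 × 3 PSM samples over a few hundred proteins, a 4-gel DIGE layout, and
a 2 × 6 × 27 ionomics table.

* **Proteins** are concatenations of random tryptic building blocks
  (6–24 residues, ending K/R, no internal cleavage sites, no leading
  proline), so digestion returns exactly the building blocks and every
  emitted peptide is a true tryptic fragment of all its listed parents.
  A configured fraction of building blocks is copied into a second
  protein to create genuinely shared peptides. Sharing is restricted
  to background proteins: a planted fold change must remain
  identifiable from expected counts (spectra shared with a flat
  partner would pull the observable ratio toward 1 and no noise-free
  limit could reproduce the truth).
* **Counts** are negative binomial with var = μ + αμ² (Poisson at
  α = 0, default α = 0.05), with expected counts proportional to
  abundance × observable peptides; the proportionality constant is
  fixed on the control condition, so a planted protein's expected
  salt/control ratio equals its true fold change exactly. Abundances
  are log-normal (σ = 1), giving a realistic ~2-decade dynamic range.
* **DIGE volumes** are true abundance × gel effect × dye effect ×
  log-normal noise on the experimental channels. The pooled standard is
  the equal-weight mean of all samples' true values and its channel is
  generated without a stochastic term: noise on a channel shared by
  both same-gel samples would positively correlate the two conditions
  and make the unpaired spot t-test conservative by construction.
  Consequently all measurement variance is attributed to the
  experimental channels.
* **Element concentrations** are baseline × treatment multiplier ×
  log-normal noise (σ_ln = 0.2, a ~20 % CV typical of ICP-MS biological
  replicates). The default profile puts the major ions at the study's
  control means and plants its headline effects (Na ×21, Cl ×5.7,
  K ÷4.5, S ÷4, Mn/P/V/Zn up, Mg/Co down); trace elements sit below
  0.05 mg/L so the table spans ~7 orders of magnitude. Optional gross
  outliers (×20) can be injected into named elements to exercise the
  3-SD screen.

All four generators draw from independent streams derived from one
master seed, so outputs are bit-identical across runs and platforms.

What the generator does **not** emulate: raw spectra or search-engine
behaviour (identification error, modified peptides, chimeric spectra),
gel-image artefacts beyond a boolean overlap flag, saturation or
detection limits in either assay, and replicate-level variance
heterogeneity. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the stated noise models,
not robustness to the full messiness of real acquisitions.

## Calibration and recovery experiments

The reproducibility script and the slower tests run four simulation
studies (sizes chosen to keep a full run to a few minutes on one CPU):

* **Spectral null calibration** — 500 null experiments (40 proteins,
  depth 2000, no planted effects); the fraction of retained proteins
  flagged at α = 0.05 should sit within 0.05 ± 0.02.
* **DIGE null calibration** — 500 null experiments (60 spots, log-noise
  0.1, dye effects set to 1 — the dye bias is a systematic term the
  balanced swap cancels in the condition means, not sampling noise);
  spot significance at α = 0.03 should sit within 0.03 ± 0.015.
* **Fold-change recovery** — 6 experiments with planted effects
  {4× 8, 8× 7}, dispersion 0.001 and depth 4 × 10⁴ spectra/sample, a
  depth at which even the least abundant planted proteins accumulate
  enough control spectra that the ±25 % accuracy band reflects the
  estimator rather than Poisson shot noise. Measured: ≥ 95 % of
  planted proteins reach consensus tier ≥ 2 and estimate their ratio
  within ±25 %.
* **Ionomics structure recovery** — 50 seeds of the default profile;
  all ten planted elements must be flagged with the planted direction,
  and PC1 scores of control and salt samples must not overlap.

## Known limitations

* No multiple-testing correction anywhere; reported p-values are raw.
* WSC's "most evidence" metric (unique-peptide spectra, experiment-wide)
  is one of several defensible choices; no parsimony-based protein
  grouping is performed.
* TSC/NSAF fold changes of proteins that share peptides across
  differentially abundant partners are biased toward unity; only the
  synthetic generator guarantees planted proteins are free of this.
* The DIGE model omits CyDye preferential-labelling correction beyond
  the swap, and the ionomics model omits instrument drift,
  interferences and detection-limit censoring.
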