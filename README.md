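# ebcquant

Quantitative pipelines for two-condition, single-cell-type salt-stress
omics: label-free spectral-count proteomics, 2D-DIGE spot statistics
with a pooled internal standard, and ICP-MS ionomics — plus a
ground-truth synthetic-data generator so every stage can be exercised
and calibrated without any external download.

The motivating system is the epidermal bladder cell (EBC) of halophyte
plants: a giant single-celled trichome that accumulates ions under salt
stress. Extracts of such cells are profiled three ways — peptide
spectrum matches from GeLC-MS/MS, spot volumes from DIGE gels, and
27-element concentration tables from ICP-MS — and each assay needs its
own differential statistics. `ebcquant` is aimed at analysts who have
those post-identification tables in hand and want a reproducible,
tested implementation of the downstream quantification.

## What it computes

**Spectral counting.** Four abundance indices per protein and sample:

* TSC — total (unweighted) spectral counts; shared spectra count for
  every candidate protein;
* WSC — weighted counts; each spectrum is assigned to the single
  candidate with the most unique-peptide evidence (ΣWSC = #spectra);
* emPAI = 10^(N_observed/N_observable) − 1, with observability defined
  by monoisotopic m/z in the 300–1800 scan window at charges 1–3;
* NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j).

Proteins detected in every replicate of at least one condition with
≥ 2 unique peptides are tested per index (equal-variance Student's
t-test, flags `**`/`*`/`NS` at p ≤ 0.01/0.05) and gated on signed fold
change |FC| > 2; the consensus tier (0–4) counts how many indices
agree. Condition-exclusive proteins are reported as INF/ZERO rather
than given an arbitrary ratio.

**DIGE.** Spot volumes are standardised against the same-gel pooled
internal standard (Cy2), log10-transformed and t-tested (p ≤ 0.03)
after a strict all-maps matching filter (12/12 for four gels) and an
overlap screen; ratios are reported on the signed scale.

**Ionomics.** Single-pass >3 SD outlier removal, one-way ANOVA per
element (F = t² is asserted for the two-group design), box-plot
summaries, PCA of the correlation matrix with deterministic sign
convention, and the Na/K and Cl/(Na+K) diagnostic ratios.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Generate a synthetic experiment (300 proteins with thirty planted
fold changes of 4× and 8×, six condition-exclusive proteins, a 4-gel
DIGE design with seven planted spot ratios, and the default ion
profile), then run all three pipelines:

```bash
ebcquant simulate --seed 7 --out inputs
ebcquant run --inputs inputs --out reports
```

which prints:

```text
wrote synthetic inputs to inputs
47 salt-responsive proteins (tier >= 1); reports in reports/spectral
7 significant spots of 110 retained; reports in reports/dige
significant elements: Cl, Co, Mg, Mn, P, K, Na, S, V, Zn; reports in reports/ionomics
evaluation written to reports/evaluation.json
pipeline complete; stages: {'spectral': 'ok', 'dige': 'ok', 'ionomics': 'ok', 'evaluate': 'ok'}
```

The 47 tier ≥ 1 proteins include all 30 planted effects, the 6
exclusive proteins, and 16 tier-1 false positives — single-index calls
carry no multiple-testing correction, which is why the consensus tier
matters; `reports/evaluation.json` quantifies this against the planted
truth (at tier ≥ 2 the same seed gives 31 true and 4 false positives).
The ten significant elements are exactly the ten planted ones, and
`reports/ionomics/element_ratios.tsv` shows the diagnostic panel, e.g.
Na/K rising from 0.085 (control) to 7.22 (salt) for this seed:

```text
        Na_K      Na_plus_K  Cl_over_NaK
control 0.0848    7949.4     0.408
salt    7.2206    14425.8    1.060
```

Each stage is also exposed separately (`ebcquant quant-spectral`,
`ebcquant quant-dige`, `ebcquant ionomics`, `ebcquant evaluate`) and as
a plain Python API (`ebcquant.spectral.spectral_workflow`,
`ebcquant.dige.dige_workflow`, `ebcquant.ionomics.ionomics_workflow`).

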