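# fragbench

A toolkit for evaluating MS/MS fragment-intensity predictions against
experimental spectra. It annotates singly- and doubly-charged b/y fragment
intensities from MGF spectra, computes per-PSM similarity (Pearson
correlation, normalized angle) between predicted and experimental intensity
vectors, builds precursor-weighted binned similarity distributions (bin
width 0.001), compares them against an experimental-reproducibility
reference distribution via quantiles and the W1 (Wasserstein) distance, and
ranks prediction methods overall and stratified by charge, peptide length,
collision energy, and PTM status.

A seedable synthetic-data module generates ground-truth fragmentation
profiles, noisy replicate spectra (multiplicative intensity noise, peak
dropout, m/z jitter within instrument tolerance), and simulated predictors
of controlled accuracy, so the whole pipeline is testable offline.

## Command line

```sh
# generate a synthetic bundle (spectra.mgf, psms.tsv, precursors.tsv,
# predictions_<method>.tsv, truth.json)
fragbench simulate --seed 42 --n-precursors 500 --out-dir bundle/

# annotate spectra with b/y intensities (20 ppm FTMS / 0.5 Da ITMS defaults)
fragbench annotate --mgf bundle/spectra.mgf --psms bundle/psms.tsv \
    --precursors bundle/precursors.tsv --out-dir annotated/

# score predictions, build distributions, rank methods
fragbench evaluate --store annotated/annotated.tsv \
    --predictions methodA=bundle/predictions_methodA.tsv \
    --predictions methodB=bundle/predictions_methodB.tsv \
    --metric both --stratify-by charge --out-dir results/

# pretty-print a summary
fragbench report --summary results/summary.json
```

`simulate` accepts a YAML config (`--config`) covering cohort size, length
range, charge and replicate-count distributions, Dirichlet concentration of
the true profiles, replicate noise CV, dropout probability, m/z jitter, and
per-method predictor noise CVs.

Exit codes: 0 success, 1 usage/configuration error, 2 data error.

## File formats

- **Spectra**: MGF; scan numbers from `SCANS=` or a `scan=<n>` token in
  `TITLE` (the source-file name is taken from the first TITLE token when
  present).
- **PSM table**: TSV with columns `raw_file, scan, sequence, modifications,
  charge` (MaxQuant msms.txt headers are accepted). Modifications are
  `pos:Name` tokens separated by `;`, e.g. `5:Oxidation (M)`; only
  methionine oxidation and cysteine carbamidomethylation are supported,
  and rows with other PTMs or U/O residues are routed to an exclusion list.
- **Precursor table**: TSV with `sequence, charge, nce, instrument,
  dissociation (HCD|CID), mass_analyzer (FTMS|ITMS)`.
- **Prediction table**: long-format TSV with `sequence, charge, series,
  ordinal, fragment_charge, intensity`; absent fragments are zero-filled.
- Modified sequences use inline tags: `AM[Oxidation]K`.

Every intensity vector uses one canonical layout: b1..b(N−1), y1..y(N−1)
at charge 1, then the same blocks at charge 2.

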