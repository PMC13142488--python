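# dialion

Ion-level quantification for data-independent acquisition (DIA) proteomics.

DIA instruments co-fragment all precursors in wide isolation windows, so a
peptide's signal is present in every run whether or not the identification
software reported it there. `dialion` exploits this: starting from an
upstream identification report and a spectral library, it re-extracts each
precursor's ion signals directly from the raw spectra in **every** run —
MS1 chromatograms for the monoisotopic peak and its predicted isotope peaks,
MS2 chromatograms for the top six library fragments — infers the remaining
missing ion intensities from condition-local neighborhoods, and summarizes
to complete precursor- and protein-level quantification matrices. A
synthetic two-proteome experiment generator and a benchmarking module
(differential-abundance FDR, partial AUC, CV and fold-change-error profiles
against species ground truth) make every stage testable without any raw
data download.

## The method in brief

- **Coordinate transfer.** Per run and axis (retention time, and ion
  mobility when present), a monotone piecewise cubic spline maps library
  iRT to observed coordinates, fitted on low-variability anchor precursors
  seen in ≥ 3 runs; precursors lacking an observation in a run get
  predicted coordinates.
- **Observable isotope envelope.** The number of heavy-isotope
  substitutions for a peptide of monoisotopic mass *m* is modeled as
  Poisson with λ = 0.00052 · *m* (averagine approximation); peaks with
  pmf ≥ 10 % of the envelope mode, from M+0 upward, are extracted at
  spacing 1.0033548 / z.
- **XIC engine.** Traces are extracted at 15 ppm within ±1 min of the
  (observed or predicted) RT. One representative elution profile per
  precursor-run is chosen by a weighted composite of peer correlation,
  Gaussian shape with apex balance, and integrated intensity; its apex and
  FWHM define the quantification window [apex − FWHM, apex + FWHM]. Each
  ion is integrated there after truncating interference against the scaled
  representative profile, and receives a correlation-based quality score.
- **LION inference.** Low-quality or zero entries are treated as missing;
  ions missing in more than half the runs are excluded; every remaining
  missing entry is filled with `scale ×` the minimum observed intensity of
  that ion among runs of the same biological condition (default scale 1.0).
  MS1 and MS2 vectors are processed separately.
- **Median summarization.** Ion vectors are log2-transformed, row-centered,
  and per-run medians rescaled by the mean abundance of the three most
  abundant ions give precursor quantities; proteins are summarized the same
  way over precursor vectors (MS1-only, MS2-only, or integrated), falling
  back to the highest-quality precursor when fewer than three contribute.
- **Benchmarking.** On two-proteome mixtures (human unchanged, yeast up,
  E. coli down) the package computes a limma-style moderated t-test
  (re-implemented, BH-adjusted), classifies differentially abundant
  proteins at |log2FC| > 0.5 and adjusted P < 0.05, and reports
  daFDR = FP/(FP + TP), partial AUC at FPR ≤ 0.1, CV profiles and
  fold-change errors.

## Worked example

```bash
# generate a ground-truthed synthetic two-condition experiment
dialion synth --out exp --seed 3 --n-human 6 --n-yeast 3 --n-ecoli 3

# quantify it end to end
dialion quantify --report exp/report.tsv --library exp/library.tsv \
    --spectra-dir exp/spectra --metadata exp/metadata.tsv \
    --out results --mode integrated

# score all three summarization modes against the ground truth
dialion benchmark --report exp/report.tsv --library exp/library.tsv \
    --spectra-dir exp/spectra --metadata exp/metadata.tsv \
    --truth-dir exp/truth --out results
```

The benchmark command prints one row per summarization mode, e.g.

```
      mode  TP  FP  TN  FN    daFDR      TPR     pAUC  median_CV_pct  median_fc_error
       ms1   6   0   6   0 0.000000 1.000000 0.100000       9.265873         0.076854
       ms2   5   1   5   1 0.166667 0.833333 0.083333       4.617525         0.061585
integrated   6   0   6   0 0.000000 1.000000 0.100000       4.186228         0.061070
```

In MS1-only and integrated modes all six spiked proteins (yeast up 2×,
E. coli down 4×) are recovered with no false positives (daFDR 0) and a
perfect ROC within FPR ≤ 0.1 (pAUC 0.1, its maximum); at this toy scale of
twelve proteins a single misclassified protein moves the MS2-only rates by
1/6. Replicate CVs are a few percent and the median
|observed − expected| log2 fold change is ≈ 0.06–0.08, tightest in the
integrated mode. `results/` also contains
`protein_matrix.tsv` (no empty cells), `precursor_matrix.tsv`, and
`manifest.json` recording the config hash and the fractions of inferred
coordinates and ion intensities.

The same workflow runs on real data: point `--report` at a DIA-NN-style
main report (a thin column-name mapping is applied), `--library` at a
tab-separated spectral library, and `--spectra-dir` at per-run mzML files
with `--spectra-format mzml`.

## File formats

Spectra are read from mzML or from the internal plain-text scan table used
by the synthetic generator: one tab-separated row per scan with columns
`ms_level, rt, im, isolation_low, isolation_high, mz_array,
intensity_array`, the two array fields comma-separated; the run identity is
the file stem. Identification reports, libraries, sample metadata and
output matrices are tab-separated with missing cells rendered as empty
fields (never 0), as documented in `dialion/io.py`.

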