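# msidiscrim

Discrimination of cancerous vs. normal tissue regions in MALDI mass
spectrometry imaging (MSI) data, in two molecular domains (tryptic
peptides, lipids). The package implements a complete analysis pipeline
and a synthetic phantom generator with planted ground truth, so every
stage is testable without real tissue data.

## Pipeline stages

| Module | What it does |
| --- | --- |
| `msidiscrim.io_core` | Data model; imzML (minimal continuous-mode reader/writer) and plain-text spectra; TSV ROI masks, feature tables, candidate mass lists |
| `msidiscrim.synthetic_data` | Phantom images: region maps, component libraries with target robust effect sizes and isotope-like right-side satellites, spectrum rendering with baseline/jitter/TIC corruption and outlier pixels |
| `msidiscrim.preprocessing` | Resampling, adaptive (morphological) baseline correction, TIC-based outlier screening with a generalized-boxplot criterion, FFT alignment to the average spectrum, TIC normalization |
| `msidiscrim.gmm_features` | Gaussian mixture modelling of the average spectrum (per-region EM with BIC sweep), variance/amplitude filtering, right-skew satellite merging, abundance quantification by component-density inner products |
| `msidiscrim.segmentation` | Divisive 2-means segmentation with 1 %-size and dip-test unimodality stopping; cluster summaries |
| `msidiscrim.comparative_stats` | CVs, Lilliefors/F screens, Mann-Whitney U with Benjamini-Hochberg control, robust Cohen's d (trimmed means / pooled Winsorized SD), effect categories, similarity-index curves |
| `msidiscrim.classification` | Multiple random validation (stratified 50/50, downsampling), forward stepwise BIC logistic regression, feature scoring/ranking, knee-rule signature sizing, validation metrics, probability maps, signature correlations |
| `msidiscrim.annotation` | Peptide matching at ±0.05 % relative tolerance; lipid matching with H/Na/K adducts at ±0.5 Da; lowest-delta best hits |

The Hartigan dip statistic is implemented in `msidiscrim._dip` (validated
in the tests against an exact linear-programming oracle); its null
quantile table is frozen in `_dip_table.py` and regenerable with
`python scripts/make_dip_table.py`.

## CLI

```sh
# generate a phantom dataset (imzML + ROI TSV + truth JSON)
msidiscrim synth --shape 40x40 --domain peptide --n-components 300 --seed 7 --out phantom/

# preprocess: resample -> baseline -> outliers -> align -> TIC normalize
msidiscrim preprocess --in phantom/phantom.imzml --out prep.imzml --report report.json

# GMM features
msidiscrim features --in prep.imzml --out features.tsv --model gmm.json

# unsupervised segmentation
msidiscrim segment --features features.tsv --min-frac 0.01 --seed 7 --out seg.tsv

# cancer-vs-epithelium statistics
msidiscrim stats --features features.tsv --roi phantom/roi.tsv --out effects.tsv

# classifier training and validation
msidiscrim classify train --features features.tsv --roi phantom/roi.tsv --iters 50 --seed 7 --out model.json
msidiscrim classify validate --model model.json --features val.tsv --roi val_roi.tsv --out metrics.json

# mass annotation
msidiscrim annotate --components effects.tsv --peptides pep.tsv --lipids lip.tsv --out annot.tsv
```

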