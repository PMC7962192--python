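# prednts

Prediction of nitrotyrosine sites in proteins from sequence alone.

Tyrosine nitration is a post-translational modification produced by reactive
nitrogen species (e.g. peroxynitrite); identifying which tyrosines of a
protein are nitration targets is a prerequisite for studying the function of
nitrated proteins, and experimental mapping is slow and expensive. `prednts`
implements a sequence-based classifier for this problem: every tyrosine (Y)
is represented by a window of 2w + 1 residues centred on it (default w = 20,
window length 41, `-`-padded at the protein termini), and the window is
scored by an ensemble of four random forests, one per feature encoding.

## Model

For a window x the score is a convex fusion of per-encoding forest
probabilities

    s(x) = Σ_e  λ_e · P_e(y = 1 | φ_e(x)),   λ_e ≥ 0,  Σ_e λ_e = 1

over four encodings φ_e:

| encoding | features | dimension (w = 20) |
|----------|----------|--------------------|
| binary   | per-position one-hot over 20 amino acids + gap | 41 × 21 = 861 |
| AAindex  | per-position physicochemical property values (15 indices, z-scored) | 41 × 15 = 615 |
| CKSAAP   | composition of k-spaced amino-acid pairs, k = 0…4 | 5 × 400 = 2000 |
| K-mer    | contiguous K-letter word composition, K = 1, 2, 3 | 20 + 400 + 8000 = 8420 |

Before training, each encoding optionally passes through recursive feature
elimination with a random-forest ranker, evaluating prefix sizes
50, 100, … by five-fold cross-validated AUC. The fusion weights λ are
either fixed (the published operating point `PAPER_WEIGHTS` = 0.01, 0.01,
0.30, 0.68 for binary/AAindex/CKSAAP/K-mer) or optimized by exhaustive
simplex-lattice search against out-of-fold probabilities. Performance is
reported as Sn, Sp, Acc, MCC and ROC AUC.

The library is organised as scikit-learn-style estimators — `WindowEncoder`
(transformer), `RFESubsetSelector`, and the `PredNTS` classifier
(`fit` / `predict_proba` over `SiteWindow` sequences) — plus a
`prednts` command-line interface. A `synthetic` module generates
planted-motif benchmark data (charged residues K/R/E enriched and Y/S/F/L
depleted around positive sites) so the whole pipeline is testable without
any external download.

## Worked example

```sh
prednts simulate --out-fasta train.fasta --out-sites train.tsv --n-proteins 60 --seed 11
# wrote 60 proteins, 298 Y sites (113 positive)

prednts train --fasta train.fasta --sites train.tsv --w 7 --folds 5 --n-trees 150 \
    --weights optimize --no-feature-selection --seed 11 \
    --out-model model.joblib --report cv.tsv
# fused out-of-fold AUC: 0.943
# fusion weights: {'binary': 0.12, 'aaindex': 0.88, 'cksaap': 0.0, 'kmer': 0.0}
#          mean        se
# Sn   0.786166  0.035000
# Sp   0.908108  0.018331
# Acc  0.862260  0.013856
# MCC  0.706943  0.030643
# AUC  0.942260  0.014620
```

The report is the five-fold cross-validated performance of the fused score
(mean and standard error across folds): on this synthetic dataset the
ensemble separates planted nitration sites from ordinary tyrosines with AUC
0.94. Scoring new sequences yields one row per tyrosine, with the fused
probability and the per-encoding scores:

```sh
printf '>demo\nMKTAYERRKEAYLDKSATYRRKEG\n' > query.fasta
prednts predict --model model.joblib --fasta query.fasta --out pred.tsv
# protein_id  position  window           score   call
# demo        5         ---MKTAYERRKEAY  0.709   1
# demo        12        YERRKEAYLDKSATY  0.260   0
# demo        19        YLDKSATYRRKEG--  0.443   0
```

The tyrosine at position 5, flanked by the charged K/R/E context the
generator plants around true sites, scores highest and is the only site
called at the default 0.5 threshold. The same workflow is available from
Python via `PredNTS(...).fit(windows)` / `.decision_scores(windows)`.

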