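# Methods

## Problem and data model

Every tyrosine in an input protein is a candidate nitration site. A
candidate is represented by its sequence window of length 2w + 1 centred on
the Y (default w = 20, length 41), padded with `-` where the window extends
past a terminus. Positions are 1-based wherever a user sees them (site
tables, prediction output); internal indices are 0-based. Labels come from
a TSV site table (`protein_id`, `position`, `label` ∈ {1,0}): positions
listed with label 1 are positive, every other tyrosine of a protein that
appears in the table is negative, and tyrosines of unlisted proteins stay
unlabelled. A listed position that is not a tyrosine is a hard validation
error rather than a silent skip.

Dataset assembly follows the usual conventions for this predictor family:
redundancy reduction at a 40% identity threshold, a randomly held-out 20%
independent partition that keeps its natural class imbalance, and a 1:1
balanced training partition obtained by down-sampling the majority class.
Redundancy reduction is a greedy longest-first clustering on window strings
(identity = matching positions / window length; `-` matches only `-`),
operating at the window level by default; a CD-HIT `.clstr` file produced
externally can be ingested instead, since CD-HIT itself is an external
published tool we do not reimplement. Whether reduction should run at the
protein or window level is genuinely open; window level is the default
because windows are the unit entering the model.

Non-standard residues (B, J, O, U, Z) are mapped to `X` with a warning; `X`
encodes as an all-zero block in every scheme.

## Encodings

All four encoders emit named columns in a fixed canonical order (positions
ascending, letters alphabetical with the gap last, k/K ascending), so
selected-subset files are portable across runs.

* **binary** — 21-letter one-hot per position (20 amino acids plus the gap
  as 21st letter): (2w+1)·21 features, 861 at the default window.
* **AAindex** — one numeric property per position per table:
  (2w+1)·15 = 615 features. The original 15-index choice is not
  recoverable, so the package bundles 15 canonical physicochemical scales
  (Kyte–Doolittle hydropathy, residue mass/volume/surface area, Grantham
  polarity, isoelectric point, net charge at pH 7, aromatic and aliphatic
  indicators, side-chain H-bond donor/acceptor counts, Chou–Fasman
  helix/sheet/turn propensities, Hopp–Woods hydrophilicity) in an
  AAindex1-format file, fully overridable via `parse_aaindex`. Values are
  z-scored across the 20 letters before use, so the particular scale of
  each index is immaterial and the gap contributes 0, the standardized
  mean.
* **CKSAAP** — frequencies of ordered standard-letter pairs separated by k
  positions, 400 pairs per k, k = 0…4 → 2000 features. Pairs touching `-`
  or `X` are skipped while the denominator stays the number of pair slots
  (2w+1−k−1); heavily padded windows therefore have block sums below 1,
  a deliberate, documented signal of terminal proximity. Frequencies, not
  raw counts, are the default (`raw_counts=True` switches).
* **K-mer** — contiguous K-letter word frequencies, 20^K features per K,
  denominator 2w+1−K+1. The default K = (1,2,3) gives 20+400+8000 = 8420
  features; K = (1,3) (8020 features) is available because the two totals
  circulate in the literature for this scheme and the package does not
  adjudicate between them.

## Feature selection

Classic recursive feature elimination with a random-forest ranker: fit,
drop the `step = 50` least-important features by impurity decrease
(permutation importance available), refit, repeat; the final ranking is the
reverse elimination order. The per-round elimination step matches the
reporting grid granularity. Ties in importance break by canonical feature
name for determinism. The reported importance score of a feature is
`round_index + normalized within-round importance`, which is monotone along
the ranking by construction (raw importances from different rounds are not
comparable). A one-shot mode (`mode="single"`) ranks from a single fit.

Subset size is chosen on the grid 50, 100, … , p by five-fold
cross-validated AUC with a fresh forest per size; ties go to the smaller
subset. Selection runs once on the full training set by default (the
protocol the per-size grid reports imply); a selection-inside-every-fold
protocol is available through `cross_validate_windows`, which builds a
fresh estimator per fold so no stage ever sees its test fold. That helper
re-encodes windows per fold rather than slicing one precomputed matrix —
equivalent output, simpler code, and encoding is a small fraction of fold
cost.

## Ensemble and fusion

One `RandomForestClassifier` per encoding on its selected columns. The
original work does not state forest hyperparameters; defaults here are 500
trees and √p features per split, configurable. Comparator classifiers
(Gaussian naive Bayes; k-NN with k ∈ {3,5,7,9} chosen by internal CV) sit
behind the same train/predict interface for benchmarking and are not part
of the shipped predictor.

Fusion weights: either the published fixed vector (0.01, 0.01, 0.30, 0.68
for binary/AAindex/CKSAAP/K-mer) or exhaustive search over the weight
simplex — a 0.05-step lattice pass refined at 0.01 around the coarse
optimum — maximizing the AUC of the fused score. The search is always fed
out-of-fold probabilities (forests trained per CV fold), never
training-fold probabilities, to avoid optimistic fusion; exact AUC ties
prefer the sparser weight vector (largest single-scheme mass), then
lexicographic order, so results are deterministic.

Thresholding: default 0.5 (a score equal to the threshold is called
positive). A fixed-specificity mode instead picks the smallest threshold
whose out-of-fold specificity reaches a target (default 0.80), the
operating point this predictor family conventionally reports.

All randomness flows from one `random_state`, expanded into per-stage seeds
via `SeedSequence` keyed on CRC32 stage names; every stage is bit-reproducible
and every derived seed stays below 2^31.

Model bundles are joblib archives tagged with a format marker and the
library version; loading a corrupted file, a foreign payload, or a bundle
missing one of the four schemes raises a load error rather than returning
partial state.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/n, and
MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)) are evaluated
exactly from integer confusion counts; a zero marginal makes the MCC
denominator zero, in which case MCC is reported as 0 with a degeneracy flag
(the standard convention). AUC is computed two independent ways — trapezoid
integration of the ROC curve, and the rank-based Mann–Whitney statistic
P(score_pos > score_neg) + ½P(tie) — and the test suite holds them to 1e−9
agreement against a brute-force pairwise oracle. Cross-validation uses
stratified folds (stabilizes the 1:1 design under "random" partitioning)
and reports mean ± standard error across folds.

## Synthetic data

See the `prednts.synthetic` docstring for the generative model. Defaults,
chosen once: uniform background over the 20 letters; motif offsets −5…+5
around the site; multiplicative boosts `exp(±effect_size)` for the
enriched (K, R, E) and depleted (Y, S, F, L) letters, mirroring the
charged-residue enrichment observed around genuine nitration sites;
`positive_fraction = 0.35`, roughly the positive share of curated
nitrotyrosine site collections before balancing; `effect_size = 2.5`,
calibrated so the default represents a strong, clearly learnable motif
(fused CV AUC ≳ 0.95) while `effect_size = 0` is an exact null (positives
and negatives identically distributed — only non-Y flank positions are
resampled, from the boosted law conditioned on non-Y, which at effect 0
equals the law those positions already follow). The generator does not
model homology, positional dependence, or realistic proteome composition;
green tests on it certify pipeline correctness and recoverability of a
planted signal, not real-proteome accuracy.

## Problem sizes used in tests and the acceptance script

The recovery runs use ~200 proteins (~1,000 windows), half-window w = 10,
K-mer lengths (1,2), 150-tree forests and no feature selection; the RFE
recovery check uses a 300 × 150 planted-feature matrix. These sizes keep a
full from-scratch rerun at about a minute on a single CPU while leaving the
measured quantities (fused AUC vs. single-encoding AUC, chance-level null,
selector recall) well away from their decision boundaries. The published
headline numbers (training CV AUC 0.910, independent AUC 0.860) were
obtained on a curated experimental dataset that is not redistributable with
this package, so they are not reproduced here; the acceptance quantities
are the package's own computed results on synthetic data.

## Known limitations

* No PSSM/evolutionary features: encodings are sequence-composition only.
* The bundled AAindex set is a documented stand-in for an unrecoverable
  original choice; results with other property sets will differ.
* Redundancy reduction is a naive greedy clustering, not CD-HIT; for
  publication-grade dataset construction, run CD-HIT externally and ingest
  its cluster file.
* Weight optimization searches a lattice; with strongly correlated scheme
  scores the optimum is flat and the reported weights are one of many
  near-equivalent vectors (deterministically tie-broken).
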