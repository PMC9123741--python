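# Methods

This note documents the models and procedures implemented in
`xtclass`, the parameters that matter, the scope of the synthetic data
generator, and the numerical choices a user auditing results should
know about.

## Problem setting

Given protein sequences with binary labels (1 = verified xylose
transporter), an aligned set of the known positives, and an annotation
of functional regions (non-cytoplasmic domains, putative sugar-binding
sites) in the coordinates of one reference row, the pipeline trains a
classifier whose predictions are intended for *screening*: a large
candidate pool is ranked, and only near-certain candidates are called
positive. The operating regime is extreme class imbalance (tens of
positives against hundreds of negatives), which drives three design
commitments: resampling confined to training data, average precision
as the selection metric, and a strict decision threshold.

## Redundancy filter

Sequences are clustered greedily in order of decreasing length: each
sequence joins the first representative it matches at ≥ *t* identity
(default t = 0.8), else founds a cluster. Identity is the number of
identical positions in a global BLOSUM62 alignment (gap open 10,
extend 1) divided by the length of the shorter sequence — the CD-HIT
convention. Labelled positives can be *protected*: after clustering,
any absorbed protected id is re-added, so curated positives are never
lost. Ties in the greedy order break lexicographically by id, making
the output deterministic.

Each candidate pair is prescreened with a unit-cost edit distance
(edlib): for any global alignment with M identical columns,
M ≤ (|a| + |b| − d)/2 where d is the edit distance, so pairs whose
bound falls below t are skipped without computing the BLOSUM62
alignment. The bound is exact-safe — the output is identical to the
unscreened algorithm — and reduces the all-pairs cost on unrelated
sequences by three orders of magnitude.

## Descriptor inventory

All descriptors are computed over the 20 standard residues; B/Z/U/O/J
are mapped to X on input, X is excluded from composition denominators
and skipped pairwise in correlation sums (no property value is defined
for it).

* **Compositions** — amino-acid (20), dipeptide (400), tripeptide
  (8000; names are the raw 3-mers, so `GFV` is a column). k-mer counts
  divide by L−k+1.
* **AAindex autocorrelation** — Moreau-Broto
  ATS_d = mean_i P(r_i)P(r_{i+d}), plus the centred Moran and Geary
  variants, over all 531 embedded complete AAindex property tables,
  z-scored over the 20 residues, lags d = 1..30. Features are named
  by accession (`DAYM780201.lag.3`, `Moran.BIGC670101.lag.7`, …).
* **Amphiphilic pseudo-amino-acid composition** — Chou's APAAC with
  hydrophobicity (ARGP820101) and hydrophilicity (HOPT810101):
  τ_{2j−1} and τ_{2j} are mean lag-j products of the two property
  series, j = 1..λ (default λ = 30, weight w = 0.05); the 20
  composition entries and 2λ τ-terms are jointly normalized by
  Σf + wΣτ. λ = 0 reduces exactly to the plain composition. Feature
  names are `Pc1.<residue>` and `Pc2.<j>`.
* **Scales auto-cross covariance** — per-residue scores on the top
  k = 5 principal components of the standardized 531×20 property
  block (components centred over the 20 residues, sign fixed at the
  largest-magnitude loading), with
  ACC_{i,j}(d) = mean_t s_i(t)s_j(t+d) for d = 1..13. Names follow
  `scl<i>.<j>lag.<d>`.

The default inventory has ~56,600 named columns; training runs use a
compact preset (~130 columns: composition, the two named accessions ×
5 lags, APAAC λ = 5, scales lag 3, the GFV count, and the profile
features below) because recursive elimination over the full inventory
is not informative at the data sizes this package targets — the
compact preset keeps one representative of every family the full
inventory contains.

## Profile features

Built once from the positives' alignment and the region annotation;
all alignment coordinates at the API surface are 1-based.

* **PROSITE signatures** — patterns compiled from PROSITE syntax
  (elements, `[..]`, `{..}`, `x`, `(n)`/`(n,m)`, `<`, `>`) and scanned
  with overlapping matches; two features per pattern (count,
  presence). The sugar-transport signature strings are supplied by the
  user/config; none are hard-coded.
* **PSSM** — per-column probabilities
  p(a|col) = (count_a + α)/(n_nongap + 20α) over the annotated region
  columns (α = 1, uniform background), log₂ odds against the
  background. A query is aligned semi-globally (free end gaps) to the
  profile consensus and summarized into 23 features: mean log-odds per
  residue class, overall mean, max, and profile coverage. A reader for
  PSI-BLAST-style ASCII PSSMs is provided for precomputed per-protein
  matrices.
* **Profile HMM** — Krogh match/insert/delete architecture over the
  annotated columns of each region kind: selected columns with ≥ 50%
  residue occupancy become match states, the rest feed insert states
  (background emissions). Emissions and transitions are
  maximum-likelihood counts from the row state paths with Laplace
  pseudocount α = 1 on every allowed outcome; transitions into the
  non-existent delete state past the last layer are structurally zero.
  Scoring uses the forward algorithm (all paths, scaled
  probability-space recursion) and reports
  log₂ P(seq|HMM) − log₂ P(seq|background) in bits.

Two scoring details matter. First, **flank calibration**: a
region-restricted profile observes no flanking residues in training,
so the self-transitions of its first and last insert states fall back
to pseudocounts (≈ 1/3) and would charge ≈ 1.6 bits per flank residue,
burying the domain signal under a length-proportional penalty. At
scoring time those two self-loops are reset to L/(L+2) for a length-L
query — the standard practice of profile-search tools — leaving paths
inside the core model untouched. Without calibration the HMM feature
is length noise (class AUC ≈ 0.65 on synthetic data); with it the
domain signal dominates. Second, **jackknifed scoring for alignment
members**: a sequence that is itself a row of the source alignment is
scored against models re-estimated without its row. Self-match
otherwise inflates every profile feature for exactly the training
positives, a leak that distorts both feature selection and any
in-sample diagnostics.

`X` residues emit 1/20 under profile and background alike, so they are
score-neutral.

## Resampling

* **SMOTE** — synthetic minority rows x + u(x_nn − x), u ~ U(0,1),
  x_nn among the k = 5 Euclidean nearest minority neighbours;
  synthesis continues until minority = target_ratio × majority
  (default 1.0).
* **ENN** — removes any sample whose label disagrees with the strict
  majority of its k = 3 nearest neighbours (self excluded); all
  removals are decided on the original neighbourhood structure in one
  pass. A tie (k even) keeps the sample.
* **SMOTE+ENN** (default) — SMOTE then ENN; if cleaning ever removes
  an entire class the SMOTE output is used unchanged.

Distances are computed on internally z-scored features (heterogeneous
descriptor scales would otherwise dominate), outputs are returned in
the original scale, surviving original rows are never altered, and
neighbour ties break by sample index, so resampling is bitwise
reproducible under a fixed seed. Resampling is applied only inside
training folds/splits, never to evaluation rows.

## Training, selection and evaluation

* **Split** — stratified 70/30, seeded.
* **Learner** — XGBoost gradient-boosted trees behind a minimal
  contract (fit / positive-class probability / importance). Defaults:
  100 trees, depth 3, learning rate 0.2, `tree_method="exact"`,
  single-threaded. Exact split search matters here: histogram binning
  places thresholds at bin edges that can hug one class across the
  wide empty margin the HMM feature opens, misclassifying held-out
  sequences whose scores fall inside the gap; exact search splits at
  midpoints between adjacent training values. Hyperparameters are
  recorded in the model metadata, not tuned.
* **RFECV** — within each of 5 stratified folds, the fold's training
  part is resampled and features are eliminated stepwise (default
  step: 25% of the remaining set per round, floor 13 features),
  recording validation average precision at each count; the final
  size is the smallest count within one standard error of the
  cross-fold maximum, and a last elimination pass on the full
  training split names the set. The 13-feature floor matches the size
  of the reported importance table and avoids the degenerate
  single-feature collapse that occurs when several profile features
  are individually sufficient on clean data.
* **Metrics** — confusion counts, precision (flagged undefined when
  nothing is predicted positive), recall, accuracy, balanced accuracy,
  MCC, ROC AUC via the Mann-Whitney rank statistic with tie mid-ranks,
  average precision as the step-wise PR integral, plus ROC/PR curve
  points. AUC is reported as absent, not 0, on single-class data.
* **Thresholding** — bundles carry a decision threshold in (0,1);
  `fixed` mode sets it verbatim (0.98 default for screening), while
  `precision_floor` mode sweeps the unique validation probabilities
  for the lowest threshold reaching a required precision and errors
  with the best achievable value when the floor is unattainable.
  Classification uses ≥, so a probability exactly at the threshold is
  positive; predictions within 0.05 below the threshold are flagged
  `near_miss`.

Models serialize to versioned JSON (booster included) and reload with
bitwise-identical predictions.

## Synthetic data

The generator emulates the statistical *shape* of a curated
transporter study set, not its biology: negatives are i.i.d. sequences
from a background distribution (uniform by default; a
Robinson-Robinson table is selectable), positives are background
sequences with a 15-residue motif implanted at a fixed offset inside a
designated region (default residues 151–200), each motif site
substituted with probability `mutation_rate` (default 0.1). The
positives' "alignment" is exact by construction (left-aligned rows,
right gap padding), and the annotation marks the motif region on the
first positive. `default_paper_shape` produces the standard study set:
25 positives / 371 negatives, lengths 400–600.

What passing tests on this data do show: the pipeline recovers a
domain-restricted motif signal under severe imbalance, the profile-HMM
feature is selected as most informative, and threshold raising behaves
as designed. What they do not show: performance on real transporter
families, where negatives are homologous to positives (not random),
alignments contain gaps and alignment error, and the discriminative
signal is distributed rather than a single implanted motif.
`mutation_rate` is a difficulty dial: at 0 the HMM feature alone
separates the classes perfectly; at 0.45 held-out AUC degrades
markedly (≈ 0.8 in our measurements) but does not collapse to chance —
an implanted 15-mer at 45% per-site mutation still matches the profile
at ~8 sites against ~0.8 expected by chance, and a forward-algorithm
detector finds that residue of signal.

## Problem sizes and runtime

The bundled verification suite and the reproduction script run the
full pipeline on the 25/371 study set with the compact descriptor
preset (five seeded replicates, ~15 s each on one CPU), and verify the
numeric kernels against brute-force oracles at small sizes (HMMs with
≤ 3 match states against exhaustive path enumeration; descriptors on
≤ 100-mers against direct summation; ranking metrics on ≤ 20 samples
against pair counting). The >30,000-column property of the full
descriptor inventory is checked on a 2-sequence set.

## Known limitations

* The greedy clustering is O(n²) pairwise comparisons; the edit-
  distance prescreen makes this fast for unrelated sequences but
  datasets of tens of thousands would need a word-index filter.
* The profile HMM has no local (Smith-Waterman-style) alignment mode;
  glocal scoring with calibrated flanks is a deliberate simplification
  and will under-score sequences containing the domain twice.
* Probabilities are raw booster outputs (no isotonic/Platt
  recalibration); the strict threshold operates on them directly, so
  thresholds are not comparable across learners.
* Tree learners do not extrapolate margins: a held-out sequence whose
  profile score falls outside the training range is classified by the
  nearest split, which can cost recall when training positives are
  few. Exact split search mitigates, but does not remove, this.
* "Pc1.c" as printed in field reports is ambiguous (no residue "c");
  the package implements and names the full APAAC family (`Pc1.*`,
  `Pc2.*`) rather than guessing a single column.
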