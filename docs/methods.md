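# Methods

## Model and pipeline

`cazlearn` implements two-stage CAZyme annotation over fixed-length
per-protein embeddings. An embedding x ∈ R^D (D = 1024 for the reference
pLM; the package accepts any declared dimension) is first scored by a
binary *gate* — a random forest with 200 trees and a fixed random state —
whose score is the fraction of trees voting CAZyme. Gate-positives
(score ≥ τ, default τ = 0.5) are passed to the *family* stage, a
feedforward network D → h1 → h2 → K with ReLU activations and a softmax
output over the K family/subfamily labels (reference dimensions
1024 → 256 → 512 → K). K is always derived from the labels present in the
training data; it is never hard-coded, because the label space of a CAZyme
catalogue shifts with every release and with how subfamilies are folded in.

The pipeline assumes that the embedder maps each protein to a single
vector. When an embedder emits per-residue matrices (L × D), they are
pooled by the arithmetic mean over residues (configurable to sum or max);
mean pooling is the convention of the common embedding toolkits, and the
classifiers are agnostic to the choice as long as training and inference
agree. Sequences longer than 5,000 residues are rejected at embedding time
to match the training-set curation, so queries stay within the training
length distribution.

## Weighted cross-entropy

Family sizes in CAZy-style catalogues span four orders of magnitude.
Training minimises

    L = Σ_i w_{y_i} · (−log p_{i, y_i}) / Σ_i w_{y_i},   w_c ∝ 1/n_c

where n_c is the number of training sequences for class c. Weights are
normalised to mean 1, which keeps loss magnitudes comparable across
ontologies without changing the optimum. The per-sample weighted loss and
the weighted-mean batch reduction follow the semantics of the major deep
learning frameworks, so reported losses are directly comparable.
Probabilities are clamped at a configurable epsilon (default 1e-12) before
the log so that a degenerate prediction produces a large finite loss rather
than an infinity.

The network and its Adam optimiser are implemented directly in numpy. At
the scale of fixed-length embedding inputs this is fast (seconds per
candidate at desk scale), has no framework dependency, and — because all
randomness flows through a single seeded generator — is bit-reproducible
across platforms, which the determinism contracts require.

## Hyperparameter search

Random search draws `n_candidates` (default 20) configurations — hidden
sizes log-uniform in [128, 1024], batch size log-uniform in [32, 512],
learning rate log-uniform in [1e-4, 1e-2] — and trains them under
synchronous successive halving: rungs at epochs g·η^i (grace period g = 5,
reduction factor η = 2) capped at the epoch budget (default 100); at each
rung the surviving pool is ranked by validation loss and cut by η (never
below one candidate); survivors of the last rung complete the budget. The
asynchronous variant of this scheduler exists for parallel workers; at
single-process scale the synchronous schedule makes identical pruning
decisions and is exactly reproducible, so it is used here. The returned
model is the final survivor with the best validation accuracy; the search
report records every candidate's hyperparameters, epochs survived, rung
count and final metrics.

## Curation parameters

| step | default | rationale |
|---|---|---|
| length filter | drop length > 5,000 aa (boundary kept) | strict reading of the curation rule; keeps the embedder within memory limits |
| deduplication | exact sequence, representative = smallest id | deterministic tie-break; labels of duplicates are merged |
| identity clustering | threshold 0.60, greedy longest-first | CD-HIT's strategy; identity = matches / alignment length from a global alignment |
| negative purge | shared exact 8-mer screen, then local alignment at ≥ 30 % identity over ≥ 50 % query coverage | the reference workflow used an ultra-sensitive homology search without a printed threshold; the fallback is conservative and every knob is configurable, and an external search tool can be plugged in through the same contract |

Pairwise identity uses a Needleman–Wunsch alignment (edlib, unit costs)
with identity = match columns / alignment columns; ambiguity letters
(B, Z, X, U, O) are retained in stored sequences but mapped to X for
identity computation. The purge's local-alignment confirmation uses
BLOSUM62 with gap open −11 / extend −1.

## Latent-space probes

Nearest-neighbor search is exact (all pairwise Euclidean distances; no
approximate index), with ties broken by reference order and an
exclude-self switch for in-database queries.

The substitution probe slides a window (default 10 residues, step 1,
0-based half-open coordinates) along the sequence; every residue in the
window is replaced by its *most distant* BLOSUM62 substitution — the
amino acid minimising the matrix row score, ties broken alphabetically —
the mutant is re-embedded, and the family model's probability for a target
class is recorded against the unmutated baseline. The row-minimum
substitution is the strongest single perturbation consistent with
"more distant substitutions"; a sampled-distance mode (substitution drawn
with probability inversely related to similarity) and an identity mode
(no-op control, which must trace flat at the baseline) are provided behind
flags. Windows containing non-canonical residues are skipped and logged by
default. BLOSUM62 is loaded from Biopython's substitution-matrix tables
with symmetry and row-dominance asserted at load.

## Differential abundance

The stages run in a fixed order, enforced by a stage tag on the count
matrix: prevalence filter → zero imputation → log2 fold change → per-gene
model → BH correction.

- *Prevalence*: genes nonzero in < 10 % of samples are removed; exactly
  10 % is retained (strict reading of the rule).
- *Imputation*: zeros become (per-gene minimum nonzero)/2, making the log
  transform defined without a pseudocount that would distort nonzero
  values.
- *logFC*: log2(mean over disease / mean over control) on imputed counts.
- *Per-gene model*: counts are log2-transformed and z-scored within the
  gene (sample SD, n−1 denominator), then regressed by OLS on an
  intercept, the disease indicator, and the covariates jointly; the
  reported p-value is the two-sided t-test on the disease coefficient.
  Joint modelling (rather than residualising covariates first) is the
  standard choice when the estimand is the adjusted disease effect.
  Collinear designs and missing metadata are hard errors; genes with zero
  variance after transformation are dropped with a log entry rather than
  yielding NaN statistics.
- *BH correction*: textbook step-up with monotone enforcement;
  significance declared at q ≤ 0.25.
- *Volcano labels*: disjunctions of (logFC, p) clauses; presets encode the
  Crohn's-disease rule set {logFC > 0} ∪ {logFC < 0 ∧ p < 1e−8} ∪
  {logFC < −4.5 ∧ p < 1e−3} and the IgG4-related-disease rule set
  {logFC > 2 ∧ p < 1e−5} ∪ {logFC < −2 ∧ p < 10^−3.5} ∪
  {logFC > 3 ∧ p < 10^−2.5} ∪ {logFC < −3.5 ∧ p < 1e−2}.
- *Prioritization*: for CAZyme-predicted genes,
  priority = (percentile of logFC among all tested genes + family
  probability) / 2, with percentile = (rank − 1)/(n − 1) and average ranks
  on ties; monotone in both components.

## Synthetic data: what it emulates and what it does not

The fixture generators define the conditions under which the pipeline is
validated.

*Embeddings* are isotropic Gaussian clusters: class means are random
directions on a sphere of radius `separation·σ` (inflated if two
directions happen to fall closer, so every pairwise mean distance is at
least `separation·σ`), points are N(mean, σ²I), with a heavier-tailed
Student-t option. This is the minimal geometry under which both
classifiers should succeed and gives a clean chance-level control at
separation 0. Real pLM embeddings are not isotropic, families are not
equally far apart, and class manifolds are curved — so passing tests show
that the training and inference machinery recovers separable structure,
not that any particular accuracy transfers to real catalogues.

*Sequences* are i.i.d. uniform residues, with mutated copies (point
substitutions at a set rate), planted shared segments, and chimeras for the
homology-purge tests. Real proteins have composition bias and domain
structure; the fixtures only guarantee that planted identity/homology is
the sole signal present.

*Counts* are negative binomial (variance μ + αμ², dispersion α = 0.3 by
default) around lognormal per-gene baselines (log2 mean 5, SD 1 — tens to
hundreds of reads), with per-sample depth factors (log-SD 0.2), a planted
multiplicative disease effect on a chosen gene fraction, optional covariate
effects, and a prevalence control that thins selected genes below the
filter threshold. A lognormal mode generates counts as 2^N(m, s) so a
planted shift is an exact standardized effect on the log2 scale; the power
study (effect 1.5 SD, 40 samples/group, 200 genes) uses this mode.

Two calibration notes. First, the null-calibration study (2,000 genes, 30
samples/group) runs with depth factors disabled: the depth factor is a
nuisance shared across genes, so it correlates p-values between genes
without invalidating any single gene's test — a pooled KS uniformity check
assumes independent p-values and would reject for that reason alone.
With depth off, the disease p-values are uniform and the BH false-call
fraction is controlled; with depth on, per-gene validity still holds but a
depth-normalisation step (outside this pipeline's scope, as in standard
practice it happens upstream) would be needed before pooling inference
across genes. Second, the two-stage recovery study uses 20 families of 60
points in dimension 64 at 6σ separation plus one size-matched non-CAZyme
cloud; the gate forest is kept at its fixed 200 trees throughout.

## Numerical choices and degenerate inputs

- Activation ReLU, optimiser Adam (lr from the search), He initialisation;
  recorded in the model manifest together with the seed and hyperparameters.
- argmax ties in family prediction resolve to the lowest class index.
- ROC/PR curves emit one point per distinct score (ties grouped), include
  the (0, 0) / (recall 0, precision 1) endpoints, and integrate areas by
  trapezoid; e-value-style scores are handled by rank negation; queries
  missing from a hit file are imputed the worst score so curves cover the
  full truth set.
- Precision/recall/F1 use the 0/0 → 0 convention so degenerate classes
  remain scorable.
- Empty embedding sets, empty queries, and single-class ontologies are
  valid inputs wherever the operation is well-defined; single-class truth
  for curve construction is an error.

## Problem sizes

The test-suite and acceptance-script experiments run at desk scale, chosen
so each study is statistically informative while the whole suite completes
in well under a minute of compute: 1,200–2,400 embedding vectors for the
recovery study, 4 search candidates with a 20-epoch budget, 2,000 genes for
the null study, 200 genes for the power study, and 100 randomized instances
per metric-oracle comparison.

## Known limitations

- No real pLM is bundled; the embedder is a contract, and all shipped
  embedders are deterministic mocks. Results on real catalogues depend
  entirely on the external embedder's quality.
- The built-in clusterer and homology screen are desk-scale fallbacks
  (quadratic in the number of sequences); production-size catalogues should
  plug external tools into the same contracts.
- The gate forest gives vote fractions, not calibrated probabilities; τ
  should be tuned on a validation set when precision/recall trade-offs
  matter.
- The differential-abundance model is per-gene OLS on transformed counts;
  it does not model library size explicitly and inherits the robustness
  limits of linear models on heavy-tailed count data.
- Multi-label proteins (several families on one sequence) are carried
  through curation, but the family stage predicts exactly one label per
  protein.
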