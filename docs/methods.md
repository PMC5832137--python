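# Methods

`emrdx` models the admitting diagnosis of a first-course clinical record
as a multilabel classification target.  A record carries four text
sections — chief complaints, physical examination, obstetric examination
and auxiliary examinations — and a set of diagnosis labels.  The package
covers the full experimental pipeline: corpus generation, label-space
standardisation, feature extraction, four multilabel classifiers, five
ranking-based evaluation measures, and a cross-validated experiment
runner.

## Synthetic corpus generator

Real first-course corpora of this kind are private, so the package ships
a seeded generator that reproduces the statistics that drive multilabel
learning difficulty rather than any clinical language:

* **Label frequencies** follow a power law: the sampling weight of the
  rank-r label is proportional to r^(−`label_skew`).  The default skew
  of 1.0 produces a skewed but fully populated label set at desk scale
  (2,000 records, Q = 60).  A skew near 2.0 at the scale of a real
  corpus (≈11,000 records, ≈233 labels) reproduces the reported shape of
  such label sets — roughly a third of labels occurring once and a third
  with frequency 2–10 — and is the right choice when the label-frequency
  floor experiments should have rare labels to remove.
* **Label cardinality** per record is drawn from a distribution on 1..8
  whose default has mean 2.67, matching the reported cardinality of real
  obstetric admitting diagnoses.
* **Text sections.** Each label owns one dominant topic.  An affinity
  row is (1 − f)·onehot(topic) + f·uniform with noise floor f = 0.05 —
  i.e. the floor is a probability *mass*, so signal strength does not
  depend on the topic count.  A record's topic mixture is the normalised
  sum of its labels' affinity rows plus a total smoothing mass
  `dirichlet_alpha` (default 0.05) spread uniformly over topics.
  Section tokens then follow the standard LDA generative process: draw a
  topic from the mixture, then a word from that topic's distribution.
  True topic–word rows are drawn from a symmetric Dirichlet with
  concentration `dirichlet_beta` (default 0.1) per word; smaller values
  give more separated topics.
* **Section lengths** are Poisson with means 40/35/35/30
  (chief/physical/obstetric/auxiliary), ≈140 tokens per record — the
  order of magnitude of a segmented first-course note.
* Tokens are synthetic integer strings (`w0017`); tokenisation and
  learning are language-agnostic after segmentation, so no attempt is
  made to imitate clinical orthography.

What the generator deliberately does **not** emulate: label
co-occurrence structure beyond what shared sampling induces (real
diagnoses co-occur for clinical reasons), section-specific vocabulary,
narrative word order, and noisy or contradictory labelling.  Passing
tests on this corpus therefore demonstrate that the pipeline recovers
planted statistical structure, not that it reaches any particular
accuracy on real records.

## Label standardisation

Raw diagnosis strings are standardised in three steps:

1. **Exclusion** of calculated pseudo-diagnoses (gestational age
   "pregnancy 28+2 weeks", gravida/para counts) by configurable regular
   expressions.
2. **Merging** of synonymous spellings.  Each label is mapped to a
   term-frequency vector over its tokenised components (an external
   ontology can be plugged in) and pairs whose cosine similarity reaches
   a threshold (default 0.8) are clustered by single linkage; the most
   frequent member becomes canonical, ties broken lexicographically.
   The similarity of two semantic vectors S1, S2 is their cosine
   S1·S2/(|S1||S2|), symmetric and in [0, 1].  Merges are recorded in a
   `merge_map` for audit.  In the original workflow this step was a
   similarity-guided manual review; a threshold rule is the testable
   surrogate, and the threshold is a free parameter.
3. **Frequency filtering.**  Labels below a corpus-frequency floor are
   removed, and records left without labels drop out of the evaluation
   corpus.  Floors of 1, 2 and 11 correspond to the full, singleton-free
   and rare-free label sets (the 233 → 153 → 71 progression of the
   motivating study; the arithmetic of those set sizes requires the
   third floor to remove frequencies ≤ 10, i.e. keep ≥ 11).

## Features

**LDA topics.**  Sections are concatenated into one document per record
(the study design gives no per-section modelling).  Inference is
collapsed Gibbs sampling with the conditional
p(z = k | rest) ∝ (C_dk + α)(C_wk + β)/(C·k + V β), the sampled token
excluded from all counts.  Defaults: α = 50/K (module-level), β = 0.01,
500 sweeps.  The topic-word estimator normalises over the vocabulary —
the standard estimator — and the document-topic estimator over topics.
The cross-validation pipeline uses a sparser document prior (α = 0.1),
because records genuinely mix only a handful of topics, and estimates
document-topic vectors as posterior means over 50 post-burn-in sweeps
(`n_average`), since a single final Gibbs state is a one-sample estimate
with needless variance.  Held-out documents are folded in against
frozen word-topic counts (30 burn-in + 30 averaged sweeps);
out-of-vocabulary tokens are skipped.

Document-topic vectors enter classifiers through a square-root map
(Hellinger embedding).  Euclidean distance between √θ vectors tracks
Hellinger distance between the underlying distributions and stabilises
the variance of small proportions, which measurably helps the
distance-based classifier.

**Skip-gram vectors.**  The skip-gram objective maximises the average
log-probability of context words within a window c = 5 of each
position, with p(w_O | w_I) the softmax of output·input vectors.  Two
seeded trainers are provided: the exact softmax gradient (used by the
verification tests, feasible at synthetic vocabulary sizes) and
negative sampling (5 noise words from the unigram^0.75 distribution,
default for experiment runs).  The learning rate (0.025) decays
linearly over all updates.  Document vectors are the mean of the input
vectors of in-vocabulary tokens; input vectors only, by convention.

## Classifiers

All four expose `fit`, `score` (the ranking function f) and `predict`
(the bipartition h), and all fits are bit-reproducible given a seed.

**BP-MLL** is a single-hidden-layer tanh network trained on the
pairwise exponential ranking loss
E_i = (1/|Y_i||Ȳ_i|) Σ_{k∈Y_i, l∈Ȳ_i} exp(−(c_k − c_l)), i.e. the
difference of network outputs between each relevant and irrelevant
label.  (The legacy per-instance sum-of-squares objective is kept as a
reference loss.)  Instances with no (relevant, irrelevant) pair are
skipped and flagged.  Training is full-batch gradient descent on the
mean loss plus an L2 penalty.  Features are standardised internally —
the loss surface is badly scaled otherwise, and with raw
topic-proportion inputs the network learns little beyond label priors.
Defaults chosen for that optimiser: hidden = ⌈0.5·d⌉ units (a narrower
0.2·d bottleneck demonstrably underfits when the label space is wider
than the feature space), 500 epochs, learning rate 2.0 (the tanh output
layer bounds the loss, so large full-batch steps are safe), L2 = 1e−5.
Because the loss only constrains rankings, a bipartition threshold t(x)
is fitted afterwards: each training instance's optimal separating
threshold is computed exactly, and a linear function from score rows to
thresholds is fitted by least squares.

**MLkNN** estimates, per label, a prior P(H) = (s + #positives)/(2s + p)
and neighbour-count conditionals P(E_c | H), P(E_c | ¬H) with Laplace
smoothing s = 1 from the k = 10 Euclidean nearest neighbours of each
training point (self excluded); scoring returns the posterior of H
given the observed positive-neighbour count.

**RAkEL** draws m = min(2Q, C(Q,k)) distinct labelsets of size k = 3,
trains one label-powerset multiclass learner per set, and scores each
label by the fraction of its labelsets voting positive.  Labels in no
labelset score 0 with a warning.

**Classifier chains** train one binary learner per label in chain order
(default: label-space order; a seeded random order is available), each
consuming the features plus the true labels of earlier positions;
prediction propagates hard 0/1 decisions down the chain and reports
positive-class probabilities.  Single-class label columns get a
constant predictor with a warning.

The base learner for RAkEL and chains is L2-regularised logistic
regression (deterministic, fast, adequate on topic/embedding features);
any scikit-learn classifier can be substituted.

## Evaluation

Hamming loss, one-error, coverage, ranking loss and average precision
follow their standard set/rank definitions.  Ranks are deterministic:
descending score, ties broken by ascending label index — the measures
are otherwise undefined under ties.  Degenerate rows (no relevant
label; for ranking loss also no irrelevant label) are excluded from the
affected measure with a warning instead of failing the evaluation,
because frequency-filtered label sets can produce them.

Cross-validation partitions instances at random (seeded) into k folds
(default 10).  Feature extractors are fitted on the training fold only;
held-out documents are projected through the fitted extractor (topic
fold-in, vector averaging), so no test token reaches any fitted
parameter.  Reports give per-fold values and mean ± sample standard
deviation.

## Experiment runner

Three experiment families mirror the study's axes: performance across
label-frequency floors, across LDA topic counts K, and across
word-vector dimensions T.  Reports are TSV tables (classifier × feature
rows, metrics as "mean ± std", the best value per column flagged with
`*`) plus a JSON manifest carrying the full configuration and seed.
Reports contain no wall-clock data — timings go to the logger — so a
rerun with the same seed is byte-identical.

## Problem sizes and numerical choices

Default experiment scale is 2,000 records with Q = 60 and a 2,000-word
vocabulary, chosen so that full sweeps run at desk scale; the original
study scale (≈11,300 × 233) is a configuration away.  The verification
suite uses smaller instances: topic recovery uses 1,000 documents over
a 300-word vocabulary with three well-separated planted topics
(`dirichlet_beta` = 0.05) and is scored by mean total-variation
distance after optimal (Hungarian) topic matching; trend checks use
700–800-record corpora and 3-fold cross-validation.

Numerical details worth knowing: Gibbs sampling uses one pre-drawn
uniform per token per sweep from a single `numpy` Generator, making
fits reproducible to the bit; softmax computations subtract the row
maximum; the cosine similarity of a zero semantic vector is defined as
0 with a warning; `filter_labels_by_frequency` recomputes frequencies
from the actual label matrix, so filters compose exactly; all random
labelset draws, chain orders, fold partitions and weight
initialisations derive from explicit integer seeds kept below 2^31.

## Known limitations

* Collapsed Gibbs mixes slowly at larger topic counts; topic-word
  recovery at K = 60 is partial even when downstream features are good.
  Variational inference is out of scope.
* The generator's labels are conditionally independent given their
  topics; methods whose advantage is exploiting label dependencies
  (classifier chains) cannot show that advantage here.
* The bipartition threshold of BP-MLL is a linear function of scores;
  per-label calibrated thresholds are out of scope.
* Tokenisation is a dictionary longest-match with whitespace fallback;
  real segmentation of clinical Chinese is replaced, not reproduced.
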