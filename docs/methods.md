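# Methods

## Problem and data model

The unit of analysis is a peptide–HLA pair: a mutant peptide of 8–11
amino acids (the length range presentable by HLA class I) and the
presenting allele, labeled immunogenic or non-immunogenic by T-cell
assay evidence. Curation enforces the length window, the 20-letter
amino-acid alphabet, completeness of peptide/allele/label, and uniqueness
of each (peptide, canonical allele) pair. Duplicates keep the first
occurrence; conflicting labels across duplicates are counted and
reported, not resolved — source databases disagree and silently picking a
winner would hide that. HLA alleles are normalized to
`HLA-<locus>*<group>:<protein>` with two-digit-minimum fields; common
alias spellings (missing prefix, missing separators, lowercase) are
accepted.

## Encoders

Peptide and HLA representation (full allele name by default, binding
groove pseudo-sequence optionally) are merged with an explicit `|`
separator before k-mer slicing, so k-mers spanning the boundary are
distinct tokens rather than chimeric amino-acid words. The full allele
name is the default because it carries supertype/subtype identity that
the pseudo-sequence alone does not.

* **k-mer slicing** is a stride-1 sliding window: non-overlapping slicing
  would discard frame information.
* **TF-IDF** uses raw term counts, smoothed idf `ln((1+N)/(1+df)) + 1`
  and ℓ₂ row normalization (sublinear tf off). Out-of-vocabulary tokens
  are ignored at transform time; an all-unseen document is a zero row.
* **Contextual embeddings** come from any object implementing the
  `ContextualEmbedder` protocol (deterministic token-sequence → matrix).
  The bundled `DeterministicStubEmbedder` maps each token to a fixed
  pseudo-random unit-variance vector derived from a BLAKE2 digest of the
  token string: fully offline, bitwise reproducible, no semantic content.
  A pre-trained biomedical transformer checkpoint can be wrapped in the
  same interface; it is used frozen (no fine-tuning). Pooling for the
  fused submodel is the mean over token embeddings (the CLS-token
  alternative is exposed as an option).

## Preprocessing

Structured features are z-scored with the population-(n) standard
deviation, so the fitting data itself maps exactly to mean 0 / std 1;
constant columns map to 0 with a warning. The scaler can only be fitted
on a train-tagged matrix and its statistics are immutable afterwards.

SMOTE rebalances the minority class to parity (target ratio 1.0) using
k = 5 Euclidean nearest minority neighbors — the algorithm's canonical
defaults. Every synthetic row is a segment interpolation
`x + u·(x_nn − x)`, u ~ U[0,1], hence lies in the convex hull of the
minority class. Synthetic rows are flagged and exist only inside the
training design matrix; evaluation partitions are encoded separately and
never pass through SMOTE. Each submodel rebalances in its own design
matrix space; for the token-level CNN input this means the zero-padded
token×dimension tensor is flattened for interpolation and reshaped back
(interpolating two same-class embedding matrices position-wise).

Splits default to 60/20/20 train/validation/test, stratified by label —
with ~30% positives, an unstratified 20% test set at n ≈ 1500–2000 would
be unstable. 5-fold cross-validation is available for classical models.

## Submodels and training

Architectures and training settings are fixed per submodel (see README
table). Design notes:

* The convolutional model uses 1-D convolutions of widths 3/4/5 spanning
  the full embedding dimension (the standard text-CNN construction for
  "kernel sizes [3,4,5] with 120 filters"), each branch followed by ReLU
  and a global max over valid (non-padding) token positions.
* The classifier head emits raw logits; training minimizes two-class
  cross-entropy (softmax applied inside the loss), and the reported score
  is the softmax probability of the immunogenic class.
* No early stopping: epoch counts are fixed; validation data is scored
  for monitoring only.
* The engine is plain numpy with explicit backprop and Adam
  (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). All randomness — init, batch
  shuffling, dropout masks — flows from one seeded generator, so training
  histories are reproducible to float tolerance independent of thread
  count. Dropout is inverted dropout, active only during training.
* Rankings break score ties lexicographically on record id, making every
  downstream ordering deterministic.

## Rank fusion

The consensus rule ("top-50 of each model; support ≥ 2 models ⇒
consensus block first; remainder by model-specific score") leaves two
sub-orderings open, fixed here as:

* within the consensus block: support count descending, then mean
  per-model rank ascending, then record id — rank-level information only,
  consistent with a late-fusion design;
* remainder block: per-model min–max normalization of scores, then each
  record's maximum across models, descending (record-id tie-break).
  Raw probabilities from different submodels are not on a comparable
  scale, so some normalization is required; min–max is monotone per model
  and therefore preserves each model's own ordering. A degenerate model
  whose scores are all equal normalizes to 0.

Both rules are implementation choices, localized in `ensemble.py`.

## Neoepitope enumeration and features

Protein coordinates are 1-based and windows are closed intervals,
matching standard protein mutation nomenclature. For a variant at
interior distance ≥ L−1 from both protein ends there are exactly L
windows of length L (38 candidates over lengths 8–11); windows clip at
the boundaries. Identical peptide strings from different windows collapse
to one candidate — they are indistinguishable to the classifier.

The 11 structured features are a registry split by provenance:

* **external columns** (5): peptide–HLA binding affinity, complex
  stability, TAP transport efficiency, combined processing score,
  gene expression — scores produced by external predictors/quantifiers
  and ingested by a join on (peptide, allele). A declared-external
  feature that is missing raises an error; there is no silent imputation.
* **local proxies** (6): hydrophobicity of TCR-contact residues (mean
  Kyte–Doolittle over positions 4..L−1, the peptide's TCR-facing stretch
  by common convention), full-peptide hydropathy, net charge
  (K+R+H − D−E), polar fraction, aromatic fraction, and mutant-vs-wild-
  type dissimilarity (negated BLOSUM62 substitution score — higher means
  a more foreign-looking substitution).

The model layer treats all 11 slots identically, so replacing a proxy
with an external tool's score changes no interface. The proxy formulas
are documented stand-ins, not validated immunogenicity predictors.

## Statistics

* ROC AUC is computed by the Mann–Whitney U identity on average ranks
  (ties count ½).
* Length differences between classes use a chi-square test on the 8–11
  contingency table; per-position residue differences use residue × class
  chi-square tables with rows of expected count < 5 pooled into "other"
  before testing. Positional p-values are reported raw by default; a
  multiple-testing correction switch exists but is off, since the
  per-position report is descriptive.
* Feature screening: Spearman correlations (pairs involving a constant
  feature are reported as undefined, never 0), Shapiro–Wilk normality,
  Mann–Whitney group comparisons, and random-forest importance
  (500 trees, impurity-based, fixed seed).
* ELISpot: the adjusted count is the replicate mean after outlier removal
  minus the background mean, floored at 0 (negative spot counts are
  non-physical). Strong ≥ 81 takes precedence at the boundary; weak is
  [8, 81). The replicate-outlier rule is leave-one-out: a replicate is
  dropped if it deviates from the mean of the remaining replicates by
  more than 2 of their SDs, with the SD floored at a counting-noise scale
  (0.1·mean + 1). A plain z-score against the full-sample SD cannot
  exceed (n−1)/√n and therefore can never flag anything in triplicate
  data, which is why the leave-one-out form is used. The rule is
  pluggable.

## Synthetic data generator

The generator emulates the structural signatures of curated
immunogenicity training sets so every stage is testable offline:

* lengths: immunogenic class 6/59/28/7% over 8/9/10/11-mers (9-mers
  dominant), non-immunogenic 3/49/46/2% (9- and 10-mers comparable);
* positional residue enrichment in the immunogenic class: K/R at P1 and
  E/D at P2–P4, as multiplicative odds (default 3) on realistic
  background amino-acid frequencies;
* HLA usage: a 12-allele pool; the non-immunogenic class concentrates on
  three common alleles while the immunogenic class is spread more evenly
  (immunogenic peptides associate with a more diverse allele range);
* features: class-conditional unit-variance Gaussians, seven of eleven
  shifted upward in the immunogenic class (0.8 SD default);
* class balance: 30% positive — curated immunogenicity sets are
  imbalanced; 0.30 is a representative middle ground;
* wild-type peptides differ from the mutant in exactly one residue.

`GeneratorSpec.strong_signal()` is the planted-signal condition used for
parameter-recovery experiments: enrichment odds 25, a stronger allele
tilt, 1.5-SD shifts on seven features, and — crucially — peptides drawn
as 1-residue variants of a finite per-class repertoire of 25 prototype
epitopes (emulating shared/public epitope families). The repertoire is
what makes the sequence signal *recoverable* by bag-of-k-mers models:
with fully i.i.d. positional draws, held-out 6-mers are almost all
out-of-vocabulary, and a TF-IDF model can exploit nothing but the allele
distribution regardless of how strong the positional enrichment is.
`GeneratorSpec.null()` removes every class difference and is used for
type-I-error calibration (positional chi-square rejects at ≈ 5%).

What the generator does **not** emulate: real binding-motif structure per
allele, correlations between features and sequence, label noise from
assay variability, and batch effects across source studies. Passing the
recovery tests therefore demonstrates that the pipeline trains, ranks and
fuses correctly and can recover a planted signal — not that it attains
any particular accuracy on real immunogenicity data, which requires the
curated external datasets.

ELISpot fixtures draw replicate counts as Poisson around background + a
class signal (+2 / +40 / +150 for negative / weak / strong at background
10), so threshold classification recovers the planted class with
probability ≥ 0.95. Read mixing samples without replacement at the
requested tumor fraction (default 15%), floor-rounded, and shuffles with
the seed; a manifest traces every output read to its source pool. Toy
FASTQ reads are drawn from a random 10 kb reference — read counts, not
molarity, define depth at toy scale.

## Problem sizes

The recovery experiments run at n = 2000 records (1200 train / 400
validation / 400 test) with the 32-dimensional stub embedder, three
seeds; Monte-Carlo calibration uses 200 replicates at n = 400 (null) and
n = 2000 (planted). These sizes give stable estimates (binomial SE < 1%
on calibration rates) while keeping a full run on one CPU in minutes.

## Known limitations

* The bundled embedder carries no biological prior; with it, the
  contextual-embedding submodels are effectively learning over random
  token projections. Plugging in a real frozen transformer changes only
  the embedder adapter.
* The feature proxies are literature-motivated descriptors, not the
  outputs of the named external predictors; results on real data depend
  on supplying those columns.
* Only single-residue missense variants are handled; frameshifts,
  indels and fusions are out of scope.
* The minimal VCF reader expects a pre-annotated protein-consequence tag;
  it does not annotate variants.
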