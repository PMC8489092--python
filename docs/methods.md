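# Methods

This note documents the models and procedures implemented in `ddikit`,
the synthetic study conditions the test battery runs under, the
numerical choices that matter, and what the desk-scale results do and do
not show.

## Data model and task

A DDI database is a set of *m* unordered drug pairs over a phenotype
vocabulary 𝒴. Pairs are stored canonically sorted by drug id and
deduplicated by OR-ing label vectors; labels are symmetric in the two
drugs (nothing in the data model distinguishes their roles). Phenotypes
not reported for a pair are negatives — the closed-world assumption —
so the label matrix is binary, sparse and noisy, and the task is
multilabel classification with strong intra-class (positives vs
negatives per phenotype) and inter-class (frequent vs rare phenotypes)
imbalance. The label density LD = mean(|y|)/|𝒴| summarizes the former;
the reference extracts this toolkit is modelled after have LD between
about 0.01 and 0.16.

Molecules are identified by canonical SMILES. Structural features are
2048-bit binary ECFP6 fingerprints (Morgan radius 3, no counts),
compared by Tanimoto similarity. Two degenerate conventions are fixed
here because the formalism is silent: the Tanimoto of two all-zero
fingerprints is defined as 1.0 (identical objects; unreachable for real
molecules), and rare-phenotype filtering keeps pairs whose last positive
column was removed (they remain informative all-negative examples).

## Prediction engine

The predictor is f(x) = g_Ω([φ_θ(x¹), φ_θ(x²)]) with one extractor φ_θ
shared by both drugs (weight sharing is structural: a single extractor
object featurizes both) and a fully connected head g_Ω with equal-width
ReLU hidden layers (default 2 × 64) and a sigmoid output per phenotype.
Training minimizes the multilabel binary cross-entropy over **all**
negatives, by Adam (default learning rate 1e-3 in the library, 3e-3 in
the benchmarks; batch 128/256), with early stopping on validation
micro-AUPRC (patience in epochs, best-epoch parameters restored).
Scores are clipped to [1e-7, 1 − 1e-7] inside the loss.

The concatenation [φ(x¹), φ(x²)] is order-sensitive but DDI labels are
not, so by default every training pair is presented in both orders and
inference averages both orders, making predict(a,b) = predict(b,a)
exactly.

Extractors:

- **ssp_mlp** — the fingerprint is expanded into a structural
  similarity profile (SSP): Tanimoto against a reference panel fixed to
  the unique *training* drugs (never validation/test drugs, so no
  information about unseen drugs leaks into the representation), then a
  batch-normalized ReLU MLP. The SSP is fed to the MLP directly, without
  a PCA step.
- **smiles_cnn** — character embeddings (vocabulary built from the
  training strings plus PAD/UNK; PAD-position embeddings are zeroed so a
  sequence's features are independent of batch padding), stacked
  width-7 'same' convolutions with batch normalization, width-2 masked
  max pooling between layers, and a global masked max pool; a linear
  projection sets the output width.
- **smiles_blstm** — character embeddings through bidirectional LSTM
  layers with state frozen across padded steps; the final forward state
  and the backward state at the first character summarize the string,
  followed by a ReLU projection.
- **graph_gin** — GIN message passing, h ← MLP(h + Σ_neighbours h)
  (ε = 0), with mean pooling over atoms. Node features are element
  one-hot (+ catch-all), capped degree one-hot and an aromaticity flag;
  bond features are not used. Atoms are renumbered to canonical ranks
  when the graph is built, so the representation is *bitwise* invariant
  to the atom order of the input SMILES — the mechanism that makes
  graph models insensitive to SMILES enumeration, in contrast to the
  sequence extractors.

The engine is a ~400-line NumPy reverse-mode autodiff core with fused
convolution/pooling/batch-norm kernels, single precision by default
(switchable; the numerical gradient checks run in float64). All
randomness flows through named PCG64 streams seeded from the recorded
run seed, so training is bit-reproducible on a given machine.

## Evaluation schemes and audit

`random_split` shuffles a canonically sorted pair list (file order never
leaks) and cuts at the pair fractions. `drug_disjoint_split` partitions
*drugs* at the given fractions into (D_tr, D_va, D_te) and derives both
drug-disjoint schemes from one partition: shared train = pairs inside
D_tr; one-unseen validation/test = pairs joining a training drug with a
D_va/D_te drug; both-unseen validation/test = pairs inside D_va/D_te;
everything else is unused. The two schemes therefore share one training
set per seed — one trained model serves both — and their test sets are
mutually exclusive. Splits are driven by drug fractions because pair
counts scale quadratically (achieved pair counts are reported, not
targeted). Drugs whose every pair lands in unused are reported, not
rebalanced.

The SS/SU/UU audit counts, for each evaluated pair, how many of its
drugs occur in the training pairs: by construction one-unseen test sets
are pure SU and both-unseen pure UU, while random test sets are almost
pure SS whenever each drug occurs in several pairs. `validate_split`
checks disjointness, exhaustiveness and these composition rules and
returns machine-readable violations.

Metrics: AUPRC is the step-wise sum Σ_n (R_n − R_{n−1}) P_n over
descending unique score thresholds — no trapezoidal or linear
interpolation — and AUROC is the tie-corrected Mann–Whitney rank
statistic. Micro aggregates flatten the (pair, phenotype) matrix; macro
is the unweighted mean over phenotypes that have both a positive and a
negative in the evaluated subset; degenerate phenotypes are listed and
excluded. Frequency binning stratifies phenotypes by their training-set
frequency into half-open percent intervals (default edges 0, 11, 22,
33, 44, with a warned catch-all top bin). Scheme gaps are reported as
μ1 = random − one-unseen, μ2 = random − both-unseen,
μ3 = one-unseen − both-unseen (μ2 ≡ μ1 + μ3).

A caveat worth stating explicitly: micro-averaged AUROC is inflated by
skewed per-phenotype base rates — a model that merely ranks phenotypes
by frequency already beats 0.5. Chance-level readings are therefore
only meaningful against equalized marginals, which is how the
non-learnability benchmark below is constructed.

## Robustness tooling

**Randomized-SMILES augmentation.** `enumerate_smiles` draws randomized
atom-order SMILES (with replacement when a molecule admits few
variants); every variant canonicalizes back to the input.
`augment_dataset` replicates each training pair n_variants times
(replicate 0 canonical, the rest independently sampled variants for
both drugs); labels, pair identity and the evaluation partitions are
untouched. Training can consume the flat n-fold view directly, or — via
`augment_groups` and the trainer's `example_groups` argument — by
epoch-wise variant cycling (epoch e uses variant group e mod n), which
keeps the per-epoch optimization budget identical across n settings.
The benchmarks use cycling: presenting all n variants every epoch
multiplies gradient steps by n, and at desk scale that extra compute
lifts the easy scheme as much as the hard one, drowning the
regularization signal the comparison is after.

**MMD diagnostics.** Distribution shift between drug sets is measured
with Gaussian-kernel maximum mean discrepancy (biased V-statistic,
median pairwise-distance bandwidth heuristic unless overridden). Drug
features are the trained extractor's embeddings, or ECFP6 fingerprints
as an accepted model-free fallback (used in the benchmark, where no
trained model should be in the loop).

**Triage and similarity distributions.** The database-validation scan
flags (label 0, score ≥ 0.7) cells as potential missing interactions
and (label 1, score ≤ 0.1) cells as potential mislabels, sorted by
score. For confusion-category analysis the binarization threshold is
0.5, and each test pair's similarity to the training evidence is the
*maximum* pair similarity over positive training pairs of the same
phenotype — nearest-neighbour aggregation, chosen because the question
is whether any trusted training pair resembles the candidate. Pair
similarity itself is 0.5·max(t(a,c), t(a,d)) + 0.5·max(t(b,c), t(b,d)),
which is deliberately not symmetric in its two pair arguments (it scores
how well the first pair is covered by the second).

## Multitask learning

The auxiliary task regresses a transcriptional-response similarity
score in [−100, 100] per drug pair through a single linear head on the
same concatenated pair embedding (symmetrized like the main head).
Scores are scaled to [−1, 1] by default and the auxiliary weight λ
defaults to 1.0 — both are declared choices; the joint loss is
BCE + λ·MSE. Protocols: C1 draws one shuffled stream over the union of
DDI and auxiliary pairs and masks each task's loss to its labelled rows
(with λ = 0 and no auxiliary-only pairs this reproduces single-task
training batch-for-batch); C2 alternates task-specific batches; T1/T2
pre-train the extractor and auxiliary head on MSE, then train the DDI
head with the extractor frozen (T1 — batch-norm statistics frozen too)
or trainable (T2). Early stopping always monitors the DDI validation
metric only.

## Synthetic study conditions

`generate_molecules` assembles unique drug-like molecules from a fixed
fragment grammar — ring cores (benzene, pyridine, cyclohexane,
naphthalene, piperidine, thiophene, furan, oxane, quinoxaline,
pyrrolidine) decorated with 1–4 small substituents drawn from a
cluster-specific palette. Cluster identity = shared core, which gives
controllable structural clusters (mean within-cluster Tanimoto exceeds
between-cluster). The grammar guarantees chemical validity without a
rejection loop; molecules are deduplicated by canonical SMILES.

`generate_ddi_dataset` samples a fraction of all unordered pairs and
labels them under one of two regimes:

- **structure**: phenotype j is positive iff a sparse random linear
  functional (32 signed Gaussian weights on informative bits) of the
  pair's fingerprint union exceeds a per-phenotype threshold set at the
  k-th largest score, k ≈ base-rate × m (clamped to keep ≥ 2 positives
  and negatives). Base rates are log-uniform over ~[0.5%, 40%], giving
  the skewed frequency spectrum characteristic of real DDI databases.
  Optional symmetric label-flip noise ε (default 2%) is the noise
  channel; at ε = 0 identical fingerprint unions receive identical
  labels by construction.
- **lookup**: each drug carries a Gaussian latent trait per phenotype
  and a pair is positive iff the two traits sum above the base-rate
  threshold. Labels are deterministic in drug identity and independent
  of structure given identity, so a random split is learnable (a model
  can memorize each training drug's traits through its structure,
  which uniquely identifies it) while drug-disjoint generalization is
  impossible by construction. Note that *unconditional*
  structure–label correlations still exist in this regime — a drug's
  fingerprint identifies the drug — so non-learnability is correctly
  tested as transfer to disjoint drugs, not as zero marginal
  correlation.

`generate_cmap_scores` emits auxiliary pair scores as
−100 + 200·Tanimoto + Gaussian noise (σ = 10 by default), clipped to
the [−100, 100] range: structurally identical pairs sit at the top of
the range and the score correlates strongly with structural similarity,
a noiseless-mechanism stand-in for a transcriptional-similarity source.

## Reproduction benchmarks (`ddikit.benchmarks`)

Problem sizes were chosen so the battery runs in minutes on one CPU
core; all randomness derives from a single base seed.

- **Generalization gap** — 200 drugs, 30 phenotypes, ~2,985 pairs
  (density 0.15), character-CNN, 3 replicate seeds, random vs
  both-unseen micro-AUROC. The structure arm uses the default CNN
  (2 × 32 conv channels, 32-dim embedding output, 64-unit head,
  ≤ 15 epochs); the lookup arm must memorize 200 drugs' traits and
  gets more capacity (64 channels, 48-dim output, 128-unit head,
  ≤ 30 epochs) and a uniform 15% base rate so that chance-level
  micro-AUROC actually reads 0.5 (see the caveat above). Typical
  outcome: structure ≈ 0.85–0.87 random vs 0.68–0.78 both-unseen;
  lookup ≈ 0.88 random vs 0.46–0.50 both-unseen.
- **Augmentation effect** — 150 drugs, 12 phenotypes, ~1,340 pairs,
  default CNN, ≤ 30 epochs with patience 4, gap μ1 on micro-AUROC at
  n_variants ∈ {1, 8} consumed by epoch-wise cycling; 5 replicate
  seeds, each cell averaging two training runs (training noise
  otherwise dominates replicates whose initial gap is small).
  Augmentation consistently narrows μ1.
- **MMD ordering** — 120 clustered drugs (4 clusters), fingerprint
  features: MMD²(train drugs, test drugs) under both-unseen vs random
  splits over 5 seeds. Random-split test drugs largely coincide with
  training drugs, so their discrepancy is near zero; drug-disjoint test
  drugs are a disjoint finite sample and sit strictly higher.

## What the synthetic results do and do not show

The generator reproduces the *structural* features that drive the
methodology: multilabel pairs, skewed phenotype frequencies, structural
clusters, a structure-driven learnable regime and an identity-driven
unlearnable one. It does not attempt pharmacological realism: phenotype
labels have no biological meaning, molecules are small and grammar-
bound, label noise is symmetric, and real databases are larger, more
diverse and biased by reporting practices. Passing the battery
demonstrates that the *machinery* — splitting, metrics, training,
augmentation, diagnostics — behaves as designed and that the
qualitative phenomena (scheme ordering, gap narrowing under
augmentation, shift under drug-disjoint evaluation) emerge when their
causes are present; it does not certify performance numbers on any real
DDI database, which require the original extracts and far longer
training.

## Numerical and degenerate-input choices

- ε for log-clipping in the loss: 1e-7. Ties in metric thresholds:
  unique score values; AUROC uses midranks.
- Tanimoto of two empty fingerprints: 1.0. Empty SSP reference:
  rejected. All-zero prediction rows for pairs outside the scored
  subset: filled with 0.5 (uninformative).
- Quantile thresholds in the generator are rank-based with a ≥ 2
  positives/negatives clamp, so tiny datasets cannot produce degenerate
  phenotype columns; after noise flips a safety pass restores at least
  one positive and one negative per column.
- Early stopping: patience counts consecutive non-improving epochs;
  patience 0 runs exactly one epoch. Divergence (non-finite loss)
  aborts with a diagnostic rather than continuing.
- Experiment cells are cached by a content hash of (dataset digest,
  model config, scheme, seed); reruns with the same output directory
  retrain nothing. Aggregates use the sample (n−1) standard deviation.
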