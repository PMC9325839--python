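# Methods

## Problem and overall design

`promgen` studies whether a character-level SMILES generative model can be
steered, by transfer learning alone, toward multi-target (promiscuous)
compounds — molecules with confirmed activity against several distinct
protein targets — and quantifies that shift with likelihood, retrieval,
similarity, scaffold and classifier analyses. The package implements the
whole chain at desk scale: a synthetic screening universe with a planted
structure–promiscuity signal stands in for a large public-screening
extraction, so every stage runs in minutes on one CPU and every claim the
test suite makes is about quantities the package itself computes.

## Synthetic screening universe

Real screening collections are far too large to regenerate in a test
environment, and no generative description of what distinguishes real
promiscuous chemotypes exists. The generator therefore *plants* a signal:

* Compounds are assembled by linking 2–4 fragments with single bonds
  (first-atom/last-atom attachment, ring-closure digits remapped per slot).
  Fragments are chosen so concatenation is always valid SMILES; assembly
  validity is ~100% and every compound is canonicalized and de-duplicated
  across the whole universe.
* Three classes are built: `multi` compounds contain exactly one
  *promiscuity motif* fragment (furan, thiophene, thiazole or thiolane —
  the only sources of aromatic O/S rings in the library) plus common
  fragments; `single` and `none` compounds are built from the 14 common
  fragments only. Because bond-wise concatenation cannot create rings, a
  motif occurs as a substructure iff its fragment was used, which makes
  motif exclusivity structural; it is additionally verified by RDKit
  substructure matching during generation.
* Class sizes default to 50 : 1000 : 2000 (multi rarest, mirroring the
  strong imbalance of real screening data at roughly 1 : 20 : 40).
* Assay records per compound straddle the curation thresholds: multi
  compounds receive 5–8 active and 10–16 inactive target outcomes, single
  compounds 1 active and 25–35 inactive, none compounds 25–35 inactive.
  The generous inactive counts keep every per-target assay's hit rate near
  1.4%, safely below the 2% artifact filter; active targets are dealt to
  the least-loaded assays so rates do not fluctuate across the cutoff.
  Separate "artifact" assays with ~50% hit rate are appended so the filter
  has real work to do; they are removed before consensus building, which
  also neutralises the conflicting outcomes they carry.
* `inject_noise` flips outcomes independently at a given rate for testing
  the consistency filter.

What the universe does *not* emulate: physicochemical realism (logP,
synthesizability, size distributions), assay panels with correlated
targets, and — most importantly — the unknown, diffuse nature of real
structure–promiscuity patterns. The planted motif is a strong, localized
signal; passing the end-to-end tests shows the machinery can find and
exploit such a signal, not that real promiscuity is this learnable.

## Curation

Given records `(assay_id, compound_id, target_id, outcome)`:

1. **Hit-rate filter** — any assay whose fraction of `active` records
   strictly exceeds `max_hit_rate` (default 0.02) is dropped whole.
   "Higher than 2%" is read literally, so an assay at exactly 2% stays.
   The filter runs *first*, so consensus building only sees
   high-confidence assays; the audit report records this ordering.
2. **Consensus profiles** — per (compound, target), agreeing outcomes
   become one consensus call; disagreement marks the target inconsistent.
   Contradictory duplicate rows *within* one assay are a data-integrity
   error, not an inconsistency.
3. **Class rules** (distinct-target counts, configurable):
   `multi_target` ≥ 5 active; `single_target` exactly 1 active and ≥ 4
   confirmed inactive others; `no_target` 0 active and ≥ 5 inactive;
   anything else, or any compound with an inconsistent target, is
   unassigned and discarded. The four inactive targets backing a
   single-target call must be distinct from each other and from the active
   target (they are distinct target identifiers by construction).
4. **Exclusion hook** — liability filtering (pan-assay interference,
   aggregators, medicinal-chemistry rules) is out of scope as an
   implementation; a pluggable list of SMILES is canonicalized and matched
   instead.
5. **Split** — `n_train` randomly chosen multi-target compounds form the
   fine-tuning set; remaining multi plus all single compounds are test
   sets; the no-target test set is downsampled to the single-target set's
   size when larger. All randomness flows from one split seed.

## Generative model

A GRU language model over SMILES tokens, written directly in NumPy
(embedding → 1+ GRU layers → softmax; teacher forcing; Adam; global
gradient-norm clipping at 5). The implementation is checked against
finite-difference gradients and two closed-form NLL oracles (uniform model:
`L·ln V`; fixed-bias categorical model: hand-computed `−Σ ln p`).

* **Tokenisation**: bracket expressions, `Cl`/`Br` and `%nn` ring closures
  are single tokens; everything else is per-character. The vocabulary is
  frozen after pretraining and padded with all ring-closure digits because
  randomized spellings can open more ring numbers than canonical strings
  use; out-of-vocabulary fine-tuning input fails loudly.
* **NLL** is reported in nats and covers every token after BOS up to and
  including EOS, always on canonical SMILES when scoring compound sets.
* **Pretraining** uses the full universe (canonical spellings);
  **fine-tuning** re-randomizes each training SMILES every epoch
  (fresh-spelling augmentation — redrawn per epoch rather than fixed once,
  the stronger variant). Checkpoints are in-memory snapshots or
  self-describing `.npz` archives (weights, Adam moments, vocabulary,
  hyperparameters, epoch counter); a save/load round-trip reproduces
  sampling bit-for-bit.
* **Sampling** is ancestral with one explicit seed; identical
  (weights, n, seed) give identical output lists, so differences between
  checkpoints sampled with the same seed are attributable to fine-tuning
  alone. Sequences hitting the length cap (default 120 tokens) come back
  unterminated and virtually always fail parsing, i.e. they are counted
  invalid downstream.
* **Desk-scale defaults** (embedding 48, hidden 128, 1 layer, batch 128,
  lr 1e-3, 60 pretraining epochs, 200 fine-tuning epochs, 20,000 samples
  at the first and last evaluated checkpoint) were chosen so a complete
  study takes about a minute per seed on one CPU while pretraining reaches
  ~85% sampled-SMILES validity. Learning rate, batch size and the decision
  to keep the Adam state across the pretrain→fine-tune boundary are
  configuration with these documented defaults.

## Evaluation

* **Batch reduction**: raw strings → RDKit canonicalization (failures
  counted) → de-duplication → partition into reproduced-known vs novel.
* **NLL summaries**: 25%/50%/75% quantiles per set per checkpoint
  (linear-interpolation percentiles).
* **Retrieval**: exact canonical-SMILES reproduction counts and
  percentages per set, counted independently per checkpoint.
* **Neighbors**: ECFP6 (Morgan radius 3, 2048 bits) Tanimoto ≥ 0.6
  (inclusive) between novel generated molecules and set members; reported
  as pair counts, pairs per known compound, and distinct generated
  molecules with a neighbor (the pair/unique ambiguity is resolved by
  emitting both).
* **Scaffolds**: non-generic Bemis–Murcko frameworks (atom/bond types
  retained); acyclic molecules have no scaffold and are excluded from
  denominators. Reported per set and, for the multi-test set, the number
  of scaffolds absent from the training set that were still generated.
* **Classifier**: XGBoost on ECFP6 bits (the fingerprint is chosen for
  consistency with the similarity analysis; the representation is a design
  decision). Positives: the multi-target training set; negatives: equally
  sized random subsets of single/no-target compounds (default 300 + 300);
  held-out evaluation on the multi-test set plus all remaining negatives;
  metrics ROC AUC, MCC and recall at a 0.5 probability threshold. Empty
  generated batches report a missing value, not zero.

## Pipeline

`run_pipeline` executes universe → curation → pretraining → fine-tuning →
sampling → evaluation from one configuration with a single master seed;
every stage draws a named child seed (SHA-256 derivation) and records
output hashes in a manifest, making re-runs no-ops and any stage
independently reproducible. `report` renders the epoch-wise tables and the
five qualitative verdicts (NLL ordering, retrieval ordering, neighbor
gain, novel-scaffold recovery, classifier shift) recomputed from the CSVs.

## Numerical and degenerate-input choices

* float32 weights/activations (float64 option used by gradient tests);
  NLL sums accumulate in float64.
* Sampling inverts the CDF of the softmax; no tokens are masked, so
  sampled frequencies match `exp(−NLL)` exactly (verified on a tiny
  enumerable model).
* Tanimoto of two empty fingerprints is defined as 0.
* Empty SMILES strings and parse failures canonicalize to "invalid", never
  raise mid-batch.
* `fine_tune(n_epochs=0)` is the identity; `sample(n=0)` returns `[]`.

## Known limitations

* The planted-motif universe makes the classification task much easier
  than real promiscuity prediction; held-out AUC near 1 on synthetic data
  says nothing quantitative about real screening data.
* The model is small and the SMILES grammar of the fragment universe is
  narrow; validity and retrieval numbers are not comparable to models
  pretrained on millions of drug-like molecules.
* Retrieval orderings at desk scale are stochastic properties; the
  acceptance tests therefore require them to hold jointly in at least 4 of
  5 independent seeds rather than in every run.
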