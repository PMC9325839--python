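# promgen

Transfer-learning a SMILES generative model toward **multi-target
(promiscuous) compounds**, with high-confidence assay curation and
per-epoch evaluation of the resulting distribution shift.

## The problem

True multi-target activity underlies polypharmacology — drugs acting on
several proteins at once — and is hard to design for. If structural
patterns distinguish promiscuous from single-target compounds, a
character-level generative model fine-tuned on known multi-target
compounds should pick those patterns up without ever being told about
activity, and start producing multi-target candidates preferentially.
`promgen` implements that experiment end to end for computational
chemists: curating qualitative screening outcomes into multi-, single-
and no-target compound classes, fine-tuning a SMILES recurrent language
model on the multi-target training set, and measuring the shift.

A synthetic screening universe with a *planted* structure–promiscuity
signal (motif fragments exclusive to the multi-target class) replaces the
large public-screening extraction, so the full study runs in about a
minute per seed on one CPU and is fully reproducible from a single seed.

## Model and analyses

The generator is a GRU language model over SMILES tokens trained by
teacher forcing to minimise the sequence negative log-likelihood
NLL(s) = −Σᵢ ln p(tᵢ | t₁…tᵢ₋₁) in nats, with the Adam optimizer
(NumPy implementation, finite-difference-checked gradients). Fine-tuning
continues training on the multi-target split with each SMILES re-spelled
by random atom ordering every epoch. Checkpoints are sampled with one
shared seed (identical models ⇒ identical samples), and each batch is
evaluated by:

1. **NLL quartiles** per compound set (canonical SMILES);
2. **retrieval** — exact canonical reproduction of known compounds;
3. **fingerprint neighbors** — ECFP6/2048, Tanimoto ≥ 0.6, reproductions
   excluded, normalised per known compound;
4. **Bemis–Murcko scaffold** recovery, including test-set scaffolds absent
   from training;
5. an **XGBoost promiscuity classifier** on ECFP6 bits scoring the
   generated compounds.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```bash
promgen run --config run.yaml     # or: python -m promgen.cli …
promgen report --run-dir runs/demo
```

with `run.yaml`:

```yaml
seed: 1
out_dir: runs/demo
```

Defaults build a 50/1000/2000 multi/single/none universe, curate it
(2% assay hit-rate cutoff, 30-compound training split), pretrain 60
epochs, fine-tune 200 epochs, and sample 20,000 SMILES at the first and
last checkpoints (~1.5 min on one CPU). The report (actual output,
seed 1) includes:

```
Exact retrieval per epoch and set
---------------------------------
 epoch         set  n_set  retrieved       pct
     0 multi_train     30          5 16.666667
     0  multi_test     20          1  5.000000
     0 single_test   1000        565 56.500000
     0   none_test   1000        451 45.100000
   200 multi_train     30         20 66.666667
   200  multi_test     20         11 55.000000
   200 single_test   1000        102 10.200000
   200   none_test   1000         63  6.300000
```

Before fine-tuning the model — pretrained on the whole universe, where
multi-target compounds are rarest — reproduces mostly single/no-target
compounds (56.5% / 45.1%) and few multi-target ones (16.7% / 5%). After
200 fine-tuning epochs the ordering inverts: 66.7% of the training set
and 55.0% of the *held-out* multi-target test set are regenerated versus
10.2% / 6.3% for single/no-target compounds — the model has generalised
the planted promiscuity motifs rather than memorised the training set.
The report's verdict block summarises the five qualitative checks
(NLL ordering, retrieval ordering, neighbor gain, novel-scaffold
recovery, classifier shift), all `PASS` in this run; the classifier
reaches ROC AUC 0.998 on held-out compounds and the fraction of generated
molecules it labels multi-target rises from 1.9% to 61.1%.

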