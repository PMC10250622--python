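# helixcpi

Compound-protein interaction (CPI) prediction for class A G protein-coupled
receptors (GPCRs) from transmembrane-region sequence encodings.

## The problem

Class A GPCRs — the largest drug-target family — bind ligands inside their
seven-transmembrane (7TM) helical bundle, sometimes gated by extracellular
loop 2 (ECL2). Because the family is full of orphan receptors, per-protein
activity models are often impossible, and CPI prediction (a binary
classifier over compound-receptor pairs, labelled positive when
pIC50/pEC50 >= 6) is the standard formulation. Generic CPI encoders embed
the *whole* protein sequence, including termini and intracellular stretches
that can never touch a ligand; those regions act as noise. This package
implements a family-specific encoder that consumes only the annotated
TM1-TM7 subsequences — optionally plus ECL1/ECL2/ECL3 — so the model sees
exactly the regions domain knowledge says matter.

## The model

* **Protein.** Each annotated region is tokenised into overlapping 3-mers
  and embedded by skip-gram word2vec (p x 100 per region, p the tokenised
  length). Regions are zero-padded to the receptor's maximum region length
  p_max, passed through region-specific 1D-convolution + gated-linear-unit
  blocks, concatenated in anatomical order (loops at their anatomical
  slots), positionally encoded, and refined by one self-attention block.
  The output is a (p_max x R) x 64 matrix, R = 7 (TM-only) or 8 (one loop).
* **Compound.** RDKit parses the SMILES; each heavy atom gets a
  34-dimensional feature vector, and three rounds of normalised-adjacency
  neighbour averaging with learned maps give an a x 64 atom embedding
  (a = heavy-atom count).
* **Decoder.** Three layers of multi-head cross-attention (atom queries,
  protein keys/values) with feedforward/residual/layer-norm, attention
  pooling over atoms, and a sigmoid head produce the interaction
  probability. Cross-attention weights can be retained and aggregated into
  per-residue and per-region importance profiles.
* **Evaluation.** Tie-aware rank AUC (verified against exhaustive pair
  enumeration), per-subfamily AUC, and one-sided paired t-tests across
  split seeds. Models are selected at the best validation-AUC epoch.

Everything runs on a small numpy reverse-mode autodiff engine bundled with
the package; no GPU or deep-learning framework is needed, and training is
deterministic for a fixed seed.

A bundled synthetic-data generator emulates the full input surface
(FASTA + UniProt-style region TSV + membership list + interaction TSV)
with a planted, region-localised binding rule: receptors carry a short
pocket motif in TM3/TM6 (or ECL2), compounds belong to matching scaffold
classes, and a pair is positive exactly when motif class matches compound
class, flipped with 10% label noise. At that noise the best achievable
AUC is 0.90.

## Worked example

```python
import helixcpi as hx
from helixcpi.encoder import EncoderConfig
from helixcpi.training import TrainConfig

# synthetic benchmark: 16 receptors, 32 compounds, 500 pairs, 10% noise
data = hx.generate(hx.GeneratorConfig(n_proteins=16, n_compounds=32,
                                      n_pairs=500, seed=7))
records = hx.filter_ligand_bias(data.records)
train_recs, val_recs, test_recs = hx.make_splits(records, hx.SplitSpec(seed=0))
print(hx.summarize(records))

model, log = hx.train(EncoderConfig(), train_recs, val_recs, data.receptors,
                      TrainConfig(epochs=12, batch_size=32, seed=0))
report = hx.evaluate(model, test_recs, data.receptors,
                     subfamilies=data.subfamilies)
print(f"selected epoch {log.selected_epoch}, "
      f"validation AUC {log.best_val_auc:.3f}, test AUC {report.auc:.3f}")
```

which prints

```
DatasetSummary(n_proteins=16, n_compounds=32, n_interactions=500, n_positive=149, n_negative=351)
selected epoch 6, validation AUC 0.680, test AUC 0.784
```

The positives are the class-matched pairs that survived the 10% label
noise (the small receptor/compound pools cap the matched fraction), and
the planted rule is already partly recovered after a dozen epochs on a
400-record training split — the noise ceiling for this benchmark is 0.90.
The full-size benchmark in `tests/test_acceptance.py` (50 receptors,
80 compounds, 2000 pairs) reaches a test AUC above 0.85 within 30 epochs. The same pipeline is available from
the shell:

```bash
helixcpi simulate --seed 7 --out data/
helixcpi build-dataset --interactions data/interactions.tsv \
    --fasta data/receptors.fasta --regions data/regions.tsv \
    --class-a data/class_a.txt --seed 0 --mode random --out splits/
helixcpi train --split-dir splits/ --fasta data/receptors.fasta \
    --regions data/regions.tsv --include-ecls ECL2 --epochs 30 --out run/
helixcpi evaluate --checkpoint-dir run/ --test splits/test.tsv \
    --fasta data/receptors.fasta --regions data/regions.tsv --out report.json
```

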