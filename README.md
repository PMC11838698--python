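# coscreen

Drug–target co-embedding for fast interaction prediction, virtual-screening
evaluation, and library-scale retrieval.

Drugs are featurized as Morgan fingerprints (2048 bits, radius 2 by
default); proteins as per-residue embedding matrices from a pluggable
provider (a deterministic context-sensitive toy encoder ships built in;
real protein-language-model adapters register through the same interface).
A multi-head attention pooler collapses residue embeddings to one vector,
and modality-specific MLPs project both sides into a shared latent space
where

- **interaction probability** = `sigmoid(alpha * cosine(Zd, Zt))`
  (`alpha = 5`), and
- **predicted affinity (pK)** = `Zd . Zt` on the raw latents.

Around that core the package provides: negative-sampling dataset assembly
with Kd-threshold labeling, train/val/test splitting (random, unseen-drug,
unseen-target, and homology-aware with a brute-force audit), screening
metrics (AUROC, AUPR, BEDROC, enrichment factors) validated against
independent oracles, an exact top-k vector index, residue-level attention
interpretation against bound structures, and a synthetic-data generator
with planted latent structure and planted sequence motifs so everything is
testable offline.

The model is implemented in NumPy with hand-written gradients (the network
is small enough that no autodiff framework is needed); training is fully
deterministic for a given seed.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` implements the acceptance criteria; the
parameter-recovery tests train a model on the default synthetic dataset
(500 drugs x 200 targets, 20k pairs) and take several minutes on one CPU.

## CLI

Everything runs offline on synthetic data:

```sh
coscreen simulate data/ --seed 0                      # generate a dataset
coscreen featurize data/ features.npz                 # residue embeddings
coscreen train data/ model.npz --epochs 30            # fit the classifier
coscreen score model.npz data/ scores.tsv             # score pairs
coscreen evaluate scores.tsv metrics.tsv              # AUROC/AUPR/BEDROC/EF
coscreen index build model.npz data/ index/           # build a drug index
coscreen index query index/ model.npz data/ --query-id target_00000 --k 10
coscreen screen model.npz data/ screen.tsv --k 10     # top-k per target
coscreen attention model.npz data/ attention.tsv      # motif enrichment
coscreen attention model.npz data/ report.tsv --pdb bound.pdb \
    --pdb-out colored.pdb                             # binding-site analysis
```

Each command writes a RunManifest (resolved config, input digests, seeds)
next to its outputs; deterministic commands reproduce primary outputs byte
for byte when re-run.

## Package layout

```
src/coscreen/
  featurizers.py   fingerprints, residue-embedding providers, toy encoder
  model/           attention pooling, projection MLPs, scoring heads, I/O
  training/        labels, negative sampling, splits + audits, fitting loop
  metrics.py       AUROC / AUPR / BEDROC / enrichment factor
  retrieval.py     exact top-k vector index + persistence
  attention.py     binding residues, enrichment reports, PDB export
  synthetic.py     planted-structure dataset generator
  cli.py           typer CLI wiring the above
```
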