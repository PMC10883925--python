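# nadescreen

Stability screening for multi-component (deep-eutectic-style) mixtures with a
small transfer-learning pipeline:

1. **Pre-training** — a compact replaced-token-detection transformer pair
   (generator with a masked-token head + larger discriminator) is trained on a
   reaction corpus of SMILES lines (`reactants>products`).
2. **Fine-tuning** — the discriminator gets a fresh two-class softmax head and
   is trained on a labeled mixture database (stable = 1 / unstable = 0).
   Mixtures are encoded as single lines with stoichiometric-ratio tokens:
   `[R2]CCO.[R1]O` is ethanol : water at 2 : 1.  Training defaults follow the
   reference protocol: max sequence length 128, batch 32, learning rate 4e-5.
3. **Augmentation** — random 3–5-component mixtures over the compound library
   at coefficients 1–10 are labeled unstable and added to the training set to
   counter the 4:1 class imbalance.
4. **Screening** — a generator produces a large unlabeled candidate universe,
   the classifier scores every mixture (softmax stability probability,
   stable means score strictly above 50%), results can be filtered by a query
   compound, binned into 5-point score intervals, and exported as CSV.

Real corpora of this kind are not redistributable, so `nadescreen.syndata`
builds a fully synthetic stand-in world: a 198-compound library of
valid-by-construction acyclic C/O/N SMILES, a deterministic latent stability
rule visible in the token stream (coefficient-weighted oxygen window +
nitrogen minimum), a 1000-mixture labeled DB at 800/200, and a small reaction
corpus.  Everything — including the transformer, which is implemented directly
on NumPy with hand-written backprop — is deterministic under fixed seeds.

## CLI

One entry point, `nadescreen`, with the pipeline subcommands:

```sh
nadescreen synth --what library --seed 1 --out library.csv
nadescreen synth --what db --seed 1 --out db.csv
nadescreen synth --what corpus --seed 1 --n 500 --out corpus.txt
nadescreen pretrain --corpus corpus.txt --vocab-size 30000 --seed 1 --out model_001
nadescreen augment --db db.csv --library library.csv --n 100 --seed 1 --out negatives.csv
nadescreen finetune --model model_001 --train train.csv --test test.csv \
    --epochs 15 --max-seq-length 128 --batch-size 32 --lr 4e-5 --out classifier
nadescreen universe --n 1000000 --library library.csv --seed 1 --out universe.txt
nadescreen screen --model classifier --universe universe.txt --contains CCO --out hits.csv
nadescreen evaluate --model classifier --test test.csv --out metrics.csv
nadescreen demo --seed 7 --out demo_out     # end-to-end desk-scale run
```

Flags can come from a flat YAML file via `--config`; CLI flags win.  Every run
writes a `*.provenance.json` record (parameters, seed, versions) beside its
outputs.  All subcommands are importable library functions with identical
behavior.

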