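# retroseq

Single-step retrosynthesis as machine translation: given the SMILES string
of a product molecule (optionally tagged with one of 10 reaction-class
tokens), an attention-only encoder–decoder proposes ranked reactant sets,
and an evaluation layer scores them the way the retrosynthesis-translation
literature does — canonical exact match at top-N, grammatical-validity
analysis, substructure categorization of failures, and expert-annotation-
corrected ("true") accuracy.

The package is aimed at researchers studying *how* translation models
behave on retrosynthesis — the scaling of top-N accuracy, the effect of
token-budget batch sizes and checkpoint averaging, and the anatomy of
invalid or "wrong but plausible" predictions — on desk-scale, fully
reproducible synthetic benchmarks.

## The model

A product SMILES is tokenized at atom level (`Cl`, `Br`, `[nH]`, `%12`,
ring digits and bond symbols are single tokens) and translated into the
'.'-joined reactant SMILES with a standard attention-only stack: N encoder
layers (multi-head self-attention + feed-forward, post-norm residuals) and
N decoder layers adding causally masked self-attention and cross-attention,
with sinusoidal positional encodings

    PE(pos, 2i) = sin(pos / 10000^(2i/d)),  PE(pos, 2i+1) = cos(...)

and scaled dot-product attention `softmax(QK^T / sqrt(d_k)) V`.  Training
uses token-budget batching (a "batch size" is a token count), Adam with an
inverse-square-root warmup schedule, and checkpoint averaging — the
element-wise mean of the last k saved parameter sets — at inference.
Decoding is beam search with deterministic lexicographic tie-breaks; a
prediction counts as correct only if its canonical molecule multiset
equals the recorded reactants'.

Everything numerical runs on a small reverse-mode autodiff core over numpy
(`retroseq._autograd`), gradient-checked against finite differences.

## Worked example

Generate a synthetic benchmark (five reaction-family templates, 516
single-product records, held out by fragment *combination* so the test set
requires recombination), train the desk-scale model, and evaluate:

```bash
retroseq pipeline --config examples/desk.yaml --out runs/desk
```

or in Python:

```python
from retroseq import ModelConfig, TrainConfig, generate_dataset
from retroseq.training import build_corpus_vocabulary, train, average_checkpoints
from retroseq.decoding import predict_reactants

split = generate_dataset(seed=1)
vocab = build_corpus_vocabulary(split.all_records)
ckpts = train(split, vocab,
              ModelConfig(n_layers=2, d_model=128, n_heads=4, d_ff=256, max_len=64),
              TrainConfig(batch_tokens=1200, max_steps=3500, checkpoint_interval=100,
                          warmup_steps=200, lr_scale=0.5, averaging_window=12,
                          label_smoothing=0.1, seed=1))
params = average_checkpoints(ckpts, 12)
rec = split.test[0]
for cand in predict_reactants(params, ModelConfig(), rec.product, vocab,
                              class_id=rec.class_id, n=3):
    print(cand.rank, f"{cand.score:.3f}", cand.smiles)
```

The evaluation layer also renders markdown tables (per-class accuracy,
failure categories such as `R-Boc` / `R-CF3` / `R-tBu` and
fused/spiro/bridged ring systems, and the corrected-accuracy breakdown)
via `retroseq report`.

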