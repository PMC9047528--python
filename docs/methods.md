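# Methods

## Problem and model

`retroseq` treats single-step retrosynthesis as text translation: the
"sentence" to translate is the SMILES string of a product molecule
(optionally prefixed with a reaction-class token `<RX_1>`..`<RX_10>`), and
the "translation" is the '.'-joined SMILES of its reactant set.  The model
is the standard attention-only encoder-decoder.  Both stacks have N
identical layers; an encoder layer is

    x  <- LayerNorm(x + MultiHeadSelfAttention(x))
    x  <- LayerNorm(x + FeedForward(x))

and a decoder layer inserts a causally masked self-attention sub-layer and a
cross-attention sub-layer over the encoder memory.  Normalization follows
the residual sum (post-norm).  Token embeddings are scaled by sqrt(d_model)
and summed with the sinusoidal positional table

    PE(pos, 2i)   = sin(pos / 10000^(2i/d_model))
    PE(pos, 2i+1) = cos(pos / 10000^(2i/d_model)),

and the output projection is the transposed embedding matrix plus a bias.
Scaled dot-product attention masks disallowed (query, key) pairs with -inf
before the softmax, so masked weights are exactly zero; PAD positions are
masked out of encoder self-attention and of cross-attention, which keeps
non-pad memory rows bit-identical under padding.

The numerical core is a small reverse-mode autodiff over numpy arrays
(`retroseq._autograd`) providing exactly the primitives the model needs
(broadcast arithmetic, batched matmul, softmax, layer norm, embedding
gather, a fused cross-entropy).  Every backward rule is checked against
central finite differences in the test suite.  All computation is float64;
at the desk scales this package targets, numerical robustness and exact
reproducibility were judged worth more than the throughput of lower
precision.

## Tokenization and matching semantics

SMILES are tokenized at atom level with the regular-expression scheme
conventional for molecular translation: bracket atoms `[...]`, the
two-letter halogens `Cl`/`Br`, two-digit ring closures `%NN`, and every
remaining symbol (including stereo marks `/ \ @`) are single tokens.
Concatenating tokens always reproduces the input string.  Vocabularies are
laid out deterministically: PAD=0, BOS, EOS, UNK, then class tokens, then
corpus tokens sorted lexicographically.

A prediction is scored correct iff the *multiset* of its canonical
molecules (RDKit canonical SMILES, computed per '.'-separated component)
equals that of the recorded reactants.  Multiset rather than set semantics
is the committed choice: a reactant required twice must be predicted twice.
Order is irrelevant; a string that fails to parse can never match, but it
stays in the ranked list because the invalidity statistic is reported
separately.  Stereochemistry is preserved and respected in matching; no
stripping is applied.

## Training

"Batch size" is a token budget: greedy in-order packing adds a sequence
pair while `max_len_in_batch x (batch_size + 1) <= batch_tokens`, counting
source plus target tokens because both occupy memory during a step.
Optimization is Adam (beta1 0.9, beta2 0.98, eps 1e-9) under the
inverse-square-root schedule `lr = lr_scale * d_model^-0.5 *
min(step^-0.5, step * warmup^-1.5)` with global-norm gradient clipping at
1.0; teacher-forced cross-entropy ignores PAD positions and supports a
single constant label-smoothing rate.  The optimizer, schedule and dropout
placement are engineering choices documented here because no single
convention is forced by the task.  Two of them mattered a great deal for
the post-norm stack at this scale and are worth recording: the peak
learning rate must stay low (lr_scale 0.5, i.e. peak ~3e-3 — twice that
and optimization plateaus an order of magnitude above its floor), and
label smoothing of 0.1 substantially improves held-out exact-match
accuracy even though the target mapping is deterministic, by discouraging
the overconfident memorization of seen fragment combinations.

Checkpoints are snapshots of the full parameter set at a fixed interval;
`average_checkpoints` takes the element-wise arithmetic mean of the last k,
discarding optimizer state.  At full translation scale the conventional
cadence is 2000-step intervals with k = 20; the desk-scale defaults are a
50-step interval and k = 5.  Averaging matters here for the same reason it
does at scale: late checkpoints oscillate around a minimum and their mean
sits closer to it than any single iterate.

The recovery-study schedule (`retroseq.study`) is batch_tokens 1200,
3500 steps, warmup 200, lr_scale 0.5, label smoothing 0.1, checkpoints
every 100 steps with an averaging window of 12 (covering roughly the last
third of the run).  Small batches at fixed wall time buy more optimizer
updates, which is what the copy-style attention circuits of this task need
to form on a single CPU; dense late averaging smooths the oscillation of
individual iterates and is worth roughly 15-20 accuracy points over the
final checkpoint alone.

## Decoding

Beam search expands length-wise over next-token log-distributions, keeping
`beam_width` partial hypotheses; finished hypotheses (EOS emitted) are set
aside and the search stops when no unfinished hypothesis can still beat the
current n-best bar (scores are additive log-probabilities, hence
non-increasing).  Ties break lexicographically on the token-id sequence so
results never depend on heap order.  There is no length normalization by
default — scores are pure sums — but a penalty exponent is exposed because
top-10 rankings can depend on it.  If nothing finishes within `max_len`,
truncated hypotheses are returned flagged unfinished.  After decoding,
valid candidates that canonicalize to the same molecule multiset are
collapsed to their best rank.

## Evaluation

* Top-N accuracy: fraction of records whose recorded reactant multiset
  matches some candidate of rank <= N; per-class tables restrict the same
  statistic to each reaction class (empty classes are absent, not zero).
* Invalidity: fraction of rank-1 candidates failing to parse, overall and
  per class; validity + invalidity = 1 by construction.
* Ring-system classes from the smallest set of smallest rings, pairwise:
  one shared atom -> spiro, one shared bond -> fused, >= 2 shared atoms not
  all on one bond -> bridged; precedence bridged > spiro > fused;
  multi-fragment strings take the most complex fragment.  The SSSR comes
  from RDKit; the classification rules are this package's.
* Failure categories tag non-matching records by substructure motifs in the
  recorded reactants and product: Boc (tert-butyl carbamate), CF3, tBu, and
  the fused/spiro/bridged ring classes.  The SMARTS registry is versioned
  in `evaluation.SUBSTRUCTURE_REGISTRY`; Boc takes precedence over tBu (a
  tert-butyl inside a Boc match is not double-counted).  Category rates use
  the failed-record count as denominator and a record counts once per
  category it belongs to, so the total row can exceed the failed count.
* Corrected ("true") accuracy adds expert plausibility annotations to the
  exact matches.  Both forms are reported: the count-based fraction
  (exact + plausible) / n_test, and the rate-sum form in which the
  exact-match and plausible percentages are rounded to one decimal
  independently and then summed — the convention used when quoting headline
  "true" accuracies assembled from separately rounded tables.  Annotating a
  record that already matches exactly is rejected as double counting.

## Synthetic data generator

The generator emulates the statistical shape of the USPTO-derived
retrosynthesis benchmarks: single-product records, 1-3 reactants, opaque
class labels, dot-separated multi-molecule fields in TSV.  Five templates
cover common medicinal-chemistry families — esterification (the
ester <-> acid/alcohol pair), SN2 etherification, Boc protection, amide
condensation (with a carbodiimide third reactant), and aryl-aryl
coupling — instantiated by plain string substitution of fragments at marked
attachment points, so records are auditable by eye.  Alphabets are sized to
yield 516 records.  The ester family is generated in the esterification
direction (product ester -> acid + alcohol) because the reverse direction
is underdetermined at the product: an acid does not identify which ester it
came from, and a generator whose target is not a function of its input
would make exact-match recovery ill-posed by construction.

Held-out splitting removes whole slot *combinations* per template, never
individual fragments: every fragment in the test set has been seen in
training, but never in that combination, so test accuracy measures
recombination rather than memorization.

What the generator does **not** emulate: real reaction-center chemistry
(substitutions are textual), stereochemistry, reagent/condition context,
the long-tail length distribution of patent SMILES, and chemically
ambiguous retrosynthetic alternatives.  Passing the recovery study
therefore shows that the translation stack can learn a deterministic
compositional string mapping from a few hundred examples — not that it
attains any particular accuracy on patent-scale data.

## Numerical and procedural choices

* -inf masking with max-shifted softmax gives exactly-zero masked weights;
  a fully masked query row is rejected as a contract violation.
* Glorot-uniform initialization from a recorded seed; LayerNorm gains start
  at 1, biases at 0.
* Fisher-Yates shuffles seeded from the user seed make splits portable
  across platforms; floor-based split sizes send the remainder to train.
* Beam tie-break: lexicographic on token ids; dedup keeps the best rank.
* Training divergence (non-finite loss) aborts, retaining the checkpoints
  collected so far.
* Rendered tables round percentages to one decimal; JSON keeps full
  precision.

## Known limitations

* Throughput: the numpy core is single-threaded BLAS at small matrix
  sizes; wall-clock budgets, not statistical considerations, set the
  desk-scale step counts.
* The grammar-recovery study uses greedy-equivalent small beams for top-1;
  large-beam top-10 statistics on the synthetic set are cheap but not part
  of the recovery property.
* Duplicate reactions across splits are not deduplicated by default
  (`make_splits` exposes no dedup; the generator's combination-level
  holdout makes it unnecessary there).
* The plausibility workflow only does bookkeeping: the chemical judgment
  itself is expert input, supplied as an annotations TSV.
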