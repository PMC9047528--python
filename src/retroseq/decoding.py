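"""Beam-search decoding: product SMILES in, ranked reactant candidates out.

Scores are pure sums of token log-probabilities (no length normalization by
default; a penalty knob is exposed because top-10 rankings can depend on
it).  Ties are broken lexicographically by token-id sequence so results do
not depend on heap iteration order.  Grammatically invalid candidate strings
stay in the ranked list — they feed the invalidity statistic — but they can
never match ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lang import CanonicalizationError, Vocabulary, canonicalize, is_valid_smiles
from .model import ModelConfig, batched_next_logprobs, encode_batch
from .training import encode_source


@dataclass(frozen=True)
class BeamCandidate:
    """A decoded hypothesis: BOS ... EOS token ids with a cumulative score."""

    token_ids: tuple[int, ...]
    score: float  # sum of token log-probabilities, <= 0
    rank: int
    smiles: str = ""
    finished: bool = True


def beam_search(
    params: dict,
    config: ModelConfig,
    source_ids,
    beam_width: int = 10,
    max_len: int = 64,
    n_best: int = 10,
    bos_id: int = 1,
    eos_id: int = 2,
    length_penalty: float = 0.0,
) -> list[BeamCandidate]:
    """Length-wise beam expansion over next-token log-probabilities.

    Returns up to `n_best` finished candidates sorted by descending score
    (rank 1..n, lexicographic token-id tie-break).  If nothing finishes
    within `max_len` total tokens, truncated candidates are returned flagged
    ``finished=False``.
    """
    if not (beam_width >= n_best >= 1):
        raise ValueError("need beam_width >= n_best >= 1")
    src = np.asarray(source_ids)[None, :]
    memory, key_ok = encode_batch(src, params, config)
    mem = memory.value

    def sort_key(item):  # (seq, score)
        return (-item[1], item[0])

    frontier: list[tuple[tuple[int, ...], float]] = [((bos_id,), 0.0)]
    done: list[tuple[tuple[int, ...], float]] = []

    while frontier:
        prefixes = np.array([seq for seq, _ in frontier])
        mem_b = np.repeat(mem, len(frontier), axis=0)
        ok_b = np.repeat(key_ok, len(frontier), axis=0)
        logprobs = batched_next_logprobs(mem_b, ok_b, prefixes, params, config)
        expansions: list[tuple[tuple[int, ...], float]] = []
        for (seq, score), lp in zip(frontier, logprobs):
            for tok in range(lp.shape[-1]):
                expansions.append((seq + (tok,), score + float(lp[tok])))
        expansions.sort(key=sort_key)
        kept = expansions[:beam_width]
        frontier = []
        for seq, score in kept:
            if seq[-1] == eos_id:
                done.append((seq, score))
            elif len(seq) < max_len:
                frontier.append((seq, score))
            else:
                done.append((seq, score))  # truncated, flagged below
        if len(done) >= n_best and frontier:
            done.sort(key=sort_key)
            bar = done[n_best - 1][1]
            # additive log-probs never increase, so a frontier candidate
            # already below the n-best bar can be discarded
            frontier = [c for c in frontier if c[1] >= bar]
            if not frontier:
                break

    if length_penalty:
        # optional length normalization of final ranking; 0.0 keeps pure sums
        done.sort(key=lambda it: (-(it[1] / max(len(it[0]) - 1, 1) ** length_penalty), it[0]))
    else:
        done.sort(key=sort_key)
    out = []
    for i, (seq, score) in enumerate(done[:n_best], start=1):
        out.append(
            BeamCandidate(
                token_ids=seq,
                score=score,
                rank=i,
                finished=seq[-1] == eos_id,
            )
        )
    return out


def predict_reactants(
    params: dict,
    config: ModelConfig,
    product: str,
    vocab: Vocabulary,
    class_id: int | None = None,
    n: int = 10,
    beam_width: int | None = None,
    max_len: int = 64,
) -> list[BeamCandidate]:
    """Ranked reactant-SMILES candidates for one product.

    Valid candidates that canonicalize identically are collapsed to the
    best-ranked one and later ranks are promoted; exactly min(n, available)
    candidates are returned.
    """
    beam_width = beam_width if beam_width is not None else max(n, 1)
    source = encode_source(product, vocab, class_id)
    raw = beam_search(
        params, config, source,
        beam_width=max(beam_width, n), max_len=max_len, n_best=max(beam_width, n),
        bos_id=vocab.bos_id, eos_id=vocab.eos_id,
    )
    seen: set[str] = set()
    out: list[BeamCandidate] = []
    for cand in raw:
        smiles = "".join(vocab.decode(cand.token_ids))
        if is_valid_smiles(smiles):
            try:
                key = ".".join(sorted(canonicalize(p) for p in smiles.split(".")))
            except CanonicalizationError:
                key = smiles
        else:
            key = smiles
        if key in seen:
            continue
        seen.add(key)
        out.append(BeamCandidate(cand.token_ids, cand.score, len(out) + 1,
                                 smiles=smiles, finished=cand.finished))
        if len(out) == n:
            break
    return out
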