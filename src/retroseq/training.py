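"""Training loop: token-budget batching, Adam optimization, checkpointing.

A "batch size" here is a *token* budget, not a sequence count: greedy
in-order packing adds a sequence to the current batch only while the padded
cost (batch-max length x batch size, recomputed per addition) stays within
the budget.  Packing counts source + target tokens combined, since both
sides occupy memory during a step.

Checkpoints are emitted at a fixed step interval; `average_checkpoints`
takes the element-wise arithmetic mean of the last k parameter sets, the
standard trick for squeezing extra accuracy out of a long translation run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._autograd import Tensor
from .data import DatasetSplit, ReactionRecord
from .lang import Vocabulary, class_token, tokenize_smiles
from .model import ModelConfig, check_shapes, decode_batch, encode_batch, init_parameters

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    batch_tokens
        Token budget per batch (source + target tokens combined).
    max_steps
        Number of optimizer steps; 0 trains nothing but still emits the
        initialization checkpoint.
    checkpoint_interval
        Steps between checkpoints.  Desk-scale default is 50; full-scale
        translation runs conventionally use 2000-step intervals with a
        20-checkpoint averaging window.
    averaging_window
        Default k for checkpoint averaging.
    warmup_steps / lr_scale
        Inverse-square-root schedule: lr = lr_scale * d_model^-0.5 *
        min(step^-0.5, step * warmup^-1.5).
    """

    batch_tokens: int = 2000
    max_steps: int = 400
    checkpoint_interval: int = 50
    seed: int = 0
    warmup_steps: int = 100
    lr_scale: float = 1.0
    averaging_window: int = 5
    grad_clip: float = 1.0
    label_smoothing: float = 0.0
    use_class_token: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Checkpoint:
    """A snapshot of the run at one optimizer step."""

    step: int
    params: dict[str, np.ndarray]
    optimizer_state: dict
    val_loss: float


# ---------------------------------------------------------------------------
# sequence encoding (shared with decoding)


def encode_source(product: str, vocab: Vocabulary, class_id: int | None = None) -> list[int]:
    """Source ids: optional reaction-class token, product tokens, EOS."""
    tokens = tokenize_smiles(product)
    unknown = sorted({t for t in tokens if t not in vocab})
    if unknown:
        raise ValueError(f"tokens not in vocabulary: {unknown}")
    prefix = []
    if class_id is not None:
        ct = class_token(class_id)
        if ct not in vocab:
            raise ValueError(f"class token {ct} not in vocabulary")
        prefix = [vocab.token_to_id[ct]]
    return prefix + vocab.encode(tokens) + [vocab.eos_id]


def encode_target(reactants_str: str, vocab: Vocabulary) -> list[int]:
    """Target ids: BOS, reactant tokens ('.'-joined), EOS."""
    return [vocab.bos_id] + vocab.encode(tokenize_smiles(reactants_str)) + [vocab.eos_id]


def build_corpus_vocabulary(records: list[ReactionRecord], class_count: int = 10) -> Vocabulary:
    from .lang import build_vocabulary

    corpus = []
    for r in records:
        corpus.append(tokenize_smiles(r.product))
        corpus.append(tokenize_smiles(r.reactants_str))
    return build_vocabulary(corpus, class_count=class_count)


# ---------------------------------------------------------------------------
# batching


def pack_batches_by_tokens(lengths: list[int], batch_tokens: int) -> list[list[int]]:
    """Greedy in-order packing under a padded-token budget.

    A sequence joins the current batch iff max(batch max, its length) x
    (batch size + 1) <= batch_tokens; otherwise it starts a new batch.
    """
    for i, n in enumerate(lengths):
        if n > batch_tokens:
            raise ValueError(f"sequence {i} ({n} tokens) exceeds budget {batch_tokens}")
    batches: list[list[int]] = []
    cur: list[int] = []
    cur_max = 0
    for i, n in enumerate(lengths):
        new_max = max(cur_max, n)
        if cur and new_max * (len(cur) + 1) > batch_tokens:
            batches.append(cur)
            cur, cur_max = [], 0
            new_max = n
        cur.append(i)
        cur_max = new_max
    if cur:
        batches.append(cur)
    return batches


def _pad(seqs: list[list[int]], pad_id: int = 0) -> np.ndarray:
    t = max(len(s) for s in seqs)
    out = np.full((len(seqs), t), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


# ---------------------------------------------------------------------------
# optimizer


class _Adam:
    def __init__(self, names, beta1=0.9, beta2=0.98, eps=1e-9):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {n: 0.0 for n in names}
        self.v = {n: 0.0 for n in names}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for n, g in grads.items():
            self.m[n] = b1 * self.m[n] + (1 - b1) * g
            self.v[n] = b2 * self.v[n] + (1 - b2) * g * g
            mhat = self.m[n] / (1 - b1**self.t)
            vhat = self.v[n] / (1 - b2**self.t)
            params[n] = params[n] - lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> dict:
        return {"t": self.t}


def _lr(step: int, d_model: int, warmup: int, scale: float) -> float:
    return scale * d_model**-0.5 * min(step**-0.5, step * warmup**-1.5)


# ---------------------------------------------------------------------------
# loss


def _batch_loss(params_t, src: np.ndarray, tgt: np.ndarray, config: ModelConfig,
                dropout_rng=None, label_smoothing: float = 0.0) -> Tensor:
    memory, key_ok = encode_batch(src, params_t, config, dropout_rng=dropout_rng)
    logits = decode_batch(memory, key_ok, tgt[:, :-1], params_t, config,
                          dropout_rng=dropout_rng)
    targets = tgt[:, 1:]
    weights = (targets != 0).astype(np.float64)
    return Tensor.cross_entropy(logits, targets, weights, label_smoothing)


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; `checkpoints` holds everything saved so far."""

    def __init__(self, step: int, checkpoints: list[Checkpoint]):
        super().__init__(f"non-finite loss at step {step}")
        self.checkpoints = checkpoints


def train(
    splits: DatasetSplit,
    vocab: Vocabulary,
    model_config: ModelConfig,
    train_config: TrainConfig,
    out_dir=None,
) -> list[Checkpoint]:
    """Teacher-forced cross-entropy training; returns the checkpoint list.

    Deterministic for a fixed seed on one device: data order, initialization
    and dropout all derive from `train_config.seed`.
    """
    rng = np.random.default_rng(train_config.seed)
    params = init_parameters(model_config, len(vocab), seed=train_config.seed)
    check_shapes(params, model_config, len(vocab))

    def prep(records):
        pairs = []
        for r in records:
            cid = r.class_id if train_config.use_class_token else None
            pairs.append((encode_source(r.product, vocab, cid),
                          encode_target(r.reactants_str, vocab)))
        return pairs

    train_pairs = prep(splits.train)
    val_pairs = prep(splits.validation) if splits.validation else []
    longest = max(len(s) + len(t) for s, t in train_pairs)
    if train_config.batch_tokens < longest:
        raise ValueError(
            f"batch_tokens {train_config.batch_tokens} below longest sequence pair {longest}"
        )
    order = rng.permutation(len(train_pairs))
    train_pairs = [train_pairs[i] for i in order]
    batches = pack_batches_by_tokens(
        [len(s) + len(t) for s, t in train_pairs], train_config.batch_tokens
    )

    optimizer = _Adam(list(params))
    checkpoints: list[Checkpoint] = []
    log_rows: list[tuple] = []

    def val_loss_now() -> float:
        if not val_pairs:
            return float("nan")
        losses, weights = [], []
        vb = pack_batches_by_tokens(
            [len(s) + len(t) for s, t in val_pairs], train_config.batch_tokens
        )
        for idxs in vb:
            src = _pad([val_pairs[i][0] for i in idxs])
            tgt = _pad([val_pairs[i][1] for i in idxs])
            w = sum(len(val_pairs[i][1]) - 1 for i in idxs)
            losses.append(_batch_loss(params, src, tgt, model_config).value * w)
            weights.append(w)
        return float(np.sum(losses) / np.sum(weights))

    def snapshot(step: int):
        ckpt = Checkpoint(
            step=step,
            params={n: p.copy() for n, p in params.items()},
            optimizer_state=optimizer.state(),
            val_loss=val_loss_now(),
        )
        checkpoints.append(ckpt)
        if out_dir is not None:
            save_checkpoint(ckpt, model_config, Path(out_dir) / "checkpoints" / f"step-{step}.npz")
        return ckpt

    if out_dir is not None:
        _init_run_dir(out_dir, vocab, model_config, train_config)

    if train_config.max_steps == 0:
        snapshot(0)
    step = 0
    while step < train_config.max_steps:
        for idxs in batches:
            if step >= train_config.max_steps:
                break
            step += 1
            src = _pad([train_pairs[i][0] for i in idxs])
            tgt = _pad([train_pairs[i][1] for i in idxs])
            params_t = {n: Tensor(p, requires_grad=True) for n, p in params.items()}
            loss = _batch_loss(params_t, src, tgt, model_config,
                               dropout_rng=rng if model_config.dropout > 0 else None,
                               label_smoothing=train_config.label_smoothing)
            if not np.isfinite(loss.value):
                logger.error("loss diverged at step %d", step)
                raise TrainingDiverged(step, checkpoints)
            loss.backward()
            grads = {n: t.grad for n, t in params_t.items() if t.grad is not None}
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if train_config.grad_clip and norm > train_config.grad_clip:
                grads = {n: g * (train_config.grad_clip / norm) for n, g in grads.items()}
            optimizer.step(
                params, grads,
                _lr(step, model_config.d_model, train_config.warmup_steps,
                    train_config.lr_scale),
            )
            if step % train_config.checkpoint_interval == 0 or step == train_config.max_steps:
                ckpt = snapshot(step)
                log_rows.append((step, float(loss.value), ckpt.val_loss))
                logger.info("step %d train_loss %.4f val_loss %.4f",
                            step, loss.value, ckpt.val_loss)
            else:
                log_rows.append((step, float(loss.value), ""))
    if not checkpoints:  # max_steps smaller than first interval
        snapshot(step)
    if out_dir is not None:
        log = "\n".join("\t".join(str(x) for x in row) for row in log_rows)
        (Path(out_dir) / "train.log").write_text("step\ttrain_loss\tval_loss\n" + log + "\n")
    return checkpoints


def average_checkpoints(checkpoints: list[Checkpoint], k: int) -> dict[str, np.ndarray]:
    """Element-wise mean of the last k parameter sets, name by name.

    Optimizer state is discarded; name/shape mismatches raise.
    """
    if k < 1 or len(checkpoints) < k:
        raise ValueError(f"need at least k={k} checkpoints, have {len(checkpoints)}")
    last = checkpoints[-k:]
    names = set(last[0].params)
    for c in last[1:]:
        if set(c.params) != names:
            raise ValueError("checkpoint parameter names differ")
    out = {}
    for n in names:
        shapes = {c.params[n].shape for c in last}
        if len(shapes) > 1:
            raise ValueError(f"shape mismatch for {n}: {shapes}")
        out[n] = sum(c.params[n] for c in last) / k
    return out


# ---------------------------------------------------------------------------
# run-directory I/O


def _init_run_dir(out_dir, vocab, model_config, train_config) -> None:
    import yaml

    out = Path(out_dir)
    (out / "checkpoints").mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump({"model": model_config.to_dict(), "train": train_config.to_dict()})
    )
    vocab.save(out / "vocab.tsv")


def save_checkpoint(ckpt: Checkpoint, config: ModelConfig, path) -> None:
    """Named-tensor archive with a JSON sidecar (config, step, val loss)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **ckpt.params)
    sidecar = {"step": ckpt.step, "val_loss": ckpt.val_loss,
               "config": config.to_dict(), "optimizer_state": ckpt.optimizer_state}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], ModelConfig, dict]:
    path = Path(path)
    with np.load(path) as npz:
        params = {n: npz[n] for n in npz.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return params, ModelConfig.from_dict(sidecar["config"]), sidecar


def save_params(params: dict[str, np.ndarray], config: ModelConfig, path) -> None:
    save_checkpoint(Checkpoint(step=-1, params=params, optimizer_state={}, val_loss=float("nan")),
                    config, path)
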