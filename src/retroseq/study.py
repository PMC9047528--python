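"""The desk-scale synthetic recovery study, as one reusable recipe.

This bundles the study conditions — the default template dataset, the
2-layer / 128-wide model, and the small-batch training schedule — so the
acceptance script, the test suite and interactive use all run exactly the
same experiment.  See docs/methods.md for why each value is what it is.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import DatasetSplit
from .decoding import predict_reactants
from .evaluation import invalidity_rate, top_n_accuracy
from .lang import Vocabulary
from .model import ModelConfig
from .synthetic import generate_dataset
from .training import Checkpoint, TrainConfig, average_checkpoints, build_corpus_vocabulary, train

#: Model for the recovery study: depth 2, width 128.
RECOVERY_MODEL = ModelConfig(n_layers=2, d_model=128, n_heads=4, d_ff=256,
                             max_len=64, dropout=0.0)


def recovery_train_config(seed: int) -> TrainConfig:
    """Small-batch schedule with constant label smoothing and dense averaging."""
    return TrainConfig(batch_tokens=1200, max_steps=3500, checkpoint_interval=100,
                       seed=seed, warmup_steps=200, lr_scale=0.5,
                       averaging_window=12, label_smoothing=0.1)


@dataclass
class StudyResult:
    split: DatasetSplit
    vocab: Vocabulary
    checkpoints: list[Checkpoint]
    averaged_params: dict
    model_config: ModelConfig
    train_config: TrainConfig


def run_recovery_training(seed: int) -> StudyResult:
    """Generate the dataset and train the recovery model; no decoding yet."""
    split = generate_dataset(seed=seed)
    vocab = build_corpus_vocabulary(split.all_records)
    train_cfg = recovery_train_config(seed)
    checkpoints = train(split, vocab, RECOVERY_MODEL, train_cfg)
    averaged = average_checkpoints(checkpoints, train_cfg.averaging_window)
    return StudyResult(split, vocab, checkpoints, averaged, RECOVERY_MODEL, train_cfg)


def decode_test_set(result: StudyResult, params: dict, n: int = 1,
                    beam_width: int = 2, max_len: int = 60) -> dict[str, list[str]]:
    """Ranked predictions for every held-out record."""
    preds = {}
    for rec in result.split.test:
        cands = predict_reactants(params, result.model_config, rec.product,
                                  result.vocab, class_id=rec.class_id,
                                  n=n, beam_width=beam_width, max_len=max_len)
        preds[rec.record_id] = [c.smiles for c in cands]
    return preds


def score(result: StudyResult, preds: dict[str, list[str]],
          ns: tuple[int, ...] = (1,)) -> dict:
    truths = {r.record_id: r.reactants_str for r in result.split.test}
    acc = top_n_accuracy(preds, truths, ns=ns)
    inval, _ = invalidity_rate({rid: p[0] for rid, p in preds.items()})
    return {"top_n": acc, "invalidity": inval, "n_test": len(preds)}
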