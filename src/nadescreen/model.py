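"""Replaced-token-detection pre-training and stability fine-tuning.

Two encoders are trained jointly during pre-training: a small generator with
a masked-token prediction head proposes replacements for masked positions,
and a larger discriminator learns to flag which tokens were replaced.  The
joint objective is ``L_mlm + lambda * L_rtd``.  Fine-tuning discards the
per-token detection head, attaches a freshly initialized two-class head on a
sum-pooled sequence representation, and trains the whole stack as a binary
stability classifier; scores are softmax probabilities of the stable class.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import _nn
from .chemtext import (
    EncodedMixture,
    MixtureSpec,
    Vocabulary,
    encode_mixture,
    tokenize_smiles,
)
from .metrics import confusion_matrix, mcc

logger = logging.getLogger(__name__)

__all__ = [
    "ElectraConfig", "FinetuneConfig", "EpochMetrics", "ScoredMixture",
    "PretrainedModel", "StabilityClassifier",
    "corrupt_sequence", "pretrain", "finetune_classifier", "predict_scores",
    "write_metrics_csv", "read_metrics_csv",
]

STABLE_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# Configs

@dataclass
class ElectraConfig:
    """Pre-training configuration.

    The reference-scale depths are 4 generator / 16 discriminator blocks and
    40 epochs; :meth:`desk_scale` shrinks everything so the whole pipeline
    runs on one CPU in seconds while preserving the generator < discriminator
    sizing.
    """

    generator_layers: int = 4
    discriminator_layers: int = 16
    vocab_size: Optional[int] = None
    pretrain_epochs: int = 40
    mask_rate: float = 0.15
    disc_loss_weight: float = 50.0
    hidden_size: int = 64
    num_heads: int = 4
    ffn_size: int = 128
    max_position: int = 128
    learning_rate: float = 1e-3
    batch_size: int = 32
    test_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.generator_layers < 1 or self.discriminator_layers < 1:
            raise ValueError("layer counts must be >= 1")
        if not 0.0 < self.mask_rate < 1.0:
            raise ValueError(f"mask_rate must be in (0, 1), got {self.mask_rate}")

    @classmethod
    def desk_scale(cls, **overrides) -> "ElectraConfig":
        defaults = dict(generator_layers=1, discriminator_layers=2,
                        pretrain_epochs=10, hidden_size=64, num_heads=4,
                        ffn_size=128)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class FinetuneConfig:
    """Fine-tuning hyperparameters; defaults follow the reference protocol
    (max sequence length 128, batch 32, learning rate 4e-5)."""

    max_seq_length: int = 128
    train_batch_size: int = 32
    learning_rate: float = 4e-5
    epochs: int = 15
    seed: int = 0
    selection: str = "validation"  # or "test" to reproduce the original protocol
    validation_fraction: float = 0.1
    # small head init keeps the fresh head's random logits from swamping the
    # limited parameter movement available at the reference learning rate
    head_init_std: float = 0.01

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.selection not in ("validation", "test"):
            raise ValueError(f"selection must be 'validation' or 'test', got "
                             f"{self.selection!r}")


@dataclass
class EpochMetrics:
    epoch: int
    train_loss: float
    test_loss: float
    train_mcc: float = math.nan
    test_mcc: float = math.nan
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ScoredMixture:
    """A mixture, its softmax stability score, and the thresholded label."""

    mixture: EncodedMixture
    score: float
    label: int


# ---------------------------------------------------------------------------
# Sequence plumbing

def _to_token_ids(tokens: Sequence[str], vocab: Vocabulary,
                  max_len: int) -> tuple[list[int], bool]:
    """[CLS] tokens [SEP] as ids, truncated to *max_len*; flag = truncated."""
    ids = [vocab.cls_id] + vocab.encode_tokens(tokens) + [vocab.sep_id]
    if len(ids) > max_len:
        return ids[: max_len - 1] + [vocab.sep_id], True
    return ids, False


def _pad_batch(seqs: Sequence[Sequence[int]], pad_id: int):
    L = max(len(s) for s in seqs)
    ids = np.full((len(seqs), L), pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), L))
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return ids, mask


def _mixture_tokens(m: Union[MixtureSpec, EncodedMixture, str]) -> Sequence[str]:
    if isinstance(m, MixtureSpec):
        return encode_mixture(m).tokens
    if isinstance(m, EncodedMixture):
        return m.tokens
    return tokenize_smiles(m)


# ---------------------------------------------------------------------------
# Corruption

def corrupt_sequence(
    ids: Sequence[int],
    mask_rate: float,
    rng: np.random.Generator,
    vocab: Vocabulary,
    generator: Optional["PretrainedModel"] = None,
) -> tuple[list[int], list[bool]]:
    """Mask ``round(mask_rate * eligible)`` non-special positions and replace
    them with sampled tokens.

    With a *generator* model the replacements are drawn from its masked-token
    distribution; otherwise uniformly from the non-special vocabulary.  Flags
    mark positions whose sampled token differs from the original.
    """
    ids = list(ids)
    special = vocab.special_ids
    eligible = [i for i, t in enumerate(ids) if t not in special]
    n_mask = int(round(mask_rate * len(eligible)))
    flags = [False] * len(ids)
    if n_mask == 0:
        return ids, flags
    positions = sorted(rng.choice(len(eligible), size=n_mask, replace=False).tolist())
    positions = [eligible[i] for i in positions]
    masked = list(ids)
    for pos in positions:
        masked[pos] = vocab.mask_id
    if generator is not None:
        batch = np.asarray([masked], dtype=np.int64)
        pad_mask = np.ones_like(batch, dtype=float)
        h, _ = _nn.encoder_forward(generator.gen_params, generator.gen_spec,
                                   batch, pad_mask)
        logits = h[0] @ generator.gen_params["mlm.w"] + generator.gen_params["mlm.b"]
        sampled = _sample_rows(logits[positions], rng)
    else:
        pool = [i for i in range(len(vocab)) if i not in special]
        sampled = rng.choice(pool, size=n_mask, replace=True)
    out = list(ids)
    for pos, tok in zip(positions, np.asarray(sampled).tolist()):
        out[pos] = int(tok)
        flags[pos] = out[pos] != ids[pos]
    return out, flags


def _sample_rows(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Categorical sample per row via the Gumbel-max trick (vectorized)."""
    g = rng.gumbel(size=logits.shape)
    shifted = logits - logits.max(-1, keepdims=True)
    return (shifted + g).argmax(-1)


# ---------------------------------------------------------------------------
# Model containers

@dataclass
class PretrainedModel:
    config: ElectraConfig
    vocab: Vocabulary
    gen_params: dict
    disc_params: dict

    @property
    def gen_spec(self) -> _nn.EncoderSpec:
        c = self.config
        return _nn.EncoderSpec(len(self.vocab), c.hidden_size, c.num_heads,
                               c.generator_layers, c.ffn_size, c.max_position)

    @property
    def disc_spec(self) -> _nn.EncoderSpec:
        c = self.config
        return _nn.EncoderSpec(len(self.vocab), c.hidden_size, c.num_heads,
                               c.discriminator_layers, c.ffn_size, c.max_position)

    def save(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["model_kind"] = "pretrained"
        (out / "config.json").write_text(json.dumps(cfg, indent=2), encoding="utf-8")
        self.vocab.save(out / "vocab.txt")
        arrays = {f"gen/{k}": v for k, v in self.gen_params.items()}
        arrays.update({f"disc/{k}": v for k, v in self.disc_params.items()})
        np.savez(out / "weights.npz", **arrays)

    @classmethod
    def load(cls, model_dir: Union[str, Path]) -> "PretrainedModel":
        d = Path(model_dir)
        cfg = json.loads((d / "config.json").read_text(encoding="utf-8"))
        cfg.pop("model_kind", None)
        config = ElectraConfig(**cfg)
        vocab = Vocabulary.load(d / "vocab.txt")
        with np.load(d / "weights.npz") as data:
            gen = {k[4:]: data[k] for k in data.files if k.startswith("gen/")}
            disc = {k[5:]: data[k] for k in data.files if k.startswith("disc/")}
        return cls(config=config, vocab=vocab, gen_params=gen, disc_params=disc)


@dataclass
class StabilityClassifier:
    spec: _nn.EncoderSpec
    vocab: Vocabulary
    params: dict
    max_seq_length: int = 128
    threshold: float = STABLE_THRESHOLD
    best_params: Optional[dict] = None
    best_epoch: Optional[int] = None

    def logits(self, mixtures: Sequence[Union[MixtureSpec, EncodedMixture, str]],
               params: Optional[dict] = None) -> np.ndarray:
        params = params if params is not None else self.params
        seqs = []
        n_trunc = 0
        for m in mixtures:
            ids, truncated = _to_token_ids(_mixture_tokens(m), self.vocab,
                                           self.max_seq_length)
            n_trunc += truncated
            seqs.append(ids)
        if n_trunc:
            logger.warning("%d sequence(s) longer than %d tokens were truncated",
                           n_trunc, self.max_seq_length)
        ids, mask = _pad_batch(seqs, self.vocab.pad_id)
        h, _ = _nn.encoder_forward(params, self.spec, ids, mask)
        pooled = (h * mask[:, :, None]).sum(1)
        return pooled @ params["cls.w"] + params["cls.b"]

    def predict_proba(self, mixtures, batch_size: int = 64) -> np.ndarray:
        """(n, 2) softmax probabilities, column 1 = stable."""
        probs = []
        mixtures = list(mixtures)
        for start in range(0, len(mixtures), batch_size):
            logits = self.logits(mixtures[start: start + batch_size])
            probs.append(_nn._softmax(logits, axis=-1))
        return np.concatenate(probs) if probs else np.zeros((0, 2))

    def save(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = {
            "model_kind": "classifier",
            "spec": asdict(self.spec),
            "max_seq_length": self.max_seq_length,
            "threshold": self.threshold,
            "best_epoch": self.best_epoch,
        }
        (out / "config.json").write_text(json.dumps(cfg, indent=2), encoding="utf-8")
        self.vocab.save(out / "vocab.txt")
        arrays = {f"final/{k}": v for k, v in self.params.items()}
        if self.best_params is not None:
            arrays.update({f"best/{k}": v for k, v in self.best_params.items()})
        np.savez(out / "weights.npz", **arrays)

    @classmethod
    def load(cls, model_dir: Union[str, Path]) -> "StabilityClassifier":
        d = Path(model_dir)
        cfg = json.loads((d / "config.json").read_text(encoding="utf-8"))
        spec = _nn.EncoderSpec(**cfg["spec"])
        vocab = Vocabulary.load(d / "vocab.txt")
        with np.load(d / "weights.npz") as data:
            final = {k[6:]: data[k] for k in data.files if k.startswith("final/")}
            best = {k[5:]: data[k] for k in data.files if k.startswith("best/")}
        return cls(spec=spec, vocab=vocab, params=final,
                   max_seq_length=cfg["max_seq_length"],
                   threshold=cfg.get("threshold", STABLE_THRESHOLD),
                   best_params=best or None, best_epoch=cfg.get("best_epoch"))


# ---------------------------------------------------------------------------
# Pre-training

def _corrupt_batch(ids, pad_mask, vocab, mask_rate, rng, is_special):
    """Vectorized batch corruption; returns masked input, positions, originals."""
    B, L = ids.shape
    eligible = pad_mask.astype(bool) & ~is_special[ids]
    rows, cols = [], []
    for b in range(B):
        cand = np.flatnonzero(eligible[b])
        n_mask = int(round(mask_rate * cand.size))
        if n_mask == 0:
            continue
        pick = rng.choice(cand.size, size=n_mask, replace=False)
        rows.extend([b] * n_mask)
        cols.extend(cand[pick].tolist())
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    masked = ids.copy()
    if rows.size:
        masked[rows, cols] = vocab.mask_id
    return masked, rows, cols


def _electra_step(gen_params, disc_params, gen_spec, disc_spec, vocab, config,
                  ids, pad_mask, rng, is_special, update=None):
    """One joint generator/discriminator pass; returns (mlm, rtd) losses.

    With ``update=(gen_opt, disc_opt)`` an optimizer step is applied.
    """
    masked, rows, cols = _corrupt_batch(ids, pad_mask, vocab,
                                        config.mask_rate, rng, is_special)
    # generator masked-token prediction
    h, cache = _nn.encoder_forward(gen_params, gen_spec, masked, pad_mask)
    hm = h[rows, cols]
    logits = hm @ gen_params["mlm.w"] + gen_params["mlm.b"]
    targets = ids[rows, cols]
    mlm_loss, dlogits = _nn.softmax_xent(logits, targets)
    if update is not None and rows.size:
        grads = _nn.zeros_like_params(gen_params)
        grads["mlm.w"] += hm.T @ dlogits
        grads["mlm.b"] += dlogits.sum(0)
        dh = np.zeros_like(h)
        dh[rows, cols] = dlogits @ gen_params["mlm.w"].T
        _nn.encoder_backward(gen_params, gen_spec, cache, dh, grads)
        update[0].step(gen_params, grads)
    # sample replacements (no gradient through sampling)
    corrupted = ids.copy()
    if rows.size:
        corrupted[rows, cols] = _sample_rows(logits, rng)
    replaced = (corrupted != ids).astype(float)
    # discriminator replaced-token detection on all non-pad positions
    h_d, cache_d = _nn.encoder_forward(disc_params, disc_spec, corrupted, pad_mask)
    rtd_logits = h_d @ disc_params["rtd.w"] + disc_params["rtd.b"]
    rtd_logits = rtd_logits[:, :, 0]
    rtd_loss, drtd = _nn.sigmoid_bce(rtd_logits, replaced, pad_mask)
    if update is not None:
        lam = config.disc_loss_weight
        grads_d = _nn.zeros_like_params(disc_params)
        drtd = drtd * lam
        grads_d["rtd.w"] += (h_d.reshape(-1, h_d.shape[-1]).T
                             @ drtd.reshape(-1)[:, None])
        grads_d["rtd.b"] += drtd.sum()
        dh_d = drtd[:, :, None] * disc_params["rtd.w"][None, None, :, 0]
        _nn.encoder_backward(disc_params, disc_spec, cache_d, dh_d, grads_d)
        update[1].step(disc_params, grads_d)
    return mlm_loss, rtd_loss


def initialize_model(
    vocab: Vocabulary,
    config: ElectraConfig,
    seed: int = 0,
) -> PretrainedModel:
    """Freshly initialized, untrained generator/discriminator pair.

    Used as the no-pretraining baseline: fine-tuning from here isolates the
    contribution of the pre-training stage.
    """
    config = copy.deepcopy(config)
    config.vocab_size = len(vocab)
    rng = np.random.default_rng(seed)
    model = PretrainedModel(config=config, vocab=vocab, gen_params={},
                            disc_params={})
    gen_params = _nn.init_encoder_params(rng, model.gen_spec)
    head = _nn.init_linear(rng, config.hidden_size, len(vocab))
    gen_params["mlm.w"], gen_params["mlm.b"] = head["w"], head["b"]
    disc_params = _nn.init_encoder_params(rng, model.disc_spec)
    head = _nn.init_linear(rng, config.hidden_size, 1)
    disc_params["rtd.w"], disc_params["rtd.b"] = head["w"], head["b"]
    model.gen_params, model.disc_params = gen_params, disc_params
    return model


def pretrain(
    corpus: Iterable[str],
    vocab: Vocabulary,
    config: ElectraConfig,
    seed: int = 0,
    out_dir: Optional[Union[str, Path]] = None,
) -> tuple[PretrainedModel, list[EpochMetrics]]:
    """Joint generator/discriminator pre-training on a line corpus.

    The per-epoch loss logged is ``L_mlm + disc_loss_weight * L_rtd`` averaged
    over batches, for the training lines and an internal held-out fraction.
    """
    lines = [ln.rstrip("\n") for ln in corpus if ln.strip()]
    if not lines:
        raise ValueError("pre-training corpus is empty")
    config = copy.deepcopy(config)
    config.vocab_size = len(vocab)
    rng = np.random.default_rng(seed)

    seqs = []
    for line in lines:
        ids, _ = _to_token_ids(tokenize_smiles(line), vocab, config.max_position)
        seqs.append(ids)
    n_test = max(1, int(round(config.test_fraction * len(seqs)))) \
        if len(seqs) > 1 else 0
    order = rng.permutation(len(seqs))
    test_seqs = [seqs[i] for i in order[:n_test]]
    train_seqs = [seqs[i] for i in order[n_test:]]
    if not train_seqs:
        raise ValueError("corpus too small to carve a held-out fraction")

    model = PretrainedModel(config=config, vocab=vocab, gen_params={},
                            disc_params={})
    gen_spec, disc_spec = model.gen_spec, model.disc_spec
    gen_params = _nn.init_encoder_params(rng, gen_spec)
    head = _nn.init_linear(rng, config.hidden_size, len(vocab))
    gen_params["mlm.w"], gen_params["mlm.b"] = head["w"], head["b"]
    disc_params = _nn.init_encoder_params(rng, disc_spec)
    head = _nn.init_linear(rng, config.hidden_size, 1)
    disc_params["rtd.w"], disc_params["rtd.b"] = head["w"], head["b"]
    model.gen_params, model.disc_params = gen_params, disc_params

    gen_opt = _nn.Adam(gen_params, lr=config.learning_rate)
    disc_opt = _nn.Adam(disc_params, lr=config.learning_rate)
    is_special = np.zeros(len(vocab), dtype=bool)
    for i in vocab.special_ids:
        is_special[i] = True
    lam = config.disc_loss_weight

    def run_epoch(seq_list, train: bool, epoch_rng):
        mlm_total = rtd_total = 0.0
        n_batches = 0
        idx = epoch_rng.permutation(len(seq_list)) if train \
            else np.arange(len(seq_list))
        for start in range(0, len(seq_list), config.batch_size):
            batch = [seq_list[i] for i in idx[start: start + config.batch_size]]
            ids, pad_mask = _pad_batch(batch, vocab.pad_id)
            mlm, rtd = _electra_step(
                gen_params, disc_params, gen_spec, disc_spec, vocab, config,
                ids, pad_mask, epoch_rng, is_special,
                update=(gen_opt, disc_opt) if train else None)
            mlm_total += mlm
            rtd_total += rtd
            n_batches += 1
        return mlm_total / n_batches, rtd_total / n_batches

    history: list[EpochMetrics] = []
    for epoch in range(config.pretrain_epochs):
        tr_mlm, tr_rtd = run_epoch(train_seqs, True, rng)
        if test_seqs:
            eval_rng = np.random.default_rng([seed, epoch, 0xE7A1])
            te_mlm, te_rtd = run_epoch(test_seqs, False, eval_rng)
        else:
            te_mlm = te_rtd = math.nan
        history.append(EpochMetrics(
            epoch=epoch,
            train_loss=tr_mlm + lam * tr_rtd,
            test_loss=te_mlm + lam * te_rtd,
            detail={"train_mlm": tr_mlm, "train_rtd": tr_rtd,
                    "test_mlm": te_mlm, "test_rtd": te_rtd}))
        logger.info("pretrain epoch %d: train %.4f test %.4f",
                    epoch, history[-1].train_loss, history[-1].test_loss)

    if out_dir is not None:
        model.save(out_dir)
        write_metrics_csv(Path(out_dir) / "pretrain_metrics.csv", history)
    return model, history


# ---------------------------------------------------------------------------
# Fine-tuning

def _eval_classification(clf: StabilityClassifier, params, seqs, labels,
                         batch_size: int):
    losses = []
    preds = []
    for start in range(0, len(seqs), batch_size):
        batch = seqs[start: start + batch_size]
        ids, mask = _pad_batch(batch, clf.vocab.pad_id)
        h, _ = _nn.encoder_forward(params, clf.spec, ids, mask)
        pooled = (h * mask[:, :, None]).sum(1)
        logits = pooled @ params["cls.w"] + params["cls.b"]
        y = np.asarray(labels[start: start + batch_size])
        loss, _ = _nn.softmax_xent(logits, y)
        losses.append(loss * len(batch))
        probs = _nn._softmax(logits, axis=-1)
        preds.extend((probs[:, 1] > STABLE_THRESHOLD).astype(int).tolist())
    loss = sum(losses) / len(seqs)
    cm = confusion_matrix(list(labels), preds)
    return loss, mcc(cm)


def finetune_classifier(
    pretrained: PretrainedModel,
    train: Sequence[MixtureSpec],
    test: Sequence[MixtureSpec],
    cfg: Optional[FinetuneConfig] = None,
) -> tuple[StabilityClassifier, list[EpochMetrics]]:
    """Fine-tune the discriminator into a two-class stability classifier.

    A fresh softmax head replaces the detection head; per-epoch loss and MCC
    are recorded on the training and test sets.  Model selection uses an
    internal validation split by default (``cfg.selection='test'`` reproduces
    the protocol of watching the test curve directly).
    """
    cfg = cfg if cfg is not None else FinetuneConfig()
    if not train:
        raise ValueError("empty fine-tuning training set")
    for m in list(train) + list(test):
        if m.label not in (0, 1):
            raise ValueError(f"mixture without a binary label: {m!r}")

    rng = np.random.default_rng(cfg.seed)
    vocab = pretrained.vocab
    clf = StabilityClassifier(
        spec=pretrained.disc_spec, vocab=vocab,
        params=copy.deepcopy(pretrained.disc_params),
        max_seq_length=cfg.max_seq_length)
    clf.params.pop("rtd.w", None)
    clf.params.pop("rtd.b", None)
    head = _nn.init_linear(rng, pretrained.config.hidden_size, 2,
                           std=cfg.head_init_std)
    clf.params["cls.w"], clf.params["cls.b"] = head["w"], head["b"]

    def prep(mixtures):
        seqs, labels, n_trunc = [], [], 0
        for m in mixtures:
            ids, truncated = _to_token_ids(encode_mixture(m).tokens, vocab,
                                           cfg.max_seq_length)
            n_trunc += truncated
            seqs.append(ids)
            labels.append(m.label)
        if n_trunc:
            logger.warning("%d sequence(s) truncated to %d tokens",
                           n_trunc, cfg.max_seq_length)
        return seqs, labels

    train_seqs, train_labels = prep(train)
    test_seqs, test_labels = prep(test)
    if cfg.selection == "validation" and len(train_seqs) >= 10:
        n_val = max(1, int(round(cfg.validation_fraction * len(train_seqs))))
        val_idx = set(rng.choice(len(train_seqs), size=n_val,
                                 replace=False).tolist())
        val_seqs = [train_seqs[i] for i in sorted(val_idx)]
        val_labels = [train_labels[i] for i in sorted(val_idx)]
        fit_seqs = [s for i, s in enumerate(train_seqs) if i not in val_idx]
        fit_labels = [l for i, l in enumerate(train_labels) if i not in val_idx]
    else:
        val_seqs, val_labels = test_seqs, test_labels
        fit_seqs, fit_labels = train_seqs, train_labels

    opt = _nn.Adam(clf.params, lr=cfg.learning_rate)
    history: list[EpochMetrics] = []
    best = (-math.inf, math.inf, -1)  # (sel_mcc, -? loss, epoch) maximized
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(fit_seqs))
        for start in range(0, len(fit_seqs), cfg.train_batch_size):
            batch_idx = order[start: start + cfg.train_batch_size]
            batch = [fit_seqs[i] for i in batch_idx]
            y = np.asarray([fit_labels[i] for i in batch_idx])
            ids, mask = _pad_batch(batch, vocab.pad_id)
            h, cache = _nn.encoder_forward(clf.params, clf.spec, ids, mask)
            pooled = (h * mask[:, :, None]).sum(1)
            logits = pooled @ clf.params["cls.w"] + clf.params["cls.b"]
            _, dlogits = _nn.softmax_xent(logits, y)
            grads = _nn.zeros_like_params(clf.params)
            grads["cls.w"] += pooled.T @ dlogits
            grads["cls.b"] += dlogits.sum(0)
            dpooled = dlogits @ clf.params["cls.w"].T
            dh = dpooled[:, None, :] * mask[:, :, None]
            _nn.encoder_backward(clf.params, clf.spec, cache, dh, grads)
            opt.step(clf.params, grads)
        tr_loss, tr_mcc = _eval_classification(
            clf, clf.params, train_seqs, train_labels, cfg.train_batch_size)
        te_loss, te_mcc = _eval_classification(
            clf, clf.params, test_seqs, test_labels, cfg.train_batch_size) \
            if test_seqs else (math.nan, math.nan)
        if val_seqs is test_seqs:
            val_loss, val_mcc = te_loss, te_mcc
        else:
            val_loss, val_mcc = _eval_classification(
                clf, clf.params, val_seqs, val_labels, cfg.train_batch_size)
        history.append(EpochMetrics(
            epoch=epoch, train_loss=tr_loss, test_loss=te_loss,
            train_mcc=tr_mcc, test_mcc=te_mcc,
            detail={"val_loss": val_loss, "val_mcc": val_mcc}))
        logger.info("finetune epoch %d: loss %.4f/%.4f mcc %.3f/%.3f",
                    epoch, tr_loss, te_loss, tr_mcc, te_mcc)
        if (val_mcc, -val_loss) > (best[0], best[1]):
            best = (val_mcc, -val_loss, epoch)
            clf.best_params = copy.deepcopy(clf.params)
            clf.best_epoch = epoch
    return clf, history


# ---------------------------------------------------------------------------
# Scoring

def predict_scores(
    classifier: StabilityClassifier,
    mixtures: Sequence[Union[MixtureSpec, EncodedMixture, str]],
    batch_size: int = 64,
) -> list[ScoredMixture]:
    """Softmax stability scores; label 1 requires score strictly above 0.5."""
    mixtures = list(mixtures)
    probs = classifier.predict_proba(mixtures, batch_size=batch_size)
    out = []
    for m, p in zip(mixtures, probs[:, 1]):
        if isinstance(m, MixtureSpec):
            enc = encode_mixture(m)
        elif isinstance(m, EncodedMixture):
            enc = m
        else:
            enc = EncodedMixture(text=m, tokens=tuple(tokenize_smiles(m)))
        out.append(ScoredMixture(mixture=enc, score=float(p),
                                 label=int(p > classifier.threshold)))
    return out


# ---------------------------------------------------------------------------
# Metrics log I/O

def write_metrics_csv(path: Union[str, Path], history: Sequence[EpochMetrics]) -> None:
    lines = ["epoch,train_loss,test_loss,train_mcc,test_mcc"]
    for m in history:
        lines.append(f"{m.epoch},{m.train_loss:.6f},{m.test_loss:.6f},"
                     f"{m.train_mcc:.6f},{m.test_mcc:.6f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_metrics_csv(path: Union[str, Path]) -> list[EpochMetrics]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out = []
    for line in lines[1:]:
        epoch, tr, te, trm, tem = line.split(",")
        out.append(EpochMetrics(int(epoch), float(tr), float(te),
                                float(trm), float(tem)))
    return out
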