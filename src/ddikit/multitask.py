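"""Auxiliary-score regression and co-/pre-training protocols.

The auxiliary task regresses a transcriptional-response similarity score
in [-100, 100] for a drug pair (CMap style) through a separate linear
head on the same concatenated pair embedding, while the main task keeps
its multilabel BCE. Four protocols:

- C1: co-training on a single joint batch stream; a mask restricts each
  task's loss to its labelled rows.
- C2: co-training with alternating task-specific batches.
- T1: pre-train extractor + regression head on the auxiliary scores,
  then train the DDI head with the extractor frozen.
- T2: same, but the extractor stays trainable during fine-tuning.

Early stopping always monitors the DDI validation metric only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import DDIDataset
from .model import (
    PairPredictor,
    TrainConfig,
    TrainingExample,
    _bce_loss_t,
    _monitor_value,
    canonical_examples,
)
from .nn.layers import Adam, Linear
from .nn.tensor import Tensor, concat
from .splitting import SplitResult, validate_split
from .synth import CMapRecord

PROTOCOLS = ("C1", "C2", "T1", "T2")


@dataclass
class MultitaskConfig:
    protocol: str = "C1"
    aux_weight: float = 1.0
    scale_scores: bool = True
    pretrain_epochs: int = 10

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.aux_weight < 0:
            raise ValueError("aux_weight must be >= 0")


def scale_score(s: float) -> float:
    """Map a [-100, 100] score to [-1, 1] (exactly invertible)."""
    return s / 100.0


def descale_score(s: float) -> float:
    return s * 100.0


class AuxHead:
    """Single linear regression head on the concatenated pair embedding."""

    def __init__(self, pair_embedding_dim: int, seed: int = 0):
        rng = np.random.Generator(np.random.PCG64([seed, 0xF]))
        self.linear = Linear(pair_embedding_dim, 1, rng)

    def parameters(self):
        return self.linear.parameters()

    def predict_pairs(self, model: PairPredictor, s1, s2, symmetrize: bool = True) -> Tensor:
        z1 = model.extractor.forward(model.extractor.encode(s1))
        z2 = model.extractor.forward(model.extractor.encode(s2))
        out = self.linear(concat([z1, z2], axis=-1))
        if symmetrize:
            out = 0.5 * (out + self.linear(concat([z2, z1], axis=-1)))
        return out


def _mse_t(pred: Tensor, target: np.ndarray) -> Tensor:
    d = pred.reshape(-1) - Tensor(np.asarray(target, dtype=float))
    return (d * d).mean()


@dataclass
class JointEpochLog:
    epoch: int
    ddi_loss: float
    aux_loss: float
    joint_loss: float
    valid_metric: float
    improved: bool


def _cmap_rows(cmap_ds, ds, scale: bool):
    rows = []
    for r in cmap_ds:
        a, b = r.pair
        if a not in ds.drugs or b not in ds.drugs:
            raise ValueError(f"CMap pair ({a}, {b}) references unknown drugs")
        target = scale_score(r.score) if scale else r.score
        rows.append((ds.drugs[a].smiles_canonical, ds.drugs[b].smiles_canonical, target))
    return rows


def cotrain(
    model: PairPredictor,
    ddi_ds: DDIDataset,
    split: SplitResult,
    cmap_ds: list[CMapRecord],
    cfg: TrainConfig,
    mcfg: MultitaskConfig,
) -> tuple[AuxHead, list[JointEpochLog]]:
    """Joint training: Eq.-style BCE + aux_weight * MSE on scaled scores.

    C1 walks one shuffled stream over the union of DDI training pairs and
    auxiliary pairs; every batch contributes each task's loss only over
    its labelled rows (mask). C2 alternates a DDI-only batch with an
    auxiliary-only batch. Early stopping monitors the DDI validation
    metric; best-epoch parameters are restored.
    """
    ok, violations = validate_split(ddi_ds, split)
    if not ok:
        raise ValueError(f"invalid split: {violations}")
    if not cmap_ds:
        raise ValueError("empty auxiliary dataset")
    ddi_examples = canonical_examples(ddi_ds, split.train)
    if not model._built:
        smiles = sorted(
            {e.smiles1 for e in ddi_examples}
            | {e.smiles2 for e in ddi_examples}
            | {s for r in _cmap_rows(cmap_ds, ddi_ds, False) for s in r[:2]}
        )
        model.fit_featurizer(smiles)
    aux = AuxHead(2 * model.extractor_config.output_dim, seed=cfg.seed)
    aux_rows = _cmap_rows(cmap_ds, ddi_ds, mcfg.scale_scores)
    aux_by_pair = {}
    for s1, s2, t in aux_rows:
        aux_by_pair[(s1, s2)] = t
        aux_by_pair[(s2, s1)] = t

    if cfg.symmetrize:
        ddi_examples = ddi_examples + [
            TrainingExample(e.pair_index, e.smiles2, e.smiles1) for e in ddi_examples
        ]

    ddi_keys = {(e.smiles1, e.smiles2) for e in ddi_examples}
    extra_aux = [
        (s1, s2, t)
        for (s1, s2), t in aux_by_pair.items()
        if (s1, s2) not in ddi_keys
    ]

    rng = np.random.Generator(np.random.PCG64([cfg.seed, 0xB]))
    opt = Adam(model.parameters() + aux.parameters(), lr=cfg.learning_rate)
    logs: list[JointEpochLog] = []
    best_metric = -np.inf
    best_state = model.get_state() + [p.data.copy() for p in aux.parameters()]
    bad = 0

    # one joint C1 stream: DDI rows (which may also carry an aux score)
    # plus aux-only rows; the mask selects each task's labelled rows.
    # The stream index is shuffled in place each epoch with the same
    # generator discipline as single-task training, so with aux_weight=0
    # and no aux-only rows the batch schedules coincide exactly.
    stream = [("ddi", e) for e in ddi_examples] + [("aux", r) for r in extra_aux]
    stream_order = np.arange(len(stream))

    def batches_c1():
        rng.shuffle(stream_order)
        for lo in range(0, len(stream_order), cfg.batch_size):
            yield [stream[k] for k in stream_order[lo : lo + cfg.batch_size]]

    def batches_c2():
        idx_d = rng.permutation(len(ddi_examples))
        idx_a = rng.permutation(len(aux_rows))
        bd = [
            [("ddi", ddi_examples[k]) for k in idx_d[lo : lo + cfg.batch_size]]
            for lo in range(0, len(idx_d), cfg.batch_size)
        ]
        ba = [
            [("aux", aux_rows[k]) for k in idx_a[lo : lo + cfg.batch_size]]
            for lo in range(0, len(idx_a), cfg.batch_size)
        ]
        out = []
        for i in range(max(len(bd), len(ba))):
            if i < len(bd):
                out.append(bd[i])
            if i < len(ba):
                out.append(ba[i])
        return out

    for epoch in range(cfg.max_epochs):
        model.train()
        d_losses, a_losses, j_losses = [], [], []
        batch_iter = batches_c1() if mcfg.protocol == "C1" else batches_c2()
        for batch in batch_iter:
            ddi_rows = [e for kind, e in batch if kind == "ddi"]
            aux_items = [r for kind, r in batch if kind == "aux"]
            # aux scores available for some DDI rows of the same batch (mask)
            for e in ddi_rows:
                t = aux_by_pair.get((e.smiles1, e.smiles2))
                if t is not None:
                    aux_items = aux_items + [(e.smiles1, e.smiles2, t)]
            terms = []
            d_val = a_val = 0.0
            if ddi_rows:
                probs = model.forward_pairs(
                    [e.smiles1 for e in ddi_rows], [e.smiles2 for e in ddi_rows]
                )
                d_loss = _bce_loss_t(probs, ddi_ds.labels[[e.pair_index for e in ddi_rows]])
                terms.append(d_loss)
                d_val = d_loss.item()
            if aux_items and mcfg.aux_weight > 0:
                pred = aux.predict_pairs(
                    model,
                    [r[0] for r in aux_items],
                    [r[1] for r in aux_items],
                    symmetrize=cfg.symmetrize,
                )
                a_loss = _mse_t(pred, [r[2] for r in aux_items])
                terms.append(mcfg.aux_weight * a_loss)
                a_val = a_loss.item()
            if not terms:
                continue
            joint = terms[0]
            for t in terms[1:]:
                joint = joint + t
            if not np.isfinite(joint.data):
                raise FloatingPointError(f"joint training diverged at epoch {epoch}")
            opt.zero_grad()
            joint.backward()
            opt.step()
            d_losses.append(d_val)
            a_losses.append(a_val)
            j_losses.append(joint.item())
        valid_metric = _monitor_value(model, ddi_ds, split, cfg)
        improved = valid_metric > best_metric
        if improved:
            best_metric = valid_metric
            best_state = model.get_state() + [p.data.copy() for p in aux.parameters()]
            bad = 0
        else:
            bad += 1
        logs.append(
            JointEpochLog(
                epoch,
                float(np.mean(d_losses)) if d_losses else 0.0,
                float(np.mean(a_losses)) if a_losses else 0.0,
                float(np.mean(j_losses)) if j_losses else 0.0,
                valid_metric,
                improved,
            )
        )
        if bad >= cfg.patience:
            break
    n_model = len(model.state_arrays())
    model.set_state(best_state[:n_model])
    for p, s in zip(aux.parameters(), best_state[n_model:]):
        p.data[...] = s
    model.eval()
    return aux, logs


def pretrain_then_finetune(
    model: PairPredictor,
    cmap_ds: list[CMapRecord],
    ddi_ds: DDIDataset,
    split: SplitResult,
    cfg: TrainConfig,
    mcfg: MultitaskConfig,
) -> tuple[AuxHead, list[float], list]:
    """T1/T2: phase 1 fits extractor + aux head on auxiliary MSE; phase 2
    trains the DDI head, with the extractor frozen (T1) or trainable (T2).

    Returns (aux head, phase-1 per-epoch MSE, phase-2 epoch logs).
    """
    if mcfg.protocol not in ("T1", "T2"):
        raise ValueError("pretrain_then_finetune expects protocol T1 or T2")
    if not cmap_ds:
        raise ValueError("empty auxiliary dataset")
    ddi_examples = canonical_examples(ddi_ds, split.train)
    if not model._built:
        smiles = sorted(
            {e.smiles1 for e in ddi_examples}
            | {e.smiles2 for e in ddi_examples}
            | {s for r in _cmap_rows(cmap_ds, ddi_ds, False) for s in r[:2]}
        )
        model.fit_featurizer(smiles)
    aux = AuxHead(2 * model.extractor_config.output_dim, seed=cfg.seed)
    aux_rows = _cmap_rows(cmap_ds, ddi_ds, mcfg.scale_scores)
    rng = np.random.Generator(np.random.PCG64([cfg.seed, 0x7]))
    opt = Adam(model.extractor.parameters() + aux.parameters(), lr=cfg.learning_rate)
    phase1: list[float] = []
    for _ in range(mcfg.pretrain_epochs):
        idx = rng.permutation(len(aux_rows))
        losses = []
        for lo in range(0, len(idx), cfg.batch_size):
            rows = [aux_rows[k] for k in idx[lo : lo + cfg.batch_size]]
            pred = aux.predict_pairs(
                model, [r[0] for r in rows], [r[1] for r in rows], symmetrize=cfg.symmetrize
            )
            loss = _mse_t(pred, [r[2] for r in rows])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        phase1.append(float(np.mean(losses)))

    from .model import train as train_ddi

    if mcfg.protocol == "T1":
        frozen = {id(p) for p in model.extractor.parameters()}
        # train() builds its own optimizer over all parameters; freeze by
        # zeroing extractor gradients through a wrapper optimizer is more
        # invasive, so use a targeted training loop here instead.
        logs = _train_head_only(model, ddi_ds, split, cfg, frozen)
    else:
        logs = train_ddi(model, ddi_ds, split, cfg)
    return aux, phase1, logs


def _train_head_only(model, ddi_ds, split, cfg, frozen_ids):
    from .model import EpochLog

    examples = canonical_examples(ddi_ds, split.train)
    if cfg.symmetrize:
        examples = examples + [
            TrainingExample(e.pair_index, e.smiles2, e.smiles1) for e in examples
        ]
    params = [p for p in model.parameters() if id(p) not in frozen_ids]
    rng = np.random.Generator(np.random.PCG64([cfg.seed, 0xB]))
    opt = Adam(params, lr=cfg.learning_rate)
    logs = []
    best_metric = -np.inf
    best_state = model.get_state()
    bad = 0
    order = np.arange(len(examples))
    for epoch in range(cfg.max_epochs):
        model.train()
        # freeze batch-norm running stats along with the extractor weights
        for m in model.extractor.modules():
            m.training = False
        rng.shuffle(order)
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = [examples[k] for k in order[lo : lo + cfg.batch_size]]
            probs = model.forward_pairs(
                [e.smiles1 for e in batch], [e.smiles2 for e in batch]
            )
            loss = _bce_loss_t(probs, ddi_ds.labels[[e.pair_index for e in batch]])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        valid_metric = _monitor_value(model, ddi_ds, split, cfg)
        improved = valid_metric > best_metric
        if improved:
            best_metric, best_state, bad = valid_metric, model.get_state(), 0
        else:
            bad += 1
        logs.append(EpochLog(epoch, float(np.mean(losses)), valid_metric, improved))
        if bad >= cfg.patience:
            break
    model.set_state(best_state)
    model.eval()
    return logs
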