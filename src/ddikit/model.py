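"""Multilabel DDI prediction engine.

The predictor f(x1, x2) = g([phi(x1), phi(x2)]) shares one molecular
feature extractor phi between both drugs of a pair, concatenates the two
embeddings and maps them through a fully connected head g with
equal-width ReLU hidden layers and a sigmoid output of width |Y|. It is
trained end-to-end on the multilabel binary cross-entropy, with *every*
unreported phenotype participating as a negative (closed-world
assumption; no negative subsampling).

DDI labels are unordered, but the concatenation [phi(x1), phi(x2)] is
not: by default each training pair is presented in both orders and
inference averages both orders, which enforces the symmetry the data
model asserts.

The statsmodels-style surface is :class:`DDIModel` (built from a dataset
and a split) whose ``fit`` returns a :class:`DDIResults` carrying the
trained parameters, the training history and evaluation helpers. The
functional ``train`` / ``predict`` wrappers are thin aliases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chem import DDIDataset
from .metrics import MetricsReport, auprc, auroc, evaluate
from .nn.extractors import ExtractorConfig, build_extractor
from .nn.layers import Adam, Linear, Module
from .nn.tensor import Tensor, concat
from .splitting import SplitResult, audit_split, validate_split

EPS_CLIP = 1e-7


@dataclass
class TrainConfig:
    """Optimization settings for the DDI engine."""

    max_epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int = 3
    seed: int = 0
    monitor: str = "micro_auprc"
    symmetrize: bool = True

    def __post_init__(self):
        if self.max_epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("max_epochs, batch_size and learning_rate must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


#: default reduced hyperparameter search space (units x layers)
DEFAULT_GRID = {"hidden_units": [64, 128], "hidden_layers": [1, 2]}


def bce_multilabel_loss(scores, labels, eps: float = EPS_CLIP) -> float:
    """Multilabel binary cross-entropy of a score matrix against 0/1 labels.

    Per pair: -[sum_{k: b_k=1} log b_k_hat + sum_{k: b_k=0} log(1 - b_k_hat)],
    averaged over pairs when given a batch. Scores are clipped away from
    {0, 1} by `eps` for numerical safety.
    """
    s = np.clip(np.asarray(scores, dtype=float), eps, 1.0 - eps)
    b = np.asarray(labels, dtype=float)
    if s.shape != b.shape:
        raise ValueError(f"score shape {s.shape} != label shape {b.shape}")
    per_pair = -(b * np.log(s) + (1.0 - b) * np.log(1.0 - s)).sum(axis=-1)
    return float(per_pair.mean())


def _bce_loss_t(probs: Tensor, labels: np.ndarray) -> Tensor:
    p = probs.clip(EPS_CLIP, 1.0 - EPS_CLIP)
    b = labels.astype(float)
    ll = Tensor(b) * p.log() + Tensor(1.0 - b) * (1.0 - p).log()
    return -(ll.sum(axis=-1).mean())


class PairPredictor(Module):
    """Shared extractor + concatenation + fully connected sigmoid head."""

    def __init__(
        self,
        extractor_config: ExtractorConfig,
        n_phenotypes: int,
        head_layers: int = 2,
        head_units: int = 64,
        seed: int = 0,
    ):
        super().__init__()
        self.extractor_config = extractor_config
        self.n_phenotypes = n_phenotypes
        self.head_layers_n = head_layers
        self.head_units = head_units
        self.seed = seed
        rng = np.random.Generator(np.random.PCG64([seed, 0xE]))
        self.extractor = build_extractor(extractor_config, rng)
        self._head_rng = rng
        self.head: list[Linear] = []
        self.out: Linear | None = None
        self._built = False

    def build_head(self) -> None:
        d = 2 * self.extractor_config.output_dim
        self.head = []
        for _ in range(self.head_layers_n):
            self.head.append(Linear(d, self.head_units, self._head_rng))
            d = self.head_units
        self.out = Linear(d, self.n_phenotypes, self._head_rng)
        self._built = True

    def fit_featurizer(self, train_smiles: list[str]) -> None:
        self.extractor.fit(train_smiles)
        self.build_head()

    def forward_pairs(self, smiles1: list[str], smiles2: list[str]) -> Tensor:
        """Sigmoid phenotype probabilities for aligned SMILES lists."""
        if not self._built:
            raise RuntimeError("call fit_featurizer() before forward_pairs()")
        # both drugs pass through the SAME extractor instance (weight sharing)
        z1 = self.extractor.forward(self.extractor.encode(smiles1))
        z2 = self.extractor.forward(self.extractor.encode(smiles2))
        h = concat([z1, z2], axis=-1)
        for lay in self.head:
            h = lay(h).relu()
        return self.out(h).sigmoid()

    def embed(self, smiles: list[str]) -> np.ndarray:
        """Drug embeddings phi(x) (eval mode), as a NumPy array."""
        was_training = self.training
        self.eval()
        try:
            return self.extractor.forward(self.extractor.encode(smiles)).data.copy()
        finally:
            self.train(was_training)

    def parameters(self):
        out = list(self.extractor.parameters())
        for lay in self.head:
            out.extend(lay.parameters())
        if self.out is not None:
            out.extend(self.out.parameters())
        return out

    def modules(self):
        out = [self] + self.extractor.modules()
        for lay in self.head:
            out.extend(lay.modules())
        if self.out is not None:
            out.extend(self.out.modules())
        return out


@dataclass
class TrainingExample:
    """One training row: a pair index plus the SMILES strings to present.

    Augmented views carry randomized SMILES variants here; labels always
    come from the underlying pair.
    """

    pair_index: int
    smiles1: str
    smiles2: str


def canonical_examples(ds: DDIDataset, indices) -> list[TrainingExample]:
    out = []
    for i in np.asarray(indices, dtype=int):
        s1, s2 = ds.smiles_pair(int(i))
        out.append(TrainingExample(int(i), s1, s2))
    return out


def predict(
    model: PairPredictor,
    ds: DDIDataset,
    indices=None,
    symmetrize: bool = True,
    batch_size: int = 256,
) -> np.ndarray:
    """Score pairs with a trained model; returns an m x |Y| matrix.

    Rows not in `indices` are filled with 0.5 (uninformative). With
    symmetrized inference the two concatenation orders are averaged, so
    predict(a, b) == predict(b, a).
    """
    if indices is None:
        indices = np.arange(ds.n_pairs)
    indices = np.asarray(indices, dtype=int)
    was_training = model.training
    model.eval()
    scores = np.full((ds.n_pairs, model.n_phenotypes), 0.5)
    for lo in range(0, len(indices), batch_size):
        chunk = indices[lo : lo + batch_size]
        s1 = [ds.smiles_pair(int(i))[0] for i in chunk]
        s2 = [ds.smiles_pair(int(i))[1] for i in chunk]
        p = model.forward_pairs(s1, s2).data
        if symmetrize:
            p = 0.5 * (p + model.forward_pairs(s2, s1).data)
        scores[chunk] = p
    if was_training:
        model.train()
    return scores


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    valid_metric: float
    improved: bool


def train(
    model: PairPredictor,
    ds: DDIDataset,
    split: SplitResult,
    cfg: TrainConfig,
    train_examples: list[TrainingExample] | None = None,
    example_groups: list[list[TrainingExample]] | None = None,
) -> list[EpochLog]:
    """Minibatch training with early stopping on the validation metric.

    Minimizes the multilabel BCE on the training pairs (optionally an
    augmented view), evaluates `cfg.monitor` on the validation pairs after
    each epoch, stops after `patience` epochs without improvement and
    restores the best-epoch parameters.

    `example_groups` supports epoch-wise variant cycling for augmented
    views: epoch e trains on group e mod G, so every variant is seen
    across epochs while the per-epoch step count matches unaugmented
    training (no optimization-budget confound between n_variants
    settings).
    """
    ok, violations = validate_split(ds, split)
    if not ok:
        raise ValueError(f"invalid split: {violations}")
    if len(split.train) == 0:
        raise ValueError("empty training set")
    if example_groups is not None and train_examples is not None:
        raise ValueError("pass either train_examples or example_groups, not both")
    if example_groups is not None:
        groups = [
            g
            + (
                [TrainingExample(e.pair_index, e.smiles2, e.smiles1) for e in g]
                if cfg.symmetrize
                else []
            )
            for g in example_groups
        ]
        all_examples = [e for g in example_groups for e in g]
    else:
        if train_examples is None:
            train_examples = canonical_examples(ds, split.train)
        all_examples = train_examples
        if cfg.symmetrize:
            train_examples = train_examples + [
                TrainingExample(e.pair_index, e.smiles2, e.smiles1)
                for e in train_examples
            ]
        groups = [train_examples]
    if len({len(g) for g in groups}) != 1:
        raise ValueError("all example groups must have equal length")
    train_smiles = sorted(
        {e.smiles1 for e in all_examples} | {e.smiles2 for e in all_examples}
    )
    if not model._built:
        model.fit_featurizer(train_smiles)

    rng = np.random.Generator(np.random.PCG64([cfg.seed, 0xB]))
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    logs: list[EpochLog] = []
    best_metric = -np.inf
    best_state = model.get_state()
    bad_epochs = 0
    order = np.arange(len(groups[0]))
    for epoch in range(cfg.max_epochs):
        epoch_examples = groups[epoch % len(groups)]
        model.train()
        rng.shuffle(order)
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = [epoch_examples[k] for k in order[lo : lo + cfg.batch_size]]
            probs = model.forward_pairs(
                [e.smiles1 for e in batch], [e.smiles2 for e in batch]
            )
            labels = ds.labels[[e.pair_index for e in batch]]
            loss = _bce_loss_t(probs, labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        valid_metric = _monitor_value(model, ds, split, cfg)
        improved = valid_metric > best_metric
        if improved:
            best_metric = valid_metric
            best_state = model.get_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
        logs.append(EpochLog(epoch, float(np.mean(losses)), valid_metric, improved))
        if bad_epochs >= cfg.patience:
            break
    model.set_state(best_state)
    model.eval()
    return logs


def _monitor_value(model, ds, split, cfg) -> float:
    scores = predict(model, ds, split.valid, symmetrize=cfg.symmetrize)
    y = ds.labels[split.valid].ravel()
    s = scores[split.valid].ravel()
    if 0 < y.sum() < len(y):
        if cfg.monitor == "micro_auprc":
            return auprc(y, s)
        if cfg.monitor == "micro_auroc":
            return auroc(y, s)
    return -bce_multilabel_loss(scores[split.valid], ds.labels[split.valid])


class DDIModel:
    """Multilabel DDI prediction model bound to a dataset and a split.

    Parameters
    ----------
    dataset : DDIDataset
        The database D of drug pairs and phenotype labels.
    split : SplitResult
        Evaluation-scheme split driving training/validation/testing.
    extractor : str or ExtractorConfig
        Molecular feature extractor family (``ssp_mlp``, ``smiles_cnn``,
        ``smiles_blstm`` or ``graph_gin``) or a full config.
    train_config : TrainConfig, optional
    train_examples : list of TrainingExample, optional
        An augmented training view (see ``ddikit.robustness``); defaults
        to the canonical training pairs.
    """

    def __init__(
        self,
        dataset: DDIDataset,
        split: SplitResult,
        extractor: str | ExtractorConfig = "smiles_cnn",
        train_config: TrainConfig | None = None,
        head_layers: int = 2,
        head_units: int = 64,
        train_examples: list[TrainingExample] | None = None,
        example_groups: list[list[TrainingExample]] | None = None,
    ):
        self.dataset = dataset
        self.split = split
        if isinstance(extractor, str):
            extractor = ExtractorConfig(kind=extractor)
        self.extractor_config = extractor
        self.train_config = train_config or TrainConfig()
        self.head_layers = head_layers
        self.head_units = head_units
        self.train_examples = train_examples
        self.example_groups = example_groups

    @classmethod
    def from_files(cls, dataset_path, split_path, **kwargs) -> "DDIModel":
        from .chem import load_dataset

        ds = load_dataset(dataset_path)
        with open(split_path) as fh:
            split = SplitResult.from_json(fh.read())
        return cls(ds, split, **kwargs)

    def fit(self) -> "DDIResults":
        predictor = PairPredictor(
            self.extractor_config,
            n_phenotypes=len(self.dataset.vocab),
            head_layers=self.head_layers,
            head_units=self.head_units,
            seed=self.train_config.seed,
        )
        logs = train(
            predictor,
            self.dataset,
            self.split,
            self.train_config,
            train_examples=self.train_examples,
            example_groups=self.example_groups,
        )
        return DDIResults(self, predictor, logs)


class DDIResults:
    """Fitted DDI model: trained parameters, history and evaluation."""

    def __init__(self, model: DDIModel, predictor: PairPredictor, logs: list[EpochLog]):
        self.model = model
        self.predictor = predictor
        self.logs = logs
        self._pred_cache: dict = {}

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(l) for l in self.logs])

    @property
    def n_epochs(self) -> int:
        return len(self.logs)

    @property
    def best_epoch(self) -> int:
        best = [l.epoch for l in self.logs if l.improved]
        return best[-1] if best else 0

    def predict(self, indices=None) -> np.ndarray:
        key = "all" if indices is None else tuple(np.asarray(indices, dtype=int))
        if key not in self._pred_cache:
            self._pred_cache[key] = predict(
                self.predictor,
                self.model.dataset,
                indices,
                symmetrize=self.model.train_config.symmetrize,
            )
        return self._pred_cache[key]

    def evaluate(self, subset: str = "test", binning=None) -> MetricsReport:
        idx = self.model.split.subset(subset)
        return evaluate(self.predict(idx), self.model.dataset, idx, binning=binning)

    def summary(self) -> str:
        ds, split = self.model.dataset, self.model.split
        audits = audit_split(ds, split)
        rep_va = self.evaluate("valid")
        rep_te = self.evaluate("test")
        cfg = self.model.extractor_config
        lines = [
            "DDI model results",
            "=" * 60,
            f"extractor:        {cfg.kind} (layers={cfg.hidden_layers}, "
            f"units={cfg.hidden_units}, out={cfg.output_dim})",
            f"scheme:           {split.scheme} (seed {split.seed})",
            f"pairs:            m={ds.n_pairs}  train={len(split.train)} "
            f"valid={len(split.valid)} test={len(split.test)} unused={len(split.unused)}",
            f"phenotypes:       {len(ds.vocab)}",
            f"epochs run:       {self.n_epochs} (best epoch {self.best_epoch})",
            f"test audit:       SS={audits['test'].SS} SU={audits['test'].SU} "
            f"UU={audits['test'].UU}",
            "-" * 60,
            f"{'subset':<10}{'micro-AUROC':>12}{'micro-AUPRC':>12}"
            f"{'macro-AUROC':>12}{'macro-AUPRC':>12}",
            f"{'valid':<10}{rep_va.micro_auroc:>12.4f}{rep_va.micro_auprc:>12.4f}"
            f"{rep_va.macro_auroc:>12.4f}{rep_va.macro_auprc:>12.4f}",
            f"{'test':<10}{rep_te.micro_auroc:>12.4f}{rep_te.micro_auprc:>12.4f}"
            f"{rep_te.macro_auroc:>12.4f}{rep_te.macro_auprc:>12.4f}",
            "=" * 60,
        ]
        return "\n".join(lines)
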