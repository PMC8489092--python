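"""Molecular feature extractors phi: drug -> fixed-width real vector.

Four interchangeable families, all sharing the same interface:

- ``ssp_mlp``   — structural similarity profile (Tanimoto vs a reference
                  drug panel) through a batch-normalized ReLU MLP; the
                  reference panel is fitted on the *training* drugs only
                  so no information about unseen drugs leaks into the
                  representation.
- ``smiles_cnn``— character embeddings, stacked width-7 1D convolutions
                  with batch norm and width-2 max pooling, global masked
                  max pool over the sequence.
- ``smiles_blstm`` — character embeddings through bidirectional LSTM
                  layers; the final forward/backward states at the last
                  layer summarize the string.
- ``graph_gin`` — graph isomorphism network message passing on the
                  molecular graph with MLP node updates and mean pooling;
                  exactly invariant to the atom order of the input SMILES,
                  which the sequence extractors are not.

Each extractor exposes ``fit(train_smiles)``, ``encode(smiles_list)``
(NumPy batch construction, cached per molecule where possible) and
``forward(batch) -> Tensor of shape (B, output_dim)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from ..chem import compute_ecfp6
from .layers import BatchNorm1d, Embedding, Linear, Module, LSTMCell, MLP, lstm_scan
from .tensor import Tensor, concat, conv1d_same, global_masked_max, masked_max_pool2

EXTRACTOR_KINDS = ("ssp_mlp", "smiles_cnn", "smiles_blstm", "graph_gin")

PAD, UNK = 0, 1

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]
_MAX_DEGREE = 5
GIN_NODE_DIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1  # element+other, degree, aromatic


@dataclass
class ExtractorConfig:
    """Architecture hyperparameters for a molecular feature extractor."""

    kind: str = "smiles_cnn"
    hidden_layers: int = 2
    hidden_units: int = 32
    embedding_dim: int = 16
    output_dim: int = 32
    kernel_size: int = 7
    max_len: int = 400
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EXTRACTOR_KINDS:
            raise ValueError(f"unknown extractor kind {self.kind!r}")
        for f in ("hidden_layers", "hidden_units", "embedding_dim", "output_dim"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def pooled_length(length: int, n_layers: int) -> int:
    """Sequence length after `n_layers` width-2 max-pooling steps (ceil)."""
    for _ in range(n_layers):
        length = (length + 1) // 2
    return length


class CharVocab:
    """SMILES character vocabulary with PAD=0 and UNK=1 tokens."""

    def __init__(self, smiles_iter):
        chars = sorted(set().union(*[set(s) for s in smiles_iter]))
        self.index = {c: i + 2 for i, c in enumerate(chars)}

    def __len__(self):
        return len(self.index) + 2

    def encode(self, s: str, max_len: int) -> np.ndarray:
        if len(s) > max_len:
            raise ValueError(f"SMILES longer than configured maximum {max_len}: {s!r}")
        ids = np.full(len(s), UNK, dtype=np.int64)
        for i, c in enumerate(s):
            ids[i] = self.index.get(c, UNK)
        return ids


def _pad_batch(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    L = max(len(s) for s in seqs)
    ids = np.zeros((len(seqs), L), dtype=np.int64)  # PAD = 0
    mask = np.zeros((len(seqs), L))
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return ids, mask


class SSPMLPExtractor(Module):
    """DeepDDI-style extractor: SSP against train drugs, then an MLP."""

    kind = "ssp_mlp"

    def __init__(self, cfg: ExtractorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.reference_fps: np.ndarray | None = None
        self.reference_ids: list[str] = []
        self._rng = rng
        self.net: MLP | None = None
        self._ssp_cache: dict[str, np.ndarray] = {}

    def fit(self, train_smiles: list[str]) -> None:
        ref = sorted(set(train_smiles))
        self.reference_ids = ref
        self.reference_fps = np.stack([compute_ecfp6(s) for s in ref]).astype(float)
        self.net = MLP(
            len(ref),
            self.cfg.hidden_units,
            self.cfg.hidden_layers,
            self.cfg.output_dim,
            self._rng,
            batchnorm=True,
        )
        self._ssp_cache.clear()

    def _ssp(self, smiles: str) -> np.ndarray:
        if smiles not in self._ssp_cache:
            fp = compute_ecfp6(smiles).astype(float)
            inter = self.reference_fps @ fp
            union = self.reference_fps.sum(axis=1) + fp.sum() - inter
            with np.errstate(invalid="ignore"):
                vals = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
            self._ssp_cache[smiles] = vals
        return self._ssp_cache[smiles]

    def encode(self, smiles_list: list[str]) -> np.ndarray:
        if self.reference_fps is None:
            raise RuntimeError("ssp_mlp extractor must be fitted on train drugs first")
        return np.stack([self._ssp(s) for s in smiles_list])

    def forward(self, batch: np.ndarray) -> Tensor:
        return self.net(Tensor(batch))

    def parameters(self):
        return self.net.parameters() if self.net is not None else []

    def modules(self):
        return [self] + (self.net.modules() if self.net is not None else [])


class SmilesCNNExtractor(Module):
    """Character 1D-CNN: width-7 kernels, batch norm, width-2 max pooling."""

    kind = "smiles_cnn"

    def __init__(self, cfg: ExtractorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.vocab: CharVocab | None = None
        self._rng = rng
        self.convs: list[Linear] = []
        self.norms: list[BatchNorm1d] = []
        self.proj: Linear | None = None

    def fit(self, train_smiles: list[str]) -> None:
        self.vocab = CharVocab(train_smiles)
        rng = self._rng
        self.emb = Embedding(len(self.vocab), self.cfg.embedding_dim, rng)
        self.convs, self.norms = [], []
        d = self.cfg.embedding_dim
        k = self.cfg.kernel_size
        for _ in range(self.cfg.hidden_layers):
            self.convs.append(Linear(k * d, self.cfg.hidden_units, rng))
            self.norms.append(BatchNorm1d(self.cfg.hidden_units))
            d = self.cfg.hidden_units
        self.proj = Linear(d, self.cfg.output_dim, rng)

    def encode(self, smiles_list: list[str]) -> tuple[np.ndarray, np.ndarray]:
        if self.vocab is None:
            raise RuntimeError("smiles_cnn extractor must be fitted first")
        return _pad_batch([self.vocab.encode(s, self.cfg.max_len) for s in smiles_list])

    def forward(self, batch) -> Tensor:
        ids, mask = batch
        k = self.cfg.kernel_size
        # zero PAD-position embeddings so a sequence's features do not
        # depend on how much padding the batch carries
        x = self.emb(ids) * Tensor(mask[:, :, None])  # (B, L, E)
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv1d_same(x, conv.W, conv.b, k)).relu()
            # width-2 max pooling; PAD positions ignored
            x, mask = masked_max_pool2(x, mask)
        x = global_masked_max(x, mask)
        return self.proj(x)

    def parameters(self):
        if self.vocab is None:
            return []
        out = self.emb.parameters()
        for c, n in zip(self.convs, self.norms):
            out.extend(c.parameters())
            out.extend(n.parameters())
        out.extend(self.proj.parameters())
        return out

    def modules(self):
        if self.vocab is None:
            return [self]
        out = [self] + self.emb.modules()
        for c, n in zip(self.convs, self.norms):
            out.extend(c.modules())
            out.extend(n.modules())
        out.extend(self.proj.modules())
        return out


class SmilesBLSTMExtractor(Module):
    """Character bidirectional LSTM; final states summarize the string."""

    kind = "smiles_blstm"

    def __init__(self, cfg: ExtractorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.vocab: CharVocab | None = None
        self._rng = rng
        self.cells_f: list[LSTMCell] = []
        self.cells_b: list[LSTMCell] = []
        self.proj: Linear | None = None

    def fit(self, train_smiles: list[str]) -> None:
        self.vocab = CharVocab(train_smiles)
        rng = self._rng
        self.emb = Embedding(len(self.vocab), self.cfg.embedding_dim, rng)
        self.cells_f, self.cells_b = [], []
        d = self.cfg.embedding_dim
        for _ in range(self.cfg.hidden_layers):
            self.cells_f.append(LSTMCell(d, self.cfg.hidden_units, rng))
            self.cells_b.append(LSTMCell(d, self.cfg.hidden_units, rng))
            d = 2 * self.cfg.hidden_units
        self.proj = Linear(d, self.cfg.output_dim, rng)

    encode = SmilesCNNExtractor.encode

    def forward(self, batch) -> Tensor:
        ids, mask = batch
        lengths = mask.sum(axis=1).astype(int)
        x = self.emb(ids)
        h_f = h_b = None
        for cf, cb in zip(self.cells_f, self.cells_b):
            outs_f, h_f = lstm_scan(cf, x, mask, reverse=False)
            outs_b, h_b = lstm_scan(cb, x, mask, reverse=True)
            steps = [concat([f, b], axis=-1).reshape(x.shape[0], 1, -1)
                     for f, b in zip(outs_f, outs_b)]
            x = concat(steps, axis=1)
        final = concat([h_f, h_b], axis=-1)
        return self.proj(final.relu())

    def parameters(self):
        if self.vocab is None:
            return []
        out = self.emb.parameters()
        for cf, cb in zip(self.cells_f, self.cells_b):
            out.extend(cf.parameters())
            out.extend(cb.parameters())
        out.extend(self.proj.parameters())
        return out

    def modules(self):
        if self.vocab is None:
            return [self]
        out = [self] + self.emb.modules()
        for cf, cb in zip(self.cells_f, self.cells_b):
            out.extend(cf.modules())
            out.extend(cb.modules())
        out.extend(self.proj.modules())
        return out


def gin_graph(smiles: str) -> tuple[np.ndarray, np.ndarray]:
    """Node feature matrix and adjacency of the molecular graph.

    Node features: element one-hot (+ catch-all), degree one-hot (capped),
    aromaticity flag. Bond features are not used by the GIN update.

    Atoms are renumbered to their canonical ranks first, so two SMILES of
    the same molecule yield bitwise-identical graph tensors and the GIN
    representation is *exactly* invariant to the atom order of the input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    ranks = list(Chem.CanonicalRankAtoms(mol))
    order = [0] * mol.GetNumAtoms()
    for idx, rank in enumerate(ranks):
        order[rank] = idx
    mol = Chem.RenumberAtoms(mol, order)
    n = mol.GetNumAtoms()
    X = np.zeros((n, GIN_NODE_DIM))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        j = _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)
        X[i, j] = 1.0
        deg = min(atom.GetDegree(), _MAX_DEGREE)
        X[i, len(_ELEMENTS) + 1 + deg] = 1.0
        X[i, -1] = float(atom.GetIsAromatic())
    A = np.zeros((n, n))
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[a, b] = A[b, a] = 1.0
    return X, A


class GraphGINExtractor(Module):
    """GIN message passing with MLP node updates and mean pooling."""

    kind = "graph_gin"

    def __init__(self, cfg: ExtractorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self._graph_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.mlps: list[MLP] = []
        d = GIN_NODE_DIM
        for _ in range(cfg.hidden_layers):
            self.mlps.append(MLP(d, cfg.hidden_units, 1, cfg.hidden_units, rng))
            d = cfg.hidden_units
        self.proj = Linear(d, cfg.output_dim, rng)

    def fit(self, train_smiles: list[str]) -> None:  # nothing to fit
        pass

    def encode(self, smiles_list: list[str]):
        graphs = []
        for s in smiles_list:
            if s not in self._graph_cache:
                self._graph_cache[s] = gin_graph(s)
            graphs.append(self._graph_cache[s])
        A_max = max(g[0].shape[0] for g in graphs)
        B = len(graphs)
        X = np.zeros((B, A_max, GIN_NODE_DIM))
        Adj = np.zeros((B, A_max, A_max))
        node_mask = np.zeros((B, A_max))
        for i, (x, a) in enumerate(graphs):
            n = x.shape[0]
            X[i, :n] = x
            Adj[i, :n, :n] = a
            node_mask[i, :n] = 1.0
        return X, Adj, node_mask

    def forward(self, batch) -> Tensor:
        X, Adj, node_mask = batch
        h = Tensor(X)
        adj = Tensor(Adj)
        mask = node_mask[:, :, None]
        for mlp in self.mlps:
            agg = adj @ h + h  # (1 + eps) h + sum over neighbours, eps = 0
            h = mlp(agg) * mask  # zero out padding nodes
        counts = node_mask.sum(axis=1, keepdims=True)
        pooled = h.sum(axis=1) * (1.0 / counts)
        return self.proj(pooled)

    def parameters(self):
        out = []
        for m in self.mlps:
            out.extend(m.parameters())
        out.extend(self.proj.parameters())
        return out

    def modules(self):
        out = [self]
        for m in self.mlps:
            out.extend(m.modules())
        out.extend(self.proj.modules())
        return out


_EXTRACTORS = {
    "ssp_mlp": SSPMLPExtractor,
    "smiles_cnn": SmilesCNNExtractor,
    "smiles_blstm": SmilesBLSTMExtractor,
    "graph_gin": GraphGINExtractor,
}


def build_extractor(cfg: ExtractorConfig, rng: np.random.Generator) -> Module:
    """Instantiate an extractor of the configured kind (unfitted)."""
    try:
        cls = _EXTRACTORS[cfg.kind]
    except KeyError:
        raise ValueError(f"unknown extractor kind {cfg.kind!r}") from None
    return cls(cfg, rng)
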