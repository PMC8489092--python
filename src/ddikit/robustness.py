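"""Randomized-SMILES augmentation, MMD shift diagnostics, FP/FN triage.

A molecule admits many valid SMILES strings (one per atom output order).
Sequence extractors are sensitive to that order, graph extractors are
not; presenting several randomized variants of every training molecule
(augmentation) makes sequence models markedly less sensitive and narrows
the generalization gap between evaluation schemes.

The maximum mean discrepancy (MMD) quantifies how far the drug-feature
distribution of an evaluation subset drifts from the training drugs —
drug-disjoint schemes drift further than random splits.

Triage scans a prediction matrix for high-scoring negatives (potential
missing interactions) and low-scoring positives (potential mislabels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from .chem import DDIDataset, Molecule, compute_ecfp6, pair_similarity
from .model import TrainingExample, canonical_examples
from .splitting import SplitResult, train_drug_set


@dataclass
class AugmentationConfig:
    """Randomized-SMILES augmentation of the *training* pairs only."""

    n_variants: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


def enumerate_smiles(mol: Molecule | str, n: int, seed: int = 0) -> list[str]:
    """`n` randomized atom-order SMILES of one molecule.

    Sampling is with replacement when the molecule admits fewer distinct
    variants than requested; every returned string canonicalizes back to
    the molecule's canonical SMILES.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    smiles = mol.smiles_canonical if isinstance(mol, Molecule) else mol
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return list(Chem.MolToRandomSmilesVect(rdmol, n, randomSeed=int(seed) & 0x7FFFFFFF))


def augment_dataset(
    ds: DDIDataset, split: SplitResult, cfg: AugmentationConfig
) -> list[TrainingExample]:
    """Build an augmented training view: each pair replicated n_variants times.

    Replicate 0 presents the canonical SMILES; further replicates present
    independently sampled randomized variants for both drugs. Labels, pair
    identity and the validation/test partitions are untouched; with
    n_variants=1 the view equals the canonical training set.
    """
    base = canonical_examples(ds, split.train)
    if cfg.n_variants == 1:
        return base
    # pre-enumerate variants per training drug
    drugs = sorted(train_drug_set(ds, split))
    variants: dict[str, list[str]] = {}
    for k, d in enumerate(drugs):
        smi = ds.drugs[d].smiles_canonical
        variants[d] = enumerate_smiles(smi, (cfg.n_variants - 1) * 4, seed=cfg.seed + k)
    rng = np.random.Generator(np.random.PCG64([cfg.seed, 0xA]))
    out = list(base)
    for rep in range(1, cfg.n_variants):
        for e in base:
            d1, d2 = ds.pairs[e.pair_index]
            v1 = variants[d1][rng.integers(len(variants[d1]))]
            v2 = variants[d2][rng.integers(len(variants[d2]))]
            out.append(TrainingExample(e.pair_index, v1, v2))
    return out


def augment_groups(
    ds: DDIDataset, split: SplitResult, cfg: AugmentationConfig
) -> list[list[TrainingExample]]:
    """The augmented view split into n_variants aligned replicate groups.

    Group 0 is the canonical training set; each further group presents
    one independently sampled variant per pair. Suitable for epoch-wise
    variant cycling, which keeps the per-epoch optimization budget equal
    across n_variants settings.
    """
    flat = augment_dataset(ds, split, cfg)
    m = len(split.train)
    return [flat[i * m : (i + 1) * m] for i in range(cfg.n_variants)]


@dataclass
class MMDEstimate:
    """Biased (V-statistic) kernel MMD^2 between two feature samples."""

    value: float
    kernel: str
    bandwidth: float
    n_x: int
    n_y: int


def mmd(X: np.ndarray, Y: np.ndarray, bandwidth: float | None = None) -> MMDEstimate:
    """Gaussian-kernel maximum mean discrepancy between two samples.

    Uses the biased V-statistic estimator (always >= 0 up to rounding) and
    the median pairwise-distance heuristic for the bandwidth unless one is
    given explicitly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("both samples must be non-empty")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    Z = np.vstack([X, Y])
    D = cdist(Z, Z, metric="euclidean")
    if bandwidth is None:
        off = D[np.triu_indices_from(D, k=1)]
        med = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
        bandwidth = med if med > 0 else 1.0
    K = np.exp(-(D**2) / (2.0 * bandwidth**2))
    n, m = X.shape[0], Y.shape[0]
    kxx = K[:n, :n].mean()
    kyy = K[n:, n:].mean()
    kxy = K[:n, n:].mean()
    return MMDEstimate(
        value=float(kxx + kyy - 2.0 * kxy),
        kernel="rbf",
        bandwidth=float(bandwidth),
        n_x=n,
        n_y=m,
    )


def drug_features(
    ds: DDIDataset, drug_ids, predictor=None
) -> np.ndarray:
    """Per-drug feature matrix: trained extractor embeddings, or ECFP6
    fingerprints when no predictor is supplied (flag-style fallback)."""
    ids = sorted(drug_ids)
    smiles = [ds.drugs[d].smiles_canonical for d in ids]
    if predictor is not None:
        return predictor.embed(smiles)
    return np.stack([compute_ecfp6(s) for s in smiles]).astype(float)


@dataclass
class TriageRecord:
    """A (pair, phenotype) cell flagged by the database-validation scan."""

    pair: tuple[str, str]
    phenotype: str
    label: int
    score: float
    category: str  # potential_DDI | potential_mislabel


def triage(
    preds: np.ndarray,
    ds: DDIDataset,
    subset,
    hi: float = 0.7,
    lo: float = 0.1,
) -> list[TriageRecord]:
    """Scan predictions for potential new DDIs and potential mislabels.

    potential_DDI: label 0 with score >= `hi` (sorted by descending score);
    potential_mislabel: label 1 with score <= `lo` (ascending score).
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    subset = np.asarray(subset, dtype=int)
    pos_recs, neg_recs = [], []
    for i in subset:
        for j, name in enumerate(ds.vocab.names):
            s = float(preds[i, j])
            lab = int(ds.labels[i, j])
            if lab == 0 and s >= hi:
                neg_recs.append(
                    TriageRecord(ds.pairs[i], name, 0, s, "potential_DDI")
                )
            elif lab == 1 and s <= lo:
                pos_recs.append(
                    TriageRecord(ds.pairs[i], name, 1, s, "potential_mislabel")
                )
    neg_recs.sort(key=lambda r: -r.score)
    pos_recs.sort(key=lambda r: r.score)
    return neg_recs + pos_recs


def triage_table(records: list[TriageRecord], ds: DDIDataset, split: SplitResult):
    """Tabulate triage records with the phenotype's train frequency (%)."""
    import pandas as pd

    freq = ds.labels[split.train].mean(axis=0) * 100.0
    rows = [
        {
            "drug1": r.pair[0],
            "drug2": r.pair[1],
            "side_effect": r.phenotype,
            "se_freq_pct": round(float(freq[ds.vocab.index[r.phenotype]]), 2),
            "score": r.score,
            "category": r.category,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["drug1", "drug2", "side_effect", "se_freq_pct", "score", "category"]
    )


def similarity_distributions(
    ds: DDIDataset,
    split: SplitResult,
    preds: np.ndarray,
    phenotype: str,
    threshold: float = 0.5,
) -> dict[str, list[float]]:
    """Similarity of each test pair to its nearest positive training pair,
    grouped by confusion category (TP/FP/TN/FN) for one phenotype.

    Predictions are binarized at `threshold`; for every test pair the
    maximum pair similarity against all positive training pairs of the
    phenotype is kept (nearest-neighbour aggregation).
    """
    j = ds.vocab.index[phenotype]
    train_pos = [i for i in split.train if ds.labels[i, j] == 1]
    if not train_pos:
        raise ValueError(f"phenotype {phenotype!r} has no positive training pairs")
    cache: dict[str, np.ndarray] = {}
    train_pairs = [
        (ds.drugs[a].smiles_canonical, ds.drugs[b].smiles_canonical)
        for a, b in (ds.pairs[i] for i in train_pos)
    ]
    out: dict[str, list[float]] = {"TP": [], "FP": [], "TN": [], "FN": []}
    for i in split.test:
        lab = int(ds.labels[i, j])
        pred = int(preds[i, j] >= threshold)
        cat = {(1, 1): "TP", (0, 1): "FP", (0, 0): "TN", (1, 0): "FN"}[(lab, pred)]
        p = ds.smiles_pair(int(i))
        best = max(pair_similarity(p, q, fp_cache=cache) for q in train_pairs)
        out[cat].append(float(best))
    return out
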