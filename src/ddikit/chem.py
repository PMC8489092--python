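"""Domain types, dataset I/O, molecular featurization and similarity.

A DDI database is a set of unordered drug pairs, each annotated with a
subset of a fixed phenotype vocabulary (side effects / PK-PD effects).
Phenotypes not listed for a pair are treated as negatives (closed-world
assumption), which makes the task a noisy, heavily imbalanced multilabel
classification problem.

Molecules are identified by their canonical SMILES; structural features
are 2048-bit ECFP6 (Morgan radius-3) fingerprints, compared with the
Tanimoto coefficient, optionally expanded into structural similarity
profiles (SSP) against a reference drug panel.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

FP_BITS = 2048
FP_RADIUS = 3  # ECFP6 = diameter 6

#: reserved token in synonym maps: phenotypes mapped to it are removed
DROP_TOKEN = "__DROP__"

_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


def canonicalize_smiles(s: str) -> str:
    """Return the RDKit canonical form of a SMILES string.

    Idempotent; two SMILES of the same molecule map to the same output.
    Raises :class:`SmilesParseError` naming the offending string.
    """
    if not s:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {s!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Molecule:
    """A drug: identifier, input SMILES and its canonical form."""

    id: str
    smiles_input: str
    smiles_canonical: str = ""

    def __post_init__(self):
        if not self.smiles_canonical:
            object.__setattr__(
                self, "smiles_canonical", canonicalize_smiles(self.smiles_input)
            )

    @property
    def rdkit_mol(self):
        return Chem.MolFromSmiles(self.smiles_canonical)


def compute_ecfp6(mol: Molecule | str) -> np.ndarray:
    """2048-bit binary ECFP6 (Morgan radius-3) fingerprint as a uint8 array."""
    smiles = mol.smiles_canonical if isinstance(mol, Molecule) else mol
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    fp = _fpgen.GetFingerprint(rdmol)
    arr = np.zeros(FP_BITS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary fingerprints.

    Two all-zero fingerprints are defined to have similarity 1.0 (they are
    identical objects); this degenerate case cannot arise from a real
    molecule but keeps the function total.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return inter / union


def pair_similarity(p, q, fp_cache: dict | None = None) -> float:
    """Similarity of drug pair p=(a,b) to drug pair q=(c,d).

    Defined as 0.5*max(t(a,c), t(a,d)) + 0.5*max(t(b,c), t(b,d)) with t the
    ECFP6 Tanimoto coefficient. Note the formula is *not* symmetric in its
    two pair arguments: it scores how well each drug of p is covered by q.
    """

    def fp(m):
        key = m.smiles_canonical if isinstance(m, Molecule) else m
        if fp_cache is not None:
            if key not in fp_cache:
                fp_cache[key] = compute_ecfp6(key)
            return fp_cache[key]
        return compute_ecfp6(key)

    a, b = p
    c, d = q
    fa, fb, fc, fd = fp(a), fp(b), fp(c), fp(d)
    return 0.5 * max(tanimoto(fa, fc), tanimoto(fa, fd)) + 0.5 * max(
        tanimoto(fb, fc), tanimoto(fb, fd)
    )


@dataclass
class SimilarityProfile:
    """Tanimoto similarities of one molecule against a reference drug panel."""

    values: np.ndarray
    reference_ids: list[str]


def compute_ssp(mol: Molecule | str, reference: list[Molecule]) -> SimilarityProfile:
    """Structural similarity profile: Tanimoto of `mol` vs each reference drug."""
    if not reference:
        raise ValueError("SSP reference set must be non-empty")
    f = compute_ecfp6(mol)
    vals = np.array([tanimoto(f, compute_ecfp6(r)) for r in reference])
    return SimilarityProfile(values=vals, reference_ids=[r.id for r in reference])


@dataclass
class PhenotypeVocabulary:
    """Ordered phenotype names with a name -> column-index map."""

    names: list[str]
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("phenotype names must be unique")
        if not self.index:
            self.index = {n: i for i, n in enumerate(self.names)}

    def __len__(self):
        return len(self.names)


@dataclass
class DDIDataset:
    """The database D: drugs, unordered pairs and the m x |Y| label matrix."""

    drugs: dict[str, Molecule]
    pairs: list[tuple[str, str]]
    labels: np.ndarray
    vocab: PhenotypeVocabulary

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        seen = set()
        for i, (d1, d2) in enumerate(self.pairs):
            if d1 not in self.drugs or d2 not in self.drugs:
                raise ValueError(f"pair {i} references unknown drug id")
            if d1 == d2:
                raise ValueError(f"pair {i} is a self-pair ({d1})")
            key = (min(d1, d2), max(d1, d2))
            if key in seen:
                raise ValueError(f"duplicate unordered pair {key}")
            seen.add(key)
            self.pairs[i] = key
        if self.labels.shape != (len(self.pairs), len(self.vocab)):
            raise ValueError(
                f"label matrix shape {self.labels.shape} != "
                f"({len(self.pairs)}, {len(self.vocab)})"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.drugs)

    def smiles_pair(self, i: int) -> tuple[str, str]:
        d1, d2 = self.pairs[i]
        return self.drugs[d1].smiles_canonical, self.drugs[d2].smiles_canonical


@dataclass
class DatasetStats:
    m: int
    n_phenotypes: int
    n_unique_drugs: int
    mean_labels_per_pair: float
    median_labels_per_pair: float
    label_density: float
    phenotype_frequencies: np.ndarray


def label_density(mean_labels_per_pair: float, n_phenotypes: int) -> float:
    """Label density LD = mean positive labels per pair / vocabulary size."""
    return mean_labels_per_pair / n_phenotypes


def dataset_stats(ds: DDIDataset) -> DatasetStats:
    """Summary statistics of a DDI database (pair count, LD, frequencies)."""
    if ds.n_pairs == 0:
        raise ValueError("empty dataset")
    per_pair = ds.labels.sum(axis=1)
    mean = float(per_pair.mean())
    return DatasetStats(
        m=ds.n_pairs,
        n_phenotypes=len(ds.vocab),
        n_unique_drugs=len(ds.drugs),
        mean_labels_per_pair=mean,
        median_labels_per_pair=float(np.median(per_pair)),
        label_density=label_density(mean, len(ds.vocab)),
        phenotype_frequencies=ds.labels.mean(axis=0).astype(float),
    )


# ---------------------------------------------------------------------------
# dataset file I/O

REQUIRED_COLUMNS = ["drug1_id", "drug2_id", "drug1_smiles", "drug2_smiles", "labels"]


def load_dataset(
    path,
    sep: str = "\t",
    label_sep: str = "|",
    vocabulary: list[str] | None = None,
) -> DDIDataset:
    """Read a DDI dataset from a delimited text file.

    Expected header columns: drug1_id, drug2_id, drug1_smiles, drug2_smiles,
    labels (multi-valued, `label_sep`-separated; empty = all-negative pair).
    SMILES are canonicalized; duplicate unordered pairs are merged by OR-ing
    their label vectors. The vocabulary is the sorted union of observed
    labels unless supplied explicitly.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")

    drugs: dict[str, Molecule] = {}
    raw: dict[tuple[str, str], set[str]] = {}
    order: list[tuple[str, str]] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        for did, smi in ((row.drug1_id, row.drug1_smiles), (row.drug2_id, row.drug2_smiles)):
            try:
                canon = canonicalize_smiles(smi)
            except SmilesParseError as e:
                raise SmilesParseError(f"row {row_no}: {e}") from e
            if did in drugs:
                if drugs[did].smiles_canonical != canon:
                    raise ValueError(
                        f"row {row_no}: drug id {did!r} bound to conflicting SMILES"
                    )
            else:
                drugs[did] = Molecule(id=did, smiles_input=smi, smiles_canonical=canon)
        labels = {t for t in row.labels.split(label_sep) if t}
        key = (min(row.drug1_id, row.drug2_id), max(row.drug1_id, row.drug2_id))
        if key in raw:
            raw[key] |= labels
        else:
            raw[key] = labels
            order.append(key)

    if vocabulary is None:
        vocabulary = sorted(set().union(*raw.values())) if raw else []
    vocab = PhenotypeVocabulary(names=list(vocabulary))
    labels_mat = np.zeros((len(order), len(vocab)), dtype=np.uint8)
    for i, key in enumerate(order):
        for name in raw[key]:
            if name in vocab.index:
                labels_mat[i, vocab.index[name]] = 1
    return DDIDataset(drugs=drugs, pairs=list(order), labels=labels_mat, vocab=vocab)


def save_dataset(ds: DDIDataset, path, sep: str = "\t", label_sep: str = "|") -> None:
    """Write a dataset in the same delimited format read by :func:`load_dataset`."""
    rows = []
    for i, (d1, d2) in enumerate(ds.pairs):
        names = [ds.vocab.names[j] for j in np.flatnonzero(ds.labels[i])]
        rows.append(
            {
                "drug1_id": d1,
                "drug2_id": d2,
                "drug1_smiles": ds.drugs[d1].smiles_canonical,
                "drug2_smiles": ds.drugs[d2].smiles_canonical,
                "labels": label_sep.join(names),
            }
        )
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, sep=sep, index=False)


def load_synonym_map(path, sep: str = "\t") -> dict[str, str]:
    """Two-column table old_name -> group_name (group __DROP__ removes)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("synonym map needs two columns: old_name, group_name")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def apply_synonym_map(
    ds: DDIDataset,
    synmap: dict[str, str],
    unmapped: str = "keep",
    strict: bool = True,
) -> DDIDataset:
    """Group phenotypes under synonym names; OR the member columns.

    A pair is positive for a group iff it was positive for any member.
    Names mapped to :data:`DROP_TOKEN` are removed; unmapped names either
    pass through unchanged (``unmapped="keep"``) or are dropped
    (``unmapped="drop"``). With ``strict``, map entries that reference
    unknown phenotypes raise.
    """
    unknown = sorted(set(synmap) - set(ds.vocab.names))
    if unknown:
        if strict:
            raise ValueError(f"synonym map references unknown phenotypes: {unknown}")
        import warnings

        warnings.warn(f"ignoring unknown phenotypes in synonym map: {unknown}")
    target: dict[str, str | None] = {}
    for name in ds.vocab.names:
        g = synmap.get(name, name if unmapped == "keep" else DROP_TOKEN)
        target[name] = None if g == DROP_TOKEN else g
    groups = sorted({g for g in target.values() if g is not None})
    if not groups:
        raise ValueError("synonym map removes every phenotype")
    new_vocab = PhenotypeVocabulary(names=groups)
    new_labels = np.zeros((ds.n_pairs, len(groups)), dtype=np.uint8)
    for j, name in enumerate(ds.vocab.names):
        g = target[name]
        if g is not None:
            k = new_vocab.index[g]
            new_labels[:, k] |= ds.labels[:, j]
    return DDIDataset(
        drugs=dict(ds.drugs), pairs=list(ds.pairs), labels=new_labels, vocab=new_vocab
    )


def filter_rare_phenotypes(ds: DDIDataset, min_count: int) -> DDIDataset:
    """Drop phenotype columns with fewer than `min_count` positive pairs.

    Pairs left with zero positives are retained as all-negative examples.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = ds.labels.sum(axis=0)
    keep = np.flatnonzero(counts >= min_count)
    if keep.size == 0:
        raise ValueError(f"min_count={min_count} filters out every phenotype")
    vocab = PhenotypeVocabulary(names=[ds.vocab.names[j] for j in keep])
    return DDIDataset(
        drugs=dict(ds.drugs),
        pairs=list(ds.pairs),
        labels=ds.labels[:, keep].copy(),
        vocab=vocab,
    )


def dataset_digest(ds: DDIDataset) -> str:
    """Stable content hash of a dataset (pairs, SMILES, labels, vocab)."""
    import hashlib

    h = hashlib.blake2b(digest_size=16)
    buf = io.StringIO()
    save_dataset(ds, buf)
    h.update(buf.getvalue().encode())
    return h.hexdigest()
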