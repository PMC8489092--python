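import numpy as np
import pytest

from ddikit.synth import SyntheticSpec, generate_ddi_dataset, generate_molecules


@pytest.fixture(scope="session")
def toy_ds():
    """Small structure-regime dataset shared across tests (40 drugs)."""
    ds, _ = generate_ddi_dataset(
        SyntheticSpec(n_drugs=40, n_phenotypes=6, pair_density=0.4, seed=2)
    )
    return ds


@pytest.fixture(scope="session")
def molecules100():
    """A pool of 100 generated drug-like molecules."""
    return generate_molecules(100, n_clusters=4, seed=0)


def complete_graph_dataset(n_drugs: int, n_phenotypes: int = 3, seed: int = 0):
    """Dataset over all pairs of n simple alkane/alcohol drugs."""
    from ddikit.chem import DDIDataset, Molecule, PhenotypeVocabulary

    base = ["C", "CC", "CCC", "CCCC", "CCO", "CCCO", "CCN", "CCCN", "CCCCO", "CCCCN"]
    smiles = [base[i % len(base)] + "C" * (i // len(base)) for i in range(n_drugs)]
    drugs = {f"D{i:03d}": Molecule(id=f"D{i:03d}", smiles_input=s) for i, s in enumerate(smiles)}
    ids = sorted(drugs)
    pairs = [(ids[i], ids[j]) for i in range(n_drugs) for j in range(i + 1, n_drugs)]
    rng = np.random.Generator(np.random.PCG64(seed))
    labels = (rng.random((len(pairs), n_phenotypes)) < 0.3).astype(np.uint8)
    vocab = PhenotypeVocabulary(names=[f"P{j}" for j in range(n_phenotypes)])
    return DDIDataset(drugs=drugs, pairs=pairs, labels=labels, vocab=vocab)
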