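"""Augmentation, MMD diagnostics and triage."""

import numpy as np
import pytest
from rdkit import Chem

from ddikit.chem import DDIDataset, Molecule, PhenotypeVocabulary, canonicalize_smiles
from ddikit.nn.extractors import ExtractorConfig, build_extractor
from ddikit.robustness import (
    AugmentationConfig,
    augment_dataset,
    augment_groups,
    enumerate_smiles,
    mmd,
    similarity_distributions,
    triage,
)
from ddikit.splitting import SplitResult, random_split


class TestEnumerateSmiles:
    def test_deterministic_and_canonicalizes_back(self):
        smi = "CC(=O)Oc1ccccc1C(=O)O"
        a = enumerate_smiles(smi, 5, seed=4)
        b = enumerate_smiles(smi, 5, seed=4)
        assert a == b and len(a) == 5
        canon = canonicalize_smiles(smi)
        for v in a:
            assert canonicalize_smiles(v) == canon

    def test_ethanol_subset_of_exhaustive_enumeration(self):
        # brute-force oracle: all atom orderings of the 3-atom molecule
        mol = Chem.MolFromSmiles("CCO")
        import itertools

        universe = set()
        for perm in itertools.permutations(range(3)):
            ren = Chem.RenumberAtoms(mol, list(perm))
            universe.add(Chem.MolToSmiles(ren, canonical=False))
        variants = enumerate_smiles("CCO", 20, seed=0)
        assert set(variants) <= universe

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            enumerate_smiles("CCO", 0)
        with pytest.raises(ValueError):
            enumerate_smiles("xx$", 2)


class TestAugmentation:
    def test_counts_and_identity(self, toy_ds):
        sp = random_split(toy_ds, seed=0)
        base = augment_dataset(toy_ds, sp, AugmentationConfig(1, seed=0))
        assert len(base) == len(sp.train)
        for e in base:
            s1, s2 = toy_ds.smiles_pair(e.pair_index)
            assert (e.smiles1, e.smiles2) == (s1, s2)
        aug = augment_dataset(toy_ds, sp, AugmentationConfig(4, seed=0))
        assert len(aug) == 4 * len(sp.train)

    def test_labels_and_eval_partitions_untouched(self, toy_ds):
        sp = random_split(toy_ds, seed=0)
        aug = augment_dataset(toy_ds, sp, AugmentationConfig(3, seed=1))
        train_set = set(sp.train.tolist())
        for e in aug:
            assert e.pair_index in train_set
            assert canonicalize_smiles(e.smiles1) in {
                toy_ds.drugs[d].smiles_canonical for d in toy_ds.pairs[e.pair_index]
            }

    def test_gin_features_identical_across_variants(self, toy_ds):
        sp = random_split(toy_ds, seed=0)
        aug = augment_dataset(toy_ds, sp, AugmentationConfig(2, seed=0))
        ex = build_extractor(ExtractorConfig(kind="graph_gin", hidden_units=6, output_dim=4),
                             np.random.default_rng(0))
        ex.fit([])
        ex.eval()
        m = len(sp.train)
        for e_can, e_var in zip(aug[:5], aug[m : m + 5]):
            f1 = ex.forward(ex.encode([e_can.smiles1])).data
            f2 = ex.forward(ex.encode([e_var.smiles1])).data
            np.testing.assert_array_equal(f1, f2)

    def test_groups_align_with_flat_view(self, toy_ds):
        sp = random_split(toy_ds, seed=0)
        cfg = AugmentationConfig(3, seed=2)
        groups = augment_groups(toy_ds, sp, cfg)
        assert len(groups) == 3
        assert all(len(g) == len(sp.train) for g in groups)
        for e in groups[0]:
            assert (e.smiles1, e.smiles2) == toy_ds.smiles_pair(e.pair_index)


class TestMMD:
    def test_same_sample_is_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 5))
        assert mmd(X, X).value == pytest.approx(0.0, abs=1e-10)

    def test_shifted_gaussian_exceeds_null(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 4))
        Y0 = rng.normal(size=(500, 4))
        Y3 = rng.normal(size=(500, 4)) + 3.0
        assert mmd(X, Y3).value > mmd(X, Y0).value

    def test_permutation_invariance_and_errors(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        Y = rng.normal(size=(60, 3))
        est = mmd(X, Y)
        perm = rng.permutation(60)
        assert mmd(X, Y[perm]).value == pytest.approx(est.value, abs=1e-12)
        assert est.n_x == 50 and est.n_y == 60 and est.value >= -1e-12
        with pytest.raises(ValueError, match="dimension"):
            mmd(X, rng.normal(size=(10, 4)))


def _triage_fixture():
    drugs = {x: Molecule(id=x, smiles_input=s) for x, s in
             [("A", "CCO"), ("B", "CCC"), ("C", "CCN"), ("D", "CCS")]}
    vocab = PhenotypeVocabulary(names=["p1", "p2"])
    pairs = [("A", "B"), ("A", "C"), ("C", "D")]
    labels = np.array([[0, 1], [1, 0], [0, 0]], dtype=np.uint8)
    ds = DDIDataset(drugs=drugs, pairs=pairs, labels=labels, vocab=vocab)
    preds = np.array([[0.95, 0.05], [0.4, 0.8], [0.72, 0.3]])
    return ds, preds


class TestTriage:
    def test_manual_scan_matches(self):
        ds, preds = _triage_fixture()
        recs = triage(preds, ds, [0, 1, 2], hi=0.7, lo=0.1)
        # negatives >= 0.7: (0,p1)=0.95, (1,p2)=0.8, (2,p1)=0.72 in
        # descending score order; positives <= 0.1: (0,p2)=0.05
        ddi = [(r.pair, r.phenotype, r.score) for r in recs if r.category == "potential_DDI"]
        mis = [(r.pair, r.phenotype, r.score) for r in recs if r.category == "potential_mislabel"]
        assert ddi == [
            (("A", "B"), "p1", 0.95),
            (("A", "C"), "p2", 0.8),
            (("C", "D"), "p1", 0.72),
        ]
        assert mis == [(("A", "B"), "p2", 0.05)]

    def test_uninformative_scores_empty(self):
        ds, _ = _triage_fixture()
        preds = np.full((3, 2), 0.5)
        assert triage(preds, ds, [0, 1, 2]) == []

    def test_threshold_monotonicity(self):
        ds, preds = _triage_fixture()
        lo_recs = triage(preds, ds, [0, 1, 2], hi=0.7, lo=0.1)
        hi_recs = triage(preds, ds, [0, 1, 2], hi=0.9, lo=0.1)
        n_ddi = lambda rs: sum(r.category == "potential_DDI" for r in rs)
        assert n_ddi(hi_recs) <= n_ddi(lo_recs)
        with pytest.raises(ValueError):
            triage(preds, ds, [0], hi=0.1, lo=0.7)


class TestSimilarityDistributions:
    def test_confusion_categories_partition_and_match(self):
        ds, _ = _triage_fixture()
        split = SplitResult(
            scheme="random",
            train=np.array([0]),
            valid=np.array([1]),
            test=np.array([2, 1]),
            unused=np.array([], dtype=int),
        )
        # phenotype p2: train positives = pair 0; test pairs 1 (label 0) and 2 (label 0)
        preds = np.array([[0.5, 0.5], [0.1, 0.9], [0.2, 0.2]])
        out = similarity_distributions(ds, split, preds, "p2", threshold=0.5)
        assert len(out["FP"]) == 1 and len(out["TN"]) == 1
        assert len(out["TP"]) == 0 and len(out["FN"]) == 0

    def test_identical_pair_scores_one(self):
        ds, _ = _triage_fixture()
        split = SplitResult(
            scheme="random",
            train=np.array([0]),
            valid=np.array([2]),
            test=np.array([0]),  # the positive train pair itself
            unused=np.array([1]),
        )
        preds = np.array([[0.5, 0.9], [0.5, 0.5], [0.5, 0.5]])
        out = similarity_distributions(ds, split, preds, "p2")
        assert out["TP"] == [pytest.approx(1.0)]

    def test_requires_positive_training_pairs(self):
        ds, preds = _triage_fixture()
        split = SplitResult(
            scheme="random",
            train=np.array([2]),  # pair with no positives
            valid=np.array([0]),
            test=np.array([1]),
            unused=np.array([], dtype=int),
        )
        with pytest.raises(ValueError, match="no positive"):
            similarity_distributions(ds, split, preds, "p1")
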