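"""Domain types, SMILES handling, fingerprints, similarity, dataset ops."""

import io

import numpy as np
import pytest

from ddikit.chem import (
    DROP_TOKEN,
    DDIDataset,
    Molecule,
    PhenotypeVocabulary,
    SmilesParseError,
    apply_synonym_map,
    canonicalize_smiles,
    compute_ecfp6,
    compute_ssp,
    dataset_stats,
    filter_rare_phenotypes,
    label_density,
    load_dataset,
    pair_similarity,
    save_dataset,
    tanimoto,
)


class TestCanonicalization:
    def test_same_molecule_same_canonical_form(self):
        assert canonicalize_smiles("OCC") == canonicalize_smiles("CCO")
        # kekulized and aromatic notations of benzene coincide
        assert canonicalize_smiles("C1=CC=CC=C1") == canonicalize_smiles("c1ccccc1")

    def test_idempotent_over_generated_pool(self, molecules100):
        for m in molecules100:
            c = canonicalize_smiles(m.smiles_canonical)
            assert c == m.smiles_canonical
            assert canonicalize_smiles(c) == c

    def test_errors_name_the_offender(self):
        with pytest.raises(SmilesParseError, match="not-a-smiles"):
            canonicalize_smiles("not-a-smiles")
        with pytest.raises(SmilesParseError):
            canonicalize_smiles("")


class TestFingerprints:
    def test_variant_smiles_identical_bits(self):
        a = compute_ecfp6("c1ccccc1CCO")
        b = compute_ecfp6("OCCc1ccccc1")
        assert np.array_equal(a, b)
        assert a.shape == (2048,)
        assert set(np.unique(a)) <= {0, 1}

    def test_methane_has_set_bits(self):
        assert compute_ecfp6("C").sum() >= 1

    def test_ethanol_environment_bound(self):
        # 3 heavy atoms x radii 0..3 = at most 12 distinct environments
        assert compute_ecfp6("CCO").sum() <= 12


class TestTanimoto:
    def test_identity_and_disjoint(self):
        fp = compute_ecfp6("CCO")
        assert tanimoto(fp, fp) == 1.0
        a = np.zeros(8, dtype=np.uint8)
        b = np.zeros(8, dtype=np.uint8)
        a[[1, 2, 3]] = 1
        b[[5, 6]] = 1
        assert tanimoto(a, b) == 0.0

    def test_hand_counted_overlap(self):
        a = np.zeros(8, dtype=np.uint8)
        b = np.zeros(8, dtype=np.uint8)
        a[[1, 2, 3]] = 1
        b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_symmetry_property(self):
        rng = np.random.Generator(np.random.PCG64(0))
        for _ in range(50):
            a = (rng.random(64) < 0.3).astype(np.uint8)
            b = (rng.random(64) < 0.3).astype(np.uint8)
            assert tanimoto(a, b) == tanimoto(b, a)
            if a.sum():
                assert tanimoto(a, a) == 1.0

    def test_empty_convention_and_mismatch(self):
        z = np.zeros(16, dtype=np.uint8)
        assert tanimoto(z, z) == 1.0
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(np.zeros(8), np.zeros(16))


class TestPairSimilarity:
    def test_self_similarity_is_one(self):
        p = ("CCO", "c1ccccc1")
        assert pair_similarity(p, p) == pytest.approx(1.0)

    def test_formula_is_not_symmetric_in_pairs(self):
        # a=b=c=ethanol, d=benzene: fingerprints of ethanol and benzene
        # are disjoint, so t(a,d)=0 while t(a,c)=1
        assert tanimoto(compute_ecfp6("CCO"), compute_ecfp6("c1ccccc1")) == 0.0
        assert pair_similarity(("CCO", "CCO"), ("CCO", "c1ccccc1")) == pytest.approx(1.0)
        assert pair_similarity(("CCO", "c1ccccc1"), ("CCO", "CCO")) == pytest.approx(0.5)

    def test_fully_disjoint_pairs_score_zero(self):
        assert pair_similarity(("C", "CI"), ("c1ccccc1", "C1CCNCC1")) == 0.0


class TestSSP:
    def test_member_position_and_length(self):
        ref = [Molecule(id=f"M{i}", smiles_input=s) for i, s in enumerate(["CCO", "CCC", "CCN", "CCCl", "c1ccccc1"])]
        prof = compute_ssp("CCO", ref)
        assert len(prof.values) == 5 and prof.reference_ids[0] == "M0"
        assert prof.values[0] == 1.0

    def test_values_match_tanimoto_oracle(self):
        ref = [Molecule(id="A", smiles_input="CCO"), Molecule(id="B", smiles_input="CCC")]
        prof = compute_ssp("CCO", ref)
        expected = tanimoto(compute_ecfp6("CCO"), compute_ecfp6("CCC"))
        assert prof.values[1] == pytest.approx(expected)
        with pytest.raises(ValueError):
            compute_ssp("CCO", [])


DATA = """drug1_id\tdrug2_id\tdrug1_smiles\tdrug2_smiles\tlabels
A\tB\tCCO\tCCC\tp1|p2
B\tC\tCCC\tCCN\tp2
A\tC\tCCO\tCCN\t
"""


class TestDatasetIO:
    def test_load_basic(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text(DATA)
        ds = load_dataset(f)
        assert ds.n_pairs == 3
        assert len(ds.vocab) == 2
        assert ds.labels.sum() == 3

    def test_unordered_duplicate_pairs_or_merged(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text(
            "drug1_id\tdrug2_id\tdrug1_smiles\tdrug2_smiles\tlabels\n"
            "A\tB\tCCO\tCCC\tp1\n"
            "B\tA\tCCC\tCCO\tp2\n"
        )
        ds = load_dataset(f)
        assert ds.n_pairs == 1
        assert ds.labels.tolist() == [[1, 1]]

    def test_bad_smiles_names_row(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text(
            "drug1_id\tdrug2_id\tdrug1_smiles\tdrug2_smiles\tlabels\n"
            "A\tB\tCCO\tCCC\tp1\n"
            "A\tC\tCCO\txxx$\tp1\n"
        )
        with pytest.raises(SmilesParseError, match="row 3"):
            load_dataset(f)

    def test_missing_column_and_conflicting_id(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("drug1_id\tdrug2_id\tlabels\nA\tB\tp1\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_dataset(f)
        f.write_text(
            "drug1_id\tdrug2_id\tdrug1_smiles\tdrug2_smiles\tlabels\n"
            "A\tB\tCCO\tCCC\tp1\n"
            "A\tC\tCCN\tCCC\tp1\n"
        )
        with pytest.raises(ValueError, match="conflicting"):
            load_dataset(f)

    def test_round_trip_identity(self, toy_ds, tmp_path):
        f = tmp_path / "rt.tsv"
        save_dataset(toy_ds, f)
        ds2 = load_dataset(f)
        assert ds2.pairs == toy_ds.pairs
        assert np.array_equal(ds2.labels, toy_ds.labels)
        assert ds2.vocab.names == toy_ds.vocab.names
        # second round trip is byte-identical
        buf1, buf2 = io.StringIO(), io.StringIO()
        save_dataset(toy_ds, buf1)
        save_dataset(ds2, buf2)
        assert buf1.getvalue() == buf2.getvalue()


class TestStats:
    def _tiny(self):
        drugs = {x: Molecule(id=x, smiles_input=s) for x, s in [("A", "CCO"), ("B", "CCC"), ("C", "CCN")]}
        vocab = PhenotypeVocabulary(names=["p1", "p2", "p3", "p4"])
        labels = np.array([[1, 0, 0, 0], [1, 1, 1, 0]], dtype=np.uint8)
        return DDIDataset(drugs=drugs, pairs=[("A", "B"), ("A", "C")], labels=labels, vocab=vocab)

    def test_hand_worked_example(self):
        st = dataset_stats(self._tiny())
        assert st.mean_labels_per_pair == 2.0
        assert st.label_density == 0.5
        assert st.median_labels_per_pair == 2.0
        assert st.n_unique_drugs == 3

    def test_label_density_reported_values(self):
        # printed per-pair label means and vocabulary sizes reproduce the
        # reported label densities of the reference DDI databases
        assert label_density(72.126, 964) == pytest.approx(0.075, abs=5e-4)
        assert label_density(77.61, 477) == pytest.approx(0.16, abs=5e-3)
        assert label_density(1.002, 86) == pytest.approx(0.012, abs=5e-4)

    def test_density_definition_exact(self, toy_ds):
        st = dataset_stats(toy_ds)
        assert 0.0 <= st.label_density <= 1.0
        assert st.label_density == pytest.approx(
            toy_ds.labels.sum(axis=1).mean() / len(toy_ds.vocab), abs=0
        )


class TestSynonymMap:
    def _ds(self):
        drugs = {x: Molecule(id=x, smiles_input=s) for x, s in [("A", "CCO"), ("B", "CCC")]}
        vocab = PhenotypeVocabulary(names=["high bp", "increased bp", "nausea"])
        labels = np.array([[1, 0, 1]], dtype=np.uint8)
        return DDIDataset(drugs=drugs, pairs=[("A", "B")], labels=labels, vocab=vocab)

    def test_grouping_ors_members(self):
        ds2 = apply_synonym_map(self._ds(), {"high bp": "bp", "increased bp": "bp"})
        assert ds2.vocab.names == ["bp", "nausea"]
        assert ds2.labels.tolist() == [[1, 1]]

    def test_identity_map_is_noop(self):
        ds = self._ds()
        ds2 = apply_synonym_map(ds, {n: n for n in ds.vocab.names})
        assert ds2.vocab.names == ds.vocab.names
        assert np.array_equal(ds2.labels, ds.labels)

    def test_drop_token_removes(self):
        ds2 = apply_synonym_map(self._ds(), {"nausea": DROP_TOKEN})
        assert "nausea" not in ds2.vocab.names

    def test_unknown_name_strict(self):
        with pytest.raises(ValueError, match="unknown"):
            apply_synonym_map(self._ds(), {"ghost": "bp"})

    def test_invariants_on_random_map(self, toy_ds):
        rng = np.random.Generator(np.random.PCG64(3))
        names = toy_ds.vocab.names
        synmap = {n: f"G{rng.integers(3)}" for n in names}
        out = apply_synonym_map(toy_ds, synmap)
        assert len(out.vocab) <= len(toy_ds.vocab)
        assert np.all(out.labels.sum(axis=1) <= toy_ds.labels.sum(axis=1))
        # a pair positive before stays positive for some group
        before = toy_ds.labels.sum(axis=1) > 0
        after = out.labels.sum(axis=1) > 0
        assert np.array_equal(before, after)


class TestRareFilter:
    def test_counted_example(self):
        drugs = {x: Molecule(id=x, smiles_input=s) for x, s in [("A", "CCO"), ("B", "CCC")]}
        counts = [1, 2, 5, 5, 9]
        m = 9
        labels = np.zeros((m, 5), dtype=np.uint8)
        for j, c in enumerate(counts):
            labels[:c, j] = 1
        ids = [f"X{i}" for i in range(m + 1)]
        for i in ids:
            drugs[i] = Molecule(id=i, smiles_input="C" + "C" * ids.index(i))
        pairs = [(ids[i], ids[i + 1]) for i in range(m)]
        ds = DDIDataset(
            drugs=drugs, pairs=pairs, labels=labels,
            vocab=PhenotypeVocabulary(names=[f"p{j}" for j in range(5)]),
        )
        out = filter_rare_phenotypes(ds, 5)
        assert len(out.vocab) == 3
        assert out.n_pairs == m  # all-negative pairs retained
        same = filter_rare_phenotypes(ds, 0)
        assert same.vocab.names == ds.vocab.names
        with pytest.raises(ValueError):
            filter_rare_phenotypes(ds, 10)
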