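"""Threshold-free metrics against brute-force oracles, binning, gaps."""

import numpy as np
import pytest

from ddikit.metrics import (
    auprc,
    auroc,
    evaluate,
    frequency_bins,
    gap_report,
)
from ddikit.splitting import random_split


def auprc_bruteforce(y, s):
    """Enumerate every unique score as a threshold; step-sum P over dR."""
    y = np.asarray(y, dtype=int)
    s = np.asarray(s, dtype=float)
    thresholds = sorted(set(s), reverse=True)
    prev_r = 0.0
    total = 0.0
    n_pos = y.sum()
    for t in thresholds:
        sel = s >= t
        tp = int((y[sel] == 1).sum())
        p = tp / int(sel.sum())
        r = tp / n_pos
        total += (r - prev_r) * p
        prev_r = r
    return total


def auroc_bruteforce(y, s):
    """All positive-negative comparisons; ties count one half."""
    y = np.asarray(y, dtype=int)
    s = np.asarray(s, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRankingMetrics:
    def test_perfect_and_inverted_examples(self):
        assert auprc([1, 0], [0.9, 0.1]) == pytest.approx(1.0)
        assert auprc([0, 1], [0.9, 0.1]) == pytest.approx(0.5)
        assert auroc([1, 0], [0.9, 0.1]) == pytest.approx(1.0)
        assert auroc([0, 1], [0.9, 0.1]) == pytest.approx(0.0)

    def test_all_scores_tied_is_chance(self):
        assert auroc([0, 1, 0, 1], [0.3] * 4) == pytest.approx(0.5)

    def test_matches_bruteforce_oracles(self):
        rng = np.random.Generator(np.random.PCG64(1))
        for _ in range(100):
            n = int(rng.integers(2, 21))
            y = rng.integers(0, 2, size=n)
            if y.sum() == 0:
                y[0] = 1
            if y.sum() == n:
                y[0] = 0
            # quantized scores force ties
            s = np.round(rng.random(n), 1)
            assert auprc(y, s) == pytest.approx(auprc_bruteforce(y, s), abs=1e-9)
            assert auroc(y, s) == pytest.approx(auroc_bruteforce(y, s), abs=1e-9)

    def test_matches_sklearn(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.Generator(np.random.PCG64(2))
        for _ in range(50):
            n = int(rng.integers(5, 50))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[:2] = [0, 1]
            s = np.round(rng.random(n), 2)
            assert auprc(y, s) == pytest.approx(average_precision_score(y, s), abs=1e-12)
            assert auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.Generator(np.random.PCG64(3))
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s = rng.random(30)
        for f in (lambda x: 2 * x + 1, np.exp, lambda x: x**3):
            assert auprc(y, f(s)) == pytest.approx(auprc(y, s), abs=1e-12)
            assert auroc(y, f(s)) == pytest.approx(auroc(y, s), abs=1e-12)

    def test_degenerate_labels_raise(self):
        with pytest.raises(ValueError):
            auprc([1, 1], [0.2, 0.3])
        with pytest.raises(ValueError):
            auroc([0, 0], [0.2, 0.3])


class TestEvaluate:
    def test_single_phenotype_micro_equals_macro(self, toy_ds):
        sub = np.arange(toy_ds.n_pairs)
        preds = np.random.default_rng(0).random((toy_ds.n_pairs, len(toy_ds.vocab)))
        one_col = toy_ds.labels[:, :1]
        from ddikit.chem import DDIDataset, PhenotypeVocabulary

        ds1 = DDIDataset(
            drugs=dict(toy_ds.drugs),
            pairs=list(toy_ds.pairs),
            labels=one_col,
            vocab=PhenotypeVocabulary(names=[toy_ds.vocab.names[0]]),
        )
        rep = evaluate(preds[:, :1], ds1, sub)
        assert rep.micro_auroc == pytest.approx(rep.macro_auroc)
        assert rep.micro_auprc == pytest.approx(rep.macro_auprc)

    def test_undefined_phenotypes_listed_not_fatal(self, toy_ds):
        sub = np.arange(10)
        preds = np.full((toy_ds.n_pairs, len(toy_ds.vocab)), 0.5)
        preds[:, 0] = 0.9
        labels = toy_ds.labels.copy()
        labels[sub, 0] = 0  # no positives for phenotype 0 in the subset
        from ddikit.chem import DDIDataset

        ds = DDIDataset(
            drugs=dict(toy_ds.drugs),
            pairs=list(toy_ds.pairs),
            labels=labels,
            vocab=toy_ds.vocab,
        )
        rep = evaluate(preds, ds, sub)
        assert ds.vocab.names[0] in rep.undefined_phenotypes
        assert all(p.name != ds.vocab.names[0] or p.auroc is None for p in rep.per_phenotype)

    def test_macro_is_mean_of_per_phenotype_oracles(self, toy_ds):
        rng = np.random.Generator(np.random.PCG64(5))
        sub = np.arange(toy_ds.n_pairs)
        preds = rng.random((toy_ds.n_pairs, len(toy_ds.vocab)))
        rep = evaluate(preds, toy_ds, sub)
        per = []
        for j in range(len(toy_ds.vocab)):
            col = toy_ds.labels[:, j]
            if 0 < col.sum() < len(col):
                per.append(auprc_bruteforce(col, preds[:, j]))
        assert rep.macro_auprc == pytest.approx(np.mean(per), abs=1e-9)

    def test_macro_stable_under_phenotype_permutation(self, toy_ds):
        rng = np.random.Generator(np.random.PCG64(6))
        sub = np.arange(toy_ds.n_pairs)
        preds = rng.random((toy_ds.n_pairs, len(toy_ds.vocab)))
        rep1 = evaluate(preds, toy_ds, sub)
        perm = rng.permutation(len(toy_ds.vocab))
        from ddikit.chem import DDIDataset, PhenotypeVocabulary

        ds2 = DDIDataset(
            drugs=dict(toy_ds.drugs),
            pairs=list(toy_ds.pairs),
            labels=toy_ds.labels[:, perm],
            vocab=PhenotypeVocabulary(names=[toy_ds.vocab.names[k] for k in perm]),
        )
        rep2 = evaluate(preds[:, perm], ds2, sub)
        assert abs(rep1.macro_auroc - rep2.macro_auroc) < 1e-12
        assert abs(rep1.macro_auprc - rep2.macro_auprc) < 1e-12


class TestFrequencyBins:
    def test_interval_conventions(self, toy_ds):
        sp = random_split(toy_ds, seed=0)
        binning = frequency_bins(toy_ds, sp, edges=(0, 11, 22))
        for name, k in binning.bin_of_phenotype.items():
            f = toy_ds.labels[sp.train, toy_ds.vocab.index[name]].mean() * 100
            if f < 11:
                assert k == 0
            elif f < 22:
                assert k == 1

    def test_boundary_is_left_closed(self, toy_ds):
        # frequency exactly 11.0 belongs to [11, 22)
        ds = toy_ds
        sp = random_split(ds, seed=0)
        binning = frequency_bins(ds, sp, edges=(0, 11, 22))
        # synthetic check of the assignment rule itself
        assert np.searchsorted([0.0, 11.0, 22.0], 11.0, side="right") - 1 == 1

    def test_overflow_goes_to_top_bin_with_warning(self, toy_ds):
        sp = random_split(toy_ds, seed=0)
        with pytest.warns(UserWarning, match="catch-all"):
            binning = frequency_bins(toy_ds, sp, edges=(0, 1))
        assert set(binning.bin_of_phenotype.values()) <= {0, 1}

    def test_bad_edges(self, toy_ds):
        sp = random_split(toy_ds, seed=0)
        with pytest.raises(ValueError):
            frequency_bins(toy_ds, sp, edges=(5, 11))
        with pytest.raises(ValueError):
            frequency_bins(toy_ds, sp, edges=(0, 22, 11))


class TestGapReport:
    def test_identical_reports_zero_gaps(self):
        g = gap_report({"random": 0.8, "one_unseen": 0.8, "both_unseen": 0.8})
        assert (g.mu1, g.mu2, g.mu3) == (0.0, 0.0, 0.0)

    def test_subtraction_example_and_identity(self):
        g = gap_report({"random": 0.9, "one_unseen": 0.7, "both_unseen": 0.6})
        assert g.mu1 == pytest.approx(0.2)
        assert g.mu2 == pytest.approx(0.3)
        assert g.mu3 == pytest.approx(0.1)
        rng = np.random.Generator(np.random.PCG64(9))
        for _ in range(20):
            r, o, b = rng.random(3)
            g = gap_report({"random": r, "one_unseen": o, "both_unseen": b})
            assert g.mu2 - g.mu1 - g.mu3 == pytest.approx(0.0, abs=1e-15)

    def test_missing_scheme_raises(self):
        with pytest.raises(ValueError, match="missing"):
            gap_report({"random": 0.9, "one_unseen": 0.7})
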