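"""Desk-scale reproduction benchmarks.

These fix the study conditions under which the package reproduces the
qualitative findings about structure-based DDI models: the
generalization gap across evaluation schemes, the augmentation effect on
that gap, and the distribution-shift (MMD) ordering. Problem sizes are
chosen so the full battery runs on one CPU core in minutes; the methods
note discusses what these desk-scale runs do and do not show.

Every function takes a single base seed and derives all internal
randomness (dataset, splits, initialization, batching) from it.
"""

from __future__ import annotations

import numpy as np

from .model import DDIModel, TrainConfig
from .nn.extractors import ExtractorConfig
from .robustness import AugmentationConfig, augment_groups, drug_features, mmd
from .splitting import drug_disjoint_split, random_split, train_drug_set
from .synth import SyntheticSpec, generate_ddi_dataset

#: conditions of the generalization-gap benchmark (both regimes)
GAP_N_DRUGS = 200
GAP_N_PHENOTYPES = 30
GAP_PAIR_DENSITY = 0.15
#: uniform positive rate for the lookup arm — chance-level micro-AUROC is
#: only meaningful when the per-phenotype marginals are equal
LOOKUP_BASE_RATE = 0.15

#: model settings per regime: the lookup arm must *memorize* 200 drugs'
#: latent traits, which needs more capacity and a longer schedule
STRUCTURE_MODEL = dict(
    extractor=ExtractorConfig(kind="smiles_cnn", hidden_units=32, output_dim=32),
    head_units=64,
    max_epochs=15,
    patience=2,
)
LOOKUP_MODEL = dict(
    extractor=ExtractorConfig(kind="smiles_cnn", hidden_units=64, output_dim=48),
    head_units=128,
    max_epochs=30,
    patience=3,
)

#: conditions of the augmentation benchmark
AUG_N_DRUGS = 150
AUG_N_PHENOTYPES = 12
AUG_PAIR_DENSITY = 0.12
AUG_N_VARIANTS = 8
AUG_N_REPLICATES = 5

#: conditions of the MMD-ordering benchmark
MMD_N_DRUGS = 120
MMD_N_CLUSTERS = 4
MMD_N_REPLICATES = 5


def _fit_and_score(ds, split, model_kw, seed):
    cfg = TrainConfig(
        max_epochs=model_kw["max_epochs"],
        patience=model_kw["patience"],
        batch_size=256,
        learning_rate=3e-3,
        seed=seed,
    )
    res = DDIModel(
        ds,
        split,
        extractor=model_kw["extractor"],
        train_config=cfg,
        head_units=model_kw["head_units"],
    ).fit()
    return res.evaluate("test")


def gap_benchmark_dataset(regime: str, seed: int):
    """The generalization-gap benchmark dataset for one regime."""
    skew = (LOOKUP_BASE_RATE, LOOKUP_BASE_RATE) if regime == "lookup" else (0.005, 0.4)
    spec = SyntheticSpec(
        n_drugs=GAP_N_DRUGS,
        n_phenotypes=GAP_N_PHENOTYPES,
        pair_density=GAP_PAIR_DENSITY,
        regime=regime,
        skew=skew,
        seed=seed,
    )
    return generate_ddi_dataset(spec)[0]


def generalization_gap(regime: str, base_seed: int = 0, n_seeds: int = 3) -> dict:
    """Random-split vs both-unseen micro-AUROC over seeded replicates.

    Returns per-scheme micro-AUROC lists plus their means. In the
    structure regime the random-split score is high and both-unseen is
    strictly lower but above chance; in the lookup regime both-unseen
    sits at chance while the random split stays learnable.
    """
    ds = gap_benchmark_dataset(regime, seed=base_seed * 1000 + 11)
    model_kw = LOOKUP_MODEL if regime == "lookup" else STRUCTURE_MODEL
    out = {"random": [], "both_unseen": []}
    for k in range(n_seeds):
        seed = base_seed * 1000 + k
        sp = random_split(ds, seed=seed)
        _, bu = drug_disjoint_split(ds, seed=seed)
        out["random"].append(_fit_and_score(ds, sp, model_kw, seed).micro_auroc)
        out["both_unseen"].append(_fit_and_score(ds, bu, model_kw, seed).micro_auroc)
    out["random_mean"] = float(np.mean(out["random"]))
    out["both_unseen_mean"] = float(np.mean(out["both_unseen"]))
    return out


def augmentation_effect(base_seed: int = 0, n_replicates: int = AUG_N_REPLICATES) -> dict:
    """mu1 (random minus one-unseen micro-AUROC) at n_variants 1 vs 8.

    Training consumes the augmented view by epoch-wise variant cycling so
    both settings use the same optimization budget per epoch. Returns the
    per-replicate gaps and the number of replicates where augmentation
    did not widen the gap.
    """
    spec = SyntheticSpec(
        n_drugs=AUG_N_DRUGS,
        n_phenotypes=AUG_N_PHENOTYPES,
        pair_density=AUG_PAIR_DENSITY,
        regime="structure",
        seed=base_seed * 1000 + 5,
    )
    ds, _ = generate_ddi_dataset(spec)
    model_kw = dict(
        extractor=ExtractorConfig(kind="smiles_cnn", hidden_units=32, output_dim=32),
        head_units=64,
        max_epochs=30,
        patience=4,
    )
    mu1 = {1: [], AUG_N_VARIANTS: []}
    for k in range(n_replicates):
        seed = base_seed * 1000 + k
        sp = random_split(ds, seed=seed)
        ou, _ = drug_disjoint_split(ds, seed=seed)
        for n in (1, AUG_N_VARIANTS):
            vals = {}
            for name, split in (("random", sp), ("one_unseen", ou)):
                # each cell averages two training runs to damp the
                # optimization noise that otherwise dominates small gaps
                cell = []
                for rep in range(2):
                    tseed = seed + 500 * rep
                    groups = (
                        augment_groups(ds, split, AugmentationConfig(n, seed=tseed))
                        if n > 1
                        else None
                    )
                    cfg = TrainConfig(
                        max_epochs=model_kw["max_epochs"],
                        patience=model_kw["patience"],
                        batch_size=256,
                        learning_rate=3e-3,
                        seed=tseed,
                    )
                    res = DDIModel(
                        ds,
                        split,
                        extractor=model_kw["extractor"],
                        train_config=cfg,
                        head_units=model_kw["head_units"],
                        example_groups=groups,
                    ).fit()
                    cell.append(res.evaluate("test").micro_auroc)
                vals[name] = float(np.mean(cell))
            mu1[n].append(vals["random"] - vals["one_unseen"])
    reduced = sum(
        1 for a, b in zip(mu1[1], mu1[AUG_N_VARIANTS]) if b <= a
    )
    return {
        "mu1_canonical": mu1[1],
        "mu1_augmented": mu1[AUG_N_VARIANTS],
        "n_replicates": n_replicates,
        "n_reduced": int(reduced),
    }


def mmd_ordering(base_seed: int = 0, n_replicates: int = MMD_N_REPLICATES) -> dict:
    """MMD^2(train drugs, test drugs) under both-unseen vs random splits.

    Uses ECFP6 fingerprints as drug features on clustered synthetic
    molecules. Under a random split the test drugs largely coincide with
    training drugs, so the discrepancy is near zero; a drug-disjoint
    split forces disjoint samples and a strictly positive discrepancy.
    """
    spec = SyntheticSpec(
        n_drugs=MMD_N_DRUGS,
        n_phenotypes=10,
        pair_density=0.2,
        n_clusters=MMD_N_CLUSTERS,
        seed=base_seed * 1000 + 7,
    )
    ds, _ = generate_ddi_dataset(spec)
    rand_vals, bu_vals = [], []
    for k in range(n_replicates):
        seed = base_seed * 1000 + k
        sp = random_split(ds, seed=seed)
        _, bu = drug_disjoint_split(ds, seed=seed)
        for split, sink in ((sp, rand_vals), (bu, bu_vals)):
            tr = drug_features(ds, train_drug_set(ds, split))
            te = drug_features(ds, {d for i in split.test for d in ds.pairs[i]})
            sink.append(mmd(tr, te).value)
    wins = sum(1 for r, b in zip(rand_vals, bu_vals) if b > r)
    return {
        "mmd2_random": rand_vals,
        "mmd2_both_unseen": bu_vals,
        "n_replicates": n_replicates,
        "n_ordered": int(wins),
    }
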