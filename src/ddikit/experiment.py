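"""Orchestrate the experimental matrix: models x schemes x seeds.

Each cell draws a fresh split, trains a model and evaluates it; one
drug-disjoint split serves both the one-unseen and both-unseen schemes
per seed, so their training runs are shared instead of duplicated.
Completed cells are cached on disk by a content hash, making reruns
idempotent. Aggregates are mean +/- sample standard deviation over
seeds, alongside the SS/SU/UU audit and the mu1/mu2/mu3 gap report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import DDIDataset, dataset_digest
from .metrics import gap_report
from .model import DDIModel, TrainConfig
from .nn.extractors import ExtractorConfig
from .robustness import AugmentationConfig, augment_dataset
from .splitting import audit_split, drug_disjoint_split, random_split

AGGREGATES = ("micro_auroc", "micro_auprc", "macro_auroc", "macro_auprc")


@dataclass
class ExperimentConfig:
    extractors: list[str] = field(default_factory=lambda: ["smiles_cnn"])
    schemes: list[str] = field(default_factory=lambda: ["random", "one_unseen", "both_unseen"])
    n_seeds: int = 3
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_variants: int = 1
    train_config: TrainConfig = field(default_factory=TrainConfig)
    extractor_config: dict = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self):
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        bad = set(self.schemes) - {"random", "one_unseen", "both_unseen"}
        if bad:
            raise ValueError(f"unknown schemes: {sorted(bad)}")


def _cell_hash(ds_digest: str, extractor: str, scheme: str, seed: int, cfg: ExperimentConfig) -> str:
    payload = json.dumps(
        {
            "ds": ds_digest,
            "extractor": extractor,
            "scheme": scheme,
            "seed": seed,
            "fractions": list(cfg.fractions),
            "n_variants": cfg.n_variants,
            "train": asdict(cfg.train_config),
            "xcfg": cfg.extractor_config,
        },
        sort_keys=True,
    )
    return hashlib.blake2b(payload.encode(), digest_size=12).hexdigest()


@dataclass
class MatrixResults:
    cells: pd.DataFrame
    table: pd.DataFrame
    gaps: pd.DataFrame
    n_trained: int
    n_cached: int
    n_failed: int


def run_matrix(ds: DDIDataset, cfg: ExperimentConfig) -> MatrixResults:
    """Run the full matrix and aggregate mean +/- std per cell."""
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    digest = dataset_digest(ds)
    rows = []
    n_trained = n_cached = n_failed = 0
    for seed in range(cfg.n_seeds):
        splits = {}
        if "random" in cfg.schemes:
            splits["random"] = random_split(ds, cfg.fractions, seed=seed)
        if {"one_unseen", "both_unseen"} & set(cfg.schemes):
            ou, bu = drug_disjoint_split(ds, cfg.fractions, seed=seed)
            if "one_unseen" in cfg.schemes:
                splits["one_unseen"] = ou
            if "both_unseen" in cfg.schemes:
                splits["both_unseen"] = bu
        for extractor in cfg.extractors:
            # one shared training run covers both drug-disjoint schemes
            trained_disjoint = None
            for scheme in cfg.schemes:
                split = splits[scheme]
                h = _cell_hash(digest, extractor, scheme, seed, cfg)
                cache_file = outdir / f"cell_{h}.json" if outdir else None
                if cache_file is not None and cache_file.exists():
                    rows.append(json.loads(cache_file.read_text()))
                    n_cached += 1
                    continue
                t_cell = time.time()
                try:
                    if scheme in ("one_unseen", "both_unseen") and trained_disjoint is not None:
                        res = trained_disjoint
                        # same trained model, evaluated on this scheme's subsets
                        from .metrics import evaluate as _eval

                        preds = res.predict(split.test)
                        report = _eval(preds, ds, split.test)
                    else:
                        tc = TrainConfig(**{**asdict(cfg.train_config), "seed": seed})
                        xcfg = ExtractorConfig(kind=extractor, **cfg.extractor_config)
                        examples = None
                        if cfg.n_variants > 1:
                            examples = augment_dataset(
                                ds, split, AugmentationConfig(cfg.n_variants, seed=seed)
                            )
                        model = DDIModel(
                            ds, split, extractor=xcfg, train_config=tc,
                            train_examples=examples,
                        )
                        res = model.fit()
                        report = res.evaluate("test")
                        if scheme in ("one_unseen", "both_unseen"):
                            trained_disjoint = res
                        n_trained += 1
                    audit = audit_split(ds, split)["test"]
                    row = {
                        "extractor": extractor,
                        "scheme": scheme,
                        "seed": seed,
                        "n_test": int(len(split.test)),
                        "SS": audit.SS,
                        "SU": audit.SU,
                        "UU": audit.UU,
                        "train_checksum": float(np.float64(res.predictor.checksum())),
                        **{a: float(report.aggregate(a)) for a in AGGREGATES},
                        "seconds": round(time.time() - t_cell, 3),
                    }
                except Exception as exc:  # failed cells are recorded, not fatal
                    n_failed += 1
                    row = {
                        "extractor": extractor,
                        "scheme": scheme,
                        "seed": seed,
                        "error": str(exc),
                    }
                rows.append(row)
                if cache_file is not None:
                    cache_file.write_text(json.dumps(row))
    cells = pd.DataFrame(rows)
    ok = cells[cells["error"].isna()] if "error" in cells.columns else cells
    agg = (
        ok.groupby(["extractor", "scheme"])[list(AGGREGATES)]
        .agg(["mean", "std"])
        .reset_index()
        if len(ok)
        else pd.DataFrame()
    )
    gap_rows = []
    for extractor in cfg.extractors:
        sub = ok[ok.extractor == extractor] if len(ok) else pd.DataFrame()
        if len(sub) and set(cfg.schemes) >= {"random", "one_unseen", "both_unseen"}:
            means = sub.groupby("scheme")["micro_auprc"].mean()
            g = gap_report(means.to_dict(), metric="micro_auprc")
            gap_rows.append(
                {"extractor": extractor, "mu1": g.mu1, "mu2": g.mu2, "mu3": g.mu3}
            )
    res = MatrixResults(
        cells=cells,
        table=agg,
        gaps=pd.DataFrame(gap_rows),
        n_trained=n_trained,
        n_cached=n_cached,
        n_failed=n_failed,
    )
    if outdir:
        cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(
                {
                    "n_trained": n_trained,
                    "n_cached": n_cached,
                    "n_failed": n_failed,
                    "gaps": gap_rows,
                },
                fh,
                indent=1,
            )
    return res
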