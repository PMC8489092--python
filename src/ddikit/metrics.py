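"""Threshold-free multilabel metrics and cross-scheme gap reporting.

Because DDI label matrices are extremely imbalanced, AUPRC (area under
the precision-recall curve) is favoured over AUROC alone. AUPRC is the
step-wise sum over descending unique score thresholds,
``sum_n (R_n - R_{n-1}) * P_n`` — no trapezoid or linear interpolation.
AUROC is the tie-corrected Mann-Whitney rank statistic.

Reports carry per-phenotype values, micro (flattened pair-phenotype
matrix) and macro (unweighted mean over defined phenotypes) aggregates,
and optional stratification by training-set phenotype frequency bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .chem import DDIDataset
from .splitting import SplitResult


def _check_inputs(y_true, scores):
    y = np.asarray(y_true).ravel().astype(int)
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise ValueError("label/score length mismatch")
    return y, s


def auprc(y_true, scores) -> float:
    """Area under the precision-recall curve by step summation.

    Thresholds are the unique score values in descending order; at each,
    precision is weighted by the recall increment. Requires at least one
    positive and one negative label (otherwise undefined -> ValueError).
    """
    y, s = _check_inputs(y_true, scores)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("AUPRC undefined without both a positive and a negative")
    order = np.argsort(-s, kind="mergesort")
    y, s = y[order], s[order]
    # index of the last element of each unique-threshold group
    last = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[last]
    pred_pos = last + 1
    precision = tp / pred_pos
    recall = tp / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def auroc(y_true, scores) -> float:
    """Tie-corrected AUROC (equals the Mann-Whitney U statistic / n+ n-)."""
    y, s = _check_inputs(y_true, scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined without both a positive and a negative")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class PhenotypeMetrics:
    name: str
    auroc: float | None
    auprc: float | None
    n_pos: int
    n_neg: int

    @property
    def defined(self) -> bool:
        return self.auroc is not None


@dataclass
class MetricsReport:
    per_phenotype: list[PhenotypeMetrics]
    micro_auroc: float
    micro_auprc: float
    macro_auroc: float
    macro_auprc: float
    undefined_phenotypes: list[str]
    bins: dict[str, dict] | None = None

    def aggregate(self, name: str) -> float:
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {
            "micro_auroc": self.micro_auroc,
            "micro_auprc": self.micro_auprc,
            "macro_auroc": self.macro_auroc,
            "macro_auprc": self.macro_auprc,
            "undefined_phenotypes": list(self.undefined_phenotypes),
            "per_phenotype": [
                {
                    "name": p.name,
                    "auroc": p.auroc,
                    "auprc": p.auprc,
                    "n_pos": p.n_pos,
                    "n_neg": p.n_neg,
                }
                for p in self.per_phenotype
            ],
            "bins": self.bins,
        }


@dataclass
class FrequencyBinning:
    """Half-open train-frequency intervals [lo, hi) in percent."""

    edges: list[float]
    bin_of_phenotype: dict[str, int]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            self.labels = [
                f"[{self.edges[i]:g},{self.edges[i + 1]:g})"
                for i in range(len(self.edges) - 1)
            ] + [f"[{self.edges[-1]:g},100]"]


def frequency_bins(
    ds: DDIDataset, split: SplitResult, edges=(0.0, 11.0, 22.0, 33.0, 44.0)
) -> FrequencyBinning:
    """Assign each phenotype to a train-frequency bin (percent of train pairs)."""
    edges = [float(e) for e in edges]
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("edges must be strictly ascending")
    if edges[0] != 0.0:
        raise ValueError("edges must start at 0")
    train_labels = ds.labels[split.train]
    freq = train_labels.mean(axis=0) * 100.0
    assignment: dict[str, int] = {}
    overflow = False
    for j, name in enumerate(ds.vocab.names):
        k = int(np.searchsorted(edges, freq[j], side="right") - 1)
        if freq[j] >= edges[-1]:
            overflow = True
            k = len(edges) - 1  # catch-all top bin
        assignment[name] = k
    if overflow:
        warnings.warn(
            f"phenotype frequencies >= {edges[-1]}% assigned to the catch-all top bin"
        )
    return FrequencyBinning(edges=edges, bin_of_phenotype=assignment)


def evaluate(
    preds: np.ndarray,
    ds: DDIDataset,
    subset: np.ndarray,
    binning: FrequencyBinning | None = None,
) -> MetricsReport:
    """Score a prediction matrix on a subset of pairs.

    `preds` is the full m x |Y| score matrix (rows aligned with ds.pairs);
    per-phenotype metrics are computed on the subset columns, micro on the
    flattened subset matrix, macro as the unweighted mean over phenotypes
    with both a positive and a negative. Degenerate phenotypes are listed
    in ``undefined_phenotypes``, never fatal.
    """
    subset = np.asarray(subset, dtype=int)
    y = ds.labels[subset].astype(int)
    s = np.asarray(preds, dtype=float)[subset]
    if y.shape != s.shape:
        raise ValueError(f"prediction shape {s.shape} != label shape {y.shape}")
    per: list[PhenotypeMetrics] = []
    undefined: list[str] = []
    for j, name in enumerate(ds.vocab.names):
        n_pos = int(y[:, j].sum())
        n_neg = y.shape[0] - n_pos
        if n_pos == 0 or n_neg == 0:
            per.append(PhenotypeMetrics(name, None, None, n_pos, n_neg))
            undefined.append(name)
        else:
            per.append(
                PhenotypeMetrics(
                    name, auroc(y[:, j], s[:, j]), auprc(y[:, j], s[:, j]), n_pos, n_neg
                )
            )
    defined = [p for p in per if p.defined]
    if not defined:
        macro_roc = macro_prc = float("nan")
    else:
        macro_roc = float(np.mean([p.auroc for p in defined]))
        macro_prc = float(np.mean([p.auprc for p in defined]))
    micro_roc = auroc(y.ravel(), s.ravel())
    micro_prc = auprc(y.ravel(), s.ravel())

    bins = None
    if binning is not None:
        bins = {}
        for k, lab in enumerate(binning.labels):
            cols = [
                ds.vocab.index[n]
                for n, kk in binning.bin_of_phenotype.items()
                if kk == k
            ]
            if not cols:
                continue
            yb, sb = y[:, cols], s[:, cols]
            entry: dict = {"n_phenotypes": len(cols)}
            if 0 < yb.sum() < yb.size:
                entry["micro_auroc"] = auroc(yb.ravel(), sb.ravel())
                entry["micro_auprc"] = auprc(yb.ravel(), sb.ravel())
            in_bin = [
                p for p in per if p.defined and binning.bin_of_phenotype[p.name] == k
            ]
            if in_bin:
                entry["macro_auroc"] = float(np.mean([p.auroc for p in in_bin]))
                entry["macro_auprc"] = float(np.mean([p.auprc for p in in_bin]))
            bins[lab] = entry
    return MetricsReport(
        per_phenotype=per,
        micro_auroc=micro_roc,
        micro_auprc=micro_prc,
        macro_auroc=macro_roc,
        macro_auprc=macro_prc,
        undefined_phenotypes=undefined,
        bins=bins,
    )


@dataclass
class GapReport:
    """Signed scheme-to-scheme performance gaps on one aggregate metric.

    mu1 = random - one_unseen, mu2 = random - both_unseen,
    mu3 = one_unseen - both_unseen; mu2 == mu1 + mu3 identically.
    """

    mu1: float
    mu2: float
    mu3: float
    metric: str = "micro_auprc"


def gap_report(reports: dict, metric: str = "micro_auprc") -> GapReport:
    """Compute mu1/mu2/mu3 from per-scheme reports (or raw aggregate floats)."""
    missing = [s for s in ("random", "one_unseen", "both_unseen") if s not in reports]
    if missing:
        raise ValueError(f"gap_report needs all three schemes; missing {missing}")

    def val(r):
        return r.aggregate(metric) if isinstance(r, MetricsReport) else float(r)

    r, ou, bu = (val(reports[s]) for s in ("random", "one_unseen", "both_unseen"))
    return GapReport(mu1=r - ou, mu2=r - bu, mu3=ou - bu, metric=metric)
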