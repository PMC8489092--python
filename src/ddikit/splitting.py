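"""Evaluation-scheme construction and split auditing.

Three schemes probe increasingly hard generalization:

- ``random``: pairs are split at random; test drugs are almost all seen in
  training (discovering new interactions *within* a database).
- ``one_unseen``: exactly one drug of every validation/test pair is a
  training drug, the other is new (pairing a new drug with the
  pharmacopoeia).
- ``both_unseen``: both drugs of every validation/test pair are unseen
  (predicting interactions between two new drugs).

The drug-disjoint schemes share one training set per seed, so a single
trained model can be scored under both; their test/unused sets are
mutually exclusive. Any split can be audited by the SS/SU/UU taxonomy:
how many test pairs have both / one / neither drug in the training drug
set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .chem import DDIDataset

SCHEMES = ("random", "one_unseen", "both_unseen")


@dataclass
class DrugPartition:
    train_drugs: set[str]
    valid_drugs: set[str]
    test_drugs: set[str]

    def __post_init__(self):
        if (
            self.train_drugs & self.valid_drugs
            or self.train_drugs & self.test_drugs
            or self.valid_drugs & self.test_drugs
        ):
            raise ValueError("drug partition sets must be pairwise disjoint")


@dataclass
class SplitResult:
    """Pair-index partition for one evaluation scheme."""

    scheme: str
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    unused: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    partition: DrugPartition | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for name in ("train", "valid", "test", "unused"):
            setattr(self, name, np.sort(np.asarray(getattr(self, name), dtype=int)))

    def subset(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def to_json(self) -> str:
        d = {
            "scheme": self.scheme,
            "seed": int(self.seed),
            "train": self.train.tolist(),
            "valid": self.valid.tolist(),
            "test": self.test.tolist(),
            "unused": self.unused.tolist(),
        }
        if self.partition is not None:
            d["partition"] = {
                "train_drugs": sorted(self.partition.train_drugs),
                "valid_drugs": sorted(self.partition.valid_drugs),
                "test_drugs": sorted(self.partition.test_drugs),
            }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SplitResult":
        d = json.loads(text)
        part = None
        if "partition" in d:
            part = DrugPartition(
                train_drugs=set(d["partition"]["train_drugs"]),
                valid_drugs=set(d["partition"]["valid_drugs"]),
                test_drugs=set(d["partition"]["test_drugs"]),
            )
        return cls(
            scheme=d["scheme"],
            train=np.array(d["train"], dtype=int),
            valid=np.array(d["valid"], dtype=int),
            test=np.array(d["test"], dtype=int),
            unused=np.array(d.get("unused", []), dtype=int),
            partition=part,
            seed=d.get("seed", 0),
        )


@dataclass
class PairCategoryCounts:
    SS: int
    SU: int
    UU: int

    @property
    def total(self) -> int:
        return self.SS + self.SU + self.UU


def _canonical_pair_order(ds: DDIDataset) -> np.ndarray:
    # shuffle a canonically sorted pair list so file order never leaks
    return np.array(sorted(range(ds.n_pairs), key=lambda i: ds.pairs[i]), dtype=int)


def _check_fractions(fr) -> tuple[float, float, float]:
    fr = tuple(float(f) for f in fr)
    if len(fr) != 3 or any(f <= 0 for f in fr):
        raise ValueError("need three positive fractions")
    if abs(sum(fr) - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {sum(fr)}")
    return fr


def random_split(
    ds: DDIDataset, fractions=(0.6, 0.2, 0.2), seed: int = 0
) -> SplitResult:
    """Shuffle pairs with a seeded PRNG and cut at the fraction boundaries."""
    f_tr, f_va, _ = _check_fractions(fractions)
    order = _canonical_pair_order(ds)
    rng = np.random.Generator(np.random.PCG64(seed))
    rng.shuffle(order)
    m = ds.n_pairs
    i1 = int(round(f_tr * m))
    i2 = int(round((f_tr + f_va) * m))
    train, valid, test = order[:i1], order[i1:i2], order[i2:]
    if min(len(train), len(valid), len(test)) == 0:
        raise ValueError("random_split produced an empty partition; dataset too small")
    return SplitResult(scheme="random", train=train, valid=valid, test=test, seed=seed)


def drug_disjoint_split(
    ds: DDIDataset, drug_fractions=(0.6, 0.2, 0.2), seed: int = 0
) -> tuple[SplitResult, SplitResult]:
    """Partition *drugs* and derive the one-unseen and both-unseen schemes.

    Drugs are shuffled into (D_tr, D_va, D_te) at the given fractions.
    Shared train = pairs with both drugs in D_tr. One-unseen valid pairs
    have exactly one drug in D_tr and the other in D_va; one-unseen test
    pairs have exactly one drug in D_tr | D_va and the other in D_te.
    Both-unseen valid/test pairs have both drugs in D_va / D_te. Remaining
    pairs are unused. The two results share the train set exactly, and
    their test sets are mutually exclusive by construction.
    """
    g_tr, g_va, _ = _check_fractions(drug_fractions)
    ids = sorted(ds.drugs)
    rng = np.random.Generator(np.random.PCG64(seed))
    perm = rng.permutation(len(ids))
    n = len(ids)
    i1 = int(round(g_tr * n))
    i2 = int(round((g_tr + g_va) * n))
    d_tr = {ids[k] for k in perm[:i1]}
    d_va = {ids[k] for k in perm[i1:i2]}
    d_te = {ids[k] for k in perm[i2:]}
    part = DrugPartition(train_drugs=d_tr, valid_drugs=d_va, test_drugs=d_te)

    train, ou_valid, ou_test, bu_valid, bu_test = [], [], [], [], []
    ou_unused, bu_unused = [], []
    for i, (a, b) in enumerate(ds.pairs):
        a_tr, b_tr = a in d_tr, b in d_tr
        a_va, b_va = a in d_va, b in d_va
        a_te, b_te = a in d_te, b in d_te
        if a_tr and b_tr:
            train.append(i)
            continue
        in_ou = in_bu = False
        # one-unseen: exactly one endpoint among the training drugs; the
        # other endpoint supplies the "new" drug (validation or test drug)
        if (a_tr and b_va) or (b_tr and a_va):
            ou_valid.append(i)
            in_ou = True
        elif (a_tr and b_te) or (b_tr and a_te):
            ou_test.append(i)
            in_ou = True
        if a_va and b_va:
            bu_valid.append(i)
            in_bu = True
        elif a_te and b_te:
            bu_test.append(i)
            in_bu = True
        if not in_ou:
            ou_unused.append(i)
        if not in_bu:
            bu_unused.append(i)

    for name, s in (
        ("train", train),
        ("one_unseen valid", ou_valid),
        ("one_unseen test", ou_test),
        ("both_unseen valid", bu_valid),
        ("both_unseen test", bu_test),
    ):
        if not s:
            raise ValueError(
                f"drug-disjoint split produced an empty {name} set; "
                "use larger drug fractions or a larger dataset"
            )
    one_unseen = SplitResult(
        scheme="one_unseen",
        train=np.array(train),
        valid=np.array(ou_valid),
        test=np.array(ou_test),
        unused=np.array(ou_unused, dtype=int),
        partition=part,
        seed=seed,
    )
    both_unseen = SplitResult(
        scheme="both_unseen",
        train=np.array(train),
        valid=np.array(bu_valid),
        test=np.array(bu_test),
        unused=np.array(bu_unused, dtype=int),
        partition=part,
        seed=seed,
    )
    return one_unseen, both_unseen


def train_drug_set(ds: DDIDataset, split: SplitResult) -> set[str]:
    """Drugs occurring in the training pairs of a split."""
    out: set[str] = set()
    for i in split.train:
        a, b = ds.pairs[i]
        out.add(a)
        out.add(b)
    return out


def audit_split(ds: DDIDataset, split: SplitResult) -> dict[str, PairCategoryCounts]:
    """SS/SU/UU tally of the valid and test subsets against the train drugs."""
    seen = train_drug_set(ds, split)
    out = {}
    for name in ("valid", "test"):
        ss = su = uu = 0
        for i in split.subset(name):
            a, b = ds.pairs[i]
            k = (a in seen) + (b in seen)
            if k == 2:
                ss += 1
            elif k == 1:
                su += 1
            else:
                uu += 1
        out[name] = PairCategoryCounts(SS=ss, SU=su, UU=uu)
    return out


def validate_split(ds: DDIDataset, split: SplitResult) -> tuple[bool, list[dict]]:
    """Check disjointness, exhaustiveness and scheme composition invariants.

    Returns (ok, violations); never raises.
    """
    violations: list[dict] = []
    subsets = {n: set(split.subset(n).tolist()) for n in ("train", "valid", "test", "unused")}
    names = list(subsets)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1 :]:
            inter = subsets[n1] & subsets[n2]
            if inter:
                violations.append(
                    {"kind": "overlap", "subsets": [n1, n2], "indices": sorted(inter)[:10]}
                )
    all_idx = set().union(*subsets.values())
    expected = set(range(ds.n_pairs))
    if all_idx != expected:
        violations.append(
            {
                "kind": "coverage",
                "missing": sorted(expected - all_idx)[:10],
                "extraneous": sorted(all_idx - expected)[:10],
            }
        )
    if split.scheme in ("one_unseen", "both_unseen"):
        seen = train_drug_set(ds, split)
        want = {"one_unseen": 1, "both_unseen": 0}[split.scheme]
        for name in ("valid", "test"):
            bad = []
            for i in split.subset(name):
                a, b = ds.pairs[i]
                if (a in seen) + (b in seen) != want:
                    bad.append(int(i))
            if bad:
                violations.append(
                    {"kind": "composition", "subset": name, "expected_seen": want, "indices": bad[:10]}
                )
        if split.scheme == "both_unseen" and split.partition is not None:
            leak = [
                int(i)
                for i in split.test
                if set(ds.pairs[i]) & split.partition.valid_drugs
            ]
            if leak:
                violations.append({"kind": "test_drugs_in_valid", "indices": leak[:10]})
    return (not violations, violations)


def isolated_drugs(ds: DDIDataset, split: SplitResult) -> set[str]:
    """Drugs whose every pair landed in the unused set."""
    used: set[str] = set()
    for name in ("train", "valid", "test"):
        for i in split.subset(name):
            used.update(ds.pairs[i])
    return set(ds.drugs) - used
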