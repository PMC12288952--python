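"""Dataset balancing and leakage-aware train/test splitting.

The negative class in the m6A benchmark outnumbers positives roughly 5:1,
so the full dataset is first re-balanced: negatives are shuffled and dealt
round-robin into ``n_subsets`` disjoint, near-equal subsets, each of which
is paired with *all* positives to form a 1:1 balanced replicate D_i.

Two evaluation protocols then operate on a balanced replicate:

* **Random-Split (RS)** — a stratified 80/20 train/test split; the training
  pool is further partitioned into k cross-validation folds.  Records from
  the same chromosome may appear on both sides of the split, so RS is
  vulnerable to chromosome-level leakage.
* **Leave-One-Chromosome-Out (LOCO)** — one fold per chromosome: the fold's
  test set is exactly that chromosome's records and its training pool is
  every other chromosome, with inner cross-validation folds built on the
  pool.  LOCO eliminates within-chromosome leakage by construction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .io import Dataset


class SplitError(ValueError):
    pass


class LeakageError(AssertionError):
    """A split plan places the same chromosome in train and test of a fold."""


@dataclass
class BalancedDataset:
    """All positives P paired with one disjoint negative subset N_i."""

    parent: Dataset
    positives: tuple[str, ...]
    negatives: tuple[str, ...]
    replicate: int

    @property
    def ids(self) -> tuple[str, ...]:
        return self.positives + self.negatives

    def as_dataset(self) -> Dataset:
        return self.parent.subset(self.ids)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


@dataclass
class Fold:
    train: tuple[str, ...]
    validation: tuple[str, ...] | None
    test: tuple[str, ...]
    label: str


@dataclass
class SplitPlan:
    """Either an RS plan (CV folds sharing one test set) or a LOCO plan
    (one fold per chromosome).  ``inner`` optionally carries per-fold inner
    CV partitions for LOCO plans, keyed by fold label."""

    mode: str  # "RS" | "LOCO"
    folds: list[Fold]
    seed: int
    inner: dict[str, list[tuple[tuple[str, ...], tuple[str, ...]]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "mode": self.mode,
            "seed": self.seed,
            "folds": [
                {
                    "label": f.label,
                    "train": list(f.train),
                    "validation": None if f.validation is None else list(f.validation),
                    "test": list(f.test),
                }
                for f in self.folds
            ],
            "inner": {
                lab: [{"train": list(tr), "validation": list(va)} for tr, va in pairs]
                for lab, pairs in self.inner.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        doc = json.loads(Path(path).read_text())
        folds = [
            Fold(
                tuple(f["train"]),
                None if f["validation"] is None else tuple(f["validation"]),
                tuple(f["test"]),
                f["label"],
            )
            for f in doc["folds"]
        ]
        inner = {
            lab: [(tuple(p["train"]), tuple(p["validation"])) for p in pairs]
            for lab, pairs in doc.get("inner", {}).items()
        }
        return cls(doc["mode"], folds, doc["seed"], inner)


def balance_negatives(ds: Dataset, n_subsets: int = 5, seed: int = 0) -> list[BalancedDataset]:
    """Shuffle the negatives and deal them round-robin into ``n_subsets``
    disjoint subsets whose sizes differ by at most one; pair each with all
    positives.  Deterministic under ``seed``; no record is discarded."""
    pos = tuple(r.id for r in ds if r.label == 1)
    neg = [r.id for r in ds if r.label == 0]
    if not pos or not neg:
        raise SplitError("balancing needs both classes present")
    if len(neg) < n_subsets:
        raise SplitError(f"|N|={len(neg)} < n_subsets={n_subsets}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(neg))
    subsets: list[list[str]] = [[] for _ in range(n_subsets)]
    for j, idx in enumerate(order):
        subsets[j % n_subsets].append(neg[idx])
    return [
        BalancedDataset(ds, pos, tuple(sub), replicate=i + 1)
        for i, sub in enumerate(subsets)
    ]


def _stratified_holdout(
    ids: Sequence[str], labels: Sequence[int], n_test: int, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Class-proportional test pick of exactly n_test records."""
    ids = list(ids)
    by_class: dict[int, list[str]] = {}
    for rid, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(rid)
    classes = sorted(by_class)
    n = len(ids)
    take = {c: int(round(n_test * len(by_class[c]) / n)) for c in classes}
    # repair rounding so the total is exact
    drift = n_test - sum(take.values())
    for c in classes:
        if drift == 0:
            break
        step = 1 if drift > 0 else -1
        if 0 <= take[c] + step <= len(by_class[c]):
            take[c] += step
            drift -= step
    test, train = [], []
    for c in classes:
        pool = list(by_class[c])
        rng.shuffle(pool)
        test.extend(pool[: take[c]])
        train.extend(pool[take[c] :])
    return train, test


def _cv_partition(
    ids: Sequence[str],
    labels: Sequence[int],
    cv_folds: int,
    seed: int,
    stratified: bool,
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    ids_arr = np.asarray(ids, dtype=object)
    y = np.asarray(labels)
    if stratified:
        counts = np.bincount(y)
        if (counts[counts > 0] < cv_folds).any():
            raise SplitError(
                f"stratification error: {cv_folds} folds exceed the size of the "
                f"smallest class (class counts {dict(enumerate(counts))})"
            )
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    out = []
    for tr_idx, va_idx in splitter.split(ids_arr, y):
        out.append((tuple(ids_arr[tr_idx]), tuple(ids_arr[va_idx])))
    return out


def random_split(
    bd: BalancedDataset,
    test_fraction: float = 0.2,
    cv_folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> SplitPlan:
    """RS plan: held-out test set of round(test_fraction * n) records plus
    ``cv_folds`` cross-validation folds partitioning the training pool."""
    if not 0 < test_fraction < 1:
        raise SplitError(f"test_fraction must be in (0,1), got {test_fraction}")
    if cv_folds < 2:
        raise SplitError(f"cv_folds must be >= 2, got {cv_folds}")
    ds = bd.parent
    ids = list(bd.ids)
    lab = {r.id: r.label for r in ds}
    labels = [lab[i] for i in ids]
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(ids)))
    if stratified:
        train_pool, test = _stratified_holdout(ids, labels, n_test, rng)
    else:
        order = rng.permutation(len(ids))
        test = [ids[i] for i in order[:n_test]]
        train_pool = [ids[i] for i in order[n_test:]]
    pool_labels = [lab[i] for i in train_pool]
    cv = _cv_partition(train_pool, pool_labels, cv_folds, seed, stratified)
    folds = [
        Fold(train=tr, validation=va, test=tuple(test), label=f"cv{j + 1}")
        for j, (tr, va) in enumerate(cv)
    ]
    return SplitPlan("RS", folds, seed)


_NAT_SPLIT = re.compile(r"(\d+)")


def natural_sort_key(label: str):
    """chr2 < chr10; digit runs compare numerically."""
    return [int(p) if p.isdigit() else p for p in _NAT_SPLIT.split(label)]


def loco_split(bd: BalancedDataset, cv_folds: int = 5, seed: int = 0) -> SplitPlan:
    """LOCO plan: one fold per chromosome, ordered by natural label sort.

    Each fold tests exactly one chromosome and trains on all others; inner
    cross-validation partitions of the training pool are stored under the
    fold's label in ``plan.inner``.
    """
    ds = bd.parent
    lab = {r.id: r.label for r in ds}
    chrom = {r.id: r.chromosome for r in ds}
    by_chrom: dict[str, list[str]] = {}
    for rid in bd.ids:
        by_chrom.setdefault(chrom[rid], []).append(rid)
    chroms = sorted(by_chrom, key=natural_sort_key)
    if len(chroms) < 2:
        raise SplitError(
            f"degenerate LOCO split: only {len(chroms)} chromosome(s); the "
            "training set would be empty"
        )
    import logging

    logger = logging.getLogger(__name__)
    folds: list[Fold] = []
    inner: dict[str, list[tuple[tuple[str, ...], tuple[str, ...]]]] = {}
    for j, c in enumerate(chroms):
        test = tuple(by_chrom[c])
        test_labels = {lab[i] for i in test}
        if len(test_labels) < 2:
            logger.warning(
                "chromosome %s carries a single class; class-dependent test "
                "metrics will be undefined for this fold", c
            )
        pool = tuple(rid for cc in chroms if cc != c for rid in by_chrom[cc])
        pool_labels = [lab[i] for i in pool]
        if cv_folds >= 2:
            try:
                inner[c] = _cv_partition(pool, pool_labels, cv_folds, seed + j, True)
            except SplitError:
                inner[c] = _cv_partition(pool, pool_labels, cv_folds, seed + j, False)
        folds.append(Fold(train=pool, validation=None, test=test, label=c))
    return SplitPlan("LOCO", folds, seed, inner)


def audit_chromosome_leakage(plan: SplitPlan, ds: Dataset) -> dict[str, int]:
    """Assert zero train/test chromosome overlap in every fold of a LOCO
    plan; returns per-fold test sizes on success, raises LeakageError on
    any overlap.  RS plans are rejected (they make no such guarantee)."""
    if plan.mode != "LOCO":
        raise SplitError(f"leakage audit applies to LOCO plans, not {plan.mode!r}")
    chrom = {r.id: r.chromosome for r in ds}
    sizes: dict[str, int] = {}
    for f in plan.folds:
        train_chroms = {chrom[i] for i in f.train}
        test_chroms = {chrom[i] for i in f.test}
        overlap = train_chroms & test_chroms
        if overlap:
            raise LeakageError(
                f"fold {f.label!r}: chromosome(s) {sorted(overlap)} appear in "
                "both train and test"
            )
        if set(f.train) & set(f.test):
            raise LeakageError(f"fold {f.label!r}: record ids shared between train and test")
        sizes[f.label] = len(f.test)
    return sizes
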