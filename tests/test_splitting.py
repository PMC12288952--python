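import numpy as np
import pytest

from m6aloco.io import Dataset, SequenceRecord
from m6aloco.splitting import (
    Fold,
    LeakageError,
    SplitError,
    SplitPlan,
    audit_chromosome_leakage,
    balance_negatives,
    loco_split,
    natural_sort_key,
    random_split,
)

from conftest import random_dataset


def dataset_with_counts(n_pos, n_neg, chromosomes=("chr1", "chr2", "chr3"), L=12, seed=0):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    recs = []
    for i in range(n_pos + n_neg):
        recs.append(
            SequenceRecord(
                id=f"r{i}",
                chromosome=str(rng.choice(chromosomes)),
                sequence="".join(rng.choice(bases, size=L)),
                label=1 if i < n_pos else 0,
            )
        )
    return Dataset(recs, L)


class TestBalanceNegatives:
    def test_one_to_one_ratio_and_disjoint(self):
        ds = dataset_with_counts(10, 50)
        reps = balance_negatives(ds, 5, seed=1)
        assert len(reps) == 5
        labels = {r.id: r.label for r in ds}
        all_negs = []
        for bd in reps:
            assert len(bd.positives) == 10 and len(bd.negatives) == 10
            assert all(labels[i] == 1 for i in bd.positives)
            assert all(labels[i] == 0 for i in bd.negatives)
            all_negs.extend(bd.negatives)
        assert len(all_negs) == len(set(all_negs)) == 50  # disjoint, none discarded
        # positives identical across replicates
        assert len({bd.positives for bd in reps}) == 1

    def test_remainder_spread_at_most_one(self):
        """52 negatives over 5 subsets -> sizes {11,11,10,10,10}."""
        ds = dataset_with_counts(4, 52)
        reps = balance_negatives(ds, 5, seed=0)
        sizes = sorted(len(bd.negatives) for bd in reps)
        assert sizes == [10, 10, 10, 11, 11]

    def test_deterministic_under_seed(self):
        ds = dataset_with_counts(6, 30)
        a = balance_negatives(ds, 5, seed=7)
        b = balance_negatives(ds, 5, seed=7)
        c = balance_negatives(ds, 5, seed=8)
        assert [x.negatives for x in a] == [x.negatives for x in b]
        assert [x.negatives for x in a] != [x.negatives for x in c]

    def test_errors(self):
        single = dataset_with_counts(5, 0)
        with pytest.raises(SplitError, match="both classes"):
            balance_negatives(single, 5)
        tiny = dataset_with_counts(5, 3)
        with pytest.raises(SplitError, match="n_subsets"):
            balance_negatives(tiny, 5)


class TestRandomSplit:
    def test_80_20_with_five_folds(self):
        ds = dataset_with_counts(50, 50)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = random_split(bd, 0.2, 5, seed=3)
        assert plan.mode == "RS" and len(plan.folds) == 5
        test_sets = {f.test for f in plan.folds}
        assert len(test_sets) == 1  # identical test across CV folds
        assert len(plan.folds[0].test) == 20
        pool = set(plan.folds[0].train) | set(plan.folds[0].validation)
        assert len(pool) == 80
        # validation folds partition the pool
        vals = [set(f.validation) for f in plan.folds]
        assert all(len(v) == 16 for v in vals)
        assert set.union(*vals) == pool
        assert sum(len(v) for v in vals) == 80  # pairwise disjoint

    def test_fold_disjointness(self):
        ds = dataset_with_counts(30, 30)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = random_split(bd, 0.25, 3, seed=1)
        for f in plan.folds:
            assert not set(f.train) & set(f.validation)
            assert not set(f.train) & set(f.test)
            assert not set(f.validation) & set(f.test)

    def test_stratified_validation_folds_balanced(self):
        ds = dataset_with_counts(50, 50)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = random_split(bd, 0.2, 5, seed=2, stratified=True)
        labels = {r.id: r.label for r in ds}
        for f in plan.folds:
            n_pos = sum(labels[i] for i in f.validation)
            assert abs(n_pos - len(f.validation) / 2) <= 1

    def test_stratification_error_when_folds_exceed_class(self):
        ds = dataset_with_counts(3, 40)
        bd = balance_negatives(ds, 1, seed=0)[0]
        with pytest.raises(SplitError, match="stratification"):
            random_split(bd, 0.2, 10, seed=0, stratified=True)

    def test_json_roundtrip(self, tmp_path):
        ds = dataset_with_counts(20, 20)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = random_split(bd, 0.2, 4, seed=9)
        plan.to_json(tmp_path / "plan.json")
        back = SplitPlan.from_json(tmp_path / "plan.json")
        assert back.mode == plan.mode and back.seed == plan.seed
        assert [(f.train, f.validation, f.test, f.label) for f in back.folds] == [
            (f.train, f.validation, f.test, f.label) for f in plan.folds
        ]


class TestLocoSplit:
    def test_23_chromosome_enumeration(self):
        chroms = tuple(f"chr{i}" for i in range(1, 24))
        ds = dataset_with_counts(100, 100, chromosomes=chroms, seed=4)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = loco_split(bd, cv_folds=0)
        assert plan.mode == "LOCO"
        assert len(plan.folds) == 23
        assert [f.label for f in plan.folds] == sorted(set(ds.chromosomes), key=natural_sort_key)
        chrom = {r.id: r.chromosome for r in ds}
        all_test = []
        for f in plan.folds:
            assert {chrom[i] for i in f.test} == {f.label}
            assert f.label not in {chrom[i] for i in f.train}
            all_test.extend(f.test)
        # test sets partition the dataset
        assert sorted(all_test) == sorted(r.id for r in ds)

    def test_three_chromosome_complement(self):
        ds = dataset_with_counts(12, 12, chromosomes=("chrA", "chrB", "chrC"), seed=2)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = loco_split(bd, cv_folds=0)
        chrom = {r.id: r.chromosome for r in ds}
        fold_a = next(f for f in plan.folds if f.label == "chrA")
        assert {chrom[i] for i in fold_a.train} == {"chrB", "chrC"}

    def test_inner_cv_partitions_pool(self):
        ds = dataset_with_counts(30, 30)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = loco_split(bd, cv_folds=5, seed=1)
        for f in plan.folds:
            pairs = plan.inner[f.label]
            assert len(pairs) == 5
            vals = [set(v) for _, v in pairs]
            assert set.union(*vals) == set(f.train)
            assert sum(len(v) for v in vals) == len(f.train)

    def test_natural_fold_order(self):
        ds = dataset_with_counts(20, 20, chromosomes=("chr2", "chr10", "chr1"), seed=3)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = loco_split(bd, cv_folds=0)
        assert [f.label for f in plan.folds] == ["chr1", "chr2", "chr10"]

    def test_single_chromosome_degenerate(self):
        ds = dataset_with_counts(5, 5, chromosomes=("chr1",))
        bd = balance_negatives(ds, 1, seed=0)[0]
        with pytest.raises(SplitError, match="degenerate"):
            loco_split(bd)


class TestLeakageAudit:
    def test_clean_plan_passes(self):
        ds = dataset_with_counts(20, 20, seed=5)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = loco_split(bd, cv_folds=0)
        sizes = audit_chromosome_leakage(plan, ds)
        assert sum(sizes.values()) == len(ds)

    def test_corrupted_plan_fails(self):
        """Negative control: deliberately moving a test-chromosome record
        into a fold's training set must trip the auditor."""
        ds = dataset_with_counts(20, 20, seed=5)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = loco_split(bd, cv_folds=0)
        f = plan.folds[0]
        corrupted = Fold(train=f.train + (f.test[0],), validation=None, test=f.test, label=f.label)
        bad_plan = SplitPlan("LOCO", [corrupted] + plan.folds[1:], plan.seed)
        with pytest.raises(LeakageError):
            audit_chromosome_leakage(bad_plan, ds)

    def test_rs_plan_rejected(self):
        ds = dataset_with_counts(20, 20)
        bd = balance_negatives(ds, 1, seed=0)[0]
        plan = random_split(bd, 0.2, 2, seed=0)
        with pytest.raises(SplitError):
            audit_chromosome_leakage(plan, ds)


class TestPlanProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_datasets_satisfy_invariants(self, seed):
        ds = random_dataset(n=60, L=15, chromosomes=("chr1", "chr2", "chr5", "chr11"), seed=seed)
        bd = balance_negatives(ds, 1, seed=seed)[0]
        rs = random_split(bd, 0.2, 4, seed=seed)
        ids = set(bd.ids)
        for f in rs.folds:
            assert set(f.train) | set(f.validation) | set(f.test) == ids
        loco = loco_split(bd, cv_folds=0, seed=seed)
        audit_chromosome_leakage(loco, ds)
        covered = [i for f in loco.folds for i in f.test]
        assert sorted(covered) == sorted(bd.ids)
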