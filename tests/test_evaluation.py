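import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthokit.evaluation import (
    ConfusionCounts,
    deletion_robustness,
    gene_confusion,
    length_binned_metrics,
    metrics_from_counts,
    pairwise_confusion,
    per_orthogroup_errors,
    score_partition,
)
from orthokit.mcl import Partition

from conftest import make_catalog


def part(*groups, n=None):
    all_genes = set(range(n)) if n else set().union(*map(set, groups))
    return Partition.from_clusters([set(g) for g in groups], all_genes)


def brute_force_confusion(predicted, reference, universe):
    """Enumerate every unordered pair in the universe."""
    pm, rm = predicted.membership(), reference.membership()
    tp = fp = fn = 0
    for a, b in itertools.combinations(sorted(universe), 2):
        in_p = a in pm and b in pm and pm[a] == pm[b]
        in_r = a in rm and b in rm and rm[a] == rm[b]
        tp += in_p and in_r
        fp += in_p and not in_r
        fn += in_r and not in_p
    return ConfusionCounts(tp, fp, fn)


class TestPairwiseConfusion:
    def test_worked_example(self):
        # predicted {{A,B,C},{D}} vs reference {{A,B},{C,D}} over A..D
        predicted = part([0, 1, 2], n=4)
        reference = part([0, 1], [2, 3], n=4)
        c = pairwise_confusion(predicted, reference)
        assert (c.TP, c.FP, c.FN) == (1, 2, 1)
        m = metrics_from_counts(c)
        assert m.precision == pytest.approx(1 / 3)
        assert m.recall == pytest.approx(1 / 2)
        assert m.fscore == pytest.approx(0.4)

    def test_identity_and_all_singletons(self):
        ref = part([0, 1], [2, 3, 4], n=6)
        assert metrics_from_counts(pairwise_confusion(ref, ref)).fscore == 1.0
        empty = part(n=6)
        m = metrics_from_counts(pairwise_confusion(empty, ref))
        assert m.recall == 0.0

    def test_swap_swaps_precision_and_recall(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = _random_partition(rng, 12)
            b = _random_partition(rng, 12)
            universe = set(range(12))
            ma = metrics_from_counts(pairwise_confusion(a, b, universe))
            mb = metrics_from_counts(pairwise_confusion(b, a, universe))
            assert ma.precision == pytest.approx(mb.recall)
            assert ma.recall == pytest.approx(mb.precision)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            predicted = _random_partition(rng, 15)
            reference = _random_partition(rng, 15)
            universe = set(
                rng.choice(15, size=10, replace=False).tolist()
            ) | set().union(*reference.orthogroups, set())
            got = pairwise_confusion(predicted, reference, universe)
            exp = brute_force_confusion(predicted, reference, universe)
            assert (got.TP, got.FP, got.FN) == (exp.TP, exp.FP, exp.FN)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_confusion(part([0, 1], n=3), part(n=3))


class TestMetrics:
    def test_direct_substitution_and_degenerate(self):
        m = metrics_from_counts(ConfusionCounts(8, 2, 2))
        assert (m.precision, m.recall, m.fscore) == pytest.approx((0.8, 0.8, 0.8))
        z = metrics_from_counts(ConfusionCounts(0, 0, 5))
        assert (z.precision, z.recall, z.fscore) == (0.0, 0.0, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 1000), st.integers(0, 1000), st.integers(0, 1000))
    def test_harmonic_mean_identity_and_scale_invariance(self, tp, fp, fn):
        m = metrics_from_counts(ConfusionCounts(tp, fp, fn))
        if m.precision + m.recall > 0:
            hm = 2 * m.precision * m.recall / (m.precision + m.recall)
            assert m.fscore == pytest.approx(hm)
        k = 7
        mk = metrics_from_counts(ConfusionCounts(tp * k, fp * k, fn * k))
        assert mk.precision == pytest.approx(m.precision)
        assert mk.recall == pytest.approx(m.recall)
        assert mk.fscore == pytest.approx(m.fscore)


def _random_partition(rng, n_genes):
    genes = list(rng.permutation(n_genes))
    clusters = []
    while genes:
        k = int(rng.integers(1, 5))
        clusters.append(set(genes[:k]))
        genes = genes[k:]
    return Partition.from_clusters(clusters, set(range(n_genes)))


class TestLengthBinnedMetrics:
    def test_equal_count_bins_and_geometric_means(self):
        cat = make_catalog([[100, 200, 300, 400, 500, 600, 700, 800]])
        ref = part([0, 1], [2, 3], [4, 5], [6, 7], n=8)
        report = length_binned_metrics(ref, ref, cat)
        assert [r["n_genes"] for r in report] == [2, 2, 2, 2]
        assert report[0]["geometric_mean_length"] == pytest.approx(
            np.sqrt(100 * 200)
        )
        assert all(r["metrics"].fscore == 1.0 for r in report)

    def test_long_gene_errors_localised_to_top_bin(self):
        # mispredict only the longest genes: precision dips only in bin 3
        cat = make_catalog([list(range(100, 900, 100))])
        ref = part([0, 1], [2, 3], [4, 5], [6, 7], n=8)
        predicted = part([0, 1], [2, 3], [4, 5, 6, 7], n=8)  # fuses top groups
        report = length_binned_metrics(predicted, ref, cat)
        assert report[0]["metrics"].precision == 1.0
        assert report[3]["metrics"].precision < 1.0

    def test_per_bin_counts_match_brute_force(self):
        rng = np.random.default_rng(2)
        cat = make_catalog([list(rng.integers(50, 1000, size=20))])
        for _ in range(10):
            predicted = _random_partition(rng, 20)
            reference = _random_partition(rng, 20)
            report = length_binned_metrics(predicted, reference, cat)
            universe = set().union(*reference.orthogroups)
            genes = sorted(universe, key=lambda g: (cat.lengths[g], g))
            base, extra = divmod(len(genes), 4)
            bins, pos = [], 0
            for i in range(4):
                size = base + (1 if i < extra else 0)
                bins.append(genes[pos:pos + size])
                pos += size
            gene_bin = {g: i for i, b in enumerate(bins) for g in b}
            pm, rm = predicted.membership(), reference.membership()
            counts = [dict(TP=0, FP=0, FN=0) for _ in range(4)]
            for a, b in itertools.combinations(sorted(universe), 2):
                in_p = a in pm and b in pm and pm[a] == pm[b]
                in_r = rm.get(a) == rm.get(b) and a in rm
                if not (in_p or in_r):
                    continue
                kind = "TP" if in_p and in_r else ("FP" if in_p else "FN")
                for bb in {gene_bin[a], gene_bin[b]}:
                    counts[bb][kind] += 1
            for i in range(4):
                got = report[i]["counts"]
                assert (got.TP, got.FP, got.FN) == (
                    counts[i]["TP"], counts[i]["FP"], counts[i]["FN"]
                )
            # aggregation: per-bin TP sums to at least the global TP
            global_tp = pairwise_confusion(predicted, reference).TP
            assert sum(r["counts"].TP for r in report) >= global_tp

    def test_too_few_genes_errors(self):
        cat = make_catalog([[100, 200]])
        ref = part([0, 1], n=2)
        with pytest.raises(ValueError, match="at least 4"):
            length_binned_metrics(ref, ref, cat)


class TestPerOrthogroupErrors:
    def test_exact_match_is_error_free(self):
        ref = part([0, 1, 2], [3, 4], n=6)
        report = per_orthogroup_errors(ref, ref)
        assert report["pct_error_free"] == 100.0

    def test_split_group_flagged_fragmented(self):
        ref = part([0, 1, 2, 3, 4], n=5)
        predicted = part([0, 1, 2], [3, 4], n=5)
        report = per_orthogroup_errors(predicted, ref)
        row = report["groups"][0]
        assert row["fragmented"]
        assert row["missing"] == {3, 4}  # the smaller half
        assert report["pct_error_free"] == 0.0

    def test_random_counts_match_set_algebra(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            predicted = _random_partition(rng, 15)
            reference = _random_partition(rng, 15)
            universe = set().union(*reference.orthogroups)
            report = per_orthogroup_errors(predicted, reference)
            for ref_grp, row in zip(reference.orthogroups, report["groups"]):
                ref_u = ref_grp & universe
                overlaps = [len(ref_u & p) for p in predicted.orthogroups]
                best = max(overlaps) if overlaps else 0
                assert row["overlap"] == best
                if row["matched_group"] >= 0:
                    matched = predicted.orthogroups[row["matched_group"]]
                    assert row["missing"] == ref_u - matched
                    assert row["erroneous"] == (matched & universe) - ref_grp


class TestGeneLevelCounting:
    def test_flag_selects_counting_unit(self):
        ref = part([0, 1, 2, 3], n=6)
        predicted = part([0, 1, 2], n=6)
        pair_m = score_partition(predicted, ref, unit="pair")
        gene_m = score_partition(predicted, ref, unit="gene")
        assert pair_m.recall == pytest.approx(3 / 6)  # 3 of 6 ref pairs
        assert gene_m.recall == pytest.approx(3 / 4)  # 3 of 4 ref genes


class TestDeletionRobustness:
    def test_fraction_zero_is_identity_and_counts(self, default_dataset):
        truth, tables = default_dataset
        from orthokit.pipeline import infer_orthogroups

        def pipeline(catalog, hit_tables, surviving):
            return infer_orthogroups(catalog, hit_tables).partition

        full = pipeline(truth.catalog, tables, None)
        base = score_partition(full, truth.true_partition)
        results = deletion_robustness(
            truth.catalog, tables, truth.true_partition, pipeline,
            deletion_fractions=(0.0,), seed=5,
        )
        assert results[0.0].fscore == pytest.approx(base.fscore)

    def test_invalid_fraction(self, default_dataset):
        truth, tables = default_dataset
        with pytest.raises(ValueError, match="fraction"):
            deletion_robustness(
                truth.catalog, tables, truth.true_partition,
                lambda c, t, s: truth.true_partition,
                deletion_fractions=(1.5,),
            )

    def test_deletion_count_exact(self, default_dataset):
        truth, tables = default_dataset
        seen = {}

        def probe(catalog, hit_tables, surviving):
            seen["n"] = len(surviving)
            return truth.true_partition

        deletion_robustness(
            truth.catalog, tables, truth.true_partition, probe,
            deletion_fractions=(0.5,), seed=1,
        )
        assert seen["n"] == truth.catalog.n_genes - round(
            0.5 * truth.catalog.n_genes
        )
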