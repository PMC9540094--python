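import numpy as np
import pytest

from congruity.evaluation import (
    BinningError,
    ScoredInstance,
    accuracy_per_bin,
    attribute_vectors,
    correlate,
    equal_frequency_bins,
    evaluate,
    mean_cosine_similarity,
    score_test_set,
)
from congruity.formal_context import Instance
from congruity.measure import CongruityParams


def _scored(values, correct_flags):
    return [
        ScoredInstance(f"i{j}", v, "pos", "pos" if ok else "neg")
        for j, (v, ok) in enumerate(zip(values, correct_flags))
    ]


class TestScoreTestSet:
    def test_fixture_instances_reproduce_published_scores(self, bmi_lattice, bmi):
        labels = {"Person11": (1, 1), "Person12": (1, 0)}
        scored = score_test_set(
            bmi_lattice, bmi.instances, labels, CongruityParams(0.1, 0.9, "printed")
        )
        assert [s.id for s in scored] == ["Person11", "Person12"]
        assert [s.congruity for s in scored] == [0.913, 0.643]
        assert scored[0].correct and not scored[1].correct

    def test_empty_test_set(self, bmi_lattice):
        assert score_test_set(bmi_lattice, [], {}) == []

    def test_missing_label_is_an_error(self, bmi_lattice, bmi):
        with pytest.raises(KeyError, match="Person12"):
            score_test_set(bmi_lattice, bmi.instances, {"Person11": (0, 0)})

    def test_training_profiles_all_score_as_exact(self, bmi_lattice, bmi):
        ctx = bmi.context
        instances = [Instance(g, ctx.incidence[g]) for g in ctx.objects]
        labels = {g: (0, 0) for g in ctx.objects}
        scored = score_test_set(bmi_lattice, instances, labels)
        # exact case: value = alpha1*S + alpha2 >= alpha2
        assert all(s.congruity >= 0.9 for s in scored)


class TestEqualFrequencyBins:
    def test_even_split(self):
        bins = equal_frequency_bins(list(range(1, 11)), 2)
        assert [len(b) for b in bins] == [5, 5]

    def test_tied_values_join_a_single_bin(self):
        bins = equal_frequency_bins([0.1, 0.1, 0.1, 0.9], 2)
        assert bins == [[0, 1, 2], [3]]

    def test_hundred_uniform_values_ten_even_bins(self):
        rng = np.random.default_rng(7)
        values = list(rng.uniform(size=100))
        bins = equal_frequency_bins(values, 10)
        assert [len(b) for b in bins] == [10] * 10

    def test_partition_and_ascending_order(self):
        rng = np.random.default_rng(11)
        values = list(rng.choice([0.1, 0.2, 0.5, 0.7, 0.9, 1.0], size=60))
        bins = equal_frequency_bins(values, 5)
        flat = [i for b in bins for i in b]
        assert sorted(flat) == list(range(60))
        maxima = [max(values[i] for i in b) for b in bins]
        minima = [min(values[i] for i in b) for b in bins]
        assert all(maxima[j] < minima[j + 1] for j in range(len(bins) - 1))

    @pytest.mark.parametrize(
        "values, k",
        [([1.0, 1.0, 1.0], 2), (list(range(5)), 8), ([0.5] * 50, 3)],
    )
    def test_infeasible_k_suggests_smaller(self, values, k):
        with pytest.raises(BinningError, match="smaller k"):
            equal_frequency_bins([float(v) for v in values], k)


class TestAccuracyPerBin:
    def test_fraction_of_correct_members(self):
        scored = _scored([0.2, 0.4, 0.6, 0.8], [True, True, True, False])
        bins = accuracy_per_bin([[0, 1], [2, 3]], scored)
        assert bins[0].accuracy == 1.0
        assert bins[1].accuracy == 0.5
        assert bins[0].mean_score == pytest.approx(0.3)

    def test_three_of_four_correct(self):
        scored = _scored([0.1, 0.2, 0.3, 0.4], [True, True, True, False])
        (b,) = accuracy_per_bin([[0, 1, 2, 3]], scored)
        assert b.accuracy == 0.75

    def test_empty_bin_rejected(self):
        with pytest.raises(BinningError):
            accuracy_per_bin([[]], [])


class TestCorrelate:
    def test_perfect_monotone_series(self):
        t = correlate([1, 2, 3, 4], [10, 20, 25, 40])
        assert t.spearman == pytest.approx(1.0)
        assert t.kendall == pytest.approx(1.0)

    def test_perfect_linear_series(self):
        t = correlate([1.0, 2.0, 3.0], [2.5, 4.5, 6.5])
        assert t.pearson == pytest.approx(1.0)

    def test_hand_computed_spearman(self):
        t = correlate([1, 2, 3], [3, 1, 2])
        assert t.spearman == pytest.approx(-0.5)

    def test_constant_series_reported_undefined(self):
        t = correlate([1, 2, 3], [5, 5, 5])
        assert t.pearson is None and t.kendall is None and t.spearman is None
        assert "constant" in t.undefined["pearson"]

    def test_two_point_series_is_degenerate_but_defined(self):
        t = correlate([0.2, 0.8], [0.5, 1.0])
        assert t.spearman == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            correlate([1.0], [1.0])
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2])


class TestCosineBaseline:
    def test_identical_vectors(self):
        train = np.ones((4, 3))
        assert mean_cosine_similarity(train, np.ones(3)) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        train = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert mean_cosine_similarity(train, np.array([0.0, 1.0])) == 0.0

    def test_half_overlap(self):
        train = np.array([[1.0, 1.0, 0.0]])
        v = np.array([1.0, 0.0, 1.0])
        assert mean_cosine_similarity(train, v) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            mean_cosine_similarity(np.ones((2, 2)), np.zeros(2))

    def test_attribute_vectors_ignore_foreign_attributes(self):
        mat = attribute_vectors(
            ("a", "b"), [frozenset({"a", "zzz"}), frozenset()]
        )
        assert mat.tolist() == [[1.0, 0.0], [0.0, 0.0]]


class TestEvaluate:
    @pytest.fixture()
    def test_bed(self, bmi_lattice, bmi):
        ctx = bmi.context
        instances = [Instance(f"c{g}", ctx.incidence[g]) for g in ctx.objects]
        return bmi_lattice, instances

    def test_all_correct_predictions_give_undefined_pearson(self, test_bed):
        lattice, instances = test_bed
        labels = {i.id: ("yes", "yes") for i in instances}
        report = evaluate(lattice, instances, labels, k=2)
        assert report.overall_accuracy == 1.0
        assert all(b.accuracy == 1.0 for b in report.bins)
        assert report.correlations.pearson is None
        assert "pearson" in report.correlations.undefined

    def test_two_separated_clusters_fully_correlated(self, test_bed):
        lattice, instances = test_bed
        # low-congruity cluster half right, high-congruity cluster all right
        scored = score_test_set(lattice, instances, {i.id: (0, 0) for i in instances})
        order = sorted(range(len(scored)), key=lambda j: scored[j].congruity)
        labels = {}
        for rank, j in enumerate(order):
            inst = instances[j]
            wrong = rank < len(order) // 2 and rank % 2 == 0
            labels[inst.id] = (1, 0 if wrong else 1)
        report = evaluate(lattice, instances, labels, k=2)
        accs = [b.accuracy for b in report.bins]
        assert accs[0] < accs[1]
        assert report.correlations.spearman == pytest.approx(1.0)

    def test_bins_partition_instances(self, test_bed):
        lattice, instances = test_bed
        labels = {i.id: (0, i.id >= "cPerson5") for i in instances}
        report = evaluate(lattice, instances, labels, k=3)
        members = [m for b in report.bins for m in b.members]
        assert sorted(members) == sorted(i.id for i in instances)

    def test_coefficients_invariant_under_id_relabeling(self, test_bed):
        lattice, instances = test_bed
        labels = {
            i.id: (1, 1 if j % 3 else 0) for j, i in enumerate(instances)
        }
        rep1 = evaluate(lattice, instances, labels, k=3)
        renamed = [Instance(f"x{j}", i.attributes) for j, i in enumerate(instances)]
        labels2 = {f"x{j}": labels[i.id] for j, i in enumerate(instances)}
        rep2 = evaluate(lattice, renamed, labels2, k=3)
        assert rep1.correlations == rep2.correlations

    def test_plot_writes_figure(self, test_bed, tmp_path):
        lattice, instances = test_bed
        labels = {
            i.id: (1, 1 if j % 4 else 0) for j, i in enumerate(instances)
        }
        report = evaluate(lattice, instances, labels, k=2, baseline=True)
        from congruity.evaluation import plot_report

        out = tmp_path / "bins.png"
        plot_report(report, out)
        assert out.stat().st_size > 0

    def test_baseline_shares_binning_path(self, test_bed):
        lattice, instances = test_bed
        labels = {
            i.id: (1, 1 if j % 4 else 0) for j, i in enumerate(instances)
        }
        report = evaluate(lattice, instances, labels, k=2, baseline=True)
        assert report.baseline_bins is not None
        for coef in (
            report.baseline_correlations.pearson,
            report.baseline_correlations.kendall,
            report.baseline_correlations.spearman,
        ):
            assert coef is None or -1.0 <= coef <= 1.0
        assert sum(len(b.members) for b in report.baseline_bins) == len(instances)
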