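"""Drug-overlap curves, class prediction and comorbidity comparison."""

import math

import numpy as np
import pytest

from simfuse.diseasemap import build_map
from simfuse.evaluation import (
    class_prediction,
    comorbidity_comparison,
    drug_overlap_curve,
)
from simfuse.similarity import SimilarityMatrix, jaccard
from simfuse.spaces import ClassLabels, ComorbidityTable, FeatureSpace, ValidationError


def _sim(diseases, vec, name="sim"):
    return SimilarityMatrix.from_pair_vector(tuple(diseases), np.asarray(vec, float), name)


class TestDrugOverlapCurve:
    @pytest.fixture
    def toy(self):
        diseases = ["d1", "d2", "d3", "d4"]
        # triu order: (1,2) (1,3) (1,4) (2,3) (2,4) (3,4)
        sim = _sim(diseases, [0.9, 0.1, 0.2, 0.15, 0.3, 0.05])
        drugs = FeatureSpace(
            name="drug",
            kind="unsigned",
            members={
                "d1": {"aspirin", "statin"},
                "d2": {"aspirin", "statin"},
                "d3": {"metformin"},
                "d4": {"statin", "insulin"},
            },
        )
        return sim, drugs

    def test_level_zero_links_all_pairs(self, toy):
        sim, drugs = toy
        curve = drug_overlap_curve(sim, drugs, levels=[0.0])
        drug_j = [
            jaccard(drugs.members[a], drugs.members[b]) for a, b in sim.pair_index()
        ]
        # level 0 threshold is the minimum; strict comparison drops the min pair
        vec = sim.pair_vector()
        expected = np.mean([j for j, v in zip(drug_j, vec) if v > vec.min()])
        assert curve.mean_overlap[0] == pytest.approx(expected)
        assert curve.n_links[0] == 5

    def test_top_pair_sharing_all_drugs_scores_one(self, toy):
        sim, drugs = toy
        curve = drug_overlap_curve(sim, drugs, levels=[0.9])
        assert curve.n_links[0] == 1  # only (d1,d2), identical drug sets
        assert curve.mean_overlap[0] == pytest.approx(1.0)

    def test_hand_computed_curve_at_mid_level(self, toy):
        sim, drugs = toy
        curve = drug_overlap_curve(sim, drugs, levels=[0.5])
        # 0.5-quantile of [0.9,0.1,0.2,0.15,0.3,0.05] is 0.175; pairs above:
        # (d1,d2)=1.0, (d1,d4)=1/3, (d2,d4)=1/3
        assert curve.n_links[0] == 3
        assert curve.mean_overlap[0] == pytest.approx((1.0 + 1 / 3 + 1 / 3) / 3)

    def test_empty_link_set_is_nan_not_zero(self, toy):
        sim, drugs = toy
        constant = _sim(sim.diseases, [0.5] * 6)
        curve = drug_overlap_curve(constant, drugs, levels=[0.5])
        assert curve.n_links[0] == 0
        assert math.isnan(curve.mean_overlap[0])

    def test_n_links_nonincreasing_in_level(self, toy, rng):
        sim, drugs = toy
        curve = drug_overlap_curve(sim, drugs, levels=np.arange(0, 1, 0.05))
        assert all(a >= b for a, b in zip(curve.n_links, curve.n_links[1:]))

    def test_level_out_of_range_rejected(self, toy):
        sim, drugs = toy
        with pytest.raises(ValueError):
            drug_overlap_curve(sim, drugs, levels=[1.0])

    def test_missing_disease_in_drug_space_rejected(self, toy):
        sim, drugs = toy
        shrunk = FeatureSpace(
            name="drug", kind="unsigned", members={"d1": {"aspirin"}}
        )
        with pytest.raises(ValidationError, match="lacks"):
            drug_overlap_curve(sim, shrunk, levels=[0.0])


def _separable_fixture(n_per_class=8, gap=0.6, noise=0.05, seed=0):
    """Similarity matrix where within-class pairs clearly exceed between."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    diseases = tuple(f"d{i:02d}" for i in range(n))
    labels = ClassLabels(
        labels={d: {"pos" if i < n_per_class else "neg"} for i, d in enumerate(diseases)}
    )
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < n_per_class) == (j < n_per_class)
            v = (gap if same else 0.0) + noise * rng.random()
            values[i, j] = values[j, i] = v
    sim = SimilarityMatrix(diseases=diseases, values=values, space_name="sim", normalized=True)
    return sim, labels


class TestClassPrediction:
    def test_separable_fixture_reaches_perfect_auroc(self):
        sim, labels = _separable_fixture()
        result = class_prediction(sim, labels, "pos", n_runs=15, seed=1)
        assert result.auroc_mean == pytest.approx(1.0)

    def test_roc_curve_spans_unit_square(self):
        sim, labels = _separable_fixture()
        result = class_prediction(sim, labels, "pos", n_runs=15, seed=1)
        assert (result.roc_fpr[0], result.roc_tpr[0]) == (0.0, 0.0)
        assert (result.roc_fpr[-1], result.roc_tpr[-1]) == (1.0, 1.0)
        assert 0.0 <= result.auroc_mean <= 1.0

    def test_permuted_labels_score_near_chance(self, rng):
        # average over label permutations: any single permutation retains a
        # chance correlation with the true classes, but the permutation-null
        # expectation is exactly 0.5
        sim, labels = _separable_fixture()
        diseases = list(sim.diseases)
        classes = [labels.classes_of(d) for d in diseases]
        aurocs = []
        for perm in range(20):
            rng.shuffle(classes)
            shuffled = ClassLabels(labels=dict(zip(diseases, classes)))
            result = class_prediction(sim, shuffled, "pos", n_runs=10, seed=perm)
            aurocs.append(result.auroc_mean)
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_same_seed_reproduces_exactly(self):
        sim, labels = _separable_fixture(noise=0.3)
        a = class_prediction(sim, labels, "pos", n_runs=10, seed=3)
        b = class_prediction(sim, labels, "pos", n_runs=10, seed=3)
        assert a.auroc_mean == b.auroc_mean
        assert np.array_equal(a.roc_fpr, b.roc_fpr)

    def test_auroc_invariant_to_disease_ordering(self, rng):
        sim, labels = _separable_fixture()
        order = rng.permutation(len(sim.diseases))
        permuted = SimilarityMatrix(
            diseases=tuple(sim.diseases[i] for i in order),
            values=sim.values[np.ix_(order, order)],
            space_name="sim",
            normalized=True,
        )
        a = class_prediction(sim, labels, "pos", n_runs=10, seed=4)
        b = class_prediction(permuted, labels, "pos", n_runs=10, seed=4)
        assert abs(a.auroc_mean - b.auroc_mean) < 0.05

    def test_degenerate_task_rejected(self):
        sim, _ = _separable_fixture(n_per_class=4)
        labels = ClassLabels(labels={d: {"pos"} for d in sim.diseases})
        with pytest.raises(ValidationError, match="positives"):
            class_prediction(sim, labels, "pos", n_runs=2, seed=0)


class TestComorbidityComparison:
    def _map_with_edges(self, diseases, linked, threshold=0.5):
        n = len(diseases)
        vec = []
        linked = {tuple(sorted(p)) for p in linked}
        for i in range(n):
            for j in range(i + 1, n):
                pair = tuple(sorted((diseases[i], diseases[j])))
                vec.append(0.9 if pair in linked else 0.1)
        fused = _sim(diseases, vec, "fused")
        return build_map(fused, [], threshold)

    def test_clean_contrast(self):
        diseases = ["d1", "d2", "d3", "d4"]
        dmap = self._map_with_edges(diseases, [("d1", "d2"), ("d3", "d4")])
        table = ComorbidityTable(
            entries={
                ("d1", "d2"): 3.0,
                ("d3", "d4"): 3.0,
                ("d1", "d3"): 1.0,
                ("d2", "d4"): 1.0,
            }
        )
        summary = comorbidity_comparison(dmap, table, rr_thresholds=[1.5])
        assert summary.median_rr_linked == 3.0
        assert summary.median_rr_nonlinked == 1.0
        f_link, f_non, _ = summary.fractions_above[1.5]
        assert (f_link, f_non) == (1.0, 0.0)

    def test_empty_map_reports_coverage_failure(self):
        diseases = ["d1", "d2", "d3"]
        dmap = self._map_with_edges(diseases, [])
        table = ComorbidityTable(entries={("d1", "d2"): 2.0})
        summary = comorbidity_comparison(dmap, table)
        assert not summary.coverage_ok
        assert math.isnan(summary.median_rr_linked)

    def test_medians_match_hand_sorted_toy(self):
        diseases = ["d1", "d2", "d3", "d4"]
        dmap = self._map_with_edges(
            diseases, [("d1", "d2"), ("d1", "d3"), ("d2", "d3")]
        )
        table = ComorbidityTable(
            entries={
                ("d1", "d2"): 2.0,
                ("d1", "d3"): 5.0,
                ("d2", "d3"): 3.0,
                ("d1", "d4"): 0.8,
                ("d2", "d4"): 1.2,
                ("d3", "d4"): 1.0,
            }
        )
        summary = comorbidity_comparison(dmap, table)
        assert summary.median_rr_linked == 3.0  # median of [2, 3, 5]
        assert summary.median_rr_nonlinked == 1.0  # median of [0.8, 1.0, 1.2]
        assert summary.n_linked_covered == 3
        assert summary.n_nonlinked_covered == 3
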