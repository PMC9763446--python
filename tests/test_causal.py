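import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.weightstats import CompareMeans, DescrStatsW

from causaltext.causal import (
    CausalTable,
    UntestableEntityError,
    ZeroVarianceError,
    adjust_pvalues,
    do_partition,
    infer_causal_terms,
    probability_difference,
    z_test_one_tailed,
)
from causaltext.classifier import PredictionTable
from causaltext.ner import EntityOccurrence
from causaltext.corpus import Corpus
from conftest import make_corpus


def bh_step_up_oracle(pvalues):
    """Independent Benjamini-Hochberg step-up: sort, scale by m/i, enforce
    monotonicity from the largest rank down, cap at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


class TestZTest:
    def test_matches_independent_oracle_on_1000_inputs(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n1 = int(rng.integers(2, 40))
            n2 = int(rng.integers(2, 40))
            s1 = rng.random(n1)
            s2 = rng.random(n2)
            if np.var(s1) == 0 and np.var(s2) == 0:
                continue
            z, p = z_test_one_tailed(s1, s2)
            cm = CompareMeans(DescrStatsW(s1), DescrStatsW(s2))
            z_ref, p_ref = cm.ztest_ind(alternative="larger", usevar="unequal")
            assert z == pytest.approx(z_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_worked_example(self):
        z, p = z_test_one_tailed([0.5, 0.7], [0.2, 0.4])
        assert z == pytest.approx(2.1213, abs=5e-5)
        assert p == pytest.approx(0.0169, abs=5e-5)

    def test_identical_groups_symmetry(self):
        z, p = z_test_one_tailed([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert z == 0.0
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(ZeroVarianceError):
            z_test_one_tailed([0.6, 0.6], [0.6, 0.6])


class TestAdjustPvalues:
    def test_step_up_worked_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.012]) == pytest.approx([0.012])

    def test_all_equal_unchanged(self):
        assert adjust_pvalues([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_oracle_and_invariants(self, pvalues):
        adjusted = adjust_pvalues(pvalues)
        oracle = bh_step_up_oracle(pvalues)
        assert adjusted == pytest.approx(oracle, abs=1e-12)
        for raw, adj in zip(pvalues, adjusted):
            assert raw <= adj <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])

    def test_bonferroni_mode(self):
        assert adjust_pvalues([0.01, 0.02], method="bonferroni") == pytest.approx([0.02, 0.04])


class TestDoPartition:
    @staticmethod
    def setup_three():
        preds = PredictionTable({"i0": 0.9, "i1": 0.2, "i2": 0.3})
        occ = EntityOccurrence(
            instance_sets={"e": frozenset({"i0"}), "everywhere": frozenset({"i0", "i1", "i2"})},
            categories={"e": "disease", "everywhere": "disease"},
        )
        return preds, occ

    def test_partition_contents(self):
        preds, occ = self.setup_three()
        part = do_partition("e", occ, preds)
        assert sorted(part.s1) == [0.9]
        assert sorted(part.s2) == [0.2, 0.3]
        assert part.n_do + part.n_not_do == len(preds)

    def test_entity_in_all_instances_untestable(self):
        preds, occ = self.setup_three()
        with pytest.raises(UntestableEntityError):
            do_partition("everywhere", occ, preds)


class TestProbabilityDifference:
    @pytest.mark.parametrize(
        "mean_do, mean_not_do, expected",
        [(0.398, 0.244, 0.154), (0.547, 0.244, 0.303), (0.4, 0.4, 0.0)],
    )
    def test_examples(self, mean_do, mean_not_do, expected):
        assert probability_difference(mean_do, mean_not_do) == pytest.approx(expected, abs=1e-12)


class TestInferCausalTerms:
    @staticmethod
    def build_inputs(rng, n=60, effect=0.25):
        """Corpus of n instances; entity 'hit' raises probabilities in its
        instances by `effect`; entity 'null' is unrelated."""
        ids = [f"i{k}" for k in range(n)]
        corpus = make_corpus([(f"text {k}", "negative") for k in range(n)])
        hit_members = frozenset(ids[: n // 3])
        null_members = frozenset(rng.choice(ids, size=n // 3, replace=False).tolist())
        probs = {}
        for k, pid in enumerate(ids):
            base = 0.3 + 0.05 * rng.standard_normal()
            probs[pid] = float(np.clip(base + (effect if pid in hit_members else 0.0), 0.01, 0.99))
        preds = PredictionTable(probs)
        occ = EntityOccurrence(
            instance_sets={"hit": hit_members, "null": null_members},
            categories={"hit": "disease", "null": "disease"},
        )
        return corpus, preds, occ

    def test_strong_effect_enriched_null_not(self):
        rng = np.random.default_rng(0)
        corpus, preds, occ = self.build_inputs(rng)
        table = infer_causal_terms(corpus, preds, occ)
        assert "hit" in table.enriched_ids()
        record = table.record("hit")
        assert record.probability_difference == pytest.approx(
            record.mean_do - record.mean_not_do, abs=1e-12
        )

    def test_single_entity_bh_reduces_to_raw_p(self):
        rng = np.random.default_rng(1)
        corpus, preds, occ = self.build_inputs(rng)
        solo = EntityOccurrence(
            instance_sets={"hit": occ.instance_sets["hit"]}, categories={"hit": "disease"}
        )
        table = infer_causal_terms(corpus, preds, solo)
        record = table.record("hit")
        assert record.adjusted_p == pytest.approx(record.p_value, rel=1e-12)
        assert ("hit" in table.enriched_ids()) == (record.p_value < table.alpha)

    def test_small_group_skipped_with_reason(self):
        rng = np.random.default_rng(2)
        corpus, preds, occ = self.build_inputs(rng)
        tiny = EntityOccurrence(
            instance_sets={"rare": frozenset({"i0", "i1"}), "hit": occ.instance_sets["hit"]},
            categories={"rare": "drug", "hit": "disease"},
        )
        table = infer_causal_terms(corpus, preds, tiny, min_group=5)
        assert "rare" in table.skipped
        assert all(r.entity_id != "rare" for r in table.records)

    def test_invariant_to_instance_order(self):
        rng = np.random.default_rng(3)
        corpus, preds, occ = self.build_inputs(rng)
        table = infer_causal_terms(corpus, preds, occ)
        perm = np.random.default_rng(9).permutation(corpus.n)
        shuffled = Corpus(tuple(corpus.instances[i] for i in perm))
        shuffled_preds = PredictionTable(
            {pid: preds[pid] for pid in shuffled.ids()}
        )
        table2 = infer_causal_terms(shuffled, shuffled_preds, occ)
        assert [r.entity_id for r in table.records] == [r.entity_id for r in table2.records]
        for r1, r2 in zip(table.records, table2.records):
            assert r1.z == pytest.approx(r2.z, rel=1e-12)
            assert r1.adjusted_p == pytest.approx(r2.adjusted_p, rel=1e-12)

    def test_z_threshold_mode(self):
        rng = np.random.default_rng(4)
        corpus, preds, occ = self.build_inputs(rng)
        table = infer_causal_terms(corpus, preds, occ, z_threshold=1.645)
        for record in table.records:
            assert (record.entity_id in table.enriched_ids()) == (record.z > 1.645)

    def test_empty_occurrence_error(self):
        rng = np.random.default_rng(5)
        corpus, preds, _ = self.build_inputs(rng)
        empty = EntityOccurrence(instance_sets={}, categories={})
        with pytest.raises(ValueError):
            infer_causal_terms(corpus, preds, empty)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_effect_size_monotone_in_expected_z(self, small_synthetic):
        """Raising a planted effect raises the analytic DO/NOT-DO gap, which
        drives the z statistic; checked on the generator's analytic oracle."""
        from causaltext.synthetic import GeneratorConfig, generate_corpus, analytic_do_difference

        _, _, weak_truth = generate_corpus(
            GeneratorConfig(n_sentences=10, n_disease=5, n_causal=2, effect_size=0.5, seed=0)
        )
        _, _, strong_truth = generate_corpus(
            GeneratorConfig(n_sentences=10, n_disease=5, n_causal=2, effect_size=2.0, seed=0)
        )
        assert analytic_do_difference(strong_truth, "disease00") > analytic_do_difference(
            weak_truth, "disease00"
        )

    def test_table_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        corpus, preds, occ = self.build_inputs(rng)
        table = infer_causal_terms(corpus, preds, occ)
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        loaded = CausalTable.from_tsv(path)
        assert loaded.enriched_ids() == table.enriched_ids()
        assert [r.entity_id for r in loaded.records] == [r.entity_id for r in table.records]
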