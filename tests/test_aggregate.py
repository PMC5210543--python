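"""Harmonic-sum aggregation: oracle agreement, damping, grouping, and the
association-building tiers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdscore.aggregate import (
    AggregationConfig,
    associations_to_frame,
    build_associations,
    datasource_score,
    datatype_score,
    harmonic_sum,
    max_harmonic_sum,
    normalized_harmonic_sum,
    overall_score,
)
from tdscore.evidence import EvidenceRecord
from tdscore.scoring import ScoringConfig

RAW = AggregationConfig(normalized=False)


def brute_force_harmonic(scores, cap=100):
    """Independent oracle: plain-Python descending sort and term-by-term sum."""
    total = 0.0
    for k, s in enumerate(sorted(scores, reverse=True)[:cap], start=1):
        total += s / (k * k)
    return total


class TestHarmonicSum:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([], 0.0),
            ([0.8], 0.8),
            ([1, 1, 1], 1 + 1 / 4 + 1 / 9),
            ([0.2, 1.0], 1.0 + 0.2 / 4),
        ],
    )
    def test_known_values(self, scores, expected):
        assert harmonic_sum(scores) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(0, 201))
            v = rng.uniform(0, 1, size=n).tolist()
            assert harmonic_sum(v) == pytest.approx(brute_force_harmonic(v), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(0, 1, size=50).tolist()
        shuffled = list(v)
        rng.shuffle(shuffled)
        assert harmonic_sum(v) == harmonic_sum(shuffled)

    def test_element_domain(self):
        with pytest.raises(ValueError):
            harmonic_sum([0.5, 1.2])

    @given(
        v=st.lists(st.floats(min_value=0, max_value=1), max_size=30),
        bump=st.floats(min_value=0, max_value=1),
        idx=st.integers(min_value=0, max_value=29),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_element(self, v, bump, idx):
        if not v:
            return
        idx %= len(v)
        raised = list(v)
        raised[idx] = min(1.0, raised[idx] + bump)
        assert harmonic_sum(raised) >= harmonic_sum(v) - 1e-12


class TestNormalizedHarmonicSum:
    def test_cap_ones_reach_exactly_one(self):
        assert normalized_harmonic_sum([1.0] * 100, cap=100) == pytest.approx(1.0)

    def test_empty_is_zero(self):
        assert normalized_harmonic_sum([]) == 0.0

    def test_single_one_against_brute_forced_denominator(self):
        denominator = sum(1 / k**2 for k in range(1, 101))
        assert normalized_harmonic_sum([1.0], cap=100) == pytest.approx(1 / denominator)
        assert max_harmonic_sum(100) == pytest.approx(denominator, abs=1e-12)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            v = rng.uniform(0, 1, size=int(rng.integers(0, 300))).tolist()
            assert 0.0 <= normalized_harmonic_sum(v) <= 1.0


class TestDatasourceScore:
    def test_single_full_score_raw_mode(self):
        cfg = ScoringConfig()
        assert datasource_score([1.0], "chembl", cfg, RAW) == 1.0

    def test_damping_bounds_large_batches(self):
        """1000 pieces of identical evidence score barely above 100 pieces:
        volume is damped, not rewarded linearly."""
        cfg = ScoringConfig()
        s_1000 = datasource_score([0.5] * 1000, "chembl", cfg, RAW)
        s_10 = datasource_score([0.5] * 10, "chembl", cfg, RAW)
        assert s_1000 <= 0.5 * math.pi**2 / 6
        assert s_1000 / s_10 < 100

    def test_weight_zero_annihilates(self):
        cfg = ScoringConfig().with_weights(chembl=0.0)
        assert datasource_score([1.0, 0.9], "chembl", cfg, RAW) == 0.0

    def test_weight_applied_after_aggregation(self):
        cfg = ScoringConfig().with_weights(europepmc=0.2)
        unweighted = ScoringConfig().with_weights(europepmc=1.0)
        v = [0.5, 0.4]
        assert datasource_score(v, "europepmc", cfg, RAW) == pytest.approx(
            0.2 * datasource_score(v, "europepmc", unweighted, RAW)
        )


class TestDatatypeAndOverall:
    def test_somatic_sources_group_together(self):
        scores = {"cancer_gene_census": 0.9, "intogen": 0.5, "eva_somatic": 0.2}
        result = datatype_score(scores, RAW)
        assert set(result) == {"somatic_mutations"}
        assert result["somatic_mutations"] == pytest.approx(
            brute_force_harmonic([0.9, 0.5, 0.2])
        )

    def test_single_source_passes_through_raw(self):
        assert datatype_score({"chembl": 0.7}, RAW) == {"drugs": 0.7}

    def test_empty_input(self):
        assert datatype_score({}, RAW) == {}

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            datatype_score({"no_such_db": 0.5}, RAW)

    def test_overall_single_type_raw(self):
        assert overall_score({"drugs": 0.7}, RAW) == 0.7

    def test_overall_all_zero(self):
        assert overall_score({dt: 0.0 for dt in ("drugs", "text_mining")}, RAW) == 0.0

    def test_adding_a_datatype_never_decreases_overall(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            base = {f"t{i}": float(s) for i, s in enumerate(rng.uniform(0, 1, 3))}
            extended = dict(base, extra=float(rng.uniform(0, 1)))
            assert overall_score(extended, RAW) >= overall_score(base, RAW) - 1e-12


def _records(spec):
    """spec: list of (evidence_id, target, disease, datasource, payload)."""
    from tdscore.constants import DATASOURCE_TO_DATATYPE

    return [
        EvidenceRecord(e, t, d, src, DATASOURCE_TO_DATATYPE[src], payload)
        for e, t, d, src, payload in spec
    ]


class TestBuildAssociations:
    def test_empty_input(self, asthma_ontology):
        assert build_associations([], ontology=asthma_ontology) == []

    def test_single_record_propagates_to_each_ancestor(self, asthma_ontology):
        records = _records(
            [("ev:1", "ENSG00000000001", "EFO:0004591", "chembl", {"max_phase": 4})]
        )
        rows = build_associations(records, ontology=asthma_ontology, agg=RAW)
        assert len(rows) == 3  # direct + 2 inferred
        by_disease = {r.disease_id: r for r in rows}
        assert by_disease["EFO:0004591"].is_direct
        assert not by_disease["EFO:0000270"].is_direct
        assert not by_disease["EFO:0009687"].is_direct

    def test_two_records_same_pair_same_source_one_row(self, asthma_ontology):
        records = _records(
            [
                ("ev:1", "T1", "EFO:0009687", "chembl", {"max_phase": 4}),
                ("ev:2", "T1", "EFO:0009687", "chembl", {"max_phase": 2}),
            ]
        )
        rows = build_associations(records, ontology=asthma_ontology, agg=RAW)
        assert len(rows) == 1
        assert rows[0].evidence_count == 2
        assert rows[0].source_scores["chembl"] == pytest.approx(1.0 + 0.2 / 4)

    def test_ancestor_scores_dominate_descendant_raw_unweighted(self, asthma_ontology):
        cfg = ScoringConfig().with_weights(europepmc=1.0)
        records = _records(
            [
                ("ev:1", "T1", "EFO:0004591", "chembl", {"max_phase": 3}),
                ("ev:2", "T1", "EFO:0000270", "chembl", {"max_phase": 2}),
                ("ev:3", "T1", "EFO:0000270", "europepmc", {"score": 0.4}),
            ]
        )
        rows = build_associations(records, ontology=asthma_ontology, config=cfg, agg=RAW)
        by_disease = {r.disease_id: r for r in rows}
        for child, parent in [("EFO:0004591", "EFO:0000270"), ("EFO:0000270", "EFO:0009687")]:
            for src, val in by_disease[child].source_scores.items():
                assert by_disease[parent].source_scores[src] >= val - 1e-12

    def test_weight_monotonicity_on_overall(self, asthma_ontology):
        records = _records(
            [
                ("ev:1", "T1", "EFO:0000270", "gwas_catalog",
                 {"pvalue": 1e-8, "sample_size": 4000, "so_term": "SO:0001589"}),
                ("ev:2", "T1", "EFO:0000270", "europepmc", {"score": 0.8}),
            ]
        )
        low = ScoringConfig().with_weights(gwas_catalog=0.5)
        high = ScoringConfig().with_weights(gwas_catalog=1.0)
        rows_low = build_associations(records, ontology=asthma_ontology, config=low)
        rows_high = build_associations(records, ontology=asthma_ontology, config=high)
        for rl, rh in zip(rows_low, rows_high):
            assert rh.overall >= rl.overall - 1e-12

    def test_output_order_deterministic(self, asthma_ontology):
        records = _records(
            [
                ("ev:2", "T2", "EFO:0000270", "chembl", {"max_phase": 4}),
                ("ev:1", "T1", "EFO:0004591", "reactome", {}),
            ]
        )
        rows = build_associations(records, ontology=asthma_ontology)
        keys = [(r.target_id, r.disease_id) for r in rows]
        assert keys == sorted(keys)

    def test_frame_export_has_frozen_columns(self, asthma_ontology):
        records = _records(
            [("ev:1", "T1", "EFO:0000270", "chembl", {"max_phase": 4})]
        )
        frame = associations_to_frame(build_associations(records, ontology=asthma_ontology))
        assert list(frame.columns[:5]) == [
            "target_id", "disease_id", "is_direct", "overall", "evidence_count"
        ]
        assert frame.shape[0] == 2
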