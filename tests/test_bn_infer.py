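"""Exact inference: enumeration oracle, variable elimination, virtual evidence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from haerisk import (
    CPT,
    Cohort,
    DagModel,
    DiscreteBN,
    Evidence,
    FitConfig,
    Hard,
    ImpossibleEvidenceError,
    NodeDef,
    SchemaError,
    fit_network,
    joint_probability,
    posterior_by_elimination,
    posterior_by_enumeration,
    predict_outcome_proba,
    score_cohort,
)
from conftest import make_random_evidence, make_random_network


@pytest.fixture(scope="module")
def uniform_bn(dag):
    """Alpha-1 fit of an empty cohort: every CPT row uniform."""
    empty = Cohort(pd.DataFrame({n: [] for n in dag.node_names}), dag)
    return fit_network(empty, dag, FitConfig(alpha=1.0))


class TestJointProbability:
    def test_uniform_network_every_state_equiprobable(self, uniform_bn, dag):
        state = {n.name: n.categories[0] for n in dag.nodes}
        assert joint_probability(uniform_bn, state) == pytest.approx(1 / 65536)

    def test_chain_product_by_hand(self, chain_bn):
        # P(a1)*P(b0|a1)*P(high|b0) = 0.4 * 0.2 * 0.1
        p = joint_probability(chain_bn, {"A": "a1", "B": "b0", "C": "high"})
        assert p == pytest.approx(0.4 * 0.2 * 0.1)

    def test_joint_sums_to_one_over_all_states(self, chain_bn):
        total = sum(
            joint_probability(chain_bn, {"A": a, "B": b, "C": c})
            for a, b, c in itertools.product(
                ("a0", "a1"), ("b0", "b1"), ("low", "high")
            )
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_incomplete_assignment_rejected(self, chain_bn):
        with pytest.raises(SchemaError):
            joint_probability(chain_bn, {"A": "a0"})


class TestEnumeration:
    def test_no_evidence_uniform_network_uniform_posterior(self, uniform_bn):
        result = posterior_by_enumeration(uniform_bn, "Severity")
        assert np.allclose(result.probabilities, 0.25)

    def test_chain_posterior_by_hand(self, chain_bn):
        # P(A=a1 | C=high) = 0.4*0.42 / (0.6*0.22 + 0.4*0.42) = 0.56
        result = posterior_by_enumeration(
            chain_bn, "A", Evidence.from_dict(chain_bn.dag, {"C": "high"})
        )
        assert result["a1"] == pytest.approx(0.56, abs=1e-12)

    def test_flat_soft_evidence_is_vacuous(self, chain_bn):
        flat = Evidence.from_dict(chain_bn.dag, {"B": [1.0, 1.0]})
        with_flat = posterior_by_enumeration(chain_bn, "C", flat)
        without = posterior_by_enumeration(chain_bn, "C")
        assert np.allclose(with_flat.probabilities, without.probabilities, atol=1e-12)

    def test_degenerate_soft_equals_hard(self, chain_bn):
        soft = Evidence.from_dict(chain_bn.dag, {"B": [1.0, 0.0]})
        hard = Evidence.from_dict(chain_bn.dag, {"B": "b0"})
        a = posterior_by_enumeration(chain_bn, "C", soft)
        b = posterior_by_enumeration(chain_bn, "C", hard)
        assert np.allclose(a.probabilities, b.probabilities, atol=1e-12)

    def test_query_node_may_not_carry_evidence(self, chain_bn):
        with pytest.raises(SchemaError):
            posterior_by_enumeration(
                chain_bn, "C", Evidence.from_dict(chain_bn.dag, {"C": "high"})
            )

    def test_impossible_evidence_raises(self):
        dag = DagModel(
            nodes=(NodeDef("A", ("a0", "a1")),
                   NodeDef("B", ("low", "high"), role="outcome")),
            edges=(("A", "B"),),
        )
        bn = DiscreteBN(
            dag=dag,
            cpts={
                "A": CPT("A", (), np.array([1.0, 0.0])),
                "B": CPT("B", ("A",), np.array([[1.0, 0.0], [0.0, 1.0]])),
            },
        )
        evidence = Evidence.from_dict(dag, {"A": "a1"})
        with pytest.raises(ImpossibleEvidenceError):
            posterior_by_enumeration(bn, "B", evidence)
        with pytest.raises(ImpossibleEvidenceError):
            posterior_by_elimination(bn, "B", evidence)


class TestEliminationMatchesEnumeration:
    def test_random_networks_and_evidence(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 60:
            bn = make_random_network(rng)
            query = bn.dag.node_names[int(rng.integers(len(bn.dag.nodes)))]
            evidence = make_random_evidence(rng, bn, query)
            try:
                a = posterior_by_enumeration(bn, query, evidence)
            except ImpossibleEvidenceError:
                with pytest.raises(ImpossibleEvidenceError):
                    posterior_by_elimination(bn, query, evidence)
                continue
            b = posterior_by_elimination(bn, query, evidence)
            assert np.abs(a.probabilities - b.probabilities).max() <= 1e-9
            checked += 1

    def test_default_network_hard_evidence(self, fitted_441):
        evidence = Evidence.from_dict(fitted_441.dag, {"Age": "≥65"})
        a = posterior_by_enumeration(fitted_441, "MortalityRisk", evidence)
        b = posterior_by_elimination(fitted_441, "MortalityRisk", evidence)
        assert np.abs(a.probabilities - b.probabilities).max() <= 1e-9

    def test_soft_evidence_on_default_network(self, fitted_441):
        evidence = Evidence.from_dict(
            fitted_441.dag, {"Autoimmune": [0.1, 0.9], "Region": "Midwest"}
        )
        a = posterior_by_enumeration(fitted_441, "MortalityRisk", evidence)
        b = posterior_by_elimination(fitted_441, "MortalityRisk", evidence)
        assert np.abs(a.probabilities - b.probabilities).max() <= 1e-9


class TestFullEvidencePrediction:
    def test_uniform_network_predicts_half(self, uniform_bn, dag):
        record = {n.name: n.categories[0] for n in dag.predictors}
        assert predict_outcome_proba(uniform_bn, record) == pytest.approx(0.5)

    def test_agrees_with_enumeration(self, fitted_441, truth):
        record = dict(
            Age="40-64", Race="Black", Income="Q1", Payer="Medicare",
            Region="Midwest", Hypertension="yes", Autoimmune="no",
            Diabetes="no", Severity="major",
        )
        p = predict_outcome_proba(fitted_441, record)
        evidence = Evidence.from_dict(fitted_441.dag, record)
        oracle = posterior_by_enumeration(fitted_441, "MortalityRisk", evidence)
        assert p == pytest.approx(oracle["high"], abs=1e-9)

    def test_full_evidence_equals_markov_blanket_product(self, fitted_441):
        # with every predictor observed the posterior is the normalized
        # outcome CPT row (the outcome is a sink in the default DAG)
        record = dict(
            Age="≥65", Race="White", Income="Q4", Payer="Private",
            Region="West", Hypertension="no", Autoimmune="yes",
            Diabetes="yes", Severity="extreme",
        )
        dag = fitted_441.dag
        cpt = fitted_441.cpt("MortalityRisk")
        idx = tuple(dag.node(p).index_of(record[p]) for p in cpt.parents)
        row = cpt.table[idx]
        expected = row[dag.outcome.index_of("high")] / row.sum()
        assert predict_outcome_proba(fitted_441, record) == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_predictor_rejected(self, fitted_441):
        with pytest.raises(SchemaError):
            predict_outcome_proba(fitted_441, {"Age": "40-64"})

    def test_score_cohort_matches_per_record_elimination(self, truth, fitted_441):
        from haerisk import sample_cohort

        cohort = sample_cohort(truth, n=40, seed=13)
        scores = score_cohort(fitted_441, cohort.frame)
        for i in range(len(cohort)):
            record = cohort.frame.iloc[i].to_dict()
            record.pop("MortalityRisk")
            assert scores[i] == pytest.approx(
                predict_outcome_proba(fitted_441, record), abs=1e-12
            )

    def test_node_without_path_to_outcome_is_ignored(self):
        # two records differing only in a disconnected node score identically
        dag = DagModel(
            nodes=(
                NodeDef("X", ("x0", "x1")),
                NodeDef("Noise", ("n0", "n1")),
                NodeDef("Out", ("low", "high"), role="outcome"),
            ),
            edges=(("X", "Out"),),
        )
        bn = DiscreteBN(
            dag=dag,
            cpts={
                "X": CPT("X", (), np.array([0.7, 0.3])),
                "Noise": CPT("Noise", (), np.array([0.5, 0.5])),
                "Out": CPT("Out", ("X",), np.array([[0.8, 0.2], [0.4, 0.6]])),
            },
        )
        a = predict_outcome_proba(bn, {"X": "x0", "Noise": "n0"})
        b = predict_outcome_proba(bn, {"X": "x0", "Noise": "n1"})
        assert a == b


class TestConsistencyLaws:
    def test_law_of_total_probability_every_predictor(self, fitted_441):
        baseline = posterior_by_elimination(fitted_441, "MortalityRisk")["high"]
        from haerisk import exact_marginals

        marginals = exact_marginals(fitted_441)
        for node in fitted_441.dag.predictors:
            mix = 0.0
            for i, state in enumerate(node.categories):
                evidence = Evidence({node.name: Hard(state)})
                p = posterior_by_elimination(fitted_441, "MortalityRisk", evidence)
                mix += marginals[node.name][i] * p["high"]
            assert mix == pytest.approx(baseline, abs=1e-9)

    def test_risk_increasing_finding_never_decreases_risk(self, truth):
        contexts = [
            {},
            {"Age": "≥65"},
            {"Race": "Black", "Region": "Midwest"},
            {"Hypertension": "yes", "Severity": "major"},
        ]
        for ctx in contexts:
            base = posterior_by_elimination(
                truth, "MortalityRisk", Evidence.from_dict(truth.dag, ctx)
            )["high"]
            if "Autoimmune" in ctx:
                continue
            augmented = dict(ctx, Autoimmune="yes")
            p = posterior_by_elimination(
                truth, "MortalityRisk", Evidence.from_dict(truth.dag, augmented)
            )["high"]
            assert p >= base - 1e-12
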