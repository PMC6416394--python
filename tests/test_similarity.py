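"""Similarity metrics: Tanimoto, sequence, co-expression, GO (Wang), ATC,
and target-set overlap statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netcombo.similarity import (
    Ontology,
    atc_similarity,
    coexpression_similarity,
    cross_pairs,
    go_similarity,
    load_fingerprints,
    overlap_stats,
    pairwise_sequence_similarity,
    parse_fingerprint,
    sequence_similarity,
    similarity_profile,
    tanimoto,
    wang_term_similarity,
)


class TestTanimoto:
    def test_identical_nonzero_is_one(self):
        fp = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert tanimoto(fp, fp) == 1.0

    def test_direct_formula(self):
        # a=3, b=4, c=2 → 2/5
        fa = [1, 1, 1, 0, 0, 0]
        fb = [1, 1, 0, 1, 1, 0]
        assert tanimoto(fa, fb) == pytest.approx(0.4)

    def test_all_zero_defined_as_zero(self):
        z = np.zeros(8, dtype=bool)
        assert tanimoto(z, z) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto([1, 0], [1, 0, 1])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.booleans(), min_size=166, max_size=166),
           st.lists(st.booleans(), min_size=166, max_size=166))
    def test_matches_set_arithmetic_oracle(self, fa, fb):
        sa = {i for i, v in enumerate(fa) if v}
        sb = {i for i, v in enumerate(fb) if v}
        expected = len(sa & sb) / len(sa | sb) if (sa or sb) else 0.0
        got = tanimoto(fa, fb)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(tanimoto(fb, fa))
        assert 0.0 <= got <= 1.0

    def test_fingerprint_parsers(self, tmp_path):
        assert list(parse_fingerprint("0110")) == [False, True, True, False]
        assert list(parse_fingerprint("hex:a")) == [True, False, True, False]
        p = tmp_path / "fp.tsv"
        p.write_text("d1\t0101\nd2\t1101\n")
        fps = load_fingerprints(p)
        assert tanimoto(fps["d1"], fps["d2"]) == pytest.approx(2 / 3)


class TestSequenceSimilarity:
    def test_identical_sequences_distinct_ids_score_one(self):
        seqs = {"p1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "p2": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"}
        assert sequence_similarity({"p1"}, {"p2"}, seqs) == pytest.approx(1.0)

    def test_self_pair_exclusion_rule(self):
        # A={p1,p2}, B={p1,p3} → scored pairs exactly {(p1,p3),(p2,p1),(p2,p3)}
        assert set(cross_pairs({"p1", "p2"}, {"p1", "p3"})) == {
            ("p1", "p3"), ("p2", "p1"), ("p2", "p3"),
        }

    def test_shared_single_target_is_undefined(self):
        seqs = {"p1": "MKTAYIAKQR"}
        assert math.isnan(sequence_similarity({"p1"}, {"p1"}, seqs))

    def test_unrelated_random_sequences_score_low(self):
        rng = np.random.default_rng(21)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        vals = []
        for _ in range(20):
            s1 = "".join(rng.choice(aa, 50))
            s2 = "".join(rng.choice(aa, 50))
            vals.append(pairwise_sequence_similarity(s1, s2))
        assert float(np.mean(vals)) < 0.3
        assert max(vals) < 0.3

    def test_identity_method_available(self):
        s = "MKTAYIAKQRQISFVKSHFSRQ"
        assert pairwise_sequence_similarity(s, s, method="identity") == pytest.approx(1.0)


class TestCoexpression:
    def _expr(self, rows):
        return pd.DataFrame(rows).T

    def test_duplicated_profile_scores_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=32)
        expr = pd.DataFrame({"g1": x, "g2": x.copy()}).T
        assert coexpression_similarity({"g1"}, {"g2"}, expr) == pytest.approx(1.0)

    def test_anticorrelated_scores_one_by_absolute_value(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=32)
        expr = pd.DataFrame({"g1": x, "g2": -x}).T
        assert coexpression_similarity({"g1"}, {"g2"}, expr) == pytest.approx(1.0)

    def test_constant_vector_skipped(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame({"g1": np.ones(10), "g2": rng.normal(size=10)}).T
        assert math.isnan(coexpression_similarity({"g1"}, {"g2"}, expr))

    def test_null_mean_abs_pcc_at_32_tissues(self):
        # E|r| under independence at n=32 ≈ 0.14 (Monte-Carlo over 1000 pairs)
        rng = np.random.default_rng(4)
        vals = [
            abs(np.corrcoef(rng.normal(size=32), rng.normal(size=32))[0, 1])
            for _ in range(1000)
        ]
        data = pd.DataFrame(
            {f"g{i}": rng.normal(size=32) for i in range(60)}
        ).T
        sims = []
        genes = list(data.index)
        for a, b in itertools.combinations(genes[:40], 2):
            sims.append(coexpression_similarity({a}, {b}, data))
        assert float(np.mean(vals)) == pytest.approx(0.14, abs=0.02)
        assert float(np.mean(sims)) == pytest.approx(float(np.mean(vals)), abs=0.02)

    def test_network_restriction_filters_non_edges(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        expr = pd.DataFrame({"g1": rng.normal(size=16), "g2": rng.normal(size=16)}).T
        g = nx.Graph()
        g.add_nodes_from(["g1", "g2"])
        assert math.isnan(
            coexpression_similarity({"g1"}, {"g2"}, expr, network_restrict=g)
        )
        g.add_edge("g1", "g2")
        assert not math.isnan(
            coexpression_similarity({"g1"}, {"g2"}, expr, network_restrict=g)
        )


#: toy DAG — T0 root; T1, T2 below it; T3 is_a T1; T4 is_a T1 and part_of T2.
#: Wang semantic contributions (is_a 0.8, part_of 0.6), worked by hand:
#:   S_T3 = {T3:1, T1:0.8, T0:0.64}                     SV = 2.44
#:   S_T4 = {T4:1, T1:0.8, T2:0.6, T0:0.64}             SV = 3.04
#:   sim(T3,T4) = (0.8+0.8 + 0.64+0.64) / (2.44+3.04) = 2.88/5.48
TOY_DAG = pd.DataFrame(
    [("T1", "T0", "is_a"), ("T2", "T0", "is_a"), ("T3", "T1", "is_a"),
     ("T4", "T1", "is_a"), ("T4", "T2", "part_of"), ("T9", "T8", "is_a")],
    columns=["child", "parent", "relation"],
)


@pytest.fixture(scope="module")
def onto():
    return Ontology.from_table(TOY_DAG)


class TestGoSimilarity:

    def test_hand_worked_wang_values(self, onto):
        assert onto.s_values("T3") == pytest.approx({"T3": 1.0, "T1": 0.8, "T0": 0.64})
        assert onto.s_values("T4") == pytest.approx(
            {"T4": 1.0, "T1": 0.8, "T2": 0.6, "T0": 0.64}
        )
        assert wang_term_similarity("T3", "T4", onto) == pytest.approx(2.88 / 5.48)

    def test_identical_annotation_sets_score_one(self, onto):
        ann = {"g1": {"T3", "T4"}, "g2": {"T3", "T4"}}
        assert go_similarity({"g1"}, {"g2"}, ann, onto) == pytest.approx(1.0)

    def test_disjoint_dag_components_score_zero(self, onto):
        ann = {"g1": {"T3"}, "g2": {"T9"}}
        assert go_similarity({"g1"}, {"g2"}, ann, onto) == 0.0

    def test_unannotated_gene_skipped(self, onto):
        ann = {"g1": {"T3"}, "g2": {"T4"}, "g3": set()}
        val = go_similarity({"g1", "g3"}, {"g2"}, ann, onto)
        assert val == pytest.approx(2.88 / 5.48)

    def test_cyclic_ontology_rejected(self):
        bad = pd.DataFrame(
            [("A", "B", "is_a"), ("B", "A", "is_a")], columns=["child", "parent", "relation"]
        )
        with pytest.raises(ValueError):
            Ontology.from_table(bad)


class TestAtcSimilarity:
    def test_identical_single_codes(self):
        assert atc_similarity({"C03AA01"}, {"C03AA01"}) == 1.0

    def test_level_one_only_match(self):
        # shares only the anatomical level letter → 1/5
        assert atc_similarity({"C03AA01"}, {"C09XX99"}) == pytest.approx(0.2)

    def test_multi_code_drug_averaged_over_code_pairs(self):
        nicotine = {"N07BA01", "A11HA01", "C04AC01", "C10AD02"}
        other = {"C03AA01"}
        expected = np.mean([
            sum(a[:k] == "C03AA01"[:k] for k in (1, 3, 4, 5, 7)) / 5
            for a in sorted(nicotine)
        ])
        assert atc_similarity(nicotine, other) == pytest.approx(expected)

    def test_symmetric(self):
        a, b = {"N07BA01", "C04AC01"}, {"C03AA01", "A11HA01"}
        assert atc_similarity(a, b) == atc_similarity(b, a)

    def test_malformed_code_named_in_error(self):
        with pytest.raises(ValueError, match="C03A"):
            atc_similarity({"C03A"}, {"C03AA01"})


class TestOverlapStats:
    def test_complete_subset_gives_full_overlap_coefficient(self):
        st_ = overlap_stats({"a", "b"}, {"a", "b", "c", "d"}, 50)
        assert st_.overlap_coefficient == 1.0
        assert st_.jaccard == pytest.approx(0.5)

    def test_direct_formulas(self):
        st_ = overlap_stats(set("abcde"), set("abxy"), 100)
        assert st_.c_obs == 2
        assert st_.c_rand == pytest.approx(0.2)
        assert st_.fold_change == pytest.approx(10.0)
        assert st_.jaccard == pytest.approx(2 / 7)
        assert st_.overlap_coefficient == pytest.approx(0.5)

    def test_hypergeometric_tails_match_enumeration(self):
        # N=20, |A|=5, |B|=7: enumerate P(overlap = k) directly
        from math import comb

        n_, ka, kb = 20, 5, 7
        pmf = {
            k: comb(ka, k) * comb(n_ - ka, kb - k) / comb(n_, kb)
            for k in range(0, min(ka, kb) + 1)
        }
        a = set(range(ka))
        b = set(range(3)) | set(range(10, 14))  # overlap 3
        st_ = overlap_stats(a, b, n_)
        assert st_.p_enrich == pytest.approx(sum(p for k, p in pmf.items() if k >= 3), rel=1e-12)
        assert st_.p_deplete == pytest.approx(sum(p for k, p in pmf.items() if k <= 3), rel=1e-12)

    def test_jaccard_never_exceeds_overlap_coefficient(self):
        rng = np.random.default_rng(6)
        pool = [f"t{i}" for i in range(30)]
        for _ in range(200):
            a = set(rng.choice(pool, size=int(rng.integers(1, 10)), replace=False))
            b = set(rng.choice(pool, size=int(rng.integers(1, 10)), replace=False))
            st_ = overlap_stats(a, b, 30)
            assert 0 <= st_.jaccard <= st_.overlap_coefficient <= 1

    def test_background_smaller_than_union_rejected(self):
        with pytest.raises(ValueError):
            overlap_stats({"a", "b"}, {"c"}, 2)


class TestSimilarityProfile:
    def test_only_fingerprints_supplied(self):
        fps = {"d1": np.array([1, 0, 1], dtype=bool), "d2": np.array([1, 1, 0], dtype=bool)}
        rec = similarity_profile("d1", "d2", fingerprints=fps)
        assert rec["tanimoto"] == pytest.approx(1 / 3)
        assert rec["atc"] is None and rec["go"] is None

    def test_all_inputs_on_fixture(self, default_bundle, sim_inputs):
        from netcombo.similarity import Ontology

        onto = Ontology.from_table(sim_inputs.ontology_edges)
        rec = similarity_profile(
            "drugA", "drugC",
            drug_targets=default_bundle.drug_targets,
            fingerprints=sim_inputs.fingerprints,
            sequences=sim_inputs.sequences,
            expression=sim_inputs.expression,
            annotations=sim_inputs.annotations,
            ontology=onto,
            atc_codes=sim_inputs.atc_codes,
            n_background=default_bundle.graph.number_of_nodes(),
        )
        for key in ("tanimoto", "sequence", "coexpression", "go", "atc",
                    "jaccard", "overlap_coefficient"):
            assert rec[key] is not None

    def test_planted_effect_direction(self, default_bundle, sim_inputs):
        """Overlapping pairs (planted s<0) score higher than separated ones."""
        onto = Ontology.from_table(sim_inputs.ontology_edges)
        truth = default_bundle.truth_pairs
        groups = {-1: [], 1: []}
        for row in truth.itertuples():
            rec = similarity_profile(
                row.drug_a, row.drug_b,
                drug_targets=default_bundle.drug_targets,
                fingerprints=sim_inputs.fingerprints,
                atc_codes=sim_inputs.atc_codes,
            )
            groups[row.expected_s_sign].append((rec["tanimoto"], rec["atc"]))
        mean_overlap = np.mean([t for t, _ in groups[-1]])
        mean_separated = np.mean([t for t, _ in groups[1]])
        assert mean_overlap > mean_separated
        assert np.mean([a for _, a in groups[-1]]) > np.mean([a for _, a in groups[1]])
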