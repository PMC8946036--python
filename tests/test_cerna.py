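import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from circlact._seq import revcomp
from circlact.cerna import (
    NetworkThresholds,
    build_network,
    cerna_score,
    filter_pairs,
    pairs_to_frame,
    predict_mres,
    predict_mres_table,
    score_pairs,
    seed_site,
    shared_mirna_pvalue,
)


def hypergeom_tail_brute(M_T, m_p, m_n, m_c):
    """Exact integer arithmetic over the tail terms."""
    denom = math.comb(M_T, m_p)
    num = sum(
        math.comb(m_n, i) * math.comb(M_T - m_n, m_p - i)
        for i in range(m_c, min(m_p, m_n) + 1)
    )
    return num / denom


MIRNAS = {
    "miR_a": "UGAGGUAGUAGGUUGUAUAGUU",  # seed GAGGUAG -> site CTACCTC
    "miR_b": "ACCCGUAGAUCCGAACUUGUGA",
}


class TestPredictMres:
    def test_site_is_reverse_complement_of_seed(self):
        assert seed_site(MIRNAS["miR_a"]) == revcomp("GAGGTAG")

    def test_no_complement_no_row(self):
        out = predict_mres("A" * 50, MIRNAS)
        assert out == {}

    def test_counts_and_positions(self):
        site = seed_site(MIRNAS["miR_a"])
        rna = "AAAA" + site + "CCCC" + site + "GGGG"
        out = predict_mres(rna, MIRNAS)
        assert out == {"miR_a": [4, 15]}

    def test_overlapping_tandem_counted_greedily(self):
        # overlapping occurrences at 0, 2, 4, 6, 8; greedy left-to-right
        # takes 0, resumes at 7, and the next occurrence starts at 8
        mirna = {"m": "ATATATATATATATATATATAT"}
        site = seed_site(mirna["m"])
        assert site == "ATATATA"
        rna = "ATATATATATATATA"
        out = predict_mres(rna, mirna)
        assert out == {"m": [0, 8]}

    def test_mirna_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError, match="seed span"):
            predict_mres("ACGT" * 10, {"tiny": "ACGU"})

    def test_planted_multiplicities_recovered_exactly(self, study):
        """Predicted site counts equal planted multiplicities for every
        (RNA, miRNA) pair, and no unplanted pair is reported."""
        seqs = dict(study.circ_seqs) | dict(study.mrna_seqs)
        truth = {
            (r.rna_id, r.mirna_id): r.count
            for r in study.truth.mres.itertuples(index=False)
        }
        predicted = {}
        for rna_id, seq in seqs.items():
            for mirna_id, pos in predict_mres(seq, study.mirnas).items():
                predicted[(rna_id, mirna_id)] = len(pos)
        assert predicted == truth


class TestCernaScore:
    def test_all_shared_is_one(self):
        assert cerna_score({"a": 2, "b": 5}, ["a", "b"]) == 1.0

    def test_none_shared_is_zero(self):
        assert cerna_score({"a": 2, "b": 5}, []) == 0.0

    def test_worked_three_mirna_example(self):
        score = cerna_score({"miR_a": 3, "miR_b": 2, "miR_c": 1}, ["miR_a", "miR_c"])
        assert score == pytest.approx(4 / 6)

    def test_no_mres_is_not_a_candidate(self):
        with pytest.raises(ValueError, match="no MREs"):
            cerna_score({}, [])


class TestSharedMirnaPvalue:
    def test_zero_overlap_is_certain(self):
        assert shared_mirna_pvalue(10, 4, 5, 0) == 1.0

    def test_worked_values(self):
        assert shared_mirna_pvalue(10, 4, 5, 4) == pytest.approx(5 / 210, rel=1e-12)
        assert shared_mirna_pvalue(20, 6, 8, 5) == pytest.approx(700 / 38760, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            shared_mirna_pvalue(10, 4, 5, 5)
        with pytest.raises(ValueError):
            shared_mirna_pvalue(10, 11, 5, 2)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.data())
    def test_matches_brute_force(self, data):
        M = data.draw(st.integers(1, 50))
        m_p = data.draw(st.integers(0, M))
        m_n = data.draw(st.integers(0, M))
        m_c = data.draw(st.integers(0, min(m_p, m_n)))
        p = shared_mirna_pvalue(M, m_p, m_n, m_c)
        assert p == pytest.approx(hypergeom_tail_brute(M, m_p, m_n, m_c), rel=1e-9)
        # third-party cross-check: survival function of the hypergeometric
        assert p == pytest.approx(
            stats.hypergeom.sf(m_c - 1, M, m_n, m_p), rel=1e-9, abs=1e-12
        )

    def test_monotone_nonincreasing_in_overlap(self):
        ps = [shared_mirna_pvalue(30, 10, 12, c) for c in range(0, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


def mre_frame(rows):
    return pd.DataFrame(
        rows, columns=["rna_id", "rna_class", "mirna_id", "site_count"]
    )


class TestNetwork:
    def test_filter_boundaries(self):
        frame = pd.DataFrame(
            {
                "circ_id": ["c1", "c2", "c3", "c4"],
                "mrna_id": ["m"] * 4,
                "M_T": [20] * 4,
                "m_p": [8] * 4,
                "m_n": [8] * 4,
                "m_c": [2, 3, 3, 4],
                "shared_mirnas": ["x,y", "x,y,z", "x,y,z", "w,x,y,z"],
                "cerna_score": [0.9, 0.5, 0.7, 0.6],
                "p_value": [0.001, 0.05, 0.051, 0.04],
            }
        )
        kept = filter_pairs(frame, NetworkThresholds())
        # m_c=2 excluded however small p; p=0.05 boundary retained;
        # p just above excluded
        assert list(kept["circ_id"]) == ["c4", "c2"]

    def test_ranking_keys(self):
        frame = pd.DataFrame(
            {
                "circ_id": ["b", "a", "c"],
                "mrna_id": ["m"] * 3,
                "M_T": [20] * 3,
                "m_p": [8] * 3,
                "m_n": [8] * 3,
                "m_c": [3, 4, 3],
                "shared_mirnas": ["x,y,z", "w,x,y,z", "x,y,z"],
                "cerna_score": [0.8, 0.8, 0.8],
                "p_value": [0.01] * 3,
            }
        )
        kept = filter_pairs(frame)
        assert list(kept["circ_id"]) == ["a", "b", "c"]  # m_c desc, then id

    def test_planted_strong_pair_ranks_first(self):
        rng = np.random.default_rng(0)
        mirnas = [f"miR_{i:02d}" for i in range(20)]
        rows = []
        # strong pair: circ_hit and mRNA_hit share 6 miRNAs, all of the
        # circle's sites belong to shared miRNAs
        for m in mirnas[:6]:
            rows.append(("circ_hit", "circRNA", m, 3))
            rows.append(("mRNA_hit", "mRNA", m, 2))
        # decoys share little
        for i in range(8):
            chosen = rng.choice(mirnas, size=4, replace=False)
            for m in chosen:
                rows.append((f"circ_decoy{i}", "circRNA", m, int(rng.integers(1, 4))))
        for i in range(8):
            chosen = rng.choice(mirnas, size=4, replace=False)
            for m in chosen:
                rows.append((f"mRNA_decoy{i}", "mRNA", m, int(rng.integers(1, 4))))
        graph, ranked = build_network(mre_frame(rows), M_T=20)
        assert ranked.iloc[0]["circ_id"] == "circ_hit"
        assert ranked.iloc[0]["mrna_id"] == "mRNA_hit"
        assert ranked.iloc[0]["cerna_score"] == 1.0

    def test_pair_invariants_hold(self):
        rows = [
            ("c1", "circRNA", "x", 2), ("c1", "circRNA", "y", 1),
            ("c1", "circRNA", "z", 1),
            ("m1", "mRNA", "x", 1), ("m1", "mRNA", "y", 2), ("m1", "mRNA", "z", 3),
        ]
        pairs = score_pairs(mre_frame(rows), M_T=10)
        (pair,) = pairs
        assert pair.m_c <= min(pair.m_p, pair.m_n) <= pair.M_T
        assert 0.0 <= pair.cerna_score <= 1.0
        assert 0.0 <= pair.p_value <= 1.0
        assert len(pair.shared_mirnas) == pair.m_c

    def test_score_ignores_mrna_side_counts(self):
        rows_small = [
            ("c1", "circRNA", "x", 2), ("c1", "circRNA", "y", 2),
            ("m1", "mRNA", "x", 1),
        ]
        rows_big = [
            ("c1", "circRNA", "x", 2), ("c1", "circRNA", "y", 2),
            ("m1", "mRNA", "x", 99),
        ]
        (p1,) = score_pairs(mre_frame(rows_small), M_T=5)
        (p2,) = score_pairs(mre_frame(rows_big), M_T=5)
        assert p1.cerna_score == p2.cerna_score == 0.5

    def test_network_has_no_orphan_nodes(self):
        rows = []
        rng = np.random.default_rng(1)
        mirnas = [f"miR_{i:02d}" for i in range(15)]
        for i in range(6):
            for m in rng.choice(mirnas, size=6, replace=False):
                rows.append((f"c{i}", "circRNA", m, int(rng.integers(1, 3))))
        for i in range(6):
            for m in rng.choice(mirnas, size=6, replace=False):
                rows.append((f"m{i}", "mRNA", m, int(rng.integers(1, 3))))
        graph, ranked = build_network(mre_frame(rows), M_T=15)
        cerna_edges = {
            (u, v) for u, v, d in graph.edges(data=True) if d["edge_type"] == "ceRNA"
        }
        table_edges = {
            tuple(sorted((r.circ_id, r.mrna_id))) for r in ranked.itertuples()
        }
        assert {tuple(sorted(e)) for e in cerna_edges} == table_edges
        assert all(graph.degree(n) > 0 for n in graph.nodes)

    def test_no_mrna_rows_warns_empty(self):
        rows = [("c1", "circRNA", "x", 2)]
        with pytest.warns(UserWarning, match="no mRNA"):
            graph, ranked = build_network(mre_frame(rows), M_T=5)
        assert len(ranked) == 0 and graph.number_of_nodes() == 0
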