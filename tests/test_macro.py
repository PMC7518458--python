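import numpy as np
import pytest

from einscale import (MacroMapping, TransitionStructure, apply_mapping,
                      effective_information, normalize,
                      read_mapping_csv, stationary_distribution,
                      walker_consistency, write_mapping_csv)
from einscale.generators import complete_uniform, permutation_network

from conftest import random_transition_structure


def ts_from_rows(rows):
    return TransitionStructure([f"n{i}" for i in range(len(rows))], rows)


class TestApplyMapping:
    def test_identity_partition_preserves_everything(self):
        ts = random_transition_structure(np.random.default_rng(0), 6)
        macro = apply_mapping(ts, MacroMapping.identity(ts.node_labels))
        assert macro.macro_ts == ts
        assert (effective_information(macro.macro_ts).ei
                == effective_information(ts).ei)

    def test_average_of_member_rows(self):
        ts = ts_from_rows([[0, 0, 1, 0],
                           [0, 0, 0, 1],
                           [1, 0, 0, 0],
                           [1, 0, 0, 0]])
        m = MacroMapping.from_groups([["n0", "n1"]],
                                     all_nodes=ts.node_labels)
        macro = apply_mapping(ts, m)
        # merged row is the mean of (0,0,1,0) and (0,0,0,1) -> (0, .5, .5)
        assert macro.macro_ts.node_labels == ("mu_0", "n2", "n3")
        assert np.allclose(macro.macro_ts.row(0), [0, 0.5, 0.5])

    def test_intra_group_mass_becomes_self_loop(self):
        ts = ts_from_rows([[0, 1, 0], [1, 0, 0], [0.5, 0.5, 0]])
        m = MacroMapping.from_groups([["n0", "n1"]],
                                     all_nodes=ts.node_labels)
        macro = apply_mapping(ts, m)
        assert np.allclose(macro.macro_ts.row(0), [1.0, 0.0])
        assert np.allclose(macro.macro_ts.row(1), [1.0, 0.0])

    def test_whole_network_group_has_zero_ei(self):
        ts = random_transition_structure(np.random.default_rng(1), 5)
        m = MacroMapping.from_groups([list(ts.node_labels)])
        macro = apply_mapping(ts, m)
        assert macro.n_macro == 1
        assert np.allclose(macro.macro_ts.row(0), [1.0])
        assert effective_information(macro.macro_ts).ei == pytest.approx(0.0)

    def test_node_count_never_increases(self):
        rng = np.random.default_rng(2)
        ts = random_transition_structure(rng, 8)
        for _ in range(10):
            k = int(rng.integers(1, 9))
            labels = list(ts.node_labels)
            rng.shuffle(labels)
            groups = np.array_split(labels, k)
            m = MacroMapping.from_groups([list(g) for g in groups])
            assert apply_mapping(ts, m).n_macro <= ts.n_nodes

    def test_uncovered_node_rejected(self):
        ts = ts_from_rows([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="cover"):
            apply_mapping(ts, MacroMapping(assignment={"n0": "g"}))

    def test_stationary_weighted_preserves_stationary_mass(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            ts = random_transition_structure(rng, 9)
            labels = list(ts.node_labels)
            groups = [labels[:3], labels[3:5]]
            m = MacroMapping.from_groups(groups, method="stationary_weighted",
                                         all_nodes=labels)
            macro = apply_mapping(ts, m)
            pi = stationary_distribution(ts)
            pi_macro = stationary_distribution(macro.macro_ts)
            # group-sum of micro stationary mass == macro stationary mass
            expected = [pi[:3].sum(), pi[3:5].sum(), *pi[5:]]
            assert np.allclose(pi_macro, expected, atol=1e-9)

    def test_zero_mass_group_falls_back_to_average(self, caplog):
        # n0 is transient: no stationary mass
        ts = ts_from_rows([[0, 1, 0], [0, 0, 1], [0, 0, 1]])
        m = MacroMapping.from_groups([["n0"], ["n1", "n2"]],
                                     method="stationary_weighted")
        import logging
        with caplog.at_level(logging.WARNING):
            macro = apply_mapping(ts, m)
        assert any("zero stationary mass" in r.message
                   for r in caplog.records)
        assert macro.n_macro == 2


class TestStationaryDistribution:
    def test_uniform_complete_graph(self):
        pi = stationary_distribution(normalize(complete_uniform(4)))
        assert np.allclose(pi, 0.25, atol=1e-9)

    def test_absorbing_fixed_point(self):
        ts = ts_from_rows([[0, 1], [0, 1]])
        assert np.allclose(stationary_distribution(ts), [0, 1], atol=1e-9)

    def test_periodic_cycle_uses_cesaro_average(self):
        # 4-cycle: the chain is periodic but pi is uniform
        ts = ts_from_rows(np.roll(np.eye(4), 1, axis=1))
        assert np.allclose(stationary_distribution(ts), 0.25, atol=1e-9)

    def test_fixed_point_equation(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ts = random_transition_structure(rng, 12)
            pi = stationary_distribution(ts)
            assert np.allclose(pi @ ts.to_dense(), pi, atol=1e-9)
            assert pi.sum() == pytest.approx(1.0)
            assert (pi >= 0).all()


class TestWalkerConsistency:
    def test_identity_partition_scores_zero(self):
        ts = random_transition_structure(np.random.default_rng(6), 6)
        macro = apply_mapping(ts, MacroMapping.identity(ts.node_labels))
        assert walker_consistency(ts, macro) == pytest.approx(0.0, abs=1e-9)

    def test_exactly_lumpable_partition_scores_zero(self):
        # two groups whose members have identical aggregated rows
        ts = ts_from_rows([[0, 0, 0.5, 0.5],
                           [0, 0, 0.3, 0.7],
                           [0.2, 0.8, 0, 0],
                           [0.6, 0.4, 0, 0]])
        m = MacroMapping.from_groups([["n0", "n1"], ["n2", "n3"]])
        macro = apply_mapping(ts, m)
        assert walker_consistency(ts, macro) == pytest.approx(0.0, abs=1e-9)

    def test_bad_grouping_scores_positive_matches_simulation(self):
        # two non-communicating halves, grouped across the cut
        ts = ts_from_rows([[0, 1, 0, 0],
                           [1, 0, 0, 0],
                           [0, 0, 0.5, 0.5],
                           [0, 0, 0.9, 0.1]])
        m = MacroMapping.from_groups([["n0", "n2"], ["n1", "n3"]])
        macro = apply_mapping(ts, m)
        score = walker_consistency(ts, macro, horizon=10)
        assert score > 0
        # oracle: simulate both chains directly
        Ind = np.zeros((4, 2))
        for i, lbl in enumerate(ts.node_labels):
            Ind[i, 0 if m.assignment[lbl] == m.assignment["n0"] else 1] = 1
        pi = stationary_distribution(ts)
        p, q = pi.copy(), Ind.T @ pi
        T, M = ts.to_dense(), macro.macro_ts.to_dense()
        total = 0.0
        for _ in range(10):
            p, q = p @ T, q @ M
            pp, qq = Ind.T @ p + 1e-12, q + 1e-12
            pp, qq = pp / pp.sum(), qq / qq.sum()
            total += float((pp * np.log2(pp / qq)).sum())
        assert score == pytest.approx(total / 10, abs=1e-12)


class TestMappingCSV:
    def test_round_trip(self, tmp_path):
        m = MacroMapping(assignment={"a": "g1", "b": "g1", "c": "c"},
                         method="average")
        p = tmp_path / "map.csv"
        write_mapping_csv(m, p)
        back = read_mapping_csv(p)
        assert back.assignment == m.assignment

    def test_header_enforced(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("micro,macro\na,g\n")
        with pytest.raises(ValueError, match="micro_node"):
            read_mapping_csv(p)
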