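import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tolerograph import (DataError, DirectionalGeneList, SamConfig, SimConfig,
                         agent_confound_check, concordance,
                         derive_final_lists, derive_unique_lists,
                         generate_dataset, paired_analysis)


def dgl(pairs):
    return DirectionalGeneList.from_pairs(pairs)


directional_lists = st.dictionaries(
    st.sampled_from([f"g{i}" for i in range(30)]),
    st.sampled_from(["up", "down"]), max_size=20)


class TestDeriveUniqueLists:
    def test_three_gene_enumeration(self):
        shared, ut, un = derive_unique_lists(
            dgl([("g1", "up"), ("g2", "up")]),
            dgl([("g1", "up"), ("g3", "down")]))
        assert shared.entries == {"g1": "up"}
        assert ut.entries == {"g2": "up"}
        assert un.entries == {"g3": "down"}

    def test_disjoint_lists_pass_through(self):
        a, b = dgl([("g1", "up")]), dgl([("g2", "down")])
        shared, ut, un = derive_unique_lists(a, b)
        assert len(shared) == 0
        assert ut.entries == a.entries and un.entries == b.entries

    def test_opposite_directions_not_shared(self):
        shared, ut, un = derive_unique_lists(
            dgl([("g1", "up")]), dgl([("g1", "down")]))
        assert len(shared) == 0
        assert "g1" in ut and "g1" in un

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(directional_lists, directional_lists, directional_lists)
    def test_filter_algebra_invariants(self, two, tvc, nvc):
        res = derive_final_lists(DirectionalGeneList(two),
                                 DirectionalGeneList(tvc),
                                 DirectionalGeneList(nvc))
        shared = res.shared.entries
        # shared is a same-direction subset of both vs-control lists
        for p, d in shared.items():
            assert tvc[p] == d and nvc[p] == d
        assert not (set(res.unique_tol.entries) & set(shared))
        assert not (set(res.unique_ntol.entries) & set(shared))
        assert res.final_tol.ids() <= res.two_group.ids()
        assert res.final_tol.ids() <= res.unique_tol.ids()
        assert res.final_ntol.ids() <= res.two_group.ids()
        assert res.final_ntol.ids() <= res.unique_ntol.ids()
        # unique lists partition the vs-control lists with shared
        assert res.unique_tol.ids() | set(shared) == set(tvc)
        assert res.unique_ntol.ids() | set(shared) == set(nvc)


class TestDeriveFinalLists:
    def test_empty_two_group(self):
        res = derive_final_lists(dgl([]), dgl([("g1", "up")]),
                                 dgl([("g2", "down")]))
        assert len(res.final_tol) == 0 and len(res.final_ntol) == 0

    def test_direct_set_arithmetic(self):
        res = derive_final_lists(
            dgl([("g1", "up"), ("g2", "up"), ("g3", "down")]),
            dgl([("g1", "up")]), dgl([("g3", "down")]))
        assert res.final_tol.entries == {"g1": "up"}
        assert res.final_ntol.entries == {"g3": "down"}

    def test_conflicting_direction_kept_and_flagged(self):
        res = derive_final_lists(dgl([("g1", "down")]),
                                 dgl([("g1", "up")]), dgl([]))
        assert res.final_tol.entries == {"g1": "up"}
        assert "g1" in res.direction_conflicts


class TestAgentConfound:
    def test_no_planted_agent_effect_gives_zero_overlap(self):
        cfg = SimConfig(n_probes=800, n_tol_up=20, n_tol_down=20, n_ntol_up=0,
                        n_ntol_down=0, n_confounded=0, effect_log2=1.2,
                        sd_range=(0.4, 0.4), agent_names=["TAC", "MMF"],
                        n_agent_linked=0, seed=31)
        x, samples, truth = generate_dataset(cfg)
        from tolerograph.sam import run_sam_groups
        pheno = run_sam_groups(x, samples, "TOL", "NONTOL",
                               SamConfig(n_perm=50, seed=31)).called
        res = agent_confound_check(x, samples, pheno,
                                   SamConfig(n_perm=50, seed=32))
        assert set(res) == {"MMF", "TAC"}
        for agent in res.values():
            assert agent["overlap"] == 0

    def test_planted_agent_probes_detected(self):
        cfg = SimConfig(n_probes=800, n_tol_up=0, n_tol_down=0, n_ntol_up=0,
                        n_ntol_down=0, n_confounded=0,
                        agent_names=["TAC"], n_agent_linked=15,
                        agent_effect_log2=2.0, sd_range=(0.3, 0.3), seed=33)
        x, samples, truth = generate_dataset(cfg)
        # a phenotype list that deliberately contains the agent probes
        pheno = DirectionalGeneList(
            {p: "up" for p in truth.agent_probes["TAC"]})
        res = agent_confound_check(x, samples, pheno,
                                   SamConfig(n_perm=50, seed=34))
        assert res["TAC"]["overlap"] >= 12   # high recovery at large effect

    def test_unbalanced_agent_skipped(self):
        cfg = SimConfig(n_probes=100, n_tol_up=0, n_tol_down=0, n_ntol_up=0,
                        n_ntol_down=0, n_confounded=0, seed=35)
        x, samples, _ = generate_dataset(cfg)
        from tolerograph.core import Sample
        # give the agent to exactly one NONTOL sample
        doctored = []
        done = False
        for s in samples:
            if s.group == "NONTOL" and not done:
                doctored.append(Sample(s.sample_id, s.group,
                                       agents=frozenset({"RARE"})))
                done = True
            else:
                doctored.append(s)
        res = agent_confound_check(x, doctored, DirectionalGeneList({}),
                                   SamConfig(n_perm=20, seed=36))
        assert res["RARE"]["skipped"]


class TestPairedAnalysis:
    @staticmethod
    @pytest.fixture(scope="class")
    def paired_data():
        cfg = SimConfig(n_probes=400, n_tol_up=15, n_tol_down=10, n_ntol_up=0,
                        n_ntol_down=0, n_confounded=0, effect_log2=1.5,
                        sd_range=(0.3, 0.3), pairing=True, seed=41)
        return generate_dataset(cfg)

    def test_recovers_planted_and_directions(self, paired_data):
        x, samples, truth = paired_data
        called = paired_analysis(x, samples)
        up = set(truth.probes_in("TOL_UP"))
        down = set(truth.probes_in("TOL_DOWN"))
        assert len(called.ids() & (up | down)) / len(up | down) >= 0.8
        for p in called.ids() & up:
            assert called.direction(p) == "up"
        for p in called.ids() & down:
            assert called.direction(p) == "down"

    def test_sign_flip_antisymmetry(self, paired_data):
        x, samples, _ = paired_data
        a = paired_analysis(x, samples)
        flipped = x.to_frame() * -1
        from tolerograph import ExpressionMatrix
        b = paired_analysis(ExpressionMatrix.from_frame(flipped), samples)
        assert a.ids() == b.ids()
        for p in a.ids():
            assert a.direction(p) != b.direction(p)

    def test_constant_positive_ratio_called_up(self):
        from tolerograph.core import Sample
        import numpy as np
        n_pairs = 15
        samples = []
        for i in range(n_pairs):
            samples.append(Sample(f"T{i}", "TOL", pair_id=f"P{i}"))
            samples.append(Sample(f"N{i}", "NONTOL", pair_id=f"P{i}"))
        ids = [s.sample_id for s in samples]
        vals = np.zeros((3, len(ids)))
        rng = np.random.default_rng(5)
        vals[1] = rng.normal(size=len(ids)) * 0.01
        for j, s in enumerate(samples):
            if s.group == "TOL":
                vals[0, j] = 8.0 + 1.0     # constant +1 log2 ratio => fold 2
            else:
                vals[0, j] = 8.0
        from tolerograph import ExpressionMatrix
        x = ExpressionMatrix(["probe_up", "probe_null", "probe_flat"], ids, vals)
        called = paired_analysis(x, samples)
        assert called.entries.get("probe_up") == "up"
        assert "probe_flat" not in called

    def test_too_few_pairs_rejected(self):
        from tolerograph.core import Sample
        samples = [Sample("T0", "TOL", pair_id="P0"),
                   Sample("N0", "NONTOL", pair_id="P0")]
        from tolerograph import ExpressionMatrix
        x = ExpressionMatrix(["g"], ["T0", "N0"], np.zeros((1, 2)))
        with pytest.raises(DataError):
            paired_analysis(x, samples)


class TestConcordance:
    def test_identity_and_disjoint(self):
        a = dgl([("g1", "up"), ("g2", "down")])
        assert concordance(a, a) == 1.0
        assert concordance(a, dgl([("g9", "up")])) == 0.0

    def test_direction_mismatch_counts_against(self):
        a = dgl([("g1", "up"), ("g2", "up"), ("g3", "down"), ("g4", "up")])
        b = dgl([("g1", "up"), ("g3", "up")])
        assert concordance(a, b) == 0.25

    def test_empty_reference_rejected(self):
        with pytest.raises(DataError):
            concordance(dgl([]), dgl([("g1", "up")]))
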