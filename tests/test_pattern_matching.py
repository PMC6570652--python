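import numpy as np
import pytest

from engramkit import pattern_matching as pm
from engramkit import synthetic_data as syn

from conftest import make_session_matrix


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _pset(vectors, session="A", group="engram"):
    return pm.PatternSet(session, group, np.atleast_2d(vectors))


class TestCosine:
    def test_identical(self):
        v = _unit([1, 2, 3])
        assert pm.cosine(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        assert pm.cosine([1, 0, 0], [0, 1, 1]) == 0.0

    def test_hand_value(self):
        v = _unit([1, 1, 0])
        w = np.array([1.0, 0.0, 0.0])
        assert pm.cosine(v, w) == pytest.approx(1 / np.sqrt(2), abs=1e-10)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pm.cosine([0, 0], [1, 0])


class TestMatchingScore:
    def test_self_match_is_one(self):
        rng = np.random.default_rng(0)
        X = _pset([_unit(rng.uniform(0, 1, 8)) for _ in range(4)])
        assert pm.matching_score(X, X).ms == 1.0

    def test_hand_evaluated_half(self):
        # X has 2 patterns; Y contains partners at cosines ~{0.9, 0.4}
        e1 = _unit([1, 0, 0, 0])
        e2 = _unit([0, 1, 0, 0])
        y1 = _unit([0.9, 0.0, np.sqrt(1 - 0.81), 0.0])  # cos with e1 = 0.9
        y2 = _unit([0.0, 0.4, 0.0, np.sqrt(1 - 0.16)])  # cos with e2 = 0.4
        X = _pset(np.vstack([e1, e2]))
        Y = _pset(np.vstack([y1, y2]), session="B")
        res = pm.matching_score(X, Y, c=0.6)
        assert res.ms == 0.5
        np.testing.assert_allclose(res.best_cosine, [0.9, 0.4], atol=1e-12)

    def test_disjoint_sets_zero(self):
        X = _pset(np.vstack([_unit([1, 1, 0, 0])]))
        Y = _pset(np.vstack([_unit([0, 0, 1, 1])]), session="B")
        assert pm.matching_score(X, Y).ms == 0.0

    def test_threshold_is_strict(self):
        X = _pset([_unit([1, 0])])
        # partner at exactly cos = c must NOT count
        c = 0.6
        Y = _pset([_unit([c, np.sqrt(1 - c * c)])], session="B")
        res = pm.matching_score(X, Y, c=c)
        assert res.best_cosine[0] == pytest.approx(c, abs=1e-12)
        assert res.ms == 0.0

    def test_monotone_nonincreasing_in_c(self):
        rng = np.random.default_rng(1)
        X = _pset([_unit(rng.uniform(0, 1, 10)) for _ in range(5)])
        Y = _pset([_unit(rng.uniform(0, 1, 10)) for _ in range(5)], session="B")
        scores = [pm.matching_score(X, Y, c=c).ms for c in np.linspace(0.05, 0.95, 10)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_empty_x_rejected(self):
        Y = _pset([_unit([1, 0])])
        with pytest.raises(ValueError, match="empty"):
            pm.matching_score(pm.PatternSet("A", "engram", np.empty((0, 2))), Y)

    def test_asymmetry(self):
        X = _pset(np.vstack([_unit([1, 0, 0]), _unit([0, 1, 0])]))
        Y = _pset([_unit([1, 0, 0])], session="B")
        assert pm.matching_score(X, Y).ms == 0.5
        assert pm.matching_score(Y, X).ms == 1.0


class TestMsProfile:
    def test_identical_sets_all_one(self):
        rng = np.random.default_rng(2)
        vecs = np.vstack([_unit(rng.uniform(0, 1, 12)) for _ in range(3)])
        sets = {
            "engram": {lab: _pset(vecs, session=lab) for lab in "ABCD"},
        }
        prof = pm.ms_profile(sets)
        assert all(v == 1.0 for v in prof["engram"].values())

    def test_missing_reference(self):
        sets = {"engram": {"B": _pset([_unit([1, 0])], session="B")}}
        with pytest.raises(ValueError, match="reference"):
            pm.ms_profile(sets)

    def test_f_dropout_lowers_f_score(self, small_experiment):
        _, sset, truth, _ = small_experiment
        eng_idx = sset.registry.indices_of("engram")
        planted = truth.session_pattern_sets("engram", eng_idx)
        sets = {
            "engram": {
                lab: _pset(planted[lab], session=lab) for lab in planted
            }
        }
        prof = pm.ms_profile(sets)
        assert prof["engram"]["F"] < prof["engram"]["E"]


class TestMsShuffleNull:
    def _sessions(self, shared=True, seed=0):
        rng = np.random.default_rng(seed)
        vx = syn.generate_planted_patterns(30, 3, 6, rng)
        vy = vx if shared else syn.generate_planted_patterns(30, 3, 6, rng)
        DX = make_session_matrix(vx, seed=10 + seed)
        DY = make_session_matrix(vy, seed=20 + seed)
        return DX, DY

    def test_shared_patterns_positive_normalized_ms(self):
        DX, DY = self._sessions(shared=True)
        res = pm.ms_shuffle_null(
            DX, DY, range(1, 6), n_shuffles=5, seed=0, restarts=10
        )
        assert res.normalized_ms > 0

    def test_determinism(self):
        DX, DY = self._sessions(shared=False, seed=1)
        a = pm.ms_shuffle_null(DX, DY, range(1, 4), n_shuffles=2, seed=3, restarts=5)
        b = pm.ms_shuffle_null(DX, DY, range(1, 4), n_shuffles=2, seed=3, restarts=5)
        assert a.ms == b.ms and a.shuffled_mean == b.shuffled_mean

    def test_invalid_shuffles(self):
        DX, DY = self._sessions(seed=2)
        with pytest.raises(ValueError):
            pm.ms_shuffle_null(DX, DY, [2], n_shuffles=0)


class TestClassifyFates:
    def _sets(self, table):
        """Build pattern sets from {label: list of basis indices} over 12 cells."""
        out = {}
        for lab, idxs in table.items():
            vecs = np.zeros((len(idxs), 12))
            for r, i in enumerate(idxs):
                vecs[r, i] = 1.0
            out[lab] = _pset(vecs, session=lab)
        return out

    def test_everywhere_pattern_is_aligned(self):
        sets = self._sets({lab: [0] for lab in "ABCDE"})
        ft = pm.classify_fates(sets)
        assert ft.categories == ["+++"]
        assert ft.aligned == [True]

    def test_a_only_pattern_is_isolated(self):
        sets = self._sets({"A": [0], "B": [1], "C": [2], "D": [3], "E": [4]})
        ft = pm.classify_fates(sets)
        assert ft.categories == ["+--"]
        assert ft.isolated == [True]

    def test_mixed_categories(self):
        # pattern 0 everywhere, 1 sleep-only, 2 retrieval-only, 3 A-only
        sets = self._sets(
            {"A": [0, 1, 2, 3], "B": [0, 1], "C": [5], "D": [6], "E": [0, 2]}
        )
        ft = pm.classify_fates(sets)
        assert ft.categories == ["+++", "++-", "+-+", "+--"]
        assert sum(ft.fractions.values()) == pytest.approx(1.0)

    def test_rem_variant_uses_session_d(self):
        sets = self._sets({"A": [0], "B": [0], "C": [1], "D": [2], "E": [0]})
        nrem = pm.classify_fates(sets, sleep_variant="NREM")
        rem = pm.classify_fates(sets, sleep_variant="REM")
        assert nrem.categories == ["+++"]
        assert rem.categories == ["+-+"]

    def test_missing_required_session(self):
        sets = self._sets({"A": [0], "E": [0]})
        with pytest.raises(ValueError, match="sleep"):
            pm.classify_fates(sets)

    def test_planted_fate_recovery(self, small_experiment):
        _, sset, truth, _ = small_experiment
        eng_idx = sset.registry.indices_of("engram")
        planted = truth.session_pattern_sets("engram", eng_idx)
        sets = {lab: _pset(v, session=lab) for lab, v in planted.items()}
        ft = pm.classify_fates(sets)
        expected = [truth.fate_category(p) for p in range(len(truth.fate_plan))]
        assert ft.categories == expected


class TestPatternNetwork:
    def test_no_edges_below_threshold(self):
        sets = {
            "A": _pset([_unit([1, 0, 0, 0])], session="A"),
            "B": _pset([_unit([0, 1, 0, 0])], session="B"),
        }
        G = pm.pattern_network(sets)
        assert G.number_of_edges() == 0
        assert G.number_of_nodes() == 2

    def test_replicated_pattern_forms_component(self):
        import networkx as nx

        v = _unit([1, 1, 0, 0])
        sets = {lab: _pset(v, session=lab) for lab in "ABCD"}
        G = pm.pattern_network(sets)
        comps = list(nx.connected_components(G))
        assert len(comps) == 1 and len(comps[0]) == 4

    def test_random_high_dim_edge_density_low(self):
        rng = np.random.default_rng(0)
        n_dim, n_pat = 200, 12
        sets = {}
        for lab in "ABCD":
            vecs = np.zeros((n_pat, n_dim))
            for r in range(n_pat):
                mem = rng.choice(n_dim, size=8, replace=False)
                vecs[r, mem] = rng.uniform(0.5, 1, 8)
                vecs[r] /= np.linalg.norm(vecs[r])
            sets[lab] = _pset(vecs, session=lab)
        G = pm.pattern_network(sets)
        possible = 6 * n_pat * n_pat  # 6 session pairs
        assert G.number_of_edges() / possible < 0.05

    def test_single_session_rejected(self):
        with pytest.raises(ValueError):
            pm.pattern_network({"A": _pset([_unit([1, 0])])})

    def test_edge_list_export(self):
        v = _unit([1, 1, 0])
        sets = {"A": _pset(v, session="A"), "B": _pset(v, session="B")}
        edges = pm.network_edge_list(pm.pattern_network(sets))
        assert edges == [
            {
                "src_session": "A",
                "src_pattern": 0,
                "dst_session": "B",
                "dst_pattern": 0,
                "cosine": pytest.approx(1.0),
            }
        ]
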