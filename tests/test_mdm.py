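"""Importance propagation: closure, chained products, aggregations, rankings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pedeval as pe
from pedeval.mdm import ClosureOptions, FactorCode, LabeledMatrix, MdmError, MdmSpec


def square(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"f{i}" for i in range(values.shape[0])]
    return LabeledMatrix(ids, list(ids), values)


def closure_by_path_enumeration(a: np.ndarray, max_len: int) -> np.ndarray:
    """Independent oracle: sum of path products over all paths of length <= L."""
    n = a.shape[0]
    total = np.zeros_like(a)
    paths = [[(i,) for i in range(n)]]
    for _ in range(max_len):
        new = []
        for p in paths[-1]:
            for nxt in range(n):
                new.append(p + (nxt,))
        paths.append(new)
        for p in new:
            w = 1.0
            for u, v in zip(p, p[1:]):
                w *= a[u, v]
            if w:
                total[p[0], p[-1]] += w
        paths[-2] = []  # free
    return total


class TestFactorCode:
    def test_stage_is_function_of_leading_letter(self):
        assert FactorCode("A-1.1").stage == "pre"
        assert FactorCode("B-2.4").stage == "during"
        assert FactorCode("C-2").stage == "post"

    def test_levels_and_parent(self):
        assert FactorCode("A-3").level == 1
        assert FactorCode("A-3").parent is None
        assert FactorCode("A-3.2").level == 2
        assert FactorCode("A-3.2").parent == "A-3"

    @pytest.mark.parametrize("bad", ["D-1", "A1", ""])
    def test_invalid_ids_rejected(self, bad):
        with pytest.raises(MdmError):
            FactorCode(bad)


class TestInfluenceClosure:
    def test_zero_matrix_has_zero_closure(self):
        m = square(np.zeros((3, 3)))
        out, settings_ = pe.influence_closure(m, max_len=5, tol=1e-9)
        assert np.all(out.values == 0)

    def test_nilpotent_chain_is_its_own_closure(self):
        m = square([[0, 0.5], [0, 0]])
        out, settings_ = pe.influence_closure(m, max_len=3, tol=1e-9)
        np.testing.assert_allclose(out.values, [[0, 0.5], [0, 0]])
        assert not settings_["truncated"]  # A^2 = 0 converges the series

    def test_cycle_matches_path_enumeration_oracle(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        out, settings_ = pe.influence_closure(square(a), max_len=10, tol=1e-12)
        expected = closure_by_path_enumeration(a, settings_["length_used"])
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        # odd-power geometric series along the cycle
        by_hand = sum(0.5 ** k for k in (1, 3, 5, 7, 9))
        assert out.values[0, 1] == pytest.approx(by_hand, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 4), st.integers(1, 4))
    def test_random_matrices_match_path_enumeration(self, seed, n, max_len):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 0.6, size=(n, n))
        np.fill_diagonal(a, 0.0)
        out, settings_ = pe.influence_closure(square(a), max_len=max_len, tol=1e-300)
        expected = closure_by_path_enumeration(a, max_len)
        np.testing.assert_allclose(out.values, expected, rtol=1e-10, atol=1e-12)

    def test_divergent_series_flags_truncation(self):
        a = np.array([[0.0, 2.0], [2.0, 0.0]])
        out, settings_ = pe.influence_closure(square(a), max_len=4, tol=1e-6)
        assert settings_["truncated"]
        assert settings_["length_used"] == 4

    def test_column_normalization_rescales_before_series(self):
        a = np.array([[0.0, 2.0], [0.0, 0.0]])
        out, _ = pe.influence_closure(square(a), max_len=3, normalize="column")
        np.testing.assert_allclose(out.values, [[0, 1.0], [0, 0]])

    def test_non_square_rejected(self):
        with pytest.raises(MdmError):
            pe.influence_closure(LabeledMatrix(["a"], ["a", "b"], [[0.0, 1.0]]))


def toy_spec(af_af, af_tf, tf_mf, mf_weights, af_ids, tf_ids, mf_ids):
    return MdmSpec(
        mf_weights=dict(zip(mf_ids, mf_weights)),
        tf_mf=LabeledMatrix(list(tf_ids), list(mf_ids), tf_mf),
        af_tf=LabeledMatrix(list(af_ids), list(tf_ids), af_tf),
        af_af=LabeledMatrix(list(af_ids), list(af_ids), af_af),
    )


class TestPropagate:
    def test_identity_chain_reproduces_outcome_weights(self):
        spec = toy_spec(
            af_af=np.zeros((2, 2)),
            af_tf=np.eye(2),
            tf_mf=np.eye(2),
            mf_weights=(0.5, 0.5),
            af_ids=["A-1.1", "A-1.2"], tf_ids=["before", "during"], mf_ids=["time", "effect"],
        )
        derived = pe.propagate(spec)
        assert derived.af_pd["A-1.1"] == pytest.approx(0.5, abs=1e-12)
        assert derived.af_pd["A-1.2"] == pytest.approx(0.5, abs=1e-12)

    def test_two_factor_hand_arithmetic(self):
        # closure = A itself (max_len=1, no normalization);
        # star = [[2],[1]]; af_mf = [[4],[2]]; af_pd = (2/3, 1/3)
        spec = toy_spec(
            af_af=[[0.0, 1.0], [0.0, 0.0]],
            af_tf=[[1.0], [1.0]],
            tf_mf=[[2.0]],
            mf_weights=(1.0,),
            af_ids=["A-1.1", "B-1.1"], tf_ids=["during"], mf_ids=["effect"],
        )
        derived = pe.propagate(spec, ClosureOptions(max_len=1, normalize="none"))
        np.testing.assert_allclose(derived.af_tf_star.values, [[2.0], [1.0]])
        np.testing.assert_allclose(derived.af_mf.values, [[4.0], [2.0]])
        assert derived.af_pd["A-1.1"] == pytest.approx(2 / 3, abs=1e-12)
        assert derived.af_pd["B-1.1"] == pytest.approx(1 / 3, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 4))
    def test_matches_nested_loop_oracle(self, seed, n):
        """propagate() equals an explicit nested-loop recomputation (dim <= 4)."""
        rng = np.random.default_rng(seed)
        af_af = rng.uniform(0, 0.5, size=(n, n))
        np.fill_diagonal(af_af, 0.0)
        af_tf = rng.uniform(0, 2, size=(n, 2))
        tf_mf = rng.uniform(0, 9, size=(2, 2))
        w = rng.uniform(0.1, 1, size=2)
        w = w / w.sum()
        ids = [f"A-1.{k+1}" for k in range(n)]
        spec = toy_spec(af_af, af_tf, tf_mf, w, ids, ["before", "during"], ["time", "effect"])
        L = 3
        derived = pe.propagate(spec, ClosureOptions(max_len=L, tol=1e-300, normalize="none"))

        def matmul(a, b):
            out = [[0.0] * len(b[0]) for _ in range(len(a))]
            for i in range(len(a)):
                for j in range(len(b[0])):
                    for k in range(len(b)):
                        out[i][j] += a[i][k] * b[k][j]
            return out

        a = af_af.tolist()
        power, closure = a, [[v for v in row] for row in a]
        for _ in range(L - 1):
            power = matmul(power, a)
            closure = [[c + p for c, p in zip(cr, pr)] for cr, pr in zip(closure, power)]
        star = [[af_tf[i][j] + sum(closure[i][k] * af_tf[k][j] for k in range(n))
                 for j in range(2)] for i in range(n)]
        af_mf = matmul(star, tf_mf.tolist())
        raw = [sum(af_mf[i][j] * w[j] for j in range(2)) for i in range(n)]
        total = sum(raw)
        for i, fid in enumerate(ids):
            assert derived.af_pd[fid] == pytest.approx(raw[i] / total, rel=1e-10)

    def test_zero_influence_leaves_af_tf_unchanged(self):
        rng = np.random.default_rng(7)
        af_tf = rng.uniform(0, 1, size=(3, 2))
        spec = toy_spec(np.zeros((3, 3)), af_tf, np.ones((2, 2)), (0.5, 0.5),
                        ["A-1.1", "B-1.1", "C-1.1"], ["before", "during"], ["time", "effect"])
        derived = pe.propagate(spec)
        np.testing.assert_array_equal(derived.af_tf_star.values, af_tf)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.05, 3.0))
    def test_raising_af_tf_entry_never_lowers_raw_weight(self, seed, bump):
        """Monotonicity: a larger stage score cannot reduce that factor's raw weight."""
        rng = np.random.default_rng(seed)
        n = 3
        af_af = rng.uniform(0, 0.4, size=(n, n))
        np.fill_diagonal(af_af, 0.0)
        af_tf = rng.uniform(0, 2, size=(n, 2))
        tf_mf = rng.uniform(0, 9, size=(2, 2))
        ids = ["A-1.1", "B-1.1", "C-1.1"]
        args = dict(tf_mf=tf_mf, mf_weights=(0.3, 0.7), af_ids=ids,
                    tf_ids=["before", "during"], mf_ids=["time", "effect"])
        base = pe.propagate(toy_spec(af_af, af_tf, **args)).af_pd_raw
        bumped_tf = af_tf.copy()
        bumped_tf[1, 0] += bump
        bumped = pe.propagate(toy_spec(af_af, bumped_tf, **args)).af_pd_raw
        assert bumped["B-1.1"] >= base["B-1.1"] - 1e-12

    def test_label_mismatch_names_offending_pair(self):
        with pytest.raises(MdmError, match="af_tf"):
            MdmSpec(
                mf_weights={"time": 1.0},
                tf_mf=LabeledMatrix(["before"], ["time"], [[1.0]]),
                af_tf=LabeledMatrix(["A-1.1"], ["during"], [[1.0]]),
                af_af=LabeledMatrix(["A-1.1"], ["A-1.1"], [[0.0]]),
            )

    def test_weight_vector_normalized(self, mdm_spec):
        derived = pe.propagate(mdm_spec)
        assert sum(derived.af_pd.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in derived.af_pd.values())


class TestSpecValidation:
    def test_bad_weight_sum_rejected(self):
        with pytest.raises(MdmError, match="sum to 1"):
            toy_spec(np.zeros((1, 1)), [[1.0]], [[1.0]], (0.9,), ["A-1.1"], ["before"], ["time"])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(MdmError, match="diagonal"):
            toy_spec([[0.5]], [[1.0]], [[1.0]], (1.0,), ["A-1.1"], ["before"], ["time"])

    def test_fixture_spec_is_valid(self, mdm_spec):
        assert len(mdm_spec.af_tf.row_ids) == 17
        assert mdm_spec.af_af.values.shape == (17, 17)
        assert np.all(np.diag(mdm_spec.af_af.values) == 0)
        assert mdm_spec.mf_weight_vector.sum() == pytest.approx(1.0, abs=1e-12)


class TestAggregations:
    def test_uniform_weights_split_by_stage_counts(self, mdm_spec):
        uniform = {f.id: 1 / 17 for f in mdm_spec.factors if f.level == 2}
        shares = pe.stage_shares(uniform, mdm_spec.factors)
        assert shares["pre"]["share"] == pytest.approx(7 / 17)
        assert shares["during"]["share"] == pytest.approx(6 / 17)
        assert shares["post"]["share"] == pytest.approx(4 / 17)
        total = sum(s["share"] for s in shares.values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_stage_means_are_share_over_count(self, global_weights, mdm_spec):
        shares = pe.stage_shares(global_weights, mdm_spec.factors)
        for rec in shares.values():
            assert rec["mean"] == pytest.approx(rec["share"] / rec["count"])

    def test_unknown_factor_rejected(self, mdm_spec):
        with pytest.raises(MdmError, match="unknown"):
            pe.stage_shares({"Z-9.9": 1.0}, mdm_spec.factors)

    def test_single_parent_toy_sums_to_one(self):
        factors = [FactorCode("A-1")] + [FactorCode(f"A-1.{k}") for k in range(1, 18)]
        weights = {f"A-1.{k}": 1 / 17 for k in range(1, 18)}
        shares = pe.level1_shares(weights, factors)
        assert list(shares) == ["A-1"]
        assert shares["A-1"]["share"] == pytest.approx(1.0)

    def test_level1_rejects_level1_weights(self, mdm_spec):
        with pytest.raises(MdmError, match="level-1"):
            pe.level1_shares({"A-1": 0.5, "B-1": 0.5}, mdm_spec.factors)


class TestGoalRanking:
    def test_single_nonzero_entry_is_reference(self):
        m = LabeledMatrix(["A-1.1", "A-1.2", "B-1.1"], ["time"], [[0.0], [2.0], [0.0]])
        r = pe.goal_ranking(m, "time")
        assert r.reference == "A-1.2"
        assert r.entries[0] == ("A-1.2", 2.0, 1.0)
        assert all(e[2] == 0.0 for e in r.entries[1:])

    def test_ties_break_lexicographically(self):
        m = LabeledMatrix(["B-1.1", "A-1.1"], ["time"], [[1.0], [1.0]])
        r = pe.goal_ranking(m, "time")
        assert [e[0] for e in r.entries] == ["A-1.1", "B-1.1"]
        assert r.reference == "A-1.1"

    def test_unknown_goal_rejected(self, af_mf_block):
        with pytest.raises(MdmError, match="unknown goal"):
            pe.goal_ranking(af_mf_block, "speed")

    def test_ratios_sorted_and_bounded(self, af_mf_block):
        for goal in af_mf_block.col_ids:
            r = pe.goal_ranking(af_mf_block, goal)
            ratios = [e[2] for e in r.entries]
            assert ratios[0] == 1.0
            assert all(0.0 <= x <= 1.0 for x in ratios)
            assert ratios == sorted(ratios, reverse=True)


class TestRankAgreement:
    def test_perfect_agreement_is_one(self, global_weights):
        assert pe.rank_agreement(global_weights, global_weights) == pytest.approx(1.0)

    def test_mismatched_keys_rejected(self, global_weights):
        with pytest.raises(MdmError):
            pe.rank_agreement(global_weights, {"A-1.1": 1.0})

    def test_propagated_vs_reported_is_positive(self, mdm_spec, global_weights):
        derived = pe.propagate(mdm_spec)
        rho = pe.rank_agreement(derived.af_pd, global_weights)
        assert -1.0 <= rho <= 1.0
        assert rho > 0.5  # strong rank agreement even though scales differ
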