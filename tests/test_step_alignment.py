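import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mechsim.fixtures import GeneratorConfig, random_entry
from mechsim.reaction_model import MechanisticStep, reverse_entry
from mechsim.step_alignment import (
    compare_pair,
    find_identical_steps,
    global_align,
    local_align,
    max_possible_mechanistic,
    mechanistic_tanimoto,
    rotations,
    step_matrix,
)

from conftest import brute_force_monotone_score, changes, make_entry


def steps(*change_tokens):
    return tuple(
        MechanisticStep(index=i, changes=changes(*toks))
        for i, toks in enumerate(change_tokens, start=1)
    )


small_matrices = arrays(
    dtype=float,
    shape=st.tuples(st.integers(1, 5), st.integers(1, 5)),
    elements=st.floats(0.0, 1.0, width=16),
)


class TestStepMatrix:
    def test_self_comparison_unit_diagonal(self):
        m = steps(("f:C-O",), ("c:O-H",), ("i:C-C",))
        mat = step_matrix(m, m)
        assert mat.shape == (3, 3)
        assert np.allclose(np.diag(mat), 1.0)

    def test_disjoint_steps_all_zero(self):
        mat = step_matrix(steps(("f:C-O",)), steps(("c:N-H",), ("i:C-C",)))
        assert np.all(mat == 0)

    def test_two_vs_one_half_similarities(self):
        mat = step_matrix(steps(("f:C-O",), ("c:O-H",)), steps(("f:C-O", "c:O-H")))
        assert mat.shape == (2, 1)
        assert np.allclose(mat, 0.5)

    def test_empty_step_scores_zero(self):
        m1 = (MechanisticStep(index=1, changes=frozenset()),)
        mat = step_matrix(m1, steps(("f:C-O",)))
        assert mat[0, 0] == 0.0

    def test_empty_mechanism_raises(self):
        with pytest.raises(ValueError):
            step_matrix((), steps(("f:C-O",)))


class TestGlobalAlign:
    def test_single_cell(self):
        aln = global_align(np.array([[1.0]]))
        assert aln.score == 1.0
        assert aln.matched == ((1, 1),)

    def test_identity_two_by_two(self):
        aln = global_align(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert aln.score == 2.0
        assert aln.matched == ((1, 1), (2, 2))

    def test_mixed_two_by_two(self):
        aln = global_align(np.array([[0.5, 0.2], [0.3, 0.9]]))
        assert aln.score == pytest.approx(1.4)
        assert aln.matched == ((1, 1), (2, 2))

    def test_anti_diagonal_picks_single_best(self):
        aln = global_align(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert aln.score == 1.0
        assert len(aln.matched) == 1

    def test_zero_matrix_empty_match(self):
        aln = global_align(np.zeros((3, 4)))
        assert aln.score == 0.0
        assert aln.matched == ()

    def test_matched_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mat = rng.random((rng.integers(1, 6), rng.integers(1, 6)))
            aln = global_align(mat)
            for (i1, j1), (i2, j2) in zip(aln.matched, aln.matched[1:]):
                assert i1 < i2 and j1 < j2
            assert aln.score == pytest.approx(
                sum(mat[i - 1, j - 1] for i, j in aln.matched)
            )

    @settings(max_examples=200, deadline=None)
    @given(small_matrices)
    def test_matches_brute_force_oracle(self, mat):
        assert global_align(mat).score == pytest.approx(brute_force_monotone_score(mat))


class TestMechanisticTanimoto:
    def test_perfect_self_alignment(self):
        assert mechanistic_tanimoto(4, 4, 4) == 1.0

    def test_zero_score(self):
        assert mechanistic_tanimoto(0, 3, 7) == 0.0

    def test_fractional_score(self):
        assert mechanistic_tanimoto(1.4, 2, 2) == pytest.approx(0.5385, abs=5e-5)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            mechanistic_tanimoto(3.5, 3, 3)

    def test_monotone_in_score(self):
        scores = [mechanistic_tanimoto(s, 4, 6) for s in (0, 1, 2, 3, 4)]
        assert scores == sorted(scores)


class TestMaxPossibleMechanistic:
    def test_three_vs_nine(self):
        assert max_possible_mechanistic(3, 9) == pytest.approx(0.3333, abs=5e-5)

    def test_equal_steps(self):
        assert max_possible_mechanistic(5, 5) == 1.0

    def test_one_vs_three(self):
        assert max_possible_mechanistic(1, 3) == pytest.approx(1 / 3)

    def test_zero_raises(self):
        with pytest.raises(ValueError):
            max_possible_mechanistic(0, 3)


class TestRotations:
    def test_single_step(self):
        m = steps(("f:C-O",))
        assert rotations(m) == [m]

    def test_three_step_enumeration(self):
        a, b, c = steps(("f:C-O",), ("c:O-H",), ("i:C-C",))
        rots = rotations((a, b, c))
        assert rots == [(a, b, c), (b, c, a), (c, a, b)]

    def test_offsets_compose_modulo_n(self):
        m = steps(("f:C-O",), ("c:O-H",), ("i:C-C",))
        rots = rotations(m)
        assert rotations(rots[1])[2] == rots[(1 + 2) % 3]


class TestFindIdenticalSteps:
    def test_self_distinct_steps_forward_diagonal(self):
        m = steps(("f:C-O",), ("c:O-H",), ("i:C-C",))
        hits = find_identical_steps(m, m)
        assert {(i, j) for i, j, d in hits if d == "forward"} == {(1, 1), (2, 2), (3, 3)}

    def test_full_reversal_antidiagonal(self):
        e = make_entry(steps=(("f:C-O",), ("c:O-H",), ("i:C-C",)))
        r = reverse_entry(e)
        hits = find_identical_steps(e.mechanism, r.mechanism)
        assert {(i, j) for i, j, d in hits if d == "reversed"} == {(1, 3), (2, 2), (3, 1)}

    def test_no_shared_content_empty(self):
        assert find_identical_steps(steps(("f:C-O",)), steps(("c:N-H",))) == set()

    def test_empty_steps_never_reported(self):
        m1 = (MechanisticStep(index=1, changes=frozenset()),)
        m2 = (MechanisticStep(index=1, changes=frozenset()),)
        assert find_identical_steps(m1, m2) == set()


class TestLocalAlign:
    def test_all_zero_empty(self):
        aln = local_align(np.zeros((3, 3)))
        assert aln.score == 0.0
        assert aln.matched == ()

    def test_single_interior_cell(self):
        mat = np.zeros((3, 3))
        mat[1, 1] = 1.0
        aln = local_align(mat, mismatch_offset=0.5)
        assert aln.score == pytest.approx(0.5)
        assert aln.matched == ((2, 2),)

    def test_identity_matrix_diagonal(self):
        n = 4
        aln = local_align(np.eye(n), mismatch_offset=0.5)
        assert aln.score == pytest.approx(n * 0.5)
        assert aln.matched == tuple((i, i) for i in range(1, n + 1))

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            local_align(np.eye(2), mismatch_offset=-1.0)


def _random_pair(rng, **cfg_kwargs):
    cfg = GeneratorConfig(n_steps=(2, 5), changes_per_step=(1, 3), **cfg_kwargs)
    e1 = random_entry(cfg, rng, "A", "1.1.1.1", {"1.10.10.10"})
    e2 = random_entry(cfg, rng, "B", "1.1.1.2", {"2.20.20.20"})
    return e1, e2


class TestComparePair:
    def test_self_comparison(self):
        e = make_entry(
            overall=("f:C-O", "c:O-H"),
            steps=(("f:C-O",), ("c:O-H",)),
        )
        r = compare_pair(e, e)
        assert r.overall_raw == 1.0
        assert r.mechanistic_raw == 1.0
        assert r.best_direction == "forward"
        assert r.overall_direction == "forward"

    def test_fully_reversed_recovered(self):
        e = make_entry(
            overall=("f:C-O", "c:O-H", "i:C-C"),
            steps=(("f:C-O",), ("c:O-H", "i:C-C")),
        )
        r = compare_pair(e, reverse_entry(e))
        assert r.overall_raw == 1.0
        assert r.mechanistic_raw == 1.0
        assert r.best_direction == "reversed"

    def test_single_shared_step_formula(self):
        e1 = make_entry(
            entry_id="A",
            overall=("f:C-O", "c:N-H", "i:C-C"),
            steps=(("f:C-O",), ("c:N-H",), ("i:C-C",)),
        )
        e2 = make_entry(
            entry_id="B",
            overall=("f:C-O", "f:O-P", "c:S-H"),
            steps=(("f:O-P",), ("f:C-O",), ("c:S-H",)),
        )
        r = compare_pair(e1, e2)
        assert r.mechanistic_raw == pytest.approx(1 / (3 + 3 - 1))

    def test_symmetry_on_random_pairs(self, rng):
        for seed in range(30):
            e1, e2 = _random_pair(np.random.default_rng(seed))
            r12 = compare_pair(e1, e2)
            r21 = compare_pair(e2, e1)
            assert r12.overall_raw == pytest.approx(r21.overall_raw)
            assert r12.mechanistic_raw == pytest.approx(r21.mechanistic_raw)
            assert r12.overall_normalized == pytest.approx(r21.overall_normalized)
            assert r12.mechanistic_normalized == pytest.approx(r21.mechanistic_normalized)

    def test_double_reversal_invariance(self, rng):
        for seed in range(30):
            e1, e2 = _random_pair(np.random.default_rng(seed + 1000))
            r = compare_pair(e1, e2)
            rr = compare_pair(reverse_entry(e1), reverse_entry(e2))
            assert r.overall_raw == pytest.approx(rr.overall_raw)
            assert r.mechanistic_raw == pytest.approx(rr.mechanistic_raw)

    def test_rotations_never_decrease(self):
        for seed in range(20):
            gen = np.random.default_rng(seed)
            e1, e2 = _random_pair(gen)
            base = compare_pair(e1, e2, rotation_policy="none").mechanistic_raw
            rotated = compare_pair(e1, e2, rotation_policy="all").mechanistic_raw
            assert rotated >= base - 1e-12

    def test_rotation_recovers_permuted_mechanism(self):
        e1 = make_entry(
            entry_id="A",
            overall=("f:C-O", "c:O-H", "i:C-C"),
            steps=(("f:C-O",), ("c:O-H",), ("i:C-C",)),
            permutation_allowed=True,
        )
        # same steps, rotated by one
        e2 = make_entry(
            entry_id="B",
            overall=("f:C-O", "c:O-H", "i:C-C"),
            steps=(("c:O-H",), ("i:C-C",), ("f:C-O",)),
            permutation_allowed=True,
        )
        none = compare_pair(e1, e2, rotation_policy="none")
        whitelisted = compare_pair(e1, e2, rotation_policy="whitelist")
        assert whitelisted.mechanistic_raw == 1.0
        assert whitelisted.mechanistic_raw > none.mechanistic_raw
        assert whitelisted.best_rotations != (0, 0)

    def test_whitelist_policy_respects_flag(self):
        e1 = make_entry(
            entry_id="A",
            overall=("f:C-O", "c:O-H"),
            steps=(("f:C-O",), ("c:O-H",)),
            permutation_allowed=False,
        )
        e2 = make_entry(
            entry_id="B",
            overall=("f:C-O", "c:O-H"),
            steps=(("c:O-H",), ("f:C-O",)),
            permutation_allowed=False,
        )
        r = compare_pair(e1, e2, rotation_policy="whitelist")
        assert r.best_rotations == (0, 0)
        assert r.mechanistic_raw < 1.0

    def test_mechanistic_bounded_by_max_possible(self):
        for seed in range(20):
            e1, e2 = _random_pair(np.random.default_rng(seed + 2000))
            r = compare_pair(e1, e2)
            bound = max_possible_mechanistic(e1.n_steps, e2.n_steps)
            assert r.mechanistic_raw <= bound + 1e-12
            assert r.mechanistic_normalized <= 1.0 + 1e-12

    def test_identical_steps_in_alignment_subset_of_all(self):
        for seed in range(20):
            e1, e2 = _random_pair(np.random.default_rng(seed + 3000))
            r = compare_pair(e1, e2)
            all_pairs = {(i, j) for i, j, _ in r.identical_steps_all}
            assert {(i, j) for i, j in r.identical_steps_in_alignment} <= all_pairs

    def test_forced_direction(self):
        e = make_entry(
            overall=("f:C-O", "c:O-H", "i:C-C"),
            steps=(("f:C-O",), ("c:O-H", "i:C-C")),
        )
        r = reverse_entry(e)
        forced_fwd = compare_pair(e, r, direction="forward")
        forced_rev = compare_pair(e, r, direction="reversed")
        auto = compare_pair(e, r)
        assert forced_rev.mechanistic_raw == 1.0
        assert forced_rev.best_direction == "reversed"
        assert forced_fwd.best_direction == "forward"
        assert forced_fwd.mechanistic_raw <= auto.mechanistic_raw == 1.0

    def test_identical_steps_in_alignment_direction_consistent(self):
        e = make_entry(
            overall=("f:C-O", "c:O-H"),
            steps=(("f:C-O",), ("c:O-H",)),
        )
        r = compare_pair(e, e)
        assert r.identical_steps_in_alignment == frozenset({(1, 1), (2, 2)})
        assert (1, 1, "forward") in r.identical_steps_all
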