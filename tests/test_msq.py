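"""SNP-MSQ solving and the 3-partition reduction machinery."""

import random

import pytest

from cleavesnp import (
    DNA,
    Alphabet,
    SpectraCollection,
    ThreePartitionInstance,
    ValidationError,
    enumerate_ball,
    enumerate_optimal,
    hamming,
    inject_snps,
    is_feasible_msq,
    normalize_3partition,
    partition_to_solution,
    perturb_spectra,
    random_sequence,
    reduce_3partition,
    solution_to_partition,
    solve_msq,
    spectra_of,
)

AT = Alphabet("AT")


class TestFeasibility:
    @pytest.mark.parametrize(
        "t,feasible,dist",
        [
            ("TTATA", True, 3),
            ("TATTA", True, 5),
            ("ATATT", True, 1),
            ("ATTAT", True, 1),
            ("TTAAT", False, None),
        ],
    )
    def test_worked_instance(self, t, feasible, dist, example4_spectra):
        assert is_feasible_msq(t, example4_spectra) == feasible
        if feasible:
            assert hamming("ATAAT", t) == dist

    def test_rejection_reason_is_missing_compomer(self, example4_spectra):
        # TTAAT lacks a single-A fragment at cut base T, so A1T0 is uncovered.
        assert (1, 0) in example4_spectra.counts("T")
        assert (1, 0) not in spectra_of("TTAAT", AT).counts("T")

    def test_sequence_covers_its_own_spectra(self):
        rng = random.Random(3)
        for _ in range(20):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 12)))
            assert is_feasible_msq(s, spectra_of(s))


class TestSolveMsq:
    def test_worked_instance_minimum_and_tiebreak(self, example4_spectra):
        sol = solve_msq("ATAAT", example4_spectra, max_radius=5)
        assert (sol.status, sol.distance, sol.reconstructed) == ("optimal", 1, "ATATT")

    def test_own_spectra_solve_at_distance_zero(self):
        s = "TACGGAT"
        sol = solve_msq(s, spectra_of(s))
        assert (sol.distance, sol.reconstructed) == (0, s)

    def test_radius_exhaustion_is_a_status(self, example4_spectra):
        sol = solve_msq("ATAAT", example4_spectra, max_radius=0)
        assert sol.status == "infeasible_within_radius"

    def test_matches_exhaustive_oracle(self):
        rng = random.Random(424242)
        for rep in range(40):
            alphabet = AT if rep % 2 == 0 else DNA
            n = rng.randint(3, 9) if alphabet is AT else rng.randint(3, 6)
            s = random_sequence(n, alphabet, rng.randrange(2**31))
            sample, _ = inject_snps(s, rng.randint(0, 2), rng.randrange(2**31), alphabet)
            C = spectra_of(sample, alphabet)
            if rep % 3 == 2:
                C = perturb_spectra(C, 0, rng.randint(0, 1), rng.randrange(2**31))
            oracle = enumerate_optimal(s, C, "msq")
            sol = solve_msq(s, C, max_radius=n)
            assert (sol.distance if sol.feasible else None) == oracle.distance
            if sol.feasible:
                assert sol.reconstructed == min(oracle.optima)

    def test_removing_compomers_never_increases_the_optimum(self):
        rng = random.Random(99)
        for _ in range(25):
            alphabet = rng.choice([AT, DNA])
            n = rng.randint(3, 7)
            s = random_sequence(n, alphabet, rng.randrange(2**31))
            sample, _ = inject_snps(s, rng.randint(0, 2), rng.randrange(2**31), alphabet)
            C = spectra_of(sample, alphabet)
            thinned = perturb_spectra(C, 0, 1, rng.randrange(2**31))
            base = solve_msq(s, C, max_radius=n)
            reduced = solve_msq(s, thinned, max_radius=n)
            assert base.feasible
            assert reduced.feasible and reduced.distance <= base.distance


def _random_yes_instance(rng, m):
    """A restricted 3-partition yes-instance built triple by triple."""
    B = rng.randint(40, 60)
    while True:
        elements = set()
        triples = []
        ok = True
        for _ in range(m):
            for _ in range(200):
                lo, hi = B // 4 + 1, (B - 1) // 2
                a = rng.randint(lo, hi)
                b = rng.randint(lo, hi)
                c = B - a - b
                triple = (a, b, c)
                if (
                    len({a, b, c}) == 3
                    and all(4 * v > B and 2 * v < B for v in triple)
                    and not elements & {a, b, c}
                ):
                    elements |= {a, b, c}
                    triples.append(triple)
                    break
            else:
                ok = False
                break
        if ok:
            P = ThreePartitionInstance.of(elements, m, B)
            return P, triples


class TestReduction:
    def test_reference_and_spectra_construction(self):
        P = ThreePartitionInstance.of([4, 5, 6], 1, 15)
        R = reduce_3partition(P)
        assert R.instance.reference == "G" * 17
        assert len(R.instance.reference) == 1 * 15 + 3 * 1 - 1
        assert R.instance.spectra.counts("G") == {(0, 0), (0, 1)}
        assert R.instance.spectra.counts("T") == {(4, 0), (5, 0), (6, 0)}

    def test_reference_length_formula_on_random_instances(self):
        rng = random.Random(1)
        for m in (1, 2):
            P, _ = _random_yes_instance(rng, m)
            R = reduce_3partition(P)
            assert len(R.instance.reference) == m * P.B + 3 * m - 1

    def test_duplicate_elements_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            ThreePartitionInstance((4, 4, 7), 1, 15)

    def test_size_window_enforced(self):
        with pytest.raises(ValidationError, match="window"):
            ThreePartitionInstance.of([2, 6, 7], 1, 15)

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            ThreePartitionInstance.of([4, 5, 7], 1, 15)

    def test_normalization_enters_the_window(self):
        P = normalize_3partition([1, 2, 3], 1, 6)
        assert P.elements == (7, 8, 9)
        assert P.B == 24

    def test_partition_encodes_an_optimal_solution(self):
        P = ThreePartitionInstance.of([4, 5, 6], 1, 15)
        R = reduce_3partition(P)
        s_prime = partition_to_solution(P, [(4, 5, 6)])
        assert s_prime == "GGGGTGGGGGTGGGGGG"
        assert is_feasible_msq(s_prime, R.instance.spectra)
        assert hamming(R.instance.reference, s_prime) == 2 * P.m

    def test_solution_length_formula(self):
        rng = random.Random(2)
        P, triples = _random_yes_instance(rng, 2)
        s_prime = partition_to_solution(P, triples)
        assert len(s_prime) == P.m * P.B + 3 * P.m - 1

    def test_invalid_partition_rejected(self):
        P = ThreePartitionInstance.of([4, 5, 6], 1, 15)
        with pytest.raises(ValidationError):
            partition_to_solution(P, [(4, 5, 7)])
        with pytest.raises(ValidationError):
            partition_to_solution(P, [(4, 5, 6), (4, 5, 6)])

    def test_no_feasible_string_below_twice_m(self):
        P = ThreePartitionInstance.of([4, 5, 6], 1, 15)
        R = reduce_3partition(P)
        result = enumerate_ball(R.instance.reference, R.instance.spectra, 2 * P.m - 1, "msq")
        assert result.distance is None

    def test_ball_search_solves_the_yes_instance_at_twice_m(self):
        P = ThreePartitionInstance.of([4, 5, 6], 1, 15)
        R = reduce_3partition(P)
        sol = solve_msq(R.instance.reference, R.instance.spectra, max_radius=2 * P.m)
        assert sol.distance == 2 * P.m
        assert solution_to_partition(sol.reconstructed, R) is not None

    def test_extraction_recovers_the_partition(self):
        P = ThreePartitionInstance.of([4, 5, 6], 1, 15)
        R = reduce_3partition(P)
        triples = solution_to_partition("GGGGTGGGGGTGGGGGG", R)
        assert triples == [(4, 5, 6)]

    def test_extraction_round_trip_on_random_yes_instances(self):
        rng = random.Random(4)
        for m in (1, 2, 2):
            P, triples = _random_yes_instance(rng, m)
            R = reduce_3partition(P)
            s_prime = partition_to_solution(P, triples)
            recovered = solution_to_partition(s_prime, R)
            assert sorted(tuple(sorted(t)) for t in recovered) == sorted(
                tuple(sorted(t)) for t in triples
            )

    def test_extraction_requires_the_optimum(self):
        P = ThreePartitionInstance.of([4, 5, 6], 1, 15)
        R = reduce_3partition(P)
        with pytest.raises(ValidationError):
            solution_to_partition(R.instance.reference, R)

    def test_no_instance_admits_nothing_within_radius_twice_m(self):
        # {12,13,14,15,16,22} with B = 46: every triple containing 22 sums to
        # at least 47 and every triple avoiding it to at most 45, so no part
        # can reach B and the 3-partition answer is no.  The reduced SNP-MSQ
        # instance must then be infeasible everywhere within radius 2m = 4;
        # the ball search verifies this exhaustively (~3.5M candidates).
        P = ThreePartitionInstance.of([12, 13, 14, 15, 16, 22], 2, 46)
        R = reduce_3partition(P)
        sol = solve_msq(R.instance.reference, R.instance.spectra, max_radius=2 * P.m)
        assert sol.status == "infeasible_within_radius"
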