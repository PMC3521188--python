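"""The exact dynamic-programming solver for minimum-substitution reconstruction
under spectra containment (SNP-MSP)."""

import random
import time

import pytest
from hypothesis import given, settings, strategies as st

from cleavesnp import (
    DNA,
    Alphabet,
    SpectraCollection,
    ValidationError,
    call_snps,
    dp_solve,
    enumerate_optimal,
    hamming,
    inject_snps,
    is_feasible_msp,
    is_feasible_msp_lemma,
    perturb_spectra,
    pivot,
    random_sequence,
    spectra_of,
)

AT = Alphabet("AT")


class TestPivot:
    def test_pivot_of_CGTT(self):
        pv = pivot("CGTT", "A")
        assert (pv.k, pv.x_prime, pv.p, pv.q) == (4, "T", "ACG", "TT")

    def test_pivot_of_TGCT(self):
        pv = pivot("TGCT", "A")
        assert (pv.x_prime, pv.p, pv.q) == ("C", "ATG", "CT")

    def test_pivot_two_letter(self):
        pv = pivot("T", "A", AT)
        assert (pv.k, pv.x_prime, pv.p, pv.q) == (2, "T", "A", "T")

    def test_pivot_prefix_holds_all_bases_but_pivot_base(self):
        rng = random.Random(11)
        for _ in range(200):
            t = "".join(rng.choice("CGT") for _ in range(rng.randint(3, 8)))
            if any(b not in t for b in "CGT"):
                continue
            pv = pivot(t, "A", DNA)
            assert pv.x_prime != "A"
            assert all(b in pv.p for b in DNA.bases if b != pv.x_prime)
            assert pv.p + pv.q == "A" + t

    def test_precondition_violations_rejected(self):
        with pytest.raises(ValidationError):
            pivot("CAT", "A")
        with pytest.raises(ValidationError):
            pivot("", "A")
        with pytest.raises(ValidationError):
            pivot("CC", "A", DNA)  # lacks G and T


class TestFeasibility:
    @pytest.mark.parametrize(
        "t,feasible,dist",
        [
            ("ATATA", True, 2),
            ("TATAT", True, 3),
            ("TTATT", True, 2),
            ("ATATT", True, 1),
            ("ATTAT", True, 1),
            ("TTAAT", False, None),
        ],
    )
    def test_worked_instance(self, t, feasible, dist, example4_spectra):
        assert is_feasible_msp(t, example4_spectra) == feasible
        if feasible:
            assert hamming("ATAAT", t) == dist

    def test_rejection_reason_is_extra_compomer(self, example4_spectra):
        # TTAAT digested at T contains an AA fragment; A2T0 is not in C_T.
        assert (2, 0) in spectra_of("TTAAT", AT).counts("T")
        assert (2, 0) not in example4_spectra.counts("T")

    def test_sequence_is_feasible_for_its_own_spectra(self):
        rng = random.Random(5)
        for _ in range(20):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 12)))
            assert is_feasible_msp(s, spectra_of(s))

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_lemma_decomposition_matches_direct_definition(self, seed):
        """Fragment-decomposition feasibility agrees with the direct test
        for sequences containing every alphabet base."""
        rng = random.Random(seed)
        alphabet = rng.choice([DNA, AT])
        n = rng.randint(len(alphabet), 8)
        base = random_sequence(n, alphabet, rng.randrange(2**31))
        sample, _ = inject_snps(base, rng.randint(0, 2), rng.randrange(2**31), alphabet)
        C = spectra_of(sample, alphabet)
        if rng.random() < 0.5:
            C = perturb_spectra(C, rng.randint(0, 2), 0, rng.randrange(2**31))
        t = random_sequence(n, alphabet, rng.randrange(2**31))
        if any(b not in t for b in alphabet.bases):
            return
        assert is_feasible_msp_lemma(t, C) == is_feasible_msp(t, C)


class TestDpSolve:
    def test_worked_instance_minimum_and_tiebreak(self, example4_spectra):
        sol = dp_solve("ATAAT", example4_spectra)
        assert sol.status == "optimal"
        assert sol.distance == 1
        # ATATT and ATTAT are both optimal; ties break lexicographically.
        assert sol.reconstructed == "ATATT"
        assert sol.snps == [(4, "A", "T")]

    def test_own_spectra_solve_at_distance_zero(self):
        s = "ACATGCTACATTA"
        sol = dp_solve(s, spectra_of(s))
        assert (sol.distance, sol.reconstructed) == (0, s)

    def test_infeasible_instance_reported_as_status(self):
        empty = SpectraCollection(AT, {})
        sol = dp_solve("ATAT", empty)
        assert sol.status == "infeasible"
        assert sol.reconstructed is None

    def test_missing_base_solutions_are_found(self):
        # The only feasible strings omit T entirely: C_T holds the whole-string
        # composition and C_A only the empty compomer.
        C = SpectraCollection.from_counts(AT, {"A": [(0, 0)], "T": [(4, 0)]})
        sol = dp_solve("ATAT", C)
        assert (sol.reconstructed, sol.distance) == ("AAAA", 2)

    def test_matches_exhaustive_oracle(self):
        rng = random.Random(20240917)
        for rep in range(60):
            alphabet = AT if rep % 2 == 0 else DNA
            n = rng.randint(3, 9) if alphabet is AT else rng.randint(3, 7)
            s = random_sequence(n, alphabet, rng.randrange(2**31))
            sample, _ = inject_snps(s, rng.randint(0, 2), rng.randrange(2**31), alphabet)
            C = spectra_of(sample, alphabet)
            if rep % 3 == 2:
                C = perturb_spectra(C, rng.randint(0, 2), rng.randint(0, 1), rng.randrange(2**31))
            oracle = enumerate_optimal(s, C, "msp")
            sol = dp_solve(s, C)
            assert (sol.distance if sol.feasible else None) == oracle.distance
            if sol.feasible:
                assert is_feasible_msp(sol.reconstructed, C)
                assert sol.reconstructed == min(oracle.optima)

    def test_superset_spectra_never_increase_the_optimum(self):
        rng = random.Random(77)
        for _ in range(25):
            alphabet = rng.choice([AT, DNA])
            n = rng.randint(3, 7)
            s = random_sequence(n, alphabet, rng.randrange(2**31))
            sample, _ = inject_snps(s, rng.randint(0, 2), rng.randrange(2**31), alphabet)
            C = spectra_of(sample, alphabet)
            enlarged = perturb_spectra(C, rng.randint(1, 3), 0, rng.randrange(2**31))
            base = dp_solve(s, C)
            grown = dp_solve(s, enlarged)
            if base.feasible:
                assert grown.feasible and grown.distance <= base.distance

    def test_two_letter_scaling_smoke(self):
        # Over a two-letter alphabet the candidate sets stay linear in |s|,
        # so a length-60 instance must solve essentially instantly.
        s = random_sequence(60, AT, 7)
        sample, _ = inject_snps(s, 2, 8, AT)
        C = spectra_of(sample, AT)
        started = time.monotonic()
        sol = dp_solve(s, C)
        assert time.monotonic() - started < 30.0
        assert sol.feasible and sol.distance <= 2
        assert is_feasible_msp(sol.reconstructed, C)


class TestCallSnps:
    def test_single_substitution(self):
        assert call_snps("ATAAT", "ATTAT") == [(3, "A", "T")]

    def test_identity(self):
        assert call_snps("ACGT", "ACGT") == []

    def test_all_mismatches_reported(self):
        calls = call_snps("ATAAT", "TATAT")
        assert [c.position for c in calls] == [1, 2, 3]
        assert all(c.ref != c.alt for c in calls)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            call_snps("AT", "ATA")
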