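"""SNP-MSQ: feasibility, exact small-scale solving, and the 3-partition reduction.

SNP-MSQ is the mirror image of SNP-MSP: the in-silico spectra of the
reconstruction must *cover* the measured spectra (``C_x <= C_x(s')`` for
every cut base ``x``), which makes the formulation robust to missing peaks
but vulnerable to spurious ones.  SNP-MSQ is NP-hard even over a two-letter
alphabet, shown by reduction from a restricted 3-partition problem, so only
exact small-scale solvers are provided: a Hamming-ball search of increasing
radius around the reference, with composition-based pruning of unreachable
radii.

The reduction machinery is implemented in full: building the SNP-MSQ
instance from a restricted 3-partition instance, converting a valid
partition into an optimal reconstruction (at distance exactly ``2m``), and
extracting a partition back out of an optimal reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

from .core import (
    Alphabet,
    Compomer,
    ProblemInstance,
    SpectraCollection,
    ValidationError,
    _split_fragments,
    hamming,
)
from .msp import SnpCall, Solution, call_snps


class _MsqChecker:
    """Precompiled containment test ``C_x <= C_x(t)`` for all cut bases.

    Spectra with many cut-base occurrences are the slow ones to digest, so
    the per-candidate check orders cut bases by occurrence count, which lets
    almost-always-failing small spectra reject candidates first.
    """

    def __init__(self, C: SpectraCollection) -> None:
        self.bases = C.alphabet.bases
        self.required = [(x, C.counts(x)) for x in self.bases if C.counts(x)]

    def __call__(self, t: str) -> bool:
        bases = self.bases
        for x, req in sorted(self.required, key=lambda pair: t.count(pair[0])):
            got = {tuple(p.count(b) for b in bases) for p in _split_fragments(t, x)}
            if not req <= got:
                return False
        return True


def is_feasible_msq(t: str, C: SpectraCollection) -> bool:
    """True iff every measured compomer occurs among *t*'s fragments."""
    return _MsqChecker(C)(t)


def count_lower_bounds(C: SpectraCollection) -> dict[str, int]:
    """Base-count lower bounds forced on any feasible sequence.

    Distinct compomers in ``C_x`` must be realised by distinct, disjoint
    fragments, so a feasible sequence carries at least the summed non-cut
    base counts of ``C_x`` and at least ``|C_x| - 1`` separating cut bases.
    """
    lb = {b: 0 for b in C.alphabet.bases}
    for x in C.alphabet.bases:
        cx = C.counts(x)
        if not cx:
            continue
        lb[x] = max(lb[x], len(cx) - 1)
        for b in C.alphabet.bases:
            if b == x:
                continue
            i = C.alphabet.index(b)
            lb[b] = max(lb[b], sum(c[i] for c in cx))
    return lb


def _radius_lower_bound(s: str, C: SpectraCollection) -> int:
    """Minimum substitutions needed just to satisfy the count lower bounds."""
    lb = count_lower_bounds(C)
    return sum(max(0, lb[b] - s.count(b)) for b in C.alphabet.bases)


def _candidates_at(s: str, r: int, alphabet: Alphabet):
    """All strings at Hamming distance exactly *r* from *s*.

    Deterministic order: substituted positions in lexicographic order, and
    replacement bases in alphabet order at each position.
    """
    n = len(s)
    if r == 0:
        yield s
        return
    alts = {b: [c for c in alphabet.bases if c != b] for b in alphabet.bases}
    ba = bytearray(s.encode("ascii"))
    orig = bytes(ba)
    pos_alts = [[c.encode("ascii")[0] for c in alts[ch]] for ch in s]
    for positions in combinations(range(n), r):
        for repl in product(*(pos_alts[p] for p in positions)):
            for p, byte in zip(positions, repl):
                ba[p] = byte
            yield ba.decode("ascii")
        for p in positions:
            ba[p] = orig[p]


def solve_msq(
    s: str,
    C: SpectraCollection,
    max_radius: int = 4,
) -> Solution:
    """Exact SNP-MSQ by Hamming-ball search of increasing radius around *s*.

    Scans radii ``r = 0, 1, ...`` (starting at the composition-forced lower
    bound) up to *max_radius*, returning the lexicographically smallest
    feasible sequence at the first feasible radius.  ``status`` is
    ``"infeasible_within_radius"`` when the ball is exhausted; larger
    sequences may still admit feasible solutions further out.
    """
    alphabet = C.alphabet
    n = len(s)
    max_radius = min(max_radius, n)
    check = _MsqChecker(C)
    start = _radius_lower_bound(s, C)
    for r in range(start, max_radius + 1):
        best: str | None = None
        for cand in _candidates_at(s, r, alphabet):
            if (best is None or cand < best) and check(cand):
                best = cand
        if best is not None:
            return Solution("optimal", best, r, call_snps(s, best))
    return Solution("infeasible_within_radius")


# ---------------------------------------------------------------------------
# The 3-partition reduction
# ---------------------------------------------------------------------------

GT = Alphabet("GT")


@dataclass(frozen=True)
class ThreePartitionInstance:
    """A restricted 3-partition instance.

    ``elements`` are ``3m`` *distinct* positive integers summing to ``m * B``
    with every element strictly between ``B/4`` and ``B/2`` -- which forces
    every part of a valid partition to have exactly three members.  This
    restricted variation remains strongly NP-complete.
    """

    elements: tuple[int, ...]
    m: int
    B: int

    def __post_init__(self) -> None:
        a = self.elements
        if len(set(a)) != len(a):
            raise ValidationError("3-partition elements must be distinct (the restricted form takes a set)")
        if any(not isinstance(v, int) or v <= 0 for v in a):
            raise ValidationError("3-partition elements must be positive integers")
        if len(a) != 3 * self.m:
            raise ValidationError(f"expected 3m = {3 * self.m} elements, got {len(a)}")
        if sum(a) != self.m * self.B:
            raise ValidationError(f"elements sum to {sum(a)}, expected m*B = {self.m * self.B}")
        for v in a:
            if not (4 * v > self.B and 2 * v < self.B):
                raise ValidationError(
                    f"element {v} violates the size window B/4 < a_i < B/2 (B = {self.B})"
                )

    @classmethod
    def of(cls, elements: Iterable[int], m: int, B: int) -> "ThreePartitionInstance":
        return cls(tuple(sorted(elements)), m, B)


def normalize_3partition(elements: Iterable[int], m: int, B: int) -> ThreePartitionInstance:
    """Rescale a 3-partition instance into the restricted size window.

    Adds ``B`` to every element and multiplies ``B`` by 4, after which the
    elements sit strictly between the new ``B/4`` and ``B/2`` (provided every
    original element was below ``B``).  Partition structure is preserved.
    Elements must already be distinct.
    """
    shifted = tuple(sorted(v + B for v in elements))
    return ThreePartitionInstance(shifted, m, 4 * B)


@dataclass(frozen=True, eq=False)
class ReducedInstance:
    """The SNP-MSQ instance encoding a restricted 3-partition instance.

    Over the alphabet ``{G, T}``: the reference ``s`` satisfies
    ``s . T = (G^(B+2) T)^m`` (so ``|s| = mB + 3m - 1``), the G spectrum is
    ``{G0T0, G0T1}`` and the T spectrum is ``{G^(a_i) T0}`` over the
    elements.  The source instance has a valid partition iff the optimum
    here is exactly ``2m`` substitutions.
    """

    instance: ProblemInstance
    source: ThreePartitionInstance

    @property
    def m(self) -> int:
        return self.source.m

    @property
    def B(self) -> int:
        return self.source.B


def reduce_3partition(P: ThreePartitionInstance) -> ReducedInstance:
    """Build the SNP-MSQ instance for a restricted 3-partition instance.

    Construction is linear in ``m * B`` (the unary instance size).
    """
    m, B = P.m, P.B
    s = ("G" * (B + 2) + "T") * m
    s = s[:-1]
    assert len(s) == m * B + 3 * m - 1
    spectra = SpectraCollection(
        GT,
        {
            "G": [Compomer(GT, (0, 0)), Compomer(GT, (0, 1))],
            "T": [Compomer(GT, (a, 0)) for a in P.elements],
        },
    )
    return ReducedInstance(ProblemInstance(GT, s, spectra), P)


def partition_to_solution(
    P: ThreePartitionInstance, partition: Sequence[Iterable[int]]
) -> str:
    """Optimal reconstruction encoded by a valid partition.

    Concatenates ``G^(a) T`` over the triples in order and drops the final
    ``T``.  The result is feasible for the reduced instance and sits at
    Hamming distance exactly ``2m`` from its reference.
    """
    triples = [tuple(t) for t in partition]
    if len(triples) != P.m:
        raise ValidationError(f"expected {P.m} triples, got {len(triples)}")
    flat = [v for t in triples for v in t]
    if sorted(flat) != sorted(P.elements):
        raise ValidationError("triples do not partition the element set")
    for t in triples:
        if len(t) != 3:
            raise ValidationError(f"part {t!r} does not have exactly three members")
        if sum(t) != P.B:
            raise ValidationError(f"triple {t!r} sums to {sum(t)}, expected B = {P.B}")
    out = []
    for triple in triples:
        for a in triple:
            out.append("G" * a + "T")
    s_prime = "".join(out)[:-1]
    assert len(s_prime) == P.m * P.B + 3 * P.m - 1
    return s_prime


def solution_to_partition(
    s_prime: str, R: ReducedInstance
) -> list[tuple[int, int, int]]:
    """Extract a valid partition from an optimal reconstruction.

    Only defined at the optimum: *s_prime* must be feasible for the reduced
    instance at Hamming distance exactly ``2m`` (any feasible sequence has
    distance at least ``2m``, and optima at ``2m`` exist exactly for
    yes-instances).  Follows the linear scan over ``s . T`` / ``s' . T``
    accumulating run lengths, then validates the parts against the source
    instance.
    """
    P = R.source
    m, B = P.m, P.B
    s = R.instance.reference
    if len(s_prime) != len(s):
        raise ValidationError(f"length mismatch: {len(s_prime)} vs {len(s)}")
    if not is_feasible_msq(s_prime, R.instance.spectra):
        raise ValidationError("sequence is not feasible for the reduced instance")
    d = hamming(s, s_prime)
    if d != 2 * m:
        raise ValidationError(f"extraction requires distance exactly 2m = {2 * m}, got {d}")
    # Counting argument: any feasible sequence here has exactly 3m - 1 Ts.
    assert s_prime.count("T") == 3 * m - 1

    s_ext = s + "T"
    sp_ext = s_prime + "T"
    parts: dict[int, list[int]] = {1: []}
    i, j = 1, 1
    a = 0
    for k in range(m * B + 3 * m):
        if sp_ext[k] == "T":
            parts[i].append(a)
            j += 1
            if s_ext[k] == "T":
                i += 1
                j = 1
                parts[i] = []
            a = 0
        else:
            a += 1
    triples = [tuple(parts[i]) for i in range(1, m + 1)]
    flat = [v for t in triples for v in t]
    if sorted(flat) != sorted(P.elements):
        raise ValidationError("extracted parts do not partition the element set")
    for t in triples:
        if len(t) != 3 or sum(t) != B:
            raise ValidationError(f"extracted part {t!r} is not a triple summing to B = {B}")
    return triples  # type: ignore[return-value]
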