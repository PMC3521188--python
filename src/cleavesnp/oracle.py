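"""Brute-force reference solvers for small instances.

These are ground-truth implementations against which the dynamic program
and the ball search are validated.  They deliberately share no code with
the solvers or with :mod:`cleavesnp.core`'s fragment machinery: fragments
are recomputed here by a character scan and feasibility is evaluated
straight from the problem definitions, so that a bug in the main code path
cannot silently agree with its own oracle.

Clarity over speed throughout; the exhaustive enumeration is capped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations, product

from .core import Alphabet, CleavesnpError, SpectraCollection


class OracleCapExceeded(CleavesnpError):
    """The exhaustive search space exceeds the configured cap.

    Use :func:`enumerate_ball` to restrict the search to a Hamming ball.
    """


def _fragments(s: str, x: str) -> list[str]:
    """Maximal x-free substrings, by character scan (independent of core)."""
    frags: list[str] = []
    buf: list[str] = []
    seen_cut = False
    for ch in s:
        if ch == x:
            if seen_cut or buf:
                frags.append("".join(buf))
            buf.clear()
            seen_cut = True
        else:
            buf.append(ch)
    if buf:
        frags.append("".join(buf))
    return frags


def _spectrum(s: str, x: str, bases: tuple[str, ...]) -> set[tuple[int, ...]]:
    out = set()
    for frag in _fragments(s, x):
        c = Counter(frag)
        out.add(tuple(c[b] for b in bases))
    return out


def feasible(problem: str, t: str, C: SpectraCollection) -> bool:
    """Direct-definition feasibility for ``"msp"`` or ``"msq"``."""
    bases = C.alphabet.bases
    if problem == "msp":
        return all(_spectrum(t, x, bases) <= set(C.counts(x)) for x in bases)
    if problem == "msq":
        return all(set(C.counts(x)) <= _spectrum(t, x, bases) for x in bases)
    raise ValueError(f"unknown problem tag {problem!r}")


@dataclass(frozen=True)
class OracleResult:
    """Exact minimum and the complete set of optimal strings (or infeasible)."""

    problem: str
    distance: int | None
    optima: frozenset[str]

    @property
    def feasible(self) -> bool:
        return self.distance is not None


def enumerate_optimal(
    s: str, C: SpectraCollection, problem: str, cap: int = 4**9
) -> OracleResult:
    """Exhaustive minimum over *all* strings of length ``|s|``."""
    alphabet = C.alphabet
    n = len(s)
    if len(alphabet) ** n > cap:
        raise OracleCapExceeded(
            f"{len(alphabet)}^{n} candidates exceed the cap of {cap}; "
            "use enumerate_ball for a radius-restricted search"
        )
    best: int | None = None
    optima: list[str] = []
    for tup in product(alphabet.bases, repeat=n):
        t = "".join(tup)
        d = sum(a != b for a, b in zip(s, t))
        if best is not None and d > best:
            continue
        if not feasible(problem, t, C):
            continue
        if best is None or d < best:
            best = d
            optima = [t]
        elif d == best:
            optima.append(t)
    return OracleResult(problem, best, frozenset(optima))


def enumerate_ball(
    s: str, C: SpectraCollection, radius: int, problem: str
) -> OracleResult:
    """Exhaustive minimum restricted to Hamming distance at most *radius*."""
    alphabet = C.alphabet
    n = len(s)
    radius = min(radius, n)
    for r in range(radius + 1):
        optima = []
        for positions in combinations(range(n), r):
            others = [[b for b in alphabet.bases if b != s[p]] for p in positions]
            for repl in product(*others):
                chars = list(s)
                for p, b in zip(positions, repl):
                    chars[p] = b
                t = "".join(chars)
                if feasible(problem, t, C):
                    optima.append(t)
        if optima:
            return OracleResult(problem, r, frozenset(optima))
    return OracleResult(problem, None, frozenset())
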