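"""Exact solver for the SNP-MSP reconstruction problem.

Given a reference sequence ``s`` and a collection of measured compomer
spectra ``C``, SNP-MSP asks for a sequence ``s'`` of the same length whose
in-silico spectra are *contained* in the measured ones (``C_x(s') <= C_x``
for every cut base ``x``) at minimum Hamming distance from ``s``.  Because
only containment is required, spurious peaks in ``C`` are harmless; missing
peaks may exclude the true sample sequence.

The solver is an exact dynamic program over cleavage fragments.  A feasible
sequence that contains every alphabet base decomposes into overlapping
candidate fragments: it must begin with an L-compatible fragment, end with
an R-compatible fragment, and every internal fragment must be I-compatible
(see :mod:`cleavesnp.compat`).  The DP value ``H(i, t)`` is the minimum
Hamming distance between the length-``i`` prefix of ``s`` and a string that
is I-compatible throughout, begins with a fragment in some ``L_y``, and ends
with the fragment ``t``.  Transitions follow the pivot decomposition of
``x . t`` (the rightmost position ``k`` holding a first occurrence): writing
``x . t = p . q`` with ``|p| = k - 1``, the predecessor fragment belongs to
``I_x'`` for ``x' = (x . t)[k]`` and must carry ``p`` as a suffix, and the
transition pays the Hamming cost of ``q`` against the matching slice of
``s``.  The optimum is the best ``H(|s|, t)`` over right-end-compatible
``t``.

Sequences that omit one or more alphabet bases are not reachable by that
recurrence.  They are covered by re-running the same DP over every proper
sub-alphabet, with two adjustments: compatibility is only meaningful for
active cut bases (an absent base induces no internal fragments), and for
each excluded base ``x`` the *whole* candidate is the unique fragment with
respect to ``x``, so its full composition must appear in ``C_x``.  The
sub-alphabet runs therefore track the running composition of the prefix and
accept only compositions found in every excluded base's spectrum.  The
global optimum is the best result across all runs; ties break to the
lexicographically smallest reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, NamedTuple

from .compat import CompatibilityIndex
from .core import (
    Alphabet,
    SpectraCollection,
    ValidationError,
    hamming,
    spectrum_counts,
)


class SnpCall(NamedTuple):
    """A single substitution call, 1-based."""

    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class PivotDecomposition:
    """The split ``x . t = p . q`` at the rightmost first-occurrence position.

    ``k`` is 1-based in ``x . t``; ``x_prime`` is the base at that position
    (necessarily distinct from ``x``), ``p`` the part before it and ``q`` the
    part from it onwards.  ``p`` contains every base of the (active) alphabet
    except ``x_prime``.
    """

    k: int
    x_prime: str
    p: str
    q: str


def pivot(t: str, x: str, alphabet: Alphabet | None = None) -> PivotDecomposition:
    """Pivot decomposition of the fragment *t* with respect to cut base *x*.

    Precondition: *t* is a candidate fragment for *x* -- it contains no *x*
    and, when *alphabet* is given, every other alphabet base.
    """
    if not t:
        raise ValidationError("cannot pivot an empty fragment")
    if x in t:
        raise ValidationError(f"fragment {t!r} contains its own cut base {x!r}")
    if alphabet is not None:
        missing = [b for b in alphabet.bases if b != x and b not in t]
        if missing:
            raise ValidationError(
                f"fragment {t!r} lacks non-cut base(s) {missing!r} of alphabet "
                f"{''.join(alphabet.bases)!r}"
            )
    xt = x + t
    seen: set[str] = set()
    k = 0
    for j, ch in enumerate(xt, start=1):
        if ch not in seen:
            seen.add(ch)
            k = j
    return PivotDecomposition(k=k, x_prime=xt[k - 1], p=xt[: k - 1], q=xt[k - 1 :])


@dataclass
class Solution:
    """Result of a reconstruction: status, sequence, distance and SNP calls."""

    status: str  # "optimal" | "infeasible" | "infeasible_within_radius"
    reconstructed: str | None = None
    distance: int | None = None
    snps: list[SnpCall] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


def call_snps(s: str, s_prime: str) -> list[SnpCall]:
    """One call per mismatch: 1-based position, reference base, sample base."""
    if len(s) != len(s_prime):
        raise ValidationError(f"length mismatch: {len(s)} vs {len(s_prime)}")
    return [
        SnpCall(i + 1, a, b) for i, (a, b) in enumerate(zip(s, s_prime)) if a != b
    ]


def is_feasible_msp(t: str, C: SpectraCollection) -> bool:
    """Direct feasibility test: ``C_x(t)`` contained in ``C_x`` for every base."""
    bases = C.alphabet.bases
    for x in bases:
        if not spectrum_counts(t, x, bases) <= C.counts(x):
            return False
    return True


def is_feasible_msp_lemma(t: str, C: SpectraCollection) -> bool:
    """Fragment-decomposition form of the feasibility test.

    Equivalent to :func:`is_feasible_msp` for sequences containing every
    alphabet base: all substrings are I-compatible, the first fragment with
    respect to some base is in ``L_x``, and the last fragment with respect to
    some base is in ``R_x``.  Used as a cross-check of the DP's structural
    assumptions, not by the solver itself.
    """
    from .compat import is_I_compatible, is_L_compatible, is_R_compatible

    alphabet = C.alphabet
    n = len(t)
    if n == 0:
        return True
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not is_I_compatible(t[i:j], C):
                return False

    def in_set(frag: str, x: str, side: str) -> bool:
        if x in frag:
            return False
        if any(b != x and b not in frag for b in alphabet.bases):
            return False
        if tuple(frag.count(b) for b in alphabet.bases) not in C.counts(x):
            return False
        check = is_L_compatible if side == "left" else is_R_compatible
        return check(frag, C)

    begins = False
    for x in alphabet.bases:
        first = t.split(x, 1)[0] if x in t else t
        if in_set(first, x, "left"):
            begins = True
            break
    if not begins:
        return False
    for x in alphabet.bases:
        last = t.rsplit(x, 1)[-1] if x in t else t
        if in_set(last, x, "right"):
            return True
    return False


def _admissible_compositions(
    s: str, C: SpectraCollection, active: tuple[str, ...]
) -> frozenset[tuple[int, ...]] | None:
    """Whole-sequence compositions allowed for a sub-alphabet run.

    For every excluded base the whole candidate is its single cleavage
    fragment, so the candidate's composition must occur in that base's
    spectrum; excluded bases must not occur at all.  Returns ``None`` for the
    full alphabet (no constraint).
    """
    alphabet = C.alphabet
    excluded = [b for b in alphabet.bases if b not in active]
    if not excluded:
        return None
    n = len(s)
    idx = {b: alphabet.index(b) for b in excluded}
    allowed: frozenset[tuple[int, ...]] | None = None
    for b in excluded:
        ok = frozenset(
            c for c in C.counts(b) if sum(c) == n and all(c[i] == 0 for i in idx.values())
        )
        allowed = ok if allowed is None else (allowed & ok)
        if not allowed:
            return frozenset()
    return allowed


def _dp_run(
    s: str,
    C: SpectraCollection,
    active: tuple[str, ...],
    targets: frozenset[tuple[int, ...]] | None,
    max_index_size: int,
) -> tuple[int, str] | None:
    """One DP pass over the given active alphabet.

    Returns ``(distance, reconstruction)`` for the best candidate whose base
    set is contained in ``active`` and reachable by the fragment recurrence,
    or ``None``.  When ``targets`` is given (sub-alphabet run), the prefix
    composition is carried through the DP and the final composition must be
    one of the targets.
    """
    alphabet = C.alphabet
    n = len(s)
    idx = CompatibilityIndex(C, active=active, max_size=max_index_size)

    track = targets is not None

    def comp_of(text: str) -> tuple[int, ...] | None:
        if not track:
            return None
        return tuple(text.count(b) for b in alphabet.bases)

    def comp_ok(comp: tuple[int, ...] | None) -> bool:
        if not track:
            return True
        return any(all(a <= b for a, b in zip(comp, t)) for t in targets)

    def comp_add(comp, extra):
        if not track:
            return None
        return tuple(a + b for a, b in zip(comp, extra))

    # Per-fragment pivot data, precomputed once.
    frags: list[tuple[str, str]] = [
        (t, x) for x in active for t in idx.I[x] if 0 < len(t) <= n
    ]
    info = {}
    for t, x in frags:
        pv = pivot(t, x)
        info[t] = (x, pv.x_prime, pv.p, pv.q, comp_of(pv.q))

    # H[(i, t)] maps prefix composition (or None) -> (cost, prefix string);
    # absent entries are infinite.  Prefix strings double as backtracking
    # state and give deterministic lexicographic tie-breaking.
    H: dict[tuple[int, str], dict[tuple[int, ...] | None, tuple[int, str]]] = {}

    for i in range(1, n + 1):
        for t, x in frags:
            if len(t) > i:
                continue
            cell: dict[tuple[int, ...] | None, tuple[int, str]] = {}
            if len(t) == i:
                if t in idx.L[x]:
                    comp = comp_of(t)
                    if comp_ok(comp):
                        cell[comp] = (hamming(s[:i], t), t)
            else:
                _, xp, p, q, qcomp = info[t]
                lq = len(q)
                j = i - lq
                if j >= 1:
                    cost_q = hamming(s[j:i], q)
                    for tp in idx.suffix_matches(xp, p):
                        prev = H.get((j, tp))
                        if not prev:
                            continue
                        for pcomp, (pcost, ptext) in prev.items():
                            comp = comp_add(pcomp, qcomp)
                            if not comp_ok(comp):
                                continue
                            cand = (pcost + cost_q, ptext + q)
                            old = cell.get(comp)
                            if old is None or cand < old:
                                cell[comp] = cand
            if cell:
                H[(i, t)] = cell

    best: tuple[int, str] | None = None
    for x in active:
        for t in idx.R[x]:
            cell = H.get((n, t))
            if not cell:
                continue
            for comp, entry in cell.items():
                if track and comp not in targets:
                    continue
                if best is None or entry < best:
                    best = entry
    return best


def dp_solve(
    s: str,
    C: SpectraCollection,
    max_index_size: int = 1_000_000,
) -> Solution:
    """Solve SNP-MSP exactly: minimum-substitution feasible reconstruction.

    Runs the fragment DP over the full alphabet and over every proper
    sub-alphabet (for candidates omitting some base), returning the best
    feasible sequence of length ``|s|``; ties break to the lexicographically
    smallest sequence.  ``status`` is ``"infeasible"`` when no sequence of
    that length satisfies the spectra containment.

    Raises :class:`cleavesnp.compat.IndexSizeExceeded` if the candidate
    fragment index outgrows *max_index_size*.
    """
    alphabet = C.alphabet
    n = len(s)
    if n == 0:
        return Solution("optimal", "", 0, [])

    best: tuple[int, str] | None = None

    def consider(entry: tuple[int, str] | None) -> None:
        nonlocal best
        if entry is not None and (best is None or entry < best):
            best = entry

    # Single-base candidates are a direct check: b^n.
    for b in alphabet.bases:
        cand = b * n
        if is_feasible_msp(cand, C):
            consider((hamming(s, cand), cand))

    bases = alphabet.bases
    for size in range(len(bases), 1, -1):
        for active in combinations(bases, size):
            targets = _admissible_compositions(s, C, active)
            if targets is not None and not targets:
                continue
            consider(_dp_run(s, C, active, targets, max_index_size))

    if best is None:
        return Solution("infeasible")
    dist, text = best
    return Solution("optimal", text, dist, call_snps(s, text))
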