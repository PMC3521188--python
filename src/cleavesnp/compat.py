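"""Compatibility predicates and candidate-fragment enumeration.

A candidate sample sequence can be assembled fragment by fragment.  Whether
a fragment can occur anywhere inside / at the start / at the end of a
feasible sequence is captured by three predicates against the measured
spectra collection ``C``:

* *I-compatible*: every internal cleavage fragment (for every cut base) has
  its compomer in ``C``.
* *L-compatible*: I-compatible, and every left-ended fragment's compomer is
  in ``C`` as well.
* *R-compatible*: I-compatible, and every right-ended fragment's compomer is
  in ``C``.

For each cut base ``x`` and compomer ``c`` in ``C_x``, ``I_x(c)`` is the set
of arrangements of ``c`` that exclude ``x``, contain every other (active)
base, and are I-compatible.  ``I_x`` is the union over the compomers of
``C_x``; ``L_x`` and ``R_x`` are the analogous L-/R-compatible subsets.
These sets drive the dynamic program for the minimum-substitution
reconstruction: its states are (prefix length, fragment in some ``I_x``).

``|I_x(c)|`` is bounded by the multinomial coefficient of ``c`` and in the
worst case the whole index is factorial in the fragment size, so
construction is guarded by a configurable cap.
"""

from __future__ import annotations

import logging
from math import factorial
from typing import Iterable, Sequence

from .core import (
    Alphabet,
    CleavesnpError,
    Compomer,
    SpectraCollection,
    ValidationError,
    cleave,
)

logger = logging.getLogger(__name__)


class IndexSizeExceeded(CleavesnpError):
    """The candidate-fragment index outgrew the configured cap.

    The index is factorial in fragment size in the worst case; the cap turns
    a memory blow-up into a diagnostic.
    """


def _active_bases(C: SpectraCollection, active: Iterable[str] | None) -> tuple[str, ...]:
    if active is None:
        return C.alphabet.bases
    bases = tuple(b for b in C.alphabet.bases if b in set(active))
    if not bases:
        raise ValidationError("active alphabet is empty")
    return bases


def is_I_compatible(t: str, C: SpectraCollection, active: Iterable[str] | None = None) -> bool:
    """True iff every internal fragment of *t* (all active cut bases) is in *C*."""
    alphabet = C.alphabet
    for x in _active_bases(C, active):
        cx = C.counts(x)
        for f in cleave(t, x, alphabet):
            if f.is_internal and f.compomer.counts not in cx:
                return False
    return True


def _ends_compatible(t: str, C: SpectraCollection, active: Iterable[str] | None, side: str) -> bool:
    alphabet = C.alphabet
    attr = "is_left_ended" if side == "left" else "is_right_ended"
    for x in _active_bases(C, active):
        cx = C.counts(x)
        for f in cleave(t, x, alphabet):
            if getattr(f, attr) and f.compomer.counts not in cx:
                return False
    return True


def is_L_compatible(t: str, C: SpectraCollection, active: Iterable[str] | None = None) -> bool:
    """I-compatible and every left-ended fragment's compomer is in *C*.

    A fragment spanning the whole of *t* (cut base absent from *t*) counts
    as left-ended here: it starts at position 1.
    """
    return is_I_compatible(t, C, active) and _ends_compatible(t, C, active, "left")


def is_R_compatible(t: str, C: SpectraCollection, active: Iterable[str] | None = None) -> bool:
    """I-compatible and every right-ended fragment's compomer is in *C*."""
    return is_I_compatible(t, C, active) and _ends_compatible(t, C, active, "right")


def multinomial(counts: Sequence[int]) -> int:
    total = sum(counts)
    out = factorial(total)
    for c in counts:
        out //= factorial(c)
    return out


def enumerate_I(
    x: str,
    compomer: Compomer,
    C: SpectraCollection,
    active: Iterable[str] | None = None,
) -> frozenset[str]:
    """All arrangements of *compomer* admissible as a fragment of cut base *x*.

    A string qualifies when it (i) realises the composition, (ii) contains no
    *x* but every other active base, and (iii) is I-compatible with *C*.  The
    search builds multiset permutations character by character and prunes a
    prefix as soon as a completed internal fragment falls outside *C*, which
    keeps the factorial worst case manageable for realistic fragment sizes.

    Returns the empty set when the composition itself disqualifies: positive
    cut-base count (a fragment cannot contain its own cut base), a zero count
    for a non-cut active base, or a positive count for an inactive base.
    """
    alphabet = C.alphabet
    bases = _active_bases(C, active)
    if x not in bases:
        raise ValidationError(f"cut base {x!r} is not in the active alphabet {bases!r}")
    if compomer[x] > 0:
        return frozenset()
    non_cut = tuple(b for b in bases if b != x)
    if any(compomer[b] == 0 for b in non_cut):
        return frozenset()
    if any(compomer[b] > 0 for b in alphabet.bases if b not in bases):
        return frozenset()

    total = compomer.weight
    nb = len(alphabet)
    zeros = (0,) * nb
    remaining = {b: compomer[b] for b in non_cut}
    spectra = {b: C.counts(b) for b in non_cut}
    base_index = {b: alphabet.index(b) for b in non_cut}

    out: list[str] = []
    prefix: list[str] = []
    cum: list[tuple[int, ...]] = [zeros]  # cum[i] = counts of prefix[:i]
    last: dict[str, int | None] = {b: None for b in non_cut}

    def dfs() -> None:
        j = len(prefix)
        if j == total:
            out.append("".join(prefix))
            return
        here = cum[j]
        for b in non_cut:
            if remaining[b] == 0:
                continue
            lb = last[b]
            if lb is not None:
                inner = cum[lb + 1]
                frag = tuple(h - i for h, i in zip(here, inner))
                if frag not in spectra[b]:
                    continue
            remaining[b] -= 1
            last[b] = j
            nxt = list(here)
            nxt[base_index[b]] += 1
            cum.append(tuple(nxt))
            prefix.append(b)
            dfs()
            prefix.pop()
            cum.pop()
            last[b] = lb
            remaining[b] += 1

    dfs()
    result = frozenset(out)
    # Sanity bound stated for the candidate sets: never more arrangements
    # than the multinomial coefficient of the composition.
    assert len(result) <= multinomial(compomer.counts)
    return result


class CompatibilityIndex:
    """The ``I_x`` / ``L_x`` / ``R_x`` candidate-fragment sets plus suffix lookup.

    ``active`` restricts the construction to a sub-alphabet: candidate
    fragments are drawn from the spectra of active bases only and must
    contain every active non-cut base (used when searching for solutions
    that omit some alphabet base entirely).

    ``suffix_matches(x, p)`` answers the query needed by the reconstruction
    recurrence: all fragments in ``I_x`` having *p* as a suffix.  Results are
    cached per query.
    """

    def __init__(
        self,
        C: SpectraCollection,
        active: Iterable[str] | None = None,
        max_size: int = 1_000_000,
    ) -> None:
        self.C = C
        self.active = _active_bases(C, active)
        self.max_size = max_size
        self.I: dict[str, tuple[str, ...]] = {}
        self.L: dict[str, frozenset[str]] = {}
        self.R: dict[str, frozenset[str]] = {}
        self._suffix_cache: dict[tuple[str, str], tuple[str, ...]] = {}

        total = 0
        for x in self.active:
            ix: set[str] = set()
            for c in sorted(C[x], key=lambda c: c.counts):
                ix |= enumerate_I(x, c, C, self.active)
                total += len(ix)
                if total > max_size:
                    raise IndexSizeExceeded(
                        f"candidate-fragment index exceeded {max_size} strings while "
                        f"expanding cut base {x!r}; the fragment sets are factorial in "
                        f"fragment size -- raise max_size only if memory allows"
                    )
            self.I[x] = tuple(sorted(ix))
            self.L[x] = frozenset(t for t in ix if _ends_compatible(t, C, self.active, "left"))
            self.R[x] = frozenset(t for t in ix if _ends_compatible(t, C, self.active, "right"))
        logger.debug(
            "compatibility index over %s: %s",
            "".join(self.active),
            {x: (len(self.I[x]), len(self.L[x]), len(self.R[x])) for x in self.active},
        )

    def suffix_matches(self, x: str, p: str) -> tuple[str, ...]:
        """All fragments in ``I_x`` that end with *p*."""
        key = (x, p)
        hit = self._suffix_cache.get(key)
        if hit is None:
            hit = tuple(t for t in self.I.get(x, ()) if t.endswith(p))
            self._suffix_cache[key] = hit
        return hit

    def total_size(self) -> int:
        return sum(len(v) for v in self.I.values())


def build_index(
    C: SpectraCollection,
    active: Iterable[str] | None = None,
    max_size: int = 1_000_000,
) -> CompatibilityIndex:
    """Construct the :class:`CompatibilityIndex` for a spectra collection."""
    return CompatibilityIndex(C, active=active, max_size=max_size)
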