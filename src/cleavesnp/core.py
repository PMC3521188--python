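"""Alphabets, cleavage fragments, compomers and compomer spectra.

Base-specific cleavage (e.g. RNase A digestion of in-vitro transcripts of a
PCR amplicon) cuts a nucleic-acid sequence at *every* occurrence of one base,
producing fragments that are free of that base.  MALDI-TOF mass spectrometry
of the digest yields one mass peak per distinct fragment, and each peak
decodes to a *compomer* -- the base composition ``AiCjGkTl`` of the fragment.
Running four reactions (one per cut base) gives four *compomer spectra*,
which together heavily constrain the underlying sequence.

This module provides the combinatorial core of that picture: cleaving a
sequence into fragments, classifying fragments as internal / left-ended /
right-ended, collecting compomer spectra, and the Hamming distance used to
score candidate sample sequences against a reference.

Conventions
-----------
* A compomer spectrum is a mathematical *set*: peak multiplicities and
  intensities are not modelled, so a compomer appears at most once.
* An empty fragment arises only between two adjacent occurrences of the cut
  base.  A leading or trailing cut base contributes no empty fragment.
* Empty fragments are always classified internal.
* Internal coordinates are 0-based half-open; user-facing reports are
  1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping


class CleavesnpError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CleavesnpError, ValueError):
    """An input violated a documented precondition or invariant."""


class CompomerFormatError(ValidationError):
    """A compomer string did not follow the canonical ``A#C#G#T#`` format."""


class Alphabet:
    """An ordered alphabet of distinct single-character bases.

    The order is significant: it defines the canonical formatting of
    compomers (every base listed, in alphabet order, even with count zero).

    Parameters
    ----------
    bases:
        Iterable of single characters, e.g. ``"ACGT"`` or ``("G", "T")``.
        At least two distinct bases are required.
    """

    __slots__ = ("bases", "_index")

    def __init__(self, bases: Iterable[str] = "ACGT") -> None:
        bases = tuple(bases)
        if len(bases) < 2:
            raise ValidationError(f"alphabet needs at least 2 bases, got {bases!r}")
        for b in bases:
            if not (isinstance(b, str) and len(b) == 1):
                raise ValidationError(f"alphabet base {b!r} is not a single character")
        if len(set(bases)) != len(bases):
            raise ValidationError(f"alphabet bases are not distinct: {bases!r}")
        self.bases = bases
        self._index = {b: i for i, b in enumerate(bases)}

    def index(self, base: str) -> int:
        try:
            return self._index[base]
        except KeyError:
            raise ValidationError(f"base {base!r} is not in alphabet {''.join(self.bases)!r}") from None

    def validate_text(self, text: str) -> str:
        """Return *text* unchanged, or raise naming the first foreign character."""
        for i, ch in enumerate(text):
            if ch not in self._index:
                raise ValidationError(
                    f"character {ch!r} at position {i + 1} is not in alphabet {''.join(self.bases)!r}"
                )
        return text

    def __contains__(self, base: object) -> bool:
        return base in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alphabet) and self.bases == other.bases

    def __hash__(self) -> int:
        return hash(self.bases)

    def __repr__(self) -> str:
        return f"Alphabet({''.join(self.bases)!r})"


#: The default four-base DNA alphabet.
DNA = Alphabet("ACGT")


@dataclass(frozen=True)
class Compomer:
    """The base composition of a cleavage fragment.

    ``counts`` is aligned with ``alphabet.bases``; equality is component-wise.
    The canonical string form lists every alphabet base in order followed by
    its decimal count, e.g. ``A0C1G1T2``.
    """

    alphabet: Alphabet
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.alphabet):
            raise ValidationError(
                f"compomer has {len(self.counts)} counts for a "
                f"{len(self.alphabet)}-base alphabet"
            )
        for b, c in zip(self.alphabet.bases, self.counts):
            if not isinstance(c, int) or c < 0:
                raise ValidationError(f"count for base {b!r} must be a non-negative integer, got {c!r}")

    @classmethod
    def of_text(cls, text: str, alphabet: Alphabet = DNA) -> "Compomer":
        """Compomer of a fragment string (the composition of its characters)."""
        alphabet.validate_text(text)
        return cls(alphabet, tuple(text.count(b) for b in alphabet.bases))

    def __getitem__(self, base: str) -> int:
        return self.counts[self.alphabet.index(base)]

    @property
    def weight(self) -> int:
        """Total number of bases, i.e. the length of any realising fragment."""
        return sum(self.counts)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.alphabet.bases, self.counts))

    def __str__(self) -> str:
        return "".join(f"{b}{c}" for b, c in zip(self.alphabet.bases, self.counts))

    def __repr__(self) -> str:
        return f"Compomer({self})"


def parse_compomer(text: str, alphabet: Alphabet = DNA) -> Compomer:
    """Parse a canonical composition string such as ``"A0C1G1T2"``.

    The canonical format lists *every* alphabet base in alphabet order, each
    followed by a decimal count.  ``format`` / ``parse`` round-trip exactly:
    ``str(parse_compomer(t)) == t`` for canonical *t*.
    """
    pos = 0
    counts = []
    for b in alphabet.bases:
        if pos >= len(text) or text[pos] != b:
            found = text[pos] if pos < len(text) else "<end of string>"
            raise CompomerFormatError(
                f"expected base {b!r} at position {pos + 1} of {text!r}, found {found!r}"
            )
        pos += 1
        start = pos
        while pos < len(text) and text[pos].isascii() and text[pos].isdigit():
            pos += 1
        if start == pos:
            raise CompomerFormatError(f"missing count for base {b!r} in {text!r}")
        counts.append(int(text[start:pos]))
    if pos != len(text):
        raise CompomerFormatError(f"unexpected trailing text {text[pos:]!r} in {text!r}")
    return Compomer(alphabet, tuple(counts))


def format_compomer(compomer: Compomer) -> str:
    """Canonical string form of a compomer (see :func:`parse_compomer`)."""
    return str(compomer)


@dataclass(frozen=True)
class CleavageFragment:
    """A maximal cut-base-free substring of a host sequence.

    ``start``/``end`` are 0-based half-open coordinates in the host; the
    1-based inclusive range of the paper-style report is
    ``(start + 1, end)``.  A fragment is *internal* if it touches neither end
    of the host, *left-ended* if it starts at position 1, *right-ended* if it
    ends at the last position.  Empty fragments (between two adjacent cut
    bases) are always internal.  A fragment spanning the whole host (cut base
    absent) is simultaneously left- and right-ended.
    """

    text: str
    cut_base: str
    start: int
    end: int
    host_length: int
    alphabet: Alphabet = DNA

    @property
    def is_empty(self) -> bool:
        return not self.text

    @property
    def is_left_ended(self) -> bool:
        return self.start == 0 and not self.is_empty

    @property
    def is_right_ended(self) -> bool:
        return self.end == self.host_length and not self.is_empty

    @property
    def is_internal(self) -> bool:
        return not self.is_left_ended and not self.is_right_ended

    @property
    def position_class(self) -> str:
        """``internal``, ``left_ended``, ``right_ended`` or ``whole``."""
        if self.is_internal:
            return "internal"
        if self.is_left_ended and self.is_right_ended:
            return "whole"
        return "left_ended" if self.is_left_ended else "right_ended"

    @property
    def compomer(self) -> Compomer:
        return Compomer.of_text(self.text, self.alphabet)

    def __str__(self) -> str:
        return self.text


def cleave(s: str, x: str, alphabet: Alphabet = DNA) -> list[CleavageFragment]:
    """Cleave *s* at every occurrence of the cut base *x*.

    Returns the maximal *x*-free substrings in left-to-right order, each
    classified by position.  One empty fragment is emitted per adjacent pair
    of *x* occurrences; a leading or trailing *x* contributes none.  The
    fragment count is therefore ``#x + 1 - [s starts with x] - [s ends with
    x]`` when *x* occurs in *s*, and 1 otherwise (0 for the empty sequence).
    """
    if x not in alphabet:
        raise ValidationError(f"cut base {x!r} is not in alphabet {''.join(alphabet.bases)!r}")
    alphabet.validate_text(s)
    n = len(s)
    if n == 0:
        return []
    cuts = [i for i, ch in enumerate(s) if ch == x]
    if not cuts:
        return [CleavageFragment(s, x, 0, n, n, alphabet)]
    frags = []
    if cuts[0] > 0:
        frags.append(CleavageFragment(s[: cuts[0]], x, 0, cuts[0], n, alphabet))
    for a, b in zip(cuts, cuts[1:]):
        frags.append(CleavageFragment(s[a + 1 : b], x, a + 1, b, n, alphabet))
    if cuts[-1] < n - 1:
        frags.append(CleavageFragment(s[cuts[-1] + 1 :], x, cuts[-1] + 1, n, n, alphabet))
    return frags


def fragment_texts(s: str, x: str, alphabet: Alphabet = DNA) -> list[str]:
    """Fragment strings of ``cleave(s, x)``, in order (convenience wrapper)."""
    return [f.text for f in cleave(s, x, alphabet)]


def _split_fragments(s: str, x: str) -> list[str]:
    """Fast fragment-text computation used by hot loops (no validation)."""
    if not s:
        return []
    parts = s.split(x)
    if len(parts) == 1:
        return parts
    if not parts[0] and s[0] == x:
        parts.pop(0)
    if parts and not parts[-1] and s[-1] == x:
        parts.pop()
    return parts


def spectrum_counts(s: str, x: str, bases: tuple[str, ...]) -> set[tuple[int, ...]]:
    """Set of compomer count-tuples of ``cleave(s, x)`` (fast path)."""
    return {tuple(p.count(b) for b in bases) for p in _split_fragments(s, x)}


@dataclass(frozen=True)
class CompomerSpectrum:
    """The set of compomers of all cleavage fragments for one cut base."""

    cut_base: str
    compomers: frozenset[Compomer]

    def __len__(self) -> int:
        return len(self.compomers)

    def __iter__(self) -> Iterator[Compomer]:
        return iter(self.compomers)

    def __contains__(self, compomer: object) -> bool:
        return compomer in self.compomers


def compomer_spectrum(s: str, x: str, alphabet: Alphabet = DNA) -> CompomerSpectrum:
    """The compomer spectrum of *s* with respect to cut base *x*.

    Duplicate fragment compositions collapse: each compomer appears at most
    once.
    """
    return CompomerSpectrum(x, frozenset(f.compomer for f in cleave(s, x, alphabet)))


class SpectraCollection:
    """One compomer spectrum per alphabet base.

    This is the full data product of the four base-specific cleavage
    reactions (or of an in-silico digest of a known sequence).  Spectra may
    be empty; bases missing from the input mapping get empty spectra.
    """

    __slots__ = ("alphabet", "_spectra", "_counts")

    def __init__(self, alphabet: Alphabet, spectra: Mapping[str, Iterable[Compomer]]) -> None:
        self.alphabet = alphabet
        for x in spectra:
            if x not in alphabet:
                raise ValidationError(f"spectrum cut base {x!r} is not in alphabet {''.join(alphabet.bases)!r}")
        built: dict[str, frozenset[Compomer]] = {}
        for x in alphabet.bases:
            comps = frozenset(spectra.get(x, ()))
            for c in comps:
                if c.alphabet != alphabet:
                    raise ValidationError(f"compomer {c} uses alphabet {c.alphabet!r}, expected {alphabet!r}")
            built[x] = comps
        self._spectra = built
        self._counts = {x: frozenset(c.counts for c in comps) for x, comps in built.items()}

    @classmethod
    def of(cls, s: str, alphabet: Alphabet = DNA) -> "SpectraCollection":
        """In-silico spectra of a known sequence (one digest per base)."""
        return cls(alphabet, {x: compomer_spectrum(s, x, alphabet).compomers for x in alphabet.bases})

    @classmethod
    def from_counts(
        cls, alphabet: Alphabet, counts: Mapping[str, Iterable[tuple[int, ...]]]
    ) -> "SpectraCollection":
        return cls(
            alphabet,
            {x: [Compomer(alphabet, tuple(t)) for t in ts] for x, ts in counts.items()},
        )

    def __getitem__(self, x: str) -> frozenset[Compomer]:
        if x not in self._spectra:
            raise ValidationError(f"base {x!r} is not in alphabet {''.join(self.alphabet.bases)!r}")
        return self._spectra[x]

    def counts(self, x: str) -> frozenset[tuple[int, ...]]:
        """Spectrum of *x* as raw count-tuples (fast comparisons)."""
        return self._counts[x]

    def spectrum(self, x: str) -> CompomerSpectrum:
        return CompomerSpectrum(x, self[x])

    def items(self) -> Iterator[tuple[str, frozenset[Compomer]]]:
        return ((x, self._spectra[x]) for x in self.alphabet.bases)

    def sizes(self) -> dict[str, int]:
        return {x: len(self._spectra[x]) for x in self.alphabet.bases}

    def replace(self, x: str, compomers: Iterable[Compomer]) -> "SpectraCollection":
        """A new collection with the spectrum of *x* replaced."""
        new = {b: comps for b, comps in self.items()}
        new[x] = frozenset(compomers)
        return SpectraCollection(self.alphabet, new)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SpectraCollection)
            and self.alphabet == other.alphabet
            and self._spectra == other._spectra
        )

    def __repr__(self) -> str:
        inner = ", ".join(f"{x}:{len(c)}" for x, c in self.items())
        return f"SpectraCollection({inner})"


def spectra_of(s: str, alphabet: Alphabet = DNA) -> SpectraCollection:
    """All compomer spectra of *s*, one per alphabet base."""
    return SpectraCollection.of(s, alphabet)


@dataclass(frozen=True, eq=False)
class ProblemInstance:
    """A reconstruction instance: reference sequence plus measured spectra."""

    alphabet: Alphabet
    reference: str
    spectra: SpectraCollection

    def __post_init__(self) -> None:
        self.alphabet.validate_text(self.reference)
        if self.spectra.alphabet != self.alphabet:
            raise ValidationError("spectra alphabet differs from instance alphabet")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ProblemInstance)
            and self.alphabet == other.alphabet
            and self.reference == other.reference
            and self.spectra == other.spectra
        )


def hamming(s: str, t: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(s) != len(t):
        raise ValidationError(f"length mismatch: {len(s)} vs {len(t)}")
    return sum(a != b for a, b in zip(s, t))
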