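"""File formats: FASTA references, JSON/TSV spectra and instances, SNP reports.

The on-disk instance format is a small JSON object::

    {
      "alphabet": "ACGT",
      "reference": "ACATGCTACATTA",          # or {"fasta": "ref.fasta"}
      "spectra": {"A": ["A0C1G0T0", ...], "C": [...], "G": [...], "T": [...]}
    }

Compomers are canonical composition strings (every alphabet base, in
alphabet order).  Spectra alone may also be given as a 2-column TSV of
``cut_base<TAB>compomer``.  SNP calls are written as a TSV of 1-based
POS/REF/ALT columns or as a minimal VCF 4.2 with the reference sequence as
its single contig.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Alphabet,
    CompomerFormatError,
    ProblemInstance,
    SpectraCollection,
    ValidationError,
    parse_compomer,
)
from .msp import SnpCall, Solution


class InstanceFormatError(ValidationError):
    """A spectra/instance file violated the schema; the message carries a
    JSON-pointer-style location of the offending element."""


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA; returns ``(record id, sequence)``.

    Multi-record files are rejected: an instance has exactly one reference.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(
            f"{path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_fasta(path: str | Path, name: str, sequence: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def _parse_alphabet(obj: dict, where: str) -> Alphabet:
    raw = obj.get("alphabet", "ACGT")
    if not isinstance(raw, str):
        raise InstanceFormatError(f"{where}/alphabet: expected a string, got {type(raw).__name__}")
    try:
        return Alphabet(raw)
    except ValidationError as exc:
        raise InstanceFormatError(f"{where}/alphabet: {exc}") from exc


def _parse_spectra(obj: dict, alphabet: Alphabet, where: str) -> SpectraCollection:
    raw = obj.get("spectra")
    if not isinstance(raw, dict):
        raise InstanceFormatError(f"{where}/spectra: expected an object mapping cut base to compomer list")
    spectra = {}
    for x, items in raw.items():
        if x not in alphabet:
            raise InstanceFormatError(f"{where}/spectra/{x}: cut base not in alphabet")
        if not isinstance(items, list):
            raise InstanceFormatError(f"{where}/spectra/{x}: expected a list of compomer strings")
        comps = []
        for i, text in enumerate(items):
            try:
                comps.append(parse_compomer(text, alphabet))
            except (CompomerFormatError, TypeError) as exc:
                raise InstanceFormatError(f"{where}/spectra/{x}/{i}: {exc}") from exc
        spectra[x] = comps
    return SpectraCollection(alphabet, spectra)


def read_spectra(path: str | Path, alphabet: Alphabet | None = None) -> SpectraCollection:
    """Read a spectra collection from JSON (schema above) or 2-column TSV.

    For TSV input the alphabet is taken from the *alphabet* argument or, if
    omitted, inferred from the base ordering of the first compomer string.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        obj = json.loads(text)
        file_alphabet = _parse_alphabet(obj, "")
        if alphabet is not None and alphabet != file_alphabet:
            raise InstanceFormatError(
                f"/alphabet: file alphabet {''.join(file_alphabet.bases)!r} differs from "
                f"expected {''.join(alphabet.bases)!r}"
            )
        return _parse_spectra(obj, file_alphabet, "")
    # TSV: cut_base <TAB> compomer
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InstanceFormatError(f"/line/{ln}: expected 2 tab-separated columns, got {len(parts)}")
        rows.append((ln, parts[0], parts[1]))
    if alphabet is None:
        if not rows:
            raise InstanceFormatError("/: empty spectra TSV and no alphabet given")
        letters = [ch for ch in rows[0][2] if not ch.isdigit()]
        alphabet = Alphabet(letters)
    spectra: dict[str, list] = {}
    for ln, x, comp_text in rows:
        if x not in alphabet:
            raise InstanceFormatError(f"/line/{ln}: cut base {x!r} not in alphabet")
        try:
            spectra.setdefault(x, []).append(parse_compomer(comp_text, alphabet))
        except CompomerFormatError as exc:
            raise InstanceFormatError(f"/line/{ln}: {exc}") from exc
    return SpectraCollection(alphabet, spectra)


def write_spectra(C: SpectraCollection, path: str | Path) -> None:
    obj = {
        "alphabet": "".join(C.alphabet.bases),
        "spectra": {x: sorted(str(c) for c in comps) for x, comps in C.items()},
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_instance(path: str | Path) -> ProblemInstance:
    """Read a full problem instance (reference plus spectra) from JSON."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InstanceFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(obj, dict):
        raise InstanceFormatError("/: expected a JSON object")
    alphabet = _parse_alphabet(obj, "")
    ref = obj.get("reference")
    if isinstance(ref, dict) and "fasta" in ref:
        fasta_path = Path(ref["fasta"])
        if not fasta_path.is_absolute():
            fasta_path = path.parent / fasta_path
        _, ref = read_fasta(fasta_path)
    if not isinstance(ref, str):
        raise InstanceFormatError("/reference: expected a sequence string or {\"fasta\": path}")
    try:
        alphabet.validate_text(ref)
    except ValidationError as exc:
        raise InstanceFormatError(f"/reference: {exc}") from exc
    spectra = _parse_spectra(obj, alphabet, "")
    return ProblemInstance(alphabet, ref, spectra)


def write_instance(instance: ProblemInstance, path: str | Path) -> None:
    obj = {
        "alphabet": "".join(instance.alphabet.bases),
        "reference": instance.reference,
        "spectra": {x: sorted(str(c) for c in comps) for x, comps in instance.spectra.items()},
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def write_snps_tsv(calls: Sequence[SnpCall], path: str | Path) -> None:
    lines = ["POS\tREF\tALT"]
    lines += [f"{c.position}\t{c.ref}\t{c.alt}" for c in calls]
    Path(path).write_text("\n".join(lines) + "\n")


def read_snps_tsv(path: str | Path) -> list[SnpCall]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["POS", "REF", "ALT"]:
        raise InstanceFormatError("/line/1: expected header POS<TAB>REF<TAB>ALT")
    calls = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        pos, ref, alt = line.split("\t")
        calls.append(SnpCall(int(pos), ref, alt))
    return calls


def write_snps_vcf(
    calls: Sequence[SnpCall],
    path: str | Path,
    contig: str,
    contig_length: int,
) -> None:
    """Minimal VCF 4.2: single contig, no samples or genotypes."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=cleavesnp",
        f"##contig=<ID={contig},length={contig_length}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    lines += [f"{contig}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\t.\t." for c in calls]
    Path(path).write_text("\n".join(lines) + "\n")


def write_snps(
    solution: Solution | Sequence[SnpCall],
    path: str | Path,
    fmt: str = "tsv",
    contig: str = "ref",
    contig_length: int | None = None,
) -> None:
    """Write a solution's calls as TSV (default) or minimal VCF 4.2."""
    calls = solution.snps if isinstance(solution, Solution) else list(solution)
    if fmt == "tsv":
        write_snps_tsv(calls, path)
    elif fmt == "vcf":
        if contig_length is None:
            raise ValidationError("VCF output needs the contig length")
        write_snps_vcf(calls, path, contig, contig_length)
    else:
        raise ValidationError(f"unknown SNP output format {fmt!r}")
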