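"""FASTA I/O, sequence records, translation, and IUPAC nucleotide handling.

Sequences are canonicalized to upper case on construction; ``U`` is mapped
to ``T`` so RNA-style deposits are tolerated. The gap character ``-`` is
legal only inside alignment rows, never in raw records.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "translate",
    "reverse_complement",
    "degeneracy",
    "expand_degenerate",
    "IUPAC_SETS",
    "CODON_TABLE",
    "STOP_CODONS",
]

#: IUPAC nucleotide ambiguity codes mapped to their base sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

#: Standard genetic code, codon -> one-letter amino acid (stops excluded).
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

_PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWY*X-")
_DNA_CHARS = frozenset(IUPAC_SETS) | {"-"}


class Alphabet(str, Enum):
    """Alphabet tag for a :class:`SequenceRecord`."""

    DNA = "dna_iupac"
    PROTEIN = "protein"


@dataclass(frozen=True)
class SequenceRecord:
    """An identified sequence with an explicit alphabet.

    Raw records never contain gaps; gapped strings live in alignment rows.
    """

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.DNA
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        res = self.residues.upper()
        if self.alphabet is Alphabet.DNA:
            res = res.replace("U", "T")
        object.__setattr__(self, "residues", res)
        if not res:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = _DNA_CHARS if self.alphabet is Alphabet.DNA else _PROTEIN_CHARS
        bad = set(res) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid {self.alphabet.value} "
                f"character(s) {sorted(bad)}"
            )
        if "-" in res:
            raise ValueError(
                f"record {self.id!r}: gap characters are only legal in alignments"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.DNA) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, preserving record order.

    The record id is the first whitespace-delimited token of the header;
    the remainder becomes the description. Duplicate ids and records with
    no sequence are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        parts = header.split(None, 1)
        rid = parts[0] if parts else ""
        desc = parts[1] if len(parts) > 1 else ""
        if not rid:
            raise ValueError(f"{path}: FASTA header with no id")
        if rid in seen:
            raise ValueError(f"{path}: duplicate sequence id {rid!r}")
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{path}: record {rid!r} has no sequence")
        seen.add(rid)
        records.append(SequenceRecord(id=rid, residues=seq, alphabet=alphabet, description=desc))
        header, chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
        flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def translate(cds: SequenceRecord, strip_terminal_stop: bool = False) -> SequenceRecord:
    """Translate an unambiguous CDS with the standard genetic code.

    Parameters
    ----------
    cds
        DNA record, length a multiple of 3, ACGT only.
    strip_terminal_stop
        Remove a trailing stop codon instead of raising on it.

    Raises
    ------
    ValueError
        On length not divisible by 3, ambiguity codes, or an internal
        stop codon.
    """
    if cds.alphabet is not Alphabet.DNA:
        raise ValueError(f"record {cds.id!r}: translate requires a DNA record")
    seq = cds.residues
    if len(seq) % 3 != 0:
        raise ValueError(f"record {cds.id!r}: CDS length {len(seq)} not divisible by 3")
    if set(seq) - set("ACGT"):
        raise ValueError(f"record {cds.id!r}: ambiguity codes not allowed in a CDS")
    aas: list[str] = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1 and strip_terminal_stop:
                break
            raise ValueError(
                f"record {cds.id!r}: stop codon {codon} at codon {i + 1}"
                + ("" if i < n_codons - 1 else " (terminal; pass strip_terminal_stop)")
            )
        aas.append(CODON_TABLE[codon])
    return SequenceRecord(
        id=cds.id, residues="".join(aas), alphabet=Alphabet.PROTEIN, description=cds.description
    )


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement of a nucleotide string."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(seq.upper().replace("U", "T")))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r}") from None


def degeneracy(seq: str) -> int:
    """Number of concrete ACGT strings a degenerate sequence stands for."""
    n = 1
    for c in seq.upper().replace("U", "T"):
        try:
            n *= len(IUPAC_SETS[c])
        except KeyError:
            raise ValueError(f"invalid IUPAC character {c!r}") from None
    return n


def expand_degenerate(seq: str, limit: int = 100_000) -> Iterator[str]:
    """Yield every concrete ACGT expansion of a degenerate sequence.

    Guarded by ``limit`` to keep accidental combinatorial blow-ups loud.
    """
    if degeneracy(seq) > limit:
        raise ValueError(f"degeneracy of {seq!r} exceeds limit {limit}")
    pools = [sorted(IUPAC_SETS[c]) for c in seq.upper().replace("U", "T")]
    for combo in itertools.product(*pools):
        yield "".join(combo)
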