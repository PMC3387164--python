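"""Sequence domain types, FASTA I/O and translation utilities.

Coordinate convention used throughout the package: positions are 1-based and
inclusive at both ends, so the span ``47GDGGVG52`` covers six residues.
Converters to 0-based half-open slices exist only at I/O boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import molecular_weight as _bp_molecular_weight

PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
DNA_LETTERS = "ACGT"

#: Wildcard residues that a permissive parse maps ambiguity codes onto.
#: A wildcard never counts as an identity anywhere in the package.
PROTEIN_WILDCARD = "X"
DNA_WILDCARD = "N"

_ALPHABETS = {
    "dna": set(DNA_LETTERS),
    "protein": set(PROTEIN_LETTERS),
}


class SequenceError(ValueError):
    """Raised for malformed sequences or invalid residues."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide or protein sequence.

    Parameters
    ----------
    id : accession-like identifier.
    description : free-text description (may be empty).
    alphabet : ``"dna"`` or ``"protein"``.
    residues : upper-case residue string over the declared alphabet.
    permissive : if True, the wildcard character (``X`` for protein,
        ``N`` for dna) is additionally allowed; it never counts as an
        identity in any comparison.
    """

    id: str
    residues: str
    alphabet: str = "protein"
    description: str = ""
    permissive: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        allowed = set(_ALPHABETS[self.alphabet])
        if self.permissive:
            allowed.add(PROTEIN_WILDCARD if self.alphabet == "protein" else DNA_WILDCARD)
        for ch in self.residues:
            if ch not in allowed:
                raise SequenceError(
                    f"record {self.id!r}: invalid {self.alphabet} residue {ch!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def slice1(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive span ``start..end``."""
        if not (1 <= start <= end <= len(self.residues)):
            raise SequenceError(f"span {start}-{end} outside 1..{len(self.residues)}")
        return self.residues[start - 1 : end]


def _map_ambiguity(seq: str, alphabet: str) -> str:
    wildcard = PROTEIN_WILDCARD if alphabet == "protein" else DNA_WILDCARD
    allowed = _ALPHABETS[alphabet]
    return "".join(ch if ch in allowed else wildcard for ch in seq)


def read_fasta(path: str | Path, alphabet: str = "protein", permissive: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Lines starting with ``;`` (old-style comments) are ignored; wrapped
    sequence lines are concatenated and upper-cased; record order is
    preserved. With ``permissive=True`` ambiguity codes are mapped to the
    alphabet's wildcard instead of being rejected.
    """
    path = Path(path)
    text = path.read_text()
    cleaned = "\n".join(ln for ln in text.splitlines() if not ln.startswith(";"))
    if not cleaned.strip():
        raise SequenceError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(io.StringIO(cleaned), "fasta"):
        residues = str(rec.seq).upper().replace(" ", "")
        if permissive:
            residues = _map_ambiguity(residues, alphabet)
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description[len(rec.id) :].strip(),
                alphabet=alphabet,
                residues=residues,
                permissive=permissive,
            )
        )
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records to ``path`` in FASTA format (fixed line wrapping)."""
    bio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio_records)


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    for ch in seq:
        if ch not in _ALPHABETS["dna"]:
            raise SequenceError(f"invalid DNA base {ch!r}")
    return seq


def reverse_complement(seq: str | SequenceRecord) -> str:
    """Reverse complement of a DNA string (strict ACGT)."""
    if isinstance(seq, SequenceRecord):
        if seq.alphabet != "dna":
            raise SequenceError("reverse_complement requires a dna record")
        seq = seq.residues
    return str(Seq(_check_dna(seq)).reverse_complement())


def translate(orf: str) -> str:
    """Translate an ORF to protein with the standard genetic code.

    The ORF must start with ATG, have length divisible by 3, and contain
    exactly one stop codon located at the terminal position.  The stop is
    excluded from the product, so a 3k-nt ORF yields k-1 residues.
    """
    orf = _check_dna(orf)
    if len(orf) % 3 != 0:
        raise SequenceError(f"ORF length {len(orf)} not divisible by 3")
    if not orf.startswith("ATG"):
        raise SequenceError("ORF does not begin with ATG")
    protein = str(Seq(orf).translate(table=1))
    stops = [i for i, aa in enumerate(protein) if aa == "*"]
    if not stops:
        raise SequenceError("ORF has no stop codon")
    if stops[0] != len(protein) - 1:
        raise SequenceError(f"internal stop codon at codon {stops[0] + 1}")
    product = protein[:-1]
    if not product:
        raise SequenceError("ORF encodes a zero-length product")
    return product


def protein_molecular_weight(protein: str) -> float:
    """Average molecular mass in Da (residue masses plus one water)."""
    if not protein:
        raise SequenceError("empty protein string")
    for ch in protein:
        if ch not in _ALPHABETS["protein"]:
            raise SequenceError(f"invalid protein residue {ch!r}")
    return float(_bp_molecular_weight(protein, seq_type="protein", monoisotopic=False))


def to_slice(start: int, end: int) -> slice:
    """Convert a 1-based inclusive span to a Python slice (I/O boundary only)."""
    if start < 1 or end < start:
        raise SequenceError(f"invalid 1-based span {start}-{end}")
    return slice(start - 1, end)
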