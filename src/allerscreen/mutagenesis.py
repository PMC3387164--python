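"""Codon-level point mutagenesis and overlap-extension primer verification.

A mutation such as ``T10P`` (threonine 10 to proline) is applied to a coding
sequence by replacing the target codon with the mutant-residue codon that is
closest in Hamming distance, mimicking how mutagenic primers are designed in
practice.  Overlap-extension primer pairs are verified at the sequence
level: the two internal primers must be exact reverse complements, cover the
target codon, and anneal to the coding strand with no edits other than the
intended codon substitution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable
from Bio.SeqUtils import MeltingTemp

from .seq_core import (
    PROTEIN_LETTERS,
    SequenceError,
    _check_dna,
    reverse_complement,
    translate,
)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: mapping amino acid -> sorted tuple of its sense codons (standard code)
CODONS_BY_AA: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in _STANDARD.forward_table.items() if a == aa))
    for aa in PROTEIN_LETTERS
}

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A protein point substitution, e.g. ``T10P``."""

    wild_aa: str
    position: int
    mutant_aa: str

    def __post_init__(self) -> None:
        for aa in (self.wild_aa, self.mutant_aa):
            if aa not in PROTEIN_LETTERS:
                raise SequenceError(f"unknown amino acid {aa!r}")
        if self.wild_aa == self.mutant_aa:
            raise SequenceError("wild and mutant residues must differ")
        if self.position < 1:
            raise SequenceError("position must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        m = _MUTATION_RE.match(text.strip().upper())
        if not m:
            raise SequenceError(f"cannot parse mutation spec {text!r}")
        return cls(wild_aa=m.group(1), position=int(m.group(2)), mutant_aa=m.group(3))

    def __str__(self) -> str:
        return f"{self.wild_aa}{self.position}{self.mutant_aa}"


@dataclass(frozen=True)
class PrimerPair:
    """A named overlap-extension primer pair with its coding-strand span.

    ``span`` is the 1-based inclusive nucleotide range on the coding strand
    that the forward primer is designed against (CDS numbering anchored at
    the first base of the start codon).
    """

    name: str
    forward: str
    reverse: str
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        _check_dna(self.forward)
        _check_dna(self.reverse)
        if not self.forward or not self.reverse:
            raise SequenceError("primers must be non-empty")


@dataclass
class PrimerVerdict:
    """Outcome of verifying one primer pair; discrepancies are reported here,
    never raised."""

    is_exact_revcomp: bool
    mismatch_positions: list[int] = field(default_factory=list)
    covers_target_codon: bool | None = None
    introduced_codon: str | None = None
    edits_vs_wild_codon: int | None = None
    anneal_mismatches: list[int] = field(default_factory=list)
    introduces_mutant_aa: bool | None = None


def codon_span(position: int) -> tuple[int, int]:
    """CDS nucleotide span of residue ``position``: (3p-2, 3p), 1-based."""
    if position < 1:
        raise SequenceError("residue position must be >= 1")
    return (3 * position - 2, 3 * position)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def minimal_edit_codon(wild_codon: str, target_aa: str) -> str:
    """The codon of ``target_aa`` closest in Hamming distance to ``wild_codon``.

    Ties are broken by preferring a codon that preserves the wild codon's
    third position, then lexicographically — deterministic, and consistent
    with how mutagenic primers minimise introduced edits.
    """
    wild_codon = _check_dna(wild_codon)
    if len(wild_codon) != 3:
        raise SequenceError("wild codon must be 3 nt")
    candidates = CODONS_BY_AA.get(target_aa)
    if not candidates:
        raise SequenceError(f"unknown target amino acid {target_aa!r}")
    return min(
        candidates,
        key=lambda c: (_hamming(c, wild_codon), c[2] != wild_codon[2], c),
    )


def apply_mutations(
    cds: str, specs: list[MutationSpec]
) -> tuple[str, str, dict[str, int]]:
    """Apply point substitutions to a CDS with minimal nucleotide edits.

    Returns ``(mutant_cds, mutant_protein, edit_counts)`` where
    ``edit_counts`` maps each spec string to the number of nucleotide edits
    made in its codon.  The wild residue of every spec is checked against
    the translated CDS before any edit is made.
    """
    cds = _check_dna(cds)
    protein = translate(cds)
    for spec in specs:
        if spec.position > len(protein):
            raise SequenceError(
                f"{spec}: position beyond protein length {len(protein)}"
            )
        found = protein[spec.position - 1]
        if found != spec.wild_aa:
            raise SequenceError(
                f"{spec}: expected {spec.wild_aa} at position {spec.position}, found {found}"
            )
    bases = list(cds)
    edits: dict[str, int] = {}
    for spec in specs:
        start, end = codon_span(spec.position)
        wild_codon = cds[start - 1 : end]
        new_codon = minimal_edit_codon(wild_codon, spec.mutant_aa)
        edits[str(spec)] = _hamming(wild_codon, new_codon)
        bases[start - 1 : end] = new_codon
    mutant_cds = "".join(bases)
    return mutant_cds, translate(mutant_cds), edits


def verify_primer_pair(
    pair: PrimerPair,
    cds: str | None = None,
    spec: MutationSpec | None = None,
) -> PrimerVerdict:
    """Sequence-level verification of an overlap-extension primer pair.

    Always checks that the reverse primer is the exact reverse complement of
    the forward primer (mismatch positions are 1-based on the forward
    primer; a length difference marks the overhanging positions as
    mismatches).  With ``cds`` and ``spec`` given, additionally checks that
    the forward primer anneals to the stated span with only the intended
    codon edits and that the introduced codon encodes the mutant residue.
    """
    rc = reverse_complement(pair.reverse)
    fwd = pair.forward
    nmin = min(len(fwd), len(rc))
    mismatches = [i + 1 for i in range(nmin) if fwd[i] != rc[i]]
    mismatches += list(range(nmin + 1, max(len(fwd), len(rc)) + 1))
    verdict = PrimerVerdict(
        is_exact_revcomp=not mismatches, mismatch_positions=mismatches
    )
    if spec is not None and pair.span is not None:
        c_start, c_end = codon_span(spec.position)
        s_start, s_end = pair.span
        verdict.covers_target_codon = s_start <= c_start and c_end <= s_end
        if verdict.covers_target_codon:
            offset = c_start - s_start
            if offset + 3 <= len(fwd):
                verdict.introduced_codon = fwd[offset : offset + 3]
                verdict.introduces_mutant_aa = (
                    _STANDARD.forward_table.get(verdict.introduced_codon) == spec.mutant_aa
                )
    if cds is not None and pair.span is not None:
        cds = _check_dna(cds)
        s_start, s_end = pair.span
        region = cds[s_start - 1 : s_end]
        n = min(len(region), len(fwd))
        verdict.anneal_mismatches = [i + 1 for i in range(n) if region[i] != fwd[i]]
        if spec is not None:
            c_start, c_end = codon_span(spec.position)
            wild_codon = cds[c_start - 1 : c_end]
            if verdict.introduced_codon is not None:
                verdict.edits_vs_wild_codon = _hamming(
                    verdict.introduced_codon, wild_codon
                )
    return verdict


def primer_tm(primer: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) °C."""
    primer = _check_dna(primer)
    if not primer:
        raise SequenceError("empty primer")
    return float(MeltingTemp.Tm_Wallace(primer))


def read_primer_table(path: str | Path) -> list[tuple[PrimerPair, MutationSpec | None]]:
    """Read a TSV primer table: columns name, forward, reverse, span
    (``start-end``, optional), mutation (optional, e.g. ``T10P``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for _, row in df.iterrows():
        span = None
        if "span" in df.columns and isinstance(row.get("span"), str) and row["span"].strip():
            a, b = row["span"].replace("–", "-").split("-")
            span = (int(a), int(b))
        spec = None
        if "mutation" in df.columns and isinstance(row.get("mutation"), str) and row["mutation"].strip():
            spec = MutationSpec.parse(row["mutation"])
        pair = PrimerPair(
            name=row["name"],
            forward=row["forward"].replace(" ", ""),
            reverse=row["reverse"].replace(" ", ""),
            span=span,
        )
        out.append((pair, spec))
    return out
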