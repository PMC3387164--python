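"""Seeded generators for every input class the pipeline consumes.

All generators are pure functions of their spec and seed (byte-identical
reruns) and return ground-truth tables alongside the data, so downstream
flags can be asserted without re-deriving the truth.

The panel generator emulates an allergen sequence database: random protein
backgrounds in the length range of PR-10 homologs (137–161 residues) with
known epitope-region motifs planted at recorded spans.  The immunology
generator emulates three-group (control / wild / mutant) mouse experiments
with normally distributed measurements, n = 5 per group by default, using
the sensitization study's printed means and standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .immuno_stats import GroupData
from .seq_core import PROTEIN_LETTERS, SequenceError, SequenceRecord

#: Approximate residue frequencies of the UniProt/Swiss-Prot proteome,
#: normalised; used when a natural background composition is requested.
NATURAL_FREQUENCIES = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

#: Epitope-region motifs of the cacao PR-10 query and their 1-based query
#: positions (P-loop core, conserved surface regions).
QUERY_MOTIFS = {
    "DSDNLI": 26,
    "GDGGVGSIK": 47,  # P-loop; contains the GDGGVG hexamer at 47
    "FPEGSHFKY": 59,
    "TSHYHT": 116,
    "EEEIKAGK": 129,
}

#: Printed group summaries of the serum IgE assay: label -> (mean, sd).
IGE_GROUP_PARAMS = {
    "control": (1.80, 0.32),
    "wild": (3.02, 0.16),
    "mutant": (2.18, 0.34),
}


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic allergen panel.

    ``plantings`` holds one tuple per sequence, each a tuple of
    ``(motif, position-or-None)`` to plant (None = random placement).
    Sequences beyond ``len(plantings)`` get no motif.  ``lengths``, when
    given, fixes each sequence's length; otherwise lengths are drawn
    uniformly from ``length_range``.
    """

    n_sequences: int
    length_range: tuple[int, int] = (137, 161)
    plantings: tuple[tuple[tuple[str, int | None], ...], ...] = ()
    lengths: tuple[int, ...] | None = None
    seed: int = 0
    background: str = "uniform"

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length range")
        if self.background not in ("uniform", "natural"):
            raise ValueError("background must be 'uniform' or 'natural'")
        if self.lengths is not None and len(self.lengths) != self.n_sequences:
            raise ValueError("lengths must have one entry per sequence")
        for i, seq_plants in enumerate(self.plantings):
            min_len = self.lengths[i] if self.lengths is not None else lo
            for motif, pos in seq_plants:
                if len(motif) > min_len:
                    raise ValueError(f"motif {motif!r} longer than minimum sequence length")
                if pos is not None and pos + len(motif) - 1 > min_len:
                    raise ValueError(f"motif {motif!r} at {pos} may not fit in all lengths")

    @classmethod
    def reference_default(cls, seed: int = 0) -> "PanelSpec":
        """Panel mirroring the reference allergen screen: one sequence per
        reference row, each with its motif(s) planted at the recorded
        subject position."""
        rows = load_reference_panel()
        plantings = tuple(
            tuple((motif, pos) for motif, pos in row["motifs"]) for row in rows
        )
        lengths = tuple(row["length"] for row in rows)
        return cls(
            n_sequences=len(rows),
            length_range=(min(lengths), max(lengths)),
            plantings=plantings,
            lengths=lengths,
            seed=seed,
        )


@dataclass(frozen=True)
class ImmunoSpec:
    """Per-group (label, mean, sd, n) parameters for normal draws."""

    groups: tuple[tuple[str, float, float, int], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        for label, mean, sd, n in self.groups:
            if sd < 0:
                raise ValueError(f"group {label!r}: sd must be >= 0")
            if n < 2:
                raise ValueError(f"group {label!r}: n must be >= 2")

    @classmethod
    def ige_default(cls, seed: int = 0, n: int = 5) -> "ImmunoSpec":
        return cls(
            groups=tuple(
                (label, m, s, n) for label, (m, s) in sorted(IGE_GROUP_PARAMS.items())
            ),
            seed=seed,
        )


def load_reference_panel() -> list[dict]:
    """Rows of the packaged reference allergen panel (report schema context)."""
    text = (
        resources.files("allerscreen")
        .joinpath("data", "reference_allergen_panel.tsv")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        rec = dict(zip(header, ln.split("\t")))
        rec["length"] = int(rec["length"])
        rec["motifs"] = [
            (m.split("@")[0], int(m.split("@")[1])) for m in rec["motifs"].split(";")
        ]
        rows.append(rec)
    return rows


def _draw_background(rng: np.random.Generator, length: int, background: str) -> list[str]:
    letters = list(PROTEIN_LETTERS)
    if background == "uniform":
        idx = rng.integers(0, 20, size=length)
    else:
        p = np.array([NATURAL_FREQUENCIES[a] for a in letters])
        idx = rng.choice(20, size=length, p=p / p.sum())
    return [letters[i] for i in idx]


def make_allergen_panel(spec: PanelSpec) -> tuple[list[SequenceRecord], list[tuple]]:
    """Generate a synthetic allergen panel with planted motifs.

    Returns ``(records, truth)`` where ``truth`` lists
    ``(sequence_id, motif, start, end)`` for every planted motif (1-based
    inclusive spans).  Reproducible: the same spec yields byte-identical
    sequences.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[SequenceRecord] = []
    truth: list[tuple] = []
    for i in range(spec.n_sequences):
        if spec.lengths is not None:
            length = spec.lengths[i]
        else:
            length = int(rng.integers(lo, hi + 1))
        residues = _draw_background(rng, length, spec.background)
        plants = spec.plantings[i] if i < len(spec.plantings) else ()
        for motif, pos in plants:
            if len(motif) > length:
                raise SequenceError(f"motif {motif!r} longer than sequence of {length}")
            if pos is None:
                pos = int(rng.integers(1, length - len(motif) + 2))
            if pos + len(motif) - 1 > length:
                raise SequenceError(f"motif {motif!r} at {pos} exceeds length {length}")
            residues[pos - 1 : pos - 1 + len(motif)] = list(motif)
            truth.append((f"syn{i + 1}", motif, pos, pos + len(motif) - 1))
        records.append(
            SequenceRecord(
                id=f"syn{i + 1}",
                description=f"synthetic panel member {i + 1}",
                alphabet="protein",
                residues="".join(residues),
            )
        )
    return records, truth


def make_query_protein(seed: int = 0, length: int = 159) -> tuple[SequenceRecord, list[tuple]]:
    """A synthetic 159-residue PR-10-like query with the epitope-region
    motifs planted at their canonical query positions (see QUERY_MOTIFS)."""
    rng = np.random.default_rng(seed)
    residues = _draw_background(rng, length, "uniform")
    truth = []
    for motif, pos in QUERY_MOTIFS.items():
        residues[pos - 1 : pos - 1 + len(motif)] = list(motif)
        truth.append(("query", motif, pos, pos + len(motif) - 1))
    return (
        SequenceRecord(
            id="query",
            description="synthetic PR-10-like query",
            alphabet="protein",
            residues="".join(residues),
        ),
        truth,
    )


def make_window_pair(
    identities_in_window: int, window: int = 80, seed: int = 0
) -> tuple[str, str, dict]:
    """A sequence pair whose optimal local alignment is a gapless pairing of
    ``window`` columns with exactly the requested number of identities.

    Identity columns carry the same high self-scoring residue (W/W); every
    other column is a similar-but-distinct pair (K vs R) whose substitution
    score is positive, so the full gapless pairing is the unique optimal
    local alignment and no window elsewhere scores more identities.
    Returns ``(query, subject, truth)`` with the identity positions and the
    exact expected window identity percent in ``truth``.
    """
    if not (0 <= identities_in_window <= window):
        raise ValueError("identity count must be between 0 and the window size")
    rng = np.random.default_rng(seed)
    positions = sorted(rng.choice(window, size=identities_in_window, replace=False))
    query = ["K"] * window
    subject = ["R"] * window
    for p in positions:
        query[p] = "W"
        subject[p] = "W"
    truth = {
        "identity_positions": [int(p) + 1 for p in positions],
        "expected_percent": 100.0 * identities_in_window / window,
        "window": window,
    }
    return "".join(query), "".join(subject), truth


def make_immuno_groups(spec: ImmunoSpec) -> list[GroupData]:
    """Normal draws per group under the spec's means/SDs (seeded)."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for label, mean, sd, n in spec.groups:
        values = mean + sd * rng.standard_normal(n)
        out.append(GroupData(label=label, values=tuple(float(v) for v in values)))
    return out


#: Default dose -> survival probability for the antifungal assay generator;
#: chosen so expected inhibition matches the reported dose response of the
#: wild protein (73% at 8 ug/mL, 91% at 10 ug/mL).
WILD_SURVIVAL_PROBS = {4.0: 0.55, 8.0: 0.27, 10.0: 0.09}
MUTANT_SURVIVAL_PROBS = {4.0: 0.70, 8.0: 0.39, 10.0: 0.44}


def make_survival_counts(
    seed: int = 0,
    control_count: int = 200,
    survival_probs: dict[float, float] | None = None,
) -> list[tuple[float, int, int]]:
    """Dose-wise fungal survival counts by binomial thinning of a control
    colony count: treated ~ Binomial(control, survival_prob(dose))."""
    probs = WILD_SURVIVAL_PROBS if survival_probs is None else survival_probs
    rng = np.random.default_rng(seed)
    out = []
    for dose in sorted(probs):
        treated = int(rng.binomial(control_count, probs[dose]))
        out.append((dose, treated, control_count))
    return out
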