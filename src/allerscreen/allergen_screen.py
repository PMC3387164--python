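"""FAO/WHO sequence-comparison allergenicity screen.

Two criteria from the Codex transgene-safety guidance are implemented:

* a shared stretch of at least ``k`` (default 6) identical contiguous
  amino acids with a known allergen, and
* identity strictly greater than 35% inside a sliding window of 80
  alignment columns of the optimal local alignment.

The screen additionally reports a Karlin–Altschul E-value for the local
alignment score and the property-distance (PD) of the aligned residues,
mirroring the report layout of database allergen searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice
from math import exp
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_core import SequenceRecord, SequenceError

#: The protein wildcard never counts as an identity (permissive ambiguity
#: mapping maps unknown residues onto it).
_WILDCARDS = frozenset("X")


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the two FAO/WHO criteria and the alignment model.

    ``identity_threshold`` is strict: a window at exactly the threshold does
    not flag.  ``gap_open``/``gap_extend`` follow the BLAST convention (a gap
    of length L costs ``gap_open + L*gap_extend``).  ``evalue_k`` and
    ``evalue_lambda`` are the Karlin–Altschul parameters; the defaults are
    the customary gapped values for the BLOSUM62 family.
    """

    k: int = 6
    window: int = 80
    identity_threshold: float = 35.0
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    evalue_k: float = 0.041
    evalue_lambda: float = 0.267

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 < self.identity_threshold < 100):
            raise ValueError("identity_threshold must be in (0, 100)")


@dataclass(frozen=True)
class ContiguousMatch:
    """A maximal identical substring shared by query and subject.

    Spans are 1-based inclusive on both sequences; the match cannot be
    extended by one identical residue on either side.
    """

    peptide: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1

    def region_query(self) -> str:
        """Table-style span string in query coordinates, e.g. ``47GDGGVG52``."""
        return f"{self.query_start}{self.peptide}{self.query_end}"

    def region_subject(self) -> str:
        return f"{self.subject_start}{self.peptide}{self.subject_end}"


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment of query vs subject with derived statistics."""

    aligned_query: str
    aligned_subject: str
    score: float
    percent_identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    evalue: float

    @property
    def columns(self) -> int:
        return len(self.aligned_query)

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings differ in length")


@dataclass
class ScreenReportRow:
    """One allergen's comparison result (one row of the screen report)."""

    allergen_id: str
    description: str
    subject_length: int
    contiguous_matches: list[ContiguousMatch]
    best_window_identity: float
    full_identity: float
    evalue: float
    pd_value: float
    kmer_hit: bool
    window_hit: bool
    alignment: AlignmentResult = field(repr=False, default=None)


def _is_identity(a: str, b: str) -> bool:
    return a == b and a not in _WILDCARDS


def find_contiguous_matches(query: str, subject: str, k: int = 6) -> list[ContiguousMatch]:
    """All maximal identical substrings of length >= k shared by two proteins.

    Walks every diagonal of the comparison matrix and reports each maximal
    run of identities; nested shorter matches are therefore never emitted.
    Results are sorted by query start, then subject start.  ``k`` longer
    than either sequence yields an empty list.
    """
    if not query or not subject:
        raise SequenceError("find_contiguous_matches requires non-empty sequences")
    if k < 1:
        raise ValueError("k must be >= 1")
    m, n = len(query), len(subject)
    matches: list[ContiguousMatch] = []
    for d in range(-(n - 1), m):  # diagonal offset = query_idx - subject_idx
        i = max(d, 0)
        j = i - d
        run = 0
        while i < m and j < n:
            if _is_identity(query[i], subject[j]):
                run += 1
            else:
                if run >= k:
                    matches.append(_make_match(query, i - run, j - run, run))
                run = 0
            i += 1
            j += 1
        if run >= k:
            matches.append(_make_match(query, i - run, j - run, run))
    matches.sort(key=lambda mt: (mt.query_start, mt.subject_start))
    return matches


def _make_match(query: str, qi0: int, sj0: int, run: int) -> ContiguousMatch:
    return ContiguousMatch(
        peptide=query[qi0 : qi0 + run],
        query_start=qi0 + 1,
        query_end=qi0 + run,
        subject_start=sj0 + 1,
        subject_end=sj0 + run,
    )


def _make_aligner(config: ScreenConfig) -> Align.PairwiseAligner:
    try:
        matrix = substitution_matrices.load(config.matrix)
    except FileNotFoundError as err:
        raise ValueError(f"unknown substitution matrix {config.matrix!r}") from err
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def align_pair(query: str, subject: str, config: ScreenConfig | None = None) -> AlignmentResult:
    """Optimal local alignment under the configured matrix and gap costs.

    Among equal-scoring optima the alignment with the smallest query start,
    then smallest subject start, is chosen (deterministic tie-break; at most
    32 co-optimal alignments are inspected).  Percent identity is computed
    over all aligned columns, gap columns included.
    """
    config = config or ScreenConfig()
    if not query or not subject:
        raise SequenceError("align_pair requires non-empty sequences")
    aligner = _make_aligner(config)
    alignments = aligner.align(query, subject)
    best = min(
        islice(alignments, 32),
        key=lambda al: (al.coordinates[0][0], al.coordinates[1][0]),
    )
    aligned_q, aligned_s = best[0], best[1]
    identities = sum(
        1 for a, b in zip(aligned_q, aligned_s) if a != "-" and _is_identity(a, b)
    )
    ncols = len(aligned_q)
    qspan = (int(best.coordinates[0][0]) + 1, int(best.coordinates[0][-1]))
    sspan = (int(best.coordinates[1][0]) + 1, int(best.coordinates[1][-1]))
    evalue = estimate_evalue(float(best.score), len(query), len(subject), config)
    return AlignmentResult(
        aligned_query=str(aligned_q),
        aligned_subject=str(aligned_s),
        score=float(best.score),
        percent_identity=100.0 * identities / ncols,
        query_span=qspan,
        subject_span=sspan,
        evalue=evalue,
    )


def window_identity_scan(
    alignment: AlignmentResult,
    window: int = 80,
    threshold: float = 35.0,
) -> tuple[float, bool, list[int]]:
    """Sliding-window identity over alignment columns.

    Returns ``(best_percent, window_hit, hit_window_starts)``.  Windows of
    ``window`` columns slide in steps of one; per-window identity is
    ``100 * identities / window``.  The flag is true iff some window
    *strictly* exceeds ``threshold``.  An alignment shorter than the window
    is scored as a single window whose denominator is the column count.
    Hit starts are 1-based column offsets.
    """
    cols = [
        a != "-" and _is_identity(a, b)
        for a, b in zip(alignment.aligned_query, alignment.aligned_subject)
    ]
    n = len(cols)
    if n <= window:
        pct = 100.0 * sum(cols) / n
        hit = pct > threshold
        return pct, hit, [1] if hit else []
    best = -1.0
    hits: list[int] = []
    count = sum(cols[:window])
    for start in range(n - window + 1):
        if start > 0:
            count += cols[start + window - 1] - cols[start - 1]
        pct = 100.0 * count / window
        if pct > best:
            best = pct
        if pct > threshold:
            hits.append(start + 1)
    return best, bool(hits), hits


def estimate_evalue(score: float, query_len: int, subject_len: int, config: ScreenConfig | None = None) -> float:
    """Karlin–Altschul expected number of alignments: E = K·m·n·exp(-λ·S)."""
    config = config or ScreenConfig()
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return config.evalue_k * query_len * subject_len * exp(-config.evalue_lambda * score)


def screen(
    query: SequenceRecord,
    panel: Sequence[SequenceRecord],
    config: ScreenConfig | None = None,
    descriptor_table=None,
) -> list[ScreenReportRow]:
    """Run both FAO/WHO criteria for the query against every panel member.

    One report row per panel member, sorted by ascending E-value.  The PD
    column is the property distance over the gap-free aligned columns (see
    :mod:`allerscreen.pd_metric`).
    """
    from .pd_metric import load_descriptor_table, pd_best_window

    config = config or ScreenConfig()
    if query.alphabet != "protein":
        raise SequenceError("screen requires a protein query")
    if not panel:
        raise SequenceError("screen requires a non-empty panel")
    table = descriptor_table or load_descriptor_table()
    rows = []
    for subject in panel:
        matches = find_contiguous_matches(query.residues, subject.residues, config.k)
        alignment = align_pair(query.residues, subject.residues, config)
        best_pct, window_hit, _ = window_identity_scan(
            alignment, config.window, config.identity_threshold
        )
        pd_res = pd_best_window(alignment, table)
        rows.append(
            ScreenReportRow(
                allergen_id=subject.id,
                description=subject.description,
                subject_length=len(subject),
                contiguous_matches=matches,
                best_window_identity=best_pct,
                full_identity=alignment.percent_identity,
                evalue=alignment.evalue,
                pd_value=pd_res.value,
                kmer_hit=bool(matches),
                window_hit=window_hit,
                alignment=alignment,
            )
        )
    rows.sort(key=lambda r: r.evalue)
    return rows


def report_frame(rows: Sequence[ScreenReportRow]) -> pd.DataFrame:
    """Tabular view of screen rows; matching regions are printed in both the
    query and the subject coordinate frame (``47GDGGVG52/38GDGGVG43``)."""
    return pd.DataFrame(
        {
            "allergen": [r.allergen_id for r in rows],
            "description": [r.description for r in rows],
            "length": [r.subject_length for r in rows],
            "matching_regions": [
                ";".join(
                    f"{m.region_query()}/{m.region_subject()}" for m in r.contiguous_matches
                )
                for r in rows
            ],
            "evalue": [r.evalue for r in rows],
            "pd": [r.pd_value for r in rows],
            "alignment_span": [
                f"{r.alignment.query_span[0]}-{r.alignment.query_span[1]}" for r in rows
            ],
            "identity_pct": [r.full_identity for r in rows],
            "best_window_identity_pct": [r.best_window_identity for r in rows],
            "kmer_hit": [r.kmer_hit for r in rows],
            "window_hit": [r.window_hit for r in rows],
        }
    )


def write_report(rows: Sequence[ScreenReportRow], path: str | Path) -> None:
    report_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
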