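"""Property-distance (PD) index over the five-descriptor amino-acid space.

Each of the 20 standard amino acids is a point in a five-dimensional space
of descriptors E1-E5 obtained by multidimensional scaling of 237
physicochemical properties.  The PD between two equal-length peptides A, B is
the eigenvalue-weighted Euclidean distance

    PD = sqrt( sum_i sum_j  lambda_j * (E_j(A_i) - E_j(B_i))^2 )

summed over positions i and descriptor components j.  Identical peptides
score 0; PD is a metric on fixed-length peptide space.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import sqrt
from pathlib import Path

import numpy as np

from .seq_core import SequenceError

_DEFAULT_RESOURCE = "aa_descriptors_e1e5.tsv"


@dataclass(frozen=True)
class DescriptorTable:
    """The E1-E5 descriptor components and eigenvalue weights.

    ``values`` maps each of the 20 standard one-letter codes to a 5-vector;
    ``eigenvalues`` is the decreasing non-negative weight vector
    (lambda1..lambda5); ``version`` records the provenance tag of the data
    file and is carried into every PD result.
    """

    values: dict[str, tuple[float, ...]]
    eigenvalues: tuple[float, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if sorted(self.values) != sorted("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("descriptor table must cover exactly the 20 standard amino acids")
        for aa, vec in self.values.items():
            if len(vec) != 5 or not all(np.isfinite(vec)):
                raise ValueError(f"descriptor row for {aa!r} must be 5 finite values")
        lam = self.eigenvalues
        if len(lam) != 5 or any(not np.isfinite(x) for x in lam):
            raise ValueError("eigenvalues must be 5 finite values")
        if any(lam[i] < lam[i + 1] for i in range(4)) or lam[-1] < 0:
            raise ValueError("eigenvalues must satisfy l1 >= ... >= l5 >= 0")

    def vector(self, aa: str) -> np.ndarray:
        try:
            return np.asarray(self.values[aa])
        except KeyError:
            raise SequenceError(f"residue {aa!r} not in descriptor table") from None

    def scaled(self, c2: float) -> "DescriptorTable":
        """Table with all eigenvalues multiplied by ``c2`` (scaling checks)."""
        return DescriptorTable(
            values=self.values,
            eigenvalues=tuple(c2 * l for l in self.eigenvalues),
            version=self.version + f"*lam x{c2:g}",
        )


@dataclass(frozen=True)
class PDResult:
    """A PD value, the peptide length it covers, and the table version."""

    value: float
    length: int
    table_version: str
    window_value: float | None = None
    window_start: int | None = None


def load_descriptor_table(path: str | Path | None = None) -> DescriptorTable:
    """Load the descriptor table from ``path`` or the packaged default.

    File format: tab-separated, ``#`` comment lines (a ``# version:`` comment
    sets the version tag), 20 rows ``aa E1..E5`` and one ``lambda`` row.
    """
    if path is None:
        text = (
            resources.files("allerscreen").joinpath("data", _DEFAULT_RESOURCE).read_text()
        )
    else:
        text = Path(path).read_text()
    values: dict[str, tuple[float, ...]] = {}
    eigenvalues: tuple[float, ...] | None = None
    version = "unversioned"
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "version:" in line:
                version = line.split("version:", 1)[1].strip()
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ValueError(f"malformed descriptor line: {line!r}")
        key, nums = fields[0], tuple(float(x) for x in fields[1:])
        if key == "lambda":
            eigenvalues = nums
        else:
            values[key] = nums
    if eigenvalues is None:
        raise ValueError("descriptor table has no lambda row")
    return DescriptorTable(values=values, eigenvalues=eigenvalues, version=version)


def pd_peptides(a: str, b: str, table: DescriptorTable | None = None, normalize: bool = False) -> PDResult:
    """PD between two equal-length gap-free peptides.

    ``normalize=True`` divides the summed squared distance by the peptide
    length before the square root (a per-residue variant useful when
    comparing peptides of different lengths across reports; the plain
    definition applies no length normalisation).
    """
    table = table or load_descriptor_table()
    if len(a) != len(b):
        raise SequenceError(f"peptides differ in length ({len(a)} vs {len(b)})")
    if not a:
        raise SequenceError("empty peptides")
    total = 0.0
    lam = np.asarray(table.eigenvalues)
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            raise SequenceError("gap symbols are not allowed in pd_peptides")
        diff = table.vector(x) - table.vector(y)
        total += float(np.dot(lam, diff * diff))
    if normalize:
        total /= len(a)
    return PDResult(value=sqrt(total), length=len(a), table_version=table.version)


def pd_best_window(
    alignment,
    table: DescriptorTable | None = None,
    window: int | None = None,
    normalize: bool = False,
) -> PDResult:
    """PD over the gap-free columns of an alignment.

    Gap columns are dropped (PD is undefined on gaps).  The returned
    ``value`` covers all gap-free columns; ``window_value``/``window_start``
    give the minimum PD over contiguous gap-free windows of ``window``
    residues (default: the full gap-free length, so both values coincide).
    ``window_start`` is the 1-based index into the gap-free column list.
    """
    table = table or load_descriptor_table()
    pairs = [
        (a, b)
        for a, b in zip(alignment.aligned_query, alignment.aligned_subject)
        if a != "-" and b != "-"
    ]
    if not pairs:
        raise SequenceError("alignment has no gap-free columns")
    qa = "".join(p[0] for p in pairs)
    sa = "".join(p[1] for p in pairs)
    whole = pd_peptides(qa, sa, table, normalize=normalize)
    n = len(pairs)
    w = n if window is None else min(window, n)
    lam = np.asarray(table.eigenvalues)
    terms = np.array(
        [float(np.dot(lam, (table.vector(a) - table.vector(b)) ** 2)) for a, b in pairs]
    )
    csum = np.concatenate([[0.0], np.cumsum(terms)])
    window_sums = csum[w:] - csum[:-w]
    best_idx = int(np.argmin(window_sums))
    best = float(window_sums[best_idx])
    if normalize:
        best /= w
    return PDResult(
        value=whole.value,
        length=n,
        table_version=table.version,
        window_value=sqrt(best),
        window_start=best_idx + 1,
    )
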