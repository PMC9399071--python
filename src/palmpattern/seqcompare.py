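"""Pairwise comparison of aligned nucleotide sequences.

Given a pre-aligned pair, the comparison enumerates the overlap (columns
where both sequences carry an unambiguous A/C/G/T), catalogues every
difference with its transition/transversion class, reports percent identity
over the overlap, and computes the Kimura 2-parameter (K2P) distance

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

where P and Q are the transition and transversion proportions over the
overlap.  No alignment is performed here; gaps, Ns and IUPAC ambiguity codes
are simply excluded from the overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .morpho import round_half_up

__all__ = [
    "AlignedPair",
    "DifferenceRecord",
    "IdentityResult",
    "SequenceFormatError",
    "SaturationError",
    "read_fasta_pair",
    "compare_aligned",
    "k2p_distance",
    "format_report",
]

_UNAMBIGUOUS = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SequenceFormatError(ValueError):
    """Input does not form a valid aligned pair."""


class SaturationError(ValueError):
    """Substitution proportions outside the K2P log domain."""


@dataclass(frozen=True)
class AlignedPair:
    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise SequenceFormatError(
                f"aligned sequences differ in length: {len(self.seq_a)} vs {len(self.seq_b)}"
            )
        if not self.seq_a:
            raise SequenceFormatError("empty alignment")
        object.__setattr__(self, "seq_a", self.seq_a.upper())
        object.__setattr__(self, "seq_b", self.seq_b.upper())


@dataclass(frozen=True)
class DifferenceRecord:
    position: int  # 1-based within the compared overlap
    base_a: str
    base_b: str
    klass: str  # "transition" | "transversion"


@dataclass(frozen=True)
class IdentityResult:
    overlap_length: int
    n_diff: int
    percent_identity: float
    differences: tuple[DifferenceRecord, ...]
    P: float  # transition proportion over overlap
    Q: float  # transversion proportion over overlap

    @property
    def n_transitions(self) -> int:
        return sum(1 for d in self.differences if d.klass == "transition")

    @property
    def n_transversions(self) -> int:
        return sum(1 for d in self.differences if d.klass == "transversion")

    def to_dict(self) -> dict[str, object]:
        return {
            "overlap_length": self.overlap_length,
            "n_diff": self.n_diff,
            "percent_identity": self.percent_identity,
            "transitions": self.n_transitions,
            "transversions": self.n_transversions,
            "P": self.P,
            "Q": self.Q,
            "differences": [
                {"position": d.position, "base_a": d.base_a, "base_b": d.base_b, "class": d.klass}
                for d in self.differences
            ],
        }


def read_fasta_pair(path: str | Path) -> AlignedPair:
    """Read exactly two equal-length records from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise SequenceFormatError(f"{path}: expected exactly 2 records, found {len(records)}")
    a, b = records
    if len(a.seq) != len(b.seq):
        raise SequenceFormatError(
            f"{path}: records differ in length ({len(a.seq)} vs {len(b.seq)}); "
            "inputs must be pre-aligned"
        )
    return AlignedPair(id_a=a.id, id_b=b.id, seq_a=str(a.seq), seq_b=str(b.seq))


def classify_substitution(base_a: str, base_b: str) -> str:
    """A<->G and C<->T are transitions; every other unordered pair a transversion."""
    if {base_a, base_b} <= _PURINES or {base_a, base_b} <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def compare_aligned(pair: AlignedPair) -> IdentityResult:
    """Enumerate differences over the unambiguous overlap of an aligned pair.

    Overlap columns are those where both bases are in {A, C, G, T}; gap
    characters, N and IUPAC ambiguity codes are excluded.  Difference
    positions are 1-based indices counted *within the overlap*.
    """
    overlap = 0
    differences: list[DifferenceRecord] = []
    for a, b in zip(pair.seq_a, pair.seq_b):
        if a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS:
            continue
        overlap += 1
        if a != b:
            differences.append(
                DifferenceRecord(
                    position=overlap,
                    base_a=a,
                    base_b=b,
                    klass=classify_substitution(a, b),
                )
            )
    if overlap == 0:
        raise SequenceFormatError("no unambiguous overlap between the sequences")
    n_diff = len(differences)
    transitions = sum(1 for d in differences if d.klass == "transition")
    return IdentityResult(
        overlap_length=overlap,
        n_diff=n_diff,
        percent_identity=round_half_up(100.0 * (overlap - n_diff) / overlap, 1),
        differences=tuple(differences),
        P=transitions / overlap,
        Q=(n_diff - transitions) / overlap,
    )


def k2p_distance(result: IdentityResult | None = None, P: float | None = None, Q: float | None = None) -> float:
    """Kimura 2-parameter distance in substitutions per site.

    Accepts either an :class:`IdentityResult` or explicit proportions ``P``
    (transitions) and ``Q`` (transversions).  Raises :class:`SaturationError`
    when the proportions leave the domain of the logarithms
    (``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``).
    """
    if result is not None:
        P, Q = result.P, result.Q
    if P is None or Q is None:
        raise ValueError("provide an IdentityResult or both P and Q")
    if P < 0 or Q < 0:
        raise ValueError("proportions must be non-negative")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitution proportions saturated (1-2P-Q={w1:.4g}, 1-2Q={w2:.4g})"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def format_report(pair: AlignedPair, result: IdentityResult) -> str:
    """Plain-text comparison table."""
    lines = [
        f"sequences: {pair.id_a} vs {pair.id_b}",
        f"overlap: {result.overlap_length} bp",
        f"differences: {result.n_diff} "
        f"({result.n_transitions} transitions, {result.n_transversions} transversions)",
        f"identity: {result.percent_identity}%",
    ]
    try:
        lines.append(f"K2P distance: {k2p_distance(result):.6f} substitutions/site")
    except SaturationError:
        lines.append("K2P distance: saturated (not computable)")
    if result.differences:
        lines.append(f"{'pos':>6}  {pair.id_a[:12]:<12} {pair.id_b[:12]:<12} class")
        for d in result.differences:
            lines.append(f"{d.position:>6}  {d.base_a:<12} {d.base_b:<12} {d.klass}")
    return "\n".join(lines)
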