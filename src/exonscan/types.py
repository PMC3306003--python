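"""Core value types shared across the package.

Coordinates are 1-based inclusive throughout (the convention exon
positions are printed in GenBank-style annotation); BED's 0-based
half-open records are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_ALPHABET = frozenset("ACGTN")


@dataclass
class NucleotideSequence:
    """A DNA sequence over the alphabet {A, C, G, T, N}.

    Residues are normalised on construction: uppercased, with any
    character outside {A, C, G, T} mapped to N.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = normalize_residues(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(residues: str) -> str:
    """Uppercase and map everything outside {A,C,G,T} to N."""
    up = residues.upper()
    if set(up) <= VALID_ALPHABET:
        return up
    return "".join(c if c in "ACGT" else "N" for c in up)


@dataclass
class ExonAnnotation:
    """Coding intervals on one sequence, 1-based inclusive, sorted and merged.

    Strand is accepted by the readers but ignored: the detector measures
    period-3 energy on the given strand only, which is strand-symmetric
    at the level of a binary indicator decomposition.
    """

    sequence_id: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if end < start:
                raise ValueError(f"interval end < start: ({start}, {end})")
            if start < 1:
                raise ValueError(f"interval start must be >= 1, got {start}")
        self.intervals = merge_intervals(self.intervals)

    def total_bases(self) -> int:
        return sum(end - start + 1 for start, end in self.intervals)

    def mask(self, length: int) -> np.ndarray:
        """Boolean per-base vector of length `length`; True inside exons."""
        m = np.zeros(length, dtype=bool)
        for start, end in self.intervals:
            if end > length:
                raise ValueError(
                    f"interval ({start}, {end}) exceeds sequence length {length}"
                )
            m[start - 1 : end] = True
        return m


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort 1-based inclusive intervals and merge overlapping ones.

    Abutting-but-disjoint intervals are kept separate so that valid
    BED/GFF3 records round-trip unchanged.
    """
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


@dataclass
class ScoreTrack:
    """Per-base period-3 energy M[j] aligned to sequence coordinates.

    ``values[i]`` is the score of the base at 1-based position
    ``offset + i``; the scoring pipeline produces tracks with
    ``offset == 1`` and one value per base (window-centre alignment is
    applied internally, so no residual shift remains).
    """

    sequence_id: str
    values: np.ndarray
    offset: int = 1
    window_length: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if self.offset < 1:
            raise ValueError("offset is a 1-based position and must be >= 1")

    def __len__(self) -> int:
        return len(self.values)
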