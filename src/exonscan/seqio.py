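"""Readers and writers for the formats the tool touches.

FASTA in, BED/GFF3 truth annotations in (both normalised to 1-based
inclusive coordinates), bedGraph score tracks out.  Interval merging and
coordinate conversion live here so the rest of the package only ever
sees the internal convention.
"""

from __future__ import annotations

import os
from collections import OrderedDict
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .types import ExonAnnotation, NucleotideSequence, ScoreTrack


class FormatError(ValueError):
    """A file failed to parse; the message names the offending line."""


def read_fasta(path: str | os.PathLike) -> list[NucleotideSequence]:
    """Read all records of a FASTA file.

    Residues are uppercased; characters outside {A,C,G,T} become N.
    Raises FileNotFoundError for a missing file and FormatError (with a
    line number) for an empty file or a malformed header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_fasta_layout(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(NucleotideSequence(id=rec.id, residues=str(rec.seq)))
    return records


def _validate_fasta_layout(path: Path) -> None:
    saw_content = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not saw_content and not stripped.startswith(">"):
                raise FormatError(
                    f"{path}:{lineno}: expected FASTA header starting with '>', "
                    f"got {stripped[:30]!r}"
                )
            if stripped.startswith(">") and len(stripped) == 1:
                raise FormatError(f"{path}:{lineno}: FASTA header has no identifier")
            saw_content = True
    if not saw_content:
        raise FormatError(f"{path}:1: empty FASTA file")


def write_fasta(records: Iterable[NucleotideSequence], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_annotations(path: str | os.PathLike, dialect: str = "bed") -> list[ExonAnnotation]:
    """Read exon truth intervals from a BED or GFF3 file.

    BED records (0-based, half-open) and GFF3 records (1-based,
    inclusive) are both converted to 1-based inclusive coordinates;
    overlapping intervals on the same sequence are merged.  Strand
    columns are read and ignored.
    """
    dialect = dialect.lower()
    if dialect not in {"bed", "gff3", "gff"}:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    per_seq: "OrderedDict[str, list[tuple[int, int]]]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed":
                    seq_id = fields[0]
                    start = int(fields[1]) + 1  # 0-based half-open -> 1-based inclusive
                    end = int(fields[2])
                else:
                    seq_id = fields[0]
                    start = int(fields[3])
                    end = int(fields[4])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed {dialect} record") from exc
            if end < start:
                raise FormatError(
                    f"{path}:{lineno}: interval end {end} < start {start}"
                )
            per_seq.setdefault(seq_id, []).append((start, end))
    return [ExonAnnotation(sequence_id=s, intervals=iv) for s, iv in per_seq.items()]


def write_annotations(annotations: Iterable[ExonAnnotation], path: str | os.PathLike,
                      dialect: str = "bed") -> None:
    """Write annotations as BED (0-based half-open) or GFF3 (1-based inclusive)."""
    dialect = dialect.lower()
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        for ann in annotations:
            for start, end in ann.intervals:
                if dialect == "bed":
                    fh.write(f"{ann.sequence_id}\t{start - 1}\t{end}\n")
                elif dialect in {"gff3", "gff"}:
                    fh.write(
                        f"{ann.sequence_id}\texonscan\texon\t{start}\t{end}\t.\t+\t.\t.\n"
                    )
                else:
                    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def write_score_track(track: ScoreTrack, path: str | os.PathLike,
                      header_lines: Iterable[str] = (), mode: str = "w") -> None:
    """Write a score track as bedGraph (0-based half-open runs).

    Consecutive equal values are collapsed into one run.  Values are
    printed with repr precision so a write/read round-trip is exact.
    """
    with open(path, mode) as fh:
        if mode == "w":
            for line in header_lines:
                fh.write(f"#{line}\n")
            fh.write("track type=bedGraph\n")
        _write_track_runs(fh, track)


def _write_track_runs(fh, track: ScoreTrack) -> None:
    vals = track.values
    n = len(vals)
    i = 0
    base0 = track.offset - 1  # 0-based coordinate of values[0]
    while i < n:
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        fh.write(f"{track.sequence_id}\t{base0 + i}\t{base0 + j + 1}\t{float(vals[i])!r}\n")
        i = j + 1


def read_score_track(path: str | os.PathLike) -> list[ScoreTrack]:
    """Read bedGraph back into per-sequence ScoreTracks (inverse of the writer)."""
    per_seq: "OrderedDict[str, list[tuple[int, int, float]]]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                seq_id, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph record") from exc
            per_seq.setdefault(seq_id, []).append((start, end, value))
    tracks = []
    for seq_id, runs in per_seq.items():
        runs.sort(key=lambda r: r[0])
        first = runs[0][0]
        last = runs[-1][1]
        vals = np.zeros(last - first, dtype=np.float64)
        for start, end, value in runs:
            vals[start - first : end - first] = value
        tracks.append(ScoreTrack(sequence_id=seq_id, values=vals, offset=first + 1))
    return tracks
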