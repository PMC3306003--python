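"""Synthetic genomes with codon-biased exons and near-i.i.d. introns.

Coding DNA carries a period-3 statistical signal because codon usage is
non-uniform: over-represented codons repeat the same base at the same
position of consecutive triplets.  The generator reproduces exactly
that mechanism — exon segments are concatenated codons drawn from a
biased codon table (by default the GCN alanine family is weighted 8x,
so G and C dominate the first and second codon positions), while intron
segments are i.i.d. (or optionally first-order Markov) nucleotides with
no triplet structure.  Splice sites, GC isochores and repeats are not
modelled, so detection results here bound only the period-3 signal
itself, not real-genome confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .types import ExonAnnotation, NucleotideSequence

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)


def default_codon_weights(favoured: tuple[str, ...] = ("GCA", "GCC", "GCG", "GCT"),
                          favour: float = 8.0) -> dict[str, float]:
    """Sharply biased codon usage: `favour`-fold weight on the favoured codons."""
    return {c: (favour if c in favoured else 1.0) for c in SENSE_CODONS}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic genome.

    Exon lengths are forced to multiples of 3 (whole codons); exons are
    separated by at least one intron base.  All randomness derives from
    ``seed``.
    """

    n_sequences: int = 10
    sequence_length: int = 10_000
    exon_count_range: tuple[int, int] = (3, 6)
    exon_length_range: tuple[int, int] = (120, 450)
    codon_weights: dict[str, float] = field(default_factory=default_codon_weights)
    intron_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    intron_markov: np.ndarray | None = None  # optional 4x4 transition matrix (ACGT order)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.sequence_length < 1:
            raise ValueError("need at least one sequence of positive length")
        lo, hi = self.exon_count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid exon count range")
        llo, lhi = self.exon_length_range
        if llo < 3 or lhi < llo:
            raise ValueError("invalid exon length range")
        if not np.isclose(sum(self.intron_base_probs), 1.0):
            raise ValueError("intron base probabilities must sum to 1")
        total = sum(self.codon_weights.values())
        if total <= 0:
            raise ValueError("codon weights must have positive total mass")

    def codon_probs(self) -> tuple[tuple[str, ...], np.ndarray]:
        codons = tuple(self.codon_weights)
        w = np.array([self.codon_weights[c] for c in codons], dtype=np.float64)
        return codons, w / w.sum()


def _draw_exon_lengths(rng: np.random.Generator, spec: SyntheticSpec, count: int) -> list[int]:
    lo = -(-spec.exon_length_range[0] // 3)  # ceil to a codon boundary
    hi = spec.exon_length_range[1] // 3
    if hi < lo:
        raise ValueError("exon length range contains no multiple of 3")
    return [3 * int(rng.integers(lo, hi + 1)) for _ in range(count)]


def _place_exons(rng: np.random.Generator, length: int, exon_lengths: list[int]) -> list[tuple[int, int]]:
    """Place exons left to right with >= 1 intron base between and around them."""
    k = len(exon_lengths)
    if k == 0:
        return []
    slack = length - sum(exon_lengths) - (k + 1)
    if slack < 0:
        raise ValueError("exon lengths cannot fit in sequence_length")
    # distribute the slack over the k+1 gaps uniformly at random
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    extra = np.diff(np.concatenate([[0], cuts, [slack]]))
    intervals = []
    pos = 1 + 1 + int(extra[0])  # 1-based start after the leading gap (>= 1 base)
    for exon_len, gap_extra in zip(exon_lengths, extra[1:]):
        intervals.append((pos, pos + exon_len - 1))
        pos += exon_len + 1 + int(gap_extra)
    return intervals


def _intron_bases(rng: np.random.Generator, n: int, spec: SyntheticSpec) -> str:
    if n <= 0:
        return ""
    bases = np.array(list("ACGT"))
    if spec.intron_markov is None:
        return "".join(rng.choice(bases, size=n, p=np.asarray(spec.intron_base_probs)))
    p = np.asarray(spec.intron_markov, dtype=np.float64)
    out = [rng.choice(4, p=np.asarray(spec.intron_base_probs))]
    for _ in range(n - 1):
        out.append(rng.choice(4, p=p[out[-1]]))
    return "".join(bases[out])


def generate_genome(spec: SyntheticSpec) -> tuple[list[NucleotideSequence], list[ExonAnnotation]]:
    """Generate sequences and their exon annotations, deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    codons, probs = spec.codon_probs()
    codon_arr = np.array(codons)
    sequences, annotations = [], []
    for i in range(spec.n_sequences):
        count = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
        exon_lengths = _draw_exon_lengths(rng, spec, count)
        intervals = _place_exons(rng, spec.sequence_length, exon_lengths)
        parts = []
        cursor = 1
        for start, end in intervals:
            parts.append(_intron_bases(rng, start - cursor, spec))
            n_codons = (end - start + 1) // 3
            parts.append("".join(rng.choice(codon_arr, size=n_codons, p=probs)))
            cursor = end + 1
        parts.append(_intron_bases(rng, spec.sequence_length - cursor + 1, spec))
        seq_id = f"synth_{i}"
        sequences.append(NucleotideSequence(id=seq_id, residues="".join(parts)))
        annotations.append(ExonAnnotation(sequence_id=seq_id, intervals=intervals))
    return sequences, annotations


def generate_from_intervals(
    intervals: list[tuple[int, int]],
    sequence_length: int,
    codon_weights: dict[str, float] | None = None,
    intron_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    sequence_id: str = "synth_layout",
) -> tuple[NucleotideSequence, ExonAnnotation]:
    """Synthetic sequence with exons at explicitly given 1-based intervals.

    Useful for emulating the exon layout of a real gene: exon segments
    are codon runs truncated to the interval length (so intervals need
    not be codon multiples), introns are i.i.d. bases.
    """
    ann = ExonAnnotation(sequence_id=sequence_id, intervals=intervals)
    rng = np.random.default_rng(seed)
    weights = codon_weights or default_codon_weights()
    codons = tuple(weights)
    w = np.array([weights[c] for c in codons], dtype=np.float64)
    probs = w / w.sum()
    codon_arr = np.array(codons)
    spec = SyntheticSpec(sequence_length=sequence_length,
                         intron_base_probs=intron_base_probs, seed=seed)
    parts = []
    cursor = 1
    for start, end in ann.intervals:
        if end > sequence_length:
            raise ValueError("interval exceeds sequence length")
        parts.append(_intron_bases(rng, start - cursor, spec))
        n_bases = end - start + 1
        n_codons = -(-n_bases // 3)
        parts.append("".join(rng.choice(codon_arr, size=n_codons, p=probs))[:n_bases])
        cursor = end + 1
    parts.append(_intron_bases(rng, sequence_length - cursor + 1, spec))
    return NucleotideSequence(id=sequence_id, residues="".join(parts)), ann


#: exon layout of a canonical 8 kb five-exon test gene (1-based inclusive)
F56F11_LIKE_INTERVALS = [
    (928, 1039), (2528, 2857), (4114, 4377), (5465, 5644), (7255, 7605)
]


def periodic_template(period: int, n: int) -> np.ndarray:
    """A fixed deterministic periodic waveform of the given period."""
    base = np.cos(2 * np.pi * np.arange(period) / period) \
        + 0.5 * np.sin(2 * np.pi * np.arange(period) / period)
    return np.tile(base, -(-n // period))[:n]


def make_noisy_periodic(signal_period: int, n: int, noise_sd: float, seed: int) -> np.ndarray:
    """Fixed periodic template plus seeded i.i.d. Gaussian noise."""
    if n < signal_period:
        raise ValueError("length must be at least one period")
    if noise_sd < 0:
        raise ValueError("noise standard deviation must be non-negative")
    rng = np.random.default_rng(seed)
    return periodic_template(signal_period, n) + rng.normal(0.0, noise_sd, size=n)
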