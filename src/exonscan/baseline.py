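"""Sliding-window DFT spectral-content baseline.

The classic period-3 detector: over a window of length N_w (a multiple
of 3), evaluate each indicator channel's DFT coefficient at bin
k = N_w/3 and sum the four squared magnitudes,

    S[t] = sum_X | sum_{m=0}^{N_w-1} I_X[t+m] * e^{-i 2 pi m / 3} |^2 .

Because e^{-i 2 pi m / 3} only depends on m mod 3, the coefficient is a
function of three integer counts — the number of ones at window offsets
congruent to 0, 1 and 2 mod 3.  Both code paths here (direct per-window
counting and sliding prefix-sum updates) compute those integers exactly
and then evaluate the same float expression, so they are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encode import encode_indicators
from .types import NucleotideSequence, ScoreTrack

_W = np.exp(-2j * np.pi / 3.0)
_PHASES = np.array([1.0 + 0j, _W, _W * _W])


@dataclass
class DftWindowSpec:
    """Sliding DFT window: length in bases (multiple of 3) and step."""

    window_length: int = 351
    step: int = 1

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 3 != 0:
            raise ValueError("window length must be >= 3 and divisible by 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def _phase_counts_direct(channel: np.ndarray, start: int, length: int) -> np.ndarray:
    """Integer ones-count per window offset class (m mod 3), by direct slicing."""
    window = channel[start : start + length]
    return np.array(
        [int(window[p::3].sum()) for p in range(3)], dtype=np.int64
    )


def _coefficient_power(counts: np.ndarray) -> float:
    """|S0 + S1 w + S2 w^2|^2 from the integer phase counts."""
    coeff = complex(counts[0]) * _PHASES[0] + complex(counts[1]) * _PHASES[1] \
        + complex(counts[2]) * _PHASES[2]
    return float(coeff.real * coeff.real + coeff.imag * coeff.imag)


def window_s3(seq_or_channels, start: int, window_length: int) -> float:
    """Spectral content S of one window (sum of the four channel powers)."""
    channels = (
        encode_indicators(seq_or_channels).channels()
        if isinstance(seq_or_channels, (NucleotideSequence, str))
        else seq_or_channels
    )
    return sum(
        _coefficient_power(_phase_counts_direct(ch.astype(np.int64), start, window_length))
        for ch in channels.values()
    )


def dft_s3_track(
    seq: NucleotideSequence,
    spec: DftWindowSpec | None = None,
    method: str = "sliding",
) -> ScoreTrack:
    """Per-base DFT spectral-content track.

    The window slides in steps of ``spec.step``; each window's S value
    is assigned to the window-centre base and, for step > 1, held until
    the next evaluated window.  Bases not covered by any window centre
    (the half-window edges) are zero.  ``method`` selects the direct
    per-window counting path or the sliding prefix-sum path; the two
    are bit-identical.
    """
    spec = spec or DftWindowSpec()
    if method not in {"direct", "sliding"}:
        raise ValueError(f"unknown method {method!r}")
    n = len(seq)
    if n < spec.window_length:
        raise ValueError("sequence shorter than the DFT window")
    channels = {
        b: ch.astype(np.int64) for b, ch in encode_indicators(seq).channels().items()
    }
    nw = spec.window_length
    starts = np.arange(0, n - nw + 1, spec.step)
    powers = np.zeros(starts.size, dtype=np.float64)
    if method == "direct":
        for wi, t in enumerate(starts):
            powers[wi] = sum(
                _coefficient_power(_phase_counts_direct(ch, int(t), nw))
                for ch in channels.values()
            )
    else:
        for ch in channels.values():
            # prefix[r][i] = ones among positions < i congruent to r mod 3
            prefix = [np.concatenate([[0], np.cumsum(np.where(
                np.arange(n) % 3 == r, ch, 0))]) for r in range(3)]
            for wi, t in enumerate(starts):
                t = int(t)
                counts = np.array(
                    [prefix[(t + p) % 3][t + nw] - prefix[(t + p) % 3][t] for p in range(3)],
                    dtype=np.int64,
                )
                powers[wi] += _coefficient_power(counts)
    values = np.zeros(n, dtype=np.float64)
    centers = starts + nw // 2
    for wi in range(starts.size):
        lo = centers[wi]
        hi = centers[wi + 1] if wi + 1 < starts.size else centers[wi] + 1
        values[lo:hi] = powers[wi]
    return ScoreTrack(sequence_id=seq.id, values=values, offset=1, window_length=nw)
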