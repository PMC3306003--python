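"""Binary (Voss) indicator mapping of DNA sequences.

A sequence of length N becomes four binary vectors I_A, I_T, I_C, I_G;
I_X[n] is 1 exactly when the base at position n is X.  At every A/C/G/T
position the four channels sum to 1; at an N (ambiguous) position all
four are 0, so ambiguity contributes nothing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import NucleotideSequence

BASES = ("A", "T", "C", "G")


@dataclass
class IndicatorSet:
    """The four binary indicator channels of one sequence."""

    I_A: np.ndarray
    I_T: np.ndarray
    I_C: np.ndarray
    I_G: np.ndarray

    def channels(self) -> dict[str, np.ndarray]:
        return {"A": self.I_A, "T": self.I_T, "C": self.I_C, "G": self.I_G}

    def __len__(self) -> int:
        return len(self.I_A)


def encode_indicators(seq: NucleotideSequence | str) -> IndicatorSet:
    """Map a DNA sequence onto its four binary indicator vectors."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else \
        NucleotideSequence(id="", residues=seq).residues
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return IndicatorSet(
        I_A=(arr == ord("A")).astype(np.float64),
        I_T=(arr == ord("T")).astype(np.float64),
        I_C=(arr == ord("C")).astype(np.float64),
        I_G=(arr == ord("G")).astype(np.float64),
    )
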