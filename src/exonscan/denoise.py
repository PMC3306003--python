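"""Wavelet denoising of score tracks.

One (or more) levels of discrete wavelet decomposition split the track
into half-band approximation and detail coefficients; the detail bands
are discarded wholesale and the track is rebuilt from the approximation
alone.  The default basis is the discrete Meyer ("dmey") wavelet, whose
near-brick-wall half-band response suits removal of the high-frequency
ripple that survives the correlation stage.  No shrinkage thresholding
is applied — the detail band is zeroed, not attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .types import ScoreTrack


@dataclass
class WaveletSpec:
    """Wavelet denoising parameters.

    levels=1 is the default decomposition depth; ``boundary`` is the
    signal extension mode ("periodization" keeps coefficient counts
    halving exactly, so reconstruction to the original length is exact
    bookkeeping).
    """

    wavelet: str = "dmey"
    levels: int = 1
    boundary: str = "periodization"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("decomposition depth must be >= 1")
        if self.wavelet not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet name: {self.wavelet!r}")


def dwt_step(x: np.ndarray, wavelet: str = "dmey",
             boundary: str = "periodization") -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: returns (approximation, detail) half-band vectors.

    The approximation is the low-pass/downsample branch, the detail the
    high-pass/downsample branch; each holds about half the samples of x.
    """
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet name: {wavelet!r}")
    x = np.asarray(x, dtype=np.float64)
    approx, detail = pywt.dwt(x, wavelet, mode=boundary)
    return approx, detail


def idwt_step(approx: np.ndarray, detail: np.ndarray, wavelet: str = "dmey",
              boundary: str = "periodization") -> np.ndarray:
    """Inverse of :func:`dwt_step` (perfect reconstruction)."""
    return pywt.idwt(approx, detail, wavelet, mode=boundary)


def denoise_track(track: ScoreTrack, spec: WaveletSpec | None = None) -> ScoreTrack:
    """Remove the detail band(s) of a score track.

    Decomposes to ``spec.levels``, zeroes every detail coefficient
    vector, inverse-transforms, trims to the original length and clamps
    small negative reconstruction artefacts to zero (the track is an
    energy and must stay non-negative).  Offset and length are
    preserved so downstream per-base evaluation is unaffected.
    """
    spec = spec or WaveletSpec()
    w = pywt.Wavelet(spec.wavelet)
    n = len(track.values)
    if n < w.dec_len:
        raise ValueError(
            f"track of length {n} is shorter than the {spec.wavelet} support ({w.dec_len})"
        )
    coeffs = pywt.wavedec(track.values, w, mode=spec.boundary, level=spec.levels)
    coeffs = [coeffs[0]] + [np.zeros_like(d) for d in coeffs[1:]]
    rec = pywt.waverec(coeffs, w, mode=spec.boundary)
    if rec.size < n:
        rec = np.pad(rec, (0, n - rec.size))
    rec = np.clip(rec[:n], 0.0, None)
    return ScoreTrack(
        sequence_id=track.sequence_id,
        values=rec,
        offset=track.offset,
        window_length=track.window_length,
    )
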