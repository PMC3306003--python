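"""Run configuration: the tunable parameters of the whole pipeline.

Defaults are the method's canonical settings (FIR order 8, Hamming,
centre 2*pi/3; impulse train length 270, period 3; dmey wavelet at one
level; DFT baseline window 351).  A plain ``key = value`` text file can
override any field, and CLI flags override the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

from .baseline import DftWindowSpec
from .denoise import WaveletSpec
from .dsp import FilterSpec, ImpulseTrainSpec


@dataclass
class RunConfig:
    filter_order: int = 8
    filter_window: str = "hamming"
    center_freq: float = 2.0 * math.pi / 3.0
    half_bandwidth: float = 0.05
    window_length: int = 270  # impulse-train length L
    period: int = 3
    wavelet: str = "dmey"
    dwt_levels: int = 1
    dft_window: int = 351
    method: str = "xcorr"  # or "dft"
    use_dwt: bool = True
    min_exon_len: int = 0
    merge_gap: int = 0
    seed: int = 0

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            order=self.filter_order,
            window=self.filter_window,
            center_freq=self.center_freq,
            half_bandwidth=self.half_bandwidth,
        )

    def impulse_spec(self) -> ImpulseTrainSpec:
        return ImpulseTrainSpec(period=self.period, length=self.window_length)

    def wavelet_spec(self) -> WaveletSpec:
        return WaveletSpec(wavelet=self.wavelet, levels=self.dwt_levels)

    def dft_spec(self) -> DftWindowSpec:
        return DftWindowSpec(window_length=self.dft_window)

    def summary_items(self) -> list[str]:
        return [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]


def parse_freq(text: str | float) -> float:
    """Parse a centre frequency written as radians or as 'Npi/M' shorthand."""
    if isinstance(text, (int, float)):
        return float(text)
    t = text.strip().lower().replace(" ", "")
    if "pi" in t:
        head, _, tail = t.partition("pi")
        num = float(head) if head and head not in {"+", "-"} else (1.0 if head != "-" else -1.0)
        den = float(tail.lstrip("/")) if tail else 1.0
        return num * math.pi / den
    return float(t)


_FIELD_PARSERS = {
    "filter_order": int, "filter_window": str, "center_freq": parse_freq,
    "half_bandwidth": float, "window_length": int, "period": int,
    "wavelet": str, "dwt_levels": int, "dft_window": int, "method": str,
    "use_dwt": lambda s: str(s).strip().lower() in {"1", "true", "yes", "on"},
    "min_exon_len": int, "merge_gap": int, "seed": int,
}


def load_config(path: str | Path, base: RunConfig | None = None) -> RunConfig:
    """Read ``key = value`` lines (# comments allowed) over a base config."""
    cfg = base or RunConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _FIELD_PARSERS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        setattr(cfg, key, _FIELD_PARSERS[key](value.strip()))
    return cfg
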