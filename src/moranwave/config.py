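"""Analysis configuration: one JSON file driving a full workflow run."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .wavelets import WaveletConfig

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Paths, bands, wavelet parameters, surrogate counts, and the master seed.

    Bands are (low, high) intervals in years; they must be ordered and
    non-overlapping. The defaults split at 4 years: fluctuations slower
    than 4 years behave persistently year to year, faster ones
    anti-persistently, making 4 years a natural boundary for annual
    ecological data.
    """

    inputs: dict[str, str] = field(default_factory=dict)
    short_band: tuple[float, float] = (2.0, 4.0)
    long_band: tuple[float, float] = (4.0, 30.0)
    sigma_min: float = 2.0
    sigma_max: float | None = None
    spacing: float = 1.05
    f0: float = 1.0
    n_surrogates: int = 1000
    alpha: float = 0.05
    max_k: int = 5
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        self.short_band = tuple(self.short_band)  # type: ignore[assignment]
        self.long_band = tuple(self.long_band)  # type: ignore[assignment]
        for name, band in (("short_band", self.short_band), ("long_band", self.long_band)):
            if len(band) != 2 or not band[0] < band[1]:
                raise ValueError(f"{name} must be an increasing (low, high) pair; got {band}")
        if self.short_band[1] > self.long_band[0]:
            raise ValueError(
                f"bands overlap: short {self.short_band} vs long {self.long_band}"
            )
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha}")

    @property
    def wavelet(self) -> WaveletConfig:
        return WaveletConfig(self.sigma_min, self.sigma_max, self.spacing, self.f0)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))
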