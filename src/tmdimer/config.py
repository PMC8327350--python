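"""Run configuration: physical conditions and analysis settings.

The configuration captures the experimental conditions all analyses share
(temperature 318 K and detergent-to-protein ratio 80 for the micelle
titrations, water viscosity for the hydrodynamic sizing) plus the knobs
of the trajectory analysis.  Files are YAML with a JSON fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from tmdimer.sizing import DEFAULT_TEMPERATURE, WATER_VISCOSITY_318K
from tmdimer.trajectory import (DEFAULT_CONTACT_CUTOFF, DEFAULT_DIMER_CUTOFF,
                                DEFAULT_DWELL_FRAMES)


@dataclass
class RunConfig:
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE  # K
    viscosity: float = WATER_VISCOSITY_318K  # Pa s
    lpr: float = 80.0  # detergent-to-protein molar ratio
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF  # A
    dimer_cutoff: float = DEFAULT_DIMER_CUTOFF  # A
    dwell_frames: int = DEFAULT_DWELL_FRAMES
    #: (label, (azimuth_lo, azimuth_hi)) intervals in degrees, [0, 360),
    #: non-overlapping; a zero-width interval is the catch-all label.
    sector_definitions: list = field(default_factory=lambda: [
        ["facing", [300.0, 360.0]],
        ["opposed", [120.0, 180.0]],
        ["other", [0.0, 0.0]],
    ])
    bin_edges: list = field(default_factory=lambda: [
        0.0, 500.0, 1000.0, 1500.0, 2000.0, 3000.0, 6000.0])  # receptors/um^2
    ngf_mass_kda: float = 26.5
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if self.temperature <= 0 or self.viscosity <= 0:
            raise ValueError("temperature and viscosity must be positive")
        if self.contact_cutoff <= 0 or self.dimer_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.dwell_frames < 1:
            raise ValueError("dwell_frames must be >= 1")
        intervals = []
        for label, (lo, hi) in self.sector_definitions:
            if not (0 <= lo <= 360 and 0 <= hi <= 360):
                raise ValueError(f"sector {label}: azimuths must lie in [0, 360]")
            if lo < hi:
                intervals.append((lo, hi, label))
        intervals.sort()
        for (a_lo, a_hi, a_lab), (b_lo, b_hi, b_lab) in zip(intervals, intervals[1:]):
            if b_lo < a_hi:
                raise ValueError(f"sectors {a_lab} and {b_lab} overlap")
        edges = self.bin_edges
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin_edges must be strictly increasing")

    @property
    def sectors(self) -> list[tuple[str, tuple[float, float]]]:
        return [(label, tuple(iv)) for label, iv in self.sector_definitions]

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (JSON accepted as a fallback)."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
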