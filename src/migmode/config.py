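"""Analysis configuration.

All quantitative steps of the pipeline read their parameters from a single
:class:`AnalysisConfig`.  Defaults correspond to the acquisition and analysis
settings the toolbox was designed around: confocal time-lapse imaging at
0.21 µm/pixel and 5 min frame intervals, CMAC (cell–matrix adhesion complex)
segments larger than 0.05 µm², a 24-frame moving window for mean squared
displacement with the first 12 lags fitted, membrane-dynamics windows of
1–15 frames, and ±12-frame cross-correlation lags.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Parameters shared across the analysis pipeline.

    Parameters
    ----------
    pixel_size_um:
        Physical size of one pixel, µm.
    frame_interval_min:
        Time between consecutive frames, minutes.
    cmac_min_area_um2:
        CMAC observations with area less than or equal to this are discarded.
    msd_window_frames:
        Length of the moving window (frames) used for MSD profiles.
    msd_fit_lags:
        Number of leading time lags fitted to the Furth model; must not
        exceed half the MSD window.
    xcov_max_lag_frames:
        Maximum lag (frames) for protrusion–retraction cross-correlation.
    dynamics_windows:
        Time-window sizes (frames) over which membrane protrusion/retraction
        events are extracted.
    n_permutations:
        Number of permutations for correlation-difference null distributions.
    rng_seed:
        Seed for all stochastic steps (permutations, blinding, simulation).
    """

    pixel_size_um: float = 0.21
    frame_interval_min: float = 5.0
    cmac_min_area_um2: float = 0.05
    msd_window_frames: int = 24
    msd_fit_lags: int = 12
    xcov_max_lag_frames: int = 12
    dynamics_windows: tuple = field(default_factory=lambda: tuple(range(1, 16)))
    n_permutations: int = 100
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "frame_interval_min",
            "cmac_min_area_um2",
            "msd_window_frames",
            "msd_fit_lags",
            "xcov_max_lag_frames",
            "n_permutations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        self.dynamics_windows = tuple(int(w) for w in self.dynamics_windows)
        if any(w <= 0 for w in self.dynamics_windows):
            raise ValueError("dynamics_windows must all be positive")
        if self.msd_fit_lags > self.msd_window_frames / 2:
            raise ValueError(
                "msd_fit_lags must be at most half of msd_window_frames "
                f"({self.msd_fit_lags} > {self.msd_window_frames}/2)"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML or JSON file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = asdict(self)
        data["dynamics_windows"] = list(self.dynamics_windows)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data))
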