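"""Run configuration: one serializable object drives the whole pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .acquisition import DEFAULT_NOISE_SD
from .errors import InvalidInputError
from .interferometry import (
    DEFAULT_BAND_CENTERS,
    DEFAULT_BANDWIDTH,
    DEFAULT_N_POSITIONS,
    DEFAULT_PAD_FACTOR,
    DEFAULT_TRAVEL_CM,
    SUPPORT_THRESHOLD,
)
from .stitching import DEFAULT_ANCHORS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Fully resolved parameters of a simulation/analysis run."""

    # scene
    scene_kind: str = "blend"  # blend | hair
    shape: Tuple[int, int] = (62, 82)
    pixel_size_nm: float = 30.0
    # laser bands
    band_centers: Tuple[float, ...] = DEFAULT_BAND_CENTERS
    bandwidth_cm: float = DEFAULT_BANDWIDTH
    support_threshold: float = SUPPORT_THRESHOLD
    # interferometer
    n_positions: int = DEFAULT_N_POSITIONS
    travel_cm: float = DEFAULT_TRAVEL_CM
    pad_factor: int = DEFAULT_PAD_FACTOR
    apodization: Optional[str] = None
    # scan plan
    m: int = 2
    reposition: bool = True
    reference_row: int = 0
    t_spectrum_s: float = 1.66
    # disturbances
    noise_sd: float = DEFAULT_NOISE_SD
    stage_drift_nm_per_s: Tuple[float, float] = (0.0, 0.0)
    path_drift_cm: Tuple[float, ...] = (-2.0e-5, 0.0, 1.5e-5)
    # stitching / analysis
    anchors: Tuple[float, float] = DEFAULT_ANCHORS
    hca_range: Tuple[float, float] = (1000.0, 1850.0)
    n_clusters: int = 5
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scene_kind not in ("blend", "hair"):
            raise InvalidInputError(f"unknown scene kind {self.scene_kind!r}")
        if len(self.path_drift_cm) != len(self.band_centers):
            raise InvalidInputError("need one path drift per band")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("shape", "band_centers", "stage_drift_nm_per_s", "path_drift_cm",
                    "anchors", "hca_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    def config_hash(self) -> str:
        """Stable digest of the fully resolved configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
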