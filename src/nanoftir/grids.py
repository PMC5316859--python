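"""Uniform wavenumber grids (cm^-1)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["FrequencyGrid"]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class FrequencyGrid:
    """A strictly increasing, uniformly spaced wavenumber axis in cm^-1."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise InvalidInputError("frequency grid needs >= 2 points")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise InvalidInputError("frequency grid must be strictly increasing")
        step = steps[0]
        if np.any(np.abs(steps - step) > _REL_TOL * max(abs(step), 1.0) + 1e-12):
            raise InvalidInputError("frequency grid must be uniformly spaced")
        object.__setattr__(self, "values", values)

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "FrequencyGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @property
    def resolution(self) -> float:
        """Grid spacing in cm^-1."""
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=0, atol=1e-9
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((len(self.values), float(self.values[0]), float(self.values[-1])))

    def mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask selecting lo <= values <= hi."""
        if hi <= lo:
            raise InvalidInputError(f"empty range [{lo}, {hi}]")
        return (self.values >= lo) & (self.values <= hi)

    def index_of(self, value: float) -> int:
        """Index of the grid point nearest ``value``."""
        return int(np.argmin(np.abs(self.values - value)))
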