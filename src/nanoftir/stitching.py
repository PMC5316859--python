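"""Combine band-limited phase cubes into one broadband hyperspectral cube.

Per pixel: bands I and III are shifted by constant phase offsets (circular
means of the wrapped phase differences over the spectral overlap regions)
to match band II, the three spectra are multiplied by weight functions
forming a partition of unity over the union of band supports and summed,
and finally the linear baseline through two anchor frequencies is
subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .acquisition import BandCube
from .errors import GridMismatchError, InvalidInputError, UnsupportedBandConfigError
from .grids import FrequencyGrid

__all__ = [
    "OverlapRegion",
    "WeightFunctions",
    "BaselineAnchors",
    "HyperCube",
    "estimate_phase_offset",
    "correct_offsets",
    "build_weights",
    "stitch",
    "baseline_correct",
    "stitch_cubes",
]

DEFAULT_ANCHORS = (1030.0, 1870.0)


@dataclass(frozen=True)
class OverlapRegion:
    """Frequency interval where two band supports both hold."""

    band_pair: tuple
    lo: float
    hi: float

    def mask(self, grid: FrequencyGrid) -> np.ndarray:
        return grid.mask(self.lo, self.hi)


@dataclass(frozen=True)
class BaselineAnchors:
    """Two assumed absorption-free frequencies for baseline correction."""

    w1: float = DEFAULT_ANCHORS[0]
    w2: float = DEFAULT_ANCHORS[1]

    def __post_init__(self) -> None:
        if not self.w1 < self.w2:
            raise InvalidInputError("anchors must satisfy w1 < w2")


@dataclass
class WeightFunctions:
    """Stitching weights F^k on a common grid; partition of unity."""

    grid: FrequencyGrid
    weights: np.ndarray  # (n_bands, nf)
    band_ids: tuple

    @property
    def union_support(self) -> np.ndarray:
        return self.weights.sum(axis=0) > 0.5  # 1 on union, 0 outside


@dataclass
class HyperCube:
    """Stitched broadband phase cube phi(x, y, w) in degrees."""

    grid: FrequencyGrid
    phase: np.ndarray  # (ny, nx, nf)
    pixel_size: float = 30.0
    provenance: Dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.phase.shape[:2]


def _wrap_deg(x: np.ndarray) -> np.ndarray:
    """Wrap degrees to (-180, 180]."""
    return -((-np.asarray(x) + 180.0) % 360.0 - 180.0)


def _circular_mean_deg(diff: np.ndarray, axis=-1) -> np.ndarray:
    z = np.exp(1j * np.radians(diff)).mean(axis=axis)
    return np.degrees(np.angle(z))


def estimate_phase_offset(
    phase_a: np.ndarray,
    phase_b: np.ndarray,
    overlap_mask: np.ndarray,
) -> np.ndarray:
    """Circular mean of (phase_b - phase_a) over the overlap, in degrees.

    Works on single spectra (1-D) or cubes (..., nf); the mean is taken
    over the last axis restricted to ``overlap_mask``.
    """
    overlap_mask = np.asarray(overlap_mask, dtype=bool)
    if overlap_mask.sum() < 3:
        raise InvalidInputError("overlap must contain at least 3 grid points")
    diff = np.asarray(phase_b)[..., overlap_mask] - np.asarray(phase_a)[..., overlap_mask]
    return _circular_mean_deg(diff)


def _ordered(cubes: Sequence[BandCube]) -> list:
    cubes = sorted(cubes, key=lambda c: c.center)
    grid = cubes[0].grid
    for c in cubes[1:]:
        if c.grid != grid:
            raise GridMismatchError("band cubes must share the reconstruction grid")
    return cubes


def find_overlaps(cubes: Sequence[BandCube]) -> list:
    """Overlap regions of consecutive band supports (must be non-empty)."""
    cubes = _ordered(cubes)
    grid = cubes[0].grid
    out = []
    for a, b in zip(cubes, cubes[1:]):
        both = a.support & b.support
        if not both.any():
            raise InvalidInputError(
                f"bands {a.band_id} and {b.band_id} have no spectral overlap"
            )
        w = grid.values[both]
        out.append(OverlapRegion((a.band_id, b.band_id), float(w[0]), float(w[-1])))
    return out


def correct_offsets(cubes: Sequence[BandCube]) -> tuple:
    """Shift bands I and III per pixel to match band II in the overlaps.

    Returns ``(corrected_phases, offset_maps)`` where ``corrected_phases``
    is a list of per-band phase arrays (middle band unchanged) and
    ``offset_maps`` maps band_id -> applied per-pixel offset (degrees).
    """
    cubes = _ordered(cubes)
    if len(cubes) != 3:
        raise InvalidInputError("offset correction expects exactly three bands")
    lo_c, mid_c, hi_c = cubes
    overlaps = find_overlaps(cubes)
    grid = mid_c.grid
    mask_lo = overlaps[0].mask(grid) & lo_c.support & mid_c.support
    mask_hi = overlaps[1].mask(grid) & hi_c.support & mid_c.support
    d_lo = estimate_phase_offset(lo_c.phase, mid_c.phase, mask_lo)
    d_hi = estimate_phase_offset(hi_c.phase, mid_c.phase, mask_hi)
    phases = [
        lo_c.phase + d_lo[..., None],
        mid_c.phase.copy(),
        hi_c.phase + d_hi[..., None],
    ]
    offsets = {lo_c.band_id: d_lo, hi_c.band_id: d_hi}
    return phases, offsets


def build_weights(cubes: Sequence[BandCube]) -> WeightFunctions:
    """Linear-ramp partition of unity over the band supports.

    F^k is 1 on band k's exclusive support, ramps linearly across each
    pairwise overlap, and is 0 elsewhere.  A frequency covered by three
    supports is rejected (unsupported configuration).
    """
    cubes = _ordered(cubes)
    grid = cubes[0].grid
    supports = np.stack([c.support for c in cubes])
    coverage = supports.sum(axis=0)
    if np.any(coverage > 2):
        raise UnsupportedBandConfigError(
            "three band supports overlap at one frequency; reduce bandwidth or spacing"
        )
    weights = supports.astype(float)
    w = grid.values
    for a, b in zip(range(len(cubes)), range(1, len(cubes))):
        both = supports[a] & supports[b]
        if not both.any():
            continue
        lo = w[np.nonzero(supports[b])[0][0]]  # start of upper band's support
        hi = w[np.nonzero(supports[a])[0][-1]]  # end of lower band's support
        ramp_down = np.clip((hi - w) / (hi - lo), 0.0, 1.0)
        weights[a, both] = ramp_down[both]
        weights[b, both] = 1.0 - ramp_down[both]
    return WeightFunctions(grid=grid, weights=weights, band_ids=tuple(c.band_id for c in cubes))


def stitch(
    phases: Sequence[np.ndarray],
    weights: WeightFunctions,
    pixel_size: float = 30.0,
    provenance: Optional[Dict] = None,
) -> HyperCube:
    """Weighted sum of offset-corrected band phases, cropped to the union support."""
    union = weights.union_support
    total = np.zeros(phases[0].shape, dtype=float)
    for phi, wk in zip(phases, weights.weights):
        total += np.asarray(phi) * wk
    keep = np.nonzero(union)[0]
    sl = slice(int(keep[0]), int(keep[-1]) + 1)
    if not union[sl].all():
        raise InvalidInputError("union of band supports is not contiguous")
    return HyperCube(
        grid=FrequencyGrid(weights.grid.values[sl]),
        phase=total[..., sl],
        pixel_size=pixel_size,
        provenance=dict(provenance or {}),
    )


def _interp_at(grid: FrequencyGrid, data: np.ndarray, w0: float) -> np.ndarray:
    """Linear interpolation of (..., nf) data at frequency w0 (exact at nodes)."""
    v = grid.values
    if not (v[0] <= w0 <= v[-1]):
        raise InvalidInputError(f"anchor {w0} cm^-1 outside the spectral range")
    i = int(np.searchsorted(v, w0, side="right")) - 1
    i = min(max(i, 0), len(v) - 2)
    t = (w0 - v[i]) / (v[i + 1] - v[i])
    return data[..., i] * (1.0 - t) + data[..., i + 1] * t


def baseline_correct(obj, anchors: BaselineAnchors = BaselineAnchors()):
    """Subtract the linear baseline through the phase values at two anchors.

    Accepts a :class:`HyperCube` (returns a new cube with provenance) or a
    plain phase array with shape (..., nf) together with a grid via
    ``baseline_correct((grid, phase), anchors)``.
    """
    if isinstance(obj, HyperCube):
        corrected = _baseline_array(obj.grid, obj.phase, anchors)
        prov = dict(obj.provenance)
        prov["baseline_anchors"] = (anchors.w1, anchors.w2)
        return HyperCube(grid=obj.grid, phase=corrected, pixel_size=obj.pixel_size,
                         provenance=prov)
    grid, phase = obj
    return _baseline_array(grid, np.asarray(phase, dtype=float), anchors)


def _baseline_array(grid: FrequencyGrid, phase: np.ndarray, anchors: BaselineAnchors) -> np.ndarray:
    v1 = _interp_at(grid, phase, anchors.w1)
    v2 = _interp_at(grid, phase, anchors.w2)
    slope = (v2 - v1) / (anchors.w2 - anchors.w1)
    line = v1[..., None] + slope[..., None] * (grid.values - anchors.w1)
    return phase - line


def stitch_cubes(
    cubes: Sequence[BandCube],
    anchors: Optional[BaselineAnchors] = BaselineAnchors(),
    pixel_size: Optional[float] = None,
) -> HyperCube:
    """Full per-pixel pipeline: offset correction, weighting, stitch, baseline."""
    cubes = _ordered(cubes)
    phases, offsets = correct_offsets(cubes)
    weights = build_weights(cubes)
    prov = {f"offset_{bid}": off for bid, off in offsets.items()}
    hyper = stitch(phases, weights, pixel_size=pixel_size or 30.0, provenance=prov)
    if anchors is not None:
        hyper = baseline_correct(hyper, anchors)
    return hyper
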