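"""Asymmetric-Michelson interferogram model and Fourier reconstruction.

The detector record for one pixel and one laser setting is modelled as

    I(d_i) = Re[ sum_w E(w) * sigma(w) * exp(i*2*pi*w*(delta - u_i)) * dw ] + noise

with ``E`` the spectral power envelope of the laser, ``sigma`` the complex
response of the probed pixel, ``delta`` the relative path error between the
two interferometer arms and ``u_i`` the signed optical path difference of
sample ``i``.  The response ``sigma`` is causal, so its interferometric
signature decays away from zero path difference on one side only; the
mirror therefore scans that side, and the stored coordinate ``d_i`` (one
sided, starting at zero path difference) is the travel distance.  As in
standard FTIR practice a short segment on the far side of zero path
difference is also recorded so that the non-resonant centre burst is fully
captured; it occupies the final ``PRE_ZPD_FRACTION`` of the record
(wrap-around storage):  u_i = d_i for the main segment and u_i = d_i - D
(D = total travel) for the trailing segment.

Fourier transforming the record recovers ``E*sigma/2`` at positive
wavenumbers; amplitude and phase spectra follow after normalization to a
reference pixel, and a path error ``delta`` shifts the normalized phase by
``+360 * w * delta`` degrees.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GridMismatchError, InvalidInputError
from .grids import FrequencyGrid

__all__ = [
    "LaserEnvelope",
    "Interferogram",
    "ComplexSpectrum",
    "InterferometerState",
    "default_simulation_grid",
    "default_bands",
    "mirror_positions",
    "simulate_interferogram",
    "spectrum_from_interferogram",
    "phase_offset_from_path_drift",
    "path_drift_for_phase_offset",
]

#: fraction of the envelope maximum that defines the usable band support
SUPPORT_THRESHOLD = 0.2

#: reconstruction window in cm^-1 (spectra outside carry no laser power)
RECON_RANGE = (800.0, 2100.0)

#: default band centres (cm^-1); supports at the 20% threshold tile
#: ~1,000-1,900 cm^-1 with pairwise (I,II) and (II,III) overlaps only
DEFAULT_BAND_CENTERS = (1175.0, 1450.0, 1725.0)
DEFAULT_BANDWIDTH = 350.0

#: default one-sided mirror travel (cm); 1/travel = 35 cm^-1 resolution
DEFAULT_TRAVEL_CM = 1.0 / 35.0
DEFAULT_N_POSITIONS = 128
DEFAULT_PAD_FACTOR = 4

#: fraction of the record holding the short pre-ZPD segment (wrap-around)
PRE_ZPD_FRACTION = 0.15


def pre_zpd_samples(n: int) -> int:
    """Number of trailing samples recorded on the far side of ZPD."""
    return int(round(PRE_ZPD_FRACTION * n))


def signed_delays(positions: np.ndarray) -> np.ndarray:
    """Signed optical path differences u_i for a stored one-sided record."""
    positions = np.asarray(positions, dtype=float)
    n = positions.size
    period = n * (positions[1] - positions[0])
    n_pre = pre_zpd_samples(n)
    u = positions.copy()
    if n_pre:
        u[n - n_pre:] -= period
    return u


def default_simulation_grid() -> FrequencyGrid:
    """Dense wavenumber grid on which scenes and envelopes are defined."""
    return FrequencyGrid.regular(800.0, 2100.0, 2.0)


@dataclass(frozen=True)
class LaserEnvelope:
    """Non-negative spectral power envelope of one tunable laser setting."""

    band_id: str
    center: float
    effective_bandwidth: float
    grid: FrequencyGrid
    envelope: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        env = np.asarray(self.envelope, dtype=float)
        if env.shape != self.grid.values.shape:
            raise GridMismatchError("envelope and grid lengths differ")
        if np.any(env < 0) or env.max() <= 0:
            raise InvalidInputError("envelope must be >= 0 with positive maximum")
        object.__setattr__(self, "envelope", env)

    @classmethod
    def gaussian(
        cls,
        band_id: str,
        center: float,
        bandwidth: float,
        grid: FrequencyGrid,
        threshold: float = SUPPORT_THRESHOLD,
    ) -> "LaserEnvelope":
        """Gaussian envelope whose width at ``threshold*max`` equals ``bandwidth``."""
        sigma = bandwidth / (2.0 * np.sqrt(2.0 * np.log(1.0 / threshold)))
        env = np.exp(-0.5 * ((grid.values - center) / sigma) ** 2)
        return cls(band_id, center, bandwidth, grid, env)

    def support(self, threshold: float = SUPPORT_THRESHOLD) -> np.ndarray:
        """Boolean mask where the envelope exceeds ``threshold`` of its max."""
        return self.envelope >= threshold * self.envelope.max()

    def support_on(self, grid: FrequencyGrid, threshold: float = SUPPORT_THRESHOLD) -> np.ndarray:
        """Support mask resampled onto another grid."""
        env = np.interp(grid.values, self.grid.values, self.envelope, left=0.0, right=0.0)
        return env >= threshold * self.envelope.max()


def default_bands(
    grid: Optional[FrequencyGrid] = None,
    centers: Sequence[float] = DEFAULT_BAND_CENTERS,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> list[LaserEnvelope]:
    """The three standard laser settings I, II, III."""
    if grid is None:
        grid = default_simulation_grid()
    ids = ["I", "II", "III", "IV", "V"][: len(centers)]
    if len(centers) > 5:
        ids = list(string.ascii_uppercase[: len(centers)])
    return [
        LaserEnvelope.gaussian(band_id, float(c), bandwidth, grid)
        for band_id, c in zip(ids, centers)
    ]


@dataclass(frozen=True)
class InterferometerState:
    """Arm lengths and their relative drift (all in cm)."""

    L_R: float = 6.0
    L_t: float = 6.0
    drift: float = 0.0  # delta = dL_R - dL_t


@dataclass
class Interferogram:
    """One-sided detector record I(d) for a single pixel and band."""

    positions: np.ndarray  # optical path difference, cm, starting at 0
    values: np.ndarray
    band_id: str = ""
    meta: Optional[object] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 1 or pos.shape != val.shape:
            raise InvalidInputError("positions and values must be 1-D and equal length")
        if abs(pos[0]) > 1e-15:
            raise InvalidInputError("positions must start at zero path difference")
        steps = np.diff(pos)
        if np.any(steps <= 0) or np.any(np.abs(steps - steps[0]) > 1e-12 * steps[0] + 1e-18):
            raise InvalidInputError("positions must be uniformly increasing")
        if not np.all(np.isfinite(val)):
            raise InvalidInputError("interferogram values must be finite")
        self.positions = pos
        self.values = val

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class ComplexSpectrum:
    """Amplitude/phase spectrum on a uniform wavenumber grid.

    The complex values are kept so that normalization (complex division)
    stays exact; ``amplitude`` and ``phase`` (degrees) are views of them.
    """

    grid: FrequencyGrid
    values: np.ndarray  # complex
    nominal_resolution: Optional[float] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=complex)
        if values.shape != self.grid.values.shape:
            raise GridMismatchError("spectrum and grid lengths differ")
        self.values = values

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        """Phase in degrees, wrapped to (-180, 180]."""
        return np.degrees(np.angle(self.values))


def mirror_positions(
    n: int = DEFAULT_N_POSITIONS, travel: float = DEFAULT_TRAVEL_CM
) -> np.ndarray:
    """Uniform one-sided mirror path coordinates d_i = i * travel / n (cm)."""
    if n < 2 or travel <= 0:
        raise InvalidInputError("need n >= 2 positions and positive travel")
    return (travel / n) * np.arange(n)


def _interferogram_matrix(
    responses: np.ndarray,
    envelope: LaserEnvelope,
    positions: np.ndarray,
    path_drifts: np.ndarray,
) -> np.ndarray:
    """Noiseless records for a batch of responses; shape (n_resp, n_d).

    ``path_drifts`` is broadcast against the first axis of ``responses``.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=complex))
    w = envelope.grid.values
    dw = envelope.grid.resolution
    drifts = np.broadcast_to(np.asarray(path_drifts, dtype=float), (responses.shape[0],))
    weighted = responses * envelope.envelope * dw  # (n_resp, n_w)
    # a path error delta multiplies the weighted spectrum by exp(i*2*pi*w*delta)
    weighted = weighted * np.exp(2j * np.pi * np.outer(drifts, w))
    kernel = np.exp(-2j * np.pi * np.outer(w, signed_delays(positions)))  # (n_w, n_d)
    return np.real(weighted @ kernel)


def simulate_interferogram(
    response,
    envelope: LaserEnvelope,
    positions: np.ndarray,
    path_drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Interferogram:
    """Simulate one one-sided interferogram.

    Parameters
    ----------
    response
        Complex pixel response on the envelope's grid (array or an object
        with a ``response`` attribute, e.g. a ``ComponentSpectrum``).
    envelope
        Laser power spectrum.
    positions
        Uniform mirror-path coordinates in cm starting at 0.
    path_drift
        Relative arm-path error delta in cm; shifts the record along the
        path coordinate and the normalized phase by +360*w*delta degrees.
    noise_sd
        Standard deviation of additive Gaussian detector noise.
    """
    sigma = np.asarray(getattr(response, "response", response), dtype=complex)
    if sigma.shape != envelope.grid.values.shape:
        raise GridMismatchError("pixel response and envelope must share the grid")
    values = _interferogram_matrix(sigma, envelope, np.asarray(positions, float), path_drift)[0]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return Interferogram(positions=np.asarray(positions, float), values=values,
                         band_id=envelope.band_id)


def _apodization_window(n: int, step: float, apodization: Optional[str]) -> np.ndarray:
    if apodization is None or apodization == "none":
        return np.ones(n)
    if apodization == "half-hann":
        # falls from 1 at ZPD to 0 at the largest |optical path difference|
        u = np.abs(signed_delays(step * np.arange(n)))
        return 0.5 * (1.0 + np.cos(np.pi * u / u.max()))
    raise InvalidInputError(f"unknown apodization {apodization!r}")


def _fft_grid(n: int, step: float, pad_factor: int) -> tuple[np.ndarray, slice]:
    freqs = np.fft.rfftfreq(pad_factor * n, d=step)
    lo, hi = RECON_RANGE
    keep = np.nonzero((freqs >= lo) & (freqs <= hi))[0]
    return freqs, slice(int(keep[0]), int(keep[-1]) + 1)


def _spectra_from_records(
    records: np.ndarray,
    step: float,
    pad_factor: int = DEFAULT_PAD_FACTOR,
    apodization: Optional[str] = None,
) -> tuple[FrequencyGrid, np.ndarray]:
    """Batched FFT reconstruction; records shape (..., n_d)."""
    records = np.asarray(records, dtype=float)
    n = records.shape[-1]
    if pad_factor < 1:
        raise InvalidInputError("pad_factor must be >= 1")
    windowed = records * _apodization_window(n, step, apodization)
    # zero-pad between the main segment and the wrapped pre-ZPD segment so
    # the circular structure of the record is preserved
    n_pre = pre_zpd_samples(n)
    shape = records.shape[:-1] + (pad_factor * n,)
    padded = np.zeros(shape)
    padded[..., : n - n_pre] = windowed[..., : n - n_pre]
    if n_pre:
        padded[..., shape[-1] - n_pre:] = windowed[..., n - n_pre:]
    spectra = np.conj(np.fft.rfft(padded, axis=-1)) * step
    freqs, keep = _fft_grid(n, step, pad_factor)
    return FrequencyGrid(freqs[keep]), spectra[..., keep]


def spectrum_from_interferogram(
    interferogram: Interferogram,
    pad_factor: int = DEFAULT_PAD_FACTOR,
    apodization: Optional[str] = None,
) -> ComplexSpectrum:
    """Fourier transform of a one-sided record.

    Returns the complex spectrum on the zero-padded FFT grid restricted to
    800-2,100 cm^-1.  The nominal spectral resolution 1/(N*dd) (before
    padding) is reported on the result.
    """
    if interferogram.values.size < 64:
        raise InvalidInputError("need at least 64 interferogram samples")
    grid, values = _spectra_from_records(
        interferogram.values, interferogram.step, pad_factor, apodization
    )
    nominal = 1.0 / (interferogram.values.size * interferogram.step)
    return ComplexSpectrum(grid=grid, values=values, nominal_resolution=nominal)


def phase_offset_from_path_drift(nu: float, delta: float) -> float:
    """Phase offset in degrees produced by a relative arm-path error.

    Parameters
    ----------
    nu
        Wavenumber in cm^-1 at which the offset is evaluated.  The package
        convention for single-number quotes is nu = 1,660 cm^-1.
    delta
        Relative path error in cm (100 nm = 1e-5 cm).

    Returns
    -------
    float
        360 * nu * delta, the first-order phase of exp(i*2*pi*nu*delta).
    """
    if nu <= 0:
        raise InvalidInputError("wavenumber must be positive")
    return 360.0 * nu * delta


def path_drift_for_phase_offset(nu: float, offset_deg: float) -> float:
    """Inverse of :func:`phase_offset_from_path_drift`; returns delta in cm."""
    if nu <= 0:
        raise InvalidInputError("wavenumber must be positive")
    return offset_deg / (360.0 * nu)
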