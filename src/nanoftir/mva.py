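"""Multivariate analysis of hyperspectral phase cubes.

Distance maps against reference spectra, composite colour maps, D-value /
Ward hierarchical clustering, per-cluster statistics and non-negative
linear-superposition (unmixing) tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import lsq_linear
from scipy.spatial.distance import squareform

from .errors import InvalidInputError, UndefinedCorrelationError
from .grids import FrequencyGrid
from .stitching import HyperCube

__all__ = [
    "DistanceMap",
    "CompositeMap",
    "ClusterResult",
    "UnmixResult",
    "euclidean_distance_map",
    "composite_map",
    "d_value",
    "hca",
    "cluster_stats",
    "unmix",
    "superposition_test",
    "DEFAULT_HCA_RANGE",
]

DEFAULT_HCA_RANGE = (1000.0, 1850.0)

HUES = {
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
    "magenta": (1.0, 0.0, 1.0),
    "cyan": (0.0, 1.0, 1.0),
}

#: fixed palette for cluster maps (cl1.. in the documented order)
CLUSTER_PALETTE = (
    (0.12, 0.31, 0.85),  # blue
    (0.91, 0.46, 0.74),  # pink
    (0.18, 0.68, 0.25),  # green
    (0.86, 0.13, 0.13),  # red
    (0.25, 0.25, 0.25),  # dark grey
    (0.95, 0.70, 0.12),
    (0.10, 0.75, 0.75),
    (0.55, 0.30, 0.75),
)


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance to a named reference spectrum."""

    values: np.ndarray  # (ny, nx), >= 0
    reference_name: str
    analysis_range: tuple


@dataclass
class CompositeMap:
    """RGB image combining several distance maps, one hue each."""

    rgb: np.ndarray  # (ny, nx, 3) in [0, 1]
    hues: tuple


@dataclass
class ClusterResult:
    """Hierarchical-clustering segmentation with per-cluster statistics."""

    labels: np.ndarray  # (ny, nx) int; 1..K, 0 = excluded pixels
    linkage: np.ndarray  # scipy linkage matrix (merge heights non-decreasing)
    mean_spectra: Dict[int, np.ndarray]
    sd_spectra: Dict[int, np.ndarray]
    analysis_range: tuple

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


@dataclass
class UnmixResult:
    """Least-squares linear-superposition fit of reference spectra."""

    coefficients: np.ndarray  # per reference, >= 0 when nonneg
    offset: float
    residual_rms: float  # degrees
    r_squared: float
    condition_number: float
    ill_conditioned: bool = False
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def _cube_phase(cube: Union[HyperCube, np.ndarray]) -> Tuple[np.ndarray, Optional[FrequencyGrid]]:
    if isinstance(cube, HyperCube):
        return cube.phase, cube.grid
    return np.asarray(cube, dtype=float), None


def _range_mask(grid: Optional[FrequencyGrid], nf: int, rng: Optional[tuple]) -> np.ndarray:
    if rng is None or grid is None:
        return np.ones(nf, dtype=bool)
    mask = grid.mask(*rng)
    if not mask.any():
        raise InvalidInputError(f"analysis range {rng} selects no grid points")
    return mask


def euclidean_distance_map(
    cube: Union[HyperCube, np.ndarray],
    reference: np.ndarray,
    analysis_range: Optional[tuple] = None,
    reference_grid: Optional[FrequencyGrid] = None,
    name: str = "reference",
) -> DistanceMap:
    """sqrt(sum_w (phi - phi_ref)^2) per pixel over the analysis range."""
    phase, grid = _cube_phase(cube)
    reference = np.asarray(reference, dtype=float)
    if reference_grid is not None and grid is not None:
        reference = np.interp(grid.values, reference_grid.values, reference)
    if reference.shape[-1] != phase.shape[-1]:
        raise InvalidInputError("reference spectrum is not on the cube grid")
    mask = _range_mask(grid, phase.shape[-1], analysis_range)
    diff = phase[..., mask] - reference[mask]
    values = np.sqrt(np.sum(diff**2, axis=-1))
    lo, hi = (analysis_range if analysis_range else
              ((grid.values[0], grid.values[-1]) if grid else (0.0, float(phase.shape[-1]))))
    return DistanceMap(values=values, reference_name=name, analysis_range=(lo, hi))


def composite_map(
    distance_maps: Sequence[DistanceMap],
    hues: Sequence,
    clip_percentiles: tuple = (2.0, 98.0),
) -> CompositeMap:
    """Superpose distance maps as colour channels.

    Each map is converted to an intensity in [0, 1] through the monotone
    decreasing scaling ``1 - (D - p_lo) / (p_hi - p_lo)`` (percentile
    clipped), multiplied by its hue and summed; channels are clipped to
    [0, 1].  Small distance -> high colour intensity.
    """
    if len(distance_maps) < 2:
        raise InvalidInputError("composite map needs at least 2 distance maps")
    shape = distance_maps[0].values.shape
    rgb = np.zeros(shape + (3,))
    used = []
    for dm, hue in zip(distance_maps, hues):
        if dm.values.shape != shape:
            raise InvalidInputError("distance maps must share the image shape")
        colour = np.asarray(HUES[hue] if isinstance(hue, str) else hue, dtype=float)
        lo, hi = np.percentile(dm.values, clip_percentiles)
        if hi <= lo:
            intensity = np.ones(shape)
        else:
            intensity = 1.0 - np.clip((dm.values - lo) / (hi - lo), 0.0, 1.0)
        rgb += intensity[..., None] * colour
        used.append(tuple(colour))
    return CompositeMap(rgb=np.clip(rgb, 0.0, 1.0), hues=tuple(used))


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise UndefinedCorrelationError(
            "zero-variance spectrum in analysis range: Pearson correlation undefined"
        )
    return (x - mu) / sd


def d_value(
    spec_a: np.ndarray,
    spec_b: np.ndarray,
    grid: Optional[FrequencyGrid] = None,
    analysis_range: Optional[tuple] = None,
) -> float:
    """Inter-spectral D-value: (1 - Pearson r) * 1000, in [0, 2000]."""
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("spectra must have equal length")
    mask = _range_mask(grid, a.shape[-1], analysis_range)
    if mask.sum() < 3:
        raise InvalidInputError("need at least 3 points in the analysis range")
    za = _standardize_rows(a[mask][None, :])[0]
    zb = _standardize_rows(b[mask][None, :])[0]
    r = float(np.mean(za * zb))
    return (1.0 - r) * 1000.0


def hca(
    cube: Union[HyperCube, np.ndarray],
    n_clusters: int,
    grid: Optional[FrequencyGrid] = None,
    analysis_range: Optional[tuple] = DEFAULT_HCA_RANGE,
    mask: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Ward hierarchical clustering on the pairwise D-value matrix.

    The D-value matrix over ``analysis_range`` is agglomerated with the
    Ward (Lance-Williams) update applied directly to the D-values, the
    tree is cut at ``n_clusters`` and labels are renumbered by descending
    cluster size (ties broken by lowest pixel index).  Pixels excluded by
    ``mask`` get label 0.  Cluster mean/sd spectra cover the full grid.
    """
    phase, cube_grid = _cube_phase(cube)
    grid = grid or cube_grid
    ny, nx, nf = phase.shape
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    flat = phase[mask]
    n = flat.shape[0]
    if n_clusters < 1:
        raise InvalidInputError("n_clusters must be >= 1")
    if n_clusters > n:
        raise InvalidInputError("n_clusters exceeds number of pixels")
    rmask = _range_mask(grid, nf, analysis_range)
    z = _standardize_rows(flat[:, rmask])
    r = np.clip((z @ z.T) / rmask.sum(), -1.0, 1.0)
    d = (1.0 - r) * 1000.0
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    merges = linkage(condensed, method="ward")
    raw = fcluster(merges, t=n_clusters, criterion="maxclust")

    # renumber 1..K by descending size; ties by first occurrence
    order = sorted(
        np.unique(raw),
        key=lambda lab: (-(raw == lab).sum(), int(np.argmax(raw == lab))),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.zeros((ny, nx), dtype=np.int32)
    labels[mask] = np.array([remap[v] for v in raw], dtype=np.int32)

    means, sds = cluster_stats(phase, labels)
    lo, hi = (analysis_range if analysis_range else (grid.values[0], grid.values[-1])
              ) if grid is not None else (0.0, float(nf))
    return ClusterResult(
        labels=labels,
        linkage=merges,
        mean_spectra=means,
        sd_spectra=sds,
        analysis_range=(lo, hi),
    )


def cluster_stats(
    cube: Union[HyperCube, np.ndarray],
    labels: np.ndarray,
) -> tuple:
    """Per-cluster mean and population-sd spectra.

    Label 0 marks excluded pixels and gets no statistics; empty clusters
    among 1..max(labels) are flagged with empty arrays.
    """
    phase, _ = _cube_phase(cube)
    labels = np.asarray(labels)
    if labels.shape != phase.shape[:2]:
        raise InvalidInputError("labels must partition the pixel grid")
    means: Dict[int, np.ndarray] = {}
    sds: Dict[int, np.ndarray] = {}
    for lab in range(1, int(labels.max()) + 1):
        sel = phase[labels == lab]
        if sel.size == 0:
            means[lab] = np.empty(0)
            sds[lab] = np.empty(0)
        else:
            means[lab] = sel.mean(axis=0)
            sds[lab] = sel.std(axis=0)  # population sd
    return means, sds


def unmix(
    spectrum: np.ndarray,
    references: Sequence[np.ndarray],
    allow_offset: bool = True,
    nonneg: bool = True,
) -> UnmixResult:
    """Fit phi ~ sum_i c_i * phi_ref_i (+ c0) by (non-negative) least squares."""
    y = np.asarray(spectrum, dtype=float)
    refs = [np.asarray(r, dtype=float) for r in references]
    if not refs:
        raise InvalidInputError("need at least one reference spectrum")
    for r in refs:
        if r.shape != y.shape:
            raise InvalidInputError("spectrum and references must share the grid")
    a = np.column_stack(refs)
    cond = float(np.linalg.cond(a))
    ill = cond > 1e8
    if ill:
        warnings.warn(
            f"reference spectra are nearly collinear (condition number {cond:.3g}); "
            "coefficients are poorly determined",
            RuntimeWarning,
            stacklevel=2,
        )
    cols = a if not allow_offset else np.column_stack([a, np.ones_like(y)])
    if nonneg:
        lb = np.zeros(cols.shape[1])
        ub = np.full(cols.shape[1], np.inf)
        if allow_offset:
            lb[-1] = -np.inf
        sol = lsq_linear(cols, y, bounds=(lb, ub))
        coef = sol.x
    else:
        coef, *_ = np.linalg.lstsq(cols, y, rcond=None)
    fitted = cols @ coef
    resid = y - fitted
    rms = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    offset = float(coef[-1]) if allow_offset else 0.0
    c = coef[:-1] if allow_offset else coef
    return UnmixResult(
        coefficients=np.asarray(c, dtype=float),
        offset=offset,
        residual_rms=rms,
        r_squared=r2,
        condition_number=cond,
        ill_conditioned=ill,
        fitted=fitted,
    )


def superposition_test(
    spectrum: np.ndarray,
    references: Sequence[np.ndarray],
    threshold: Optional[float] = None,
    pure_residuals: Optional[Sequence[float]] = None,
    **kwargs,
) -> tuple:
    """Is the spectrum a linear superposition of the references?

    True iff the unmixing residual RMS is <= ``threshold``.  When no
    threshold is given it defaults to 3x the median residual of
    known-pure pixels (``pure_residuals``).
    """
    result = unmix(spectrum, references, **kwargs)
    if threshold is None:
        if pure_residuals is None:
            raise InvalidInputError(
                "provide either a threshold or pure-pixel residuals for the default"
            )
        threshold = 3.0 * float(np.median(pure_residuals))
    return bool(result.residual_rms <= threshold), result
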