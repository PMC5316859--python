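"""Synthetic organic scenes with ground truth.

A scene is a label map over a pixel grid plus, per label, a composition
rule: a pure component, a convex combination of components (lateral or
vertical mixing), or a chemically modified ("interaction") component.
Component responses are sums of Lorentzian oscillators over a non-resonant
background.  Mixing is defined directly on the *phase* spectra (and, for
the forward model, on the amplitude spectra) so that a mixed pixel's
ground-truth phase is exactly the convex combination of the pure phases;
this makes linear-superposition tests exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .grids import FrequencyGrid
from .interferometry import default_simulation_grid

__all__ = [
    "Oscillator",
    "ComponentSpectrum",
    "SyntheticScene",
    "component_response",
    "oscillator_strength_for_peak",
    "make_blend_scene",
    "make_hair_scene",
    "BLEND_COMPONENTS",
    "HAIR_COMPONENTS",
]


@dataclass(frozen=True)
class Oscillator:
    """One Lorentzian vibrational band."""

    center: float  # cm^-1
    strength: float  # dimensionless amplitude (units of cm^-2)
    width: float  # damping, cm^-1

    def __post_init__(self) -> None:
        if self.center <= 0 or self.width <= 0 or self.strength < 0:
            raise InvalidInputError(
                "oscillator requires center > 0, width > 0, strength >= 0"
            )


@dataclass(frozen=True)
class ComponentSpectrum:
    """Complex response of one material on a wavenumber grid."""

    name: str
    oscillators: tuple
    background: complex
    grid: FrequencyGrid
    response: np.ndarray = field(repr=False)

    @property
    def phase(self) -> np.ndarray:
        """arg(response) in degrees."""
        return np.degrees(np.angle(self.response))

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.response)

    def resampled_phase(self, grid: FrequencyGrid) -> np.ndarray:
        return np.interp(grid.values, self.grid.values, self.phase)


def component_response(
    oscillators: Sequence[Oscillator],
    background: complex,
    grid: FrequencyGrid,
    name: str = "",
) -> ComponentSpectrum:
    """Evaluate sigma(w) = background + sum_j s_j / (c_j^2 - w^2 - i*g_j*w)."""
    w = grid.values
    sigma = np.full_like(w, background, dtype=complex)
    for osc in oscillators:
        sigma = sigma + osc.strength / (osc.center**2 - w**2 - 1j * osc.width * w)
    if not np.all(np.isfinite(sigma)):
        raise InvalidInputError("component response is not finite everywhere")
    return ComponentSpectrum(
        name=name,
        oscillators=tuple(oscillators),
        background=complex(background),
        grid=grid,
        response=sigma,
    )


def oscillator_strength_for_peak(
    center: float, width: float, peak_phase_deg: float, background: float = 1.0
) -> float:
    """Strength giving ~``peak_phase_deg`` of phase at resonance.

    At w = center the oscillator contributes i*s/(width*center); over a real
    background b the phase there is atan(s / (width*center*b)).
    """
    return float(np.tan(np.radians(peak_phase_deg)) * width * center * background)


# ---------------------------------------------------------------------------
# fixture component sets
# ---------------------------------------------------------------------------

_GRID = default_simulation_grid()


def _comp(name: str, bands: Sequence[tuple], background: float = 1.0) -> ComponentSpectrum:
    """bands: sequence of (center, width, peak_phase_deg)."""
    oscs = [
        Oscillator(c, oscillator_strength_for_peak(c, g, p, background), g)
        for c, g, p in bands
    ]
    return component_response(oscs, background, _GRID, name=name)


def blend_components(grid: Optional[FrequencyGrid] = None) -> Dict[str, ComponentSpectrum]:
    """Pure + interaction components of the three-polymer blend fixture.

    AC: acrylic copolymer with the ester C=O band at 1,740 cm^-1 and the
    C-O ester stretch at 1,155 cm^-1.  FP: fluorinated copolymer with the
    CF2 stretch at 1,195 cm^-1.  PS: polystyrene with weak aromatic bands.
    The interaction component models FP/AC mixing chemistry: the 1,195
    band shifted onto 1,155 with enhanced strength and a reduced C=O
    contribution; it is deliberately *not* a linear combination of AC and
    FP.
    """
    comps = {
        "AC": _comp("AC", [(1740.0, 65.0, 16.0), (1155.0, 70.0, 9.0), (1452.0, 70.0, 4.0)]),
        "FP": _comp("FP", [(1195.0, 65.0, 15.0), (1402.0, 75.0, 3.5)]),
        "PS": _comp("PS", [(1493.0, 65.0, 3.0), (1601.0, 65.0, 2.5)]),
        "FP_AC_interaction": _comp(
            "FP_AC_interaction",
            [(1155.0, 68.0, 21.0), (1740.0, 65.0, 5.0), (1452.0, 70.0, 2.5)],
        ),
        "silicon": _comp("silicon", []),
    }
    if grid is not None:
        comps = {
            k: component_response(v.oscillators, v.background, grid, name=k)
            for k, v in comps.items()
        }
    return comps


def hair_components(grid: Optional[FrequencyGrid] = None) -> Dict[str, ComponentSpectrum]:
    """Components of the hair cross-section fixture.

    Keratin carries the amide I/II bands (~1,660 / ~1,550 cm^-1); melanin
    the four bands at 1,290, 1,454, 1,563 and 1,638 cm^-1; the embedding
    resin has only a weak broad carbonyl remnant.
    """
    comps = {
        "keratin": _comp("keratin", [(1660.0, 70.0, 18.0), (1550.0, 75.0, 12.0)]),
        "melanin": _comp(
            "melanin",
            [
                (1290.0, 60.0, 9.0),
                (1454.0, 60.0, 8.0),
                (1563.0, 42.0, 9.0),
                (1638.0, 45.0, 11.0),
            ],
        ),
        "resin": _comp("resin", [(1730.0, 90.0, 1.5)]),
        "silicon": _comp("silicon", []),
    }
    if grid is not None:
        comps = {
            k: component_response(v.oscillators, v.background, grid, name=k)
            for k, v in comps.items()
        }
    return comps


BLEND_COMPONENTS = blend_components()
HAIR_COMPONENTS = hair_components()


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScene:
    """Label map + per-label composition rules with exact ground truth."""

    shape: tuple
    pixel_size: float  # nm
    labels: np.ndarray  # (ny, nx) int
    label_names: Dict[int, str]
    compositions: Dict[int, Mapping[str, float]]  # label -> {component: weight}
    components: Dict[str, ComponentSpectrum]
    heights: Dict[int, float]  # nm, for topography rendering
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != tuple(self.shape):
            raise InvalidInputError("label map shape mismatch")
        present = set(np.unique(self.labels).tolist())
        if not present <= set(self.compositions):
            raise InvalidInputError("every label needs a composition rule")
        for lab, rule in self.compositions.items():
            weights = np.array(list(rule.values()), dtype=float)
            if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-12:
                raise InvalidInputError(
                    f"label {lab}: mixing weights must be >= 0 and sum to 1"
                )
            if not set(rule) <= set(self.components):
                raise InvalidInputError(f"label {lab}: unknown component in rule")

    @property
    def grid(self) -> FrequencyGrid:
        return next(iter(self.components.values())).grid

    @property
    def sorted_labels(self) -> list:
        return sorted(self.compositions)

    def phase_for_label(self, label: int) -> np.ndarray:
        """Ground-truth phase: convex combination of component phases (deg)."""
        rule = self.compositions[label]
        out = np.zeros(len(self.grid))
        for name, w in rule.items():
            out += w * self.components[name].phase
        return out

    def amplitude_for_label(self, label: int) -> np.ndarray:
        rule = self.compositions[label]
        out = np.zeros(len(self.grid))
        for name, w in rule.items():
            out += w * self.components[name].amplitude
        return out

    def response_for_label(self, label: int) -> np.ndarray:
        """Complex forward-model response: mixed amplitude * exp(i*mixed phase)."""
        return self.amplitude_for_label(label) * np.exp(
            1j * np.radians(self.phase_for_label(label))
        )

    @property
    def truth_phase(self) -> np.ndarray:
        """Ground-truth broadband phase cube, shape (ny, nx, n_w), degrees."""
        table = np.stack([self.phase_for_label(lab) for lab in self.sorted_labels])
        index = np.searchsorted(self.sorted_labels, self.labels)
        return table[index]

    @property
    def truth_labels(self) -> np.ndarray:
        return self.labels

    @property
    def surface_texture(self) -> np.ndarray:
        """Persistent nm-scale roughness; moves with the sample under drift.

        Seeded from the scene seed so topography-based registration has
        texture to lock onto even for geometrically degenerate label maps.
        """
        if getattr(self, "_texture", None) is None:
            rng = np.random.default_rng(0 if self.seed is None else self.seed + 7919)
            self._texture = rng.normal(0.0, 3.0, self.shape)
        return self._texture

    def height_map(self) -> np.ndarray:
        table = np.array([self.heights.get(lab, 0.0) for lab in self.sorted_labels])
        index = np.searchsorted(self.sorted_labels, self.labels)
        return table[index] + self.surface_texture

    def label_id(self, name: str) -> int:
        for lab, nm in self.label_names.items():
            if nm == name:
                return lab
        raise KeyError(name)


# blend label ids
BLEND_LABELS = {
    0: "reference",
    1: "AC",
    2: "FP+AC",
    3: "PS",
    4: "interaction",
    5: "interface",
}

_BLEND_HEIGHTS = {0: 0.0, 1: 60.0, 2: 170.0, 3: 120.0, 4: 165.0, 5: 150.0}


def _paint_ellipse(labels, cy, cx, ry, rx, value) -> None:
    ny, nx = labels.shape
    y, x = np.ogrid[:ny, :nx]
    labels[((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0] = value


def make_blend_scene(
    shape: tuple = (62, 82),
    pixel_size: float = 30.0,
    seed: int = 0,
    grid: Optional[FrequencyGrid] = None,
    n_reference_rows: int = 2,
) -> SyntheticScene:
    """Three-component polymer-blend scene.

    Layout: a clean silicon reference strip along the first rows, an AC
    matrix, elliptical FP clusters whose pixels are vertical FP+AC
    mixtures, weak PS disks, interaction rims (modified FP component)
    around half of the FP clusters and plain lateral-interface rims (an
    FP/AC convex combination) around the rest.
    """
    ny, nx = shape
    if ny < 8 or nx < 8:
        raise InvalidInputError("scene shape must be at least (8, 8)")
    rng = np.random.default_rng(seed)
    components = blend_components(grid)

    labels = np.ones(shape, dtype=np.int32)  # AC matrix
    labels[:n_reference_rows, :] = 0

    usable_y = (n_reference_rows + 4, ny - 3)
    usable_x = (3, nx - 3)
    if usable_y[1] - usable_y[0] < 10 or usable_x[1] - usable_x[0] < 10:
        raise InvalidInputError(f"shape {shape} too small to place all region types")

    span_y = usable_y[1] - usable_y[0]
    span_x = usable_x[1] - usable_x[0]
    area = span_y * span_x
    n_fp = max(2, area // 900)
    n_ps = max(1, area // 1500)
    r_cap = max(2.0, min(6.5, span_y / 2.0 - 0.5, span_x / 2.0 - 0.5))

    # PS disks first so FP clusters can overwrite them
    for _ in range(n_ps):
        r = rng.uniform(2.5, min(4.5, r_cap))
        cy = rng.uniform(usable_y[0] + r, usable_y[1] - r)
        cx = rng.uniform(usable_x[0] + r, usable_x[1] - r)
        _paint_ellipse(labels, cy, cx, r, r, 3)

    # FP ellipses with rims: alternate interaction / interface
    for i in range(n_fp):
        ry = rng.uniform(min(3.0, r_cap - 0.5), r_cap)
        rx = rng.uniform(min(3.0, r_cap - 0.5), r_cap)
        cy = rng.uniform(usable_y[0] + ry, usable_y[1] - ry)
        cx = rng.uniform(usable_x[0] + rx, usable_x[1] - rx)
        core = np.zeros(shape, dtype=bool)
        y, x = np.ogrid[:ny, :nx]
        core[((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0] = True
        core[:n_reference_rows, :] = False  # never overwrite the reference strip
        rim = ndimage.binary_dilation(core, iterations=2) & ~core
        rim &= labels != 0
        rim_label = 4 if i % 2 == 0 else 5
        labels[rim] = rim_label
        labels[core] = 2

    present = set(np.unique(labels).tolist())
    if present != set(BLEND_LABELS):
        raise InvalidInputError(
            f"shape {shape} too small to place all region types (got labels {sorted(present)})"
        )

    compositions = {
        0: {"silicon": 1.0},
        1: {"AC": 1.0},
        2: {"FP": 0.7, "AC": 0.3},  # vertical mixture: FP cluster over AC layer
        3: {"PS": 1.0},
        4: {"FP_AC_interaction": 1.0},
        5: {"FP": 0.35, "AC": 0.65},  # lateral interface mixture
    }
    return SyntheticScene(
        shape=shape,
        pixel_size=pixel_size,
        labels=labels,
        label_names=dict(BLEND_LABELS),
        compositions=compositions,
        components=components,
        heights=dict(_BLEND_HEIGHTS),
        seed=seed,
    )


HAIR_LABELS = {
    0: "reference",
    1: "resin",
    2: "cortex",
    3: "melanin",
    4: "rim",
    5: "subsurface",
}

_HAIR_HEIGHTS = {0: 0.0, 1: 20.0, 2: 80.0, 3: 140.0, 4: 110.0, 5: 90.0}


def make_hair_scene(
    shape: tuple = (62, 82),
    pixel_size: float = 25.0,
    seed: int = 0,
    grid: Optional[FrequencyGrid] = None,
    n_reference_rows: int = 2,
) -> SyntheticScene:
    """Hair cross-section scene: resin, keratin cortex, melanin granules.

    One surface melanin disk of ~300 nm diameter with a keratin/melanin
    rim, and one ~200 nm disk of vertically mixed melanin+keratin
    (subsurface granule).
    """
    ny, nx = shape
    if ny < 8 or nx < 8:
        raise InvalidInputError("scene shape must be at least (8, 8)")
    rng = np.random.default_rng(seed)
    components = hair_components(grid)

    labels = np.ones(shape, dtype=np.int32)  # resin
    labels[:n_reference_rows, :] = 0

    # cortex occupies the right part of the field, wavy boundary
    split = int(0.35 * nx) + int(rng.integers(-2, 3))
    y_idx = np.arange(ny)
    wave = (2.0 * np.sin(2 * np.pi * y_idx / max(ny, 1) * rng.uniform(0.8, 1.6))).astype(int)
    for yy in range(n_reference_rows, ny):
        labels[yy, max(split + wave[yy - n_reference_rows], 1):] = 2

    r300 = 0.5 * 300.0 / pixel_size  # radius in px of a 300 nm disk
    r200 = 0.5 * 200.0 / pixel_size
    min_extent = min(ny - n_reference_rows, nx - split)
    if min_extent < 2 * r300 + 6:
        raise InvalidInputError(f"shape {shape} too small to place all region types")

    cy = rng.uniform(n_reference_rows + r300 + 3, ny - r300 - 3)
    cx = rng.uniform(split + r300 + 4, nx - r300 - 2)
    core = np.zeros(shape, dtype=bool)
    y, x = np.ogrid[:ny, :nx]
    core[(y - cy) ** 2 + (x - cx) ** 2 <= r300**2] = True
    rim = ndimage.binary_dilation(core, iterations=2) & ~core
    rim &= labels == 2
    labels[rim] = 4
    labels[core] = 3

    for _ in range(64):  # place the subsurface disk away from the granule
        cy2 = rng.uniform(n_reference_rows + r200 + 2, ny - r200 - 2)
        cx2 = rng.uniform(split + r200 + 3, nx - r200 - 1)
        if np.hypot(cy2 - cy, cx2 - cx) > r300 + r200 + 4:
            break
    else:
        raise InvalidInputError(f"shape {shape} too small to place all region types")
    sub = (y - cy2) ** 2 + (x - cx2) ** 2 <= r200**2
    labels[sub & (labels == 2)] = 5

    present = set(np.unique(labels).tolist())
    if present != set(HAIR_LABELS):
        raise InvalidInputError(
            f"shape {shape} too small to place all region types (got labels {sorted(present)})"
        )

    compositions = {
        0: {"silicon": 1.0},
        1: {"resin": 1.0},
        2: {"keratin": 1.0},
        3: {"melanin": 1.0},
        4: {"melanin": 0.5, "keratin": 0.5},
        5: {"melanin": 0.5, "keratin": 0.5},
    }
    return SyntheticScene(
        shape=shape,
        pixel_size=pixel_size,
        labels=labels,
        label_names=dict(HAIR_LABELS),
        compositions=compositions,
        components=components,
        heights=dict(_HAIR_HEIGHTS),
        seed=seed,
    )
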