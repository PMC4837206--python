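"""Synthetic vessel-wall Z-stack generator with recorded ground truth.

The phantom emulates an en face aortic measurement: a thin endothelium on
top of the media, imaged as 75×75-pixel planes over 15×15 μm² at 0.5 μm
axial steps.  Each pixel spectrum is a depth-attenuated mixture of pure
lipid, protein, and (for fresh tissue) water component spectra built from
Gaussian bands at the marker positions seen in vessel-wall Raman spectra
(2968, 2940, 2881, 3053, 1660, 1452, 1007 cm⁻¹; broad water band near
3300 cm⁻¹ in the unfixed dialect), plus a smooth degree-2 fluorescence
baseline, additive Gaussian noise, and sparse single-channel cosmic-ray
spikes.  There is deliberately no band at 3005 cm⁻¹: unsaturated-lipid
=CH stretching is absent from these spectra.

The "metastasis" condition multiplies the endothelial protein and lipid
concentrations by configurable factors (defaults +18 % protein, −4 %
lipid), so the planted effect is confined to the endothelium while the
media is identical between conditions.  Every planted quantity — layer
labels, concentrations, spike coordinates, per-pixel baseline
coefficients, the spike-free data, and the noiseless mixture spectrum per
plane — is recorded in :class:`GroundTruth` so downstream stages can be
validated quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Any, Sequence

import numpy as np

from .errors import ConfigError
from .stack import PlaneImage, ZStack

__all__ = [
    "BandSpec",
    "LayerSpec",
    "PhantomConfig",
    "GroundTruth",
    "default_band_library",
    "default_layers",
    "pure_component_spectrum",
    "render_plane",
    "generate_stack",
    "COMPONENTS",
    "CONDITIONS",
]

COMPONENTS = ("lipid", "protein", "water")
CONDITIONS = ("control", "metastasis")


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band of a pure chemical component.

    ``amplitude_per_unit`` is the peak height (counts) contributed per unit
    component concentration; ``width`` is the Gaussian sigma in cm⁻¹.
    """

    center: float
    width: float
    amplitude_per_unit: float
    component: str

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ConfigError(
                f"unknown component {self.component!r}; valid components: {COMPONENTS}"
            )
        if not self.width > 0:
            raise ConfigError(f"band width must be > 0, got {self.width}")
        if self.amplitude_per_unit < 0:
            raise ConfigError("band amplitude_per_unit must be >= 0")


@dataclass(frozen=True)
class LayerSpec:
    """A vessel-wall layer: z extent (μm) and component concentrations (a.u.)."""

    name: str
    z_range: tuple[float, float]
    lipid_conc: float
    protein_conc: float
    water_conc: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.z_range
        if not lo < hi:
            raise ConfigError(f"layer {self.name!r} z_range {self.z_range} is empty")
        for attr in ("lipid_conc", "protein_conc", "water_conc"):
            v = getattr(self, attr)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigError(f"layer {self.name!r} {attr}={v} must be finite and >= 0")

    def contains(self, z: float) -> bool:
        lo, hi = self.z_range
        return lo <= z < hi

    def concentration(self, component: str) -> float:
        return {
            "lipid": self.lipid_conc,
            "protein": self.protein_conc,
            "water": self.water_conc,
        }[component]


def default_band_library(dialect: str = "fixed") -> list[BandSpec]:
    """Gaussian band library for the chosen preparation dialect.

    Positions follow the marker bands of vessel-wall tissue spectra.  The
    CH-stretch envelope (2800–3100 cm⁻¹) is a superposition of lipid and
    protein CH₂/CH₃ bands with the lipid shoulder at 2881 cm⁻¹; the sharp
    phenylalanine ring-breathing band at 1007 cm⁻¹ is the pure protein
    marker.  The unfixed dialect adds the broad water band at ~3300 cm⁻¹
    and broadens amide I at 1660 cm⁻¹ (aqueous environment); neither
    dialect contains a 3005 cm⁻¹ band.  Amplitudes are chosen for
    testability: the CH envelope dominates the spectrum and is
    lipid-dominated at the default compositions.
    """
    if dialect not in ("fixed", "unfixed"):
        raise ConfigError(f"unknown dialect {dialect!r}; valid dialects: fixed, unfixed")
    amide_width = 17.0 if dialect == "unfixed" else 11.0
    bands = [
        # lipid CH stretches + fingerprint
        BandSpec(2881.0, 15.0, 0.75, "lipid"),
        BandSpec(2940.0, 21.0, 1.00, "lipid"),
        BandSpec(2968.0, 13.0, 0.45, "lipid"),
        BandSpec(1660.0, amide_width, 0.35, "lipid"),
        BandSpec(1452.0, 9.0, 0.50, "lipid"),
        # protein CH stretches, aromatic CH, amide I, CH2 wag, phenylalanine
        BandSpec(2940.0, 21.0, 0.75, "protein"),
        BandSpec(2968.0, 13.0, 0.50, "protein"),
        BandSpec(3053.0, 11.0, 0.20, "protein"),
        BandSpec(1660.0, amide_width, 0.55, "protein"),
        BandSpec(1452.0, 9.0, 0.30, "protein"),
        BandSpec(1007.0, 4.5, 0.70, "protein"),
    ]
    if dialect == "unfixed":
        bands.append(BandSpec(3300.0, 85.0, 1.20, "water"))
    return bands


def default_layers(dialect: str = "fixed") -> list[LayerSpec]:
    """Two-layer wall: lipid-richer endothelium above protein-richer media.

    The endothelium occupies the top 0.5 μm slab (one plane at the default
    z-step), the media the two planes below.  Water is present only in the
    unfixed (fresh tissue in buffer) dialect.
    """
    water = 1.5 if dialect == "unfixed" else 0.0
    return [
        LayerSpec("media", (-0.30, 0.75), lipid_conc=0.70, protein_conc=1.05, water_conc=water),
        LayerSpec("endothelium", (0.75, 1.30), lipid_conc=1.55, protein_conc=0.55, water_conc=water),
    ]


# default acquisition grids at 3 cm⁻¹ sampling, covering the dialect's
# normalization region ([450, 3200] fixed, [200, 1500] unfixed) and all bands
_DEFAULT_AXIS = {"fixed": (449.0, 3200.0, 3.0), "unfixed": (200.0, 3600.0, 3.0)}


@dataclass
class PhantomConfig:
    """All knobs of the synthetic acquisition.

    Defaults reproduce the reference acquisition geometry: 75×75 pixels
    over 15×15 μm² (0.2 μm pixels), 3 planes 0.5 μm apart, 3 cm⁻¹
    spectral sampling, with the metastasis condition scaling endothelial
    protein by 1.18 (+18 %) and lipid by 0.96 (−4 %).
    """

    dialect: str = "fixed"
    layers: list[LayerSpec] | None = None
    axis: tuple[float, float, float] | None = None  # (min, max, step) cm⁻¹
    plane_grid: tuple[int, int] = (75, 75)  # (H, W) pixels
    pixel_size: float = 0.2  # μm
    z_step: float = 0.5  # μm
    n_planes: int = 3
    z_start: float = 0.0  # μm of the first (deepest) plane
    baseline_coeffs_range: tuple[tuple[float, float], ...] = (
        (0.10, 0.30),
        (-0.20, 0.20),
        (0.00, 0.40),
    )
    noise_sd: float = 0.05  # counts
    spike_rate: float = 0.01  # probability of one cosmic-ray spike per spectrum
    spike_amplitude: float = 5.0  # counts
    depth_attenuation_scale: float = 1.0  # μm (≈ confocal axial response)
    focus_z: float = 0.0  # μm; z of maximal signal (inside the media)
    metastasis_protein_factor: float = 1.18
    metastasis_lipid_factor: float = 0.96
    seed: int = 0
    bands: list[BandSpec] | None = None
    record_clean: bool = True

    def __post_init__(self) -> None:
        if self.dialect not in ("fixed", "unfixed"):
            raise ConfigError(f"unknown dialect {self.dialect!r}; valid dialects: fixed, unfixed")
        if self.layers is None:
            self.layers = default_layers(self.dialect)
        if self.axis is None:
            self.axis = _DEFAULT_AXIS[self.dialect]
        if self.bands is None:
            self.bands = default_band_library(self.dialect)
        lo, hi, step = self.axis
        if not (lo < hi and step > 0):
            raise ConfigError(f"invalid axis specification {self.axis}")
        if self.z_step <= 0:
            raise ConfigError("z_step must be > 0")
        if self.n_planes < 2:
            raise ConfigError("n_planes must be >= 2 (layer separation undefined otherwise)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ConfigError("spike_rate must be in [0, 1]")
        if len(self.baseline_coeffs_range) != 3:
            raise ConfigError("baseline_coeffs_range needs 3 (lo, hi) pairs for degree 2")
        for pair in self.baseline_coeffs_range:
            if pair[0] > pair[1]:
                raise ConfigError(f"baseline coefficient range {pair} has lo > hi")
        if self.metastasis_protein_factor < 0 or self.metastasis_lipid_factor < 0:
            raise ConfigError("metastasis factors must be >= 0")
        if self.plane_grid[0] < 1 or self.plane_grid[1] < 1:
            raise ConfigError("plane_grid must have at least one pixel")
        h, w = self.plane_grid
        self.plane_grid = (int(h), int(w))

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.axis
        n = int(math.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)

    def z_values(self) -> np.ndarray:
        return self.z_start + self.z_step * np.arange(self.n_planes)

    def attenuation(self, z: float | np.ndarray) -> np.ndarray:
        """Scalar confocal depth attenuation, maximal at ``focus_z``."""
        return np.exp(-np.abs(np.asarray(z, dtype=float) - self.focus_z) / self.depth_attenuation_scale)

    def layer_at(self, z: float) -> LayerSpec | None:
        for layer in self.layers:
            if layer.contains(z):
                return layer
        return None

    def to_dict(self) -> dict[str, Any]:
        return {
            "dialect": self.dialect,
            "layers": [
                {
                    "name": l.name,
                    "z_range": list(l.z_range),
                    "lipid_conc": l.lipid_conc,
                    "protein_conc": l.protein_conc,
                    "water_conc": l.water_conc,
                }
                for l in self.layers
            ],
            "axis": list(self.axis),
            "plane_grid": list(self.plane_grid),
            "pixel_size": self.pixel_size,
            "z_step": self.z_step,
            "n_planes": self.n_planes,
            "z_start": self.z_start,
            "baseline_coeffs_range": [list(p) for p in self.baseline_coeffs_range],
            "noise_sd": self.noise_sd,
            "spike_rate": self.spike_rate,
            "spike_amplitude": self.spike_amplitude,
            "depth_attenuation_scale": self.depth_attenuation_scale,
            "focus_z": self.focus_z,
            "metastasis_protein_factor": self.metastasis_protein_factor,
            "metastasis_lipid_factor": self.metastasis_lipid_factor,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhantomConfig":
        d = dict(d)
        if "layers" in d and d["layers"] is not None:
            d["layers"] = [
                LayerSpec(
                    name=l["name"],
                    z_range=tuple(l["z_range"]),
                    lipid_conc=l["lipid_conc"],
                    protein_conc=l["protein_conc"],
                    water_conc=l.get("water_conc", 0.0),
                )
                for l in d["layers"]
            ]
        if "axis" in d and d["axis"] is not None:
            d["axis"] = tuple(d["axis"])
        if "plane_grid" in d:
            d["plane_grid"] = tuple(d["plane_grid"])
        if "baseline_coeffs_range" in d:
            d["baseline_coeffs_range"] = tuple(tuple(p) for p in d["baseline_coeffs_range"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown phantom config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation.

    ``pre_spike`` holds the spike-free data (signal + baseline + noise) per
    plane; ``noiseless`` holds the attenuated pure mixture spectrum of each
    plane (no baseline, no noise).  ``planted_percent_change`` is exactly
    100 × (factor − 1) for the metastasis condition and 0 for controls.
    """

    condition: str
    labels: list[str]
    concentrations: list[dict[str, float]]
    planted_percent_change: dict[str, float]
    spikes: list[tuple[int, int, int, int]]  # (plane, row, col, channel)
    noiseless: list[np.ndarray]
    pre_spike: list[np.ndarray] | None
    baseline_coeffs: list[np.ndarray] | None

    def spikes_in_plane(self, k: int) -> list[tuple[int, int, int, int]]:
        return [s for s in self.spikes if s[0] == k]

    def summary_dict(self) -> dict[str, Any]:
        """JSON-serializable summary (arrays omitted)."""
        return {
            "condition": self.condition,
            "labels": self.labels,
            "concentrations": self.concentrations,
            "planted_percent_change": self.planted_percent_change,
            "n_spikes": len(self.spikes),
            "spikes": [list(s) for s in self.spikes],
        }


def pure_component_spectrum(
    component: str, axis: np.ndarray, bands: Sequence[BandSpec]
) -> np.ndarray:
    """Noiseless sum of Gaussian band profiles of one component on ``axis``.

    Returns intensity per unit concentration; non-negative everywhere.
    """
    if component not in COMPONENTS:
        raise ConfigError(
            f"unknown component {component!r}; valid components: {COMPONENTS}"
        )
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2 or not np.all(np.diff(axis) > 0):
        raise ConfigError("axis must be a strictly ascending 1-D wavenumber grid")
    mine = [b for b in bands if b.component == component]
    if not mine:
        raise ConfigError(f"no bands defined for component {component!r}")
    out = np.zeros_like(axis)
    for b in mine:
        out += b.amplitude_per_unit * np.exp(-0.5 * ((axis - b.center) / b.width) ** 2)
    return out


def _effective_concentrations(
    layer: LayerSpec | None, condition: str, config: PhantomConfig
) -> dict[str, float]:
    if layer is None:
        return {c: 0.0 for c in COMPONENTS}
    conc = {c: layer.concentration(c) for c in COMPONENTS}
    if condition == "metastasis" and layer.name == "endothelium":
        conc["protein"] *= config.metastasis_protein_factor
        conc["lipid"] *= config.metastasis_lipid_factor
    return conc


@lru_cache(maxsize=128)
def _pure_cached(
    component: str, bands: tuple[BandSpec, ...], axis_spec: tuple[float, float, float]
) -> np.ndarray:
    # content-keyed cache: identical band libraries across many generated
    # stacks (e.g. simulation replicates) share one evaluation
    lo, hi, step = axis_spec
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    axis = lo + step * np.arange(n)
    out = pure_component_spectrum(component, axis, bands)
    out.setflags(write=False)
    return out


def _mixture_spectrum(
    config: PhantomConfig, conc: dict[str, float], axis: np.ndarray
) -> np.ndarray:
    mix = np.zeros_like(axis)
    for component, c in conc.items():
        if c > 0:
            mix += c * _pure_cached(component, tuple(config.bands), tuple(config.axis))
    return mix


def _render_plane_arrays(
    config: PhantomConfig,
    z: float,
    condition: str,
    rng: np.random.Generator,
):
    """Render one plane; returns (data, pre_spike, spikes, coeffs, mixture)."""
    axis = config.wavenumbers()
    h, w = config.plane_grid
    n_ch = axis.size
    layer = config.layer_at(z)
    conc = _effective_concentrations(layer, condition, config)
    mixture = float(config.attenuation(z)) * _mixture_spectrum(config, conc, axis)

    # degree-2 baseline in the normalized coordinate u ∈ [0, 1]
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    ranges = np.asarray(config.baseline_coeffs_range, dtype=float)
    coeffs = rng.uniform(ranges[:, 0], ranges[:, 1], size=(h, w, 3))
    baseline = (
        coeffs[..., 0:1]
        + coeffs[..., 1:2] * u
        + coeffs[..., 2:3] * u**2
    )

    data = mixture + baseline
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=(h, w, n_ch))
    else:
        data = data + np.zeros((h, w, n_ch))
    pre_spike = data.copy()

    spikes: list[tuple[int, int, int]] = []
    if config.spike_rate > 0:
        hit = rng.random((h, w)) < config.spike_rate
        channels = rng.integers(0, n_ch, size=(h, w))
        for r, c in zip(*np.nonzero(hit)):
            ch = int(channels[r, c])
            data[r, c, ch] += config.spike_amplitude
            spikes.append((int(r), int(c), ch))
    return data, pre_spike, spikes, coeffs, mixture


def render_plane(
    config: PhantomConfig,
    z: float,
    condition: str,
    rng: np.random.Generator | int | None = None,
) -> PlaneImage:
    """Render a single confocal plane at depth ``z`` (μm).

    A ``z`` outside every layer yields baseline + noise only.  For the
    metastasis condition the endothelial concentrations are scaled by the
    configured factors.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}; valid conditions: {CONDITIONS}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    data, *_ = _render_plane_arrays(config, z, condition, rng)
    return PlaneImage(config.wavenumbers(), data, z=z, pixel_size=config.pixel_size)


def generate_stack(
    config: PhantomConfig, condition: str = "control"
) -> tuple[ZStack, GroundTruth]:
    """Generate a full synthetic Z-stack plus its ground truth.

    Deterministic for a fixed ``config.seed``: the same seed renders the
    same noise field for both conditions, so unit-factor metastasis stacks
    are bitwise identical to controls.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}; valid conditions: {CONDITIONS}")
    rng = np.random.default_rng(config.seed)
    axis = config.wavenumbers()
    zs = config.z_values()

    planes: list[PlaneImage] = []
    labels: list[str] = []
    concentrations: list[dict[str, float]] = []
    spikes: list[tuple[int, int, int, int]] = []
    noiseless: list[np.ndarray] = []
    pre_spike: list[np.ndarray] | None = [] if config.record_clean else None
    coeffs_all: list[np.ndarray] | None = [] if config.record_clean else None

    for k, z in enumerate(zs):
        data, clean, plane_spikes, coeffs, mixture = _render_plane_arrays(
            config, float(z), condition, rng
        )
        planes.append(PlaneImage(axis, data, z=float(z), pixel_size=config.pixel_size))
        layer = config.layer_at(float(z))
        labels.append(layer.name if layer is not None else "none")
        concentrations.append(
            _effective_concentrations(layer, condition, config)
        )
        spikes.extend((k, r, c, ch) for r, c, ch in plane_spikes)
        noiseless.append(mixture)
        if config.record_clean:
            pre_spike.append(clean)  # type: ignore[union-attr]
            coeffs_all.append(coeffs)  # type: ignore[union-attr]

    stack = ZStack(
        planes,
        config.z_step,
        metadata={
            "condition": condition,
            "dialect": config.dialect,
            "sample_id": f"phantom-seed{config.seed}-{condition}",
            "source": "phantom",
        },
    )
    truth = GroundTruth(
        condition=condition,
        labels=labels,
        concentrations=concentrations,
        planted_percent_change={
            "protein": 100.0 * (config.metastasis_protein_factor - 1.0)
            if condition == "metastasis"
            else 0.0,
            "lipid": 100.0 * (config.metastasis_lipid_factor - 1.0)
            if condition == "metastasis"
            else 0.0,
        },
        spikes=spikes,
        noiseless=noiseless,
        pre_spike=pre_spike,
        baseline_coeffs=coeffs_all,
    )
    return stack, truth
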