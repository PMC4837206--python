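"""Spectral preprocessing: cosmic-ray removal, degree-2 baseline
correction, and region-restricted vector normalization.

The chain runs despike → baseline → normalize on every pixel spectrum.
Spikes are removed first because a cosmic ray corrupts both the baseline
fit and the Euclidean norm; normalization comes last so that band-ratio
statistics downstream are computed on unit-norm spectra.

Two preparation dialects are supported, each pairing a baseline method
with a normalization region:

========  ===============  =======================
dialect   baseline          normalization region
========  ===============  =======================
fixed     ``poly2``         450–3200 cm⁻¹
unfixed   ``autopoly2``     200–1500 cm⁻¹
========  ===============  =======================

``poly2`` is a plain ordinary-least-squares degree-2 fit over all
channels, subtracted.  ``autopoly2`` is an iterative peak-clipped variant
(fit, clip the working spectrum to the fit wherever it lies above it,
refit; repeat to convergence) that is robust to strong bands and suits
fresh-tissue spectra whose water background is not well described by a
single unweighted fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import ConfigError, DataError
from .stack import Spectrum, ZStack

__all__ = [
    "PreprocessConfig",
    "despike",
    "despike_batch",
    "baseline_correct",
    "baseline_correct_batch",
    "vector_normalize",
    "vector_normalize_batch",
    "preprocess_stack",
    "DIALECT_BASELINE",
    "DIALECT_NORMALIZATION_REGION",
]

log = logging.getLogger(__name__)

DIALECT_BASELINE = {"fixed": "poly2", "unfixed": "autopoly2"}
DIALECT_NORMALIZATION_REGION = {"fixed": (450.0, 3200.0), "unfixed": (200.0, 1500.0)}

#: relative floor on the local spike-detection scale, as a fraction of the
#: robust (running-median) signal maximum.  Cosmic-ray spikes exceed the
#: signal scale by construction of the detector physics; this floor keeps
#: resolution-limited real bands from being misread as spikes when the
#: noise — and hence the local MAD — is very small.
DEFAULT_DESPIKE_REL_FLOOR = 0.05


@dataclass
class PreprocessConfig:
    """Preprocessing parameters; unset fields default from the dialect."""

    dialect: str = "fixed"
    baseline_method: str | None = None
    normalization_region: tuple[float, float] | None = None
    despike_threshold: float = 8.0
    despike_window: int = 7
    despike_rel_floor: float = DEFAULT_DESPIKE_REL_FLOOR

    def __post_init__(self) -> None:
        if self.dialect not in DIALECT_BASELINE:
            raise ConfigError(
                f"unknown dialect {self.dialect!r}; valid dialects: fixed, unfixed"
            )
        if self.baseline_method is None:
            self.baseline_method = DIALECT_BASELINE[self.dialect]
        if self.baseline_method not in ("poly2", "autopoly2"):
            raise ConfigError(
                f"unknown baseline method {self.baseline_method!r}; valid: poly2, autopoly2"
            )
        if self.normalization_region is None:
            self.normalization_region = DIALECT_NORMALIZATION_REGION[self.dialect]
        lo, hi = self.normalization_region
        if not lo < hi:
            raise ConfigError(f"normalization region {self.normalization_region} is empty")
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise ConfigError("despike_window must be an odd integer >= 3")
        if self.despike_threshold <= 0:
            raise ConfigError("despike_threshold must be > 0")
        if self.despike_rel_floor < 0:
            raise ConfigError("despike_rel_floor must be >= 0")


# ---------------------------------------------------------------------------
# cosmic-ray removal


def despike_batch(
    y: np.ndarray,
    threshold: float = 8.0,
    window: int = 7,
    rel_floor: float = DEFAULT_DESPIKE_REL_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove single-channel spikes from spectra along the last axis.

    A channel is a spike when its residual from the running median
    (window ``window``) exceeds ``threshold`` × a local scale.  The local
    scale is the median absolute residual over the same window, floored at
    machine-epsilon level (guards all-constant spectra) and at
    ``rel_floor`` × the robust signal maximum of the spectrum (guards the
    noiseless limit, where sharp real bands would otherwise dominate an
    arbitrarily small MAD).  Flagged channels are replaced by the running
    median; everything else is returned bit-identical.

    Returns ``(corrected, spike_mask)``.
    """
    y = np.asarray(y, dtype=float)
    n_ch = y.shape[-1]
    if window >= n_ch:
        raise ConfigError(f"despike window {window} must be < spectrum length {n_ch}")
    if window < 3 or window % 2 == 0:
        raise ConfigError("despike window must be an odd integer >= 3")
    size = (1,) * (y.ndim - 1) + (window,)
    runmed = median_filter(y, size=size, mode="nearest")
    resid = y - runmed
    local_mad = median_filter(np.abs(resid), size=size, mode="nearest")

    signal_scale = np.max(np.abs(runmed), axis=-1, keepdims=True)
    eps_floor = np.finfo(float).eps * np.maximum(
        1.0, np.max(np.abs(y), axis=-1, keepdims=True)
    )
    scale = np.maximum(local_mad, np.maximum(eps_floor, rel_floor * signal_scale))
    mask = np.abs(resid) > threshold * scale
    corrected = np.where(mask, runmed, y)
    return corrected, mask


def despike(
    spectrum: Spectrum,
    threshold: float = 8.0,
    window: int = 7,
    rel_floor: float = DEFAULT_DESPIKE_REL_FLOOR,
) -> tuple[Spectrum, list[int]]:
    """Cosmic-ray removal for a single spectrum.

    Returns the corrected spectrum and the list of replaced channel
    indices.
    """
    corrected, mask = despike_batch(
        spectrum.intensity[None, :], threshold=threshold, window=window, rel_floor=rel_floor
    )
    return (
        Spectrum(spectrum.axis, corrected[0]),
        [int(i) for i in np.nonzero(mask[0])[0]],
    )


# ---------------------------------------------------------------------------
# baseline correction


def _design_matrix(axis: np.ndarray) -> np.ndarray:
    """Degree-2 Vandermonde in the normalized coordinate u ∈ [0, 1]."""
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    return np.column_stack([np.ones_like(u), u, u**2])


def baseline_correct_batch(
    y: np.ndarray,
    axis: np.ndarray,
    method: str = "poly2",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Degree-2 baseline correction of spectra in rows of ``y`` (N, C).

    ``poly2``: OLS fit over all channels, subtracted (an exact linear
    projection, hence idempotent and annihilating any degree ≤ 2
    polynomial).  ``autopoly2``: iterative peak-clipped fit — each round
    the working spectrum is clipped to the current fit wherever it lies
    above it, and the polynomial is refit, until the coefficients change
    by less than ``tol`` relative or ``max_iter`` rounds.

    Returns ``(corrected, coefficients)`` where coefficients are in the
    basis 1, u, u² with u the axis normalized to [0, 1].
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    axis = np.asarray(axis, dtype=float)
    n_ch = axis.size
    if y.shape[-1] != n_ch:
        raise ConfigError("spectra and axis length mismatch")
    if n_ch < 3:
        raise ConfigError(f"baseline correction needs >= 3 channels, got {n_ch}")
    if method not in ("poly2", "autopoly2"):
        raise ConfigError(f"unknown baseline method {method!r}; valid: poly2, autopoly2")

    X = _design_matrix(axis)
    # unweighted OLS projector components, shared across spectra
    pinv = np.linalg.pinv(X)  # (3, C)

    coeffs = y @ pinv.T  # (N, 3)
    if method == "autopoly2":
        # dev-aware peak clipping: each round, clip the working spectrum to
        # (current fit + residual spread).  The spread term keeps baseline
        # channels from being eroded below the true baseline, so planted
        # degree-2 coefficients are recovered exactly in the noiseless limit.
        work = y.copy()
        for _ in range(max_iter):
            fit = coeffs @ X.T
            dev = np.std(work - fit, axis=-1, keepdims=True)
            work = np.minimum(work, fit + dev)
            new = work @ pinv.T
            delta = np.max(np.abs(new - coeffs), axis=-1)
            scale = np.maximum(np.max(np.abs(coeffs), axis=-1), np.finfo(float).tiny)
            coeffs = new
            if np.all(delta <= tol * scale):
                break
    corrected = y - coeffs @ X.T
    return corrected, coeffs


def baseline_correct(
    spectrum: Spectrum, method: str = "poly2", return_coeffs: bool = False
):
    """Baseline-correct a single spectrum; see :func:`baseline_correct_batch`."""
    corrected, coeffs = baseline_correct_batch(
        spectrum.intensity[None, :], spectrum.axis, method=method
    )
    out = Spectrum(spectrum.axis, corrected[0])
    if return_coeffs:
        return out, coeffs[0]
    return out


# ---------------------------------------------------------------------------
# vector normalization


def _region_mask(axis: np.ndarray, region: tuple[float, float]) -> np.ndarray:
    lo, hi = region
    if not lo < hi:
        raise ConfigError(f"normalization region ({lo}, {hi}) is empty")
    if lo < axis[0] - 1e-9 or hi > axis[-1] + 1e-9:
        raise ConfigError(
            f"normalization region ({lo}, {hi}) cm⁻¹ not within axis "
            f"[{axis[0]}, {axis[-1]}] cm⁻¹"
        )
    mask = (axis >= lo) & (axis <= hi)
    if mask.sum() < 2:
        raise ConfigError(f"normalization region ({lo}, {hi}) contains fewer than 2 channels")
    return mask


def vector_normalize_batch(
    y: np.ndarray, axis: np.ndarray, region: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each spectrum by the Euclidean norm of its in-region channels.

    Returns ``(normalized, norms)``.  A zero in-region norm raises
    :class:`DataError` naming the region; callers that know pixel
    coordinates re-raise with them attached.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mask = _region_mask(np.asarray(axis, dtype=float), region)
    norms = np.sqrt(np.sum(y[..., mask] ** 2, axis=-1))
    if np.any(norms == 0):
        raise DataError(
            f"zero Euclidean norm in normalization region ({region[0]}, {region[1]}) cm⁻¹"
        )
    return y / norms[..., None], norms


def vector_normalize(spectrum: Spectrum, region: tuple[float, float]) -> Spectrum:
    """Normalize one spectrum to unit Euclidean norm inside ``region``."""
    normalized, _ = vector_normalize_batch(spectrum.intensity[None, :], spectrum.axis, region)
    return Spectrum(spectrum.axis, normalized[0])


# ---------------------------------------------------------------------------
# whole-stack chain


def preprocess_stack(stack: ZStack, config: PreprocessConfig | None = None) -> ZStack:
    """Apply despike → baseline correction → vector normalization per pixel.

    The dialect pairs the baseline method and the normalization region
    (fixed → poly2 with 450–3200 cm⁻¹; unfixed → autopoly2 with
    200–1500 cm⁻¹) unless explicitly overridden in ``config``.  Errors
    are re-raised with (plane, pixel) coordinates.
    """
    if config is None:
        config = PreprocessConfig(dialect=str(stack.metadata.get("dialect", "fixed")))
    log.info(
        "preprocess: dialect=%s baseline=%s region=%s despike(threshold=%g, window=%d)",
        config.dialect,
        config.baseline_method,
        config.normalization_region,
        config.despike_threshold,
        config.despike_window,
    )
    axis = stack.axis
    out = np.empty((stack.n_planes, *stack.planes[0].shape, axis.size))
    n_spikes_total = 0
    for k, plane in enumerate(stack.planes):
        pixels = plane.pixels()
        try:
            despiked, mask = despike_batch(
                pixels,
                threshold=config.despike_threshold,
                window=config.despike_window,
                rel_floor=config.despike_rel_floor,
            )
            corrected, _ = baseline_correct_batch(
                despiked, axis, method=config.baseline_method
            )
            try:
                normalized, _ = vector_normalize_batch(
                    corrected, axis, config.normalization_region
                )
            except DataError:
                lo, hi = config.normalization_region
                norms = np.sqrt(
                    np.sum(corrected[:, (axis >= lo) & (axis <= hi)] ** 2, axis=-1)
                )
                bad = int(np.nonzero(norms == 0)[0][0])
                h, w = plane.shape
                raise DataError(
                    f"zero Euclidean norm in normalization region ({lo}, {hi}) cm⁻¹ "
                    f"at plane {k}, pixel ({bad // w}, {bad % w})"
                ) from None
        except ConfigError as exc:
            raise ConfigError(f"plane {k}: {exc}") from exc
        n_spikes = int(mask.sum())
        n_spikes_total += n_spikes
        log.debug("plane %d: %d spike channels corrected", k, n_spikes)
        out[k] = normalized.reshape(plane.data.shape)
    log.info("preprocess: %d spike channels corrected in total", n_spikes_total)
    return stack.with_data(out, metadata={"preprocessed": True})
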