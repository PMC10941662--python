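"""Per-pixel non-negative linear unmixing of spectral image stacks.

Each pixel's measured M-vector ``b`` is modeled as a non-negative linear
superposition of the reference spectra: ``b ≈ R x`` with ``x ≥ 0``, where R is
the M×C reference matrix (C = fluorophores plus one or more autofluorescence
channels).  Solving the non-negative least-squares (NNLS) problem per pixel
yields one unmixed coefficient image per channel plus a residual-norm map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .spectra import AcquisitionScheme, ReferenceMatrix, ReferenceSpectrum, SchemeError

__all__ = ["SpectralImage", "UnmixedImage", "solve_nnls", "unmix_image", "add_af_channels"]


@dataclass
class SpectralImage:
    """A (Z, Y, X, M) spectral intensity stack with physical pixel sizes.

    ``pixel_size`` is (z, y, x) in µm.  Negative raw intensities (detector
    offset artifacts) are clamped to zero with a warning.
    """

    data: np.ndarray
    pixel_size: tuple[float, float, float]
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"spectral image must be (Z, Y, X, M); got shape {arr.shape}")
        if arr.shape[-1] != self.scheme.m:
            raise SchemeError(
                f"image has {arr.shape[-1]} measurements; scheme expects M={self.scheme.m}"
            )
        if len(self.pixel_size) != 3 or any(p <= 0 for p in self.pixel_size):
            raise ValueError("pixel_size must be three positive values (z, y, x) in µm")
        if np.any(arr < 0):
            n = int(np.count_nonzero(arr < 0))
            warnings.warn(f"clamping {n} negative intensities to 0", stacklevel=2)
            arr = np.clip(arr, 0, None)
        self.data = arr
        self.pixel_size = tuple(float(p) for p in self.pixel_size)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class UnmixedImage:
    """Unmixed coefficient stack (Z, Y, X, C) plus per-pixel residual norms."""

    coefficients: np.ndarray
    residual: np.ndarray
    relative_residual: np.ndarray
    channel_names: list[str]
    pixel_size: tuple[float, float, float]

    def channel(self, name: str) -> np.ndarray:
        """The (Z, Y, X) coefficient image for one named channel."""
        return self.coefficients[..., self.channel_names.index(name)]


def solve_nnls(b: np.ndarray, ref: ReferenceMatrix | np.ndarray) -> tuple[np.ndarray, float]:
    """Solve ``min ||R x - b||_2  s.t.  x >= 0`` for a single pixel spectrum.

    Uses an active-set NNLS solver (exact for the small C here).  Returns the
    coefficient vector and the residual norm; ``x = 0`` is always feasible so
    the residual never exceeds ``||b||``.
    """
    r = ref.matrix if isinstance(ref, ReferenceMatrix) else np.asarray(ref, dtype=float)
    b = np.asarray(b, dtype=float)
    if b.ndim != 1 or b.size != r.shape[0]:
        raise ValueError(f"b has length {b.size}; R expects {r.shape[0]}")
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite entries in pixel spectrum")
    x, rnorm = nnls(r, b)
    return x, float(rnorm)


def unmix_image(
    img: SpectralImage,
    ref: ReferenceMatrix,
    chunk_size: int = 8192,
) -> UnmixedImage:
    """Unmix every pixel of a spectral image against a reference matrix.

    Pixels are processed in chunks of ``chunk_size`` (memory bound only; the
    result is identical to a per-pixel loop).  The output carries the
    reference matrix's channel names and the input's pixel sizes.
    """
    if img.scheme != ref.scheme:
        raise SchemeError(_scheme_mismatch_message(img.scheme, ref.scheme))
    r = ref.matrix
    flat = img.data.reshape(-1, img.scheme.m)
    n = flat.shape[0]
    coeffs = np.empty((n, ref.c), dtype=float)
    resid = np.empty(n, dtype=float)
    for start in range(0, n, max(1, chunk_size)):
        stop = min(n, start + max(1, chunk_size))
        for i in range(start, stop):
            coeffs[i], resid[i] = nnls(r, flat[i])
    norms = np.linalg.norm(flat, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(norms > 0, resid / norms, 0.0)
    shape = img.spatial_shape
    return UnmixedImage(
        coefficients=coeffs.reshape(*shape, ref.c),
        residual=resid.reshape(shape),
        relative_residual=rel.reshape(shape),
        channel_names=list(ref.channel_names),
        pixel_size=img.pixel_size,
    )


def add_af_channels(
    ref: ReferenceMatrix, extra_af: list[ReferenceSpectrum]
) -> ReferenceMatrix:
    """Append auxiliary autofluorescence columns to a reference matrix.

    Samples whose tissues differ widely in intrinsic fluorescence can be
    unmixed with several AF channels, one reference spectrum per channel.
    Appended columns are renamed ``AF2, AF3, ...`` continuing after the
    existing AF column count.
    """
    spectra = list(ref.spectra)
    next_idx = ref.n_af + 1
    existing = set(ref.channel_names)
    for i, s in enumerate(extra_af):
        if s.scheme != ref.scheme:
            raise SchemeError(f"extra AF spectrum '{s.channel_name}' uses a different scheme")
        name = f"AF{next_idx + i}"
        if name in existing:
            raise ValueError(f"duplicate channel name {name!r}")
        spectra.append(
            ReferenceSpectrum(channel_name=name, intensities=s.intensities.copy(), scheme=ref.scheme)
        )
        existing.add(name)
    return ReferenceMatrix(scheme=ref.scheme, spectra=spectra, n_af=ref.n_af + len(extra_af))


def _scheme_mismatch_message(a: AcquisitionScheme, b: AcquisitionScheme) -> str:
    parts = ["image and reference matrix use different acquisition schemes"]
    if a.excitations != b.excitations:
        parts.append(f"excitations differ: {list(a.excitations)} vs {list(b.excitations)}")
    for e, (da, db) in zip(a.excitations, zip(a.detectors, b.detectors)):
        if da != db:
            parts.append(f"detector bands differ at excitation {e} nm: {da} vs {db}")
    return "; ".join(parts)
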