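"""Acquisition schemes and reference spectra for multi-excitation spectral imaging.

A spectral acquisition interrogates each pixel with a sequence of laser
excitation lines; for each line, emitted fluorescence is integrated over one or
more detector emission bands.  The flattened list of (excitation, band) pairs
forms the measurement axis of length ``M``.  Each fluorophore — and the
sample's intrinsic autofluorescence (AF) — has a characteristic *reference
spectrum*: its response across all M measurements, recorded in a sample
containing only that one source of fluorescence.  The reference spectra,
stacked as columns, form the M×C reference matrix used for linear unmixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "ReferenceSpectrum",
    "ReferenceMatrix",
    "EEMScan",
    "ConditionReport",
    "extract_reference_spectrum",
    "optimize_af_channel",
    "condition_report",
]


class SchemeError(ValueError):
    """Invalid acquisition scheme or scheme mismatch."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered excitation lines, each with ordered detector emission bands.

    Parameters
    ----------
    excitations
        Excitation wavelengths in nm, strictly increasing.
    detectors
        For each excitation, a tuple of ``(band_start_nm, band_end_nm)``
        detector bands.  Between 1 and 4 bands per excitation; every band must
        start at or red of its excitation line (no anti-Stokes collection).
    """

    excitations: tuple[float, ...]
    detectors: tuple[tuple[tuple[float, float], ...], ...]

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitations, dtype=float)
        if ex.size == 0:
            raise SchemeError("scheme needs at least one excitation")
        if len(self.detectors) != ex.size:
            raise SchemeError("one detector-band list required per excitation")
        if not np.all(np.diff(ex) > 0):
            raise SchemeError("excitation wavelengths must be strictly increasing")
        for e, bands in zip(self.excitations, self.detectors):
            if not 1 <= len(bands) <= 4:
                raise SchemeError(
                    f"excitation {e} nm has {len(bands)} detector bands; 1-4 allowed"
                )
            for a, b in bands:
                if not a < b:
                    raise SchemeError(f"detector band ({a}, {b}) has start >= end")
                if a < e:
                    raise SchemeError(
                        f"detector band start {a} nm is blue of excitation {e} nm"
                    )

    @property
    def m(self) -> int:
        """Length of the measurement axis (total excitation×detector pairs)."""
        return sum(len(b) for b in self.detectors)

    @property
    def pairs(self) -> list[tuple[float, tuple[float, float]]]:
        """Flattened ``(excitation, (band_start, band_end))`` measurement axis."""
        return [(e, band) for e, bands in zip(self.excitations, self.detectors) for band in bands]

    def describe_rows(self) -> list[dict]:
        """One dict per measurement: excitation_nm, band_start_nm, band_end_nm."""
        return [
            {"excitation_nm": e, "band_start_nm": a, "band_end_nm": b}
            for e, (a, b) in self.pairs
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AcquisitionScheme):
            return NotImplemented
        return self.excitations == other.excitations and self.detectors == other.detectors

    def __hash__(self) -> int:
        return hash((self.excitations, self.detectors))


@dataclass
class ReferenceSpectrum:
    """A single channel's normalized response across the measurement axis.

    ``intensities`` holds M non-negative values; after construction the
    maximum entry is 1 (per-spectrum max normalization, so unmixed
    coefficients share the raw image's intensity scale).
    """

    channel_name: str
    intensities: np.ndarray
    scheme: AcquisitionScheme
    normalization: str = "max"

    def __post_init__(self) -> None:
        v = np.asarray(self.intensities, dtype=float)
        if v.ndim != 1 or v.size != self.scheme.m:
            raise SchemeError(
                f"spectrum '{self.channel_name}' has {v.size} entries; "
                f"scheme expects M={self.scheme.m}"
            )
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError(f"spectrum '{self.channel_name}' has negative or non-finite entries")
        peak = v.max()
        if peak == 0:
            raise ValueError(f"spectrum '{self.channel_name}' is all-zero")
        self.intensities = v / peak


@dataclass
class ReferenceMatrix:
    """M×C stack of reference spectra: fluorophore columns first, then AF columns."""

    scheme: AcquisitionScheme
    spectra: list[ReferenceSpectrum]
    n_af: int = 1

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("reference matrix needs at least one column")
        if not 0 <= self.n_af <= len(self.spectra):
            raise ValueError("n_af out of range")
        names = [s.channel_name for s in self.spectra]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names: {names}")
        for s in self.spectra:
            if s.scheme != self.scheme:
                raise SchemeError(f"spectrum '{s.channel_name}' uses a different scheme")

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([s.intensities for s in self.spectra])

    @property
    def channel_names(self) -> list[str]:
        return [s.channel_name for s in self.spectra]

    @property
    def c(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class EEMScan:
    """Excitation-emission matrix: intensity on an excitation×emission grid."""

    excitations: tuple[float, ...]
    emissions: tuple[float, ...]
    intensity: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.shape != (len(self.excitations), len(self.emissions)):
            raise ValueError(
                f"intensity shape {arr.shape} does not match axes "
                f"({len(self.excitations)}, {len(self.emissions)})"
            )
        if np.any(arr < 0):
            raise ValueError("EEM intensities must be non-negative")
        object.__setattr__(self, "intensity", arr)


def extract_reference_spectrum(
    image,
    scheme: AcquisitionScheme,
    *,
    quantile: float = 0.001,
    mask: np.ndarray | None = None,
    channel_name: str = "reference",
) -> ReferenceSpectrum:
    """Extract a reference spectrum from a 1-plex (or unlabeled AF) image.

    Operationalizes "region of maximum expression" as the brightest pixels:
    by default the top ``quantile`` fraction (0.1%) of pixels ranked by
    intensity summed over the measurement axis; an explicit boolean ``mask``
    over (Z, Y, X) overrides the quantile selection.  The mean spectrum of
    the selected pixels is normalized to peak 1.
    """
    data = np.asarray(getattr(image, "data", image), dtype=float)
    if data.shape[-1] != scheme.m:
        raise SchemeError(
            f"image has {data.shape[-1]} measurements; scheme expects M={scheme.m}"
        )
    flat = data.reshape(-1, scheme.m)
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).reshape(-1)
        if sel.shape[0] != flat.shape[0]:
            raise ValueError("mask shape does not match image spatial shape")
        if not sel.any():
            raise ValueError("degenerate reference: empty selection mask")
    else:
        if not 0 < quantile < 1:
            raise ValueError("selection quantile must lie in (0, 1)")
        totals = flat.sum(axis=1)
        n_keep = max(1, int(np.ceil(quantile * totals.size)))
        # brightest n_keep pixels; stable against ties via argsort
        order = np.argsort(totals, kind="stable")
        sel = np.zeros(totals.size, dtype=bool)
        sel[order[-n_keep:]] = True
    mean_spec = flat[sel].mean(axis=0)
    if mean_spec.max() <= 0:
        raise ValueError("degenerate reference: selected pixels are all zero")
    return ReferenceSpectrum(channel_name=channel_name, intensities=mean_spec, scheme=scheme)


def optimize_af_channel(
    scan: EEMScan,
    n_detectors: int = 4,
    *,
    guard_nm: float = 10.0,
) -> tuple[float, tuple[tuple[float, float], ...]]:
    """Place the autofluorescence channel from an excitation-emission scan.

    Chooses the excitation line whose total emission — summed over emission
    wavelengths red of the line plus a guard offset — is maximal (ties go to
    the shortest wavelength), then partitions the remaining red-shifted
    emission range into ``n_detectors`` contiguous equal-width bands starting
    ``guard_nm`` past the chosen line.

    Returns ``(af_excitation_nm, bands)``.
    """
    if n_detectors < 1:
        raise ValueError("n_detectors must be >= 1")
    ex = np.asarray(scan.excitations, dtype=float)
    em = np.asarray(scan.emissions, dtype=float)
    if scan.intensity.max() <= 0:
        raise ValueError("no autofluorescence detected: scan is all zero")
    totals = np.array(
        [scan.intensity[i, em >= e + guard_nm].sum() for i, e in enumerate(ex)]
    )
    best = int(np.argmax(totals))  # np.argmax returns the first (shortest-wavelength) tie
    af_ex = float(ex[best])
    lo, hi = af_ex + guard_nm, float(em.max())
    if hi <= lo:
        raise ValueError(
            f"no emission range red of excitation {af_ex} nm + {guard_nm} nm guard"
        )
    edges = np.linspace(lo, hi, n_detectors + 1)
    bands = tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))
    return af_ex, bands


@dataclass(frozen=True)
class ConditionReport:
    """Diagnostics of reference-matrix conditioning for unmixing."""

    condition_number: float
    cosine_similarity: np.ndarray  # C×C, diagonal 1
    min_pairwise_angle_deg: float
    warn: bool
    angle_threshold_deg: float

    @property
    def messages(self) -> list[str]:
        if not self.warn:
            return []
        return [
            f"minimum pairwise column angle {self.min_pairwise_angle_deg:.3g} deg "
            f"below threshold {self.angle_threshold_deg:g} deg: unmixing may be ill-posed"
        ]


def condition_report(
    ref: ReferenceMatrix | np.ndarray,
    *,
    angle_threshold_deg: float = 5.0,
) -> ConditionReport:
    """Conditioning diagnostics: condition number, pairwise column cosine
    similarities, and the minimum pairwise angle.

    Near-parallel columns (small minimum angle) make per-pixel unmixing
    ill-posed: noise moves intensity between the colinear channels.  The
    report warns (never errors) when the minimum angle drops below the
    threshold.
    """
    r = ref.matrix if isinstance(ref, ReferenceMatrix) else np.asarray(ref, dtype=float)
    cond = float(np.linalg.cond(r))
    norms = np.linalg.norm(r, axis=0)
    unit = r / norms
    cos = np.clip(unit.T @ unit, -1.0, 1.0)
    c = cos.shape[0]
    if c > 1:
        off = cos[np.triu_indices(c, k=1)]
        min_angle = float(np.degrees(np.arccos(np.max(off))))
    else:
        min_angle = 90.0
    return ConditionReport(
        condition_number=cond,
        cosine_similarity=cos,
        min_pairwise_angle_deg=min_angle,
        warn=min_angle < angle_threshold_deg,
        angle_threshold_deg=angle_threshold_deg,
    )
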