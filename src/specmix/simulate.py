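"""Forward model of multi-excitation/multi-detector spectral acquisition.

Renders synthetic multiplexed-stain samples with known ground truth.  Each
fluorophore is a parametric stand-in with Gaussian excitation and emission
profiles (real dye spectra are asymmetric, but Gaussians give analytic band
integrals and controllable spectral overlap).  A scene is a set of per-channel
abundance fields — geometric domains, explicit arrays, or diffraction-limited
point sources — plus a smooth low-frequency autofluorescence field.  The
expected pixel spectrum is the linear superposition of each channel's
response vector weighted by its abundance; optional shot noise is Poisson on
a photon scale set by ``photon_budget``, plus additive Gaussian read noise.

All randomness flows from a single scene seed; independent sub-streams are
derived per stage (field synthesis, dot placement, shot noise) so stages are
individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .spectra import AcquisitionScheme, EEMScan, ReferenceMatrix, ReferenceSpectrum
from .unmixing import SpectralImage

__all__ = [
    "FluorophoreModel",
    "Box",
    "Ellipsoid",
    "Stripe",
    "PointSource",
    "ChannelSpec",
    "SceneSpec",
    "RenderResult",
    "predict_response",
    "render_spectral_image",
    "make_redundant_detection_scene",
    "make_single_molecule_scene",
    "default_scheme",
    "default_fluorophores",
    "default_af_model",
    "true_reference_matrix",
    "simulate_eem",
]


@dataclass(frozen=True)
class FluorophoreModel:
    """Parametric fluorophore: Gaussian excitation and emission profiles.

    ``brightness`` is the expected photon yield per unit abundance at peak
    excitation with the full emission spectrum captured.
    """

    name: str
    excitation_peak: float  # nm
    excitation_width: float  # Gaussian sigma, nm
    emission_peak: float  # nm
    emission_width: float  # Gaussian sigma, nm
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.emission_peak < self.excitation_peak:
            raise ValueError(f"{self.name}: emission peak blue of excitation peak")
        if self.excitation_width <= 0 or self.emission_width <= 0:
            raise ValueError(f"{self.name}: spectral widths must be positive")
        if self.brightness < 0:
            raise ValueError(f"{self.name}: brightness must be non-negative")


def predict_response(f: FluorophoreModel, scheme: AcquisitionScheme) -> np.ndarray:
    """Expected M-vector response of a fluorophore under an acquisition scheme.

    Entry for excitation ``e`` and band ``[a, b]``:
    ``brightness × exp(−(e−ex_peak)²/(2σ_ex²)) × ∫_a^b N(em_peak, σ_em)``,
    with the emission profile a unit-area Gaussian.
    """
    out = np.empty(scheme.m, dtype=float)
    for i, (e, (a, b)) in enumerate(scheme.pairs):
        exc = math.exp(-((e - f.excitation_peak) ** 2) / (2.0 * f.excitation_width**2))
        frac = ndtr((b - f.emission_peak) / f.emission_width) - ndtr(
            (a - f.emission_peak) / f.emission_width
        )
        out[i] = f.brightness * exc * frac
    return out


# ---------------------------------------------------------------------------
# Scene geometry


@dataclass(frozen=True)
class Box:
    """Axis-aligned box domain: corners ``lo``/``hi`` in µm (z, y, x)."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    amplitude: float


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid domain: center and semi-axes in µm (z, y, x)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    amplitude: float


@dataclass(frozen=True)
class Stripe:
    """Slab between two coordinates along one axis (0=z, 1=y, 2=x), µm."""

    axis: int
    start: float
    end: float
    amplitude: float


@dataclass(frozen=True)
class PointSource:
    """Diffraction-limited dot: Gaussian of per-axis sigma (µm) at a position."""

    position: tuple[float, float, float]  # µm (z, y, x)
    amplitude: float
    sigma: tuple[float, float, float]  # µm (z, y, x)


@dataclass
class ChannelSpec:
    """Abundance field for one fluorophore channel.

    Composed of geometric domains and/or point sources; ``array`` supplies an
    explicit precomputed field instead (added to any domains/points).
    """

    name: str
    domains: list = field(default_factory=list)
    points: list = field(default_factory=list)
    array: np.ndarray | None = None


@dataclass
class SceneSpec:
    """Full description of a synthetic sample and its acquisition noise.

    ``photon_budget=None`` disables shot noise entirely (the rendered image
    is the exact linear model); otherwise intensities are Poisson sampled at
    ``expected × photon_budget`` photons and rescaled.  ``read_noise_sigma``
    adds Gaussian read noise on the intensity scale after rescaling.
    """

    shape: tuple[int, int, int]  # (Z, Y, X) pixels
    pixel_size: tuple[float, float, float]  # µm per (z, y, x)
    channels: list[ChannelSpec]
    af_amplitude: float = 0.0
    af_modes: int = 3
    photon_budget: float | None = None
    read_noise_sigma: float = 0.0
    seed: int = 0
    truth_dots: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or any(p <= 0 for p in self.pixel_size):
            raise ValueError("scene shape and pixel sizes must be positive")
        if self.af_amplitude < 0 or self.read_noise_sigma < 0:
            raise ValueError("amplitudes and noise sigmas must be non-negative")
        if self.photon_budget is not None and self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive (or None for noise-free)")

    @property
    def fov_um(self) -> tuple[float, float, float]:
        return tuple(s * p for s, p in zip(self.shape, self.pixel_size))


def _pixel_centers(scene: SceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * p for n, p in zip(scene.shape, scene.pixel_size)
    ]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_channel(scene: SceneSpec, ch: ChannelSpec) -> np.ndarray:
    """Evaluate a channel's abundance field on the scene's pixel-center grid."""
    zz, yy, xx = _pixel_centers(scene)
    out = np.zeros(scene.shape, dtype=float)
    for d in ch.domains:
        if isinstance(d, Box):
            m = (
                (zz >= d.lo[0]) & (zz < d.hi[0])
                & (yy >= d.lo[1]) & (yy < d.hi[1])
                & (xx >= d.lo[2]) & (xx < d.hi[2])
            )
            out += d.amplitude * m
        elif isinstance(d, Ellipsoid):
            q = (
                ((zz - d.center[0]) / d.radii[0]) ** 2
                + ((yy - d.center[1]) / d.radii[1]) ** 2
                + ((xx - d.center[2]) / d.radii[2]) ** 2
            )
            out += d.amplitude * (q <= 1.0)
        elif isinstance(d, Stripe):
            coord = (zz, yy, xx)[d.axis]
            out += d.amplitude * ((coord >= d.start) & (coord < d.end))
        else:
            raise TypeError(f"unknown domain primitive: {type(d).__name__}")
    for p in ch.points:
        out += p.amplitude * np.exp(
            -(
                ((zz - p.position[0]) ** 2) / (2 * p.sigma[0] ** 2)
                + ((yy - p.position[1]) ** 2) / (2 * p.sigma[1] ** 2)
                + ((xx - p.position[2]) ** 2) / (2 * p.sigma[2] ** 2)
            )
        )
    if ch.array is not None:
        arr = np.asarray(ch.array, dtype=float)
        if arr.shape != scene.shape:
            raise ValueError(
                f"channel '{ch.name}' array shape {arr.shape} != scene shape {scene.shape}"
            )
        out += arr
    if np.any(out < 0):
        raise ValueError(f"channel '{ch.name}' abundance field has negative values")
    return out


def af_field(scene: SceneSpec) -> np.ndarray:
    """Smooth low-frequency autofluorescence map, reproducible from the seed.

    A sum of a few random low-frequency cosine modes, rescaled so the field
    spans ``[0.3, 1] × af_amplitude`` — broad tissue-like variation with no
    sharp structure.
    """
    if scene.af_amplitude == 0:
        return np.zeros(scene.shape, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(scene.seed).spawn(3)[0])
    zz, yy, xx = _pixel_centers(scene)
    fov = scene.fov_um
    f = np.zeros(scene.shape, dtype=float)
    for _ in range(scene.af_modes):
        freq = rng.uniform(0.2, 1.0, size=3) / np.asarray(fov)  # cycles per µm
        phase = rng.uniform(0, 2 * np.pi, size=3)
        f += (
            np.cos(2 * np.pi * freq[0] * zz + phase[0])
            * np.cos(2 * np.pi * freq[1] * yy + phase[1])
            * np.cos(2 * np.pi * freq[2] * xx + phase[2])
        )
    lo, hi = f.min(), f.max()
    norm = (f - lo) / (hi - lo) if hi > lo else np.full(scene.shape, 0.5)
    return scene.af_amplitude * (0.3 + 0.7 * norm)


@dataclass
class RenderResult:
    """A rendered spectral image with its ground truth.

    ``truth`` is (Z, Y, X, C+1): per-channel abundance fields with the AF
    field as the final channel; ``responses`` is the true (unnormalized)
    M×(C+1) response matrix used by the renderer.
    """

    image: SpectralImage
    truth: np.ndarray
    channel_names: list[str]
    responses: np.ndarray


def render_spectral_image(
    scene: SceneSpec,
    fluorophores: list[FluorophoreModel],
    af_spectrum: np.ndarray,
    scheme: AcquisitionScheme,
) -> RenderResult:
    """Render a scene to a spectral image stack with known ground truth.

    Expected spectrum per pixel = Σ_c abundance_c × response_c + AF × af_spectrum.
    With ``photon_budget`` set, the observed stack is
    ``Poisson(expected × budget) / budget + N(0, read_noise_sigma)`` clamped
    at zero; noise disabled means observed == expected exactly.
    """
    if len(fluorophores) != len(scene.channels):
        raise ValueError(
            f"{len(scene.channels)} scene channels but {len(fluorophores)} fluorophore models"
        )
    af_spectrum = np.asarray(af_spectrum, dtype=float)
    if af_spectrum.shape != (scheme.m,):
        raise ValueError(f"af_spectrum must have length M={scheme.m}")
    fields = [rasterize_channel(scene, ch) for ch in scene.channels]
    fields.append(af_field(scene))
    truth = np.stack(fields, axis=-1)  # (Z, Y, X, C+1)
    responses = np.column_stack(
        [predict_response(f, scheme) for f in fluorophores] + [af_spectrum]
    )
    expected = truth @ responses.T  # (Z, Y, X, M)
    observed = expected
    if scene.photon_budget is not None or scene.read_noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(scene.seed).spawn(5)[4])
        observed = expected.copy()
        if scene.photon_budget is not None:
            observed = rng.poisson(expected * scene.photon_budget) / scene.photon_budget
        if scene.read_noise_sigma > 0:
            observed = observed + rng.normal(0.0, scene.read_noise_sigma, size=observed.shape)
        observed = np.clip(observed, 0.0, None)
    image = SpectralImage(data=observed, pixel_size=scene.pixel_size, scheme=scheme)
    names = [ch.name for ch in scene.channels] + ["AF"]
    return RenderResult(image=image, truth=truth, channel_names=names, responses=responses)


# ---------------------------------------------------------------------------
# Scene factories


def _blob_field(
    shape: tuple[int, int, int],
    pixel_size: tuple[float, float, float],
    rng: np.random.Generator,
    n_blobs: int = 6,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Smooth expression-like field: a few soft Gaussian blobs of varying size."""
    fov = np.asarray([s * p for s, p in zip(shape, pixel_size)])
    axes = [(np.arange(n) + 0.5) * p for n, p in zip(shape, pixel_size)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    out = np.zeros(shape, dtype=float)
    for _ in range(n_blobs):
        c = rng.uniform(0.15, 0.85, size=3) * fov
        s = rng.uniform(0.08, 0.25, size=3) * fov
        a = amplitude * rng.uniform(0.4, 1.0)
        out += a * np.exp(
            -(
                ((zz - c[0]) ** 2) / (2 * s[0] ** 2)
                + ((yy - c[1]) ** 2) / (2 * s[1] ** 2)
                + ((xx - c[2]) ** 2) / (2 * s[2] ** 2)
            )
        )
    return out


def make_redundant_detection_scene(
    base_abundance: np.ndarray | None,
    gains: tuple[float, float],
    seed: int,
    *,
    shape: tuple[int, int, int] = (2, 88, 88),
    pixel_size: tuple[float, float, float] = (1.2, 0.18, 0.18),
    af_amplitude: float = 0.3,
    photon_budget: float | None = None,
    read_noise_sigma: float = 0.0,
) -> SceneSpec:
    """Two fluorophore channels sharing one abundance field scaled by gains.

    The simulator analog of redundant detection: one target detected by two
    probe sets triggering different amplifiers/fluorophores.  With gains
    (gA, gB), channel-B truth is everywhere (gB/gA) × channel-A truth, so a
    two-channel voxel scatter of a noise-free render lies exactly on a line
    through the origin.
    """
    if gains[0] <= 0 or gains[1] <= 0:
        raise ValueError("channel gains must be positive")
    if base_abundance is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
        base = _blob_field(shape, pixel_size, rng)
    else:
        base = np.asarray(base_abundance, dtype=float)
        shape = base.shape
    channels = [
        ChannelSpec(name="chA", array=gains[0] * base),
        ChannelSpec(name="chB", array=gains[1] * base),
    ]
    return SceneSpec(
        shape=tuple(shape),
        pixel_size=pixel_size,
        channels=channels,
        af_amplitude=af_amplitude,
        photon_budget=photon_budget,
        read_noise_sigma=read_noise_sigma,
        seed=seed,
    )


def make_single_molecule_scene(
    n_dots: int,
    *,
    shape: tuple[int, int, int] = (8, 64, 64),
    pixel_size: tuple[float, float, float] = (0.4, 0.18, 0.18),
    psf_sigma_um: tuple[float, float, float] = (0.5, 0.25, 0.25),
    amplitude: float = 10.0,
    min_separation_um: float = 1.5,
    seed: int = 0,
    af_amplitude: float = 0.2,
    photon_budget: float | None = None,
    read_noise_sigma: float = 0.0,
    max_attempts: int = 100_000,
) -> SceneSpec:
    """Shared-truth single-molecule scene for a redundant channel pair.

    ``n_dots`` positions are sampled uniformly (rejection sampling enforces
    ``min_separation_um`` pairwise and a 2σ margin from the field-of-view
    edges) and written as identical point sources into both channels.  The
    ground-truth positions are stored on the returned scene as
    ``truth_dots`` (µm).
    """
    if n_dots < 0:
        raise ValueError("n_dots must be >= 0")
    if min_separation_um < 0:
        raise ValueError("min_separation_um must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    fov = np.asarray([s * p for s, p in zip(shape, pixel_size)])
    margin = 2.0 * np.asarray(psf_sigma_um)
    if np.any(fov - 2 * margin <= 0):
        raise ValueError("field of view too small for the PSF margin")
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n_dots:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_dots} dots with min separation "
                f"{min_separation_um} µm after {max_attempts} attempts"
            )
        attempts += 1
        cand = rng.uniform(margin, fov - margin)
        if all(np.linalg.norm(cand - p) >= min_separation_um for p in positions):
            positions.append(cand)
    points = [
        PointSource(position=tuple(p), amplitude=amplitude, sigma=tuple(psf_sigma_um))
        for p in positions
    ]
    channels = [
        ChannelSpec(name="chA", points=list(points)),
        ChannelSpec(name="chB", points=list(points)),
    ]
    return SceneSpec(
        shape=tuple(shape),
        pixel_size=tuple(pixel_size),
        channels=channels,
        af_amplitude=af_amplitude,
        photon_budget=photon_budget,
        read_noise_sigma=read_noise_sigma,
        seed=seed,
        truth_dots=[tuple(float(v) for v in p) for p in positions],
    )


def make_multiplex_scene(
    n_channels: int = 10,
    *,
    shape: tuple[int, int, int] = (3, 64, 64),
    pixel_size: tuple[float, float, float] = (1.2, 0.57, 0.57),
    amplitude: float = 1.0,
    af_amplitude: float = 0.3,
    photon_budget: float | None = None,
    read_noise_sigma: float = 0.0,
    seed: int = 0,
) -> SceneSpec:
    """Embryo-like multiplexed scene: one smooth blob field per channel.

    Each channel gets an independent expression-like field (a few soft
    Gaussian blobs, overlapping across channels as real expression patterns
    do) over a shared low-frequency autofluorescence background.
    """
    children = np.random.SeedSequence(seed).spawn(n_channels)
    channels = [
        ChannelSpec(
            name=f"Ch{i + 1}",
            array=_blob_field(shape, pixel_size, np.random.default_rng(children[i]),
                              amplitude=amplitude),
        )
        for i in range(n_channels)
    ]
    return SceneSpec(
        shape=tuple(shape),
        pixel_size=tuple(pixel_size),
        channels=channels,
        af_amplitude=af_amplitude,
        photon_budget=photon_budget,
        read_noise_sigma=read_noise_sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Default 10-plex fixture: 11 excitations, 26 detectors, emissions ~420-810 nm


_FLUOR_TABLE = [
    # name, ex_peak, sigma_ex, em_peak, sigma_em
    ("F405", 405.0, 18.0, 430.0, 20.0),
    ("F425", 425.0, 18.0, 455.0, 22.0),
    ("F488", 488.0, 20.0, 517.0, 22.0),
    ("F514", 514.0, 20.0, 542.0, 24.0),
    ("F546", 546.0, 20.0, 572.0, 24.0),
    ("F594", 594.0, 22.0, 620.0, 26.0),
    ("F633", 633.0, 22.0, 657.0, 26.0),
    ("F700", 700.0, 24.0, 722.0, 28.0),
    ("F750", 750.0, 24.0, 776.0, 28.0),
    ("F775", 775.0, 24.0, 800.0, 30.0),
]

_AF_EXCITATION = 470.0
# detectors per excitation line; the AF line (470 nm) carries four
_DETECTOR_COUNTS = {
    405.0: 3,
    425.0: 3,
    _AF_EXCITATION: 4,
    488.0: 3,
    514.0: 2,
    546.0: 2,
    594.0: 2,
    633.0: 2,
    700.0: 2,
    750.0: 2,
    775.0: 1,
}
_GUARD_NM = 10.0
_BAND_WIDTH_NM = 25.0


def default_scheme() -> AcquisitionScheme:
    """The bundled 10-plex acquisition scheme.

    Eleven excitation lines (one per fluorophore plus one for AF) with one to
    four contiguous 25 nm detector bands each — 26 detectors total, spanning
    emissions from ~415 to 810 nm.
    """
    excitations = tuple(sorted(_DETECTOR_COUNTS))
    detectors = []
    for e in excitations:
        k = _DETECTOR_COUNTS[e]
        start = e + _GUARD_NM
        bands = tuple(
            (start + i * _BAND_WIDTH_NM, start + (i + 1) * _BAND_WIDTH_NM) for i in range(k)
        )
        detectors.append(bands)
    return AcquisitionScheme(excitations=excitations, detectors=tuple(detectors))


def default_fluorophores() -> list[FluorophoreModel]:
    """Ten parametric fluorophores with overlapping spectra spanning 405-800 nm."""
    return [
        FluorophoreModel(name=n, excitation_peak=ex, excitation_width=sx,
                         emission_peak=em, emission_width=se)
        for n, ex, sx, em, se in _FLUOR_TABLE
    ]


def default_af_model() -> FluorophoreModel:
    """Broad-band autofluorescence stand-in (wide excitation and emission)."""
    return FluorophoreModel(
        name="AF",
        excitation_peak=_AF_EXCITATION,
        excitation_width=80.0,
        emission_peak=545.0,
        emission_width=80.0,
    )


def true_reference_matrix(
    fluorophores: list[FluorophoreModel] | None = None,
    af_models: list[FluorophoreModel] | None = None,
    scheme: AcquisitionScheme | None = None,
) -> tuple[ReferenceMatrix, np.ndarray]:
    """Noise-free reference matrix from fluorophore models.

    Returns the normalized matrix plus the per-column peak responses, so that
    an unmixed coefficient equals ``true_abundance × peak`` for each channel.
    """
    scheme = scheme or default_scheme()
    fluorophores = fluorophores if fluorophores is not None else default_fluorophores()
    af_models = af_models if af_models is not None else [default_af_model()]
    spectra = []
    peaks = []
    for f in fluorophores + af_models:
        resp = predict_response(f, scheme)
        peaks.append(resp.max())
        spectra.append(ReferenceSpectrum(channel_name=f.name, intensities=resp, scheme=scheme))
    ref = ReferenceMatrix(scheme=scheme, spectra=spectra, n_af=len(af_models))
    return ref, np.asarray(peaks)


def simulate_eem(
    model: FluorophoreModel,
    excitations: np.ndarray,
    emissions: np.ndarray,
) -> EEMScan:
    """Separable excitation-emission scan of a single (AF-like) emitter."""
    ex = np.asarray(excitations, dtype=float)
    em = np.asarray(emissions, dtype=float)
    f_ex = np.exp(-((ex - model.excitation_peak) ** 2) / (2 * model.excitation_width**2))
    g_em = np.exp(-((em - model.emission_peak) ** 2) / (2 * model.emission_width**2))
    return EEMScan(
        excitations=tuple(ex),
        emissions=tuple(em),
        intensity=model.brightness * np.outer(f_ex, g_em),
    )
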