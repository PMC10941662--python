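"""File I/O: OME-TIFF spectral stacks, reference-spectrum / dot / voxel CSVs,
and acquisition-scheme YAML.

Arrays are indexed (Z, Y, X) with the channel/measurement axis last in
memory; on disk, stacks are OME-TIFF with axes ZCYX, physical pixel sizes in
the OME metadata, and channel names as OME channel annotations.  All CSVs use
physical µm coordinates with the origin at the corner of pixel (0, 0, 0).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dots import Dot
from .quantitation import VoxelTable
from .spectra import AcquisitionScheme, ReferenceMatrix, ReferenceSpectrum, SchemeError
from .unmixing import SpectralImage, UnmixedImage

__all__ = [
    "read_scheme",
    "write_scheme",
    "read_spectral_stack",
    "write_spectral_stack",
    "write_unmixed",
    "read_reference_matrix",
    "write_reference_matrix",
    "read_dots",
    "write_dots",
    "write_voxel_table",
]


# ---------------------------------------------------------------------------
# Acquisition scheme YAML


def write_scheme(path: str | Path, scheme: AcquisitionScheme) -> None:
    doc = {
        "excitations": [
            {
                "wavelength_nm": float(e),
                "detectors": [[float(a), float(b)] for a, b in bands],
            }
            for e, bands in zip(scheme.excitations, scheme.detectors)
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scheme(path: str | Path) -> AcquisitionScheme:
    doc = yaml.safe_load(Path(path).read_text())
    entries = doc["excitations"]
    return AcquisitionScheme(
        excitations=tuple(float(e["wavelength_nm"]) for e in entries),
        detectors=tuple(
            tuple((float(a), float(b)) for a, b in e["detectors"]) for e in entries
        ),
    )


# ---------------------------------------------------------------------------
# Spectral stacks (OME-TIFF, axes ZCYX)


def write_spectral_stack(path: str | Path, image: SpectralImage) -> None:
    """Write a (Z, Y, X, M) stack as OME-TIFF with pixel sizes in metadata."""
    data = np.moveaxis(image.data, -1, 1)  # -> (Z, M, Y, X)
    pz, py, px = image.pixel_size
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeZ": pz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": py,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": px,
            "PhysicalSizeXUnit": "µm",
        },
    )


def _read_stack_array(path: str | Path) -> tuple[np.ndarray, str | None, dict]:
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
        meta: dict = {}
        if tif.ome_metadata:
            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px_el = root.find(".//ome:Pixels", ns)
            if px_el is not None:
                for key in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX"):
                    if key in px_el.attrib:
                        meta[key] = float(px_el.attrib[key])
                meta["channel_names"] = [
                    ch.attrib.get("Name", "") for ch in px_el.findall("ome:Channel", ns)
                ]
    return arr, axes, meta


def read_spectral_stack(
    path: str | Path,
    scheme: AcquisitionScheme,
    pixel_size: tuple[float, float, float] | None = None,
) -> SpectralImage:
    """Read a TIFF/OME-TIFF stack and normalize axes to (Z, Y, X, M).

    Single-plane images are promoted to Z=1.  The channel count must equal
    the scheme's M; pixel sizes come from OME metadata unless ``pixel_size``
    overrides them.
    """
    arr, axes, meta = _read_stack_array(path)
    if arr.ndim == 2:  # (Y, X): one plane, one channel
        arr = arr[None, None]  # (Z=1, C=1, Y, X)
    elif arr.ndim == 3:  # assume (C, Y, X) per plain multi-page convention
        arr = arr[None]
    elif arr.ndim == 4:
        if axes == "CZYX":
            arr = np.moveaxis(arr, 0, 1)
        elif axes not in (None, "ZCYX", "QQYX"):
            raise ValueError(f"unsupported axis order {axes!r} in {path}")
    else:
        raise ValueError(f"cannot interpret {arr.ndim}-D stack in {path}")
    data = np.moveaxis(arr, 1, -1)  # (Z, Y, X, M)
    if data.shape[-1] != scheme.m:
        raise SchemeError(
            f"{path}: stack has {data.shape[-1]} channels; scheme expects M={scheme.m}"
        )
    if pixel_size is None:
        try:
            pixel_size = (
                meta["PhysicalSizeZ"],
                meta["PhysicalSizeY"],
                meta["PhysicalSizeX"],
            )
        except KeyError:
            raise ValueError(
                f"{path}: no physical pixel sizes in metadata; pass pixel_size explicitly"
            ) from None
    return SpectralImage(data=data, pixel_size=pixel_size, scheme=scheme)


def write_unmixed(path: str | Path, unmixed: UnmixedImage) -> None:
    """Write unmixed coefficient channels as OME-TIFF with channel names."""
    data = np.moveaxis(unmixed.coefficients, -1, 1)
    pz, py, px = unmixed.pixel_size
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeZ": pz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": py,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": px,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(unmixed.channel_names)},
        },
    )


def write_residual(path: str | Path, unmixed: UnmixedImage) -> None:
    """Write the per-pixel residual-norm map as a single-channel TIFF."""
    tifffile.imwrite(str(path), unmixed.residual)


# ---------------------------------------------------------------------------
# Reference spectra CSV
# columns: channel, excitation_nm, band_start_nm, band_end_nm, intensity
# (M rows per channel in measurement order; AF columns are the channels whose
# names start with "AF")


def write_reference_matrix(path: str | Path, ref: ReferenceMatrix) -> None:
    rows = ref.scheme.describe_rows()
    records = []
    for spec in ref.spectra:
        for row, v in zip(rows, spec.intensities):
            records.append({"channel": spec.channel_name, **row, "intensity": v})
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_reference_matrix(path: str | Path, scheme: AcquisitionScheme) -> ReferenceMatrix:
    df = pd.read_csv(path)
    spectra = []
    for name in df["channel"].unique():
        sub = df[df["channel"] == name]
        if len(sub) != scheme.m:
            raise SchemeError(
                f"channel {name!r} has {len(sub)} rows; scheme expects M={scheme.m}"
            )
        spectra.append(
            ReferenceSpectrum(
                channel_name=str(name),
                intensities=sub["intensity"].to_numpy(dtype=float),
                scheme=scheme,
            )
        )
    n_af = sum(1 for s in spectra if s.channel_name.startswith("AF"))
    return ReferenceMatrix(scheme=scheme, spectra=spectra, n_af=n_af)


# ---------------------------------------------------------------------------
# Dot lists and voxel tables


_DOT_COLUMNS = ["z_um", "y_um", "x_um", "sigma_um", "intensity", "channel"]


def write_dots(path: str | Path, dots: list[Dot]) -> None:
    pd.DataFrame(
        [
            {
                "z_um": d.z_um,
                "y_um": d.y_um,
                "x_um": d.x_um,
                "sigma_um": d.sigma_um,
                "intensity": d.intensity,
                "channel": d.channel,
            }
            for d in dots
        ],
        columns=_DOT_COLUMNS,
    ).to_csv(path, index=False)


def read_dots(path: str | Path) -> list[Dot]:
    df = pd.read_csv(path)
    return [
        Dot(
            z_um=float(r.z_um),
            y_um=float(r.y_um),
            x_um=float(r.x_um),
            sigma_um=float(r.sigma_um),
            intensity=float(r.intensity),
            channel="" if pd.isna(r.channel) else str(r.channel),
        )
        for r in df.itertuples()
    ]


def write_voxel_table(path: str | Path, table: VoxelTable) -> None:
    table.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Excitation-emission scans (long CSV: excitation_nm, emission_nm, intensity)


def write_eem(path: str | Path, scan) -> None:
    from .spectra import EEMScan  # noqa: F401  (type only)

    records = [
        {"excitation_nm": e, "emission_nm": m, "intensity": scan.intensity[i, j]}
        for i, e in enumerate(scan.excitations)
        for j, m in enumerate(scan.emissions)
    ]
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_eem(path: str | Path):
    from .spectra import EEMScan

    df = pd.read_csv(path)
    pivot = df.pivot_table(
        index="excitation_nm", columns="emission_nm", values="intensity", sort=True
    )
    return EEMScan(
        excitations=tuple(float(v) for v in pivot.index),
        emissions=tuple(float(v) for v in pivot.columns),
        intensity=pivot.to_numpy(dtype=float),
    )


def read_unmixed(path: str | Path, residual_path: str | Path | None = None) -> UnmixedImage:
    """Read an unmixed OME-TIFF written by :func:`write_unmixed`.

    The residual map is read from ``residual_path`` when given, else zeros.
    """
    arr, axes, meta = _read_stack_array(path)
    if arr.ndim == 3:
        arr = arr[None]
    if axes == "CZYX":
        arr = np.moveaxis(arr, 0, 1)
    coeffs = np.moveaxis(arr, 1, -1).astype(float)
    names = meta.get("channel_names") or [f"Ch{i + 1}" for i in range(coeffs.shape[-1])]
    try:
        pixel_size = (meta["PhysicalSizeZ"], meta["PhysicalSizeY"], meta["PhysicalSizeX"])
    except KeyError:
        raise ValueError(f"{path}: no physical pixel sizes in metadata") from None
    if residual_path is not None:
        residual = tifffile.imread(str(residual_path)).astype(float)
        if residual.ndim == 2:
            residual = residual[None]
    else:
        residual = np.zeros(coeffs.shape[:3])
    with np.errstate(invalid="ignore"):
        rel = np.zeros_like(residual)
    return UnmixedImage(
        coefficients=coeffs,
        residual=residual,
        relative_residual=rel,
        channel_names=list(names),
        pixel_size=tuple(float(p) for p in pixel_size),
    )
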