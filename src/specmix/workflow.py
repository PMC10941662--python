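"""End-to-end workflow: reference extraction → matrix build → unmixing →
optional quantitation stages, driven by a validated YAML config.

The workflow mirrors the standard multiplexed spectral-imaging experiment:
one spectral stack of the multiplexed sample, one 1-plex reference stack per
fluorophore, and one unlabeled stack for the autofluorescence reference.
Reference spectra are extracted from the brightest pixels of each reference
stack, stacked into a reference matrix (with a conditioning report), and the
multiplexed stack is unmixed per pixel.  Optional stages compute
signal-to-background, voxel-level two-channel linearity statistics, and
single-molecule dot detection with cross-channel colocalization.

All randomness flows from the config's master seed; rerunning an identical
config over identical inputs reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, io, quantitation, simulate
from .dots import coloc_summary, colocalize, detect_dots
from .spectra import condition_report, extract_reference_spectrum
from .unmixing import ReferenceMatrix, unmix_image

__all__ = ["RunConfig", "run_workflow", "load_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateStage(_StrictModel):
    """Generate the workflow's input stacks from the bundled simulator."""

    preset: str = "embryo_10plex"
    n_channels: int = Field(default=10, ge=1)
    shape: tuple[int, int, int] = (2, 32, 32)
    pixel_size: tuple[float, float, float] = (1.2, 0.57, 0.57)
    photon_budget: float | None = None
    read_noise_sigma: float = Field(default=0.0, ge=0)
    af_amplitude: float = Field(default=0.3, ge=0)


class S2BStage(_StrictModel):
    channel: str
    high_quantile: float = Field(default=0.999, gt=0, lt=1)
    low_quantile: float = Field(default=0.2, gt=0, lt=1)
    high_mask: str | None = None
    low_mask: str | None = None


class QHCRStage(_StrictModel):
    channel_a: str
    channel_b: str
    voxel_size_um: tuple[float, float, float] = (1.2, 2.0, 2.0)
    quantile: float = Field(default=0.999, gt=0, lt=1)


class DotsStage(_StrictModel):
    channel_a: str
    channel_b: str
    scales_um: list[float] = [0.35, 0.5, 0.7]
    threshold: float = Field(default=0.03, gt=0)
    min_separation_um: float = Field(default=0.8, ge=0)
    radius_um: float | None = None  # default: 2 × mean detection scale


class RunConfig(_StrictModel):
    """Validated workflow configuration (YAML; unknown keys are errors)."""

    output_dir: str
    seed: int = 0
    scheme: str = "default"  # "default" or a path to a scheme YAML
    pixel_size: tuple[float, float, float] | None = None
    tenplex_image: str | None = None
    reference_images: dict[str, str] = Field(default_factory=dict)
    af_image: str | None = None
    selection_quantile: float = Field(default=0.001, gt=0, lt=1)
    saturation_fraction: float = Field(default=0.001, ge=0, lt=1)
    simulate: SimulateStage | None = None
    s2b: S2BStage | None = None
    qhcr: QHCRStage | None = None
    dots: DotsStage | None = None


def load_config(path: str | Path) -> RunConfig:
    import yaml

    return RunConfig.model_validate(yaml.safe_load(Path(path).read_text()))


def _simulate_inputs(cfg: RunConfig, scheme, outdir: Path) -> RunConfig:
    """Render the simulated 10-plex sample, 1-plex references, and AF stack."""
    sim = cfg.simulate
    assert sim is not None
    fluors = simulate.default_fluorophores()[: sim.n_channels]
    af_model = simulate.default_af_model()
    af_spec = simulate.predict_response(af_model, scheme)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)

    scene = simulate.make_multiplex_scene(
        n_channels=sim.n_channels,
        shape=sim.shape,
        pixel_size=sim.pixel_size,
        af_amplitude=sim.af_amplitude,
        photon_budget=sim.photon_budget,
        read_noise_sigma=sim.read_noise_sigma,
        seed=cfg.seed,
    )
    render = simulate.render_spectral_image(scene, fluors, af_spec, scheme)
    tenplex = indir / "tenplex.ome.tif"
    io.write_spectral_stack(tenplex, render.image)

    refs: dict[str, str] = {}
    for i, f in enumerate(fluors):
        one = simulate.SceneSpec(
            shape=sim.shape,
            pixel_size=sim.pixel_size,
            channels=[scene.channels[i]],
            af_amplitude=0.0,
            seed=cfg.seed,
        )
        r = simulate.render_spectral_image(one, [f], np.zeros(scheme.m), scheme)
        p = indir / f"ref_{f.name}.ome.tif"
        io.write_spectral_stack(p, r.image)
        refs[f.name] = str(p)

    af_scene = simulate.SceneSpec(
        shape=sim.shape,
        pixel_size=sim.pixel_size,
        channels=[],
        af_amplitude=max(sim.af_amplitude, 0.3),
        seed=cfg.seed,
    )
    r = simulate.render_spectral_image(af_scene, [], af_spec, scheme)
    af_path = indir / "af.ome.tif"
    io.write_spectral_stack(af_path, r.image)

    return cfg.model_copy(
        update={
            "tenplex_image": str(tenplex),
            "reference_images": refs,
            "af_image": str(af_path),
        }
    )


def run_workflow(cfg: RunConfig) -> dict:
    """Execute the configured pipeline; returns the JSON-serializable report."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = simulate.default_scheme() if cfg.scheme == "default" else io.read_scheme(cfg.scheme)
    report: dict = {
        "specmix_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "parameters": json.loads(cfg.model_dump_json(exclude={"output_dir"})),
        "warnings": [],
        "stages": {},
    }
    stage = "simulate"
    try:
        if cfg.simulate is not None:
            cfg = _simulate_inputs(cfg, scheme, outdir)
            report["stages"]["simulate"] = {"inputs_dir": str(outdir / "inputs")}

        stage = "refspec"
        if not cfg.reference_images or cfg.af_image is None or cfg.tenplex_image is None:
            raise ValueError(
                "config must provide tenplex_image, reference_images and af_image "
                "(directly or via the simulate stage)"
            )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            spectra = []
            for name, path in cfg.reference_images.items():
                img = io.read_spectral_stack(path, scheme, pixel_size=cfg.pixel_size)
                spectra.append(
                    extract_reference_spectrum(
                        img, scheme, quantile=cfg.selection_quantile, channel_name=name
                    )
                )
            af_img = io.read_spectral_stack(cfg.af_image, scheme, pixel_size=cfg.pixel_size)
            spectra.append(
                extract_reference_spectrum(
                    af_img, scheme, quantile=cfg.selection_quantile, channel_name="AF"
                )
            )
            ref = ReferenceMatrix(scheme=scheme, spectra=spectra, n_af=1)
            diag = condition_report(ref)
            io.write_reference_matrix(outdir / "reference_spectra.csv", ref)
            report["stages"]["refspec"] = {
                "n_channels": ref.c,
                "condition_number": diag.condition_number,
                "min_pairwise_angle_deg": diag.min_pairwise_angle_deg,
            }
            report["warnings"] += diag.messages

            stage = "unmix"
            img = io.read_spectral_stack(cfg.tenplex_image, scheme, pixel_size=cfg.pixel_size)
            unmixed = unmix_image(img, ref)
            io.write_unmixed(outdir / "unmixed.ome.tif", unmixed)
            io.write_residual(outdir / "residual.tif", unmixed)
            report["stages"]["unmix"] = {
                "channels": unmixed.channel_names,
                "mean_residual": float(unmixed.residual.mean()),
            }

            stage = "s2b"
            if cfg.s2b is not None:
                ch = unmixed.channel(cfg.s2b.channel)
                if cfg.s2b.high_mask and cfg.s2b.low_mask:
                    import tifffile

                    hi = tifffile.imread(cfg.s2b.high_mask).astype(bool)
                    lo = tifffile.imread(cfg.s2b.low_mask).astype(bool)
                else:
                    hi = ch >= np.quantile(ch, cfg.s2b.high_quantile)
                    lo = (ch <= np.quantile(ch, cfg.s2b.low_quantile)) & ~hi
                ratio = quantitation.signal_to_background(ch, hi, lo)
                report["stages"]["s2b"] = {"channel": cfg.s2b.channel, "ratio": ratio}

            stage = "qhcr"
            if cfg.qhcr is not None:
                table = quantitation.bin_voxels(unmixed, cfg.qhcr.voxel_size_um)
                io.write_voxel_table(outdir / "voxels.csv", table)
                stats = quantitation.qhcr_scatter_from_table(
                    table, cfg.qhcr.channel_a, cfg.qhcr.channel_b, cfg.qhcr.quantile
                )
                report["stages"]["qhcr"] = {
                    "pearson_r": stats.pearson_r,
                    "slope_through_origin": stats.slope_through_origin,
                    "slope": stats.slope,
                    "intercept": stats.intercept,
                    "n_voxels": stats.n_voxels,
                }

            stage = "dots"
            if cfg.dots is not None:
                d = cfg.dots
                lists = {}
                for name in (d.channel_a, d.channel_b):
                    found = detect_dots(
                        unmixed.channel(name),
                        unmixed.pixel_size,
                        d.scales_um,
                        d.threshold,
                        d.min_separation_um,
                        channel=name,
                    )
                    io.write_dots(outdir / f"dots_{name}.csv", found)
                    lists[name] = found
                radius = d.radius_um or 2.0 * float(np.mean(d.scales_um))
                coloc = colocalize(lists[d.channel_a], lists[d.channel_b], radius)
                summary = coloc_summary([coloc])
                report["stages"]["dots"] = {
                    "n_a": coloc.n_a,
                    "n_b": coloc.n_b,
                    "fraction_a": coloc.fraction_a,
                    "fraction_b": coloc.fraction_b,
                    "radius_um": coloc.radius_um,
                    "summary": summary,
                }
            report["warnings"] += [str(w.message) for w in caught]
    except Exception as exc:
        report["error"] = {"stage": stage, "message": str(exc)}
        (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
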