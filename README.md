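# specmix

Spectral unmixing and quantitation for highly multiplexed fluorescence
imaging of RNA and protein targets in autofluorescent samples.

## The problem

Conventional bandpass fluorescence microscopy separates at most four or five
fluorophores because their spectra overlap.  Spectral imaging works around
this by measuring each pixel many times — a sequence of laser excitation
lines, each read out by one or more detector emission bands — and treating
the resulting M-vector **b** as a linear superposition of known *reference
spectra*:

```
b ≈ R x,   x ≥ 0
```

where **R** is the M×C reference matrix whose columns are the normalized
responses of each fluorophore (measured in 1-plex reference samples) plus
one or more autofluorescence (AF) columns (measured in unlabeled samples),
and **x** is the per-pixel vector of non-negative channel contributions.
Solving this non-negative least-squares problem per pixel yields one unmixed
image per fluorophore plus an AF channel — ten-target imaging in a single
round, with the sample's intrinsic fluorescence absorbed into its own
channel rather than contaminating the others.

`specmix` implements this pipeline end to end for amplified-FISH-style
(HCR) experiments:

- **spectra**: acquisition schemes, reference-spectrum extraction from
  1-plex/unlabeled stacks, excitation-emission-scan placement of the AF
  channel, reference-matrix conditioning diagnostics;
- **unmixing**: per-pixel active-set NNLS with residual maps;
- **quantitation**: signal-to-background estimation, subcellular-voxel
  binning and two-channel linearity statistics (the analog, "relative
  quantitation" readout), display scaling;
- **dots**: scale-space Laplacian-of-Gaussian detection of single-molecule
  punctae in anisotropic 3-D stacks and one-to-one cross-channel
  colocalization (the digital, "absolute quantitation" readout);
- **simulate**: a forward model of the whole acquisition — parametric
  fluorophores, scene geometry, Poisson shot noise and Gaussian read noise —
  providing ground truth for every downstream test;
- **io / workflow / cli**: OME-TIFF and CSV I/O, a validated YAML-driven
  workflow, and the `specmix` command line.

## Worked example

Two channels redundantly detect the same target (two probe sets, two
fluorophores), channel B with twice the gain of channel A.  If the amplified
signal is linear in target content, the two unmixed channels — summed into
2.0×2.0×1.2 µm subcellular voxels — must fall on a line through the origin
with slope equal to the gain ratio:

```python
import numpy as np
from specmix import simulate as sim
from specmix.unmixing import unmix_image
from specmix.quantitation import bin_voxels, qhcr_scatter_from_table

scheme = sim.default_scheme()                      # 11 excitations, 26 detectors
pair = [sim.default_fluorophores()[3], sim.default_fluorophores()[6]]
ref, peaks = sim.true_reference_matrix(pair)       # 2 fluorophores + 1 AF column
af = sim.predict_response(sim.default_af_model(), scheme)

# one target detected redundantly by both channels, channel B at twice the gain
scene = sim.make_redundant_detection_scene(None, (1.0, 2.0), seed=11,
                                           shape=(2, 88, 88), photon_budget=1e4)
render = sim.render_spectral_image(scene, pair, af, scheme)
unmixed = unmix_image(render.image, ref)

table = bin_voxels(unmixed, voxel_size_um=(1.2, 2.0, 2.0))
stats = qhcr_scatter_from_table(table, "F514", "F633")
print(f"voxels: {stats.n_voxels}")
print(f"Pearson r: {stats.pearson_r:.4f}")
print(f"free intercept (normalized): {stats.intercept:.4f}")
a = table.table["F514"].to_numpy() / peaks[0]
b = table.table["F633"].to_numpy() / peaks[1]
print(f"recovered gain ratio: {a @ b / (a @ a):.4f}")
```

Output:

```
voxels: 128
Pearson r: 1.0000
free intercept (normalized): -0.0003
recovered gain ratio: 2.0004
```

The correlation near 1 and intercept near 0 say the voxel scatter is a tight
line through the origin (high precision and accuracy of the relative
quantitation); the recovered gain ratio of ≈2 says the unmixed intensities
preserved the simulated 2:1 labeling gain through excitation cross-talk, AF
background, shot noise at a 10⁴ photon budget, unmixing and binning.

The same pipeline runs from the shell:

```sh
specmix run --config run.yaml        # refspec → unmix → s2b/qhcr/dots stages
specmix simulate --out demo/ --seed 1
specmix unmix --image stack.ome.tif --refs refs.csv --out unmixed.ome.tif
```

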