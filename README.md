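# topomap

Quantitative 3D mapping of FISH-labeled genomic loci onto
chromatin-compaction-classified nuclear landscapes from 3D structured
illumination microscopy (3D-SIM) image stacks.

## The problem

Transcription regulatory elements move between two co-aligned nuclear
compartments: the decondensed, transcriptionally active periphery of
chromatin domain clusters (CDCs) adjoining the interchromatin
compartment, and the compact, inactive CDC interior.  To quantify where
a locus sits in this landscape, the DAPI counterstain of a nucleus is
classified voxel-by-voxel into seven intensity classes that serve as a
proxy for local chromatin compaction (class 1 ≈ DNA-free interchromatin
space, class 7 = most compact chromatin), and the voxels of segmented
FISH signals are mapped onto those classes.  Comparing the signal's
class distribution with the DAPI distribution of the same nucleus gives
a per-class enrichment/depletion profile in percentage points.

`topomap` implements this workflow end to end for anisotropic 3D stacks
(default voxel 125 × 39.5 × 39.5 nm), together with a synthetic
3D-nucleus phantom generator that makes every stage verifiable against
ground truth without any real microscopy data.

## The model at the core

In-mask DAPI intensities x_i are modeled as a K = 7 component Gaussian
mixture with a single shared variance σ² (equal intensity variance),
coupled to a Potts prior over voxel labels c_i on the 6-connected
lattice — a hidden Markov random field.  The per-voxel labeling energy
is

    E(c_i) = (x_i − μ_c)² / (2σ²) + log σ − log π_c
             + β · #{6-neighbors j in mask : c_j ≠ c_i}

Parameters (μ, σ², π) are fitted by shared-variance EM with multiple
restarts (model selection by incomplete-data likelihood); labels are
then optimized by checkerboard iterated conditional modes (ICM)
alternating with parameter re-estimation.  β = 0 recovers the plain
mixture MAP.  Components are ordered so that μ₁ < … < μ₇.

Downstream stages: nuclear mask by Gaussian smoothing + Otsu threshold;
FISH spot segmentation by `mean + k·SD` thresholding with a
relative-intensity floor and 26-connected components; background
rejection by the 0.5 µm cross-channel centroid pairing rule (10 kb of
fully extended 10-nm fiber spans ≈ 500 nm, so genuine signals from two
adjacent differently labeled probes must lie closer than that);
neighbor-class matrices, anisotropy-aware minimal class-to-class
distances, centroid distance analyses, Wilcoxon/t tests with Bonferroni
correction and second-order polynomial trend fits.

## Worked example

Generate a synthetic nucleus with spots planted preferentially in the
decondensed classes 2–4 and run the full pipeline:

```python
import numpy as np
import topomap as tm

phantom = tm.generate_phantom(tm.PhantomConfig(seed=1))
cfg = tm.PipelineConfig(mask_sigma_nm=0.0)  # phantom is already blurred
res = tm.analyze_nucleus(phantom.dapi, phantom.ch1, phantom.ch2, cfg, "demo")

print("class means:", np.round(res.params.mu, 1))
print("DAPI class fractions:", np.round(res.dapi_profile.fractions, 3))
print("ch1 enrichment (pp):", np.round(res.enrichments["ch1"].points, 1))
```

prints

```
class means: [ 48.   59.4  71.9  84.8  97.9 111.4 125.6]
DAPI class fractions: [0.189 0.186 0.149 0.134 0.114 0.096 0.132]
ch1 enrichment (pp): [  2.3  33.1   6.5  -8.4 -10.7  -9.6 -13.2]
```

The seven fitted class means ascend with compaction; the DAPI voxel
fractions sum to 1 over the classes.  The enrichment profile is the
percentage-point difference between the channel-1 signal distribution
and the DAPI distribution: the planted preference for open chromatin
shows up as strong enrichment at class 2 (+33 points) and depletion
across the compact classes 4–7 — the signature expected of active
regulatory elements at the decondensed CDC periphery.  Of the channel-1
signals, 11 spots were retained and the planted unpaired background
speckles were discarded by the 500-nm pairing filter.

The same workflow runs from the shell:

```sh
topomap phantom --out demo/            # writes dapi/ch1/ch2.tif + truth
topomap run --dapi demo/dapi.tif --ch1 demo/ch1.tif --ch2 demo/ch2.tif \
            --out demo/results/
```

which writes per-nucleus CSV tables (class profiles, enrichments,
spot centroids/volumes, neighbor matrix, minimal class distances), the
class-label and color heat-map TIFFs, and a JSON summary.

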