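# pengcensus

A tested, reusable implementation of a multi-modal penguin colony census
pipeline for the Danger Islands archipelago (Antarctic Peninsula): direct
ground counts, computer-automated counts of UAV orthomosaics, and
medium-resolution satellite imagery, combined into an archipelago-wide
abundance estimate with propagated uncertainty.

It is written for quantitative ecologists who want to study, stress-test or
extend the census methodology on fully synthetic data: every input the
pipeline consumes — colony point patterns, orthomosaic-like rasters with
confusable artifacts, observer counting error, paired multispectral
scenes — is generated by seeded simulators with known ground truth.

## What the pipeline does

1. **Simulate** an island: nests follow a cluster process (uniform
   sub-colony centres, isotropic Gaussian offspring, hard-core minimum
   spacing *h* = 0.7 m), rendered as Gaussian blobs on a raster at a fixed
   ground sample distance; false-positive sources ("rocks and shadows")
   come from a homogeneous Poisson field with identical appearance.
2. **Detect** candidate nests by tiling the raster into 512 × 512
   sub-images and running a difference-of-Gaussians blob detector with
   local-maxima extraction (a classical, high-recall stand-in honouring
   the same I/O contract as a neural point detector).
3. **Filter** detections with a nearest-neighbour rule: keep a point iff
   at least *m* other detections fall within radius *r*, where *r* is fit
   from the bimodal distribution of k-NN distances (colonial nests are
   tightly clustered; unstructured false positives are not).
4. **Calibrate** the automated count against manual validation plots with
   a per-site simple linear regression (manual ~ detected) and classify
   the result into the standard N1/N2/N4 precision classes
   (≤5% / ±10% / ±50% relative error).
5. **Aggregate** the per-island counts: total `T = Σᵢ cᵢ`, with a
   Monte-Carlo 95% CI obtained by redrawing each island's count with the
   standard deviation implied by its precision class
   (σᵢ = hᵢ·cᵢ/1.96 under the `normal95` reading), and the regional share
   `100·T/(T + B)` against the published subarea baseline
   B = 606,526 pairs.
6. **Cross-calibrate** multispectral scenes from different sensors by
   per-band mean differences, classify guano-stained pixels, reduce fine
   classifications to a 30 m grid and compare colony areas across epochs.

The nine-island census summary table is packaged as a fixture
(`pengcensus/data/table1_census.csv`); its Adélie row sums to 751,527
breeding pairs.

## Worked example

Aggregate the packaged census table into the archipelago estimate:

```sh
$ pengcensus census --n-reps 100000 --seed 1
{
  "ci_high": 793993,
  "ci_low": 709232,
  "error_interpretation": "normal95",
  "n_reps": 100000,
  "regional_share_pct": 55,
  "regional_share_pct_exact": 55.34,
  "species": "adeliae",
  "total": 751527
}
```

The point total (751,527 pairs) is the deterministic sum over islands; the
CI redraws each island within its precision class, so the four big
UAV-derived N2 counts dominate the width; the share says the archipelago
holds 55% of the Adélie penguins in the surrounding management subarea.

The full synthetic chain (simulate → detect → filter → calibrate → census)
runs from a single seeded config:

```sh
pengcensus run-all --seed 1 --out results/run
```

and the numbered drivers under `analysis/` walk through the study step by
step (`01_simulate_colonies.py` … `05_landsat_change.py`), each printing
what it found and writing its tables under `results/`. For example,
`analysis/04_calibrate_census.py --seed 0` reports a mean absolute
recovery error of 0.51% across ten synthetic islands (max 1.48%) — every
island comfortably inside the ±10% band that justifies the N2 label for
automated counts.

Other CLI stages: `simulate`, `detect`, `filter`, `fieldcount`,
`calibrate`, `landsat`, `validate-config` (see `pengcensus --help`).

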