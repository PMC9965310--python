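# rwnseg

Semi-automated segmentation of the round window niche (RWN) in CBCT
temporal-bone volumes, and generation of a patient-individual niche
implant model (voxel labels → watertight STL), together with the
validation metrics used to compare segmentations.

The workflow mirrors the interactive clinical tool it reimplements:

1. **Crop** a cubic 5 mm region of interest around the estimated niche
   position and **resample** to ≤ 0.1 mm isotropic when the scan is
   coarser.
2. **Membrane model** — the round window membrane is invisible in
   clinical CBCT, so it is modeled as an oval cut-out of a bilinear
   saddle surface over four control points, placed from a mean model in
   the cochlear coordinate system (CCS: z along the modiolar axis,
   x toward the membrane, origin at the membrane center). The surface
   classifies every voxel as cochlea-side or middle-ear-side.
3. **Bone threshold** — the air / soft-tissue / bone peaks of the ROI
   histogram are fitted (EM Gaussian mixture anchored on histogram
   modes) and the bone threshold is placed between the soft-tissue and
   bone peaks; the mask is thresholded after optional Gaussian
   smoothing.
4. **Crater-lake fill** — the niche is filled like a crater lake whose
   bottom is the membrane: non-bone, middle-ear-side voxels within a
   "water level" (Euclidean distance from a fill center) are kept if
   connected to the seed next to the membrane. The maximal level before
   the lake spills out of the ROI is estimated automatically. Every
   excluded voxel records which rule removed it.
5. **Handle + export** — a pointed cuboid handle is attached on the
   middle-ear-facing surface (arrow toward the basal turn, clipped
   against bone), and the labeled voxels are converted to a watertight,
   Taubin-smoothed triangle mesh written as binary STL.

Validation metrics: niche volume, membrane contact area, Dice and
Jaccard coefficients, and the per-rule attribution of differences
between a manual and the semi-automated segmentation.

Because no clinical data is distributed, the package ships a phantom
generator (`rwnseg.phantom`) producing synthetic 5 mm temporal-bone
ROIs with tri-modal intensities (air / soft tissue–fluid / bone),
spherical air cells, a fluid duct behind the membrane, and analytic
ground-truth masks — including degradation to the 0.3 mm intraoperative
scanner resolution.

## CLI

```sh
# generate a synthetic ground-truth phantom
rwnseg phantom --shape box_pit --seed 0 --out-dir phantom/

# run the full semi-automated workflow from a YAML config
rwnseg segment --config run.yaml

# crop a working ROI
rwnseg crop --volume scan.nrrd --center 12.1,-3.4,8.8 --edge 5.0 --out roi.nrrd

# compare two segmentation masks
rwnseg metrics --a niche.nrrd --b truth.nrrd --report report.json
```

A minimal `run.yaml`:

```yaml
volume: phantom/volume.nrrd
fiducials: phantom/fiducials.mrk.json   # apex / basal / rw_center
membrane: phantom/membrane.mrk.json     # optional; defaults to the mean model
bone_threshold: auto
fill_level: auto
fill_center: auto
handle: {width: 1.0, length: 1.5, height: 1.0, tip_fraction: 0.25}
out_dir: out/
```

The run report (`report.json`) logs every stage with its parameters,
fitted values and voxel counts; runs are fully deterministic for a
fixed config and seed.

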