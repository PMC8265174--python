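# vmi — vascular and metabolic imaging toolkit

`vmi` segments 3D vascular networks from the *dark* background of whole-organ
autofluorescence volumes (hemoglobin quenches NADH/FAD fluorescence, so
vessels appear as dark tubes in a bright tissue foreground), traces the
vessel tree, and quantifies it with the Dice overlap coefficient and a
cube-law (Murray) branching analysis. A voxelwise NADH/FAD redox-ratio
module provides the metabolic half. Because no suitable public imaging data
exists, the package ships a synthetic phantom generator — Murray-compliant
vascular trees rasterized into noisy, unevenly illuminated volumes with
ground-truth masks and trees — which serves as the validation surface for the
whole pipeline.

## Pipeline

1. **Rescale** intensities over the whole 3D volume to the full 16-bit range.
2. **Invert** each slice (dark vessels become bright); skipped in *bright*
   mode for dye-filled airways or reporter fluorescence.
3. **Rolling-ball background subtraction** per slice (classical
   opening-by-ball envelope; removes uneven illumination).
4. **Rescale** again, then **binarize** (robust background-outlier threshold
   by default; Otsu and percentile available) and optionally **exclude**
   regions (heart cavities, renal medulla) via a user-supplied or
   threshold-derived mask.
5. **Trace**: 3D thinning, skeleton-graph extraction, spur pruning, rooting
   each component at its widest endpoint; branch depth starts at 1 and
   increments at every junction; diameters come from the Euclidean distance
   transform along the centerline.
6. **Quantify**: Dice overlap, vascular volume fraction, per-depth
   cubed-diameter sums and the identity-line fit.

## CLI

```sh
# synthetic phantom bundle: volume.tif, mask.tif, tree.swc, branches.csv
vmi phantom --seed 1 --out-dir phantom1/

# segmentation (dark = vasculature from autofluorescence; bright = FITC/reporter)
vmi segment --in phantom1/volume.tif --spacing 10,10,10 --radius-um 50 \
    --mode dark --out mask.tif

# tracing and branch table
vmi trace --mask mask.tif --spacing 10,10,10 --out tree.swc --table branches.csv

# overlap and branching analysis
vmi dice --a mask.tif --b phantom1/mask.tif
vmi murray --table branches.csv --exclude-terminal --out murray.csv

# redox ratio
vmi redox --nadh nadh.tif --fad fad.tif --flat flat.tif --out rr.tif --summary rr.json

# everything chained
vmi pipeline --in phantom1/volume.tif --spacing 10,10,10 --radius-um 50 --out-dir run/
```

Voxel spacing is always given explicitly (Z,Y,X in µm); TIFF resolution tags
are ignored. Organ presets (`--organ kidney|heart|liver|lung`) set the
rolling-ball radius default. Every run writes a `provenance.json` with
inputs, parameters, version, and seed.

## Notes

- `skimage.restoration.rolling_ball` records only the ball *apex* and is not
  the classical rolling-ball envelope; `vmi.segmentation.rolling_ball_background`
  implements the envelope (grayscale opening by a ball structuring function)
  and is verified against a brute-force oracle to exact agreement.
- Default binarization is a robust outlier threshold
  (median + 8×1.4826×MAD): after background subtraction the residual
  background is noise and vessels are its bright outliers. Otsu is kept as
  an option but fails when vessels occupy a tiny fraction of the volume.
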