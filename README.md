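# fundusmosaic

Detection and mosaicing for low-quality smartphone-ophthalmoscope retinal
video. The package implements a two-task pipeline:

1. **Retinal-region detection** — a classical chain locates the small bright
   circular retinal window in each frame: red-channel extraction, Gaussian
   blur, Otsu binarization, contour extraction, Circle Hough Transform, and
   the enclosing square of the top-voted circle.
2. **Mosaicing** — cropped retinal regions are merged into a single
   wider-field image: root-SIFT keypoint description, Lowe-ratio matching,
   RANSAC homography registration into the base frame's referential, and
   feathering blending with Euclidean-distance weight masks.

Supporting stages: set-wise intensity normalization (every frame scaled to
the set's minimum mean intensity), crop-and-pad to a square 400×400 canvas
preserving scale, bounding-box evaluation (MAE over the four box
coordinates, IoU, Successful/Acceptable/Failed binning, per-class summary
tables), and a synthetic fundus generator producing frames and
small-motion sequences with exact ground truth, so everything is testable
without any external dataset.

## CLI

The umbrella command `fundusmosaic` exposes each stage plus an end-to-end
pipeline:

```sh
# generate a synthetic sequence with ground truth
fundusmosaic synth --out seq/ --frames 5 --seed 1 --width 640 --height 480 --radius 120

# individual stages
fundusmosaic normalize --in seq/ --out normed/
fundusmosaic detect    --in seq/ --out detections.csv
fundusmosaic crop      --in seq/ --detections detections.csv --out crops/ --canvas 400
fundusmosaic mosaic    --in crops/ --out mosaic.png --save-homographies h.csv
fundusmosaic evaluate  --gt seq/gt_boxes.csv --pred detections.csv --out report.csv

# everything at once (normalize -> detect -> crop -> mosaic [-> evaluate])
fundusmosaic pipeline --in seq/ --out run/ --gt seq/gt_boxes.csv
```

Inputs may be directories of stills or video files (video decoding depends
on an imageio ffmpeg backend being available). Stage parameters live in a
flat YAML config passed with `--params`; unknown keys are rejected.

## Testing

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
geometric/metric invariants, and `tests/test_acceptance.py` with the
end-to-end recovery studies (homography recovery rate, detection recovery
rate, mosaic landmark geometry).

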