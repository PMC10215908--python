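# fluoarea

Estimate the physical area (mm²) of bright regions — e.g. fluorescent-dye
contamination viewed under UV light — from an orthogonal photograph of a flat
surface taken at a known camera-to-surface distance.

The pipeline is: RGB → grayscale (BT.601 luma) → Otsu threshold (exhaustive
maximization of the interclass variance `g = ω₀ω₁(μ₀−μ₁)²`) → binary mask →
white/total pixel ratio → physical area via one of two explicit calibration
routes:

* **lambda**: a single reference object of known area photographed at a known
  distance fixes a constant `λ = ref_area / (d · ref_ratio)`; any later
  measurement is `λ · d · ratio`;
* **curves**: per-distance ordinary least-squares lines
  `area = a0 + a1 · pixels`, linearly blended between the two bracketing
  distances for measurements taken in between (no extrapolation unless
  explicitly allowed).

A synthetic-scene module renders shapes of known physical area at a given
distance (pinhole 1/d² scaling by default, with a linear-in-d alternative),
with optional color cast, illumination gradient and Gaussian noise, plus an
exact ground-truth mask — so the whole pipeline is testable end to end
without photographs.

## CLI

```sh
# render a ground-truthed synthetic scene
fluoarea simulate src/fluoarea/data/scene_two_rectangles.json --out scene/

# fit per-distance calibration curves from a CSV table (or --scenes scene-dir/)
fluoarea calibrate --table src/fluoarea/data/table1.csv --out curves.json

# measure an image: Otsu by default, --threshold K to override
fluoarea measure scene/image.png --distance 50 --calibration curves.json --out report.json

# distance-sensitivity sweep
fluoarea sweep --areas-table src/fluoarea/data/table2.csv \
    --center 50.5 --offsets=-1,0,1 --true-area 1000
```

Reports are JSON (areas to 2 decimals, ratios to 6; reruns are
byte-identical); sweeps are CSV or JSON. Exit codes: 0 ok, 2 usage,
3 data/parse/I-O, 4 distance out of calibrated range.

Shipped fixtures (`src/fluoarea/data/`): two measured calibration tables
(`table1.csv`: area/pixel pairs at 50, 75 and 100 cm; `table2.csv`: area vs
distance at a fixed 1000 mm² target) and three canonical scene specs (a coin
of radius 11 mm, a two-rectangle 1000 mm² target, and a 4×4 cm square).

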