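# femorph

Monte Carlo morphometry of the femoral medullary canal from transverse
grayscale slice stacks.

The pipeline extracts the cortical-bone and medullary-cavity regions of each
slice (Gaussian smoothing, low-cut thresholding, Canny edge detection,
contour filling/subtraction), estimates their areas by uniform random-point
sampling (with an exact pixel-traversal oracle for validation), locates the
key cross sections (trochanteric reference section, the sections 20 mm
above/below it, and the isthmus at the medullary-area minimum), and computes
the canal's morphometric parameters: diameters (T+20, T−20, T0, T_mi, T_mo,
per-slice cortical thickness), lengths (IH, LH), ratio indices (CFI, MCFI,
DCFI, CI, IH/LH), per-slice areas and ratios (s_c, s_m, q1, q2), growth
rates (r1, r2), and the canal-shape classification
(chimney < 3.0 ≤ normal < 4.7 ≤ champagne < 6.5 by CFI).

A fully synthetic femur phantom (elliptical annulus slices with a
trumpet-shaped canal, analytically known masks/areas and designed key
sections) makes the whole pipeline testable without patient data.

## Command line

```sh
# generate a 50-slice synthetic stack (PNGs + JSON manifest)
femorph phantom --out phantom_dir --n-slices 50 --seed 0

# stage by stage
femorph extract --input phantom_dir --out masks_dir --sigma 3 --window 7 --t0 117
femorph mcarea  --masks masks_dir --n 230400 --seed 0 --out results.csv
femorph morph   --masks masks_dir --areas results.csv --out report.json
femorph validate --mc results.csv --out agreement.json

# or all-in-one from a YAML config
femorph run --config config.yaml --out outdir --seed 0
```

A config file may set `source_kind` (`phantom` | `png` | `dicom`),
preprocessing parameters (`sigma`, `window`, `t0`, `canny_low`,
`canny_high`), sampling (`n_points`, `seed`), `slice_range`, a manual
`trochanter_override`, and `lh_mm` (true femur length for cropped stacks).
CLI flags override file values. A run log with all parameters and seeds is
written next to the outputs; identical config + seed reproduces outputs
byte-for-byte.

## Library

```python
from femorph import trumpet_spec, generate_phantom, mc_area, traversal_area
from femorph.imaging import extract_stack
from femorph.montecarlo import mc_area_stack
from femorph.morphometry import analyze_stack

stack, truth = generate_phantom(trumpet_spec(n_slices=50, seed=0))
masks, flags = extract_stack(stack)
results, _ = mc_area_stack(masks, n=230_400, seed=0)
report = analyze_stack(masks, results,
                       slice_interval=stack.slice_interval,
                       pixel_spacing=stack.pixel_spacing,
                       n_slices=stack.n_slices)
print(report.canal_class, report.rounded)
```

## Layout

- `src/femorph/phantom.py` — synthetic stacks with ground truth
- `src/femorph/imaging.py` — preprocessing and region-mask extraction
- `src/femorph/montecarlo.py` — random-point area estimation + traversal oracle
- `src/femorph/morphometry.py` — key sections and all morphometric parameters
- `src/femorph/validation.py` — descriptive stats and one-way ANOVA agreement
- `src/femorph/io.py`, `src/femorph/cli.py` — file formats and the CLI
- `tests/` — unit, property (hypothesis) and acceptance tests
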