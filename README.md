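# valveseg

Fully automatic, unsupervised segmentation of a fast-moving thin structure
(e.g. a heart valve) in grayscale video, implemented for echo-like data.

The pipeline decomposes the pixels-by-frames video matrix into a nonnegative
low-rank background (`W @ H`, the near-rigid muscle) plus a nonnegative
sparse component (`S`, the fast valve) using robust NMF whose l1 shrinkage
bias is removed by Bregman (running-subgradient) iterations. The sparse
component is then segmented by a convex relaxed Chan–Vese-style energy —
data term thresholded at `Θ`, isotropic per-frame TV, an area penalty, and a
muscle-exclusion penalty absorbed into a per-pixel threshold map
`Θ2 = Θ + 2·λ3·WH` — solved with a primal–dual hybrid gradient iteration and
binarized at 0.5. A refinement step locates the valve via an iterative
Gaussian-attenuated centroid of the temporally accumulated sparse component
and keeps only the nearest 6-connected spatiotemporal cluster. An optional
windowing mode first localizes the valve with an exclusion-regularized
factorization and a sliding-window energy scan, then segments inside the
window.

Everything is testable end-to-end on synthetic phantoms (low-rank background
+ swinging two-leaflet valve + optional moving distractors + noise) with
voxel-level ground truth; no external data is required.

## Library quick start

```python
from valveseg import (
    PipelineConfig, generate_phantom, phantom_fixture_suite,
    run_automatic, run_windowed, evaluate, window_recall,
)

spec = dict(phantom_fixture_suite())["easy"]
ph = generate_phantom(spec)

mask = run_automatic(ph.video, PipelineConfig.default("automatic", seed=0))
print(evaluate(mask, ph.truth_valve_mask))  # (recall, precision, f1)

wmask, window = run_windowed(
    ph.video, PipelineConfig.default("windowed", window_size=(44, 60), seed=0)
)
print(window_recall(window, ph.truth_valve_mask))
```

## CLI

```sh
# generate a synthetic phantom (multi-frame TIFF + ground-truth masks)
valveseg phantom --preset easy --out phantom_dir

# segment a video (multi-frame TIFF, a directory of PNG/JPEG frames,
# or a .npy/.npz tensor of shape (height, width, frames))
valveseg run --input phantom_dir/video.tif --mode automatic --out results_dir
valveseg run --input phantom_dir/video.tif --mode windowed --window 44 60 --out results_dir

# pixelwise recall / precision / f1 between two binary-mask TIFFs
valveseg eval --pred results_dir/mask.tif --truth phantom_dir/truth_valve_mask.tif
```

`valveseg run` accepts `--config cfg.yaml` with flat keys mirroring the
defaults (`lam`, `rank`, `lam1`, `lam2`, `lam3`, `theta`, `mu1`, `mu2`,
`window_rank`, `seed`, ...); omitted keys keep the documented defaults
(sparsity 0.1, rank 2, TV 0.04, area 0.075 automatic / 0.05 windowed,
exclusion 1.0, threshold 0.01; windowing factorization: sparsity 1.0,
overlap penalty 0.4, rank 5).

## Layout

- `src/valveseg/phantom.py` — synthetic videos with ground truth
- `src/valveseg/factorization.py` — NMF, Bregman-debiased robust NMF,
  exclusion-regularized variant
- `src/valveseg/segmentation.py` — relaxed energy, PDHG solver, binarization
- `src/valveseg/refinement.py` — iterative centroid, 3-D connected
  components, cluster selection
- `src/valveseg/windowing.py` — integral-image window scan, restriction,
  window recall
- `src/valveseg/pipeline.py` — orchestration, evaluation, config
- `src/valveseg/io.py`, `src/valveseg/cli.py` — I/O containers and the
  `valveseg` command
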