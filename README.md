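# smlmfit

Unconstrained 3D structure fitting from 2D projection images of a single
kind of structure, as produced by single-molecule localisation microscopy
(SMLM) or similar modalities.

A convolutional network predicts, for every input image, a rigid pose
(axis-angle rotation + in-plane translation) and a rendering sigma.  A
differentiable Gaussian splatter renders a shared 3D point-cloud "model
matrix" under each predicted pose, and a masked L1 loss against the input
image is backpropagated into both the network weights and the 3D point
coordinates.  The deliverable is the fitted point cloud; the network is
discarded after training.  A coarse-to-fine input-sigma schedule (stepped
per epoch) smooths the loss landscape early and sharpens it over time.

Everything — the renderer with its analytic gradients, the CNN with its
backward passes, ICP evaluation — is implemented on NumPy/SciPy; there is
no deep-learning framework dependency.  All gradients are verified against
central finite differences in the test suite.

## Modules

| module | contents |
| --- | --- |
| `smlmfit.geometry` | axis-angle rotations, Haar-uniform SO(3) sampling, orthographic projection |
| `smlmfit.renderer` | differentiable Gaussian splatting, image normalisation |
| `smlmfit.simulator` | synthetic datasets: poses, scatter / dropout / multi-binding noise, parametric models |
| `smlmfit.io` | localisation tables, TIFF stacks + sum projection, pre-render cache, PLY/XYZ, YAML configs |
| `smlmfit.trainer` | pose CNN, sigma schedule, masked L1, training loops (CNN and direct-pose ablation) |
| `smlmfit.evaluation` | multi-start mirror-aware ICP, closest-point RMSD, random-cloud baseline |

## CLI

```sh
# generate a synthetic dataset (TIFFs + manifest + ground-truth PLY)
smlmfit simulate --model two_cylinder --n-base 200 --augment 4 \
    --sigma 4 --p-missing 0.3 --seed 1 --out runs/sim

# train from a YAML config; checkpoints the model matrix per epoch
smlmfit train --config examples/train.yaml --seed 1 --out runs/fit
smlmfit train --config examples/train.yaml --seed 1 --out runs/direct --direct

# align two point clouds and report RMSD (+ mirror flag)
smlmfit evaluate runs/fit/model_final.ply runs/fit/ground_truth.ply --out runs/eval
```

Trainer options worth knowing: `verts_learning_rate` decouples the model
matrix's Adam step from the network's (short runs need more per-step vertex
travel), `sigma_head` selects how the predicted output-sigma is
parameterised (`free`, `bounded`, or `fixed`, the last tying it to the
known input-sigma — an option suited to clean simulated data), and
`dtype: float32` roughly halves CPU time.

A run config looks like:

```yaml
train:    {model_size: 100, epochs: 10, batch_size: 32, learning_rate: 0.0004}
schedule: {sigma_start: 5.0, sigma_floor: 1.2, epochs: 10}
noise:    {p_missing: 0.0, scatter_sigma: 0.0, spawn_rate: 0.0, max_spawn: 1}
data:     {model: two_cylinder, n_base: 500, augment_factor: 4, size: 64}
```

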