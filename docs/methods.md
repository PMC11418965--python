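# Methods

This note documents the models, numerical choices and limitations of
`cryoenhance` in the package's own terms. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The simulated-map model

The clean target for a structure is a sum of isotropic Gaussians, one per
atom, scaled by atomic number:

ρ_c(y) = Σ_i C · A_i · exp(−k‖x_i − y‖²), k = π/(0.9·R0)², C = (k/π)^{3/2}.

`C` makes each atom's kernel integrate to exactly `A_i`, which the test
suite verifies on a fine grid (voxel ≤ 0.25/√k) to within 1%. R0 is taken
as an explicit input everywhere: in real use it is the deposited map's
unmasked FSC@0.143 resolution, for synthetic data it is sampled per entry.

Numerical choices:

- **k parenthesization.** The width formula is implemented as
  k = π/(0.9·R0)² by default; the alternative reading (π/(0.9·R0))² is
  selectable via `k_convention="squared-ratio"` in `gaussian_constants`.
  Both are exercised by tests; only the default is used downstream.
- **Cutoff.** Atom contributions are truncated where the kernel falls to
  1e-6 of its peak (`cutoff_radius = sqrt(ln 1e6 / k)`). The absolute error
  this introduces is bounded by 1e-6·ΣA_i per voxel, which keeps the map
  within 1e-4 of the exact (no-cutoff) sum relative to its peak even when
  many atom tails overlap. Setting `cutoff_radius` to 0 disables
  truncation.
- **Occupancy.** A_i is weighted by occupancy (standard practice); with all
  occupancies 1 the literal formula is recovered.
- **Hydrogens** are included by default when present and excludable by
  flag; waters are always excluded when reading structures, other
  heteroatoms are kept unless `include_hetero=False`.

## Map conventions

A `DensityMap` stores `data[ix, iy, iz]` with voxel centers at
`origin + index * voxel_size` (0-based). Files are canonicalized at read
time: the MAPC/MAPR/MAPS axis permutation is undone, the voxel size comes
from cell/sampling, and the origin from the MRC2014 ORIGIN words or, if
unset, the start indices. Non-orthogonal cells are rejected. Writing emits
mode-2 (float32) MRC2014. Resampling to the common 1 Å grid uses trilinear
interpolation over the same physical extent (cubic available via
`order=3`), with zero fill outside the source; normalization divides by the
linear-interpolation percentile (99.999 by default) and clips to [0, 1].
Normalization statistics are computed after resampling, matching the
pipeline's processing order.

## Tiling

Blocks are cut on a stride lattice with the final offset per axis clamped
to `dim − block` so the last block is flush with the boundary; maps smaller
than one block are zero-padded (and cropped again at assembly). Overlapping
predictions are combined by a count-weighted mean — the simplest
order-invariant rule; split-then-assemble of unmodified blocks is exact to
float rounding. Training keeps only pairs whose *target* block contains at
least one positive voxel (`min_fraction` raises the bar); validation,
testing and inference always use all blocks.

## Network

Four encoder stages (strided 3×3×3 conv, batch norm, three transformer
blocks) halve the edge and widen channels by multipliers (1, 2, 4, 8) over
a base width; a ConvRes bottleneck (three conv + instance-norm pairs, two
leaky ReLUs, residual from input to the third pair) sits at the bottom;
four decoder stages fuse the matching encoder output by concatenation plus
a 1×1×1 reduction, upsample with a kernel-2/stride-2 transposed conv, and
run three more transformer blocks. The head is a 1×1×1 conv to one channel
with no output activation (targets are nonnegative but unbounded sums of
Gaussians).

Each transformer block adds a learned positional embedding, applies
Efficient Paired Attention with a residual connection, then a
conv/batch-norm/leaky-ReLU/dropout feed-forward with a second residual.
EPA shares query/key projections between two branches: the spatial branch
attends from every position to a learned low-rank projection of the
positions (p = 64 projected tokens, cost O(N·p)); the channel branch forms
a per-head channel×channel affinity softmax(QᵀK·τ) with a learned
temperature τ. Branch outputs are concatenated and fused back to C
channels.

Size-independence: positional embeddings and the spatial projection
patterns are stored on small lattices (edge ≤ 8 and 4 respectively) and
regridded trilinearly to the working edge, so one trained model accepts any
cubic block whose edge divides by 2^levels, and the parameter count is
dominated by conv/linear weights (hence ~quadratic in the base width).

Initialization: He for convolutions; the attention fuse layer and the
residual-branch norm gains start at 0.1× so every residual branch begins
near identity — without this the 24-block residual stack amplifies
activations multiplicatively at depth.

Defaults (base 32 channels, 4 heads, p = 64, dropout 0.1, leaky slope 0.01,
input edge 48) are declared in `ArchitectureConfig` and serialized into
every checkpoint; desk-scale tests use base 8 at edge 16.

## Training

The loss is a masked mean square error: voxels with |prediction| ≤ ε and
target exactly 0 are excluded, and the mean runs over the survivors; ε
defaults to 0 (the literal reading — in practice float outputs are almost
never exactly zero, so the default masks only where the target is zero and
the output is too), with ε = 1e-6 as a practical preset. A fully masked
batch contributes zero loss and no parameter update.

Augmentation draws one of the 24 proper 90° cube rotations plus independent
per-axis flips — exact voxel permutations applied identically to input and
target, so they commute with the loss. Cropping (64³→48³ at full scale) is
applied before rotation.

Adam starts at 5e-4; after two *consecutive* validations without strict
improvement over the running best, the rate halves, floored at 1e-5
("improvement" is read against the running best, not the previous
validation). Validation runs every 5 epochs by default (every epoch in the
toy tests). Batch size defaults to 4 at desk scale; 15 is the documented
full-scale preset. Runs are reproducible from (seed, config, data order);
divergence (non-finite loss) aborts with the offending batch named.

## Inference

`enhance_map` reproduces the training-time preprocessing (resample to 1 Å,
normalize by the 99.999th percentile), tiles with block 48/stride 38 by
default, forwards in batches with dropout off and normalization in
inference mode, and mean-assembles. The output keeps the network's native
scale — enhanced and input maps are *not* on the same density scale — and
the normalization divisor is recorded in the sidecar run manifest so users
can rescale. The output grid is 1 Å with the input's origin, so enhanced
maps superimpose on their inputs in any viewer.

## Metrics

FSC uses shells one reciprocal voxel wide (1/(N_max·voxel)), assigning each
Fourier coefficient to its nearest-integer radial shell, up to Nyquist; the
DC term is not a correlation and is skipped. The threshold resolution
interpolates the first downward crossing linearly in (frequency,
correlation) and returns its reciprocal; curves that never cross report the
Nyquist-limited value with a flag, as do curves that start below threshold.
`map_model_fsc` simulates the model map on the experimental grid with the
kernel above — a simplified, self-contained analogue of a phenix map-model
FSC, not its equivalent (no molecular masking, no B-factor handling).
CC_box is the plain Pearson correlation over all voxels.

## Synthetic data

`make_toy_structure` builds backbone-only poly-alanine traces: an ideal
helix (rise 1.5 Å, 100°/residue, radius set so consecutive CA–CA = 3.8 Å),
an extended zig-zag strand, or a correlated random-walk coil; N, C and O
atoms are placed in a local chain frame. Side chains add nothing to testing
the kernel and are omitted.

`degrade_map` stands in for a deposited experimental map: Gaussian blur
(real-space, truncated at 4σ) + constant background offset + white noise,
all relative to the clean map's peak, deterministic under its seed. The
default noise level (10–20% of peak across a dataset) was chosen so the
degraded maps' whole-box correlation with their clean counterparts lands
around 0.3–0.7 — the regime reported for deposited primary maps versus
model-calculated maps — giving the network a realistic margin to improve.
This degradation is explicitly *not* an image-formation model: no CTF,
no missing wedge, no local resolution variation, no reconstruction
artifacts. Passing tests therefore demonstrate that the architecture,
loss and pipeline can learn to invert a blur+noise corruption at toy
scale; they do not certify performance on real microscope data.

## Desk-scale problem sizes

The test suite and acceptance script use: 25 synthetic entries of 6–14
residues (20 train / 5 held out), 16³ blocks at stride 12, a base-8
network, a 30-epoch run on 20 block pairs (the fixed-budget convergence
check) continued for 18 epochs on the full ~200-pair set before evaluating
enhancement. These sizes were chosen so the full pipeline — data
generation through held-out evaluation — completes in minutes on a single
CPU while still exercising every component at full fidelity.

## Known limitations

- The numpy autodiff engine is single-threaded apart from BLAS matmuls;
  full-scale (48³ blocks, base 32) training is out of reach on a CPU —
  the full-scale configuration is validated for shape/finiteness only.
- Percentile normalization assumes a mostly-positive density distribution;
  maps dominated by negative values are rejected rather than guessed at.
- The published method's exact channel widths, head counts and projection
  sizes are not public; the defaults here are declared choices, not
  inferences, and checkpoints carry their full configuration.
- Half maps need no special handling: they are ordinary maps and take the
  identical pipeline.
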