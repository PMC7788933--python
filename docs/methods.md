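# Methods

## Architecture

Both networks share one skeleton, parameterized by `NetworkTopology`:

- **Encoder** — `n_downsamplings` (default 4) double-conv blocks; channel
  width doubles per stage starting at `base_width` (default 32); 2×2
  stride-2 max pooling between stages.
- **Bottleneck** — one double-conv block at `base_width · 2^n` channels.
- **Decoder** — per stage a 2×2 stride-2 transposed convolution that
  halves the channel count, concatenation with the same-resolution encoder
  feature (skip connection), then a double-conv block.
- **Head** — 1×1 convolution to `out_channels` (1 for binary masks)
  followed by a sigmoid, yielding a per-pixel foreground probability in
  (0, 1); a threshold (default 0.5, `>=` convention) produces the mask.

Every double-conv-block convolution is same-padded and followed by batch
normalization then ReLU, so all feature maps keep the input's spatial
size; inputs must be divisible by `2^n_downsamplings` and no silent
padding is performed (the data pipeline offers none by default).

All convolutions carry bias terms. The biases preceding BN are redundant
in function (BN's shift absorbs them) but they are genuine trainable
parameters of the reference configuration this package's budgets are
calibrated against, so they are kept and counted.

**PyConvU-Net** replaces each double-conv-block convolution with a
pyramidal convolution; up-convolutions and the 1×1 head stay standard,
since the multiscale argument concerns feature extraction, not resampling
or class mapping.

Weight initialization is Kaiming fan-in normal for all conv kernels, zero
biases, BN scale 1 / shift 0, drawn from a `numpy` generator seeded by the
caller — two builds with the same seed are bit-identical.

## Pyramid schedule

A `PyConvSpec` fixes, per level: odd kernel size (strictly increasing),
output channels (equal split of the layer total, remainder to level 1 —
the cheapest kernel, which targets fine detail), and group count (depth
`in/groups` non-increasing across levels). Group counts must divide both
the input channels and the level's output split; where a nominal group
count is unrealizable (the 1-channel stem, narrow stages) it is lowered by
halving to the largest feasible power of two, preserving the
depth-monotonicity invariant.

The default (`CalibratedSchedule`) uses kernels (3, 5, 7, 9) and:

- **bottleneck-width layers**: the canonical depth-decreasing groups
  (1, 4, 8, 16);
- **all other layers**: maximal feasible grouping (the largest power of
  two dividing both channel counts, per level).

This placement is a deliberate calibration. Parameters are cheapest, per
MAC, at the bottleneck (lowest resolution), so the canonical
full-capacity pyramid lives there, while high-resolution stages — which
dominate MACs but hold few weights — are grouped as hard as the
divisibility constraints allow. At base width 32 / four down-samplings /
1-channel input this yields 3,657,505 trainable parameters (3.7 M at one
decimal), 47 % of the baseline U-Net's 7,765,409 (7.77 M), reproducing the
published budget pair. The schedule is configuration, not code: a
`UniformSchedule` (one tuple everywhere) is provided, and any per-level
tuple can be passed explicitly.

The lightweight property is width-dependent: below base width ~16 the
per-level output splits become too small to group (a 9×9 level over a
2-channel split costs more than the 3×3 it replaces), and at base width 8
the pyramid is *heavier* than the baseline. Desk-scale configurations
should use base width ≥ 16.

## Counting convention

Published complexity figures are only comparable under a stated
convention; FLOP counters disagree on what they include. The calibrated
convention this repository documents (`CountingConvention`, defaults):

| item | counted as |
|---|---|
| convolution | `K²·(Cin/g)·Cout` MACs per output pixel |
| transposed conv 2×2/2 | `4·Cin·Cout` MACs per **input** pixel (its true cost: output blocks are disjoint) |
| bias | 1 MAC per output element |
| batch norm | 2 ops per element (scale, shift) |
| ReLU | 1 op per element |
| max pool 2×2 | 1 op per input element |
| sigmoid | not counted |
| parameters | all trainable arrays: weights + biases + 2 per BN channel (running statistics are buffers, not parameters) |

"FLOPs" are multiply-accumulate counts; totals are reported in GMac
(10⁹ MACs). The headline MAC figures are measured at 512×512 with a
**3-channel stem** (`table_stem_channels = 3`): the reference measurement
configuration loads images as RGB. Under this convention the baseline
U-Net costs 48.5724 GMac (48.57 at two decimals); with a 1-channel stem,
48.42. Parameter totals are insensitive to the stem choice at the printed
precision (7.77 M either way).

Under the same convention the default PyConvU-Net costs 17.06 GMac
(3-channel stem) or 16.37 GMac (1-channel). This is the honest floor of
the design space, not a shortfall of the chosen schedule: an exhaustive
search over all non-decreasing power-of-two group tuples per width class
(kernels 3,5,7,9, equal split) bottoms out at 16.49 GMac unconstrained,
and 17.06 GMac within the 3.7 M-parameter window, because high-resolution
stages cannot be grouped below `164/(9·width)` of standard cost — group
counts must divide the per-level output split. A MAC total as low as
~10.7 GMac at 3.7 M parameters would require a parameter-to-MAC
allocation no realizable pyramid over this skeleton provides.
`scripts/acceptance.py` and the verification suite report the computed
values; the per-layer table is available via
`pyconvunet complexity --per-layer`.

The analytic parameter accounting is verified exactly against an
enumeration of the instantiated weight arrays for every layer kind and
for whole networks; the analytic/enumerated totals must agree to the unit.

## Metrics

Confusion counts are accumulated truth-by-row, prediction-by-column (the
final MIoU is invariant to transposition, so the orientation is a
documented bookkeeping choice, not a modeling one). MIoU averages IoU over
the k+1 = 2 classes; Dice is the binary foreground statistic. A class
absent from both masks contributes 1.0 (agreement on absence) rather than
0/0; this is configurable. Dataset-level metrics pool confusion counts
before computing the statistic (micro-average); the per-image table gives
the macro view, since conventions differ across papers.

## Synthetic data

`organ_ct` draws 1–3 super-ellipses with low-frequency radial wobble,
brighter than a smoothly textured background, Gaussian-blurs the *image*
edge by `edge_blur_sigma` (default 1 px) and adds pixel noise (sd 0.03).
The mask is the exact **pre-blur** support and is bit-independent of the
blur setting, so boundary fuzziness — the known hard case for this
architecture family — can be varied with the truth held fixed. A rejection
loop enforces a foreground fraction in [0.05, 0.4] (re-drawing from the
same seeded stream, hence still deterministic). `cell_em` builds a
seeded Voronoi tessellation (18–32 cells at 64×64), renders dark ~2-px
membranes between bright per-cell interiors, and labels membrane pixels
as foreground. Images are min-max normalized so the 8-bit PNG round trip
is exact for masks and within 1/255 for images.

What the generator does *not* emulate: acquisition physics (beam
artifacts, CT reconstruction streaks), anatomical shape priors,
inter-slice correlation, annotation noise. Passing the desk-scale
training check therefore demonstrates that the implementation can fit
structured segmentation targets — optimizer, gradients, data plumbing are
sound — not that it reaches any particular accuracy on clinical data.

## Training protocol

The reference protocol is 50 epochs at batch size 5; the loss is
per-pixel binary cross-entropy computed from logits (the sigmoid head and
binary masks force this family; soft Dice is available as `loss="dice"`),
optimized with Adam at learning rate 1e-3 — a default chosen for stable
convergence at desk scale. Each epoch shuffles with a run-seeded
generator, evaluates pooled MIoU/Dice on the test set, and checkpoints
the best-pooled-Dice weights. Runs are deterministic for a fixed seed.
A non-finite loss aborts with a diagnostic.

The desk-scale verification setting is 8 synthetic `organ_ct` images at
64×64, base width 16, three down-samplings, batch 2, 30 epochs — sizes
chosen so both networks overfit to training Dice > 0.9 in about a minute
on one CPU (the baseline in seconds, the pyramid network a few times
slower per step because grouped multi-kernel convolutions vectorize less
favorably in NumPy).

## Numerical notes and limitations

- Training math is float32; the functional `pyconv_forward` preserves the
  caller's dtype, and the test oracle (a nested-loop direct convolution)
  runs in float64, where agreement is ~1e-12 against the 1e-5 gate.
- Max-pool gradient ties route to the first element of the 2×2 window.
- BN uses eps 1e-5, momentum 0.1; evaluation uses running statistics.
- Checkpoints are a single `.npz` with the topology as JSON plus all
  arrays; round trips are bit-exact.
- 2-D single-channel binary segmentation only: no multi-class heads, no
  3-D volumes, no dilated/strided pyramid variants, no attention/deep
  supervision, no DICOM/NIfTI readers, no GPU path.
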