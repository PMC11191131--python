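# Methods

`cryosse` segments α-helix and β-sheet voxels in chain-level cryo-EM
density volumes at medium resolution (5–10 Å), where helices read as
cylinders and sheets as thin slabs but individual residues are invisible.
This note records the model, the conventions, and the design choices made
where the design was genuinely open.

## Coordinate conventions

All grids use 0-based voxel indices; positions refer to voxel centers; the
center of voxel (i, j, k) is `origin + (i, j, k) · voxel_size` (Å).
Distances are Euclidean in Å.  Maps are resampled to 1 Å/voxel (trilinear
interpolation — simple, monotone, and adequate at this target spacing)
before labeling or training, and MRC axis permutations (MAPC/MAPR/MAPS) are
normalized to (x, y, z) on read.

## Data curation

**Chain extraction.** A chain submap is the heavy-atom bounding box padded
by a mask radius, with voxels farther than the mask radius from every heavy
atom zeroed.  The mask radius defaults to 4 Å from any heavy atom — wide
enough to keep side-chain density at medium resolution, tight enough to
exclude neighboring chains.  Whether masking should use all heavy atoms or
Cα only is an open choice; all-heavy-atom was picked because Cα-only
envelopes clip β-sheet density noticeably at 4 Å.

**Deduplication.** Chains with more than 70% pairwise sequence identity are
collapsed greedily in input order.  Identity comes from a Needleman–Wunsch
global alignment with match +1, mismatch −1, gap −2 (the standard simple
scheme; the scoring scheme is exposed in `cryosse.curation`), defined as
identical aligned positions over alignment length.  Among co-optimal
alignments the identity is made deterministic by preferring the alignment
with the most identical positions, then the shortest; the DP optimizes the
lexicographic triple (score, matches, −length), which is valid because all
three components are additive.  `X` never counts as a match.  A separate
check verifies that no test chain shares more than 35% identity with any
training chain.

**Quality score and bins.** Map-model agreement is scored per chain by a
simplified cylindrical helix fit: for every helix of at least four
residues, the axis is the least-squares line through that helix's Cα atoms,
and a cylinder of radius 2.5 Å spans the helix's axial extent.  Against a
density threshold, precision is the fraction of above-threshold voxels
falling inside the cylinder among above-threshold voxels within 5 Å of it,
recall is the fraction of cylinder voxels above threshold, and the chain
score is the mean F1 over helices.  The 2.5 Å radius and 5 Å neighborhood
are package constants chosen to bracket the Cα cylinder radius (2.3 Å) of
an ideal helix; the fit threshold is a required parameter because no single
density level suits all maps.  This fit is deliberately simple — a
least-squares axis and hard cylinder — and is not a reimplementation of any
published cylinder-fit procedure.

Bins follow one half-open convention: bin 1 iff score ≥ 0.7; bin 2 iff
score ∈ [0.6, 0.7) and |P−R| < 0.15; bin 3 iff score ∈ [0.6, 0.7) with
|P−R| ≥ 0.15, or score ∈ [0.55, 0.6) with |P−R| < 0.15; bin 4 otherwise.
Bin-4 chains are excluded from training and evaluation.  Submaps larger
than 100 voxels in any direction are dropped; the limit is inclusive at
100 (a "maximum" is read as a permitted value).

**Split.** Within each retained bin, chains are shuffled with a seed and
allocated to train/validation/test proportionally; the rounding remainder
goes to train, so per-bin proportions deviate from the requested fractions
by less than one chain.

## Voxel labels

STRIDE codes H/G/I map to helix, B/b/E to sheet, everything else to
background.  A voxel is labeled with a class when its center lies within
3 Å of a Cα of that class; helix wins any overlap.  The 3 Å sphere is
closed (≤ 3.0): boundary voxels at exactly 3 Å are labeled, which makes the
on-lattice sphere contain exactly 123 voxels and keeps tie handling
deterministic.  The comparison convention is this package's choice, made
for determinism, not a documented property of any reference pipeline.

## Network

A 5-layer 3D U-Net: two down-sampling layers, a bottleneck, and two
up-sampling layers.  Every layer is two (3×3×3 convolution → batch
normalization → ReLU) blocks.  Channel widths follow the original 3D U-Net
progression truncated to two pooling levels, at base width 32:

| stage | convolutions |
| --- | --- |
| layer 1 | 1→32, 32→64 |
| layer 2 | 64→64, 64→128 |
| bottleneck | 128→128, 128→256 |
| layer 4 (up) | tconv 256→128, concat skip 128; 256→256, 256→128 |
| layer 5 (up) | tconv 128→128, concat skip 64; 192→64, 64→64 |
| output | 1×1×1 conv 64→3, softmax |

Down layers end with dropout then 2×2×2 stride-2 max pooling; up layers
start with dropout then a 3×3×3 stride-2 transpose convolution.  The total
trainable-parameter count — convolution kernels and biases plus batch-norm
scale and offset, excluding running statistics — is **6,142,723**.

The schedule was fixed by enumerating candidate channel schedules (base
width; doubling once per level vs per convolution; decoder mirrored vs
halved; transpose-convolution width and kernel) and computing each total
analytically.  No schedule with kernel-2 transpose convolutions matches the
target total; with kernel-3 stride-2 transpose convolutions the schedule
above matches it exactly, and it is also the natural truncation of the
original 3D U-Net this architecture derives from, so it is the default.
Alternative policies remain constructible for comparison; representative
totals from the constructible space (kernel-3 transpose convolutions):

| doubling | decoder | base 8 | base 16 | base 32 | base 64 |
| --- | --- | --- | --- | --- | --- |
| per level | mirror | 384,835 | 1,536,899 | **6,142,723** | 24,561,155 |
| per level | halve | 248,091 | 990,387 | 3,957,603 | 15,822,531 |
| per conv. | mirror | 3,863,315 | 15,447,331 | 61,777,475 | 247,086,211 |
| per conv. | halve | 3,158,115 | 12,626,883 | 50,496,387 | 201,963,267 |

A straightforward forward receptive-field computation over these layers
gives 32 voxels at the bottleneck and grows through the decoder; the
implementation makes no claim about a single canonical receptive-field
number, since the value depends on the counting convention for strided and
transposed layers.

**Engine.** No GPU framework is used: layers are implemented directly in
numpy (float32, channels-first).  Convolutions evaluate as 27 shifted
GEMMs, which keeps peak memory at one padded activation copy; the stride-2
transpose convolution decomposes by output parity into 8 small
convolutions, costing the same FLOPs as a stride-1 convolution of the
input-sized grid.  All forward/backward passes are verified against
scipy.ndimage correlations and finite differences in the test suite.

## Loss

Weighted categorical cross-entropy plus a soft-dice complement, both with
unit weight: `L = CE_w + (1 − mean dice)`.  Class weights are inversely
proportional to voxel class frequency, normalized to sum to 3
(`w_c = 3 (1/f_c) / Σ_k 1/f_k`), computed over the whole training set by
default (per-chain weighting is a config switch).  Frequencies are clipped
at 10⁻⁶.  Soft dice per class uses smoothing ε = 1.0 on voxel counts.
Probabilities are clipped to [10⁻⁷, 1−10⁻⁷] inside the log.  The analytic
gradient of the combined loss with respect to the logits is exact (verified
against finite differences), including the softmax-Jacobian chain of the
dice term.

## Training and inference

Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁷) at learning rate 0.001, batch size 1,
40 epochs, dropout 0.5, L2 penalty 10⁻⁴ on convolution kernels.  Inputs
are per-chain z-scored — input normalization is a package choice; z-scoring
is the standard treatment for maps with arbitrary intensity scale — and
zero-padded to the next multiple of 4 (zeros match the masked-background
convention of chain extraction); predictions are cropped back.  One seed
drives weight initialization, epoch shuffling, and dropout masks, making
runs bit-reproducible on CPU.  Final-epoch weights are used; no early
stopping (validation data serves hyperparameter search only).

Batch normalization at batch size 1 over whole volumes is per-volume
(instance) normalization.  Inference therefore normalizes each volume with
its own statistics as well: running averages accumulated over a handful of
heterogeneous chain volumes cannot stand in for per-volume statistics, and
using them creates a severe train/inference mismatch (on the 2-chain
fixture, eval-mode helix F1 collapses while train-mode dice is near
perfect).  Running statistics are still tracked (momentum 0.9) and stored
in checkpoints for reference.  A consequence of per-volume statistics is
that translation equivariance holds only up to the small global coupling
through the volume mean and SD (≈ 0.03% of the output scale on the test
fixture).

There is no size ceiling at inference; the 100-voxel limit applies to
training data only.

## Evaluation

Voxel metrics are one-vs-rest precision/recall/F1 per foreground class over
the full submap grid (masked voxels are background in both prediction and
truth).  Residue-level metrics assign each residue the majority class of
predicted voxels within 3 Å of its Cα — ties break helix > sheet >
background, mirroring the labeling precedence — then count one-vs-rest over
residues.  A class is NA for a chain with zero true residues of that class,
regardless of false positives; per-class aggregates weight each chain's F1
by its true-class residue count and skip NA chains.

The threshold sweep evaluates a detector at 20 thresholds
`t_i = μ + i·5σ/19` (map mean μ, SD σ) and reports, per class: the best
residue F1; the best-neighborhood F1 (mean over three consecutive
thresholds around the best index whose values are all nonzero, preferring
the centered triple, then the left- and right-shifted triples, falling back
to the mean of nonzero values in the centered triple); and the F1 at the
thresholds nearest μ+3.25σ and μ+2.5σ.  The neighborhood preference order
is a package convention for the zero-neighbor edge case.

## Synthetic data

Toy chains use ideal geometry: helical Cα atoms on a 2.3 Å-radius cylinder
with 1.5 Å rise and 100° twist per residue (Cα–Cα 3.83 Å), strand Cα atoms
on a 3.3 Å-rise zigzag with ±0.9 Å lateral alternation (Cα–Cα 3.76 Å), coil
as a smoothed random walk with 3.8 Å steps.  Toy residues carry only their
Cα as a heavy atom.  Density places a unit Gaussian per atom with FWHM
equal to the nominal resolution (SD = resolution/2.355 — the standard
resolution-interpretable blur convention), samples at 1 Å over the padded
bounding box, and adds seeded Gaussian noise scaled to the peak density.
Defaults: resolution 8 Å (midpoint of the medium-resolution regime), noise
SD 10% of peak, 5 Å box margin.

Two fixture families matter downstream:

- the *standard* chain (helix 12, coil 24, strand 10; 8 Å margin), whose
  long coil and margin reproduce the composition of real chain submaps —
  its label distribution is ≈ 98.8% background, mirroring the extreme
  imbalance of experimental chain volumes;
- the *training* pair: two compact two-segment chains with segments laid
  side by side so each map stays within 40³ voxels (≈ 25×16×30), sized so
  the full 40-epoch schedule completes in minutes on one CPU core.

Quality degradation for bin studies is modeled by the noise level alone
(no anisotropy or B-factor variation); noisy fixtures then spread across
bins through the cylinder fit naturally.

What the fixtures do **not** emulate: CTF effects, solvent/neighboring-
chain density, anisotropic resolution, deposition-dependent intensity
scales, real side-chain mass, or multi-chain contacts.  Passing tests on
fixtures therefore demonstrate that the pipeline's mechanics (labeling,
loss, optimization, evaluation) are correct and that the network can fit
helix/sheet density shapes, not that the shipped defaults reach any
particular accuracy on experimental EMDB maps.

## Numerical choices and degenerate inputs

- Maps with zero SD: z-scoring returns zeros; the threshold sweep refuses
  them (`σ = 0` has no threshold grid).
- Zero-count metric denominators yield 0 (precision, recall, F1) rather
  than NaN; residue classes with no true members are NA, not 0.
- A Cα with no in-grid voxels within the vote radius predicts background
  with a warning.
- Non-finite training loss aborts with a diagnostic rather than continuing.
- Checkpoints (`.npz`) store parameters plus batch-norm running statistics;
  loading validates shapes.

## Known limitations

- The numpy engine is CPU-only and single-volume; it is sized for
  chain-level volumes (≤ 100³), not tomograms.
- The cylindrical fit is a stand-in: scores are comparable within this
  package but not calibrated against any external quality metric.
- Training at scale (hundreds of chains) is functional but slow on one
  core; the package's scope is the method, its correctness, and desk-scale
  experiments.
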