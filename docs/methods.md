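# Methods

This note documents the models, conventions and numerical choices behind
`cyberbeam`, in the order data flows through the toolkit.

## Coordinate conventions

All geometry lives in the DICOM patient coordinate system (LPS,
millimetres) with the voxel-center convention and 0-based indices; the
world position of index `(i, j, k)` is `origin + axes · (spacing ∘ (i, j,
k))`. Arrays are indexed `(x, y, z)`. Every reader resamples onto the CT
grid at load (`harmonize_bundle`), with fixed background fills: −1000 HU
for CT, 0 for dose and masks. Clinical pipelines that stitch axial
planes to a fixed in-plane size can use the optional 512 × 512
pad/crop; the synthetic pipeline keeps its native grid.

## The beam matrix

A CyberKnife plan is a list of beams `(source b_j, aim a_j, cone
diameter, MU_j)` plus a prescription. The beam matrix assigns every
voxel the sum of MU-ratio weights of the beams whose cones contain it:

- *Half-angle model.* The collimator cone of diameter `c` at
  source-to-exit distance `L` (400 mm by default, per the treatment-head
  geometry) subtends `arctan((c/4)/L)` — a deliberately simple
  one-parameter divergence model; there is no attenuation or
  inverse-square factor in the encoding.
- *Membership.* Voxel `p` is inside beam `j` iff the angle between
  `p − b_j` and the axis `a_j − b_j` is at most the half-angle **and**
  `p` projects forward along the axis. The forward-half-space
  restriction excludes the mirror cone and removes the numerically
  ill-conditioned region near the source; physical beams travel forward.
- *Weights.* `w_j = MU_j / min{MU_k : MU_k > 0}`. The minimum runs
  over deliverable beams only — a minimum over all beams would divide by
  zero whenever a beam is parked with MU = 0; parked beams keep weight
  0. Weights are invariant under rescaling all MUs.
- *Target term.* Voxels inside the target mask that are covered by at
  least one collimator projection receive +1, once. The printed form of
  this composition is ambiguous in the source formula (the term may
  multiply the weight only inside the target instead); both behaviours
  are implemented behind the `target_term` flag, default on, and the
  choice is recorded in the matrix provenance.
- *Determinism.* The accumulator is a plain sum over beams in plan
  order (the recursive form of the definition is presentational);
  voxel blocks may be distributed over threads, so results are
  bit-identical for any thread count.
- *Network scaling.* The raw matrix is unbounded (MU ratios reach
  hundreds); it is min–max scaled to [0, 1] per case at channel
  assembly, not in the encoder.

A per-voxel/per-beam brute-force encoder (`encode_brute_force`) is kept
in the package as the validation oracle; on small grids the vectorized
encoder must (and does) match it bit-for-bit, because both evaluate the
same floating-point predicate.

When a plan lacks per-beam aim points (synthetic plans), the target is
partitioned into sub-targets by deterministic farthest-point sampling of
target voxel centers seeded at the centroid; clinical plans carry their
own aim points and never use the partition.

## Gamma analysis

For reference dose `D_r` and evaluated dose `D_e`, a voxel passes at
criteria `(dta, b%)` when some candidate point `q` within the search
radius satisfies `(|q−p|/dta)² + ((D_e(q)−D_r(p))/tol)² ≤ 1`.

- Candidates lie on a sub-voxel lattice at `spacing/subdivisions` per
  axis (default 3) with trilinear interpolation of `D_e`; with
  `subdivisions=1` the candidates are exactly the voxel centers, which
  is the resolution at which the exhaustive oracle operates and at
  which implementation–oracle equality is required to be exact.
- Pass/fail needs only candidates within the DTA (beyond it the spatial
  term alone exceeds 1), so the passing-rate path processes offsets in
  increasing spatial distance and retires voxels as soon as they pass;
  remaining voxels fail when the DTA is exhausted. This early-exit
  search changes nothing about the decision, only the cost.
- Normalization: `tol = b% · max(D_r)` (global, the community default
  and the default here) or `b% · D_r(p)` (local); both are exposed and
  every report records which was used. Where the local tolerance is
  zero, a candidate passes only with an exactly matching dose.
- Low-dose threshold: voxels with `D_r` below `threshold_pct` of the
  reference maximum are excluded. The evaluation pipeline applies 0.5 %
  to OARs and no threshold to body/targets, following the two regimes
  used in stereotactic practice.
- Undefined results (no voxels evaluated) are reported as `None`, never
  as 0 or 100.

## DVH and plan-quality indices

Cumulative DVHs use fixed-width bins (0.1 Gy default) with the fraction
of structure voxels at or above each edge; `dose_at_volume`
interpolates linearly between edges. Where identities must hold to
machine precision (HI, difference reports), quantiles are computed
directly from sorted voxel doses with the step-function convention:
`D_q` is the `ceil(n·q/100)`-th hottest voxel.

`nCI = (TV·V_RI)/TV_RI²`, `HI = D5/D95` on the target, `GI =
V(≥Rx/2)/V(≥Rx)`; volumes are voxel counts × voxel volume and isodose
membership is `dose ≥ level`. Empty denominators yield `None`.

## Synthetic phantom cases

The generator emulates the intracranial stereotactic setting so the
whole pipeline is testable without clinical data:

- *Phantom.* An ellipsoidal head (semi-axes ≈ 75 × 90 × 62 mm, jittered
  ±8 % per case), homogeneous soft tissue (0 HU) with a thin +700 HU
  skull shell; air at −1000 HU. The homogeneity matches the scope of
  primary-path dose engines, and keeps depth integrals analytic for
  oracle checks; the skull shell affects only CT appearance, not the toy
  dose.
- *Structures.* A spherical PTV (radius 8–14 mm) placed well inside the
  head, a GTV at 80 % of the PTV radius, and ellipsoidal OARs laid out
  like eyes/lenses/optic nerves/chiasm/brainstem. Halo rings are
  distance shells around the target at (0, 5] and (5, 10] mm by
  default. Ring distances use the Euclidean distance transform with a
  quarter-voxel bias correction, because the rasterized target boundary
  sits on average about a quarter voxel inside the continuous surface.
- *Plans.* 30–60 beams per case by default (config-exposed; clinical
  plans span roughly 30–150), sources on a superior hemisphere of
  radius 800 mm about the target centroid, aim points from
  farthest-point partitioning, cone diameters from the fixed CyberKnife
  set capped at the target diameter, MUs integer log-uniform in
  [10, 500] — the wide ratio spread that makes MU-ratio weighting
  meaningful. Prescriptions are drawn from {21, 24, 30, 36} Gy (brain
  stereotactic range).
- *Reference dose.* Per beam: inverse-square falloff from the source
  (unit weight at 800 mm), exponential attenuation `exp(−μ·depth)` with
  μ = 0.005/mm (≈ 6 MV in water), and a Gaussian penumbra of σ = 2 mm
  beyond the cone edge (zero past 3σ). Depth through the body is
  ray-marched at half the voxel size from one grid diagonal before each
  voxel (every external ray crosses that span), counting in-body
  samples; marched depths match analytic ellipsoid chords to within the
  voxel scale. The summed dose is rescaled so the target D95 equals the
  prescription exactly (hence independent of overall MU scale).
- *Reproducibility.* All randomness flows from one integer seed through
  spawned per-case generators; regenerating a dataset reproduces every
  array bit-for-bit, and the manifest records per-case seeds and
  checksums.

What the generator does **not** emulate: tissue heterogeneity, scatter,
beam blocking, multi-target cases, realistic anatomical variability
(heads differ only by a mild affine jitter), or planner-driven MU
optimization (MUs are random, not optimized). Passing desk-scale tests
therefore demonstrates that the pipeline recovers a smooth geometric
beam-to-dose mapping, not clinical accuracy.

## Dose-prediction network

A dense-block 3-D U-Net: at every level a dense block (`dense_layers`
repetitions of ReLU → 3×3×3 convolution producing `growth` channels →
batch normalization → concatenation with the block input), 2×2×2
max-pool downsampling, and symmetric 2×2×2 transposed-convolution
upsampling with skip concatenation; a linear 1×1×1 head produces the
single-channel dose. The clinical-scale configuration is 4 levels,
growth 16, 128-channel deconvolutions and 96×96×32 patches; the
desk-scale configuration used throughout the tests is 2 levels, growth
4, dense depth 2, 8-channel deconvolutions and 32×32×16 patches
(≈ 23 k parameters). The dense depth per level is not fixed by the
architecture sketch this follows; 3 is the clinical default here,
config-exposed.

- *Input arms.* TB = (target, beam), TBR = (target+rings composite,
  beam), CT+TB, CT+TBR. One fixed 3-channel head serves all arms;
  two-channel arms zero-fill the third channel, keeping checkpoints
  structurally compatible. The rings composite grades target 1.0 and
  successive rings at descending fractions.
- *Normalizations.* CT windowed to [−1000, 1000] HU → [0, 1]; masks as
  indicators; beam matrix min–max per case; dose divided by the
  prescription (making the regression target prescription-independent).
  These scalings are the package's own choice and are recorded in the
  run manifest.
- *Patch sampling.* Patches per case per epoch (100 at clinical scale)
  with corners uniform over valid positions, except that half are
  centered on random target voxels: uniform sampling over a mostly
  empty head volume starves the small-target signal. The "random
  slices" of the original recipe are realized as random 3-D patches,
  consistent with the 3-D patch shape.
- *Training.* Adam on voxelwise MSE, batch 2, learning rate decaying
  exponentially between the configured endpoints (1e-4 → 1e-6 at
  clinical scale; the schedule shape between the stated endpoints is
  this package's choice). The desk-scale configuration uses 3e-3 →
  3e-4: with only a few hundred optimization steps the clinical
  schedule leaves the network far from convergence, and the higher
  range is standard for small batch-normalized networks. The retained
  checkpoint is the epoch with the lowest *training* loss among epochs
  with a finite validation loss — the selection rule appropriate when
  the validation set is too small to rank models. Divergence (NaN
  loss) aborts with a diagnostic.
- *Inference.* Sliding window at 50 % overlap with Hann-window
  blending; accumulated weights are divided out, so any positive window
  reproduces constants exactly (partition of unity); output clipped at
  0 and rescaled to Gy.
- *Determinism.* All initialization and sampling flows from the
  estimator seed; repeated runs reproduce the loss log bit-for-bit on
  the same BLAS.

The network runs on `cyberbeam.nn`, a compact numpy layer/backprop
engine written for this package (channels-last tensors; convolution as
one GEMM per kernel offset). It implements exactly the layers above
plus Adam, is fully deterministic, and is validated against
finite-difference gradients in the test suite.

## Desk-scale study conditions

The end-to-end experiments (tests and `scripts/acceptance.py`) use: 8
synthetic cases split 5 train / 1 validation / 2 test on 64×64×48 grids
at 3 mm spacing; the tiny network; 60 patches per case per epoch, batch
2, 3 epochs (450 optimization steps); three training seeds per arm.
Held-out performance is measured as (i) body gamma at 3 mm/3 % between
the predicted and reference dose of the test cases and (ii) the
full-volume MSE on prescription-normalized dose of the held-out cases,
the metric on which the TB vs CT+TB input-arm comparison is made
(median over the three seeds). Because the phantoms share nearly the
same anatomy, the CT channel carries far less case-discriminative
information here than in clinical data; desk-scale arm differences are
accordingly small.

## Known limitations

- The gamma search interpolates the evaluated dose on a finite
  sub-voxel lattice; the continuous minimum can be smaller by up to one
  lattice step. Exactness is guaranteed (and tested) only at voxel
  resolution against the exhaustive oracle.
- The analytic dose engine is a toy: no scatter, no heterogeneity, no
  source model beyond inverse-square × attenuation × penumbra. It
  exists to define a learnable, physics-flavoured mapping, not to
  approximate a clinical dose engine.
- Desk-scale training budgets leave both network arms short of
  convergence; arm comparisons at this scale indicate direction, not
  clinical effect sizes.
- RTPLAN support covers this package's documented profile (standard
  tags plus a private block for the robot source position); vendor
  RTPLANs with proprietary private tags should be converted to the
  `.ckplan` sidecar.
- Multi-frame enhanced CT, inter-frame registration and MLC-shaped or
  variable-aperture fields are out of scope; cones are fixed circles.
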