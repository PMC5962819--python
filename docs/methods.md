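# Methods

## The problem and the model

A linear EEG inverse solution estimates a source field from scalp
potentials as `jhat = A v`.  With the forward model `v = K j + eps` this
composes to `jhat = R j` (noiselessly), where `R = A K` is the resolution
matrix.  Because the average-referenced lead field has rank `m = d - 1`
(with `d` electrodes), `R` is far from the identity: every voxel estimate
is a weighted mixture of all true sources.  That mixing injects spurious
statistical dependence between voxel time courses and badly distorts
directed connectivity estimates computed in source space.

The correction implemented here assumes a piecewise source model on `L`
disjoint regions of interest `B_1 .. B_L`:

* **general variant** — the source is an unknown constant 3-vector `b_l`
  on each region (and zero outside all regions).  The region-aggregated
  resolution matrix `Q` with 3x3 blocks
  `Q(l,s) = sum_{u in B_l} sum_{w in B_s} R(u,w)`
  relates the ROI sums of `jhat` linearly to the `b_l`; solving
  `Q b = ROI sums` removes the leakage.  Identifiability requires
  `3L <= m`, i.e. at most 6 regions for the 19-channel 10-20 montage.
* **directional variant** — each voxel has a known unit direction `d(u)`
  (here: the outward surface normal) and each region one unknown scalar
  intensity `a_l`.  `Q` becomes the `L x L` matrix
  `q_ls = sum sum d(u)^T R(u,w) d(w)` and up to `L = m = 18` regions are
  admissible.

Both systems are exact: when the true source satisfies the piecewise model
and there is no noise, the solved parameters equal the truth up to solver
precision.  This is the package's headline property and is asserted at
`1e-6` relative error in the tests (observed: `~1e-10` or better).  The
per-region `1/#B_l` normalizations cancel on both sides of the defining
equations, so the implementation uses unnormalized ROI sums.

The comparison method (`directfit`) skips the distributed inverse: it
writes `j = M alpha` for the region-indicator design `M` and solves
`min ||v - K M alpha||^2` by QR least squares (equivalent to the normal
equations, better conditioned).  Both routes agree on exact noiseless
parceled sources; they differ under model misspecification, which is what
the simulation scenarios probe.

## Forward model and head geometry

The head is three concentric homogeneous spheres in a dimensionless frame
(scalp radius 1).  Defaults: radii `(0.87, 0.92, 1.0)`, conductivities
`(1.0, 0.0125, 1.0)` — the classical 80:1 scalp-to-skull ratio; both are
configurable.  The dipole potential is the Legendre series whose
per-degree shell transmission is obtained by solving, for each harmonic
degree `n`, the 5x5 linear system expressing continuity of potential and
radial current at the two interfaces plus the insulating scalp boundary.
The series is truncated when the bound on the next term falls below
`1e-10` of the leading term (hard cap 200 degrees); with sources at radius
0.8 this converges in roughly 130 degrees.  At equal conductivities the
layered model must degenerate to the homogeneous sphere, whose closed-form
dipole potential serves as an independent oracle (agreement `~1e-13`
relative; asserted at `1e-6`).

Electrode positions are the 19-channel 10-20 montage on the unit sphere
(documented construction in `data/montage_1020.txt`: ring electrodes at
90 degrees inclination, midline/central at 45 degrees, F3/F4/P3/P4 as
spherical midpoints of their neighbors).  Synthetic cortical grids are
Fibonacci-lattice shells with radial normals, rotated by a seeded random
rotation so seeds give distinct but equally uniform grids; a two-layer
variant appends a concentric inner shell for the superficial-lead-field
experiment.  Gain units are arbitrary-but-consistent: every quantity in
scope depends on ratios and spatial patterns only.

## Inverse operators

* minimum norm: `A = K^T (K K^T + alpha H)^+`, with `H` the average-
  reference centering matrix and the pseudo-inverse computed by eigen-
  decomposition (eigenvalues below `1e-12 lambda_max` nulled).
* sLORETA: the minimum-norm operator standardized by the inverse square
  root of the 3x3 (or scalar) diagonal blocks of `S = T K`.  This gives
  exactly zero localization error for noiseless single dipoles — verified
  at every voxel of the test grids, for free and fixed orientation.
* custom: any externally built operator can be injected; everything
  downstream consumes only `R`, so the unmixing is method-agnostic by
  construction (e.g. an eLORETA operator computed elsewhere drops in).

Default regularization `alpha = 1e-5 * trace(K K^T) / d`; the noiseless
localization tests use `alpha = 0`, the natural choice when no measurement
noise is simulated.  Localization ties break to the lowest voxel index.

Diagnostics: per-voxel localization error (distance from a simulated unit
dipole to the power argmax) and the minimum unmixing distance — for each
voxel, the smallest separation beyond which every two-point directional
unmixing system is invertible at condition number below `1e8` (double-
precision headroom).  On the synthetic shell, sLORETA unmixes every voxel
against its nearest neighbor, and minimum-norm localization degrades with
depth, both as expected.

## Parcellations

Regions are ordered disjoint voxel-index sets (overlaps are rejected with
the shared voxels named).  Two canonical constructions ship with the
experiment layer:

* point ROIs — single voxels under `d - 1 = 18` electrodes (the maximum
  admissible number, which the simulations show should always be used);
* surface ROIs — 18 disjoint spherical caps of angular radius 20 degrees
  centered under the 18 non-vertex electrodes.  On a rotationally
  symmetric sphere, equal-area *partitions* of the full shell at the
  identifiability boundary `L = m` are nearly degenerate (condition
  numbers `1e5`-`1e7`): the aggregated smooth resolution kernel of 18
  large symmetric patches spans mostly low-order spherical harmonics.
  Compact caps break the degeneracy; their `Q` conditions at ~20-40, the
  comfortable regime an asymmetric anatomical grid reaches naturally.

## Simulation framework

The three-node reference system is a MAR(2) with feedback between nodes 1
and 2, a one-way link 2 -> 3, and unit-variance white innovations; its
spectral radius is 0.979.  The five- and seventeen-node systems fix their
directed topologies exactly (one bidirectional pair Fp1<->Fp2; O1/O2 pure
senders; all other links one-way) and draw diagonal/coupling magnitudes
from the same palette per seed.  Because the non-pair edges form a DAG,
the companion matrix is block-triangular over strongly connected
components and one-way couplings cannot destabilize; the bidirectional
pair reuses the reference feedback block.  Stability is therefore
guaranteed by construction (a shrink-couplings rescue remains as a safety
net); simulation refuses unstable models.  Simulations start from zero
state, discard 1000 burn-in samples (comfortably beyond the mixing time of
these models), and are deterministic per seed.  Sample autocovariances
match the companion-form Yule-Walker solution in the tests.

Point-source scenarios place each series at the grid voxel nearest its
named electrode's radial projection, oriented along the voxel normal, with
independent Gaussian background noise (default sd 0.1) at every voxel.
Surface scenarios modulate each target region's series by a Gaussian
spatial profile equal to 1 at the centroid voxel (default width: half the
centroid-to-edge distance) plus per-voxel noise; non-target voxels carry
white noise.  The forward step adds optional white measurement noise at
the electrodes and re-centers to the average reference.

## Connectivity: MVAR estimation and iCoh

`mvar_fit` is equationwise OLS on the lagged regression with innovation
covariance denominator `T - P - nP`.  The isolated effective coherence for
an ordered pair `j -> i` prunes the fitted model to the `j -> i` lag
coefficients plus all self coefficients and evaluates the pruned model's
partial coherence, which reduces to the closed form

    iCoh_{i<-j}(w) = w_i |Abar_ij(w)|^2
                     / (w_i |Abar_ij(w)|^2 + w_j |Abar_jj(w)|^2),

with `Abar(w) = I - sum_k A(k) exp(-i 2 pi w k)` and precision weights
`w_i = [V^-1]_ii`.  Since pruning leaves the diagonal and `(i,j)` entries
unchanged, the computation vectorizes over a default grid of 128
frequencies in `(0, 0.5]` (fractions of the sampling rate, which is fixed
at 1).  A value of exactly zero for every absent directed path is
structural (the numerator vanishes identically).  The closed form is
cross-checked in the tests against a brute-force route that builds the
pruned spectral density `Abar^-1 V Abar^-H` and inverts it; the two agree
to machine precision whenever `V` is diagonal — the setting of every
scenario here — and the diagonal-`V` assumption is the stated domain of
the closed form.  The fit order is user-specified (default 2, matching
all scenarios); there is no automatic order selection.

## Scenario defaults and problem sizes

All experiment scenarios run on a 400-voxel shell (radius 0.8) with
`T = 5000` samples, sLORETA, iCoh threshold 0.1, and measurement noise off
unless the scenario is about it (`measurement_noise` uses noise sd equal
to 10% of the noiseless scalp RMS).  The acceptance script uses 360- and
200-voxel grids.  These sizes were chosen as the smallest at which the
geometric quantities (condition numbers, localization behavior) are
stable; everything runs in seconds on one core.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the validation setting —
known point/surface sources with known directed dynamics on a spherical
head — not realistic EEG: no 1/f background, no rhythms, no artifacts, a
spherical rather than anatomical cortex, and white Gaussian noise
everywhere.  Passing tests therefore demonstrate the algebraic and
statistical properties of the method (exact unmixing under the model,
ordering of robustness between routes), not clinical performance.

Two observed sensitivities are worth stating plainly.  First, near-unit-
root MAR modules make iCoh hypersensitive at resonance: `|Abar_jj|^2` at
the resonant frequency is of order `1e-6`, so minute coefficient errors —
from finite samples or from background-noise leakage through the unmixing
solve — can produce isolated spurious peaks near the 0.1 threshold.  With
the default background noise a minority of seeds show one marginal
spurious edge at ~0.10 in the three-node pipeline; noise-free runs are
exact.  Second, in the surface-region scenario the Gaussian profile makes
the source non-constant within regions; the resulting model error leaks
target signal into silent-region estimates, and with 15 silent regions the
18-node iCoh shows substantial spurious structure under the default
profile width.  A nearly flat profile restores clean recovery.  Both
effects are properties of the statistic and the study conditions, not of
the unmixing algebra, whose exactness the noiseless tests pin down.

## Numerical choices

* pseudo-inverse and rank thresholds: `1e-12 lambda_max` (operators),
  `1e-8 sigma_max` (rank counting);
* unmixing solves: LU with partial pivoting; condition number by SVD;
  systems at condition `>= 1e8` are rejected as unidentifiable;
* multi-sample fields are unmixed in a single factorized solve, which is
  also what makes samplewise and matrix solves bit-compatible;
* voxels outside all regions reconstruct to zero (the model's support
  convention);
* on-disk indices are 1-based (documented in every format), in-memory
  0-based.

## Known limitations

* eLORETA is supported only through operator injection, not built in.
* No statistical inference on unmixed parameters (standard errors, tests)
  and no significance thresholds for iCoh; the 0.1 edge threshold is the
  conventional display cut used throughout.
* The spherical grids cannot reproduce numbers tied to a specific
  anatomical template; loaders for externally supplied grids, lead fields
  and parcellations are provided for that purpose.
* `icoh` with a non-diagonal innovation covariance uses the same
  closed form with `[V^-1]_ii` weights; it then no longer coincides with
  the brute-force pruned-model partial coherence.
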