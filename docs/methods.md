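# Methods

## The model

The apical surface of the early *Drosophila* embryo is represented as a
two-dimensional monolayer of soft disks in a periodic box: every apical
cell end is one force center with an effective diameter `d_i` (the range
of the repulsive branch of its pair potential).  Cells interact through
the pairwise spring potential

    V_ij = (eps/2) (1 - r_ij/d_ij)^2

acting in full (repulsion + adhesion) between *connected neighbors* —
pairs with `r_ij/d_ij < 1.1` in the initial packing, a list frozen for
the whole run because cells do not intercalate during the slow phase of
ventral furrow formation — and as repulsion only (`r < d_ij`) between
all other pairs.  `d_ij = (d_i + d_j)/2`; `eps` and the mean large
diameter set the units and drop out of every reported quantity.

Cells in a horizontal stripe of width 12 diameters (the mesoderm
primordium, roughly 12 cells wide spanning the anteroposterior axis) are
*active*: in each simulation step an unconstricted active cell `i`
constricts with probability

    P_i = alpha_i (1 + beta s_i) / (N_a (1 + beta)),
    s_i = (sigma_i / sigma_ref)^p  for sigma_i > 0, else 0,
    sigma_i = -(1/eps) sum_j d_ij f_ij,

where `N_a` is the current number of unconstricted active cells,
`f_ij = -dV/dr` the radial pair force, and `sigma_i` the triggering
stress (positive = net tension).  A successful constriction is ratcheted:
`d_i -> f_c d_i`, once, permanently.  After every step with at least one
constriction the system is relaxed back to mechanical equilibrium, so
the process is quasistatic and governed by the equilibrium stress field.

Parameters, units dimensionless throughout:

| parameter | default | meaning |
|---|---|---|
| `N_tot` | 6,400 full / 1,600 reduced | particles in the square box |
| diameter ratio | 1.1 | 50:50 bidisperse mixture (prevents crystallization) |
| stripe width `w_a` | 12 | active-region width, mean large diameters |
| `p` | 3 | stress-sensitivity exponent (sensitive to strong stresses) |
| `beta` | 250 | stress coupling; 0 = uncorrelated random constrictions |
| `f_c` | 0.6 strong / 0.85 weak | diameter constriction factor |
| `alpha_i` | 1 | per-cell probability amplitude (`alpha_r < 1` in a disrupted zone) |
| `sigma_ref` | calibrated | mean tensile stress of one isolated constriction |
| `b` | 0.5 | pairwise dissipation of the damped relaxation dynamics |
| `dt` | 0.02 | integration step (unit mass, unit stiffness springs) |

`sigma_ref` is measured, not chosen: single active cells are constricted
one at a time in the initial state, the system is relaxed, and the
constricted cell's `sigma_i` is averaged over 50 such probes.  The probe
runs use the full 6,400-particle reference system even when production
runs are smaller, because a small periodic box is mechanically stiffer
and overestimates the reference stress, which would damp the feedback
through the cubic normalization `(sigma/sigma_ref)^3`.

## Initial packings

The initial state is a mechanically stable, disordered 50:50 mixture at
area fraction 0.845, just above the jamming (random-close-packing) point
of bidisperse disks.  Particles are seeded uniformly at random, inflated
to the target fraction in 24 steps with an energy minimization after
each step, and polished until the largest net force is below 1e-8.
Packing at the jamming margin matters physically: a strongly
overcompressed packing carries a compressive background that the
`Theta(sigma_i)` gate of the feedback parameter subtracts from every
tensile signal, which visibly weakens chain formation and the
disrupted-zone rescue.  Boxes smaller than twice the
interaction range (only relevant for toy systems of a few particles)
are automatically enlarged so the minimum-image convention stays valid.

## Energy minimization

Two minimizers drive the same quasistatic minima.  The damped
velocity-Verlet dynamics — pairwise dissipation `-b (v_ij . r_hat)
r_hat` within interaction range, a small global drag 0.01 against
rigid-body drift, and the energy-window stopping rule (relative change
below 1e-3 per 1,000 steps) — is the reference dynamics.  Production
runs default to FIRE with a force criterion (max net force below 1e-6),
which reaches the same minima several-fold faster; the tolerance sits
orders of magnitude below the stress scales that enter the feedback.
Both kernels guard the truncated candidate pair list with a Verlet-skin
displacement check and hand control back for a rebuild whenever any
particle has moved far enough that a new contact could be missed; FIRE
additionally falls back to short bursts of damped dynamics if it
limit-cycles on a degenerate landscape.  Minimizer choice, tolerances
and the stopping rule only control numerical efficiency, not the
physics.

## Stress-augmented Voronoi tessellation

Rendered cell shapes come from a weighted Voronoi construction.  Each
cell carries a shape tensor `D_i = d_i (I + S_i/s0)` built from the
normalized virial stress `S_i = -(1/2 eps) sum_j r_ij (x) f_ij`
(symmetric; its larger-magnitude eigenvalue is the major stress,
positive = tension), with `s0 = 2.1`, the typical number of springs
loading a cell in one direction.  A pixel at offset `rho` from cell `i`
is scored with

    rho_bar_i = rho / (rho_hat . D_i . rho_hat)

and assigned to the arg-min cell (ties to the lowest id; 8 pixels per
diameter by default).  The division form is chosen because it reduces
exactly to the standard Voronoi diagram for `D = I`, to multiplicative
size weighting for `D = d_i I`, and makes the boundary between two cells
split the center-to-center distance in the ratio of their directional
ellipse extents; a square-root variant is available behind a flag since
the algebraic placement of the quadratic form is ambiguous in the
source.  Eigenvalues of `D_i` are clamped at `0.05 d_i` — strong
compression can otherwise invert the weight.  Tension along a
constriction chain inflates the chain cells' reach along the chain,
reproducing their elongation; the standard construction shows no such
effect (see `examples/02_stress_voronoi.py`).

## Cluster statistics and disruption recovery

Constricted-cell clusters are connected components of the constricted
set on the frozen neighbor graph.  Reported statistics: normalized
cluster count `C_ave = <N_clu/N_a0>`, fractions `eta_s, eta_d, eta_m` of
constricted cells in singlets, doublets and multiplets (size >= 3), and
the constricted fraction `%N_c = N_c/N_a0`.  "At `%N_c = x`" always
means the first event at which the trajectory reaches that fraction
(trajectories advance in ~1-cell increments, so this is deterministic
and unbiased to O(1/N_a0)).

A disrupted zone (band, or ellipse with semi-minor axis 0.375 of the
stripe width) reduces `alpha_i` to `alpha_r` for active cells inside.
Recovery is measured by `chi_cp = <%N_c^test> / <%N_c^ref>` across
replicates, with the reference region the active tissue outside the
zone's bounding strip; the standard error uses the delta method for a
ratio of means.  For `beta = 0` the process is exactly exponential
saturation (`%N_c^t = 1 - exp(-alpha_r tau)` etc.), and `tau` is
obtained from the global `%N_c` by bracketed root finding, giving the
closed-form `chi_cp` baseline without simulating thousands of random
replicates.

Because a `beta = 0` (or neighbor-triggered) run's constriction choices
do not depend on the mechanics at all, those ensembles skip the
relaxations entirely; the pattern statistics are identical in
distribution.

## Image metrics

Segmented movies arrive as integer label rasters (0 = membrane).  A
cell's minor axis is the equivalent-ellipse convention `lambda = 4
sqrt(e_min/area)` from the eigenvalues of its unnormalized central
second-moment matrix; this matches scikit-image's region properties to
float precision and the true diameter of rasterized disks to ~3%.  A
cell is constricted when `r = lambda/lambda_ref <= r_c` (boundary
inclusive), with `lambda_ref` the mean over 20 pre-onset frames
(configurable 15–20; cells with too few pre-onset frames are excluded).
Time zero is the first frame whose constriction persists for 3
subsequent frames at `r_c = 0.65`.  Cell adjacency uses Chebyshev pixel
distance <= 2 ("primary or secondary neighbors"), which tolerates
1-pixel membranes; it also links cells that touch only at a corner — a
property of the criterion itself, kept as-is.  Active cells are those
reaching `r <= 0.85` at some point; they form the `N_a0` denominator.
The binned constricted fraction `nu_avg` supports both the relative
rule and an absolute minor-axis threshold (1.3 um) when the pixel size
is known.

## Synthetic movie generator

The test fixture emulates segmentation output: jittered-lattice cells
rendered as weighted-Voronoi regions with 1-pixel membranes, consistent
ids across frames, and a constriction schedule (none / random / chain /
band-disrupted) that shrinks scheduled cells' vertical weight from their
scheduled frame on.  Because cell boundaries are weighted bisectors, a
requested measured reduction `f` is rendered with internal weight
`f/(2-f)`.  The generator emits ground truth (adjacency, constriction
frames, reference minor axes measured independently with scikit-image)
for round-trip tests.  It does not emulate unratcheted pulsation,
tracking loss, segmentation errors, curvature foreshortening, or
anisotropic pixel sizes — so passing round-trip tests demonstrates the
correctness of the metric pipeline, not robustness to real segmentation
noise.

## Scales, run sizes, and what the desk-scale results mean

Full scale is the 6,400-particle box (stripe 12 x ~80).  Production
statistics in the tests and the acceptance script use the reduced
1,600-particle box (stripe 12 x ~40) with 20 replicates per condition
and a shared packing per condition (replicates differ in the
constriction RNG stream; the packing and `sigma_ref` calibration are
properties of the ensemble).  One reduced-scale feedback run to
`%N_c = 0.4` performs ~200 constriction events with a relaxation each.
At this scale the disrupted band occupies a larger fraction of the
shorter stripe (q ~ 0.27 vs ~0.125 at full scale) and the unaffected
flanks feeding stress chains into it are shorter, so the recovery
coefficients can land slightly below their full-scale counterparts;
the cluster-count reduction and the recovery orderings are insensitive
to this.

## Known limitations

- No intercalation, no cell divisions, no 3D curvature, no pulsatile
  (unratcheted) constrictions, no Fog/T48 fast-phase signaling.
- The tessellation is raster-only; shape measures inherit pixelation
  error at the default 8 px/diameter resolution.
- `chi_cp` ratios are undefined once the reference region saturates;
  analyses stop at `%N_c = 0.4`, before saturation matters.
- Near the jamming point, per-packing fluctuations in pressure make
  `sigma_ref` vary by a few percent between reference packings; this is
  inherent to calibrating on a single reference system.
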