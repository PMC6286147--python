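# Methods

## Model

Cells are point particles at positions $\bar r_i$ (lengths in units of
the cell radius) carrying two unit vectors: apical–basal polarity
$\hat p_i$ and planar cell polarity (PCP) $\hat q_i$.  Interacting pairs
$(i,j)$ at separation $r_{ij}$ contribute the potential

$$V_{ij} = e^{-r_{ij}} - S\, e^{-r_{ij}/\beta},$$

a short-range repulsion plus a longer-range attraction whose strength
$S$ depends on how the polarities of the two cells are oriented relative
to each other and to the separation direction $\hat r_{ij}$:

$$S = \lambda_1 S_1 + \lambda_2 S_2 + \lambda_3 S_3,\qquad
S_1 = (\hat p_i \times \hat r_{ij})\cdot(\hat p_j \times \hat r_{ij}),\quad
S_2 = (\hat p_i \times \hat q_i)\cdot(\hat p_j \times \hat q_j),\quad
S_3 = (\hat q_i \times \hat r_{ij})\cdot(\hat q_j \times \hat r_{ij}).$$

$S_1$ rewards parallel AB polarities perpendicular to the separation
(epithelial sheets), $S_2$ rewards matching orthogonal $(\hat p,\hat q)$
frames, and $S_3$ rewards parallel PCP with like poles adjacent (the
anisotropic adhesion that drives convergent extension).  The strengths
satisfy $\lambda_1+\lambda_2+\lambda_3 = 1$ per cell, so a perfectly
aligned pair ($S=1$) always rests at
$r^* = \frac{\beta}{\beta-1}\ln\beta$, two cell radii for the default
$\beta = 5$.  For pairs of cells with different strengths the effective
$\lambda_k$ is the pairwise mean, which keeps pair forces equal and
opposite.  A quartic-exponent variant
$V_{ij} = e^{-r_{ij}^4} - S e^{-(r_{ij}/\beta)^4}$ is available and
behaves qualitatively the same.

Neighbors are determined by a line-of-sight rule: $i$ and $j$ interact
only if no third cell lies within $r_{ij}/2$ of the segment midpoint
(equivalently, the midpoint is not inside any third cell's Voronoi
region).  Ties block, conservatively.  The search examines the
`prefilter_k = 100` nearest candidates of each cell; any potential
blocker of a candidate pair is strictly closer than the candidate
itself, so the prefilter provably does not alter the result for any
pair it contains.  An alternative mode uses Delaunay adjacency with a
distance cutoff (default 4 cell radii, twice the aligned-pair rest
separation; the value is a package choice, made configurable).

## Dynamics

Overdamped gradient descent with uncorrelated Gaussian noise,
integrated by the explicit Euler method:

$$\dot{\bar r}_i = -\partial V_i/\partial \bar r_i + \eta\,\xi,\qquad
\dot{\bar p}_i = -\partial V_i/\partial \bar p_i + \eta\,\xi,\qquad
\dot{\bar q}_i = -\partial V_i/\partial \bar q_i + \eta\,\xi,$$

with $V_i = \sum_j V_{ij}$ over graph neighbors.  Polarity gradients
are taken along all three Cartesian coordinates and projected onto the
tangent plane of the unit sphere (the derivative through the
normalization, evaluated at unit norm); vectors are renormalized after
every step.  The analytic gradients are validated against central
finite differences of the potential (`polarsim validate-gradients`,
worst relative error below 1e-6 over random configurations; the same
check runs in the test suite).  Neighbor exchange is a non-equilibrium
event: energy can rise when the graph changes, and with zero noise it
is non-increasing between graph changes.

Defaults: `dt = 0.1` (0.2 in the longer scenario presets; larger steps
destabilize the morphologies), `eta = 1e-4`, `beta = 5`.  Noise is a
per-step Gaussian kick added to the rate and multiplied by `dt`, so the
per-step displacement is `dt*eta*xi` and a quoted `eta` is meaningful
only together with its `dt`; there is no sqrt(dt) Brownian scaling.

Constraint masks: `fixed_polarity_mask` freezes both polarity vectors
(boundary-condition experiments); `pcp_in_plane_mask` confines PCP to
the apical plane — the cell uses $\lambda_2 = 0$ in its AB-polarity
update and its PCP is re-projected orthogonal to $\hat p$ (then
renormalized) after each step, so PCP cannot reorient AB polarity.
The projection order (update $\hat p$, renormalize, project $\hat q$,
renormalize) keeps the frame orthonormal each step.

External fields:

- Medium resistance (growing organoids in a stiff gel): an inward force
  of magnitude $P\, r/r_\text{max}$ toward the center of mass, where
  $r_\text{max}$ is the distance of the outermost cell — constant in
  time at the periphery of a growing sphere, weaker deep inside folds.
  The potential form this derives from would literally give an outward
  gradient; the implementation follows the physical description (a gel
  resists outward growth), i.e. the force points inward.
- Gastrulation (bottle-cell) force on AB polarity: selected cells
  receive $-k\,\hat\rho\, e^{-(x^2+y^2)/\sigma^2}$ added to $\bar p$
  once per step (a per-step reorientation kick, not multiplied by
  `dt` — like the noise amplitude, $k$ is meaningful together with
  `dt`), where $\hat\rho$ points from the anterior–posterior ($z$)
  axis to the cell.  Tilting AB polarity toward the axis makes the
  epithelial normals converge and bends the sheet inward; with the
  per-unit-time convention instead, the resulting torque (~$k$ against
  an alignment stiffness of order 1) is far too weak to bend anything
  at the default $k$.  Cells exactly on the axis receive no force.
  Defaults $k = 0.02$, $\sigma = 10$.
- PCP whirl boundary condition: a mask of cells whose PCP is re-imposed
  after every step as the azimuthal direction about a given axis,
  projected into the apical plane.  The gastrulation preset uses it for
  the vegetal third of the blastula — the organizer-oriented PCP is a
  standing boundary condition there, not an initial condition.  With
  PCP left free instead, convergent extension reorients it and the
  tube everts regardless of the bottle-cell force strength.

## Proliferation

Growing systems follow $N(t) = n_0 \exp(\ln 2\, t/t_G)$ with doubling
time $t_G$, starting from $n_0 = 200$.  Whenever the realized count
falls below $\lfloor N(t)\rfloor$, mothers are drawn uniformly from the
whole population and each daughter is placed half a cell radius away in
a uniformly random direction, inheriting the mother's polarities,
strengths, and masks (the model has no cell identity beyond these, so
inheritance is the only choice that preserves cell type).  Divisions
happen between integration steps.  While growing, the AB attraction is
gated to zero for pairs whose AB polarities differ by more than
$\pi/2$.

## Initial conditions

- Bulk aggregate: random sequential insertion (minimum separation 1.6
  cell radii) in a ball at number density 0.15 cells per unit volume,
  then 50 noiseless relaxation steps with $S = 1$; the relaxed
  nearest-neighbor spacing is ~2 cell radii.  The density is a package
  choice — it reproduces a compact, non-overlapping aggregate.  AB
  polarities are uniform on the sphere; PCP inactive.
- Hollow sphere: deterministic Fibonacci spiral lattice (low sampling
  variance for the tube measurements) at a radius giving one cell per
  hexagonal-packing area at spacing 2; AB polarity radially outward;
  optional PCP whirling azimuthally about an axis (default $\hat z$;
  the choice of axis is free).
- Polarity fields for boundary conditions: radial from a point, radial
  from an axis, or away from a plane; cells exactly on the symmetry
  locus get $+\hat x$ (radial fields) or the $+$normal (planar) with a
  warning.

## Quantification

- Energy per cell: $V_i = \sum_j V_{ij}$ over graph neighbors.
- Local minima (folds): cells with no neighbor strictly closer to the
  center of mass whose mean angle between $\hat p_i$ and the
  displacements to their neighbors is below $\pi/2$.  Zero-neighbor
  cells are excluded.
- Tube semi-axes: half the maximum/minimum pair distance over cell
  pairs with $\hat p_i\cdot\hat p_j < -0.9$ (opposite walls of a closed
  epithelium).  The threshold is a package choice; sensitivity to
  −0.8/−0.95 is covered in the tests.  The minor estimate uses chords
  between near-opposite normals slightly off the waist and is biased a
  few percent low on smooth ellipsoids.
- Shell count: connected components of the neighbor graph restricted to
  edges shorter than 3 cell radii (nested shells are separated by more
  than this; in-shell neighbors are closer).
- Fold geometry: for each local-minimum cell, depth is the largest
  radial distance within 5 graph hops minus its own; extent is the
  graph-geodesic diameter of the connected below-median-radius patch
  containing it.  This measurement is defined by this package (the
  ~2x pressure-vs-growth fold contrast it quantifies is otherwise
  only described qualitatively).

## Scenario presets and problem sizes

The presets run at a few hundred to a thousand cells so a full suite
fits on a desk machine; the originals used thousands to tens of
thousands.  All qualitative outcomes tested here (shell/tube/plane
boundary morphologies, growth-vs-pressure folding, tube scaling with
PCP strength, gastrulation stage sequence) are scale-robust in the
tested ranges, with the caveats below.  Every preset emits a manifest
(all parameters plus seed) from which the run is bitwise reproducible
on one platform.

Fold counting protocol: fold counts are taken after a 50-time-unit
settle at the final size (with any pressure field still applied), so
that freshly divided daughters — which transiently register as local
minima — do not contaminate the count.  Genuine out-of-equilibrium
buckling requires the division interval to beat the whole-system
relaxation time, which shrinks the buckling size with the generation
time; at desk scale the growth-folding arm therefore runs at the
fastest schedules ($t_G = 25$ to ~2000 cells), where tens of shallow
folds survive the settle, while the slow arm ($t_G = 500$) stays a
sphere and the pressure arm produces a few folds several radii deep.

Gastrulation stage detection tracks the cells that start nearest the
vegetal (bottom) pole: flattening when their mean radial distance
drops below 0.95 of the shell mean, invagination below 0.8,
exvagination above 1.1, and merging when the nearest of them comes
within 4 cell radii (two rest spacings) of an animal-pole cell.

Known limitations at desk scale:

- The nested "Russian-doll" multi-shell outcome of the high-noise
  symmetric boundary experiment is a large-system effect: a few hundred
  to a thousand cells fit comfortably in one or two shells, so the
  interior cannot template three closed layers (see the boundary
  scenario notes in the test suite).
- Convergent-extension tubes at strong PCP evolve slowly; the sweep is
  measured mid-transient, and the monotone length/width trend, not the
  asymptotic axes, is the meaningful output.

## What the generators do and do not emulate

Synthetic initial states emulate idealized tissues: perfectly
spherical lumens, exactly radial polarity, noise-free lattices.  Real
epithelia have cell-size variability, apical-basal asymmetry of shape,
and signaling-patterned polarity domains none of which are modeled;
passing tests therefore demonstrate the internal consistency of the
model and the reproducibility of its emergent morphologies, not
agreement with any particular experimental tissue.
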