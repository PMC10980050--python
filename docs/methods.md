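# Methods

This note documents the models, conventions and numerical choices behind
`bmcshell`, and what the synthetic fixtures do and do not establish
about real data.

## Systems and units

Coordinates are in Ångström, frame times in nanoseconds, rates in s⁻¹.
Atom indexing is 0-based internally; 1-based only at PDB serialization.
Periodic boxes are orthorhombic only; all periodic distances use the
minimum-image convention. Van der Waals radii come from named
per-element tables: `simple` (H 1.20, C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80 Å) and `hole` (the larger united-atom-style set of the classic
channel-profiling program: H 1.00, C 1.85, N 1.75, O 1.65, S 2.00,
P 2.10 Å). Unknown elements receive a configurable default (1.70 Å)
with a logged warning. Solvent is identified by residue name
({HOH, TIP3, TIP3P, WAT, SOL}, configurable), monatomic ions likewise;
"protein" means neither.

Shell tiles are declared, not detected: a tile specification maps chains
to tiles of kind hexamer (6 chains), trimer_upper or trimer_lower
(3 chains each; a stacked pseudohexamer is the upper/lower pair). Which
chains of an experimental structure form which tile is user input — the
assignment is not derivable from coordinates alone — and the synthetic
facet is the tested path. Hexamer monomers are classed **buried**
(any atom within 5 Å of a trimer-tile atom) or **exposed** otherwise;
5 Å matches the contact cutoff used throughout. With no trimer present
all monomers are exposed and a warning is logged.

## Facet flattening

A tile's pore normal is the normalized sum of cross products of vectors
from the tile centroid to consecutive per-chain reference points — for
three points exactly v₁ × v₂ of the adjacent-pair vectors. Reference
points are per-chain Cα centroids ordered by angle about the tile
centroid: centroids are robust to missing side-chain atoms, and the
angular ordering makes "adjacent" well defined. Normals are oriented
away from the assembly centroid; when that is degenerate (a flat sheet,
where tile centers are coplanar with the centroid) the sign is
canonicalized so the largest-magnitude component is positive.

Flattening applies, per tile, the minimal rotation (Rodrigues, about
n̂ × t̂) taking its normal to the target axis, pivoting about the tile's
own pore center, so every intra-tile distance is preserved exactly. The
reference tile — the first trimer, else the most central tile — lands at
the origin. In-plane placement of the remaining tiles is the gnomonic
projection of tile centers from the best-fit sphere of the hexamer
centers (algebraic least-squares fit), rescaled so the mean
nearest-neighbor tile spacing matches the input; radial offsets become
offsets along the target axis, which is what keeps a stacked trimer pair
coaxial. The projection rule is this package's own choice — any
area-reasonable map of a shallow cap to the plane would do — and is
validated by post-conditions rather than assumed: normals on target to
1e-6, inter-tile center distances preserved within 5 %, and no new
inter-tile contacts closer than 1 Å below the input minimum (hard
error). Near-planar inputs (center deviation < 1e-6 of the extent)
bypass the sphere fit, making a planar facet an exact fixed point up to
one global rigid transform; as curvature → 0 the projected placement
converges continuously to the same limit.

The periodic cell assumes the hexagonal tiling of BMC sheets: the
nearest-neighbor tile spacing a (stacked trimers collapsed to one
lattice site) gives lattice constants a along x and a√3 along y,
multiplied up to cover the motif; z is the atomic slab thickness plus
the solvent padding on each face. With the
three-hexamers-plus-stacked-trimer motif this yields the 2a × a√3 cell
in which every trimer is surrounded by hexamer images.

Synthetic density maps are sums of unit-peak isotropic Gaussians with
σ = resolution / (2√(2 ln 2)) — i.e. the stated resolution is the FWHM,
the common cryo-EM reading; the convention is stated here because map
generators differ. Grids cover all atoms plus a 2×resolution margin;
Gaussians are truncated at 5σ, keeping the integral within 1 % of
n_atoms·(2πσ²)^{3/2}. Flexible fitting of the structure into the map is
deliberately out of scope: this package produces the rigid-body model
and the target density that such a run consumes.

## Pore profiling

In each plane along the channel axis the package maximizes the clearance
f(c) = min_i (|c − x_i| − r_i) over sphere centers c confined to the
plane, reporting max(f, 0) as the pore radius (with a `buried` flag when
no positive clearance exists). Obstacles are protein atoms only by
default; solvent and ions are excluded.

The in-plane search is Monte-Carlo annealing: 1000 Gaussian proposals,
step σ starting at 0.5 Å and temperature at 0.1 Å (both in radius
units), each decaying ×0.9 every 100 proposals; default seed 2024. Two
constraints make the search physical: proposals beyond a bound
(default 15 Å) from the seed are rejected, and a walker may never cross
from positive into negative clearance — a buried walker climbs greedily
instead. Without these, a closed pore lets the optimizer tunnel through
the atom wall and diverge to unbounded "radius". The anneal is followed
by a deterministic Nelder–Mead polish of the best point (xatol 1e-6).
On systems of ≤ 200 atoms the result agrees with an exhaustive 0.05 Å
grid search over the same in-plane disk to ≪ 0.05 Å; the comparison is
only meaningful when both methods search the same bounded region, since
an unbounded clearance maximum is "open to bulk", not a pore radius.

Profiles walk outward from the slice nearest z = 0 (the tile pore
center), seeding each slice with the previous slice's optimized center
stepped along the axis — the guided walk that keeps the profile inside
a winding or narrow channel. Default step 0.5 Å and z-range ±25 Å cover
a hexamer slab plus a stacked trimer. Bottleneck ties break toward the
smallest |z|, then the more negative z. Trajectory envelopes pool per-z
min/mean/max over frames *and* over all tiles of a kind; for stacked
trimers the upper tile, lower tile, or both ("trimer") can be pooled,
since the appropriate pooling is a presentation choice. Per-tile
per-frame bottleneck series are retained for dynamics plots.

## Hydration statistics

Distances are atom-to-atom minima (any residue atom to any water atom):
the paper-style phrase "water within 5 Å of a residue" is read
inclusively, matching the usual contact-function idiom. A water counts
once per frame however many of its atoms are in range. Contact counting is
vectorized under the minimum image and verified exactly against an
O(N²) double loop.

The residence clock opens an event at the first frame a water's minimum
distance is ≤ 5 Å (entry cutoff) and closes it at the first frame the
distance exceeds 8 Å (exit cutoff), duration = close − start frames;
the 3 Å hysteresis band keeps frames at 5–8 Å inside an open event, so
boundary flicker does not fragment a visit. A water re-entering after an
exit starts a new event. Events still open at the last frame are flagged
censored with duration to that frame; pooled means include censored
events at observed length by default (inclusion biases short, exclusion
biases long — both are available and the flag is reported). Residence
requires stride 1 — skipping frames breaks the clock — while contact
averaging accepts a stride. Tables pool over the hexamer monomers of a
class, aligned by residue number (monomers of a tile kind share one
sequence), and report event and censored counts alongside the means.

## Structural metrics

Per-tile Cα RMSD uses the Kabsch algorithm (SVD with the
proper-rotation sign correction) to superpose each frame's tile onto a
single shared reference tile before the deviation is taken, so global
drift and inter-tile rearrangement do not register — only internal
deformation. Rank-deficient point sets (collinear) are a hard error.

SASA is Shrake–Rupley: each atom's sphere of radius vdW + probe is
sampled with quasi-uniform points (golden-angle spiral; default 960,
minimum 100), a point is exposed iff outside every other context atom's
expanded sphere, and residue area sums its atoms. Probe radius defaults
to 1.4 Å (water). The occluding context defaults to all protein atoms
of the system — waters and ions never occlude — and can be restricted
(e.g. tile-only, to mimic a dilute free tile). The 960-point quadrature
reproduces the isolated-sphere area 4π(r+probe)² within 2 %, and
burial is monotone: adding context atoms never increases any area.
Trajectory SASA averages over frames by default, with single-snapshot
use available by passing one frame.

## Footprinting (XFMS) analysis

Dose-response curves (fraction unmodified vs. exposure, on the 0, 100,
250, 500, 750, 1000, 2000 s schedule) are fitted by nonlinear least
squares to F(t) = exp(−kt) with k ≥ 0. No amplitude is fitted by
default: fraction unmodified is 1 at zero dose by construction (an
optional amplitude exists but is off). The initial k comes from
log-linear regression on strictly positive fractions; the standard
error from the fit covariance; an all-ones curve gives k = 0; and
non-convergence falls back to the log-linear estimate with
`converged=False`. Fitting is unweighted unless per-point SDs are
supplied. Noiseless recovery at the standard schedule is exact to 1e-9
relative; under 2 % multiplicative noise the median fitted k is within
5 % of truth over 500 replicates.

Rate ratios are k_solution / k_shell with first-order error propagation
(se = ratio·√((se₁/k₁)² + (se₂/k₂)²)); a zero denominator is flagged,
not filtered — including the site whose solution-state SE exceeds its
value, which is propagated and flagged rather than dropped. Reported
ratios round to two decimals; full precision is kept internally.
Simulation-side ratios divide the exposed-class metric by the
buried-class metric, averaging the metric over the residues of a
multi-residue label (e.g. "M16,23") before the ratio. Correlation is
OLS of simulated on experimental ratios with Pearson r; an exclusion
set (e.g. a known outlier site) is applied before fitting and recorded
in the result.

## Synthetic data: what it does and does not establish

The generators provide *ground truth*, not realism. Ring channels have
analytic pore radii (ring radius − vdW) but no side chains or
electrostatics; a ring only has a well-defined pore when adjacent atoms
overlap in-plane (r·sin(π/n) < vdW), and test fixtures respect that.
Pseudo-hexamer facets are rigid bead disks: 6 chains × 5 Cα-like beads,
tile radius 12 Å, spacing 26 Å (tiles nearly touching, as in a shell),
vdW 1.5 Å; they exercise tile bookkeeping, classification and the
flattening geometry, not protein flexibility. Scripted hydration
trajectories move waters discontinuously between a far shell (20 Å) and
a dwell shell (3 Å), never lingering in the 5–8 Å band at a transition,
so the recovered event list can be compared to the script *exactly*;
dwell durations are exponential (mean 30 ns — the null, memoryless
model; only means are compared so no heavier tail is assumed) over a
900-frame, 30-water window at 1 ns/frame. Dwells that would cross the
final frame are not scheduled, a slight length bias kept under ~2 % by
the 30× window. Dose-response curves are exact exponentials with
multiplicative Gaussian noise clamped to [0, 1]. All generators are
deterministic under a seed, and scripted event lists can be written as
JSON sidecars.

Consequently, passing tests establish algorithmic correctness —
bookkeeping, optimization accuracy, estimator consistency — on inputs
with known answers. They do not establish that a real shell and sheet
have similar pores: the headline comparisons on microsecond all-atom
trajectories of multi-million-atom systems (hexamer bottleneck
diameters near 7 Å, trimer envelopes tens of Å wide, residue-specific
long-lived waters) require MD data this package consumes but does not
produce.

## Problem sizes and reproducibility

Default test and acceptance workloads are sized for a single CPU:
20 oracle systems of ≤ 200 atoms with a 0.05 Å grid over a 4 Å disk,
~780 scripted residence events, 50 contact oracle frames of 100 waters,
500 dose-response replicates, and 7-tile facets of 210 beads. Every
stochastic path takes an explicit seed; `scripts/acceptance.py --seed`
reseeds all of them and rewrites the summary JSON from scratch.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* Pore axes are straight tile normals; no curved-axis detection, which
  matches straight tile channels but not winding transporter pores.
* The in-plane search bound means clearances larger than the bound are
  reported at the bound's scale — "open to bulk" rather than a pore.
* Tile assignment and the exposed/buried split rest on the declared
  tile spec; misdeclared chains propagate silently into every pooled
  table.
* No flexible fitting, solvation, force-field handling or permeation
  counting; trajectories are consumed, never produced.
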