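# Methods

## Geometry

The canal is described by 13 transverse sections (sagittal centroid `x, y`
in mm, cranial→caudal and ventral→dorsal, plus nested radii for syrinx, cord,
SAS and EDS), embedded as the canonical fixture.  All layers are circular and
concentric about the cord centroid — an idealization whose main cost is the
loss of ventral/dorsal stress resolution, which this package does not attempt.
Sections are interpolated with C²-continuous cubic splines in `x` (the table
parameter), arc length is accumulated along the interpolated path, and the
result is resampled on a uniform grid (default Δs = 1 mm; the caudal end is
rounded to the nearest grid multiple, at most Δs/2 of arc).  Signed sagittal
curvature κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2} is taken by centred differences
on the grid.  Nesting (syrinx < cord < SAS ≤ EDS) is validated at load and
re-validated after interpolation, since a cubic can overshoot between wildly
varying stations; a violation is an error naming the offending arc position.

Two terminal fill rules handle radii the table stops printing: a missing
terminal cord or EDS radius is reconstructed by holding the neighbouring
station's ratio to the (always present) SAS radius.  The caudal-most fixture
station lists neither syrinx nor cord radius; the cord column is filled this
way (the EDS hardly participates in the dynamics, and the filled cord radius
continues the caudal taper smoothly instead of rebounding).

The cranial end is extended by 15 mm of straight extrusion of the cranial-most
cross-section (κ = 0 there), so the inlet loading acts away from C2; the
extension is excluded from all stress binning, and positions are reported in
mm from C2.  A syrinx is flagged only between the first and last station with
a syrinx radius, and its radius ramps to zero over one grid step at an
interior terminus to avoid a hard impedance jump.

One printed inconsistency is left unresolved deliberately: the 1 mm dural
thickness exceeds the SAS-to-EDS radial gap at several stations.  The shell
mid-surface is kept at the SAS radius and the overlap is ignored.

## Cross-section elasticity

Per station, the mechanical closure is the linear response of the transverse
section, assembled as a mixed map from (syrinx pressure, SAS pressure, cord
axial strain) to (syrinx area change, SAS area change, cord axial force):

* **Cord annulus** — classical Lamé thick-wall solution in generalized plane
  strain between the syrinx radius and the cord surface.  This retains the
  Poisson coupling (radial pressure ↔ axial force) that lets the fluids drive
  cord motion and vice versa; the axial stiffness reduces exactly to `E·A`.
  With no syrinx the inner entries vanish and the block is a solid cylinder's
  surface compliance.  A wall thinner than 5% of the cord radius triggers a
  divergence warning.
* **Dura + fat** — a thin hoop shell of thickness h = 1 mm at the SAS radius
  (area compliance 2πR³(1−ν²)/(Eh)) supported by the confined plane-strain
  fat annulus whose outer edge is fixed at the canal wall.  Shell and fat
  resist the same radial displacement, so their stiffnesses add (the fat
  contributes ≈2.5% at representative geometry — the dural sac dominates the
  canal compliance).
* **Fluid compressibility** — K = 2.2 GPa adds a volumetric compliance term
  per compartment; measured contribution < 10⁻⁵ of the wall compliance, which
  is the quantitative license for treating the fluids as incompressible in
  the wave equations.

Maxwell reciprocity makes the mixed map symmetric by construction (verified
to 10⁻¹⁰ relative in the tests).  Eliminating the pressures yields, in the
conserved variables z = (a_syrinx, a_SAS, a_cord) with a_cord = −A_c ∂u/∂s,
a symmetric positive-definite stiffness `p = K(s) z` — the form the solver
consumes, and the guarantee that an energy functional exists.

## Wave solver

All three compartments obey ∂a/∂t + ∂(Av)/∂s = 0 and ρ ∂v/∂t = −∂p/∂s on the
arc-length coordinate; curvature never enters the propagation equations (its
role is confined to the stress surrogate, and the straightened-control tests
confirm pulse speeds change < 3% when the canal is straightened).  For the
cord row this is the axial elastic force balance with p_cord = −N/A_c; the
variable-area correction term p ∂A/∂s is dropped, a consistent simplification
for the gently tapering canal.

Discretization: areas/pressures at stations, velocities at half-stations,
interface areas arithmetically averaged — a staggered conservative layout
whose semi-discrete energy is exactly conserved for closed boundaries (no
artificial dissipation, no odd–even decoupling).  Time marching is implicit
midpoint (unconditionally stable; conserves the discrete energy to solver
round-off — measured drift 3×10⁻¹³ over a pulse run), with an explicit
kick-drift leapfrog behind a flag that enforces the CFL bound of the fastest
mode (~13 m/s at Δs = 1 mm would force sub-70-µs steps, hence the implicit
default: dt = 0.1 ms cardiac, 0.02 ms pulse).

Boundary conditions: the caudal cord and SAS are fixed/closed.  Cranially,
the normal scenario prescribes the volumetric inflow into the SAS with the
cord face fixed; the blocked-CSF (Chiari) scenarios move the whole cranial
face — cord plus trapped fluid columns — as a piston whose velocity
accommodates the same inflow, the flux partitioned by compartment area.  The
piston partition is a modelling choice: the mechanical pathway by which the
input loads the cord when CSF is blocked is not observable in a 1-D model.
Syrinx termini are closed (no axial flow across them); the syrinx couples to
the canal only through the compliance matrix and shared wall motion.

Mode analysis substitutes plane waves into the uniform-section equations:
`c² z = diag(A/ρ) K z`, a symmetric positive-definite eigenproblem.  Three
propagating modes exist where a syrinx is present, two otherwise; mode shapes
are the relative signed axial velocities (syrinx, cord, SAS).

### Wavefront tracking (independent oracle)

Time-of-flight speeds are measured from the transient probe (half-sine inflow
pulse, 0.01 s, 0.35 cm³/s): at every half-station the local velocity vector
is decomposed on that station's eigen-shapes; a branch's arrival at a station
is the time of its modal-amplitude maximum (stations whose packet has not
peaked inside the window, or whose amplitude is below 30% of the branch
maximum, are excluded); the branch speed is a Theil–Sen robust fit of
distance versus arrival time.  The probe window is 35 ms — the shortest for
which the slowest (~1.5 m/s) packet travels several packet widths while only
the fastest branch has reflected off the caudal end.  Eigen and time-of-flight
speeds agree within 5% per branch on a uniform waveguide; the arrival-time
measurement never uses the eigenvalues, only the sign signatures.

## Stress surrogate

Sliding the cord by `u(s,t)` along a channel of curvature κ forces its
sections to rotate by ψ = κ·u to first order (the material tangent must
realign with the channel one sliding length away).  The surrogate partitions
ψ quasi-statically into bending ψ_b and shear γ = ψ − ψ_b by minimizing

    ∫ [ EI (ψ_b′)² + GA (ψ − ψ_b)² + k_rot ψ_b² ] ds

with free-rotation (natural) ends, solved once per saved time step by a
banded SPD factorization shared across steps.  `I` and `A` carry the annulus
correction where a syrinx exists.  The restraint k_rot is the series
combination of the canal's radial stiffness acting over the snug perimeter
lever (k_radial·r_cord³, with k_radial = 2πr_SAS/c_dura from the compliance
assembly) and the cord's own shear rigidity GA — neither load path can
transmit more restraint than it possesses.  This term deserves honesty: an
inviscid fluid annulus cannot restrain section rotation at all, and a pure
slender-beam partition (no restraint) yields shear ~(EI/GA)ψ″ — an order of
magnitude below what three-dimensional continuum solves of the same problem
report at the curvature peaks.  k_rot is the 1-D stand-in for the 3-D snug-
contact load transfer; its series form makes the rigid-canal limit an
approximately even bending/shear split rather than full conformation, and the
resulting fields sit below, and within a small factor of, the two closed-form
envelopes σ ≈ E r u|dκ/ds| (fully conforming) and τ ≈ G κ u (fully
non-rotating) that ship as the in-repo oracle.  Quasi-static evaluation is
valid because the cord displacement evolves at cardiac frequency (2.5 Hz),
far below the canal's mode transit rates.

Perimeter stress magnitudes (the normal components are compressive;
worst-case, magnitude-additive): radial = |p_SAS|; axial = |p_SAS| +
E·r_cord·|Δκ|; shear = G·|γ| (mid-section Timoshenko shear, no 4/3 peak
factor — one magnitude per axial location).  Stresses are evaluated over the
final (settled) cardiac cycle, reduced per station to a temporal maximum and
then to per-1-mm-bin maxima measured from C2.

## Scenario pipeline and reported scalars

Cardiac runs simulate 4 cycles of Q0·sin(2πt/T) (T = 0.4 s) and report the
last.  The SAS pressure amplitude is zero-to-peak (max |p| at the axial
midpoint of the non-extended domain; the harmonic half peak-to-peak is also
recorded, since with a sine inflow from rest the pressure oscillates in
[0, p_max]).  The cranio-caudal difference is the final-cycle maximum of the
end-to-end |Δp_SAS| (reported in Pa and mmHg at 133.322 Pa/mmHg).  Peak layer
speeds are taken at C2; cord displacement is reported as the largest
station-wise peak-to-peak and as the largest caudally directed value.
Everything in the pipeline is deterministic: identical configuration yields
bit-identical states and reports.

## Synthetic geometry

Controls and robustness variants are generated from any sample table:
curvature nulling (y ≡ 0), curvature scaling (y → f·y), syrinx
removal/rescaling/re-windowing, and smooth random perturbation (Gaussian
process with squared-exponential correlation, PCG64 generator seeded
explicitly, so output is platform-independently reproducible; nesting is
re-validated with up to five amplitude-halving retries).  The perturbation
emulates plausible reconstruction variability of the unpublished per-slice
data; it is statistical, not morphometric — it does not model breed anatomy,
and passing perturbation tests shows numerical robustness, not anatomical
generality.  Likewise the generator cannot manufacture what the reduced model
lacks: non-concentric sections, distinct white/grey matter, tethering,
viscous CSF, or a cranial compartment.

## Numerical choices and problem sizes

Default experiment sizes, chosen as the coarsest discretization whose
headline quantities are grid-converged (mode speeds and pressure amplitude
change < 2% under Δs and dt halving): Δs = 1 mm (≈364 stations with the
extension), dt = 0.1 ms cardiac / 0.02 ms pulse, 4 cardiac cycles, 35 ms
pulse window, save strides 10/5.  A full scenario suite plus the pulse
experiment completes in well under a minute on one CPU.  Degenerate inputs
fail loudly: non-monotone stations, nesting violations (with the offending
position), vanishing cord wall (warning), zero SAS gap (singular foundation),
CFL violation (with a suggested dt), non-finite states (with the first bad
index), unresolved wavefronts (with a remedy suggestion).

## Known limitations

* Stress magnitudes inherit the factor-level uncertainty of the surrogate
  partition; they are comparative (across scenarios and positions), not
  absolute predictions.  The sensitivity of the underlying material constants
  themselves is large, so even the reference continuum values carry meaning
  only relative to their material table.
* The blocked-CSF piston partition fixes how much of the inflow drives the
  cord; reported cord speeds/displacements scale directly with it.
* No circumferential stress resolution (ventral vs dorsal), no viscous
  dissipation, no nonlinear tube laws, no brain/cranium compartment.
* The normal-scenario baseline stress equals the SAS pressure; the model does
  not reproduce a baseline axial-stress elevation between scenarios beyond
  the bending contribution, which a 3-D continuum exhibits.
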