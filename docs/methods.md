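# Methods

## The model

`morphodyn` simulates an idealized 2D crawling cell as a phase field
coupled to a three-variable reaction–diffusion signaling system, and maps
the resulting morphologies into a data-driven shape space.

### Interface mechanics

The cell interior is the region where the phase field φ(r, t) ≈ 1; outside
φ ≈ 0 and the membrane is the diffuse interface of width ε between them.
φ obeys

    τ ∂φ/∂t = η (Δφ − G′(φ)/ε²) − M (∫φ dr − A₀) |∇φ| + F_prot |∇φ|

with the double-well bulk energy G(φ) = 18 φ²(1−φ)², an area-restoring
force of strength M around the target area A₀, and an outward active force
F_prot = a_W·W applied on the interface. Bending energy is neglected.
Defaults (all in μm/pN/s units): τ = 0.83 pN·s/μm², η = 1 pN, ε = 1 μm,
M = 0.5 pN/μm³, A₀ = 78.83 μm² (a 5 μm-radius disk), a_W ∈ [0.8, 5.6] pN/μm
per unit W with default 2.4.

### Signaling

Three concentration fields live on the cell:

* U — substrate of the excitable network (rest state U = s/γ),
* V — the protrusion signal, produced autocatalytically from U at a rate
  gated by the polarity field W, decaying at rate μ,
* W — a bistable polarity marker sharing a conserved total W_tot with a
  fast-diffusing, well-mixed pool W* (so W* = (W_tot − ∫φW dr)/∫φ dr).

The equations advance the products φU, φV, φW:

    τ′ ∂(φU)/∂t = φ(−R_k + R_p + s − γU) + D_U ∇·(φ∇U) − φN
                  − χ_U U |∇φ|² / ∫|∇φ|² dr
    τ′ ∂(φV)/∂t = φ(+R_k − R_p − μV) + D_V ∇·(φ∇V) + φN
    τ′ ∂(φW)/∂t = φ(k_W1(−ρW³ + ρW²W* − W) + ζV) + D_W ∇·(φ∇W)

with the saturating conversion rates R_k = αUVW/(K_k + ⟨φVW⟩) and
R_p = βUV/(K_p + ⟨φU⟩), global means ⟨φX⟩ = ∫φX dr/∫φ dr, an
Ornstein–Uhlenbeck edge-noise field N, and a boundary flux that drains U at
the interface with coefficient χ_U. The single factor τ′ = 10 both scales
the signaling clock and converts simulation time to seconds (reported
timestamps are τ′·t).

The W reaction is the wave-pinning mechanism of cell polarity: when
W*² > 4/ρ the cubic has two stable states (0 and a high branch) and a front
between them stalls once the pool is depleted to the Maxwell level
(≈ 0.90 for ρ = 5.5556), leaving a stable high-W leading edge and a low-W
rear. V pulses, amplified from edge noise wherever W is high, locally
reinforce or split that front (ζ coupling), which is what produces
pseudopod-like morphodynamics.

### Parameters that matter

| parameter | role | default | notes |
|---|---|---|---|
| W_tot | total protrusive capacity | 80 | < ~67: no polarity (circular); ~80: single pinned front (migrating); > ~105: W engulfs the cell (circular) |
| ρ | autocatalysis of W | 5.5556 | sets the bistability window W*² > 4/ρ and the front plateau |
| k_W1 | depth of the bistable well | 90 | large values make polarity robust to V perturbations |
| a_W | protrusive force per unit W | 2.4 | low: round cells; high: multiple pseudopods |
| μ, γ | V and U decay | 0.5, 0.1 | pulse duration (~τ′/μ s) and refractory recovery (~τ′/γ s) |
| χ_U | edge drain of U | 50 | global U limitation; affects front splitting |
| D_W | polarity transport | 3 μm²/τ′ | low: fronts split; high: one coherent front |
| θ, σ | noise correlation time / amplitude | 1.4, 0.075 | θ is in simulation time units (14 s real) |

The constants of the U–V loop (α = 2, β = 0.5, K_k = 0.3, K_p = 1,
s = 0.1, ζ = 5, D_U = 1, D_V = 0.5) are not constrained by published
values; they were fixed once so that (i) the rest state (U = s/γ, V = 0) is
stable where W = 0, (ii) V amplifies noise only over the W front, with
transients limited by substrate depletion (supply s·A₀ per time unit is
the bottleneck), and (iii) the reference mechanical/kinetic set above
yields a persistently migrating, elongated cell. All quantitative claims
in the test suite are designed to be insensitive to their exact values
(e.g. the rest state is asserted symbolically as s/γ).

### Initial condition

The default start is a tanh-profile disk of area A₀ with U at rest, V = 0,
and W seeded at its high-branch root over a boundary cap (the "crescent"),
whose direction is drawn from the run seed. This is a deliberate design
choice: with the default reaction strengths the all-pool state (W ≡ 0,
everything in W*) sits behind a nucleation barrier of the bistable reaction
that the prescribed edge noise cannot cross — attempts to bootstrap
polarity purely from noise either do nothing or end in a stable interior
V/W blob that destroys the conserved-pool budget. The crescent seed is
*not* a dial: its survival is decided by the wave-pinning condition, so the
W_tot phenomenology (circular at 50, polarized at 80, engulfed at 110)
emerges from the dynamics, not the seed. The unpolarized start remains
available (`polarity="none"`).

### Discretization and numerics

Explicit Euler on a periodic square lattice (default 128×128, dx = 0.3 μm,
so a 5 μm-radius cell spans ~33 cells): 5-point Laplacian, central
differences for |∇φ|, and a conservative face-averaged stencil for
∇·(φ∇X) whose discrete flux sums to zero. `SimulationConfig.validate`
enforces dt below the minimum of the signaling-diffusion bound
dx²τ′/(4D_max), the interface bound τdx²/(4η), and the stiff double-well
bound 2τε²/(36η); the default dt = 0.005 sits at ~27% of the bound.
Concentrations are recovered from the products by division where
φ > 10⁻³ and set to zero outside; W mass "deleted" at a retracting rear
returns to the pool by construction of W*, and the conservation identity
∫φW dr + W*∫φ dr = W_tot is exact (machine precision) after every step
because W* is recomputed from it. φ excursions outside [−0.05, 1.05] or
non-finite values abort with an error naming the violated bound rather
than being clamped. Fragmentation (multiple φ ≥ 0.5 components above
0.5 μm², merged across the periodic boundary before counting) is logged
per frame; centroids use circular means and are unwrapped across the box.

## Shape space

Masks are normalized by (i) measuring the migration direction from the
centroid displacement over a frame interval (default 5 frames; frames with
< 0.25 px displacement are skipped), (ii) rotating so the direction points
down the image, and (iii) rescaling the foreground to the area of a 25
px-diameter circle centred in a 64×64 frame. Scaling precedes rotation;
the mask stays float through all resampling and is binarized once at the
end at the threshold whose area is closest to target, which keeps the area
invariant to ±1.5% even for axis-aligned shapes where a fixed 0.5
threshold is biased.

The classifier is a small CNN written directly on NumPy (im2col valid
convolutions, 3×3 max pooling, Adam): 64×64×1 → conv(16,3×3)+relu → pool
3×3 → conv(32,3×3)+relu → pool 3×3 → dense(256)+relu → dense(32)+tanh →
dense(n_classes) → softmax. The three pre-softmax activations F =
(F₁,F₂,F₃) are the shape features; the 256-unit layer is the
higher-dimensional alternative. Optimizer settings (lr 10⁻⁴, batch 64)
and epochs are configurable; the reference protocol trains 2000 epochs,
while the synthetic three-class task (disks / laterally / vertically
elongated ellipses, 100 masks per class) converges to ≥ 95% validation
accuracy within 30. Per-timeseries time-averaged F vectors feed a PCA
(sklearn, full SVD) whose explained-variance fractions are the reported
latencies; similarity to a reference class is the Euclidean distance of a
candidate's burn-in-trimmed (default 10%) mean F to the class mean, ranked
ascending with ties broken by candidate id.

Hand-crafted features on normalized masks: h₁ and h₂ are the vertical and
horizontal bounding-box extents over the equivalent-circle diameter, h₃ is
circularity 4πA/P² with the perimeter measured on a contour smoothed over
~1 px of arc (the raw marching-squares polyline overestimates pixelated
perimeters by 5–8%, which alone would push a disk's circularity to ~0.87).

## Morphodynamics

Boundary contours are traced on the 0.5 level set, smoothed along arclength
with a periodic Gaussian (default two boundary-points; an absolute
pixel-length option exists for metric quantities), resampled to equal
arclength and oriented counter-clockwise. Curvature comes from central
differences on the uniform parameterization; on anti-aliased fields every
point of a circle is recovered to within 5%, and the closed integral ∮κ ds
stays within 2% of 2π on simulated cell masks. Binary pixel art is harsher:
a pixelated disk has genuine flat runs of length ~√(2R) px at the axis
poles, so pointwise guarantees are only made for sub-pixel (float field)
inputs.

Frames are registered by the cyclic index shift minimizing the summed
squared point displacement (computed by FFT cross-correlation). This
absorbs translation and contour-start jumps completely, but the
correspondence of a closed curve has a gauge freedom: a rigid rotation is
largely (empirically ~3/4) absorbed into the registration rather than
appearing as band drift. Protrusion speed is the outward-normal component
of the registered displacement divided by the frame interval.

MSD analysis uses the time-averaged estimator up to 25% of the track
duration, fits a fixed-slope-2 line over the shortest 20% of lags and a
fixed-slope-1 line over lags beyond 50% (free intercepts), and reports the
intersection as the persistence time τ₀ with X₀ = √MSD(τ₀) in units of the
mean motion-aligned cell length. A crossover is reported only when the
free-slope fits confirm the two windows sit in different regimes (short
slope ≥ 1.5, long slope ≤ 1.5) and the intersection falls inside the lag
range; otherwise τ₀ is unresolved. The estimator is validated against a
run-and-tumble sampler with closed-form MSD: the oracle value is the same
two-line construction applied to the exact curve, and the estimator's mean
over 20 tracks recovers it within 20% for persistence times 50–200 s.
(Note the construction's τ₀ is systematically larger than the sampler's
tumble time — the asymptote intersection of the exact curve is at 2τ_p —
so τ₀ values are comparable only between analyses using the same windows.)

Pseudopod events are detected automatically (the reference analysis was
manual, so this is a documented stand-in): connected regions of the cyclic
boundary×time kymograph above the 80th percentile of positive speeds,
lasting ≥ 3 frames and spanning ≥ 5% of the perimeter. A region is *de
novo* if no activity existed within 3 frames before onset near (±3
boundary points) its onset interval; otherwise it is a *Y-split* if the
parent region stays active after onset and a *one-way-split* if not. The
extension angle is measured between the event boundary-point displacement
10 s after onset and the concurrent centroid displacement.

## Synthetic data

The geometry library provides the probe shapes (circle, isosceles and
right triangles, rectangle, rhombus, pentagon, five-point star with inner
radius ratio 0.5; vertical flips of the four asymmetric ones; aspect
variants 1:1 / 1:2 / 2:1), ellipse aspect/rotation series, seeded
multi-edge asymmetric stars, and the three-class training fixture
(disks / ~2.2:1 lateral / ~1:2.2 vertical ellipses with seeded aspect and
rotation jitter). These emulate the *composition* of real mask data —
compact vs laterally vs longitudinally elongated, smooth vs edged — but
not its texture: real masks have irregular boundaries, segmentation noise
and temporal correlation. Passing tests therefore demonstrate that the
pipeline's geometry, normalization and feature machinery behave correctly
and that the feature space orders elongation sensibly; they do not certify
classifier accuracy on microscopy data.

## Problem sizes used in the tests

Simulation tests run 60–600 s of real time on 64² (dx 0.45 μm) or the
reference 128² grid; the acceptance script runs one 600 s reference
simulation. Classifier tests train 30 epochs on 300 masks. MSD validation
uses 20 tracks of 1200 frames per persistence time. These sizes were
chosen so the full suite exercises every claim at desk scale.

## Known limitations

* The excitable-layer constants are package defaults, not published
  values; quantitative V amplitudes and pulse rates are therefore
  illustrative.
* Migration speed at the reference set is ~0.02 μm/s, slower than typical
  amoeboid cells; the MSD exponent and area control are insensitive to
  this, but absolute τ₀/X₀ values are not comparable to microscopy.
* Explicit Euler only; stiff parameter corners (k_W1 ≫ 100 with coarse dx)
  under-resolve the W domain wall, where lattice pinning adds an artificial
  stall (conservative for wave-pinning tests).
* Contour registration cannot distinguish rigid rotation from tangential
  boundary flow (gauge freedom); kymograph band drift under-reports
  rotation.
* Pseudopod classification follows a threshold rule, not expert judgment;
  counts are not comparable to manually scored data.
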