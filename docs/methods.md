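# Methods

## Orientation fields

All directions in this package are axial: θ and θ + 180° name the same
axis, so every angle is reduced to [0°, 180°) and all averaging,
interpolation and comparison is done on the doubled angle
(cos 2θ, sin 2θ). Interpolating 179° and 1° therefore gives 0°, not the
spurious 90° a naive mean would produce. Deviations between two axes live
in [0°, 90°]; the alignment score is |cos φ| ∈ [0, 1].

Coordinates follow the image convention: origin at the top-left, x
rightward, y downward, micrometres; angles measured from the +x axis
toward +y.

Four analytic patterns are provided. The azimuthal and radial patterns are
the two topological-charge +1 axial fields (θ = α ± 90° with α the polar
angle about the pattern center); the hyperbolic pattern is the charge −1
field θ = axis_angle − α, whose integral curves are hyperbola-like with a
saddle at the center. The charge −1 convention for the hyperbolic
converter is a modeling choice: commercial θ-cell converters are specified
only up to this convention, and the choice reproduces the cross-shaped
deformation such converters produce. Piecewise-constant fields model the
sequential projection of complementary masks, each with one linear
polarization state; overlapping masks are rejected because a pillar cannot
be assigned two deformation directions.

The illumination mask distinguishes *deformed* from *undeformed* regions.
θ itself is defined on the whole grid (the pattern direction is a design
quantity), and the quantification uses it as the reference direction on
both sides of the boundary — exactly how a deformed-vs-undeformed
comparison is scored — while `sample_theta` reports the undeformed
sentinel outside the mask.

## Phase retrieval

The SLM phase mask for a target intensity is computed with the
Gerchberg–Saxton algorithm between the SLM plane (unit amplitude, free
phase) and the image plane (amplitude √target, free phase), with a single
unitary FFT as the forward model and the image origin at the raster
center. The initial phase is uniform random from a caller-supplied seed;
50 iterations is the default (the image-plane RMS amplitude error is
non-increasing, so more iterations never hurt). Bench optics — zeroth-order
blocking, relay lenses, aberrations — are outside the model: the contract
is the phase computation, not the physical setup. Laser power (default
20 mW) and exposure time ride along as metadata and become the dose seen
by the substrate.

## Substrate deformation model

No constitutive law for directional photofluidization of micropillars is
available, so the package adopts the simplest model reproducing the two
documented regimes (undeformed at zero dose, near-merge at high dose):

    e(D) = e_max (1 − exp(−D / D0)),   e_max = pitch/side − 1

with D the accumulated dose (local intensity × exposure, mW·s/µm²). The
cross-section is a rectangle with sides side·(1+e) along the local
polarization axis and side/(1+e) across it, conserving the cross-section
area exactly; height stays constant (the reported deformation is lateral).
`e_max` caps the long axis at the lattice pitch, the regime where
contiguous pillars are close to merging. The default
D0 = 0.0621 mW·s/µm² is calibrated so that 20 mW spread over a
100 µm × 100 µm projection region for 50 s drives e to 0.8·e_max; it is a
config default, not a measured material constant. Elongation at fixed dose
is assumed independent of the angle between polarization and lattice axes.

Height maps render pillars as rotated rectangles with area-coverage
anti-aliasing (4× subsampling); because the long half-axis never exceeds
pitch/2, every pillar stays inside its own lattice cell and rendering is
fully vectorized. Profilometry emulation: plateau height as the histogram
mode of nonzero pixels (0.01 µm bins); lattice pitch from the first
off-origin peak of the marginal autocorrelation, searched only below half
the profile length (larger lags have too few overlapping samples); pillar
side as a per-scan-line full width at half maximum measured over an
integer number of lattice periods, which stays well defined in the
near-merge regime where footprints abut.

## Synthetic cells

**Orientation noise.** Deviations ε of cell axes from the local pattern
direction follow the axial von Mises family: 2ε ~ vonMises(0, κ). The
source experiments report only a median (22.4° on deformed substrates), so
the family is open; von Mises is the maximum-entropy circular choice.
`calibrate_kappa` inverts κ ↦ median|ε| (median = ppf(0.75)/2 of the
doubled angle, by symmetry) with bracketing bisection to 10⁻³ degrees;
κ = 0 is the isotropic limit with median 45°, so targets must lie in
(0°, 45°). For 22.4° the calibrated value is κ* ≈ 1.063, cross-checked in
the tests against direct quadrature of the von Mises density.

**Single cells.** Centroids are uniform (optionally with a minimum
separation by dart throwing — the rendered-image analogue of subconfluent
seeding). Aspect ratios are lognormal (median 2.0, σ = 0.25) with
identical parameters on deformed and undeformed regions: deformation
orients cells, it does not elongate them, matching the observation that
polarization distributions differ only minimally between the two regions.
Mean major axis 40 µm; body sizes are unreported in the source
experiments and are config defaults for a mesenchymal line.

**Migration.** Headings perform rotational diffusion with persistence time
1 h; on deformed regions the (noisy) deviation from the nearer of
{θ, θ+180°} is multiplied by exp(−bias·Δt) each step, so bias → ∞ locks
displacements exactly onto the pattern axis and bias = 0 is a pure
persistent walk. Speed (0.5 µm/min) and persistence are placeholders —
the source experiments do not quantify them. Positions reflect at the
field boundary; the boundary flips headings, so parameter-recovery
analyses should use tracks away from the edge.

**Colonies.** Cell cycles are Erlang (gamma with integer shape; default
shape 8, mean 26 h) — shape 1 would be memoryless, shape 8 gives the
moderate regularity of cultured epithelia. Founder cells start with fresh
cycle clocks at t = 0, so their first division closes a complete
birth-to-division interval observable by tracking. At each mitosis the
parent is replaced by two daughters at ±r_cell (8 µm) along the division
axis — drawn as θ_local + ε with concentration `div_bias` on deformed
regions, uniform otherwise — followed by a few sweeps of pairwise disk
repulsion to relax overlaps; cells are otherwise stationary
(contact-inhibited bulk). The colony outline is the union of cell disks
closed by a morphological buffer of one cell radius.

**Rendering.** Nuclei are Gaussian spots (σ = 3 µm), cytoplasm filled
rotated ellipses (cells) or disk unions (colonies), pillars the substrate
coverage map; noise is Poisson (200 photons at unit intensity) plus
Gaussian (σ = 0.01). Everything is reproducible from its seed. The images
emulate contrast and shot noise, not uneven illumination, debris,
out-of-focus light or segmentation-resistant morphologies — passing tests
show the pipeline's correctness on controlled inputs, not robustness to
every real-microscopy artifact.

## Quantification

Segmentation is global Otsu plus connected components, with nucleus-seeded
watershed when touching cells must be split, and a minimum-area filter.
The stage is deliberately pluggable (external label masks can be fed in);
the synthetic images have controlled contrast, and the pipeline contract
is downstream of segmentation. Orientation ψ and axis lengths come from
second central moments (ellipse of inertia); ψ is undefined below aspect
ratio 1.05, where the principal axis is numerically degenerate, and such
records are skipped. Field sampling points are fixed for determinism: cell
centroid for body alignment, window-start centroid for displacement
windows, the parent's last centroid for divisions; cells straddling the
region boundary are assigned by centroid membership.

Tracking is greedy minimum-distance frame-to-frame linking (candidate
pairs sorted by distance, accepted while both endpoints are free and
within a gate, default 12 µm at 15-min frames), matching the
minimum-distance description of the original pipeline; no gap closing.
The globally optimal assignment is kept in the tests as an oracle — greedy
agrees with it whenever greedy is optimal, and disagreements are counted,
not hidden. Displacement alignment uses non-overlapping 1-h windows with
a 2 µm minimum net displacement (the original minimum-step filter, if
any, is unstated; 2 µm is configurable).

Mitoses are inferred from track topology: a track born next to (within
the gate of) a track present in the previous frame marks a division, the
neighbor continuing as one daughter. Because a finite movie preferentially
observes short cycles, the mean division interval is estimated with the
Kaplan–Meier restricted mean, treating every track segment that had not
divided again by its last frame as right-censored; the naive mean of
completed intervals is biased low by several hours at 72 h.

The two-sample Kolmogorov–Smirnov test computes D as the exact supremum
ECDF distance and the p-value from the asymptotic Kolmogorov distribution
at n_eff = n_a·n_b/(n_a+n_b); no multiple-testing correction is applied
(comparisons are single pairwise tests). Colony morphometrics take the
largest foreground component per frame: area, outline contour, and
orientation/elongation from outline moments.

## Problem sizes and numerical choices

The end-to-end orientation recovery uses 1,000 cells over a
3.6 × 3.6 mm field (minimum separation 60 µm, ≈ 77 cells/mm² — a
subconfluent density at which most cells render disjoint), tiled into
600 µm windows at 0.65 µm/px, with a 25 µm border margin per tile (border-
clipped cells have unreliable moments; ≈ 84% of cells survive to
measurement). The colony recovery uses 5 founders for 72 h at 15-min
frames in a 420 × 420 µm field, giving ≈ 30 cells and ≈ 20–30 tracked
mitoses. Typical runtimes: ≈ 15 s and ≈ 35 s respectively on one CPU.

Degenerate inputs are rejected loudly (all-zero retrieval targets, empty
samples, absent labels, overlapping masks, side ≥ pitch) or return empty
results where that is the honest answer (blank images segment to zero
objects). Ties in the greedy tracker are broken by the sort order of
distances; equal-distance candidates are effectively ordered by index.

## Known limitations

The deformation law is phenomenological (one free constant, no azobenzene
photochemistry, no erasure dynamics, no pillar merging topology beyond the
long-axis cap). The forward optical model is a single Fourier transform —
no vectorial diffraction, aberrations or zeroth-order leakage. The cell
models contain no mechanistic cytoskeleton, junction or contact-inhibition
dynamics beyond overlap relaxation, and no collective motion. Migration
speed/persistence defaults are not fitted to data. Tracking assumes a
closed world (no cells entering or leaving the frame) and does not close
gaps across missed detections.
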