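# Methods

## Measurement model

A transmission polarimeter prepares light in one of six Stokes states
(linear 0/45/90/−45°, right and left circular) with a polarization state
generator (rotatable polarizer + insertable quarter-wave plate) and, after
the sample, projects it onto one of eight analyzer configurations with a
polarization state analyzer (quarter-wave plate + polarizer).  Writing the
generated Stokes vectors as the columns of `W` (4×6) and the analyzer
projection vectors as the rows of `A` (8×4), the per-pixel camera signal
is the 8×6 matrix

    B = A M W

with `M` the sample's 4×4 Mueller matrix.  The 48-frame schedule is
over-determined (16 frames would suffice), which is what gives the
pseudo-inverse reconstruction `M = A⁺ B W⁺` its noise-averaging benefit.

The two "redundant" analyzer configurations that complete the 6+2
structure are not uniquely determined by physics; this package uses 0°
and 45° re-analyzed with the quarter-wave plate inserted (configurable),
which keeps `A` rank 4 and well conditioned.  Frames are ordered
generator-major (all 8 analyzer configurations for state 0, then state 1,
…); the ordering is recorded in stack metadata and covered by a schedule
fingerprint.

### Conventions

- Angles in degrees in all public interfaces, counter-clockwise positive
  looking into the beam; right-circular is `S = (1,0,0,1)`.
- The linear retarder follows the Lu–Chipman sign convention: a
  quarter-wave plate at 0° maps `(1,0,0,1)` to `(1,0,1,0)`.
- Matrix elements are written 1-based (`m11` top-left) in documentation,
  matching the optics literature.
- Circular retardance ψ is reported as the optical rotation of the
  polarization ellipse; the retarder block carries the double angle, so
  the extraction uses `ψ = ½·arctan2(mR32 − mR23, mR22 + mR33)`.  With
  this choice `make_rotator(ψ)` round-trips to ψ through the
  decomposition.

## Instrument imperfections and noise

Systematic errors are modeled per arm: one polarizer mounting offset, one
wave-plate mounting offset, one wave-plate retardance error and one
polarizer leakage per arm, because a single physical element is rotated
to produce all states of that arm.  Offsets are bounded (±10° angles,
±20° retardance) — beyond that the design degrades toward rank
deficiency, which `build_instrument` rejects.

The camera model is Poisson shot noise on `gain × intensity` counts,
additive Gaussian read noise, optional averaging of `k` independent
exposures (the bench's rolling averaging), then clipping and quantization.
The packaged default `NOISE_8BIT` uses gain 230 (near full well of an
8-bit camera for a unit-transmittance sample), read σ = 1.5 counts and
k = 4.  Averaging matters for weakly retarding samples: δ enters the
matrix through elements of size sin δ, and the arccos extraction
rectifies noise into a positive bias (≈ +0.5° at δ = 3.3° for k = 1,
< 0.1° at k = 4 at these settings).

## Eigenvalue calibration

With `B0 = A W` (air) and `Bᵢ = A Mᵢ W` for reference i, the 6×6
similarity matrix `Cᵢ = B0⁺ Bᵢ = W⁺ Mᵢ W` satisfies `W Cᵢ = Mᵢ W`
exactly, so its four nonzero eigenvalues equal those of `Mᵢ` — basis
invariant, hence independent of how precisely the reference was mounted.
The classical square-matrix ECM is generalized to the 8×6 geometry purely
through pseudo-inverses; `B0⁺` is truncated to rank 4 because `A W` has
exactly rank 4 in physics and noise-induced spurious singular values
would otherwise be inverted and dominate the spectrum.

Reference transmittances and retardance are read off the eigenvalue
spectra (diattenuator: `{q, r, √(qr), √(qr)}`; retarder: `{1, 1, e^{±iδ}}`),
with kind checks restricted to eigenvalues comparable to the dominant one:
the near-zero eigenvalues of a strong polarizer are degenerate and
scatter as noise^⅓.  `W` is then the null vector of the stacked operator
`X → Mᵢ X − X Cᵢ` (24n × 24 SVD), with scale fixed by `W11 = 1` and free
reference axis angles refined by Nelder–Mead on the smallest singular
value when the nominal angles do not already annihilate the kernel; the
first axis-bearing reference keeps its nominal angle because a common
rotation of all references and `W` is a gauge freedom.  A second null
direction within tolerance raises an ambiguity error (e.g. a single
polarizer reference).  Finally `A = B0 W⁺` with a forward-consistency
gate (default 10% relative, sized to pass honest 8-bit camera noise and
catch mismatched files).  All five bench references (air, polarizer at
0/45/90°, quarter-wave plate at 0/45°) enter one simultaneous kernel
system.  Noise-free calibration recovers a perturbed instrument to
~1e-15; the reported residual (smallest-to-next singular-value ratio)
grows monotonically with measurement noise and serves as a quality
metric.  The bench's null-intensity pre-alignment is represented as a
metadata flag only — it is a physical alignment step, not a computation.

## Lu–Chipman decomposition and MMT

`mmpd_decompose` factors `M = M_Δ M_R M_D` in the standard order:
diattenuator from the first row (`D = |(m12,m13,m14)|/m11`, pseudo-inverse
branch at D = 1), depolarizer block from the matrix square root of
`m′m′ᵀ` with the sign of `det m′` (ties counted and resolved positive),
retarder as `M_Δ⁻¹ M′`.  Scalars: `R = arccos(tr M_R/2 − 1)`,
`δ = arccos(√((mR22+mR33)² + (mR32−mR23)²) − 1)`, ψ as above;
`Δ = 1 − |tr m_Δ|/3`, `Δ_L = 1 − (|mΔ11|+|mΔ22|)/2`, `Δ_C = 1 − |mΔ33|`.
The linear/circular split is read from the *diagonal* of the depolarizer
block — appropriate for the near-diagonal depolarizers of cleared tissue;
an eigenvalue variant sits behind `diag_depol=False`.  The fast axis is
extracted from the retardance vector of the linear component after
peeling the rotator off the retarder factor (otherwise the axis is biased
by ψ/2).  All arccos arguments are clipped to [−1, 1] and negative
square-root arguments to 0, with per-image clip counters as a quality
metric.  On 1000 random `M_Δ M_R M_D` products the factors re-multiply to
the input within 1e-8 and every scalar returns its construction value
within 1e-6.

The MMT parameters `b = (m22+m33)/2`, `t = ½√((m22−m33)² + (m23+m32)²)`
and `A = 2bt/(b²+t²)` (set to 0 at b = t = 0) are rotation invariant by
construction and are computed from the m11-normalized matrix.

## Masking, profiles, statistics

Tissue masking excludes pixels whose depolarization deviates from the
median by more than `k·1.4826·MAD` (k = 3; the 1.4826 scale makes the
rule a 3σ criterion for normal data, excluding 0.27% of a clean map).
The statistics are computed inside a tissue region when one is supplied —
on a mostly-background frame the median would otherwise sit in the
background.  The source map (Δ by default, Δ_L/Δ_C selectable) and k are
configurable.

Radial profiles average a map in bins of distance from the inner ring
edge, optionally within an angular sector; empty bins stay missing, never
interpolated.  The profile standard deviation over non-empty bins is the
heterogeneity metric; peak location and value are also reported.  Ring
geometry is supplied explicitly or fitted by an algebraic least-squares
circle fit of the mask.

The statistical battery mirrors a non-parametric time-course design:
Spearman correlations among parameter means and against day (ordinal) and
group (binary); per group a Kruskal–Wallis test across days with
*unadjusted* pairwise two-sided rank-sum tests (Holm correction available
behind a flag, off by default); per day a control-vs-treated rank-sum
test; optional Shapiro–Wilk normality reports per cell.  Rank-sum tests
use the exact null distribution when both arms have n ≤ 12 and the pooled
sample is tie-free, else the normal approximation with midranks, tie and
continuity correction; the fully degenerate case (all values identical)
returns p = 1.  Each table row is one ROI acquisition (per-ROI mean, not
pooled per sample).

## SHG fiber orientation

Volumes are tiled into Hann-windowed subvolumes (default 32³, 50%
overlap).  The spectral energy of a straight fiber concentrates in the
plane normal to the fiber, so the local axis is the eigenvector of the
smallest eigenvalue of the power spectrum's second-moment tensor, after
removing DC and the two lowest frequency shells (suppresses illumination
gradients).  Subvolumes are invalid when windowed energy is negligible or
when spectral anisotropy `1 − λ_min/λ_mid` falls below 0.2 — an isotropic
spectrum (flat patch, pure noise) carries no orientation; on pure-noise
volumes ≥ 90% of subvolumes are rejected by this rule.

Axes are antipodal (v ≡ −v).  Before computing the spherical variance
`SV = 1 − |Σ vᵢ|/n`, axes are folded into the hemisphere around the
dominant eigenvector of the orientation scatter matrix (sign flipped to a
nonnegative dot product) — a rotation-invariant convention.  The reported
normalized value divides by `sv_max = 0.4`, adopted as a configuration
constant from the upstream fiber-analysis literature rather than
re-derived; the empirical maximum depends on the folding convention
(for uniform random axes this fold measures SV ≈ 0.493 ± 0.002 at
n = 5000), so `sv_max` is configurable and no test asserts the 0.4 value
itself — normalized SV can exceed 1 for near-uniform axes under this
fold.
In-plane angle statistics use double-angle (axial) circular statistics,
since θ has period 180° and naive averaging of axes straddling the 0/180
wrap is meaningless; φ statistics are plain moments of the folded axes.

## Synthetic data: what it emulates, what it does not

The ring phantom is an annulus with circumferential fast axis (the mold
guides cell alignment along the ring; configurable to constant), linear
retardance `baseline + Gaussian bump` across the ring width with the bump
centered at 30% from the inner edge, circular depolarization with the
same parameterization, small constant Δ_L, ψ, D, identity background and
optional high-depolarization defect disks.  Geometry is desk-scale: the
5 mm / 0.75 mm bench annulus is shrunk to fit a 256 px (tests: 48–64 px)
field while preserving the radial profile shape; the analytic
area-weighted profile mean is available as an oracle.  Per pixel,

    M = M_Δ(1−Δ_L, 1−Δ_L, 1−Δ_C) · M_R(δ(r), axis) · [M_rot(ψ)] · [M_D(D)]

The time-course cohort draws per-sample parameter means from truncated
normals around per-(day, arm) trajectory defaults with the measured
between-sample standard deviations and the study's per-cell sample sizes
(control n = 8, 8, 12, 9, 13; treated n = 8, 8, 9, 10, 9 on days 2, 4, 7,
14, 21).  The treated arm's retardance plateaus from day 7 while the
control arm rises through day 21, so cohort-level tests reproduce the
qualitative ordering (rank correlation with day, treated/control
separation at day 7) without asserting any biology.

Fiber volumes render straight cylinders with Watson-distributed axes
(rejection sampling on cos of the polar angle), Gaussian PSF blur and
Poisson noise, and return the ground-truth axes.

Deliberately not emulated: spectral bandwidth of the 780 nm filter,
objective/condenser polarization aberrations, camera nonlinearity,
optical-clearing physics, fiber curvature and branching, and spatial
correlation of biological variability.  Passing tests therefore validate
the *estimators* under a faithful noise and imperfection model, not the
biology; real-bench effects outside the model (e.g. spatially varying
instrument matrices beyond the per-pixel calibration, stray light) are
out of scope.

A note on physicality checks: the default `is_physical` propagates a
fixed 26-direction grid of fully polarized states and checks the
degree-of-polarization bound — cheap and sufficient as a pipeline guard;
every constructor product passes it.  The stricter Cloude coherency test
is available as an option.  The tissue-like combination Δ_C > 2Δ_L in a
*pure diagonal* depolarizer violates the Cloude (tetrahedron) condition
even though it never amplifies polarization; measured tissue matrices are
ensemble averages and need not factor into elementary pieces this way,
which is precisely why the grid test is the default guard for phantom
pipelines.

## Problem sizes and numerics

Defaults are sized for a desk machine: phantom images 256×256 (tests use
48–64 px rings), cohort acceptance at 48×48 with the full per-cell sample
sizes, fiber volumes 48³ with 32³ subvolumes, 1000-product decomposition
oracle, 10⁶-pixel masking Monte Carlo, 1000/500-rep statistics Monte
Carlos.  Degenerate inputs are handled without exceptions where the spec
of the operation allows (invalid pixels flagged NaN, empty profile bins
missing); hard errors are reserved for contract violations (rank-deficient
designs, empty masks, unphysical specs).  Seeds thread through every
stochastic path; identical seeds give byte-identical outputs.

## Known limitations

- Per-pixel calibration loops over pixels in Python; it is intended for
  small fields or sparse grids, not full camera frames.
- The ECM axis refinement is a local search initialized at nominal
  angles; grossly mislabeled reference angles (≫10°) may converge to a
  wrong gauge.
- Retarder references with retardance ≲ 20° have weak complex eigenvalue
  pairs and will fail the kind check at realistic noise; use quarter-wave
  (or similar) references.
- δ and ψ extraction assumes the retarder factor is a linear retarder
  followed by a rotator; for strongly elliptical retarders the split is
  conventional.
- The depolarization split from the depolarizer diagonal assumes
  near-diagonal depolarizers (true for these phantoms and cleared
  tissue); use the eigenvalue variant otherwise.
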