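# Methods

## Model

A fibrillar scatterer with C6 symmetry has a second-order susceptibility
with four independent molecular-frame components (fiber axis along
molecular z): χ_zzz, χ_zxx = χ_zyy, χ_xxz = χ_xzx = χ_yyz = χ_yzy, and the
chiral component χ_xyz = χ_xzy = −χ_yxz = −χ_yzx. The complex chiral
susceptibility (CCS) model takes the achiral components real and the
chiral one complex, χ_xyz = |χ_xyz| e^{iΔ}. The Kleinman-like relation
χ_zxx ≃ χ_xxz is the default but `chi_xxz` remains an independent field of
`MolecularSusceptibility`, so the assumption is configuration, not code.

The laboratory frame puts the image plane on (X, Z) with propagation along
Y. The fiber tilts out of the image plane by α (molecular z toward +Y) and
its in-plane projection makes the angle δ with lab Z, in-plane direction
(sin δ, cos δ). Only transverse field components matter at low NA, so after
the full third-rank rotation the response collapses to a 2D tensor over
{X, Z}. Normalized by χ_zxx cos α, its entries at δ = 0 are

    ZZZ = R,  ZXX = XXZ = XZX = 1,  XZZ = −2 C e^{iΔ},  ZXZ = ZZX = +C e^{iΔ},

with the effective ratios

    R = (χ_zzz/χ_zxx) cos²α + (1 + 2 χ_xxz/χ_zxx) sin²α,
    C = (|χ_xyz|/χ_zxx) sin α,      σ = 2 C cos Δ / (R + 1).

C is signed by sin α and therefore encodes polarity. At α = ±π/2 the
normalization degenerates (cos α = 0); the tensor is flagged rather than
divided by zero, while (R, C) stay defined.

### Polarization conventions

Jones vectors are ordered (X, Z); HLP = (1, 0), VLP = (0, 1),
P45 = (1, 1)/√2, RCP = (1, −i)/√2; s2 = 2 Re(E_X E_Z*),
s3 = 2 Im(E_X E_Z*). These are pinned jointly: with the opposite circular
handedness the chiral closed forms (W, SHG_CD) change sign while the
achiral ones do not, so the convention is fixed once by requiring every
closed form to carry its standard sign, and documented here. An analyzer
for state a transmits (s0 + â·(s1, s2, s3))/2, which also holds for
partially polarized light.

## Forward simulation

E_i(2ω) ∝ Σ_jk t_ijk e_j e_k over {X, Z}. Sample birefringence is modeled
as one linear retarder on the fundamental (phase φ = 2π Δn l / λ at
1030 nm) and one on the SHG (515 nm), sharing an axis — by default the
fiber's in-plane projection as the slow axis (collagen is positively
birefringent). Generation is treated as occurring at the slice midplane,
so l defaults to 5 µm for a 10 µm section; no distributed-generation
integration is attempted. Detection multiplies analyzer projections by a
gain (counts per squared field; the default 100 puts the brightest pixels
at a few hundred counts) and optionally Poisson-samples each of the 36 (or
64) images independently, emulating a photon-counting PMT. Uniform
depolarization is available as a DOP factor shrinking (s1, s2, s3) while
leaving s0 — a worst-case model in which all depolarized light reaches
every analyzer equally.

## DSP parameters and inversion

Eleven dimensionless parameters are computed per pixel from the six-state
Stokes images: A, B, SHG_LD, SHG_45 (orientation-dependent) and CA_CD, L,
T, H, SHG_CD, W, D (orientation-independent). Each has a closed-form
prediction in (R, C, Δ, δ); the forms for L, CA_CD, T, SHG_CD, W and
D = −W/T = tan Δ are exact under the CCS model and the test suite holds
the measured side to them at 1e-9. A, B and H have exact forms plus the
small-chirality approximations (σ forms); both are first-class outputs so
the approximation error is measured, not silently mixed. At the stated
validity bound 4C² = 0.01|R² − 1| the A and H approximations stay below
1e-3 while the approximate linear/diagonal dichroism forms keep a ~7e-3
remainder; all grow monotonically with C.

Inversion proceeds R → (C cos Δ, C sin Δ) → σ → δ:

- **R**: default from CA_CD and L jointly (exact in C). Both quadratic
  roots satisfy the pair exactly with different implied C², so "auto"
  branch selection takes the non-collagen plus root only when its
  back-substitution residual is decisively smaller; on the degenerate
  R = 1 manifold (vanishing quadratic leading coefficient) an L-only
  linear fallback is used. The circular-only CA_CD path (minus branch,
  small-C form) is the lightweight alternative.
- **Chiral components**: C² appears on both sides of the closed forms, so
  (C cos Δ, C sin Δ) are solved by fixed-point iteration from C = 0 to
  |ΔC| < 1e-10 (the C² corrections are small against the leading
  denominators in the physical |C| ≲ 0.3 regime, giving geometric
  convergence; non-convergent pixels are flagged). Sources: (T, W) by
  default, (H, SHG_CD) as the alternative. C = sign(C cos Δ)·√(…); Δ is
  emitted both as atan2(C sin Δ, C cos Δ) in (−π, π] and as the principal
  arctan of D in (−π/2, π/2) — the two conventions agree on the shared
  domain for noise-free data and are labeled explicitly because noisy or
  birefringent data separate them.
- **σ**: default H/3 (the direct measurement); "exact" mode uses
  2 C cos Δ/(R+1) from the recovered chiral components, removing the
  (R+1)² ≫ 8C² approximation — required when orientation accuracy below
  0.1° matters for strongly chiral fibers.
- **δ**: from B (exact algebraic inverse) or A (approximate), yielding the
  quarter range (−π/4, π/4); quadrant extension compares the measured
  (SHG_LD, SHG_45) pair with its exact model prediction at the two
  candidate angles and keeps the closer one. Ties (e.g. R = 1, C = 0:
  no orientation modulation at all) keep the in-range candidate and are
  flagged ambiguous and counted.

Masking: pixels with mean s0 below 10 counts are dropped; the circular
consistency identity s0^RCP − s0^LCP = s3^RCP + s3^LCP (exact for pure
states) masks pixels whose residual exceeds three Poisson standard errors
of the left side (the distance criterion itself is a package choice);
ratio denominators below 1e-6 of the pixel s0 scale are masked and
counted; Δ is masked where both |C cos Δ| and |C sin Δ| fall below 0.02.
All masks combine by AND and propagate as NaN.

## PIPO baseline

The 8×8 linear-state stacks use the identical forward model (no separate
trigonometric formula). The per-pixel fit parameterizes (amplitude, δ, R,
c = C cos Δ): the imaginary chiral part enters linear-only intensities at
second order and is not resolvable by PIPO. Fitting is a vectorized
Levenberg–Marquardt over all pixels at once with an analytic Jacobian,
five δ multi-starts spaced 36° screened by residual (two refined), step
tolerance 1e-12; Poisson weighting (1/√max(I, 1)) is optional and off by
default. On noise-free stacks the fit and the closed-form inversion agree
to 1e-6 in R and c and 1e-3 degrees in δ; under Poisson noise the fit's R
distribution is slightly narrower than the circular-only closed-form one,
as expected from its use of all 64 images per pixel.

## Phantoms

`longitudinal`: in-plane fibers (α = 0, hence C = 0) with δ normally
distributed around −39° (5° spread). `oblique`: fibers tilted ±30° in
alternating bands (polarity domains) with a broad in-plane orientation
ramp (±80°). The 30° tilt is calibrated so that the default tensor
(χ_zzz = 1.6, χ_xyz = 0.2 + 0.2i) gives the effective R = 1.95
characteristic of obliquely cut tendon; it is a modeling choice pinned to
the effective R, not a claim about a real tilt distribution. A left-edge
zero-signal strip of configurable fraction exercises intensity
thresholding. One seed fixes the orientation jitter and (decorrelated) the
Poisson stream; stacks are bit-reproducible. The phantoms emulate
orientation, polarity, counting noise, uniform birefringence and uniform
depolarization; they do not emulate fibril-scale texture, scattering,
focal-volume averaging or staining effects, so passing tests demonstrate
correctness of the estimators under the CCS model, not performance on
tissue.

## Birefringence bias

With Δn = 0.002, l = 5 µm, fiber-aligned slow axis and the default
tensor, the recovered R underestimates the true effective R by 2.2% for
in-plane fibers (independent of δ for the fiber-aligned axis; 2.1% via the
circular-only path) and 2.9% for the 30°-tilt oblique geometry (median
over the in-plane sweep). The bias is quadratic in the accumulated
relative phase (2φ_fund + φ_SHG ≈ 0.244 rad) and grows steeply with tilt:
it reaches ~7% only near α ≈ 60° (effective R ≈ 2.65) in this model.
Reversing which axis is fast, fixing the axis in the laboratory, or
swapping the wavelength phases changes the in-plane value between −0.6%
and +3.9% but never produces a large tilt-selective amplification, so the
in-plane and tilted biases remain within a factor ~1.5 of each other under
every axis convention tried. `scripts/acceptance.py` recomputes both
numbers.

## Filtering equivalence

Under uniform depolarization at DOP 0.9, the pure-state substitution
s0 ← √(s1² + s2² + s3²) exactly restores the closed-form ratios, while
unfiltered processing inflates every s0 by 1/DOP and biases R low. The
median shift is 0.066 for the in-plane phantom with the circular-only R
path (0.11 with the CA_CD&L path; 0.13–0.17 for the strongly tilted
preset). Uniform depolarization is the worst case — any depolarization
that does not reach the analyzers isotropically biases less.

## Problem sizes

The test suite uses grids of 1.5k–5k parameter combinations for the oracle
and recovery suites, 64×64–80×80 phantoms for noisy statistics and one
200×200 phantom for the DSP–PIPO width comparison; the acceptance script
sweeps 181 in-plane orientations for the tilted-bias median. These sizes
give medians stable to well inside the asserted tolerances.

## Known limitations

- Low-NA scalar fields; no vectorial focusing, no quadrupolar/magnetic
  contributions.
- Single-plane generation; birefringence as two lumped retarders.
- Depolarization only as a uniform DOP factor; no Mueller-matrix
  scattering model and no depolarization decomposition.
- The tilt α itself is not recovered (it requires assumed molecular
  ratios); only the effective R and C are.
- Absolute chirality sign conventions differ between publications; this
  package's handedness is internally consistent and documented above, but
  comparing signed C or Δ across instruments requires checking the
  circular-state convention first.
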