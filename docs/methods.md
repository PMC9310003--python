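# Methods

## Physical model and assumptions

`molvib` works entirely in the double-harmonic approximation: each normal
mode *m* is characterized by a harmonic wavenumber ν̅ₘ, a dipole-derivative
vector μ′ₘ (derivative of the molecular dipole with respect to the
mass-weighted normal coordinate, e·amu^−1/2) and a symmetric
polarizability-derivative tensor ᾱ′ₘ (bohr²·amu^−1/2). Static (Placzek)
polarizability derivatives are assumed — no resonance-Raman dispersion, no
anharmonicity, and no plasmonic or chemical enhancement; the quantities
computed are the *molecular* response factors that an enhancement model would
multiply.

Intensities:

- **IR**: Iᴬ = Cᴬ|e_IR·μ′|², in km/mol. The constant Cᴬ = 2.9254 × 10³
  converts the squared projection from atomic units, with the convention
  that the isotropic 1/3 is folded in so the uniform-orientation average is
  Cᴬ|μ′|²/3. `constants.derive_c_a` recovers it from CODATA values as
  3 × N_A e²/(12 ε₀ c² u) expressed in km/mol (agreement 0.03%).
- **Raman (Stokes)**: Iᴿ = Cᴿ(ν̅_R − ν̅ₘ)⁴/ν̅ₘ · n(ν̅ₘ,T) ·
  |e_out·ᾱ′·e_in|², a differential cross-section in cm²/sr. The thermal
  occupancy n = 1/(1 − exp(−hcν̅ₘ/kT)) sits in the prefactor and equals 1 at
  T = 0. Cᴿ = 2.060 × 10⁻⁴⁵ is exactly 2π²h/c in cgs times bohr⁴/amu in
  cm⁴/g (`constants.derive_c_r`, agreement 0.01%); this CODATA re-derivation
  is what pins the prefactor structure (fourth power of the scattered
  wavenumber, 1/ν̅ₘ, occupancy placement) to the stated unit conventions.
  The pump must be on the Stokes side (ν̅_R > ν̅ₘ); violating it is an error,
  not a sign flip.
- **SFG / upconversion**: Iᶜ = CᴬCᴿ(ν̅_R + ν̅ₘ)⁴/ν̅ₘ · |e_IR·μ′|² ·
  |e_out·ᾱ′·e_in|² — the net increase in anti-Stokes Raman intensity under
  IR pumping, hence the plus sign in the wavenumber factor and no occupancy.
  Its value carries product units (km·mol⁻¹ · cm²·sr⁻¹ scale) and is treated
  as a relative conversion coefficient for ranking and spectra; no absolute
  photon-count calibration is attempted.

## Orientation handling

Euler angles (ϕ, θ, ξ) use the intrinsic z-y-z convention,
R = Rz(ϕ)·Ry(θ)·Rz(ξ). The convention is a free choice — any fixed proper
parametrization yields the same orientation averages and the same
frame-covariant intensities (co-rotating molecule and all three field
polarizations leaves every intensity unchanged; this is tested to 1e-10 over
random rotations). Molecules bound through a thiol are aligned with Au at
the origin and the Au→S vector along +z; records without gold fall back to
the S atom and its nearest heavy neighbour.

## Orientation averages

Averages are over the uniform (Haar) measure on the full rotation group —
i.e. fully random molecular orientation, not an azimuth-only
surface-constrained average; this is a documented modelling choice.

- Rank 2 (IR): ⟨|e·Rμ′|²⟩ = |μ′|²/3.
- Rank 4 (Raman): with S₁ = (tr ᾱ′)² and S₂ = tr(ᾱ′²), the averaged squared
  contraction is u·c² + v(1 + c²) with u = (2S₁ − S₂)/15,
  v = (3S₂ − S₁)/30 and c = e_in·e_out. In Placzek-invariant form this is
  (45a′² + 4γ′²)/45 for parallel and 3γ′²/45 for crossed polarizations;
  oblique pairs use the exact bilinear form, not an error.
- Rank 6 (SFG): the IR and Raman factors share the molecular rotation, so
  ⟨Iᴬ·Iᴿ-factor⟩ ≠ ⟨Iᴬ⟩⟨Iᴿ-factor⟩ in general. The joint average
  ⟨|e_IR·Rμ′|²(e_out·Rᾱ′Rᵀ·e_in)²⟩ is a degree-6 polynomial in the entries
  of R and is evaluated exactly via the sixth moment of the orthogonal group:
  ⟨R⊗…⊗R⟩ = Σ_{σ,τ} Wg(σ,τ) Δ_σ ⊗ Δ_τ over the 15 pair matchings of six
  indices, where the Weingarten matrix Wg is the inverse of the Gram matrix
  G_{στ} = 3^{#loops(σ∪τ)}. (Even-degree monomials make the SO(3) and O(3)
  averages coincide, and products of two Levi-Civita symbols reduce to delta
  pairings, so the 15 matchings span all invariants.) The Gram inverse is
  computed once at import in exact rational arithmetic (`fractions.Fraction`
  Gauss–Jordan) before any floating-point enters — exact rational
  coefficients derived from the combinatorial definition rather than pasted
  literals, which keeps the derivation auditable in place. It reproduces
  known sphere moments (⟨u_z²u_x⁴⟩ = 1/35, ⟨u_z⁶⟩ = 1/7) exactly.

An independent oracle, `averaging.haar_average`, integrates any f(R) over
Euler angles with 12 Gauss–Legendre nodes in cosθ and 16 uniform nodes in
each of ϕ and ξ. Uniform nodes integrate trigonometric polynomials up to
degree 15 exactly and the Legendre rule is exact to polynomial degree 23, so
the quadrature is exact (to machine rounding) for all integrands of degree
≤ 6 in the rotation entries — everything this package averages. The test
suite requires closed form == quadrature to 1e-10 relative on 100 random
modes, and checks the quadrature itself against 10⁶-sample Monte Carlo.

A caution on exact zeros: the rank-6 contraction sums ~225 signed terms, so
configurations whose exact average is zero (e.g. isotropic tensor with
crossed polarizations) return values at the 1e-18 cancellation floor rather
than literal 0.0 — about twenty orders of magnitude below typical nonzero
cross-sections.

## Spectra

Stick spectra place each mode's intensity at its (optionally scaled)
wavenumber. The global frequency scaling factor multiplies positions only
and is applied *before* any window masking, so windows always refer to the
scaled axis. IR and Raman broadening uses unit-area Lorentzians
(γ/π)/((ν−ν̅ₘ)² + γ²), γ = fwhm/2, so each band integrates to its stick
intensity; fwhm_IR and fwhm_R are independent parameters. Lorentzian tails
are fat: the default display grid (5·fwhm margin, 1 cm⁻¹ spacing) truncates
≈6% of the area, and area-conservation checks therefore integrate over wide
grids (~100·fwhm).

The SFG band is the product of the IR and Raman Lorentzians, both centred at
the same mode position on one shared axis. A product of two unit-area
Lorentzians has no canonical area, so the product shape is *peak-normalized*:
the curve's maximum at ν̅ₘ equals the stick SFG coefficient, making
stick-vs-curve comparison direct. For equal widths w the product shape has
fwhm w·√(√2 − 1) ≈ 0.6436·w. This normalization is a documented choice
isolated in `spectra.sfg_lineshape`.

## Screening

A, R and P are plain sums of the per-mode IR, Raman and SFG intensities over
the set M of modes whose scaled wavenumbers lie in the closed window
[lo, hi] (boundary ties included); the scaling factor also enters the
Raman/SFG wavenumber prefactors so that the whole computation lives on one
consistent frequency axis. Empty M gives 0, not an error. Standardized
scores are z-scores of log₁₀(value + ε) with ε = (smallest positive
value)/100 — intensity distributions span orders of magnitude, and the log
keeps the scores comparable across targets; zero-variance input maps to
all-zero scores. Standardization is strictly monotone, so ranking (sorted by
decreasing raw value, ties broken lexicographically by molecule id for
determinism) is unaffected by it. Histograms use log-spaced bins whenever
all values are positive.

Orientation maps rotate one mode about a Cartesian axis and record the
chosen intensity on a uniform angular grid — the polar diagram of the mode's
response in the plane perpendicular to the axis.

## Surface descriptors and similarity

Layer height is max(z+r) − min(z−r) over atoms with Bondi van der Waals
radii (frozen table; Au at 1.66 Å); the XY projection is the area of the
union of vdW disks, rasterized at 0.05 Å by default (single-disk error
< 1%, halving the resolution moves the area < 0.5%). The vdW envelope — not
bare atom centers — is used because the descriptors stand in for monolayer
thickness and footprint; a `vdw=False` / `--centers-only` switch exposes the
center-only variant. Similarity is the Tanimoto coefficient on Morgan
fingerprints (radius 2, 2048 bits, rdkit); the parameters are fixed and
recorded in output metadata. Scores are internally consistent; no claim of
matching any external service's scores is made.

## Synthetic data

`synthgen.generate` emulates the structure of harmonic frequency output:
wavenumbers uniform on 100–3600 cm⁻¹, dipole-derivative components Gaussian
with scale 0.1 e·amu^−1/2 (typical IR intensities of O(1–100) km/mol),
polarizability-derivative components Gaussian with scale 3 bohr²·amu^−1/2
(typical Raman activities), 6–30 modes per molecule, and an Au–S anchor
(2.35 Å) with a linear carbon backbone sized so that the mode count respects
the 3N bound. Each record draws from `default_rng([seed, index])`, so
subsetting a database never reshuffles surviving records. The generator
reproduces *structure and scale only*: real spectra have correlated mode
frequencies, selection rules from molecular symmetry, and heavy-tailed
intensity distributions that these records do not. Passing tests therefore
certify the tensor algebra, averaging, bookkeeping and ranking logic — not
agreement with any measured spectrum.

`synthgen.make_witness_fixtures` pins qualitative behaviour: an isotropic
Raman tensor (γ′² = 0, crossed-field average vanishes, SFG average
factorizes), a traceless anisotropic tensor (γ′² = 3), and the
non-factorization witness μ′ = ẑ, ᾱ′ = diag(1,0,0), for which the joint
average is 1/35 but the product of separate averages is 1/15 — a 57%
discrepancy. `with_dominant_record` appends a record holding a 10×-scaled
copy of every mode in the database, which by additivity outranks every
record for any target, window and orientation — a constructed dominance
fixture for ranking tests.

## Numerical choices and degenerate inputs

- Tensor symmetry is validated to 1e-12 relative; rotation matrices to
  1e-10 orthogonality; polarization vectors to 1e-12 unit norm (the CLI
  normalizes explicit triples on input).
- Problem sizes in the test suite (databases of 8–16 molecules, 10⁶
  Monte-Carlo rotations, 0.001 cm⁻¹ grids for width measurements) were
  chosen to make each check sharp while keeping the full suite near
  20 seconds.
- Degenerate inputs: empty databases rank to empty tables; empty windows
  and empty records give zero targets; T = 0 gives occupancy exactly 1;
  coincident anchor atoms, non-Stokes pumps, non-positive fwhm/scaling and
  unknown elements raise named errors.

## Known limitations

- Full uniform-orientation averages only; no tilted-cone or azimuthal
  partial averaging.
- Static polarizability derivatives; no frequency-dependent (resonance)
  response, no anharmonicity.
- No vendor quantum-chemistry log parsing in core — records enter through
  the JSON interchange schema (`vibrecord/1`), and converting mass-weighting
  conventions is the importer's responsibility.
- SFG values are relative coefficients; comparisons are meaningful within
  and across molecules in this toolbox's convention, not as absolute photon
  rates.
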