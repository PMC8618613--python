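# Methods

This note documents the models and numerical choices behind `undulayer`,
what the synthetic-layer generator does and does not emulate, and the known
limitations of each stage.

## System and units

The package analyses a dense surfactant monolayer at the water surface:
amphiphilic molecules with a rigid hydrophobic core (the aglycone of a
saponin such as escin) adsorbed at ~0.49 nm² per molecule on a water slab,
in a laterally periodic box (default 14.70 × 14.70 nm) with a vacuum gap
along z.  Internal units are nm, ns and amu throughout; unit conversion
happens only at I/O boundaries (GRO is nm natively, PDB Å) and in the
elasticity chain (SI).  Coordinates are never wrapped on read: analyses that
need periodicity apply the lateral minimum image in x and y themselves, and z
is treated as non-periodic everywhere because of the vacuum gap.

Block averaging partitions a time series into fixed 50-ns segments (the
default block length used for all block statistics), anchored at the first
sample; a trailing partial block is dropped so per-block statistics stay
comparable.

## Synthetic layer generator

The generator produces configurations that stand in for a relaxed MD
trajectory, with exact ground truth for every analysis stage:

* **Placement.** Molecules sit on a jittered square lattice whose pitch is
  derived from the lateral box (L = √(n·apm)), so the realised areal density
  is exactly 1/apm.  Base-atom heights follow an analytic sine wave
  z(y) = y₀ + A sin(2πy/B + C) plus Gaussian noise (default SD 0.3 nm,
  a realistic roughness for a fluctuating monolayer).
* **Orientation.** Each molecule is a 1-nm axis (base → tip) tilted by an
  angle drawn from N(75°, 20°) relative to the *inward* local normal of the
  analytic wave (computed from the wave derivative, not numerically), with a
  uniformly random azimuth.  75° ± 20° from the inward normal corresponds to
  a local-frame tilt of 105° ± 20° in the 90–180° convention used for
  reporting.  Because azimuths are random, the *lab-frame* tilt histogram of
  a generated layer is not meant to match any particular measured layer; the
  generator's purpose is exact knowledge of the local-frame orientation.
* **Mass model.** Five inert beads along the axis bring each molecule to
  1101 amu (escin's molar mass), so density profiles carry realistic mass
  without molecular detail.  Water is a slab of 18-amu beads at 998 kg/m³
  (water at 293 K) filled below the lowest point of the wave; a 3-site water
  variant exists for H-bond tests.
* **Hydrogen bonds.** A donor / hydrogen / acceptor triad rides above each
  base atom.  A chosen fraction of molecules is paired with a lattice
  neighbour by placing the partner's acceptor collinearly 0.28 nm from the
  donor — inside any conventional cutoff — while unpaired sites stay ≥0.4 nm
  from foreign donors, so the constructed bond list is recovered exactly by
  the detector on noise-free layers.
* **Trajectories.** Frames share one ground-truth wave; frames after the
  first carry Gaussian coordinate jitter (so a 1-frame trajectory equals the
  single-layer generator bit for bit).  An optional drift model relaxes the
  bonded-molecule *fraction* along a saturating exponential
  f(t) = f_∞ + (f₀ − f_∞)e^(−t/τ), whose 95% settling time τ·ln 20 is the
  analytic oracle for plateau detection.  The drift is parameterised as a
  fraction because the minimal molecular model supports at most one
  constructed bond per molecule pair; absolute per-molecule bond counts of a
  real surfactant (≈15 bonds to water per molecule) are outside what this
  geometry can represent.
* **Determinism.** RNG streams are split per purpose (placement, tilt,
  bonds, water, jitter) from one seed, so changing one knob does not shift
  unrelated draws; the same seed gives bit-identical output.

What the generator does **not** emulate: molecular flexibility, realistic
water structure, energetics, or dynamics.  Passing tests therefore
demonstrate that the *analysis* stages measure what they claim on data with
known structure — not that any particular physical system behaves this way.

## Hydrogen bonds

A triple (donor, hydrogen, acceptor) is a bond iff the donor–acceptor
distance is ≤ 0.35 nm under the lateral minimum image *and* the
hydrogen–donor–acceptor angle is ≤ 30°.  These defaults are the convention of
widely used MD analysis tools; both are configurable because geometric
criteria are not standardised.  Hydrogens attach to the nearest
donor-capable atom of their own molecule (no bond perception); a surfactant
donor without a hydrogen is an error, while a bare one-bead water oxygen
simply acts as acceptor only.  Neighbour search uses a periodic k-d tree
wrapped in x and y with the z edge padded far beyond the cutoff.
Intramolecular bonds are counted separately and excluded from the headline
categories by default; a combined mode exists because "within and between"
counts are sometimes reported together.

Plateau detection returns the start of the earliest suffix of ≥3 block means
that all lie within a relative tolerance of the suffix mean — a deliberately
simple, monotone criterion whose behaviour on a saturating exponential is
analytically predictable.

## Density profiles and the dividing surface

Per-bin density is (mass in bin)/(L_x·L_y·Δz), averaged over frames, with SDs
across 50-ns block means.  Components are classified per molecule (water /
surfactant / other), so every binning conserves each component's total mass
identically.

The equimolecular dividing surface assumes bulk water below the interface
and vacuum above.  Bulk density is the mean over the 1-nm window with the
smallest density gradient; the window must be flat (SD and total drop each
≤5% of the mean), otherwise the profile has no bulk plateau and the analysis
refuses rather than guessing.  Given bulk density ρ_b and the window top z_a,
the EDS is z_e = z_a + (1/ρ_b)∫_{z_a}^{∞} ρ dz, which makes the deficit below
balance the excess above; it is exact for a step profile and equals the
centre of any symmetric (e.g. error-function) interface.

"Half-width" of a density peak means FWHM/2 by linear interpolation between
bins.  The term is ambiguous in the literature (FWHM/2 vs SD vs half width
at base); FWHM/2 is the standard reading and the one implemented.

## Tilt, order parameter and slope correction

Tilt α is the angle between the aglycone vector (tip − base) and +z; the
orientation convention (tip distal to the sugar head) places upright
molecules near 180°, so layers live in the 90–180° range.  The rotational
order parameter is the first-rank polar average OP = ⟨cos(180° − α)⟩ — not
the nematic P₂ — so OP(180°) = 1, OP(90°) = 0, and block-then-average equals
the global average for equal blocks (the estimator is linear).

Because the layer undulates, part of the lab-frame tilt is surface slope.
The slope is measured by a least-squares line through base-atom (y, z) points
over the central 50% of a monotonic wave segment (the quasilinear part;
windows containing a wave extremum are rejected).  Two corrections are
provided:

* **Scalar** (default): corrected mean tilt = mean α − slope angle, with the
  slope standard error and the tilt SD combined in quadrature.  This is the
  arithmetic used when a single corrected mean is reported from a measured
  mean tilt and fitted slope (e.g. 142° − 37° = 105°).  It is, however,
  ambiguous whenever α folds at 180°: a molecule exactly along the local
  normal on a slope s has α = 180° − s, and subtracting s gives 180° − 2s
  rather than 180°.
* **Local-normal** (exact): the per-molecule angle between the aglycone
  vector and the local normal of the fitted wave at the molecule's y.  This
  mode is immune to the folding ambiguity and is the one used to verify that
  molecules constructed along the local normal come out at 180° in every
  segment.

## Radial distribution functions

Pairs of aglycone-base atoms, lateral minimum image, r_max ≤ min(L_x,L_y)/2.
The 2D RDF uses in-plane distances normalised by the areal ideal-gas shell
count (exact annulus areas), so uniform in-plane placement gives g → 1.  The
3D RDF normalises by the whole-box volumetric density with exact shell
volumes — the convention of common MD tools — so slab-confined atoms give
g < 1 at large r; this depletion is documented behaviour, not an artefact to
correct.

## Undulation fit

Per block: per-molecule time-averaged base-atom coordinates → middle line by
binned means (default 50 bins; each line point is the centroid of its bin, so
noise-free curves are preserved to second order: the binning error is bounded
by |z''|·w²/8) → nonlinear least squares of z(y) = y₀ + A sin(2πy/B + C).
Initialisation is multi-start: A₀ and y₀ from the data range and mean, period
candidates from the two dominant discrete-Fourier modes of the resampled line
plus {0.5, 1.0, 1.5}×L_y as fallbacks, and 8 coarse phases; the lowest-SSE
start wins, so the returned solution is never worse than any start.  Results
are canonicalised to A ≥ 0, C ∈ (−π, π].  The period is *not* constrained to
the box: a wave can span more than one periodic image, so B/L_y may exceed 1.
Exactly flat input returns A = 0 with the period flagged unidentifiable
instead of failing; fits whose amplitude is within the residual noise floor
carry the same flag.

Each block is fitted independently (no warm-starting across blocks), so
per-block parameter series are statistically independent given the data.

## Elasticity chain

From the interfacial shear modulus G′_S, dilatational modulus G′_D and layer
thickness h: ν = G′_D/(2G′_S) − 1; Y_s = 2G′_S(1 + ν) (algebraically equal to
G′_D — asserted in tests as a consistency identity); Y = Y_s/h;
D = Yh³/(1 − ν²); D/k_BT at the given temperature (default 293 K, CODATA
k_B); λ = 2√π(D/σ)^¼ L^½ when a surface tension and sheet length are given.
The rigidity uses the divided form 1/(1 − ν²) *without* the classical
plate-theory factor 1/12; a `classical_plate` flag adds the 1/12 for
comparison with textbook thin plates.  No intermediate rounding occurs
anywhere in the chain.  ν outside (0, 0.5) is physically unusual for this
sheet model and triggers a warning, not an error.

## Problem sizes and limitations

The test suite and examples run layers of 16–441 molecules with single frames
or up to ~100 frames, water slabs of 0–5 nm, and Monte-Carlo checks with
10–50 replicates — sizes at which every stage's ground truth is exact or
analytically bounded.  Quantities that depend on the slow collective
dynamics of a real microsecond-scale trajectory (relaxation times of order
700 ns, trajectory-averaged order parameters, real peak half-widths) are not
reproduced by the generator; the generator's defaults mirror those published
conditions only so that the pipeline runs at realistic geometry.  The
wrinkle-wavelength output is validated by its closed form and scaling only,
since no (σ, L) pair is part of the default conditions.
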