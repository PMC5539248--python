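# Methods

`bnctsim` chains six components: phantom geometry → microscopic-extension
probability (MEP) field → boron bio-distribution and materials → Monte Carlo
neutron transport → RBE-weighted dose → linear-quadratic survival.  This
note records the model, its assumptions, the parameters that matter, and the
numerical and design choices behind them.

## Geometry

The phantom is a rectangular brain slab (default 9 × 9 × 2.2 cm, ICRU brain
composition, density 1.03 g/cm³ — the density is not part of the elemental
table and is configurable).  The beam travels along +z and enters at z = 0
as a parallel disc.  Dose is scored on a single plane of square cells
(20 µm at full scale) perpendicular to the beam at 2.0 cm depth; the tumour
centre sits at the lateral midpoint of that plane.  Indices are 0-based,
distances are measured between voxel centres, a cell belongs to a disc if
its centre does, and boundary ties go to the inner region.

The GTV radius is 1 mm.  The beam radius equals GTV radius + CTV margin +
PTV margin (0.1 + 2.0 + 0.4 = 2.5 cm for the standard margin), the
penumbra is the annulus 5.0 mm beyond the beam edge, and the remainder of
the plane is out-of-field; the three regions partition the plane exactly.

Two grids coexist: the fine scoring plane and a coarse 3 mm material grid
used by transport.  The 2.2 cm depth is not an integer multiple of 3 mm, so
the last coarse layer is partial and lookups clip to it; the lateral tiling
is exact and enforced.

## Microscopic extension

Every cell carries a probability of being a tumour clonogen,

    MEP(x) = a1 e^{-((x-b1)/c1)^2} + a2 e^{-((x-b2)/c2)^2} + a3 e^{-((x-b3)/c3)^2}

with x the distance from the GTV surface, truncated to 0 beyond 4.1 cm.
GTV cells are tumour with probability 1, and construction enforces
MEP(0) = 1 and 0 ≤ MEP ≤ 1.  The field is an expectation: clonogen counts
are sums of probabilities and no Bernoulli realisation is ever drawn.

The coefficients of the underlying clinical fit are not available, so the
package ships placeholder defaults — all centres at zero, amplitudes
(0.05, 0.75, 0.2), widths (0.3, 1.4, 3.5) cm — and a calibration procedure
that rescales the two outer widths until the lattice clonogen counts match
two targets: the full-plane total (default 2,908,500) and the penumbra
count of the 2.5 cm beam (default 299,420), both defined on the 20 µm
lattice.  The amplitude split was chosen so that this two-parameter system
is feasible: matching the total forces a given amount of probability mass
into mid radii, and amplitude-heavy outer terms cannot keep the penumbra
fraction as low as the targets require.  Calibration uses deterministic
Levenberg–Marquardt on log-multipliers from a unit start and verifies both
counts to 1e-3 relative; lattice sums are evaluated through a 5 µm radial
histogram of cell counts (error ≪ 1e-6 relative), so one objective
evaluation costs microseconds after a single pass over the plane.  The
two-target system is only locally identifiable — distinct width pairs can
reproduce the same two counts — so recovery of a known truth is guaranteed
only within the basin of the unit start.  Because the targets are defined
at cell scale, the pipeline always calibrates on the 20 µm lattice even
when the simulation itself runs at the reduced resolution.

## Boron bio-distribution and materials

Cellular ¹⁰B concentration is linear in tumour probability:
c = slope·MEP + c_normal, with c_normal = 13 µg/g and slope =
c_normal·(ratio − 1) = 32.5 µg/g for the consensus tumour-to-normal ratio
of 3.5.  For transport the continuous range [13, 45.5] µg/g is quantised
into 12 equal-width bins (left-closed, top bin closed) whose
representative concentration is the bin midpoint — the simplest scheme
consistent with a twelve-step ladder; the bin-edge convention matters only
on a measure-zero set.  Each step is the brain composition rescaled by
(1 − w_B) plus the boron mass fraction w_B = c·1e-6, so fractions always
sum to one.  Coarse voxels are classified by the 3-D distance of their
centre from the tumour centre (transport is 3-D); the scoring-plane maths
uses lateral distance — both evaluate the same radial function.

## Neutron transport

A vectorised analogue/weighted Monte Carlo engine, intentionally far
simpler than a general-purpose transport code:

* **Source.**  Disc beam, normal incidence, tabulated spectrum.  The
  default is an idealised pure-epithermal 1/E law tabulated on 61
  log-spaced nodes between 0.5 eV and 10 keV; the tabulation semantics are
  trapezoid interval weights with uniform sampling within an interval, and
  any user table with the same shape substitutes for it.
* **Cross sections.**  Thermal-point (2200 m/s) capture values with 1/v
  energy scaling — ¹⁰B(n,α)⁷Li 3837 b, ¹⁴N(n,p)¹⁴C 1.83 b, ¹H(n,γ)²H
  0.332 b — and flat free-atom elastic values: H 20.4, C 4.74, N 10.0,
  O 3.76 b.  These are standard evaluated thermal-point constants; no
  resonance structure, no bound-atom S(α,β) thermal scattering.
* **Kinematics.**  Isotropic centre-of-mass elastic scattering off free
  stationary nuclei: E′/E ∈ [((A−1)/(A+1))², 1] uniformly, laboratory
  angle from the standard transformation.  Charged capture products (α,
  ⁷Li, p, recoil nuclei; ranges 4–9 µm, below the 20 µm cell) deposit at
  the interaction site — no charged-particle stepping.
* **Boron capture branches.**  94% to the ⁷Li excited state (α 1.47 MeV +
  ⁷Li 0.8316 MeV + 478 keV photon), 6% ground state (1.78 + 1.01 MeV).
  Nitrogen capture deposits 0.585 + 0.041 MeV; hydrogen capture emits a
  2.2246 MeV photon only.  The capture photon is included in the gamma
  component by default (configurable).
* **Photons.**  A single exponential flight with the total attenuation
  coefficient of the line (µ/ρ = 0.0989, 0.0472 cm²/g at 478 keV and
  2.22 MeV), depositing E·µ_en/µ at the interaction point; the scattered
  remainder is discarded and there is no incident-beam gamma
  contamination.
* **Thermal bath.**  Free-gas slowing-down has no upscattering, so instead
  of an energy floor with forced capture — a straight capture flight would
  average ~30 cm in tissue and simply exit a 2.2 cm phantom — neutrons are
  clamped at 0.0253 eV and continue the elastic/capture competition walk
  at fixed energy.  This keeps the lateral diffusion of the thermal cloud,
  which is exactly what builds the dose dome.  Walks are bounded by weight
  roulette (threshold 0.05, survival weight 0.25) and a 600-collision cap;
  capped histories deposit their residual expected capture locally.
* **Estimators.**  The default pipeline mode uses implicit capture — every
  collision scores the expected capture dose w·Σ_c/Σ_t·E per channel and
  the neutron survives with weight w·Σ_el/Σ_t — plus azimuthal averaging
  of the scored grids into 1-voxel radial annuli (the configuration is
  radially symmetric by construction) and a scoring slab of ±0.5 mm around
  the scoring depth at the reduced preset (the z-gradient of the dose is
  on the cm scale, so the averaging bias is far below the noise it
  removes).  Thermal-walk deposits arrive in spatially correlated
  clusters, so the radial profile is additionally smoothed with an
  area-weighted boxcar (half-width 0.1 cm reduced / 0.02 cm full) before
  conversion to dose; the kernel stays well below the ~1 cm lateral
  variation scale.  A pure analogue mode (per-collision channel sampling,
  capture kills) exists alongside and is what the statistical physics
  tests exercise; both modes agree in expectation.
* **Scoring.**  Four co-registered components — boron (α + ⁷Li), thermal
  neutron (¹⁴N(n,p) products), fast neutron (elastic recoils), gamma — in
  Gy per source particle.  They are kept separate even though the thermal
  and fast components share a weight; merging is a report-time option.

## Weighted dose and prescription

The weighted dose is the component sum with per-tissue weights: photon 0.5,
fast 3.2, thermal 3.2, and a carrier-dependent boron CBE of 3.8 (tumour) or
1.3 (brain).  The survival chain uses tumour weights throughout (survival
concerns tumour clonogens); brain weights are available for normal-tissue
reporting, and an MEP-interpolated boron weight exists but is off by
default.  A single scalar normalises the tumour-weighted field so its mean
over GTV cells equals the prescription (73.4 RBE-Gy, one fraction); the raw
components are co-scaled so the chain stays consistent.

## Survival

Per-cell survival probability SP = MEP·exp(−(α d_eff + β d_eff²)) with
α = 0.281 Gy⁻¹, β = 0.02 Gy⁻² (GBM population means), d_eff = d/OER and
OER = 1 for high-LET radiation.  Region survival fractions divide the
expected surviving clonogens of each region by one shared denominator, the
full-plane clonogen count before treatment.  The differential SF uses
0.5 mm concentric rims around the tumour centre; rim values sum exactly to
the total SF.  The CTV-margin statistic is
SF_change = 100·(SF_small − SF_large)/SF_small.  Published photon-therapy
SFs for the same tumour model are bundled as comparison constants; the
x-ray dose chain itself is out of scope.

## Problem sizes

The full-scale configuration (20 µm cells, ~10⁹ histories) is a
cluster-scale computation.  The package's bundled analyses use the
``reduced`` preset — 100 µm scoring cells, 10⁵–10⁶ histories per replicate,
±0.5 mm scoring slab, 0.1 cm profile smoothing — which runs in seconds to a
few minutes on one CPU.  Counts and survival fractions are
resolution-consistent because numerator and denominator live on the same
lattice.  Replicate runs (the default is four) use independent child seeds
spawned from the master seed and are reported as mean ± SD.

## What the surrogate does and does not show

The transport engine is a physically grounded stand-in, not a replica of a
production code: the reactor spectrum is an idealised 1/E epithermal band,
cross sections are 1/v + flat constants, thermal scattering ignores
molecular binding, photons make one flight, and there is no beam divergence
or gamma contamination.  Passing tests therefore demonstrate the internal
consistency and the analytic limits of the chain (attenuation, kinematics,
calibration, LQ arithmetic, normalisation) and the qualitative dosimetric
behaviour (boron dose peaked at the GTV and falling with distance,
five-orders-of-magnitude in-beam cell kill), not absolute agreement with a
full transport calculation under a specific reactor beam.

A consequence worth stating explicitly: the in-beam survival fraction is
exponentially sensitive to the weighted dose at the beam edge.  With the
prescription pinned at the GTV, the surrogate beam delivers ~19–20 RBE-Gy
at r ≈ 2.5 cm, and the bundled reduced-scale runs land at in-beam SFs of
order 10⁻⁵ % (seed-to-seed roughly 10⁻⁶–10⁻⁵ %), dominated entirely by the
outermost in-beam cells.  A beam-edge dose a few RBE-Gy higher — well
within the spread spanned by real reactor spectra, divergence and thermal
scattering treatments — pushes the same quantity below 10⁻⁶ %.  The
penumbra and total SFs carry the same caveat in linear rather than
exponential form.

## Known limitations

* Homogeneous radiosensitivity and an isotropic circular infiltration
  field; no anisotropic spread, no heterogeneity, no hypoxia beyond the
  OER scalar.
* The LQ model underestimates survival at large doses; in-beam SFs are
  best read as "effectively sterilised" rather than literal probabilities.
* Expected-value semantics everywhere: no tumour-control probability or
  birth–death statistics.
* Single fraction, single beam, flat entry surface, no anatomy.
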