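# Methods

## Transmission surrogate

The package models central-axis transmission through t cm of brass as
T(t) = (1 + MSF·t)·exp(−κρt). The exponential term is standard narrow-beam
attenuation with an effective linear coefficient written as κρ so that the
density ρ is the commissionable quantity; κ is a fixed mass-attenuation
constant, default 0.037 cm²/g, a plausible value for brass in a 10 MV
spectrum. The prefactor 1 + MSF·t is the modified-scatter-factor
correction that planning systems apply to the fluence along the primary
ray; at the level of total transmission it is unobservable whether such a
factor acts before or after attenuation, so the product form is assumed.
The two behaviors that matter for commissioning follow directly: ln T is
exactly linear in t when MSF = 0 and acquires ln(1 + MSF·t) curvature
otherwise, which makes ρ and MSF separately identifiable from a
multi-thickness attenuation curve.

Assumptions and deliberate omissions: no beam hardening, divergence, or
off-axis dependence inside the model — depth in water and field size are
carried only as measurement-condition labels, because a real beam's
spectral changes show up as small shifts of the fitted optimum between
conditions rather than as terms the surrogate could absorb. Natural
logarithms throughout.

## χ² slab commissioning

The objective is χ² = Σᵢ (pᵢ − xᵢ)²/|xᵢ| over slabs of nonzero thickness,
with xᵢ = ln(I/I₀) measured and pᵢ modeled. The absolute value in the
denominator keeps the objective non-negative for attenuation data, where
the log-ratios are negative; it equals the plain formula applied to
|ln ratio|. Open-field (t = 0) rows carry the normalization and are
excluded — the weight 1/|x| is undefined there.

The optimizer is the sequential sweep procedure: for each ρ on a grid,
sweep MSF and keep the minimum χ²; the argmin of the resulting
minimum-of-minima curve is the commissioned ρ for one measurement
condition. Conditions are fit independently, the commissioned density is
the unweighted arithmetic mean of the per-condition argmins (reported
overall and per depth stratum), and the final MSF is the argmin of one
last sweep at the aggregate ρ over the pooled records. No iterated
coordinate descent beyond these passes; an exhaustive 2D (ρ × MSF) grid
evaluation is exposed as a cross-check mode (`grid_search_2d`) and is used
in tests to confirm the reduction identity
min-of-minima(ρ) = min over the MSF axis of the 2D surface.

Defaults: ρ ∈ [7.0, 9.0] in steps of 0.1 g/cm³; MSF ∈ [0.0, 0.5] in steps
of 0.05 cm⁻¹ with 0.0001 included so the "essentially no scatter" model is
on the grid. These bracket all physically plausible brass densities and
the scatter-factor range at the resolution commissioning reports are
quoted to. Argmin ties break to the smallest parameter value, which makes
results deterministic and independent of record order.

Known limitation — parameter correlation: ρ and MSF trade off along a
nearly flat valley of the χ² surface (raising MSF and raising ρ have
partially cancelling effects on the three-point attenuation curve). When
the true MSF falls between grid nodes, the recovered ρ can land several
grid steps from the truth at the default resolution even on noise-free
data. Refining both grids shrinks this error monotonically (verified in
tests), and on-grid truths are always recovered exactly, but users fitting
real data near a suspected off-grid optimum should refine the grids rather
than trust a single coarse pass. A simultaneous 2D search over finer grids
is the cross-check for such cases.

## Gamma analysis

γ(r_m) = min over r_c of √(|r_c − r_m|²/DTA² + Δ(r_m, r_c)²/ΔD²), measured
plane as reference. Δ is the percent dose difference between the
calculated dose at r_c and the measured dose at r_m, normalized to the
local measured dose by default ("local" mode) or to the measured-plane
maximum ("global"/Van Dyk mode, implemented but off by default). Measured
points below the low-dose threshold (default 10% of the measured maximum)
are excluded; the threshold is relative to the plane maximum, so at least
one point always evaluates. In local mode, zero-dose points are also
excluded (no denominator); they are only reachable with a zero threshold.

Numerics. The calculated plane is interpolated bilinearly onto a search
lattice with step DTA/10 per axis spanning its full extent; the candidate
set for each measured point is that lattice plus the measured position
itself, which guarantees γ ≡ 0 for identical planes regardless of grid
alignment. The search starts within a radius of 3·DTA and doubles until
the current minimum is *certified*: if the best value found is g and
g ≤ radius/DTA, no candidate outside the radius can beat it, because its
distance penalty alone would exceed g. Reported values are capped at a
configurable maximum (default 2): a value below the cap is the exact
minimum over the full candidate set, a value equal to the cap certifies
the true γ is at least that large. `cap=None` disables capping and always
returns the exact lattice minimum; the failing count (γ > 1) is unaffected
by any cap > 1. A plane passes per point when γ ≤ 1, and the QA statistic
is the failing-point count summed over all fields of a plan.

The failing-count scan (`failing_vs_parameter`) recomputes the calculated
plane of every field at each grid value of one parameter (the other held
fixed) and tabulates total failing points per criteria level, with the
criteria ladder 3%/3 mm, 2%/2 mm, 1.5%/1.5 mm, 1%/1 mm by default. The
loose end of the ladder is expected to be flat near the optimum and the
strict end to discriminate — this pattern is asserted qualitatively in
tests (counts are non-increasing as criteria loosen) rather than as a
specific curve shape.

## Synthetic data

The generator defines the study conditions:

* Slab campaign: thicknesses 0/1/3/5 cm (0 = open-field normalization) at
  depths 2.5/10/20 cm in water and field sizes 5/10/20 cm — nine
  conditions of three informative points each. Readings carry
  multiplicative Gaussian noise (ion-chamber repeatability is proportional
  to signal), log-ratios optionally a −c·t² beam-hardening term, and an
  optional ±2% per-condition perturbation of the effective κ that emulates
  the spread of per-condition optima a real beam shows. With the hardening
  term on and MSF pinned to zero, the fitted density inflates — the
  scatter/hardening-versus-density confound is reproducible on demand.
* Compensators: a sum of a few low-frequency cosine modes plus localized
  Gaussian hills, normalized to [0, 1] and scaled by a roughness parameter
  over [base, max] thickness (defaults 0.6 cm — the typical fabrication
  minimum — to 5 cm, matching the slab range). Gradient magnitude scales
  with roughness by construction.
* Dose planes: open field (flat unit plane by default) times T(t(x, y)),
  on a 2 mm calculation grid; diode measurement is bilinear sampling at
  7 mm pitch plus multiplicative noise. The default plane is 25×25 cm².

What the generator does *not* emulate: photon transport (no lateral
scatter kernels, so compensator gradients blur nothing), flattening-filter
horns, diode angular/field-size response, absolute dosimetry, setup error.
Passing recovery tests therefore demonstrate the *optimization machinery* —
objectives, sweeps, gamma, bookkeeping — not that the surrogate physics
matches a clinical beam; on real measurements the residual χ² would be
dominated by model error, not noise.

All randomness flows through explicit integer seeds (numpy Generator /
SeedSequence); every generator is bit-reproducible given its arguments.

## Study sizes and numerical choices

Recovery and scan tests run at desk scale, chosen as the smallest sizes
that exercise every code path with comfortable statistics: the stochastic
recovery study uses 100 replicate seeds at 0.5% reading noise over the
full nine-condition slab campaign; gamma-oracle equivalence uses twenty
random smooth 15×15 plane pairs at 2%/2 mm, compared point-by-point
against an exhaustive brute-force search with independent bilinear
interpolation; the failing-point scan uses seven fields of 10×10 cm at
7 mm diode pitch over a five-point ρ grid. File formats store doubles with
17 significant digits, so write/read round-trips are exact; χ² chooses the
smallest parameter on exact ties; grid construction rounds arange outputs
to 10 decimals so nominal values like 7.8 are exact grid members.

## Interfaces

Slab sets are CSV (`thickness_cm, depth_cm, field_size_cm, ratio`); dose
planes and compensator maps are ASCII grids with `key value` headers; all
reports are JSON/CSV and embed the resolved configuration and seed needed
to reproduce the run. The `compqa` CLI wires the stages into the two
commissioning workflows (`commission-slabs`, `commission-gamma`) plus
`simulate` and `gamma-compare`; exit codes are 0/1/2 for
success/usage/computation failure.
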