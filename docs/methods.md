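# Methods

`sedflux` reconstructs trace-element and mercury pollution histories from
lake sediment cores: a constant-rate-of-supply (CRS) ²¹⁰Pb chronology with
missing-inventory correction, mass-accumulation rates (MAR), elemental
fluxes, a three-way source apportionment, and contamination assessment
against sediment-quality thresholds.  A forward simulator generates cores
with known ground truth so that every stage is testable without field data.

## Chronology

**Model.** The CRS model assumes a constant flux P (Bq m⁻² yr⁻¹) of
unsupported ²¹⁰Pb to the sediment surface.  With I(m) the residual
unsupported inventory below the cumulative-dry-mass boundary m,

    t(m) = (1/λ) · ln(I₀ / I(m)),        MAR = λ · I / A,

where A is the unsupported activity (Bq kg⁻¹) and λ = ln 2 / 22.3 yr⁻¹
(configurable).  Supported ²¹⁰Pb defaults to the mean of measured ²²⁶Ra;
a deep-asymptote fallback (mean of the deepest three total-²¹⁰Pb values)
covers cores without ²²⁶Ra and warns when those layers do not look like an
equilibrium asymptote.  Unsupported activities are clipped at zero and
flagged, never dropped, so the depth grid stays intact.

**Integration.** Layers are slices, not points: activities are treated as
layer averages, so each layer contributes A·Δm to the inventory integral
(the trapezoidal sum for piecewise-constant layer means) and ages/MARs are
evaluated at layer mass midpoints.  For a layer of duration Δt this
introduces a bias of order (λΔt/2)²/3 in MAR and ln cosh(λΔt/2)/λ in age —
about 1.3% and 0.6 yr for 12-yr layers — which vanishes quadratically as
layers thin (verified at 1.0/0.5/0.25 cm).

**Missing inventory.** Cores truncated above radioactive equilibrium lack
part of the inventory.  We fit ln A against cumulative mass over the
deepest layers whose activity is well resolved (>2σ counting error and
≥5% of the profile maximum), widen the window beyond the 4-point minimum
until it spans at least one e-fold of decay, estimate the slope by
Theil–Sen, and integrate the fitted exponential from the last reliable
boundary to infinity.  The fitted tail *replaces* measurements below that
boundary: near the detection limit, zero-clipped activities form a flat,
positively biased noise plateau that would otherwise inflate deep
inventories, compress deep ages and bias MAR_ref high (we measured up to
2× on noisy synthetic cores before adopting this scheme).  When measured
near-zero layers exist below the trusted boundary, the tail is capped at
twice the inventory they could at most hold — an extrapolation may not
claim more ²¹⁰Pb than the deep core demonstrably lacks.  On noise-free
profiles the scheme reduces exactly to the classic tail fit.

**Dating horizon.** Dating terminates at the first layer whose age
exceeds 150 yr (beyond that, ages rest on <1% of the inventory), whose
midpoint inventory vanishes, or that sits in the deep noise floor
(inventory <5% of total *and* activity below 4× its counting error).  An
isolated low-activity layer higher up — an instantaneous event deposit
diluting the excess ²¹⁰Pb — does not terminate dating: its boundary ages
derive from the inventory, and its inflated apparent MAR is what event
screening keys on.  Undated deeper layers get years by ordinary least
squares of year on midpoint depth over the deepest four dated layers, and
the anchors' mean MAR; extrapolated years are clamped to be no younger
than the deepest dated layer.  Age uncertainties propagate first-order
from activity counting error only; no Monte Carlo.

## Fluxes and apportionment

Per layer i and element, F_tot,i = C_i × MAR_i (μg g⁻¹ × g m⁻² yr⁻¹ =
μg m⁻² yr⁻¹; tables display mg m⁻² yr⁻¹).  The decomposition follows the
background/erosion/atmosphere scheme used for remote-lake records:

* F_B = mean F_tot over included layers with midpoint year before the
  cutoff (default 1900; a sensitivity helper recomputes for 1800/1850).
* F_V,i = F_B · (MAR_i / MAR_ref − 1), with MAR_ref the arithmetic mean
  MAR of included pre-cutoff layers (unweighted — the simplest reading of
  a "pre-cutoff MAR"; an inventory-weighted variant would differ only
  when layer durations vary strongly).
* F_A,i = F_tot,i − F_B − F_V,i.

Conservation holds by construction and is asserted.  Negative F_A is
retained and reported: it diagnoses an overestimated F_B or F_V (e.g. a
catchment depleted in that element after the cutoff), never a physical
negative deposition.  Period shares are computed on time-integrated sums
(flux × layer duration) so that a share weights deposition by the time it
represents, not by how finely it happens to be sliced.  Period means and
"Recent" values (mean of the two topmost included layers) are unweighted
arithmetic means, matching how such tables are conventionally reported;
period membership is by layer-midpoint year.

**Event layers.** Instantaneous deposits (floods, turbidites) carry high
apparent MAR and dilute fluxes; they are excluded from F_B, MAR_ref and
period means.  The automatic rule detrends MAR with an 11-layer centered
rolling median and flags one-sided positive residual spikes beyond 3.5
robust standard deviations (1.4826·MAD, floored at 10% of the median MAR).
A local spike rule, rather than a global z-score, is needed because a
genuine post-1950 MAR doubling would otherwise make half the core an
"outlier"; only sudden local excursions qualify.  Manual exclusion by
layer id is always available and original data are never discarded.

## Assessment and QA

Threshold classification compares period concentrations against LEL
(low effect level), ERL (effect range-low) and TAS (threshold for
agricultural soils); "exceeds" means strictly greater, so an exact tie
reports a factor of 1.0 but classifies below (conservative).  The shipped
threshold table preserves the published values verbatim, including the
documented Hg inconsistency (LEL 0.2 > ERL 0.15), which the validator
reports as a warning rather than an error.  Between-lake comparison forms
element-wise ratios of period summaries, sorted by post-period flux ratio.
Correlation screening uses Pearson r with two-sided p on complete-case
pairs, no multiple-testing adjustment by default (raw p < 0.05 is the
convention being mirrored; apply Holm externally if desired).

QA utilities: recovery correction divides by recovery/100 (off by
default — a constant recovery is a positive scaling that cannot change
temporal trends, ratios or correlations); LOD = mean + 3·sd of blanks
(a conventional choice; blanks live in the digest domain and must be
converted before flagging sediment concentrations); replicate RSD =
100·sd/mean with sample sd (ddof = 1).

## Synthetic cores

The simulator inverts the analysis: annual slabs carry a piecewise-linear
MAR history, unsupported ²¹⁰Pb A(t) = 1000·P/MAR(t)·e^(−λt) with exact
slab inventories (so the whole-core inventory converges to P/λ for any
MAR history), and concentrations C(t) = C_B + F_A(t)/MAR(t).  The
atmospheric pulse is scaled so its time-integrated post-1950 share of
F_tot hits a target fraction exactly; a negative target emulates
post-cutoff catchment depletion and must surface downstream as negative
F_A.  Slabs are cut into fixed-thickness layers by cumulative mass with
exact exponential partitioning, so truth components conserve exactly
(F_B + F_V + F_A = F_tot per layer, pre-noise).

Two presets encode contrasting archetypes.  *remote-highland*: MAR 69
g m⁻² yr⁻¹ before 1950 stepping to 138 (a factor-2 increase), peaking
152 in 1985, dipping to 100 by 1992, recovering to 125 by 2014; supply
150 Bq m⁻² yr⁻¹; supported 25 Bq kg⁻¹; Hg background 0.094 μg g⁻¹ with a
42% post-1950 atmospheric share; slight negative shares for Cr/Ni/Co/Cd.
*peri-urban*: the same MAR history ×5, supported 30 Bq kg⁻¹, large
atmospheric shares for Pb (50%), Hg (40%), As (36%), and three flood
layers (1930, 1972, 1998) injected at background composition with 20% of
ambient excess ²¹⁰Pb (partial water-column scavenging; exactly zero would
make apparent CRS MAR infinite) and zero duration.  Event layers are
unflagged in the emitted profile — detecting them is the pipeline's job —
but fully described in the truth tables.  Background concentrations and
the noise scales follow the published study values: lognormal
multiplicative concentration noise with element CVs in the 7–16%
replicate-RSD range, 5% Gaussian counting noise on activities.  The
organic-matter series (C, with N = C/12.5 and S coupled to C) tracks the
atmospheric pulse shape, emulating organically bound Hg/As transport and
giving the correlation screen a true positive to find.

**What the simulator does not emulate:** bioturbation and other mixing,
compaction-driven porosity gradients (only a linear bulk-density ramp is
available), sediment focusing, non-constant ²¹⁰Pb supply, spectrometric
self-absorption, and spatial heterogeneity between parallel cores.
Passing recovery tests therefore demonstrate the internal consistency of
the method chain under its own assumptions, not robustness to every
process in real archives.

## Problem sizes and defaults

Synthetic spans are 260 yr at 0.5 cm layers (≈25 layers for the remote
preset, ≈96 for the peri-urban one); recovery statistics average 20
seeds; the correlation null uses 1000 repetitions at n = 24.  Key
defaults: λ = ln 2/22.3 yr⁻¹, background cutoff 1900, period split 1950,
extrapolation anchors 4, tail fit minimum 4 layers, dating horizon
150 yr, SNR cutoff 4, MAR spike threshold 3.5.

## Known limitations

* CRS MAR estimates at 3+ half-lives are noise-sensitive (MAR ∝ 1/A);
  with 5% counting error on totals, MAR_ref on the high-MAR preset
  carries a residual positive bias of ~10–15% even after the noise-floor
  safeguards.  This is a property of the method, reported honestly by the
  recovery tests.
* The background flux absorbs any pre-cutoff anthropogenic deposition;
  250-yr records cannot see a truly pristine baseline.
* Apportionment assumes erosion delivers material at background
  composition; a catchment whose soils change composition violates this
  and shows up as (diagnostic) negative F_A.
* Below-LOD concentrations are flagged, not substituted; their treatment
  is left to configuration.
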