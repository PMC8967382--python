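# Methods

This note documents the models, conventions and numerical choices behind
`laminakit`, in the spirit of a package methods section: what is computed,
under which assumptions, and where the genuinely open design decisions
were made.

## Photometry and stimulus protocols

Luminance is carried everywhere as photon flux
(photons·s⁻¹·photoreceptor⁻¹). The LED-arena calibration is a linear map
anchored at the measured pair (51.34 cd/m² ↔ 11.77×10⁵ photons·s⁻¹), with
the neutral-density foil applied as a scalar attenuation. Two attenuation
values are offered: the **measured** one, 14.71×10⁴ / 11.77×10⁵ ≈ 1/8.0
(default, because it reproduces the published photon-flux values exactly),
and the nominal 10⁻⁰·⁹ (flag `nominal_nd=True`, which would give
14.82×10⁴). The exact cd→photons conversion procedure of the original rig
is not reproducible from public information; only the anchored linear
transform is implemented.

Arena intensities live on 16 linearly spaced levels; requested fractions
are snapped to the nearest k/15, so any requested fraction moves by at
most half a level (1/30). The published percentage labels 7/14/27/53(54)%
are treated as rounded {1,2,4,8}/15 level fractions — this reproduces the
printed photon fluxes {0.98, 1.96, 3.92, 7.84, 14.71}×10⁴ — and the 53%
vs 54% discrepancy between the ON and OFF edge-set descriptions is taken
to be rounding of the same 8/15 level. Projector-based imaging screens
are modeled as effectively continuous (quantization disabled), with the
measured maxima 2.17×10⁵ (full-field stimuli) and 2.4×10⁵ (moving edges).

Protocol timing is continuous seconds from protocol start; epochs are
half-open `[t_start, t_end)`. A moving-edge trial is static pattern
(0.5 s) → motion (0.75 s) → inter-trial interval (1 s); conditions are
randomly interleaved (seeded) and presented mirror-symmetrically, each
direction equally often. Within a motion epoch the four edges (48° of
azimuth each, 160°/s) traverse their sector in 0.3 s; the pattern then
resets to the pre-motion level and the traversal repeats, so 0.75 s holds
2.5 traversals. The point-receptive-field luminance series treats each
traversal independently: background until the edge crosses the RF azimuth
(crossing time = angular distance / speed), then edge luminance until the
reset. The staircase presents its levels ascending then descending
(9 epochs per cycle for 5 levels) so the four down-steps carry Weber
contrasts {−0.25, −1/3, −0.5, −1}; the contrast axis for staircase step
responses is Weber contrast relative to the preceding epoch (Michelson
available as an option — the convention is not uniquely determined by the
figure being emulated). Random flashes use a block-shuffled design
(seeded permutations of complete level blocks), which makes level
occupancy near-uniform and guarantees every level appears whenever the
protocol holds at least one full block. The A/B protocol's seven A-step
luminance fractions (0.8 … 0.1 of the adapting level) are a package
choice — the original values are not published — subject to the published
constraints: strictly below the adapting luminance, decreasing, and
paired with B steps at exactly `I_B = 0.75·I_A`.

## Synthetic model neurons

The LMC generator is phenomenological. For a luminance series I(t) the
noise-free response is

    r(t) = polarity · [ w_c·T(t) − w_l·S(t) ] ⊛ K_ca

with

* **T(t)** — transient: at every luminance transition an impulse of
  amplitude equal to the signed Weber contrast of the transition
  (denominator floored at 5% of I_max so steps out of darkness stay
  finite; optionally tanh-saturated with scale `c_half`), decaying
  exponentially with τ_t = 0.25 s;
* **S(t) = (1 − I/I_max)^γ** — sustained darkness drive;
* **K_ca** — unit-area exponential calcium-indicator kernel,
  τ_ca = 0.3 s (the simplest kernel giving the characteristic slow decay;
  exact indicator kinetics are out of scope).

With the normal polarity (−1), a luminance increment produces a negative
transient and the sustained calcium baseline rises as luminance falls —
the standard LMC sign convention (hyperpolarize to ON, depolarize in
darkness). The minus sign between the transient and sustained terms is
deliberate: both observations above must hold simultaneously, and the
downstream ROI filter (keep iff Spearman ρ(ΔF/F, luminance) < 0) must
keep normal cells and reject the inverted-polarity "off-screen" minority
(generated with probability `p_offscreen`, default 0.1).

Cell-type presets are **qualitative** — the underlying gains were never
published as numbers and must not be read as measurements:

| preset | w_c | c_half | w_l | γ | reading |
|---|---|---|---|---|---|
| L1 | 0.6 | 0.4 | 0.4 | 1 | transient + linear sustained; transient saturates at moderate contrast |
| L2 | 1.0 | — (linear) | 0 | 1 | purely transient, larger high-contrast response |
| L3 | 0.15 | 0.4 | 0.8 | 3 | weak transient, strong sustained, dim-light amplification |

Gaussian white noise (σ = 0.03 ΔF/F) is added per sample; raw
fluorescence is `F_base·(1 + r)` with F_base jittered ±20% per ROI. No
photon-shot noise, bleaching, neuropil contamination or spatial
receptive-field structure is modeled — the generator exercises the
pipeline, it does not emulate the photophysics of a real recording, so
passing tests demonstrate correctness of the analysis chain, not
biological effect sizes.

## Synthetic behavior and the trackball model

A model fly's yaw response to one motion epoch is
`direction · A_fly · tanh(|C_M|/0.4) · g(I_edge) · bump(t)` plus a per-fly
direction-independent bias (σ = 0.1 rad/s) and white trial noise
(σ = 0.25 rad/s); `bump` is a smooth half-sine-like envelope over the
750 ms motion window peaking 300 ms after onset (only the peak matters
downstream). A_fly is the genotype amplitude with ±15% per-fly spread.
The luminance gains g(I) are again qualitative presets: *control*
`1 + 0.3·(1 − I/I_max)` (dim edges slightly over-weighted, hence a
slightly negative slope of peak velocity vs log luminance), *flat*,
*dim-underestimating* `0.2 + 0.8·I/I_max` (turning positively correlated
with luminance, as when both luminance-gain inputs are silenced),
*dim-only* `0.2 + 0.8·(1 − I/I_max)²` (rescue restricted to dim light),
plus a near-zero-amplitude transmission-deficient negative control.
Forward walking speed is constant per fly: Normal(8, 2) mm/s floored at
2 mm/s for the walking majority, Uniform(0.3, 1.9) mm/s for a `p_slow`
(default 0.25) subpopulation, so the 2 mm/s rejection rule removes ≈25%
of flies, matching the reported attrition.

The trackball forward model and analyzer share one linear map: a sensor
at equatorial azimuth θ reads horizontal displacement rate `R·ω_yaw`
(identical at any θ) and vertical rate `R·(ω_pitch·sinθ − ω_roll·cosθ)`,
where pitch (rotation about the fly's left–right axis) encodes forward
translation (`forward = R·ω_pitch`, R = 3 mm, sensors at 0° and 90°,
120 Hz). The published derivation of the original rig is not available;
this explicit geometry was chosen because it is self-consistent and
exactly invertible — the decomposition recovers (yaw, pitch, roll) to
machine precision for any sensor pair not coincident mod 180°.

## Imaging pipeline conventions

* **Registration**: reference = max-intensity projection of the first 30
  frames (all frames for shorter movies); integer shifts within ±10 px by
  maximizing cross-correlation (computed via FFT on mean-subtracted
  images). This intentionally replaces the HMM-based motion correction of
  the original toolchain with a simpler, exactly testable method; the
  synthetic movie generator uses periodic (wrap-around) translation so
  planted shifts are recoverable exactly.
* **ΔF/F₀**: F₀ is the whole-trace mean by default; A/B experiments use
  the mean of the 30 s adaptation window. F₀ = 0 is a hard error.
* **Trial averaging**: linear interpolation onto a 10 Hz grid aligned to
  each epoch's onset (half-open epochs), then the mean across repetitions
  of the same epoch label. The interpolation method and boundary
  conventions are explicit package choices; they are not uniquely
  determined by the emulated workflow.
* **ROI filter**: an ROI is kept iff Spearman ρ between its ΔF/F trace
  and the *frame-wise* stimulus luminance is strictly negative; ρ = 0 and
  undefined ρ (constant traces) are rejected. Frame-wise (rather than
  per-epoch) luminance is used because the original choice is unstated.
* **Windows**: "last 2 s" / "last 500 ms" windows are closed on the left
  and open at the epoch end, computed on the 10 Hz grid. Min-max
  normalization for cross-cell-type step comparisons is applied to the
  trial-averaged traces of each ROI (jointly over its epochs) before step
  extraction.

A note on A/B peak responses: the peak is defined relative to the
adapting-period baseline, so for a model cell with a sustained luminance
component the B-step peaks inherit the (luminance-dependent) sustained
offset and are *not* expected to be numerically identical across the
seven −25% Weber pairs; exact equality holds for transient-only cells,
and that is what the test suite asserts.

## Encoding statistics

* **Sigmoid**: `f(x) = a·(1/(1+e^{kx}) − 0.5)` is fitted exactly as
  printed (note f(0) = 0 identically). The model has an exact
  (a,k) → (−a,−k) symmetry, resolved by reporting a ≥ 0; with responses
  that increase with contrast magnitude this yields k < 0, and steepness
  comparisons use |k|. Fitting is nonlinear least squares with
  multi-start over k ∈ {±1, ±5, ±20} and a initialized at the response
  range (no initialization was published). All-zero responses return
  a = 0 with k unidentifiable, flagged rather than raised. The bootstrap
  resamples recording units (flies or ROIs) with replacement, 50 times by
  default, refitting each resample.
* **Mutual information**: the cited estimator is not reproduced in public
  detail, so the default is the transparent plug-in estimator on discrete
  stimulus levels × equal-occupancy response bins (one bin per level),
  with optional shuffle-based bias subtraction (mean MI of 100 label
  permutations); the estimator entry point is pluggable. Plug-in MI is
  biased upward at small samples — the shuffle-corrected value may dip
  slightly below zero on independent data.
* **Non-linearity index**: Pearson r − Spearman ρ of response vs
  luminance; exactly 0 for strictly linear monotone data, positive for
  convex decreasing relationships (the dim-amplifying signature),
  bounded in [−2, 2], invariant under positive affine transforms of
  either variable. Undefined for constant inputs (error).
* **Log-luminance slopes**: ordinary least squares of response on
  log luminance, natural log (the base only rescales the slope; it is
  recorded here once rather than per output). Per-fly fits are
  summarized as mean ± SEM across flies.

## Statistical conventions

The fly is the statistical unit: per-ROI quantities are averaged within
fly first, and all tests run between flies (the hierarchical mean is
exactly invariant to duplicating ROIs within a fly). Group comparisons
route on normality — a two-tailed t-test when **all** groups pass the
Lilliefors test at p > 0.05 (the routing rule is recorded in the output;
the per-group-vs-joint reading is ambiguous in the emulated convention
and "all groups" was chosen), Wilcoxon rank-sum otherwise — with
Holm–Bonferroni correction over the comparison family (per panel by
default, configurable). An experimental group is flagged significant only
when it differs from both of its genetic controls. The permutation test
on rescue-efficiency differences shuffles fly labels between the two
rescue genotypes (1000 draws), uses the add-one convention
(b+1)/(n+1) for two-tailed p-values (avoiding p = 0 at finite n, at the
cost of slight conservatism), and Bonferroni-corrects across luminances.

## Problem sizes and what the tests show

The default synthetic study conditions are desk-scale: 3 flies × 8 ROIs
per cell type for imaging (versus ~9–14 flies, 48–103 cells in vivo),
300 s of randomized flashes, 3 staircase cycles, 10 flies × 4 trials per
condition for behavior, 50 bootstrap resamples, 1000 permutations. The
calibration suites run 200 null replicates of the permutation test and
500 of the ANOVA harness; the qualitative pattern battery runs 20
replicate experiments. With these sizes the full test suite and the
acceptance script each complete in well under a minute per battery.
In vivo effect sizes are deliberately out of scope: the package
demonstrates that the analysis chain recovers the *structure* planted by
the generators (orderings, signs, calibrated error rates, exact round
trips), not that a live fly would produce these numbers.

## Known limitations

* Point receptive fields only; no spatial pooling, no wavelength/optics
  modeling beyond the scalar calibration.
* Additive white Gaussian noise everywhere; no photon-shot or slow-drift
  components, no bleaching.
* Registration is integer-shift translation with periodic boundaries;
  rotations, non-rigid motion and sub-pixel shifts are out of scope.
* ROI masks are inputs; there is no automated segmentation.
* The MI estimate depends on the binning choice at small samples; compare
  values only across conditions analyzed with identical settings.
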