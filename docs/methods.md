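# Methods

## Forward model

The simulator is the minimal tracer system that exhibits the two features
the quantifiers depend on: marked pulmonary retention of ¹²³I-IMP with slow
release into the systemic circulation, and one-tissue brain kinetics whose
influx is proportional to flow.

* **Bolus.** The pulmonary-artery concentration is a gamma variate
  pa(t) = A (t−t₀)^α e^{−(t−t₀)/β}, zero before the appearance time t₀.
  A is set so the analytic integral equals the injected dose, making every
  noise-free curve, frame and sample exactly linear in dose. Defaults:
  t₀ = 5 s, α = 2, β = 4 s (peak at t₀ + αβ = 13 s), dose 167 MBq.
* **Lung.** A single compartment traps a fraction ε of the bolus on first
  pass and releases it at rate k: dL/dt = ε·pa(t) − k·L, L(0) = 0.
  Defaults ε = 0.8, k = 0.1 min⁻¹ — about 80% trapping with a washout
  half-time of ~7 min, so most activity is still pulmonary during the
  2-min dynamic scan.
* **Arterial input.** Ca(t) = fp·pa(t−Δ) + κ·k·L(t): a small direct
  first-pass term (fp = 0.05, transit delay Δ = 3 s) plus the lung release
  scaled by a dilution constant κ (default 1; its absolute value is
  immaterial because REICA/GP are scale-invariant and ARG is calibrated by
  the blood sample).
* **Brain.** One-tissue kinetics dB/dt = f_g·Ca − (f_g/Vd)·B with
  f_g = f_true/100 in mL/(g·min) (brain density 1 g/mL) and Vd = 40 mL/g,
  so k₂ = f_g/Vd (0.0125 min⁻¹ at f = 50). The *measured* brain curve adds
  a vascular term: cbv·Ca/λ with cerebral blood volume fraction cbv = 0.04,
  the whole-blood activity occupying the blood volume.
* **λ.** The lipophilic fraction defaults to 0.8; no authoritative value is
  fixed for this protocol, so it is a configurable placeholder and results
  should be read alongside the λ used.

Integration is fixed-step RK4 at dt = 0.1 s (coupled lung–brain state, the
bolus evaluated analytically on the half-step grid), which is accurate to
well below 0.1% against an adaptive reference integrator (checked in the
tests). Cohort simulations use dt = 0.2 s; at RK4's order the difference is
negligible and the runs are twice as fast.

**Stress.** Acetazolamide is modelled purely as an elevated f_true; no
pharmacokinetics of the vasodilator, and rest/stress sessions share the
injection protocol.

## Frames, noise, samples

Planar frames place three disjoint rectangles (brain, lungs, pulmonary
artery trunk) on a 64×64 grid at 3.9 mm/pixel. Expected counts per pixel
per 2-s frame are sensitivity × frame integral of the region curve ÷ region
pixel count (trapezoidal quadrature on the fine grid); realized counts are
Poisson. ROI sensitivities default to sens_pa = 800, sens_lung = 120,
sens_brain = 12000 counts·s⁻¹ per activity unit, which gives on the order
of 20 kcounts/s over the field of view — a typical planar count rate for a
chest acquisition at this dose. Sensitivities absorb region size, depth and
collimator response; they are not modelled physically.

The 10-min arterial sample measures the whole-blood concentration
(lipophilic ÷ λ), averaged over 4 replicate draws with 2% multiplicative
Gaussian noise (well-counter precision). The ARG static measure is the
brain curve at 30 min with 1% noise. The 30-min static time is a protocol
choice of this package, not a published constant. All noise sources can be
disabled, and every random element descends from one master seed
(`numpy.random.SeedSequence` spawning), so studies are bit-reproducible.

## TAC processing

ROI TACs are masked pixel sums per frame divided by frame duration, stamped
at mid-frame. The low-pass filter is a 5-point centered moving average with
shrinking windows at the edges (unit DC gain everywhere); width is
configurable and no specific filter is canonical for this protocol.
Smoothing precedes time-zero adjustment so arrival detection sees the
denoised curve; the order is configurable. Time zero is the first frame
where the pulmonary-artery TAC reaches 10% of its peak; earlier frames are
discarded, all three curves are re-timed jointly, and the shift is recorded
in the provenance metadata.

## Linear-section selection

Neither graphical method has an objective published rule for "the linear
section", so the package uses: the longest contiguous run of valid points
whose OLS r² ≥ 0.99, requiring at least 10 of the 60 frames, ties broken
toward the later (larger-x) window; if no window qualifies, the best-r²
window of exactly 10 points is used and the result flagged. Valid points
are frames with l(t) > 0 (REICA) or C_r above 5% of its peak (GP — beyond
the bolus the Patlak normalization divides by noise). The search is
verified against brute-force enumeration of every contiguous window.

## Quantifier calibration

* **REICA** slope → flow uses a single factor fitted through the origin
  (factor = Σ slope·f / Σ slope²) on noise-free simulations at
  f = 20…80 mL/100 g/min; clinically this factor would come from
  cross-calibration against the reference method. In the lung-release
  regime the plot is linear with slope ∝ f (the plot's own intercept is
  −f_g κ/(λ·sens_lung) in model units — nonzero, and also ∝ f, which is why
  the through-origin fit of slope vs flow works).
* **GP** keeps SFR = raw Patlak slope (scale 1.0) and applies the published
  line mCBF = 1.87·SFR + 21.2. The vendor standardization behind SFR is
  not reproducible here, so absolute GP levels in the synthetic system sit
  near the intercept; correlations are unaffected (scale-free).
* **ARG** builds m(f) on a grid of 5–120 mL/100 g/min in 0.5 steps and
  inverts by linear interpolation; the grid is fine enough that inversion
  error between nodes is far below 1%. The table is anchored at m(0) = 0,
  so a measured concentration of zero maps exactly to zero flow and
  sub-grid concentrations interpolate toward zero (flagged); concentrations
  above the table maximum raise an error naming the saturation.

## Statistics

p-values for Pearson r use the exact t-transform t = r√(n−2)/√(1−r²) with
n−2 df (not the normal approximation): this reproduces published p-values
from (r, n) alone at n = 33. Comparing the two candidate methods'
correlations with the shared reference uses the Meng–Rosenthal–Rubin
dependent-correlations z-test with r12 estimated from the two methods' own
cross-correlation; the Fisher independent-samples z is available when r12
is unknown. The two tests agree only for weak correlations (their z-ratio,
√(1/h) at r12 = 0, does not vanish with n), which the tests check at
r ≈ 0.05. The dependent test's empirical size under a trivariate-normal
null is verified by simulation.

The validation report regresses each method (y) on the reference (x),
matching the orientation convention of published comparisons, and keeps the
bookkeeping of mixed cohorts: single-session patients contribute mCBF rows
but no CVR row.

## What the simulator does and does not show

Passing tests demonstrate internal consistency: the quantifiers recover the
generator's flows (REICA within 5% after calibration, ARG within 2%,
noise-free), respond monotonically, and the statistics are calibrated. The
generator does **not** emulate inter-patient variability in λ, lung
kinetics or body habitus, γ-attenuation and scatter, camera blur, motion,
or pathology-driven regional heterogeneity — so simulated-cohort
correlations are far higher than any clinical cohort's, and nothing here
validates the quantifiers' absolute accuracy in patients.

## Problem sizes

The default acceptance run uses a 59-patient cohort (92 acquisitions) at
dt = 0.2 s, noise-free recovery sweeps over 13 flow levels at dt = 0.1 s,
and 10,000 null replicates for the test-size check.
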