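# Methods

`vertperf` quantifies lumbar vertebral perfusion from axial dynamic
contrast-enhanced MRI (DCE-MRI), with particular attention to how the
choice of arterial input function (AIF) — aorta, segmental artery, or a
population-normalized curve — propagates into the fitted perfusion
parameters. This note documents the models, the numerical choices, what
the digital phantom does and does not emulate, and the known limitations.

## Signal model and T1 mapping

The steady-state spoiled gradient-echo (SPGR/FLASH) signal is

    S = M0_eff · sin(α) · (1 − E) / (1 − cos(α) · E),   E = exp(−TR/T1),

where `M0_eff` absorbs the equilibrium magnetization and the
flip-angle-independent TE/T2\* decay. Default acquisition constants match
a 1.5-T lumbar protocol: TR 19 ms, TE 4 ms, dynamic flip angle 40°, frame
interval 2 s, variable-flip-angle (VFA) series at 5°, 10°, 20°, 40°, 60°,
80°.

Pre-contrast T1 (`T10`, stored in ms by MR convention) is estimated per
voxel from the VFA series: a DESPOT1 linearization (regress S/sin α on
S/tan α) provides the initial values, refined by bounded nonlinear least
squares with T10 ∈ [50, 5000] ms and an analytic Jacobian. All-zero
voxels and failed fits are flagged `converged=False`, never silently
zeroed. B1 inhomogeneity is not modelled or corrected.

## Signal → concentration

Dynamic signal is converted per voxel through the signal ratio
S(t)/S₀, with S₀ the mean over the first `n_baseline` (default 5)
pre-bolus frames. The ratio cancels `M0_eff` and the T2\* factor, and is
inverted in closed form for T1(t); concentration follows from

    C(t) = (1/r1) · (1/T1(t) − 1/T10),

with relaxivity r1 = 3.6 s⁻¹·mmol⁻¹ (Gd-DOTA at 1.5 T) and T1 converted
to seconds at this step only. Noise can push ratios outside the
physically invertible range; the implied exponential `E1` is clamped to
(1e−6, 1−1e−6) and the voxel-frame flagged, so pixel-wise maps survive
isolated bad frames. Negative concentrations from baseline noise are
retained — flooring them would bias the baseline statistics that the AIF
temporal SNR is computed from. Concentration is labelled "mmol"
throughout, following the source convention for this analysis; mmol/L
(mM) is the conventional reading of that unit.

## AIF construction

Three AIF variants mirror the in-vivo measurement procedure:

* **Aortic (AIF_A)** — mean concentration curve of an aortic ROI.
* **Segmental-arterial (AIF_SA)** — segmental arteries are 1–2 pixels
  wide, so the dynamic series is first baseline-subtracted (each frame
  minus the mean of the first 5 frames), and the single ROI pixel with
  the largest subtracted peak is taken; ties break to the lowest
  row-major index. The asymmetry (ROI mean vs single pixel) is
  deliberate: it reproduces how each vessel is measured in practice.
* **Population (AIF_PA)** — the aortic curve rescaled so its blood peak
  equals 6 mmol (Parker-style population normalization).

The first pass is modelled as a Gaussian bolus plus an exponential
washout gated by a sigmoid:

    Cb(t) = A/(σ√2π) · exp(−(t−T)²/(2σ²)) + α_w · e^(−βt) / (1 + e^(−s(t−τ)))

(the washout amplitude is `alpha_exp` in code, to avoid colliding with
the flip angle). The fit is restricted to a first-pass window — all
frames from the start through peak + 3 points (configurable to 4) — so
recirculation cannot contaminate it. The window never extends past a
detected second-pass arrival (first post-peak local minimum followed by a
rise ≥ 2 baseline SDs; the bolus itself must exceed the baseline mean by
5 baseline SDs to count as detected). The seven-parameter fit is
multi-started over four washout/sigmoid initializations (this corner of
the model is weakly constrained by a short window and has local minima)
with the best residual kept.

Downstream kinetic modelling uses the **fitted model evaluated on the
full time grid**, which extrapolates the first pass past recirculation.
Blood-to-plasma conversion is Cp = Cb/(1 − Hct) with Hct 0.42; the fit is
performed on the blood curve and converted afterwards. Temporal SNR is
max(curve)/SD(baseline frames), computed on the *raw* measured curve. The
bolus arrival index is the first frame where the fitted curve exceeds 10%
of its peak, and must fall after the baseline window.

## Extended Tofts model

Tissue concentration follows the extended (modified) Tofts model

    Ct(t) = vp·Cp(t) + Cp(t) ⊛ Ktrans·exp(−kep·t),   kep = Ktrans/ve.

`kep` is derived, never independently fitted — the model has three free
parameters. Rates are reported in min⁻¹; times stay in seconds internally
with an explicit conversion. The convolution uses a first-order recursion
that is exact for piecewise-linear Cp (implemented as an IIR filter, with
series expansions of the quadrature weights for kep·Δt < 1e−3), avoiding
FFT wrap-around on the 2-s grid; halving the time step changes the output
by under 0.1% at study-scale parameters.

Single-curve fitting is bounded nonlinear least squares over
Ktrans ∈ [0, 10] min⁻¹, ve ∈ [1e−6, 1], vp ∈ [0, 1], multi-started from
three initializations with best-residual selection; if no start converges
the best-effort parameters are returned flagged, so mapping never aborts.
Two ROI strategies are provided: the pixel-wise method (**PWM**: fit
every ROI pixel, summarize mean ± SD over converged pixels, with the
converged fraction recorded; an inclusive summary is also computable
since exclusion rules vary between implementations) and the ROI-based
method (**RBM**: average the ROI curve, fit once).

## AIF sensitivity simulation

The sensitivity experiment fixes a template AIF and a template tissue
curve generated from it (defaults: Ktrans 0.03 min⁻¹, ve 0.12, vp 0.02 —
a healthy-vertebra operating point chosen so that even a 6-fold AIF peak
reduction keeps the rescaled ve inside the physical bound ve ≤ 1), then
fits noisy tissue replicates against *perturbed* AIFs: peaks rescaled by
{1, 1/2, 1/4, 1/6} and arrivals delayed by {0, 1, 2, 3} frames (one frame
= 2 s), in a full factorial. Peak scaling multiplies the whole curve
(shape-preserving); delays shift right with baseline padding, never
circularly. Noise is zero-mean Gaussian on the tissue curve only, in
concentration space, SD = peak/SNR with SNR 20, 1000 replicates per
condition by default (200 in the shipped acceptance checks, for runtime).
The noise distribution family is an assumption; the study it emulates
states only the SNR. One seed spawns independent child streams per
condition, so results are bit-identical across reruns and independent of
condition order. The template AIF defaults to the fitted first-pass
curve; the raw measured curve can be substituted.

Two exact consequences of the model are worth stating because they
constrain what such a simulation *can* show. First, rescaling the AIF by
s rescales the fitted Ktrans, ve and vp by exactly 1/s and leaves kep
invariant — so Ktrans and ve rise as the assumed peak falls, kep is flat,
and **vp scales with the inverse peak factor as a matter of algebra**; a
simulation finding vp unaffected by peak rescaling is inconsistent with
this model. Second, with a self-consistent template (tissue generated
from the unperturbed AIF), *delaying* the assumed AIF mis-places the
vp·Cp bolus bump and lowers fitted vp. Fitted vp rises with delay only
when the tissue's true input lags the template AIF — as a measured
vertebral curve does, because vertebrae are fed via segmental arteries
that the bolus reaches about one frame after the aorta. The
`tissue_lag_frames` option (default 0, self-consistent) reproduces that
regime; with a lag of 2–3 frames, fitted vp increases monotonically over
delays 0–3.

## The digital phantom

The phantom stands in for patient scans (none are publicly deposited): a
64×64 slice, 220 frames × 2 s (440 s), containing an aortic disk, a
7×7-pixel segmental-artery search box enclosing a 2-pixel artery (so
max-peak pixel selection is exercised), a vertebral disk, and static
background. Region curves: arteries follow the first-pass model plus a
dispersed recirculation bump (fraction 0.3 of the first-pass peak, 36 s
after the bolus center, 1.5× width); the aortic blood peak is 5.04 mmol
and the segmental 1.81 mmol with a one-frame extra delay, the in-vivo
means. The vertebra is the extended Tofts response (Ktrans 0.05 min⁻¹,
ve 0.30, vp 0.025) to the *first-pass* aortic plasma curve — the
recirculation-free input that the downstream fitted AIF represents, which
is what makes the noiseless pipeline exactly invertible. All curves are
encoded as SPGR signal at region T10 values (blood 1400 ms, vertebra
700 ms, background 900 ms), and the VFA images are generated from the
same T10 map.

Two numerical choices deserve note. The ground-truth washout is a
plateau (β = 0): the washout decay rate is not identifiable from a
first-pass window, so a decaying truth would make the fitted AIF's 400-s
extrapolation — and with it the round-trip recovery — arbitrarily wrong
even on noiseless data. β remains a free, bounded parameter of the fit.
And the bolus is centered at 33 s (10%-of-peak arrival ≈ 24 s) so the
Gaussian tail is negligible (< 1e−7 of peak) inside the 10-s baseline
window; the artery curves are zeroed over the baseline frames, making S₀
an exact pre-contrast signal.

Noise is added in signal space (the more realistic side; the simulation
module adds it in concentration space, matching the stated simulation
design — both are documented deliberately): an i.i.d. per-pixel component
(SD 2 aorta, 5 segmental artery, 2.5 vertebra, 3 background, against a
baseline tissue signal of ~35–70 at M0_eff 1000) plus a small per-frame
fluctuation shared across each vessel's pixels (SD 0.5), which ROI
averaging cannot remove and which therefore bounds the measured AIF
temporal SNR. The vertebra SD is calibrated so the tissue curve's
temporal SNR (peak/SD) is ≈ 20, the simulation operating point.
Regeneration from the same spec and seed is bit-identical, and the
manifest records every generation parameter.

What passing phantom tests do **not** show: the phantom has no B1 error,
no motion, no inflow or partial-volume physics (the 2-pixel artery only
exercises the selection logic), Gaussian rather than Rician noise, a
homogeneous vertebra, and mutually consistent forward/inverse models —
so round-trip accuracy on the phantom is an identifiability statement
about the pipeline, not an accuracy claim about patient data.

## Statistics

Paired contrasts use the Wilcoxon signed-rank test (zero differences
dropped; all-zero input reported degenerate with p = 1), unpaired
two-group contrasts the Mann–Whitney U test, multi-group contrasts the
Kruskal–Wallis test with Dunn pairwise z-tests under Bonferroni
correction (adjusted p = min(1, pairs × p)). All tests are two-sided.
Small samples get exact nulls — signed-rank and rank-sum distributions by
dynamic programming over doubled midranks (valid under ties), and the
Kruskal–Wallis permutation null by exhaustive enumeration of group
assignments — switching to tie-corrected normal / χ² approximations
(no continuity correction) above 12 total observations. The exact
thresholds are a determinism choice, sized so enumeration stays
instantaneous. Note one subtlety: monotone-transform invariance holds for
the tests that rank pooled observations (Mann–Whitney, Kruskal–Wallis)
but *not* for the signed-rank test, which ranks difference magnitudes.

Vertebrae are treated as independent observations when pooled (16
vertebrae from 8 subjects in the emulated design); the two-per-subject
clustering is not modelled — a deliberate mirror of the emulated
analysis, and a caveat on its p-values.

## Known limitations

* The washout decay β of the first-pass model is weakly identified from a
  short window; under noise the fitted extrapolated tail occasionally
  collapses, saturating fitted ve at its upper bound. This is a property
  of window-restricted AIF fitting itself and is left visible rather than
  regularized away.
* The in-vivo pattern "ROI-based ve exceeds pixel-wise ve" does not
  emerge from this phantom under Gaussian concentration noise — pixel-wise
  ve biases upward at low SNR here, and the heterogeneity patterns tried
  gave the ROI-based fit the *lower* ve. The pixel-wise Ktrans/kep
  inflation relative to the ROI-based fit does emerge (heterogeneous
  ROIs) and is tested.
* Problem sizes in the shipped checks (200 simulation replicates per
  condition, ~200-pixel vertebra, 64×64 phantom) are the package's
  desk-scale defaults; all are spec fields and scale up directly.
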