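# vertperf

Quantitative perfusion analysis of lumbar vertebrae from axial dynamic
contrast-enhanced MRI (DCE-MRI), built around one question: **how does the
choice of arterial input function (AIF) change the perfusion parameters you
report?** Each lumbar vertebra is supplied by a pair of segmental arteries
branching off the aorta, and an axial slice captures both vessels at once —
so the same vertebral tissue curve can be fitted against a patient-specific
aortic AIF, a patient-specific segmental-arterial AIF, or a
population-normalized (Parker-style) AIF, and the answers differ
systematically.

The package is aimed at researchers doing tracer-kinetic analysis of bone
marrow / vertebral DCE-MRI who want a tested, scriptable pipeline and a
ground-truth phantom to validate it against.

## What it implements

* **Relaxometry** — spoiled gradient-echo (SPGR) forward signal model,
  variable-flip-angle T1 mapping (DESPOT1 initialization + bounded
  nonlinear refinement), and closed-form conversion of dynamic signal to
  gadolinium concentration via `C(t) = (1/r1)(1/T1(t) − 1/T10)`.
* **AIF construction** — baseline-subtracted vessel highlighting, max-peak
  pixel selection for the thin segmental artery, aortic ROI averaging,
  first-pass windowing, and fitting of the first-pass model
  `Cb(t) = A/(σ√2π)·exp(−(t−T)²/2σ²) + α·e^(−βt)/(1+e^(−s(t−τ)))`,
  plus hematocrit correction `Cp = Cb/(1−Hct)`, temporal SNR, and
  population normalization of the blood peak to 6 mmol.
* **Extended Tofts model** —
  `Ct(t) = vp·Cp(t) + Cp(t) ⊛ Ktrans·e^(−kep·t)` with `kep = Ktrans/ve`,
  fitted by bounded multi-start least squares; pixel-wise (PWM) and
  ROI-based (RBM) parametric mapping.
* **AIF sensitivity simulation** — perturb the AIF peak (×1, 1/2, 1/4, 1/6)
  and delay (0–3 frames), fit 1000 noisy tissue replicates per condition at
  SNR 20, and summarize the parameter distributions.
* **Digital phantom** — a 64×64, 440-s synthetic acquisition with known
  T1 map, AIF shapes (aortic peak 5.04 mmol, segmental 1.81 mmol, one-frame
  delay), recirculation, and vertebral Tofts kinetics, so every pipeline
  stage can be validated against ground truth.
* **Statistics** — Wilcoxon signed-rank, Mann–Whitney U, and
  Kruskal–Wallis with Dunn–Bonferroni post hocs, with exact small-sample
  null distributions.

See `docs/methods.md` for the models, parameter defaults, and limitations.

## Worked example

```python
import numpy as np
from vertperf import PhantomSpec, generate_phantom
from vertperf.pipeline import analyze

bundle = generate_phantom(PhantomSpec(seed=1))   # noisy synthetic scan
an = analyze(bundle.vfa, bundle.dynamic, bundle.masks,
             bundle.spec.protocol, methods=("rbm",))
for kind in ("aortic", "segmental", "population"):
    aif = an.aifs[kind]
    print(f"{kind:10s} peak {aif.peak:6.2f} mmol   SNR {aif.snr:7.1f}   "
          f"arrival {aif.arrival_time:5.1f} s")
for kind in ("aortic", "segmental"):
    s = an.fits[(kind, "rbm")].roi_summary()
    print(f"RBM/{kind:10s} Ktrans {s['ktrans'][0]:.4f} min^-1   "
          f"kep {s['kep'][0]:.4f} min^-1   ve {s['ve'][0]:.3f}   vp {s['vp'][0]:.4f}")
```

prints

```
aortic     peak   5.14 mmol   SNR  1210.5   arrival  25.0 s
segmental  peak   1.69 mmol   SNR    50.4   arrival  27.0 s
population peak   6.00 mmol   SNR  1210.5   arrival  25.0 s
RBM/aortic     Ktrans 0.0508 min^-1   kep 0.1634 min^-1   ve 0.311   vp 0.0244
RBM/segmental  Ktrans 0.2375 min^-1   kep 0.2375 min^-1   ve 1.000   vp 0.0552
```

Reading this: the aortic AIF has the larger peak and far higher temporal
SNR; the segmental AIF arrives one frame (2 s) later. Fitting the *same*
vertebral tissue against the smaller segmental AIF inflates Ktrans
(0.24 vs 0.05 min⁻¹) and ve (saturating at 1.0) — the AIF-choice effect
the package exists to quantify. The ground truth behind this phantom is
Ktrans 0.05 min⁻¹, ve 0.30, vp 0.025; on a noiseless phantom the aortic
fit recovers it to better than 0.1%.

The same steps are available from the shell:

```bash
vertperf phantom --seed 1 --out phantom/
vertperf t1map --vfa ... --angles 5,10,20,40,60,80 --tr 19 --out t1
vertperf conc --dyn phantom/dynamic.nii.gz --t1map t1 --flip 40 --out conc.nii.gz
vertperf aif-fit --conc conc.nii.gz --roi phantom/mask_aorta.json --kind aortic
vertperf tofts-fit --conc conc.nii.gz --roi phantom/mask_vertebra.json \
    --aif aif_aortic.csv --method rbm
vertperf simulate --seed 42 --n-rep 1000 --out simulation.csv
```

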