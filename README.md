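# hsvmcc — energy-efficient activity recognition at low sampling rates

`hsvmcc` recognises six everyday activities — sitting, standing, walking,
running, climbing upstairs and going downstairs — from a smartphone-class
accelerometer and barometer sampled at rates as low as **1 Hz**, far below
the Nyquist rate of human gait (~2 Hz activity frequency). It is aimed at
people building always-on mobile/wearable recognition pipelines where the
sensor and the arithmetic, not the classifier, dominate the battery budget.

Three ideas make this work:

1. **Rate/window equivalence.** Window statistics, not waveforms, drive
   recognition. For a quasi-periodic activity signal, two sampling schemes
   with equal products `FS₁·T₁ = FS₂·T₂` (rate × window) collect the same
   number of samples per window and equivalent window statistics, so a
   sub-Nyquist rate `FS₃ < 2·Fa` can be compensated by lengthening the
   window to `T₃ = 2·Fa·T / FS₃` (e.g. Fa = 2 Hz, T = 1 s, FS₃ = 1 Hz →
   T₃ = 4 s; in practice a 5 s window is used).

2. **A hierarchical SVM (H-SVM).** Six cheap window features — signed and
   absolute pressure change `Pd`, `Pdabs`; per-axis acceleration means
   `Xmeans, Ymeans, Zmeans`; and the motion-energy feature
   `Twave = Σᵢ √(ΔXᵢ² + ΔYᵢ² + ΔZᵢ²)` — feed a binary tree of N−1 linear
   SVMs for N classes. The tree is grown by 2-means clustering candidate
   features (cheapest sensor first) and keeping the purest, most
   class-balanced split at each node. On the six activities this yields the
   five-node tree: `Pdabs` (stairs vs flat) → `Pd` (up vs down) and
   `Ymeans` (sitting) → `Ymeans` (running) → `Twave` (standing vs walking).
   A prediction evaluates at most one root-to-leaf path.

3. **Context-based correction.** Activities persist across windows, so each
   raw label is corrected by the mode of the 2k+1 labels centred on it
   (keeping the centre when it is itself a mode). Under i.i.d. per-window
   error ψ the corrected accuracy is the binomial tail
   `Σ_{i≤k} C(2k+1, i) ψⁱ (1−ψ)^{2k+1−i}`; the marginal gain collapses
   after k = 1 for realistic ψ ≤ 0.2, so the default window is 3 (delay of
   one window).

Because no public recordings accompany the method, the package ships a
seeded synthetic generator (`hsvmcc.synth`) that emulates the statistical
structure the classifier relies on — gravity on the +Y axis when upright, a
reclined device while sitting, motion energy ordered standing < walking <
running, and signed barometric drift on stairs.

## Worked example

Train on the default 90-window synthetic set (15 windows × 6 activities at
1 Hz, 5 s windows), classify a fresh six-activity session, smooth with
k = 1 and score:

```
$ hsvmcc pipeline --seed 0 --test-seconds 305
raw macro accuracy       99.7%
smoothed macro accuracy 100.0%  (5 SVM nodes, k=1)
```

The raw figure is the macro (per-class) accuracy of the bare five-node
H-SVM over 354 test windows; the smoothed figure shows the mode-window
correction removing the remaining isolated errors. The closed-form accuracy
model behind the choice of k:

```
$ hsvmcc accuracy-model --psi 0.3 --psi 0.1 --k-max 3
  k   psi=0.3     psi=0.1
  0   0.7000      0.9000
  1   0.7840      0.9720
  2   0.8369      0.9914
  3   0.8740      0.9973
```

Reading the ψ = 0.3 column: growing the vote window from 1 (k = 0) to 3
(k = 1) lifts accuracy by 8 percentage points; further growth pays less and
costs one extra window of reporting delay per step.

The same workflow is available as composable commands
(`simulate → features → train → classify → smooth → evaluate`) and as a
library (`HierarchicalSVMClassifier`, `ContextSmoother`,
`run_synthetic_pipeline`, ... — scikit-learn estimator conventions).

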