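# ecgkit

Noise-robust ECG beat classification, end to end: simulate annotated
arrhythmia beats, corrupt them with parametrized noise, denoise with
wavelet / median / Gaussian / hybrid operators, quantify signal fidelity,
and train a lightweight 1D CNN on noisy versus denoised beats.

The package is for researchers and students in biomedical signal processing
who want a self-contained, fully reproducible testbed for the question *how
much does denoising help downstream classification?* — without downloading
any external recordings.  Every stage also reads/writes plain per-beat CSV,
so the same pipeline runs on real beat datasets.

## The science in brief

Beats come in five classes (MIT-BIH annotation symbols): normal (N), left
and right bundle branch block (L, R), atrial premature (A) and premature
ventricular contraction (V).  Clean beats x are corrupted by exactly one of
five processes — additive Gaussian, salt-and-pepper impulses, multiplicative
speckle, additive uniform, mean-centred exponential — and denoised by:

* median filter: y[n] = median(x[n−k], …, x[n+k])
* Gaussian filter: convolution with a normalized kernel of SD σ samples
* wavelet thresholding: x′ = W⁻¹(T(W(x))) with soft shrinkage
  T(d) = sign(d)·max(|d| − λ, 0) of the detail bands (per-band SURE λ by
  default; universal λ = σ̂√(2 ln N) available)
* hybrid: median filter applied to the wavelet-denoised signal

Fidelity of an estimate y′ against the clean y is measured by
MSE = Σ(yᵢ−yᵢ′)²/n, MAE = Σ|yᵢ−yᵢ′|/n, R² = 1 − SS_res/SS_tot and the
Pearson correlation r.  Classification is scored by accuracy, per-class and
macro precision/recall/F1, and the 5×5 confusion matrix.

The classifier is a lightweight 1D CNN — four Conv1D+MaxPool blocks,
dropout, a dense ReLU layer with L2 and a softmax head — implemented
directly on numpy so that training is bit-deterministic under a fixed seed.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

```python
import numpy as np
from ecgkit import (make_dataset, normalize, NoiseSpec, apply_noise,
                    DenoiseConfig, denoise, compute_fidelity)

beats = make_dataset([500] * 5, seed=1)          # 2,500 labelled beats
x = normalize(beats.segments[0])                  # one clean beat in [-1, 1]
noisy = apply_noise(x, NoiseSpec("gaussian", 0.1, seed=2))
clean_again = denoise(noisy, DenoiseConfig(method="hybrid"))

print("noisy   :", compute_fidelity(x, noisy))
print("denoised:", compute_fidelity(x, clean_again))
```

```
noisy   : FidelityReport(mse=0.01000..., mae=0.08072..., r_squared=0.77485..., pearson_r=0.89749...)
denoised: FidelityReport(mse=0.00206..., mae=0.03512..., r_squared=0.95346..., pearson_r=0.97802...)
```

Hybrid denoising cuts the mean squared error roughly five-fold and lifts the
correlation with the clean beat from 0.90 to 0.98.

The same stages are available from the shell:

```bash
ecgkit synth --n-per-class 100 --seed 1 --out beats.csv
ecgkit noise --kind gaussian --intensity 0.1 --seed 2 --in beats.csv --out noisy.csv
ecgkit denoise --method hybrid --in noisy.csv --out denoised.csv
ecgkit metrics --original beats.csv --estimate denoised.csv
ecgkit bench-denoise --seed 1 --out results/
ecgkit bench-classify --seed 1 --out results/
```

`bench-denoise` writes the fidelity table (methods × {MSE, R², MAE,
Correlation} with the shared noisy baseline row); `bench-classify` trains
two CNNs from identical initial weights — one on noise-corrupted beats, one
on the same beats after hybrid denoising — and writes both classification
reports, confusion matrices and per-epoch history CSVs.  Reruns with the
same seed reproduce every output byte for byte.

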