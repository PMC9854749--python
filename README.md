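# ivimtex

Quantitative diffusion-MRI analysis of pancreatic masses: IVIM-DKI
parametric map fitting with a 3D total-variation (TV) spatial penalty,
whole-volume 3D texture analysis of the resulting maps, and machine
learning-based lesion classification — with a seeded digital-phantom
generator so the entire pipeline can be exercised and validated without
patient data.

## The problem

Distinguishing pancreatic ductal adenocarcinoma (PDAC) from
neuroendocrine tumors (pNET), mass-forming chronic pancreatitis (MFCP)
and solid pseudopapillary neoplasms (SPEN) on conventional imaging is
hard. Multi-b-value diffusion-weighted MRI probes tissue microstructure
and perfusion quantitatively: the signal of a voxel acquired at diffusion
weighting *b* (s/mm²), normalized to the *b* = 0 signal, follows the
hybrid intravoxel-incoherent-motion + diffusion-kurtosis (IVIM-DKI)
model

    S/S₀ = f·e^(−b·D*) + (1 − f)·e^(−b·D + (1/6)·b²·D²·k)

with true diffusion coefficient **D** (mm²/s), pseudo-diffusion
coefficient **D\*** (mm²/s), perfusion fraction **f**, and kurtosis
**k**. The apparent diffusion coefficient (ADC) comes from the
monoexponential model S/S₀ = e^(−b·ADC) at b ∈ {0, 500, 800, 1000}.

Fitting all four parameters voxel-by-voxel (bounded trust-region least
squares) produces noisy, non-physiological heterogeneity — especially in
D\*. The **IDTV** model regularizes the fit with the anisotropic total
variation (L1 norm of the discrete gradient) of each 3D parametric map,
applied over the whole volume at once, which suppresses spurious voxel
noise while preserving lesion edges.

The fitted maps are then characterized by 30 texture features (9 GLCM,
13 GLRLM, 3 global, 5 NGTDM; 26-voxel connectivity, 64 gray levels),
ranked by a chi-square test of independence against the class label, and
the top-10 features feed a five-hidden-layer neural network
(221, 16, 3, 2, 2; tanh; softmax; L2 λ = 0.0061374) evaluated under
stratified 5-fold cross-validation repeated 100 times.

## Worked example

```python
import numpy as np
from ivimtex.phantom import PhantomConfig, make_phantom
from ivimtex.fitting import FitConfig, fit_standard_volume, fit_idtv_volume

case = make_phantom(PhantomConfig(shape=(16, 16, 8),
                                  lesion_radii=(4, 4, 2.5),
                                  snr_b0=20.0, seed=3))
std  = fit_standard_volume(case.signal4d, case.scheme, case.organ_mask)
idtv = fit_idtv_volume(case.signal4d, case.scheme, case.organ_mask,
                       FitConfig(model="idtv"))

les = case.lesion_mask
for name in ("d", "f", "k"):
    s, i = getattr(std.maps, name)[les], getattr(idtv.maps, name)[les]
    t = getattr(case.truth, name)[les]
    print(f"{name}:  CV {np.std(s, ddof=1)/s.mean()*100:5.1f}% -> "
          f"{np.std(i, ddof=1)/i.mean()*100:5.1f}%   "
          f"RMSE {np.sqrt(np.mean((s-t)**2)):.3g} -> "
          f"{np.sqrt(np.mean((i-t)**2)):.3g}")
```

prints (PDAC-class phantom, SNR 20 at b = 0):

```
d:  CV  23.7% ->  17.8%   RMSE 0.000276 -> 0.000133
f:  CV  51.3% ->  17.2%   RMSE 0.11 -> 0.0293
k:  CV  20.3% ->   4.7%   RMSE 0.147 -> 0.0636
```

i.e. TV regularization cuts the within-lesion coefficient of variation
of the D, f and k maps (here by 25–77%) and more than halves their
error against the known ground truth, while the mean adjusted R² of the
fit stays essentially unchanged (0.983 → 0.981).

A command-line interface chains the stages on NIfTI volumes:

```sh
ivimtex simulate --n-per-class 2,1,0,0 --shape 16,16,8 --seed 7 --out cohort/
ivimtex fit --model idtv --in cohort/PDAC_000/signal.nii.gz \
        --bvals cohort/PDAC_000/bvals.txt \
        --mask cohort/PDAC_000/organ_mask.nii.gz --out fitted/
ivimtex texture --map fitted/fit_idtv_f.nii.gz \
        --mask cohort/PDAC_000/lesion_mask.nii.gz --out features.csv
```

## Layout

| module | contents |
| --- | --- |
| `ivimtex.models` | signal equations, parameter bounds, b-value scheme |
| `ivimtex.fitting` | voxelwise ADC / IVIM-DKI fits, IDTV alternation |
| `ivimtex.tv` | masked anisotropic TV norm and ROF denoiser |
| `ivimtex.texture` | quantization + GLCM / GLRLM / global / NGTDM features |
| `ivimtex.stats` | CV, Kruskal–Wallis + rank post-hoc, Wilcoxon, ROC |
| `ivimtex.ml` | chi-square ranking, ANN, repeated stratified CV |
| `ivimtex.phantom` | seeded digital phantoms and cohorts |
| `ivimtex.experiments` | end-to-end seeded experiment drivers |
| `ivimtex.io`, `ivimtex.cli` | NIfTI/CSV/JSON I/O and the CLI |

See `docs/methods.md` for the model assumptions, algorithmic choices and
limitations.
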