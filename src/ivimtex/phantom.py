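"""Seeded digital pancreas phantoms for the IVIM-DKI pipeline.

A phantom is a 3D grid holding an ellipsoidal "organ" with an embedded
ellipsoidal lesion of one of four classes (PDAC, pNET, MFCP, SPEN).
Ground-truth parameter fields are piecewise smooth: class mean plus a
smooth Gaussian-random-field perturbation scaled to the class SD
(truncated to a physiologic interior of the fit box), so TV
regularization has realistic structure to exploit. Signals follow the IVIM-DKI forward model on the
14-b-value pancreatic scheme and are corrupted by Rician magnitude noise
averaged over the per-b number of signal averages.

Class parameter means/SDs are the reported pancreatic lesion values
(D and D* in mm²/s):

=====  ==============  ===============  ===========  =========
class  D               D*               f            k
=====  ==============  ===============  ===========  =========
PDAC   1.5e-3±0.4e-3   41.6e-3±16.8e-3  0.17±0.06    0.7±0.2
pNET   1.2e-3±0.4e-3   69.5e-3±36.4e-3  0.23±0.05    1.0±0.4
MFCP   1.5e-3±0.3e-3   50.6e-3±13.7e-3  0.21±0.05    0.7±0.2
SPEN   1.3e-3±0.3e-3   46.4e-3±27.7e-3  0.19±0.05    0.9±0.3
=====  ==============  ===============  ===========  =========

The healthy-background values (D=1.7e-3, D*=20e-3, f=0.12, k=0.6) are
INVENTED plausible normal-pancreas defaults, not reported values; studies
relying on background tissue must override them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .fitting import ParamMaps, fit_adc_voxel
from .models import UPPER, BValueScheme, DiffusionParams, default_scheme

__all__ = [
    "CLASS_PARAMS",
    "BACKGROUND_PARAMS",
    "PhantomConfig",
    "PhantomCase",
    "make_phantom",
    "add_rician_noise",
    "make_cohort",
]

# (mean, sd) per parameter, order D, Dstar, f, k
CLASS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "PDAC": {"D": (1.5e-3, 0.4e-3), "Dstar": (41.6e-3, 16.8e-3),
             "f": (0.17, 0.06), "k": (0.7, 0.2)},
    "pNET": {"D": (1.2e-3, 0.4e-3), "Dstar": (69.5e-3, 36.4e-3),
             "f": (0.23, 0.05), "k": (1.0, 0.4)},
    "MFCP": {"D": (1.5e-3, 0.3e-3), "Dstar": (50.6e-3, 13.7e-3),
             "f": (0.21, 0.05), "k": (0.7, 0.2)},
    "SPEN": {"D": (1.3e-3, 0.3e-3), "Dstar": (46.4e-3, 27.7e-3),
             "f": (0.19, 0.05), "k": (0.9, 0.3)},
}

# INVENTED normal-pancreas defaults (not from any reported table).
BACKGROUND_PARAMS = DiffusionParams(D=1.7e-3, Dstar=20e-3, f=0.12, k=0.6)

PARAM_ORDER = ("D", "Dstar", "f", "k")
ADC_TRUTH_B = (0.0, 500.0, 800.0, 1000.0)

# Physiologic truncation floor for sampled fields (a strict subset of the
# fit box). The box boundaries themselves are degenerate tissue: D* = 0
# makes the perfusion compartment non-decaying and the model
# non-identifiable, so random fields are kept strictly interior.
FIELD_LOWER = np.array([1e-4, 3e-3, 0.01, 0.05])


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (32, 32, 12)
    lesion_class: str = "PDAC"
    class_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: CLASS_PARAMS
    )
    background: DiffusionParams = BACKGROUND_PARAMS
    background_rel_sd: float = 0.10  # SD as fraction of the background mean
    lesion_center: tuple[float, float, float] | None = None  # default: grid center
    lesion_radii: tuple[float, float, float] = (6.0, 6.0, 3.0)
    organ_radii: tuple[float, float, float] | None = None  # default: 0.45 * shape
    smoothness_fwhm: float = 3.0  # voxels, within-lesion heterogeneity scale
    snr_b0: float = 20.0  # b=0 signal-to-noise ratio; inf = noiseless
    seed: int = 0
    scheme: BValueScheme = field(default_factory=default_scheme)
    compute_adc_truth: bool = True  # skip the per-voxel ADC fit when False

    def __post_init__(self) -> None:
        if self.snr_b0 <= 0:
            raise ValueError("snr_b0 must be positive")
        if self.lesion_class not in self.class_params:
            raise ValueError(f"unknown lesion class {self.lesion_class!r}")
        center = self.lesion_center or tuple((s - 1) / 2.0 for s in self.shape)
        self.lesion_center = center
        if self.organ_radii is None:
            self.organ_radii = tuple(0.45 * s for s in self.shape)
        for c, r, s in zip(center, self.lesion_radii, self.shape):
            if r <= 0 or c - r < -0.5 or c + r > s - 0.5:
                raise ValueError("lesion ellipsoid must lie inside the grid")


@dataclass
class PhantomCase:
    truth: ParamMaps
    signal4d: np.ndarray
    lesion_mask: np.ndarray
    organ_mask: np.ndarray
    label: str
    scheme: BValueScheme
    case_id: str = ""


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _smooth_field(shape, rng, fwhm: float) -> np.ndarray:
    """Unit-SD smooth Gaussian random field."""
    sigma = fwhm / 2.3548
    fld = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def add_rician_noise(
    clean: np.ndarray,
    sigma: float,
    nsa: int | np.ndarray = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rician magnitude noise averaged over ``nsa`` acquisitions.

    Each acquisition observes sqrt((S + n1)² + n2²) with n1, n2 ~
    N(0, sigma²); the returned value is the mean of the nsa magnitudes
    (magnitude averaging, as done on the scanner console). sigma = 0
    returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    clean = np.asarray(clean, dtype=float)
    nsa = int(nsa)
    if nsa < 1:
        raise ValueError("nsa must be >= 1")
    if sigma == 0:
        return clean.copy()
    rng = rng or np.random.default_rng()
    draws = np.sqrt(
        (clean[None] + rng.normal(0, sigma, (nsa,) + clean.shape)) ** 2
        + rng.normal(0, sigma, (nsa,) + clean.shape) ** 2
    )
    return draws.mean(axis=0)


def make_phantom(cfg: PhantomConfig) -> PhantomCase:
    """Generate one phantom case; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape)
    organ = _ellipsoid(shape, tuple((s - 1) / 2.0 for s in shape),
                       cfg.organ_radii)
    lesion = _ellipsoid(shape, cfg.lesion_center, cfg.lesion_radii)
    lesion &= organ
    if lesion.sum() == 0:
        raise ValueError("degenerate geometry: lesion contains no voxels")

    cls = cfg.class_params[cfg.lesion_class]
    bg = cfg.background.as_array()
    fields = np.zeros((4,) + shape)
    for i, name in enumerate(PARAM_ORDER):
        mean_l, sd_l = cls[name]
        fld_l = mean_l + sd_l * _smooth_field(shape, rng, cfg.smoothness_fwhm)
        fld_b = bg[i] * (1.0 + cfg.background_rel_sd
                         * _smooth_field(shape, rng, cfg.smoothness_fwhm))
        fld = np.where(lesion, fld_l, fld_b)
        fields[i] = np.clip(fld, FIELD_LOWER[i], UPPER[i])
    # keep the kurtosis exponent in its validity region (b_max <= 3/(D k)),
    # otherwise the forward signal diverges at the highest b-values
    b_max = cfg.scheme.b[-1]
    k_cap = np.maximum(3.0 / (b_max * fields[0]), FIELD_LOWER[3])
    fields[3] = np.minimum(fields[3], np.minimum(k_cap, UPPER[3]))

    bv = cfg.scheme.b
    D, Dstar, f, k = fields
    clean = np.zeros(shape + (bv.size,))
    bD = D[..., None] * bv
    clean = (f[..., None] * np.exp(-bv * Dstar[..., None])
             + (1.0 - f[..., None]) * np.exp(-bD + bD ** 2 * k[..., None] / 6.0))
    clean[~organ] = 0.0

    if np.isinf(cfg.snr_b0):
        signal = clean.copy()
    else:
        sigma = 1.0 / cfg.snr_b0
        signal = np.empty_like(clean)
        for bi, n_avg in enumerate(cfg.scheme.averages):
            signal[..., bi] = add_rician_noise(clean[..., bi], sigma,
                                               n_avg, rng)
        signal[~organ] = 0.0

    truth = ParamMaps.empty(shape, organ)
    truth.set_params(np.where(organ[None], fields, np.nan))
    if cfg.compute_adc_truth:
        # ADC ground truth is model-derived: the monoexponential fit to the
        # noiseless signal at the 4-b ADC subset
        adc_b = np.asarray(ADC_TRUTH_B)
        adc_sig = (f[..., None] * np.exp(-adc_b * Dstar[..., None])
                   + (1.0 - f[..., None])
                   * np.exp(-adc_b * D[..., None]
                            + (adc_b * D[..., None]) ** 2 * k[..., None] / 6.0))
        for ix, iy, iz in zip(*np.nonzero(organ)):
            truth.adc[ix, iy, iz] = fit_adc_voxel(adc_sig[ix, iy, iz], adc_b)[0]

    return PhantomCase(truth, signal, lesion, organ, cfg.lesion_class,
                       cfg.scheme)


def make_cohort(
    class_sizes: Mapping[str, int],
    base_cfg: PhantomConfig | None = None,
    seed: int = 0,
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate an independent seeded cohort plus its manifest.

    ``class_sizes`` maps class name → case count (e.g. the study cohort
    {"PDAC": 25, "pNET": 13, "MFCP": 6, "SPEN": 4}).
    """
    if sum(class_sizes.values()) == 0:
        raise ValueError("cohort must contain at least one case")
    base_cfg = base_cfg or PhantomConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(
        sum(class_sizes.values())
    ) % (2 ** 31)
    cases: list[PhantomCase] = []
    rows = []
    ci = 0
    for label, count in class_sizes.items():
        for j in range(count):
            cfg = replace(base_cfg, lesion_class=label,
                          seed=int(child_seeds[ci]))
            case = make_phantom(cfg)
            case.case_id = f"{label}_{j:03d}"
            cases.append(case)
            rows.append({"case_id": case.case_id, "label": label,
                         "lesion_volume_voxels": int(case.lesion_mask.sum())})
            ci += 1
    return cases, pd.DataFrame(rows)
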