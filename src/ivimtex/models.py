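"""Forward signal models for multi-b-value diffusion-weighted MRI.

The signal in a voxel acquired at diffusion weighting ``b`` (s/mm²) is
modelled on the normalized scale S/S0, either by a monoexponential decay
governed by the apparent diffusion coefficient (ADC), or by a hybrid
intravoxel-incoherent-motion + diffusion-kurtosis (IVIM-DKI) model

    S/S0 = f·exp(−b·D*) + (1−f)·exp(−b·D + (1/6)·b²·D²·k)

with true diffusion coefficient ``D`` (mm²/s), pseudo-diffusion
coefficient ``D*`` (mm²/s), perfusion fraction ``f`` and kurtosis ``k``.
All diffusivities are stored in mm²/s (never 10⁻³ mm²/s); any rescaling
for display happens in the reporting layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BValueScheme",
    "DiffusionParams",
    "FitBounds",
    "adc_signal",
    "ivim_dki_signal",
    "validate_params",
    "default_scheme",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
]

PARAM_NAMES = ("D", "Dstar", "f", "k")

# Fit box constraints: D in [0, 0.05] mm²/s, D* in [0, 0.5] mm²/s,
# f in [0, 1], k in [0, 3].
LOWER = np.array([0.0, 0.0, 0.0, 0.0])
UPPER = np.array([0.05, 0.5, 1.0, 3.0])
# Standard initialization: D = 1.3e-3 mm²/s, D* = 13e-3 mm²/s, f = 0.3, k = 0.7
INIT = np.array([1.3e-3, 13e-3, 0.3, 0.7])


@dataclass(frozen=True)
class DiffusionParams:
    """One voxel's IVIM-DKI parameter tuple (units: D, Dstar in mm²/s)."""

    D: float
    Dstar: float
    f: float
    k: float

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.Dstar, self.f, self.k], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "DiffusionParams":
        a = np.asarray(arr, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected 4 parameters, got shape {a.shape}")
        return cls(*a.tolist())


@dataclass(frozen=True)
class FitBounds:
    """Box constraints plus the fixed start point used by the voxel fits."""

    lower: DiffusionParams = field(
        default_factory=lambda: DiffusionParams.from_array(LOWER)
    )
    upper: DiffusionParams = field(
        default_factory=lambda: DiffusionParams.from_array(UPPER)
    )
    init: DiffusionParams = field(
        default_factory=lambda: DiffusionParams.from_array(INIT)
    )

    def __post_init__(self) -> None:
        lo, hi, x0 = (p.as_array() for p in (self.lower, self.upper, self.init))
        if not (np.all(lo <= x0) and np.all(x0 <= hi)):
            raise ValueError("init must lie within [lower, upper] componentwise")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.lower.as_array(), self.upper.as_array(), self.init.as_array()


DEFAULT_BOUNDS = FitBounds()
DEFAULT_INIT = DEFAULT_BOUNDS.init


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion weightings with the number of signal averages per b.

    The default pancreatic protocol acquires 14 b-values from 0 to
    2500 s/mm² with more averages at high b to offset the lower SNR.
    """

    b_values: tuple[float, ...]
    nsa: tuple[int, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        n = np.asarray(self.nsa)
        if b.size != n.size:
            raise ValueError(
                f"b_values ({b.size}) and nsa ({n.size}) must have equal length"
            )
        if b.size == 0 or b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if np.any(n < 1) or not np.issubdtype(n.dtype, np.integer):
            raise ValueError("nsa must be positive integers")

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def averages(self) -> np.ndarray:
        return np.asarray(self.nsa, dtype=int)

    def subset_indices(self, b_subset: Sequence[float]) -> np.ndarray:
        """Indices of ``b_subset`` within the scheme; error if any is absent."""
        idx = []
        for bv in b_subset:
            hits = np.nonzero(np.isclose(self.b, bv))[0]
            if hits.size == 0:
                raise ValueError(f"b={bv} not in scheme {self.b_values}")
            idx.append(int(hits[0]))
        return np.array(idx, dtype=int)

    @classmethod
    def from_file(cls, path: str | Path) -> "BValueScheme":
        """Load a scheme from two-column text (b, nsa) or a JSON file."""
        path = Path(path)
        text = path.read_text().strip()
        if text.startswith("{") or text.startswith("["):
            obj = json.loads(text)
            if isinstance(obj, dict):
                return cls(tuple(float(x) for x in obj["b_values"]),
                           tuple(int(x) for x in obj["nsa"]))
            rows = obj
        else:
            rows = [ln.split() for ln in text.splitlines()
                    if ln.strip() and not ln.lstrip().startswith("#")]
        b = tuple(float(r[0]) for r in rows)
        n = tuple(int(float(r[1])) for r in rows)
        return cls(b, n)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{b:g} {n:d}" for b, n in zip(self.b_values, self.nsa)]
        Path(path).write_text("\n".join(lines) + "\n")


def default_scheme() -> BValueScheme:
    """The packaged 14-b-value pancreatic acquisition scheme."""
    with resources.files("ivimtex.data").joinpath("bvalues_pancreas.txt").open() as fh:
        rows = [ln.split() for ln in fh if ln.strip() and not ln.startswith("#")]
    return BValueScheme(tuple(float(r[0]) for r in rows),
                        tuple(int(r[1]) for r in rows))


def adc_signal(adc: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Monoexponential signal ratio S/S0 = exp(−b·ADC).

    Parameters
    ----------
    adc : apparent diffusion coefficient in mm²/s (nonnegative).
    b : diffusion weighting in s/mm² (nonnegative).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    return np.exp(-b * np.asarray(adc, dtype=float))


def ivim_dki_signal(
    p: DiffusionParams | Sequence[float],
    b: float | np.ndarray,
    *,
    validate: bool = True,
    clip: bool = False,
    bounds: FitBounds = DEFAULT_BOUNDS,
) -> np.ndarray:
    """IVIM-DKI signal ratio S/S0 at weighting(s) ``b``.

    S/S0 = f·exp(−b·D*) + (1−f)·exp(−b·D + (1/6)·b²·D²·k).

    The kurtosis term makes the tissue exponent quadratic in b, so the
    model is evaluated exactly as written and is not forced monotone.
    With ``clip=True`` out-of-bounds parameters are clipped instead of
    raising.
    """
    arr = p.as_array() if isinstance(p, DiffusionParams) else np.asarray(p, float)
    if validate:
        lo, hi, _ = bounds.arrays()
        if np.any(arr < lo) or np.any(arr > hi):
            if clip:
                arr = np.clip(arr, lo, hi)
            else:
                bad = [PARAM_NAMES[i] for i in range(4)
                       if arr[i] < lo[i] or arr[i] > hi[i]]
                raise ValueError(f"parameters out of bounds: {', '.join(bad)}")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    D, Dstar, f, k = arr
    return f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D + (b * D) ** 2 * k / 6.0)


def validate_params(
    p: DiffusionParams, bounds: FitBounds = DEFAULT_BOUNDS
) -> tuple[bool, dict[str, tuple[float, float, float]], DiffusionParams]:
    """Check ``p`` against the fit box.

    Returns ``(ok, violations, clipped)`` where ``violations`` maps each
    offending parameter name to (value, lower, upper) and ``clipped`` is a
    copy projected onto the box.
    """
    lo, hi, _ = bounds.arrays()
    arr = p.as_array()
    violations = {
        PARAM_NAMES[i]: (float(arr[i]), float(lo[i]), float(hi[i]))
        for i in range(4)
        if arr[i] < lo[i] or arr[i] > hi[i]
    }
    clipped = DiffusionParams.from_array(np.clip(arr, lo, hi))
    return (len(violations) == 0), violations, clipped
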