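"""Whole-volume 3D texture analysis of parametric maps within an ROI.

The map is first normalized and quantized to ``Ng`` gray levels
(equal-frequency histogram equalization by default), then 30 features are
computed from four families, using 26-voxel connectivity (the 13 unique
3D offsets at Chebyshev distance 1):

* f1–f9    gray-level co-occurrence matrix (GLCM), one symmetric matrix
           merged over all 13 offsets;
* f10–f22  gray-level run-length matrix (GLRLM), merged over the 13
           directions, runs broken at the mask boundary;
* f23–f25  global statistics of the quantized intensities;
* f26–f30  neighborhood gray-tone difference matrix (NGTDM),
           Amadasun–King features.

Degenerate (constant-ROI) cases are mapped to documented finite values so
feature vectors can always be fed to a classifier: Entropy 0,
Correlation 0, skewness 0, kurtosis 0, and Coarseness capped at
``COARSENESS_CAP`` = 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "QuantizedROI",
    "TextureVector",
    "FEATURE_NAMES",
    "OFFSETS_13",
    "COARSENESS_CAP",
    "quantize_roi",
    "glcm_features",
    "glrlm_features",
    "ngtdm_features",
    "global_features",
    "texture_vector",
]

COARSENESS_CAP = 1e6

# The 13 unique offsets of 26-connectivity (one per +/- direction pair).
OFFSETS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(OFFSETS_13) == 13

GLCM_NAMES = ("Energy", "Contrast", "Entropy", "Homogeneity", "Correlation",
              "SumAverage", "Variance", "Dissimilarity", "AutoCorrelation")
GLRLM_NAMES = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
               "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV")
GLOBAL_NAMES = ("GlobalVariance", "GlobalSkewness", "GlobalKurtosis")
NGTDM_NAMES = ("Coarseness", "NGTDMContrast", "Busyness", "Complexity", "Strength")

#: Canonical feature order f1..f30.
FEATURE_NAMES = GLCM_NAMES + GLRLM_NAMES + GLOBAL_NAMES + NGTDM_NAMES
assert len(FEATURE_NAMES) == 30


@dataclass
class QuantizedROI:
    qvol: np.ndarray  # integer levels 1..Ng inside mask, 0 outside
    mask: np.ndarray
    Ng: int


@dataclass
class TextureVector:
    values: np.ndarray  # length 30, order FEATURE_NAMES
    source_map: str = ""

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(FEATURE_NAMES, self.values)}


def quantize_roi(
    map3d: np.ndarray,
    mask: np.ndarray,
    Ng: int = 64,
    method: str = "equalized",
) -> QuantizedROI:
    """Quantize the masked values of a map to gray levels 1..Ng.

    ``equalized`` bins by equal frequency (rank-based, stable tie-break by
    storage order), so the result — and every feature downstream — is
    invariant under strictly monotone intensity transforms. ``uniform``
    uses equal-width bins over [min, max]. A constant ROI maps to level 1.
    """
    if Ng < 2:
        raise ValueError("Ng must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(map3d, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("mask selects no voxels")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values inside mask")

    q = np.zeros(mask.shape, dtype=np.int32)
    if np.ptp(vals) == 0:
        q[mask] = 1
        return QuantizedROI(q, mask, Ng)

    if method == "equalized":
        order = np.argsort(vals, kind="stable")
        levels = np.empty(vals.size, dtype=np.int32)
        levels[order] = (np.arange(vals.size) * Ng) // vals.size + 1
    elif method == "uniform":
        lo, hi = vals.min(), vals.max()
        levels = np.minimum(
            ((vals - lo) / (hi - lo) * Ng).astype(np.int32) + 1, Ng
        )
    else:
        raise ValueError(f"unknown quantization method {method!r}")
    q[mask] = levels
    return QuantizedROI(q, mask, Ng)


def _shift_pairs(q: QuantizedROI, off: tuple[int, int, int]):
    """Level pairs (a, b) across one offset, both voxels masked."""
    sl_src, sl_dst = [], []
    for d in off:
        if d >= 0:
            sl_src.append(slice(0, q.qvol.shape[len(sl_src)] - d))
            sl_dst.append(slice(d, None))
        else:
            sl_src.append(slice(-d, None))
            sl_dst.append(slice(0, d))
    a = q.qvol[tuple(sl_src)]
    b = q.qvol[tuple(sl_dst)]
    m = q.mask[tuple(sl_src)] & q.mask[tuple(sl_dst)]
    return a[m], b[m]


def _glcm_matrix(q: QuantizedROI) -> np.ndarray:
    """Symmetric co-occurrence matrix merged over the 13 offsets, sum 1."""
    nmax = int(q.qvol.max())
    mat = np.zeros((nmax + 1, nmax + 1))
    for off in OFFSETS_13:
        a, b = _shift_pairs(q, off)
        np.add.at(mat, (a, b), 1.0)
        np.add.at(mat, (b, a), 1.0)
    mat = mat[1:, 1:]
    total = mat.sum()
    if total == 0:
        raise ValueError("no masked neighbor pair: GLCM undefined")
    return mat / total


def glcm_features(q: QuantizedROI) -> np.ndarray:
    """The nine Haralick-style GLCM features f1..f9."""
    p = _glcm_matrix(q)
    n = p.shape[0]
    i = np.arange(1, n + 1)[:, None]
    j = np.arange(1, n + 1)[None, :]
    pi = p.sum(axis=1)
    mu_i = float((i[:, 0] * pi).sum())
    sigma_i = float(np.sqrt(((i[:, 0] - mu_i) ** 2 * pi).sum()))
    # matrix is symmetric: marginals coincide
    mu_j, sigma_j = mu_i, sigma_i

    energy = float((p ** 2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    if sigma_i > 0:
        correlation = float((((i - mu_i) * (j - mu_j) * p).sum())
                            / (sigma_i * sigma_j))
    else:
        correlation = 0.0
    sum_average = float(0.5 * ((i + j) * p).sum())
    variance = float(0.5 * (((i - mu_i) ** 2 + (j - mu_j) ** 2) * p).sum())
    dissimilarity = float((np.abs(i - j) * p).sum())
    autocorrelation = float((i * j * p).sum())
    return np.array([energy, contrast, entropy, homogeneity, correlation,
                     sum_average, variance, dissimilarity, autocorrelation])


def _runs_in_direction(q: QuantizedROI, d: tuple[int, int, int]):
    """Yield (level, length) of every maximal run along direction d."""
    qv, mask = q.qvol, q.mask
    shape = qv.shape
    idx = np.nonzero(mask)
    for x, y, z in zip(*idx):
        # run start: predecessor along -d is outside mask/volume or differs
        px, py, pz = x - d[0], y - d[1], z - d[2]
        if (0 <= px < shape[0] and 0 <= py < shape[1] and 0 <= pz < shape[2]
                and mask[px, py, pz] and qv[px, py, pz] == qv[x, y, z]):
            continue
        level = int(qv[x, y, z])
        length = 1
        nx, ny, nz = x + d[0], y + d[1], z + d[2]
        while (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]
               and mask[nx, ny, nz] and qv[nx, ny, nz] == level):
            length += 1
            nx, ny, nz = nx + d[0], ny + d[1], nz + d[2]
        yield level, length


def _glrlm_matrix(q: QuantizedROI) -> np.ndarray:
    """Run-length counts r[level-1, length-1], merged over 13 directions."""
    nmax = int(q.qvol.max())
    longest = int(max(q.qvol.shape)) * 2  # diagonal runs cannot exceed this
    mat = np.zeros((nmax, longest))
    max_len = 1
    for d in OFFSETS_13:
        for level, length in _runs_in_direction(q, d):
            mat[level - 1, length - 1] += 1
            max_len = max(max_len, length)
    return mat[:, :max_len]


def glrlm_features(q: QuantizedROI) -> np.ndarray:
    """The thirteen run-length features f10..f22."""
    r = _glrlm_matrix(q)
    nr = r.sum()
    if nr == 0:
        raise ValueError("empty run-length matrix")
    g = np.arange(1, r.shape[0] + 1)[:, None].astype(float)
    l = np.arange(1, r.shape[1] + 1)[None, :].astype(float)

    sre = float((r / l ** 2).sum() / nr)
    lre = float((r * l ** 2).sum() / nr)
    gln = float((r.sum(axis=1) ** 2).sum() / nr)
    rln = float((r.sum(axis=0) ** 2).sum() / nr)
    rp = float(nr / (r * l).sum())
    lgre = float((r / g ** 2).sum() / nr)
    hgre = float((r * g ** 2).sum() / nr)
    srlge = float((r / (g ** 2 * l ** 2)).sum() / nr)
    srhge = float((r * g ** 2 / l ** 2).sum() / nr)
    lrlge = float((r * l ** 2 / g ** 2).sum() / nr)
    lrhge = float((r * g ** 2 * l ** 2).sum() / nr)
    p = r / nr
    mu_g = float((p * g).sum())
    glv = float((p * (g - mu_g) ** 2).sum())
    mu_l = float((p * l).sum())
    rlv = float((p * (l - mu_l) ** 2).sum())
    return np.array([sre, lre, gln, rln, rp, lgre, hgre,
                     srlge, srhge, lrlge, lrhge, glv, rlv])


def global_features(q: QuantizedROI) -> np.ndarray:
    """Variance (n−1), skewness (Fisher, biased) and kurtosis (Pearson)
    of the masked quantized intensities (f23..f25)."""
    vals = q.qvol[q.mask].astype(float)
    if vals.size < 2:
        raise ValueError("need >=2 masked voxels")
    var = float(np.var(vals, ddof=1))
    if np.ptp(vals) == 0:
        return np.array([0.0, 0.0, 0.0])
    skew = float(scipy.stats.skew(vals, bias=True))
    kurt = float(scipy.stats.kurtosis(vals, fisher=False, bias=True))
    return np.array([var, skew, kurt])


def _ngtdm(q: QuantizedROI):
    """Amadasun–King NGTDM: per-level probability p_i and coarseness sum s_i
    over masked voxels having at least one masked 26-neighbor."""
    qv = np.asarray(q.qvol, dtype=float)
    mask = q.mask
    nb_sum = np.zeros(mask.shape)
    nb_cnt = np.zeros(mask.shape)
    for off in OFFSETS_13:
        for sign in (1, -1):
            d = tuple(sign * o for o in off)
            sl_src, sl_dst = [], []
            for ax, dd in enumerate(d):
                if dd >= 0:
                    sl_src.append(slice(0, mask.shape[ax] - dd))
                    sl_dst.append(slice(dd, None))
                else:
                    sl_src.append(slice(-dd, None))
                    sl_dst.append(slice(0, dd))
            src, dst = tuple(sl_src), tuple(sl_dst)
            both = mask[src] & mask[dst]
            add = np.zeros(mask.shape)
            add[src] = np.where(both, qv[dst], 0.0)
            nb_sum += add
            cnt = np.zeros(mask.shape)
            cnt[src] = both
            nb_cnt += cnt

    valid = mask & (nb_cnt > 0)
    levels = np.arange(1, int(q.qvol.max()) + 1)
    n_valid = int(valid.sum())
    p = np.zeros(levels.size)
    s = np.zeros(levels.size)
    abar = np.zeros(mask.shape)
    abar[valid] = nb_sum[valid] / nb_cnt[valid]
    for idx, lev in enumerate(levels):
        sel = valid & (q.qvol == lev)
        p[idx] = sel.sum() / max(n_valid, 1)
        s[idx] = float(np.abs(lev - abar[sel]).sum())
    return levels.astype(float), p, s, n_valid


def ngtdm_features(q: QuantizedROI) -> np.ndarray:
    """Amadasun–King Coarseness, Contrast, Busyness, Complexity, Strength
    (f26..f30)."""
    i, p, s, n = _ngtdm(q)
    nz = p > 0
    ngp = int(nz.sum())

    denom = float((p * s).sum())
    coarseness = min(1.0 / denom, COARSENESS_CAP) if denom > 0 else COARSENESS_CAP

    if ngp > 1 and n > 0:
        pij = p[nz][:, None] * p[nz][None, :]
        dij2 = (i[nz][:, None] - i[nz][None, :]) ** 2
        contrast = float((pij * dij2).sum() / (ngp * (ngp - 1)) * s.sum() / n)
    else:
        contrast = 0.0

    ipi = i[nz] * p[nz]
    busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = denom / busy_den if busy_den > 0 else 0.0

    complexity = 0.0
    strength_num = 0.0
    if ngp > 1 and n > 0:
        iv, pv, sv = i[nz], p[nz], s[nz]
        dij = np.abs(iv[:, None] - iv[None, :])
        complexity = float(
            (dij * (pv[:, None] * sv[:, None] + pv[None, :] * sv[None, :])
             / (n * (pv[:, None] + pv[None, :]))).sum()
        )
        strength_num = float(
            ((pv[:, None] + pv[None, :]) * (iv[:, None] - iv[None, :]) ** 2).sum()
        )
    s_sum = float(s.sum())
    strength = strength_num / s_sum if s_sum > 0 else 0.0
    return np.array([coarseness, contrast, busyness, complexity, strength])


def texture_vector(
    map3d: np.ndarray,
    mask: np.ndarray,
    Ng: int = 64,
    method: str = "equalized",
    source_map: str = "",
) -> TextureVector:
    """Quantize a masked map and compute the canonical 30-feature vector."""
    q = quantize_roi(map3d, mask, Ng=Ng, method=method)
    vec = np.concatenate([
        glcm_features(q),
        glrlm_features(q),
        global_features(q),
        ngtdm_features(q),
    ])
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[ix] for ix in np.nonzero(~np.isfinite(vec))[0]]
        raise AssertionError(f"non-finite texture features: {bad}")
    return TextureVector(vec, source_map=source_map)
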